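# Methods

## Network model and input handling

A network is a simple undirected graph over gene symbols with an optional
per-edge confidence in [0, 1]. Input edge tables may be plain TSV, STRING
exports (integer scores on a 0–1000 scale are divided by 1000; in the plain
TSV dialect any score above 1 triggers the same rescaling, since the two
conventions are otherwise indistinguishable), or SIF. Self-interactions are
dropped; duplicate pairs collapse keeping the maximum score, which matches
STRING's one-combined-score-per-pair convention. Gene symbols are uppercased
on read by default because public tables mix spellings of the same HGNC
symbol (for example C1orf56/C1ORF56); the packaged fixtures retain the
as-printed spelling in a side column. The confidence threshold defaults to
0.4, STRING's medium-confidence default. All downstream stages treat the
graph as binary: confidences gate edge inclusion and play no further role.

Analysis is restricted to the main connected component, the standard choice
for centrality-based prioritization since closeness and betweenness are only
comparable within one component. Ties for the largest component break toward
the component containing the lexicographically smallest gene, purely for
determinism.

## Centrality indices

Four indices are computed natively, with conventions chosen to match
Cytoscape's NetworkAnalyzer output scales (the tool used to produce the
reference tables):

- **degree** — raw incident-edge count;
- **betweenness** — Σ over unordered pairs {s,t} (s≠t≠v) of
  σ_st(v)/σ_st, normalized by (n−1)(n−2)/2 so values lie in [0, 1];
- **closeness** — (n_c−1)/Σ_u d(v,u), the reciprocal mean distance within
  v's component (0 for singletons), not the harmonic variant;
- **stress** — Σ σ_st(v) over *ordered* pairs, i.e. the raw number of
  shortest paths through v; on an undirected graph every unordered pair
  contributes twice, so stress is always even. The reference tables' 18
  printed stress values are all even, which is what pinned this convention.

Betweenness and stress share one Brandes dependency-accumulation pass per
source (O(|V||E|)); stress uses the path-count variant of the accumulation
(δ(v) = Σ_{w: v∈P(w)} σ_sv(1 + δ(w)/σ_sw)). Closeness reuses the same BFS
distances. Nodes are iterated in lexicographic order throughout, so all
outputs are bit-stable across runs. At the 63-node scale of the motivating
data no approximation is needed.

Components with fewer than three nodes get zero betweenness and stress
(no mediated pairs exist).

## Rank sets and panel selection

For each index the top k = max(1, ⌊q·n⌋) genes form a rank set, with
q = 0.2 by default; at n = 63 this gives the 12-gene sets of the reference
tables. Ties at the cutoff break lexicographically by default — the source
analysis is silent on ties and a deterministic rule is required for testing —
with an opt-in keep-ties mode that returns every gene tied with the k-th
value.

A gene is *important* if it satisfies any of the five criteria listed in the
README. Criteria 2–4 are subsets of criterion 5, so the important set always
equals (H∩B) ∪ ((H∪B)∩(C∪S)); all five are still evaluated and recorded per
gene because the per-criterion labels are part of the reported output.

The *exclusion rule* is set-based: important genes in B∩S but in neither H
nor C are removed. The alternative reading — excluding genes with visibly
poor connectivity inside the important-gene subnetwork — is unquantified, so
it is provided only as a diagnostic (`subnetwork_report`, flagging genes
whose within-subnetwork degree falls below 2 by default). On the reference
tables the set rule removes exactly six genes (FKBP5, ADCYAP1, PIN1,
C1ORF56, OGN, CCAR1); the source prose counts six excluded genes but names
only five, and ADCYAP1 is the unique other important gene matching the
stated rule and absent from the final panel.

## Enrichment

Over-representation of a query against a GMT annotation uses the right tail
of the hypergeometric distribution, P(X ≥ k) for X ~ Hypergeom(N, K, n),
evaluated via scipy's log-space survival function. The background defaults
to the union of annotation genes; an explicit background (for example the
analyzed network's node list) can be supplied — both conventions are common
and the choice materially changes p-values, so it is surfaced rather than
hidden. Only terms overlapping the query are tested and corrected.

Correction defaults to Holm's step-down procedure (a family-wise-error
control mirroring the ClueGO default) at α = 0.01, with Bonferroni and
Benjamini–Hochberg as options; adjustment is delegated to
statsmodels.stats.multitest behind the package's own surface.

Significant terms are grouped by Cohen's kappa between their gene-membership
indicator vectors over the background: pairs with κ ≥ 0.4 (the conventional
grouping default; exposed as a flag) are merged by single linkage, and each
group is labeled by its lowest-adjusted-p member. Degenerate contingency
tables (expected agreement 1) define κ as 1 for identical memberships and 0
otherwise.

## Synthetic data

The motivating study never deposited its edge list, so its network-level
quantities are irrecoverable; the packaged fixtures carry its printed tables
verbatim (checksummed at load), and synthetic generators stand in for the
network wherever computation is exercised:

- **preferential attachment** (default, n = 63, m = 2): starts from m
  isolated nodes; each arriving node attaches to m distinct existing nodes
  with probability proportional to degree (+1 smoothing), giving a connected
  graph with exactly m(n−m) = 122 edges and a heavy-tailed degree
  distribution. This matches the reference component's size; its hubs are
  milder than the real component's (max degree ≈ 18 versus 32) because the
  real network is denser.
- **Erdős–Rényi** (p defaulting to 0.0624, which matches the
  preferential-attachment edge count at n = 63) serves as the light-tailed
  contrast for tail-heaviness checks.
- **planted-hub**: a chosen number of hubs (5 by default) are each wired to
  a uniform 40–60% of all nodes, giving degrees in the 25–37 range typical
  of the reference hubs; recovery of the planted hubs by the degree rank set
  is the ground-truth check for the prioritization path.
- **annotations**: decoy terms draw sizes uniformly from a requested range
  (5–30 over a 500-gene background by default) and members uniformly; an
  optional planted term is forced to share an exact overlap with a
  designated query (10 of 12 by default in the validation runs — a strong
  but not saturated signal).

Every generator is a pure function of its configuration and seed. What
passing tests on these synthetics show is that the machinery is correct and
calibrated (exact set algebra, oracle-identical centralities, ≥95%
planted-signal recovery, family-wise type-I error ≤ α); they do not show
that the biological panel generalizes, since real PPI networks have
confidence-correlated, ascertainment-biased edges that no generator here
emulates.

## Numerical and design choices

- Shortest-path work is exact integer/BFS arithmetic; the only floating
  arithmetic is the betweenness fraction accumulation, and oracle tests
  require agreement to 1e-12.
- Problem sizes in the test and validation runs (graphs ≤ 7 nodes for
  brute-force path enumeration, 63-node synthetics, 200 power and 500 null
  replicates) were chosen so each property is measured with comfortable
  binomial resolution while the whole suite stays interactive.
- The published GO cluster counts depend on an unversioned annotation
  snapshot and ClueGO internals; the enrichment stage is therefore validated
  on synthetic annotations only, and the packaged regulation directions in
  the panel table are literature metadata, never computed. Direction entries
  are "na" where the source prose states no direction (the original encodes
  them as table colors, which plain-text extraction loses).
- Pipeline runs write a JSON manifest (tool version, full configuration and
  its hash, input checksum, summary counts); re-running with the manifest's
  configuration regenerates every output byte-for-byte.

## Known limitations

- The exclusion rule is exact for the reference tables but is one reading of
  a verbally stated procedure; the subnetwork-degree diagnostic is provided
  to probe the alternative reading.
- Centralities are unweighted; confidence-weighted shortest paths are out of
  scope, as are eigenvector/PageRank-style indices.
- The enrichment stage tests terms independently; no term-hierarchy
  propagation or GO OBO parsing is attempted.
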