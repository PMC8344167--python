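# netprior

Gene prioritization on protein–protein interaction (PPI) networks, built
around the hub/bottleneck selection scheme used in disease biomarker-panel
studies, with posttraumatic stress disorder (PTSD) as the worked case.

Given an undirected PPI network (a STRING-style edge table thresholded at a
confidence score, default 0.4), the pipeline

1. restricts to the main connected component;
2. computes four node centralities — degree, betweenness, closeness and
   stress — with native Brandes-style dependency accumulation;
3. takes the top 20% of genes by each index, giving the hub set *H*
   (degree), bottleneck set *B* (betweenness), and the closeness and stress
   sets *C* and *S*;
4. calls a gene **important** if it satisfies at least one of
   (1) H∩B, (2) H∩B∩C∩S, (3) H∩C∩S, (4) B∩C∩S, (5) (H∪B)∩(C∪S);
5. **excludes** important genes in B∩S that are in neither H nor C (these
   are the peripherally connected bottleneck/stress genes); the remainder is
   the **crucial panel**;
6. optionally tests the panel for gene-set over-representation with a
   right-tailed hypergeometric test against a GMT annotation, Holm
   correction (α = 0.01 by default), and kappa-score grouping of redundant
   significant terms (κ ≥ 0.4, single linkage).

Conventions match Cytoscape's NetworkAnalyzer: betweenness is normalized by
(n−1)(n−2)/2; closeness is the reciprocal mean shortest-path distance;
stress is the raw count of shortest paths through a node over ordered source–
target pairs (hence always even on an undirected graph).

The original study's edge list was never deposited, so its published rank
tables ship inside the package as fixtures (the four top-20% membership
lists, the 18 important genes with printed centralities, and the 12-gene
panel with literature-derived regulation directions), and the package
includes seeded synthetic-network and synthetic-annotation generators so
every stage is testable without downloads.

## Worked example

Reproduce the published panel from the packaged rank lists:

```sh
python analysis/01_reproduce_panel.py
```

prints

```
rank sets: |H|=12 |B|=12 |C|=12 |S|=12
important genes (18): ADCYAP1, BDNF, C1ORF56, CCAR1, CREB1, CRH, CRHR1, FKBP5, FOS, HTR1A, IL6, NPS, NPY, NR3C1, OGN, PIN1, POMC, TAC1
excluded (6): ADCYAP1, C1ORF56, CCAR1, FKBP5, OGN, PIN1
crucial panel (12): BDNF, CREB1, CRH, CRHR1, FOS, HTR1A, IL6, NPS, NPY, NR3C1, POMC, TAC1
crucial panel matches the published 12-gene panel: True
```

The five criteria select 18 of the 24 genes appearing in any top-20% list;
the exclusion rule removes the six genes that rank high on betweenness and
stress but are neither hubs nor central by closeness, leaving the 12-gene
biomarker-candidate panel.

The same run is available as a command:

```sh
netprior prioritize src/netprior/data/table1.tsv --mode sets
```

Analysing a network from scratch (here a synthetic 63-node stand-in):

```sh
netprior simulate --n-nodes 63 --seed 1 --out edges.tsv
netprior centrality edges.tsv --threshold 0 --out centrality.tsv
netprior prioritize edges.tsv --threshold 0
```

`analysis/02_synthetic_network_centrality.py` and
`analysis/03_enrichment_validation.py` exercise the centrality and
enrichment stages on networks and annotations with known ground truth; on
the current seeds they report 100% planted-hub recovery (40/40 seeds),
100% planted-term recovery (200 replicates) and a family-wise type-I error
of 0.010 at α = 0.01 (500 replicates).

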