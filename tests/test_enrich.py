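import random

import numpy as np
import pytest

from netprior import (
    AnnotationSet,
    adjust_pvalues,
    cohens_kappa,
    enrich,
    generate_annotation,
    hypergeom_pvalue,
    kappa_group,
)

from oracles import brute_kappa, hypergeom_tail, naive_bh, naive_bonferroni, naive_holm


def make_annotation(terms: dict[str, set[str]], background=None) -> AnnotationSet:
    bg = background or set().union(*terms.values())
    return AnnotationSet(
        terms={t: (t, frozenset(g)) for t, g in terms.items()},
        background=frozenset(bg),
    )


class TestHypergeom:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_pvalue(0, 12, 5, 63) == 1.0

    def test_forced_full_overlap_gives_one(self):
        assert hypergeom_pvalue(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_combinatorial_summation(self):
        assert hypergeom_pvalue(4, 12, 5, 63) == pytest.approx(
            hypergeom_tail(4, 12, 5, 63), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_oracle_on_random_counts(self, seed):
        rng = random.Random(seed)
        for _ in range(20):
            N = rng.randrange(10, 200)
            K = rng.randrange(1, N + 1)
            n = rng.randrange(1, N + 1)
            k = rng.randrange(0, min(K, n) + 1)
            assert hypergeom_pvalue(k, n, K, N) == pytest.approx(
                hypergeom_tail(k, n, K, N), rel=1e-9, abs=1e-300
            )

    @pytest.mark.parametrize("k,n,K,N", [(6, 5, 10, 100), (3, 5, 2, 100), (1, 5, 10, 8)])
    def test_inconsistent_counts_rejected(self, k, n, K, N):
        with pytest.raises(ValueError):
            hypergeom_pvalue(k, n, K, N)


class TestAdjustPvalues:
    def test_single_test_unchanged(self):
        for method in ("holm", "bonferroni", "benjamini-hochberg"):
            assert adjust_pvalues([0.01], method) == [pytest.approx(0.01)]

    def test_bonferroni_closed_form(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bonferroni") == pytest.approx(
            [0.03, 0.06, 0.09]
        )

    @pytest.mark.parametrize("method,oracle", [
        ("holm", naive_holm),
        ("bonferroni", naive_bonferroni),
        ("benjamini-hochberg", naive_bh),
    ])
    def test_matches_naive_oracle_on_random_vectors(self, method, oracle):
        rng = random.Random(hash(method) % 2**31)
        for _ in range(20):
            p = [rng.random() for _ in range(rng.randrange(1, 40))]
            got = adjust_pvalues(p, method)
            assert got == pytest.approx(oracle(p), abs=1e-12)
            assert all(g >= x for g, x in zip(got, p))  # adjusted >= raw
            assert all(0 <= g <= 1 for g in got)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])


class TestEnrich:
    def test_disjoint_query_yields_empty_result(self):
        ann = make_annotation({"T1": {"A", "B"}, "T2": {"C"}}, background={"A", "B", "C", "X"})
        assert enrich({"X"}, ann) == []

    def test_planted_term_detected(self):
        genes = [f"G{i}" for i in range(200)]
        query = frozenset(genes[:10])
        ann = generate_annotation(genes, n_terms=20, size_range=(5, 20),
                                  planted=(query, 8, 12), seed=4)
        terms = enrich(query, ann, alpha=0.01)
        assert terms[0].term_id == "PLANTED"
        assert terms[0].significant
        assert terms[0].k == 8 and terms[0].K == 12

    def test_query_outside_background_restricted_with_warning(self):
        ann = make_annotation({"T1": {"A", "B", "C"}}, background={"A", "B", "C", "D"})
        with pytest.warns(UserWarning):
            terms = enrich({"A", "B", "ZZZ"}, ann)
        assert terms[0].n == 2

    def test_sorted_by_adjusted_p_then_id(self):
        genes = [f"G{i}" for i in range(100)]
        ann = generate_annotation(genes, n_terms=30, size_range=(5, 20), seed=1)
        terms = enrich(frozenset(genes[:15]), ann, alpha=0.5, method="benjamini-hochberg")
        keys = [(t.p_adj, t.term_id) for t in terms]
        assert keys == sorted(keys)
        for t in terms:
            assert t.p_adj >= t.p_raw
            assert t.significant == (t.p_adj <= 0.5)

    def test_permutation_invariance(self):
        rng = random.Random(5)
        genes = [f"G{i}" for i in range(80)]
        ann = generate_annotation(genes, n_terms=15, size_range=(5, 15), seed=9)
        query = genes[:12]
        base = enrich(frozenset(query), ann)
        shuffled_terms = dict(ann.terms.items())
        keys = list(shuffled_terms)
        rng.shuffle(keys)
        ann2 = AnnotationSet(terms={k: shuffled_terms[k] for k in keys},
                             background=ann.background)
        rng.shuffle(query)
        again = enrich(frozenset(query), ann2)
        assert [(t.term_id, t.p_raw, t.p_adj) for t in base] == [
            (t.term_id, t.p_raw, t.p_adj) for t in again
        ]

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            enrich({"A"}, AnnotationSet(terms={}, background=frozenset({"A"})))


class TestKappaGrouping:
    def test_identical_terms_form_one_group(self):
        ann = make_annotation({"T1": {"A", "B", "C"}, "T2": {"A", "B", "C"}},
                              background={f"G{i}" for i in range(50)} | {"A", "B", "C"})
        terms = enrich({"A", "B", "C"}, ann, alpha=1.0)
        groups = kappa_group(terms, ann)
        assert groups["T1"] == groups["T2"]

    def test_disjoint_terms_form_separate_groups(self):
        bg = {f"G{i}" for i in range(100)}
        ann = make_annotation({"T1": {"G1", "G2", "G3"}, "T2": {"G10", "G11", "G12"}},
                              background=bg)
        terms = enrich({"G1", "G2", "G3", "G10", "G11", "G12"}, ann, alpha=1.0)
        groups = kappa_group(terms, ann)
        assert groups["T1"] != groups["T2"]
        assert abs(cohens_kappa(0, 3, 3, 94)) < 0.05

    def test_kappa_closed_form(self):
        # a=8 both, b=2, c=2 single, d=88 neither
        po = (8 + 88) / 100
        pe = ((8 + 2) * (8 + 2) + (2 + 88) * (2 + 88)) / 100**2
        assert cohens_kappa(8, 2, 2, 88) == pytest.approx((po - pe) / (1 - pe))

    def test_kappa_matches_membership_oracle(self):
        rng = random.Random(11)
        bg = [f"G{i}" for i in range(60)]
        for _ in range(20):
            s1 = set(rng.sample(bg, rng.randrange(1, 30)))
            s2 = set(rng.sample(bg, rng.randrange(1, 30)))
            a = len(s1 & s2)
            b = len(s1 - s2)
            c = len(s2 - s1)
            d = 60 - a - b - c
            assert cohens_kappa(a, b, c, d) == pytest.approx(brute_kappa(s1, s2, bg))

    def test_group_labels_partition_significant_terms(self):
        genes = [f"G{i}" for i in range(150)]
        query = frozenset(genes[:12])
        ann = generate_annotation(genes, n_terms=25, size_range=(5, 20),
                                  planted=(query, 9, 14), seed=3)
        terms = enrich(query, ann, alpha=0.9)
        groups = kappa_group(terms, ann, threshold=0.4)
        sig_ids = {t.term_id for t in terms if t.significant}
        assert set(groups) == sig_ids
        for t in terms:
            assert (t.group is not None) == t.significant


class TestCalibration:
    """Statistical behaviour of the enrichment stage on synthetic annotations."""

    def test_planted_term_power(self):
        # planted term: 10 of 12 query genes, size 15, background 500, 50 decoys
        genes = [f"G{i:03d}" for i in range(500)]
        hits = 0
        n_rep = 60
        rng = np.random.default_rng(2)
        for _ in range(n_rep):
            seed = int(rng.integers(2**31))
            query = frozenset(f"G{i:03d}" for i in
                              np.random.default_rng(seed + 1).choice(500, 12, replace=False))
            ann = generate_annotation(genes, n_terms=50, size_range=(5, 30),
                                      planted=(query, 10, 15), seed=seed)
            terms = enrich(query, ann, alpha=0.01)
            if terms and terms[0].term_id == "PLANTED" and terms[0].significant:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_type_i_error_controlled_under_null(self):
        genes = [f"G{i:03d}" for i in range(500)]
        alpha = 0.01
        n_rep = 150
        false_hits = 0
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            seed = int(rng.integers(2**31))
            query = frozenset(f"G{i:03d}" for i in
                              np.random.default_rng(seed).choice(500, 12, replace=False))
            ann = generate_annotation(genes, n_terms=50, size_range=(5, 30), seed=seed + 1)
            terms = enrich(query, ann, alpha=alpha)
            if any(t.significant for t in terms):
                false_hits += 1
        rate = false_hits / n_rep
        se = (alpha * (1 - alpha) / n_rep) ** 0.5
        assert rate <= alpha + 2 * se
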