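"""Enrichment score, permutation NES/FDR, and signature scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secsig import (
    AnalysisError,
    EnrichmentConfig,
    GeneSet,
    NormalizedExpression,
    RankedList,
    average_cpm_score,
    compare_scores,
    enrichment_score,
    gsea_preranked,
)


def ks_oracle(n: int, hit_positions: set[int]) -> float:
    """Independent closed-form KS statistic on hit positions (p = 0 case).

    For every prefix of the ranked list compute (fraction of hits seen) -
    (fraction of misses seen) and return the value of largest magnitude.
    """
    n_hits = len(hit_positions)
    n_miss = n - n_hits
    best = 0.0
    hits_seen = 0
    for i in range(n):
        if i in hit_positions:
            hits_seen += 1
        dev = hits_seen / n_hits - (i + 1 - hits_seen) / n_miss
        if abs(dev) > abs(best):
            best = dev
    return best


def _ranking(metrics, genes=None) -> RankedList:
    genes = genes or [f"g{i}" for i in range(len(metrics))]
    return RankedList(genes=genes, metrics=np.asarray(metrics, dtype=float))


class TestEnrichmentScore:
    def test_hand_enumerated_running_sum(self):
        r = _ranking([3, 2, 1, -1, -2])
        res = enrichment_score(r, GeneSet("top", frozenset({"g0"})), p=1)
        assert np.allclose(res.running_sum, [1.0, 0.75, 0.5, 0.25, 0.0])
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g0"]

    def test_bottom_set_negative_score(self):
        r = _ranking([5, 4, 3, 2, 1])
        res = enrichment_score(r, GeneSet("bottom", frozenset({"g4"})), p=1)
        assert res.es < 0
        assert res.leading_edge == ["g4"]

    def test_p0_matches_ks_oracle_small_exhaustive(self):
        for n in (4, 6):
            r = _ranking(np.linspace(3, -3, n))
            for k in (1, 2):
                for subset in itertools.combinations(range(n), k):
                    s = GeneSet("s", frozenset(f"g{i}" for i in subset))
                    es = enrichment_score(r, s, p=0).es
                    assert es == pytest.approx(ks_oracle(n, set(subset)), abs=1e-12)

    def test_weighted_es_matches_independent_reference_implementation(self):
        """The weighted (p=1) score agrees with an independent preranked
        GSEA implementation on a random fixture."""
        import gseapy

        rng = np.random.default_rng(0)
        n = 200
        metrics = np.sort(rng.normal(0, 1, n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        sets = {
            "top_heavy": [genes[i] for i in rng.choice(60, 20, replace=False)],
            "random": [genes[i] for i in rng.choice(n, 20, replace=False)],
        }
        ref = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": metrics}),
            gene_sets=sets,
            permutation_num=10,
            outdir=None,
            seed=1,
            no_plot=True,
            min_size=1,
            max_size=500,
            weight=1.0,
        ).res2d.set_index("Term")["ES"]
        r = _ranking(metrics, genes)
        for name, members in sets.items():
            mine = enrichment_score(r, GeneSet(name, frozenset(members)), p=1).es
            assert mine == pytest.approx(float(ref[name]), abs=1e-9)

    def test_set_covering_universe_errors(self):
        r = _ranking([2, 1])
        with pytest.raises(AnalysisError):
            enrichment_score(r, GeneSet("all", frozenset({"g0", "g1"})), p=1)

    def test_no_overlap_errors(self):
        r = _ranking([2, 1])
        with pytest.raises(AnalysisError):
            enrichment_score(r, GeneSet("none", frozenset({"x"})), p=1)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        n=st.integers(3, 40),
        data=st.data(),
    )
    def test_es_bounded_and_monotone_invariant_at_p0(self, n, data):
        metrics = np.sort(data.draw(st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=n, max_size=n
        )))[::-1]
        k = data.draw(st.integers(1, n - 1))
        subset = data.draw(
            st.sets(st.integers(0, n - 1), min_size=k, max_size=k)
        )
        r = _ranking(metrics)
        s = GeneSet("s", frozenset(f"g{i}" for i in subset))
        es = enrichment_score(r, s, p=0).es
        assert -1.0 <= es <= 1.0
        # strictly monotone rescaling of metrics cannot change the p=0 score
        rescaled = _ranking(np.asarray(metrics) * 3.0 + 7.0)
        assert enrichment_score(rescaled, s, p=0).es == pytest.approx(es)


class TestPermutationGsea:
    def _planted_ranking(self, rng, n=500, top=50, k=20):
        metrics = np.sort(rng.normal(0, 1, n))[::-1]
        hit_pos = rng.choice(top, size=k, replace=False)
        genes = [f"g{i}" for i in range(n)]
        return _ranking(metrics, genes), GeneSet("planted", frozenset(genes[i] for i in hit_pos))

    def test_planted_set_enriched(self):
        rng = np.random.default_rng(0)
        r, s = self._planted_ranking(rng)
        (res,) = gsea_preranked(r, [s], EnrichmentConfig(n_perm=200, seed=0))
        assert res.nes > 0 and res.fdr_q <= 0.25

    def test_same_seed_identical_results(self):
        rng = np.random.default_rng(1)
        r, s = self._planted_ranking(rng)
        null = GeneSet("null", frozenset(f"g{i}" for i in rng.choice(len(r), 30, replace=False)))
        a = gsea_preranked(r, [s, null], EnrichmentConfig(n_perm=100, seed=5))
        b = gsea_preranked(r, [s, null], EnrichmentConfig(n_perm=100, seed=5))
        assert [(x.es, x.nes, x.fdr_q) for x in a] == [(x.es, x.nes, x.fdr_q) for x in b]

    def test_result_order_independent_of_set_order(self):
        rng = np.random.default_rng(2)
        r, s = self._planted_ranking(rng)
        null = GeneSet("null", frozenset(f"g{i}" for i in rng.choice(len(r), 30, replace=False)))
        ab = gsea_preranked(r, [s, null], EnrichmentConfig(n_perm=100, seed=5))
        # ES of a set does not depend on which other sets are evaluated
        (alone,) = gsea_preranked(r, [s], EnrichmentConfig(n_perm=100, seed=5))
        assert ab[0].es == pytest.approx(alone.es)

    def test_zero_overlap_flagged_not_scored(self):
        r = _ranking([3, 2, 1, -1])
        ok = GeneSet("ok", frozenset({"g0"}))
        missing = GeneSet("missing", frozenset({"zzz"}))
        res = gsea_preranked(r, [ok, missing], EnrichmentConfig(n_perm=50, seed=0))
        assert res[1].no_overlap and np.isnan(res[1].fdr_q)
        assert not res[0].no_overlap

    def test_q_monotone_in_nes_within_sign(self):
        rng = np.random.default_rng(3)
        n = 400
        metrics = np.sort(rng.normal(0, 1, n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        r = _ranking(metrics, genes)
        sets = []
        for j, top in enumerate((30, 60, 120, 240, 400)):
            idx = rng.choice(min(top, n), size=15, replace=False)
            sets.append(GeneSet(f"s{j}", frozenset(genes[i] for i in idx)))
        res = gsea_preranked(r, sets, EnrichmentConfig(n_perm=100, seed=7))
        pos = sorted([x for x in res if x.nes > 0], key=lambda x: -x.nes)
        assert all(a.fdr_q <= b.fdr_q for a, b in zip(pos, pos[1:]))


def _norm(cpm: dict, conditions: dict) -> NormalizedExpression:
    df = pd.DataFrame(cpm)
    return NormalizedExpression(
        cpm=df,
        uq_factors=pd.Series(1.0, index=df.columns),
        library_sizes=pd.Series(1e6, index=df.columns),
        condition_of=pd.Series(conditions),
    )


class TestScoring:
    def test_singleton_set_is_the_gene_itself(self):
        e = _norm({"a": [10.0, 99.0]}, {"a": "P"})
        e.cpm.index = ["g1", "g2"]
        res = average_cpm_score(e, GeneSet("s", frozenset({"g1"})))
        assert res.scores["a"] == pytest.approx(10.0)

    def test_two_gene_mean(self):
        e = _norm({"a": [10.0, 30.0]}, {"a": "P"})
        e.cpm.index = ["g1", "g2"]
        res = average_cpm_score(e, GeneSet("s", frozenset({"g1", "g2"})))
        assert res.scores["a"] == pytest.approx(20.0)

    def test_missing_genes_reported(self):
        e = _norm({"a": [10.0]}, {"a": "P"})
        e.cpm.index = ["g1"]
        res = average_cpm_score(e, GeneSet("s", frozenset({"g1", "gone"})))
        assert res.missing_genes == ["gone"]

    def test_zero_overlap_errors(self):
        e = _norm({"a": [10.0]}, {"a": "P"})
        with pytest.raises(AnalysisError):
            average_cpm_score(e, GeneSet("s", frozenset({"nope"})))

    def test_sample_permutation_equivariance(self, normalized, small_config):
        s = GeneSet("planted", frozenset(small_config.planted_genes))
        res = average_cpm_score(normalized, s)
        shuffled = NormalizedExpression(
            cpm=normalized.cpm.iloc[:, ::-1],
            uq_factors=normalized.uq_factors.iloc[::-1],
            library_sizes=normalized.library_sizes.iloc[::-1],
            condition_of=normalized.condition_of.iloc[::-1],
        )
        res2 = average_cpm_score(shuffled, s)
        pd.testing.assert_series_equal(res.scores.sort_index(), res2.scores.sort_index())


class TestCompareScores:
    def test_identical_groups(self):
        diff, p = compare_scores([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert diff == 0.0 and p == pytest.approx(1.0)

    def test_separated_groups(self):
        diff, p = compare_scores([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert diff == pytest.approx(-10.0)
        assert p < 0.01

    def test_swap_flips_difference_not_p(self):
        d1, p1 = compare_scores([1.0, 2.0, 3.0], [4.0, 6.0, 8.0])
        d2, p2 = compare_scores([4.0, 6.0, 8.0], [1.0, 2.0, 3.0])
        assert d1 == pytest.approx(-d2) and p1 == pytest.approx(p2)

    def test_single_sample_returns_difference_only(self):
        diff, p = compare_scores([5.0], [1.0, 2.0])
        assert diff == pytest.approx(3.5) and p is None

    def test_zero_variance_equal_means_p_one(self):
        diff, p = compare_scores([2.0, 2.0], [2.0, 2.0])
        assert diff == 0.0 and p == 1.0
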