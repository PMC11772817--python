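"""Preranked gene-set enrichment and signature scoring.

The enrichment score (ES) is the weighted Kolmogorov-Smirnov-style running
sum: walking down the ranked list, hits increment by |metric|^p normalized
over the set's hits and misses decrement by 1/(N - N_hits); the ES is the
running-sum value of maximal absolute deviation.  With weight exponent
p = 0 this reduces to the classical KS statistic on hit positions.

Significance uses gene-set permutation: null ES values come from random
same-size gene sets drawn without replacement from the ranked universe,
each gene set using its own RNG stream derived from (seed, set index) so
results do not depend on evaluation order.  NES divides ES by the mean
|null ES| of matching sign; the FDR q-value is the sign-stratified
ratio-of-tails estimator over pooled null and observed NES, clipped to
[0, 1] and made weakly monotone in |NES| within each sign stratum.

Signature scoring is deliberately simple: the arithmetic mean CPM of the
set genes per sample, compared across conditions with a Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError
from .expression import NormalizedExpression, RankedList


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ConfigurationError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentConfig:
    weight_exponent: float = 1.0
    n_perm: int = 1000
    fdr_cutoff: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ConfigurationError("weight_exponent must be >= 0")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray = field(repr=False)
    leading_edge: list[str] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    fdr_q: float
    n_perm: int
    seed: int
    n_overlap: int
    leading_edge: list[str] = field(default_factory=list)
    no_overlap: bool = False


def _hit_positions(r: RankedList, s: GeneSet) -> np.ndarray:
    index = {g: i for i, g in enumerate(r.genes)}
    return np.sort([index[g] for g in s.genes if g in index])


def _es_core(weights: np.ndarray, hits: np.ndarray, n: int) -> tuple[float, np.ndarray, int]:
    """ES, running sum and extremum index from hit positions.

    ``weights`` are |metric|^p over the whole list; only the entries at hit
    positions are used.  When the hit weights sum to zero (e.g. all-zero
    metrics with p > 0) hits fall back to equal increments.
    """
    n_hits = len(hits)
    if n_hits == 0 or n_hits == n:
        raise AnalysisError("gene set must hit some but not all of the ranked list")
    w_hit = weights[hits]
    total = w_hit.sum()
    hit_steps = np.zeros(n)
    hit_steps[hits] = w_hit if total > 0 else 1.0
    # running sum as hit-fraction minus miss-fraction; keeping the two
    # cumulative fractions separate matches the closed form bit-for-bit, so
    # exact +/- ties resolve at the first extremum deterministically
    hit_frac = np.cumsum(hit_steps) / (total if total > 0 else float(n_hits))
    miss_steps = np.ones(n)
    miss_steps[hits] = 0.0
    miss_frac = np.cumsum(miss_steps) / (n - n_hits)
    running = hit_frac - miss_frac
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


def enrichment_score(r: RankedList, s: GeneSet, p: float = 1.0) -> ESResult:
    """Weighted running-sum enrichment score of one gene set.

    Raises :class:`AnalysisError` if the set has no overlap with the ranked
    universe or covers it entirely (the miss decrement is then undefined).
    """
    if p < 0:
        raise ConfigurationError("weight exponent p must be >= 0")
    hits = _hit_positions(r, s)
    if hits.size == 0:
        raise AnalysisError(f"gene set {s.name!r} has no overlap with the ranked list")
    weights = np.abs(r.metrics) ** p
    es, running, peak = _es_core(weights, hits, len(r))
    if es >= 0:
        edge = [r.genes[i] for i in hits if i <= peak]
    else:
        edge = [r.genes[i] for i in hits if i >= peak]
    return ESResult(es=es, running_sum=running, leading_edge=edge)


def _null_es(
    weights: np.ndarray, n: int, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty(n_perm)
    for b in range(n_perm):
        hits = np.sort(rng.choice(n, size=k, replace=False))
        out[b], _, _ = _es_core(weights, hits, n)
    return out


def _nes(es: float | np.ndarray, null: np.ndarray) -> np.ndarray:
    """Normalize ES by the mean |null ES| of matching sign."""
    pos = null[null > 0]
    neg = null[null < 0]
    pos_mean = pos.mean() if pos.size else np.nan
    neg_mean = np.abs(neg).mean() if neg.size else np.nan
    es = np.atleast_1d(np.asarray(es, dtype=float))
    out = np.zeros_like(es)
    for i, e in enumerate(es):
        if e > 0:
            out[i] = e / pos_mean if np.isfinite(pos_mean) else 0.0
        elif e < 0:
            out[i] = e / neg_mean if np.isfinite(neg_mean) else 0.0
    return out


def _ratio_of_tails(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Sign-stratified ratio-of-tails FDR over pooled NES values.

    For a positive observed NES*, q = (fraction of positive null NES >= NES*)
    / (fraction of positive observed NES >= NES*), clipped to [0, 1];
    mirrored for negative.  Within each sign stratum q is then made weakly
    monotone so a more extreme NES never gets a larger q.
    """
    q = np.ones_like(observed, dtype=float)
    for sign in (1, -1):
        idx = np.where(np.sign(observed) == sign)[0]
        if idx.size == 0:
            continue
        obs_s = sign * observed[idx]  # positive magnitudes
        null_s = sign * null[np.sign(null) == sign]
        for j, m in zip(idx, obs_s):
            num = float((null_s >= m).mean()) if null_s.size else 0.0
            den = float((obs_s >= m).mean())
            q[j] = min(1.0, num / den) if den > 0 else 0.0
        # BH-style monotonicity: walking from the least to the most extreme
        # magnitude, a more extreme NES never keeps a larger q
        order = np.argsort(obs_s)
        running_min = np.inf
        for j in order:
            running_min = min(running_min, q[idx[j]])
            q[idx[j]] = running_min
    return q


def gsea_preranked(
    r: RankedList, sets: list[GeneSet], cfg: EnrichmentConfig = EnrichmentConfig()
) -> list[EnrichmentResult]:
    """Preranked enrichment with gene-set permutation NES and FDR q-values.

    Sets with zero overlap are returned flagged (``no_overlap``; es/nes/q are
    NaN) and excluded from the FDR pool.  Output order matches input order;
    a fixed seed yields identical results.
    """
    weights = np.abs(r.metrics) ** cfg.weight_exponent
    n = len(r)

    scored: list[tuple[int, GeneSet, float, list[str], int, np.ndarray]] = []
    flagged: dict[int, GeneSet] = {}
    for i, s in enumerate(sets):
        hits = _hit_positions(r, s)
        if hits.size == 0:
            flagged[i] = s
            continue
        es, _, peak = _es_core(weights, hits, n)
        if es >= 0:
            edge = [r.genes[j] for j in hits if j <= peak]
        else:
            edge = [r.genes[j] for j in hits if j >= peak]
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), i]))
        null = _null_es(weights, n, hits.size, cfg.n_perm, rng)
        scored.append((i, s, es, edge, hits.size, null))

    obs_nes = np.array([_nes(es, null)[0] for _, _, es, _, _, null in scored])
    null_nes_pool = (
        np.concatenate([_nes(null, null) for _, _, _, _, _, null in scored])
        if scored
        else np.empty(0)
    )
    qvals = _ratio_of_tails(obs_nes, null_nes_pool) if scored else np.empty(0)

    results: dict[int, EnrichmentResult] = {}
    for (i, s, es, edge, k, _), nes, q in zip(scored, obs_nes, qvals):
        results[i] = EnrichmentResult(
            set_name=s.name,
            es=es,
            nes=float(nes),
            fdr_q=float(q),
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            n_overlap=k,
            leading_edge=edge,
        )
    for i, s in flagged.items():
        results[i] = EnrichmentResult(
            set_name=s.name,
            es=float("nan"),
            nes=float("nan"),
            fdr_q=float("nan"),
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            n_overlap=0,
            no_overlap=True,
        )
    return [results[i] for i in range(len(sets))]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [x.set_name for x in results],
            "es": [x.es for x in results],
            "nes": [x.nes for x in results],
            "fdr_q": [x.fdr_q for x in results],
            "n_overlap": [x.n_overlap for x in results],
            "leading_edge": [",".join(x.leading_edge) for x in results],
        }
    ).set_index("set")


@dataclass
class ScoreResult:
    scores: pd.Series
    missing_genes: list[str]


def average_cpm_score(e: NormalizedExpression, s: GeneSet) -> ScoreResult:
    """Per-sample arithmetic mean CPM over the set genes present."""
    present = [g for g in sorted(s.genes) if g in e.cpm.index]
    if not present:
        raise AnalysisError(f"gene set {s.name!r} has no genes in the expression matrix")
    missing = [g for g in sorted(s.genes) if g not in e.cpm.index]
    scores = e.cpm.loc[present].mean(axis=0)
    scores.name = f"avg_cpm[{s.name}]"
    return ScoreResult(scores=scores, missing_genes=missing)


def compare_scores(scores_test, scores_ref) -> tuple[float, float | None]:
    """Difference of means (test - ref) and two-sided Welch t-test p-value.

    With a single sample on either side only the difference is returned
    (p is None).  If both sides have zero variance and equal means, p = 1.
    """
    a = np.asarray(scores_test, dtype=float)
    b = np.asarray(scores_ref, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("both score groups must be non-empty")
    diff = float(a.mean() - b.mean())
    if a.size < 2 or b.size < 2:
        return diff, None
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return diff, 1.0 if diff == 0 else 0.0
    t = stats.ttest_ind(a, b, equal_var=False)
    return diff, float(t.pvalue)
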