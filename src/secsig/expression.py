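"""Bulk expression stage: count filtering, upper-quartile CPM normalization,
fold-change based differential calls, and ranked-list construction.

The pipeline starts at a gene x sample count matrix (alignment and
quantification are upstream of this package).  Normalization follows the
upper-quartile convention: each sample's scaling factor is the 75th
percentile of its *nonzero* gene counts divided by its library size, the
factors are rescaled to unit geometric mean, and counts-per-million are
computed against the resulting effective library sizes.  Differential
expression is called purely on log2 fold change of group-mean CPM (with a
pseudocount), with the boundary |log2FC| = tau counting as differential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError

#: default log2 fold-change threshold for calling a gene differential
DEFAULT_TAU_DE = 2.0

#: default pseudocount on the CPM scale
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class CountMatrix:
    """Raw integer counts (genes x samples) plus per-sample condition labels."""

    counts: pd.DataFrame
    condition_of: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ConfigurationError("duplicate gene identifiers in count matrix")
        if self.counts.columns.duplicated().any():
            raise ConfigurationError("duplicate sample identifiers in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ConfigurationError("negative counts are not allowed")
        missing = set(self.counts.columns) - set(self.condition_of.index)
        if missing:
            raise ConfigurationError(f"samples without a condition label: {sorted(missing)}")
        self.condition_of = self.condition_of.loc[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class NormalizedExpression:
    """Upper-quartile normalized counts-per-million."""

    cpm: pd.DataFrame
    uq_factors: pd.Series
    library_sizes: pd.Series
    condition_of: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.cpm.columns if self.condition_of[s] == condition]


@dataclass
class RankedList:
    """Genes strictly ordered by a ranking metric, descending.

    Exact metric ties are broken lexicographically by gene id so that the
    ordering is a pure function of the input.
    """

    genes: list[str]
    metrics: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ConfigurationError("ranked list contains duplicate gene ids")
        self.metrics = np.asarray(self.metrics, dtype=float)
        if len(self.metrics) != len(self.genes):
            raise ConfigurationError("genes and metrics length mismatch")

    def __len__(self) -> int:
        return len(self.genes)

    def to_series(self) -> pd.Series:
        return pd.Series(self.metrics, index=self.genes, name="metric")


def smallest_group_size(m: CountMatrix) -> int:
    return int(m.condition_of.value_counts().min())


def filter_low_counts(
    m: CountMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Keep genes with raw-library CPM >= ``min_cpm`` in >= ``min_samples`` samples.

    ``min_samples`` defaults to the smallest condition group size.  CPM here is
    computed against the raw library sizes (filtering precedes normalization).
    """
    if min_cpm < 0:
        raise ConfigurationError("min_cpm must be >= 0")
    if min_samples is None:
        min_samples = smallest_group_size(m)
    n_samples = m.counts.shape[1]
    if not 1 <= min_samples <= n_samples:
        raise ConfigurationError(
            f"min_samples must be in [1, {n_samples}], got {min_samples}"
        )
    lib = m.library_sizes().to_numpy(dtype=float)
    raw_cpm = m.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    keep = (raw_cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("count filter removed every gene", stacklevel=2)
    return CountMatrix(m.counts.loc[keep].copy(), m.condition_of.copy())


def upper_quartile_normalize(m: CountMatrix) -> NormalizedExpression:
    """Upper-quartile CPM normalization.

    Per sample s the factor f_s is the 75th percentile (linear interpolation)
    of the *nonzero* counts divided by the library size.  Factors are rescaled
    to unit geometric mean; CPM is count / (library x rescaled factor) x 1e6.
    Raises :class:`AnalysisError` naming the sample if a sample is all zero.
    """
    lib = m.library_sizes()
    factors = {}
    for s in m.sample_ids:
        col = m.counts[s].to_numpy(dtype=float)
        nz = col[col > 0]
        if nz.size == 0:
            raise AnalysisError(f"sample {s!r} has no nonzero counts")
        factors[s] = np.percentile(nz, 75.0) / float(lib[s])
    f = pd.Series(factors, name="uq_factor").loc[m.sample_ids]
    f_rescaled = f / np.exp(np.mean(np.log(f)))
    effective = lib.astype(float) * f_rescaled
    cpm = m.counts.astype(float).div(effective, axis=1) * 1e6
    return NormalizedExpression(
        cpm=cpm,
        uq_factors=f_rescaled,
        library_sizes=lib.astype(float),
        condition_of=m.condition_of.copy(),
    )


def differential_expression(
    e: NormalizedExpression,
    ref: str,
    test: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    tau_de: float = DEFAULT_TAU_DE,
) -> pd.DataFrame:
    """Per-gene log2 fold change of mean CPM (test vs ref) with DE calls.

    Returns a DataFrame indexed by gene id with columns ``mean_cpm_ref``,
    ``mean_cpm_test``, ``log2fc`` and ``passes_de``; ``passes_de`` is True iff
    ``|log2fc| >= tau_de`` (boundary inclusive).
    """
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    ref_samples = e.samples_in(ref)
    test_samples = e.samples_in(test)
    if not ref_samples:
        raise AnalysisError(f"condition {ref!r} has no samples")
    if not test_samples:
        raise AnalysisError(f"condition {test!r} has no samples")
    mean_ref = e.cpm[ref_samples].mean(axis=1)
    mean_test = e.cpm[test_samples].mean(axis=1)
    log2fc = np.log2((mean_test + pseudocount) / (mean_ref + pseudocount))
    out = pd.DataFrame(
        {
            "mean_cpm_ref": mean_ref,
            "mean_cpm_test": mean_test,
            "log2fc": log2fc,
            "passes_de": np.abs(log2fc) >= tau_de,
        }
    )
    out.index.name = "gene"
    return out


def build_rank_list(de: pd.DataFrame, metric: str = "log2fc") -> RankedList:
    """Order *all* genes by the ranking metric, descending, ties lexicographic."""
    ordered = (
        de[[metric]]
        .rename_axis("gene")
        .reset_index()
        .sort_values([metric, "gene"], ascending=[False, True], kind="mergesort")
    )
    return RankedList(genes=list(ordered["gene"]), metrics=ordered[metric].to_numpy())
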