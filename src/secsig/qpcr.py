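"""qRT-PCR relative expression from threshold-cycle (CT) tables.

Relative expression normalizes a target gene's CT against the arithmetic
mean CT of the housekeeping genes (equivalently, the geometric mean of the
housekeeping expression levels).  Two conventions are provided because lab
write-ups disagree on the sign of the exponent:

* ``standard`` (default): 2^-(CT_gene - CT_HK) -- the usual delta-Ct rule in
  which a *lower* target CT (more template) gives *higher* expression.
* ``as_printed``: 2^-(CT_HK - CT_gene) -- the sign-flipped form that some
  methods sections print; it is the exact reciprocal of ``standard`` and
  would make expression increase with target CT.

Cross-sample condition summaries use geometric means, since expression
values are ratio-scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError

CONVENTIONS = ("standard", "as_printed")


@dataclass
class CTTable:
    """Long-format CT records plus housekeeping genes and sample conditions."""

    records: pd.DataFrame  # columns: gene, sample, ct
    housekeeping_genes: tuple[str, ...]
    condition_of: pd.Series

    def __post_init__(self) -> None:
        missing = {"gene", "sample", "ct"} - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"CT table missing columns: {sorted(missing)}")
        if not self.housekeeping_genes:
            raise ConfigurationError("at least one housekeeping gene is required")
        self.housekeeping_genes = tuple(self.housekeeping_genes)
        if not np.isfinite(self.records["ct"]).all():
            raise ConfigurationError("CT values must be finite")
        if self.records.duplicated(["gene", "sample"]).any():
            raise ConfigurationError("duplicate (gene, sample) CT records")
        samples = set(self.records["sample"])
        for hk in self.housekeeping_genes:
            covered = set(self.records.loc[self.records["gene"] == hk, "sample"])
            if covered != samples:
                raise ConfigurationError(
                    f"housekeeping gene {hk!r} lacks a CT in some samples"
                )

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.records["gene"]) - set(self.housekeeping_genes))

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.records["sample"]))

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_of.get(s) == condition]

    def ct(self, gene: str, sample: str) -> float:
        sel = self.records[
            (self.records["gene"] == gene) & (self.records["sample"] == sample)
        ]
        if sel.empty:
            raise AnalysisError(f"no CT for gene {gene!r} in sample {sample!r}")
        return float(sel["ct"].iloc[0])


def relative_expression(
    t: CTTable, gene: str, sample: str, convention: str = "standard"
) -> float:
    """Housekeeping-normalized expression of one gene in one sample."""
    if convention not in CONVENTIONS:
        raise ConfigurationError(f"convention must be one of {CONVENTIONS}")
    ct_gene = t.ct(gene, sample)
    ct_hk = float(np.mean([t.ct(hk, sample) for hk in t.housekeeping_genes]))
    delta = ct_gene - ct_hk if convention == "standard" else ct_hk - ct_gene
    return float(2.0 ** (-delta))


def fold_change_vs_control(
    t: CTTable,
    gene: str,
    test_condition: str,
    control_condition: str,
    convention: str = "standard",
) -> float:
    """Geometric-mean relative expression in test over control samples."""
    test_samples = t.samples_in(test_condition)
    control_samples = t.samples_in(control_condition)
    if not test_samples:
        raise AnalysisError(f"condition {test_condition!r} has no samples")
    if not control_samples:
        raise AnalysisError(f"condition {control_condition!r} has no samples")

    def _gmean(samples: list[str]) -> float:
        vals = np.log2([relative_expression(t, gene, s, convention) for s in samples])
        return float(2.0 ** np.mean(vals))

    return _gmean(test_samples) / _gmean(control_samples)


def log2_fold_changes(
    t: CTTable,
    test_condition: str,
    control_condition: str,
    convention: str = "standard",
) -> pd.Series:
    """log2 fold change vs control for every non-housekeeping gene."""
    out = {
        g: np.log2(
            fold_change_vs_control(t, g, test_condition, control_condition, convention)
        )
        for g in t.genes
    }
    return pd.Series(out, name="log2fc").sort_index()
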