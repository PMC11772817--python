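"""Seeded multi-omic simulators with a planted secretory ISG signature.

The generators emulate the statistical structure of a four-condition tumor
cell panel -- parental (P), treatment-resistant (PTR), and both with an
IFN-receptor knockdown (P_KD, PTR_KD) -- assayed by bulk RNA-seq counts, a
multi-exposure cytokine antibody array, and qRT-PCR, together with the two
annotation resources the analysis filters on (a secretome membership list
and an Interferome-style IFN-regulation table).

A designated set of "planted" genes carries the true treatment-induced
effect: +planted_log2fc in PTR vs P on the log2 scale, reduced by
``kd_reversal`` in PTR_KD.  Planted genes are always annotated both
secretory and type-I-IFN up-regulated, so a correct pipeline should recover
exactly this set.  Every generator is a pure function of (config, seed); one
global seed fans out to fixed per-assay child streams so changing one
assay's structure never reshuffles another's draws.

Counts are negative binomial with Var = mu + dispersion * mu^2, gene
baseline log2 means uniform over a configurable range, and log-normal
per-sample library-size factors (sd 0.2) so that library normalization is
non-trivial.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationDB
from .errors import ConfigurationError
from .expression import CountMatrix
from .proteomics import ARRAY_COLUMNS, ArrayExperiment
from .qpcr import CTTable

CONDITIONS = ("P", "PTR", "P_KD", "PTR_KD")

HOUSEKEEPING_GENES = ("Gapdh", "Actb")

# fixed per-assay child-seed offsets
_SEED_OFFSETS = {"counts": 1, "annotation": 2, "array": 3, "qpcr": 4}


def _rng(seed: int, assay: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _SEED_OFFSETS[assay]]))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-omic study.

    Defaults reflect a typical bulk RNA-seq cell-line contrast: ~2000 genes,
    triplicates per condition, a strong planted treatment effect (log2FC 3)
    fully reversed by the knockdown, and moderate biological dispersion.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    planted_genes: tuple[str, ...] = ()
    planted_log2fc: float = 3.0
    kd_reversal: float = 1.0
    nb_dispersion: float = 0.2
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    secretome_fraction: float = 0.25
    ifn_fraction: float = 0.30
    library_size_log_sd: float = 0.2
    exposures_s: tuple[float, ...] = (1.0, 5.0, 30.0)
    saturation_ceiling: float = 65535.0
    n_array_targets: int = 80
    array_noise_sd: float = 0.10
    array_background: float = 30.0
    qpcr_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown condition labels: {sorted(unknown)}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("duplicate condition labels")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        for name in ("secretome_fraction", "ifn_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if not 0 <= self.kd_reversal <= 1:
            raise ConfigurationError("kd_reversal must be in [0, 1]")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ConfigurationError("baseline_log2_mean_range must be (lo, hi)")
        universe = set(self.gene_ids)
        outside = set(self.planted_genes) - universe
        if outside:
            raise ConfigurationError(
                f"planted genes outside the simulated universe: {sorted(outside)}"
            )
        if len(set(self.planted_genes)) != len(self.planted_genes):
            raise ConfigurationError("duplicate planted genes")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{c}_{r + 1}" for c in self.conditions for r in range(self.n_per_group)
        ]

    @classmethod
    def default(cls, n_planted: int = 50, **kwargs) -> "SimulationConfig":
        """Config with the first ``n_planted`` genes planted as true signature."""
        n_genes = kwargs.get("n_genes", cls.n_genes)
        if n_planted > n_genes:
            raise ConfigurationError("n_planted exceeds n_genes")
        planted = tuple(f"G{i:05d}" for i in range(n_planted))
        return cls(planted_genes=planted, **kwargs)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        for key in (
            "conditions",
            "planted_genes",
            "baseline_log2_mean_range",
            "exposures_s",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _effect_log2(config: SimulationConfig, gene_is_planted: np.ndarray, condition: str) -> np.ndarray:
    """Per-gene treatment effect (log2) under one condition."""
    eff = np.zeros(len(gene_is_planted))
    if condition == "PTR":
        eff[gene_is_planted] = config.planted_log2fc
    elif condition == "PTR_KD":
        eff[gene_is_planted] = config.planted_log2fc * (1.0 - config.kd_reversal)
    return eff


def simulate_counts(config: SimulationConfig) -> CountMatrix:
    """Negative-binomial gene x sample counts with the planted design."""
    rng = _rng(config.seed, "counts")
    genes = np.array(config.gene_ids)
    planted_mask = np.isin(genes, list(config.planted_genes))
    lo, hi = config.baseline_log2_mean_range
    base_mu = 2.0 ** rng.uniform(lo, hi, config.n_genes)

    samples = config.sample_ids
    cond_of = pd.Series(
        [s.rsplit("_", 1)[0] for s in samples], index=samples, name="condition"
    )
    size_factors = rng.lognormal(0.0, config.library_size_log_sd, len(samples))

    mean = np.empty((config.n_genes, len(samples)))
    for j, s in enumerate(samples):
        mult = 2.0 ** _effect_log2(config, planted_mask, cond_of[s])
        mean[:, j] = base_mu * mult * size_factors[j]

    r_nb = 1.0 / config.nb_dispersion
    p_nb = r_nb / (r_nb + mean)
    counts = rng.negative_binomial(r_nb, p_nb)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    df.index.name = "gene"
    return CountMatrix(counts=df, condition_of=cond_of)


def simulate_annotation(config: SimulationConfig) -> AnnotationDB:
    """Secretome set and Interferome-style record table.

    The secretome has size round(secretome_fraction * n_genes) and contains
    every planted gene.  Every planted gene carries a type-I "up" record with
    fold change >= 1.5; each non-planted gene independently carries one with
    probability ``ifn_fraction``.  Additional type-II/III records (some below
    the 1.5 query threshold) are sprinkled in so threshold and type logic is
    exercised.
    """
    rng = _rng(config.seed, "annotation")
    genes = np.array(config.gene_ids)
    planted = list(config.planted_genes)
    planted_set = set(planted)
    non_planted = [g for g in genes if g not in planted_set]

    target_size = round(config.secretome_fraction * config.n_genes)
    n_extra = max(0, target_size - len(planted))
    extra = list(rng.choice(non_planted, size=min(n_extra, len(non_planted)), replace=False))
    secretome = frozenset(planted) | frozenset(extra)

    records: list[tuple[str, str, float, str]] = []
    for g in planted:
        records.append((g, "I", float(rng.uniform(1.5, 8.0)), "up"))
    type1_draw = rng.random(len(non_planted))
    fc_draw = rng.uniform(1.5, 8.0, len(non_planted))
    for g, u, fc in zip(non_planted, type1_draw, fc_draw):
        if u < config.ifn_fraction:
            records.append((g, "I", float(fc), "up"))
    # secondary records across the whole universe, any direction, wide FC range
    for ifn_type, prob in (("II", config.ifn_fraction / 2), ("III", config.ifn_fraction / 4)):
        draw = rng.random(config.n_genes)
        fcs = rng.uniform(1.2, 6.0, config.n_genes)
        dirs = rng.choice(["up", "down"], size=config.n_genes)
        for g, u, fc, d in zip(genes, draw, fcs, dirs):
            if u < prob:
                records.append((str(g), ifn_type, float(fc), str(d)))

    table = pd.DataFrame(records, columns=["gene", "ifn_type", "fold_change", "direction"])
    return AnnotationDB(secretome=secretome, interferome=table)


def array_targets(config: SimulationConfig) -> list[str]:
    """Deterministic target panel: all planted genes plus non-planted fill."""
    rng = _rng(config.seed, "array")
    planted = list(config.planted_genes)
    non_planted = [g for g in config.gene_ids if g not in set(planted)]
    n_fill = max(0, config.n_array_targets - len(planted))
    fill = list(rng.choice(non_planted, size=min(n_fill, len(non_planted)), replace=False))
    return sorted(planted + fill)


def simulate_array(config: SimulationConfig) -> ArrayExperiment:
    """Multi-exposure spot volumes over target/reference/background layout.

    Each condition gets one membrane imaged at every configured exposure.
    Spot base volumes are (background + abundance) with multiplicative
    log-normal noise drawn once per physical spot; exposure only rescales
    them (gain = exposure / shortest exposure), so unsaturated volume ratios
    across exposures equal the gain exactly, and long exposures clip at the
    saturation ceiling.  Planted targets carry the planted condition effects.
    """
    rng = _rng(config.seed, "array")
    # consume the same draw used by array_targets so panels agree
    planted = list(config.planted_genes)
    non_planted = [g for g in config.gene_ids if g not in set(planted)]
    n_fill = max(0, config.n_array_targets - len(planted))
    fill = list(rng.choice(non_planted, size=min(n_fill, len(non_planted)), replace=False))
    targets = sorted(planted + fill)
    planted_mask = np.isin(targets, planted)

    abundance = 2.0 ** rng.uniform(7.0, 11.0, len(targets))
    ref_abundance = 3000.0
    n_dup, n_ref, n_bg = 2, 6, 4
    gains = [e / min(config.exposures_s) for e in config.exposures_s]

    rows = []
    for condition in config.conditions:
        eff = _effect_log2(config, planted_mask, condition)
        level = config.array_background + abundance * 2.0 ** eff
        # one noise draw per physical spot; exposures rescale the same spot
        spot_levels: list[tuple[str, str, float]] = []
        for i, t in enumerate(targets):
            for _ in range(n_dup):
                spot_levels.append((t, "target", level[i] * rng.lognormal(0.0, config.array_noise_sd)))
        for _ in range(n_ref):
            spot_levels.append(
                ("", "reference", (config.array_background + ref_abundance) * rng.lognormal(0.0, config.array_noise_sd))
            )
        for _ in range(n_bg):
            spot_levels.append(
                ("", "background", config.array_background * rng.lognormal(0.0, config.array_noise_sd))
            )
        n_col = 12
        for exposure, gain in zip(config.exposures_s, gains):
            for k, (t, cls, base) in enumerate(spot_levels):
                rows.append(
                    (
                        condition,
                        condition,
                        float(exposure),
                        k // n_col,
                        k % n_col,
                        t,
                        cls,
                        min(config.saturation_ceiling, gain * base),
                    )
                )
    spots = pd.DataFrame(rows, columns=ARRAY_COLUMNS)
    return ArrayExperiment(spots=spots, saturation_ceiling=config.saturation_ceiling)


def qpcr_genes(config: SimulationConfig, n_controls: int = 5) -> list[str]:
    """Genes on the qPCR panel: planted genes plus a few unaffected controls."""
    planted = list(config.planted_genes)
    non_planted = [g for g in config.gene_ids if g not in set(planted)]
    return sorted(planted + non_planted[:n_controls])


def simulate_qpcr(config: SimulationConfig) -> CTTable:
    """CT values for the planted panel plus two stable housekeeping genes.

    One log2 unit of expression change equals one CT cycle, so a planted
    gene's CT drops by ``planted_log2fc`` cycles in PTR.  Gaussian technical
    noise (sd ``qpcr_noise_sd`` cycles) is added to every CT; housekeeping
    genes have no condition effect.
    """
    rng = _rng(config.seed, "qpcr")
    genes = qpcr_genes(config)
    planted_mask = np.isin(genes, list(config.planted_genes))
    base_ct = rng.uniform(22.0, 28.0, len(genes))
    hk_base = {"Gapdh": 19.0, "Actb": 20.5}

    samples = config.sample_ids
    cond_of = pd.Series(
        [s.rsplit("_", 1)[0] for s in samples], index=samples, name="condition"
    )
    records = []
    for s in samples:
        eff = _effect_log2(config, planted_mask, cond_of[s])
        noise = rng.normal(0.0, config.qpcr_noise_sd, len(genes)) if config.qpcr_noise_sd > 0 else np.zeros(len(genes))
        for g, b, e, n in zip(genes, base_ct, eff, noise):
            records.append((g, s, b - e + n))
        for hk, b in hk_base.items():
            n = rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd > 0 else 0.0
            records.append((hk, s, b + n))
    table = pd.DataFrame(records, columns=["gene", "sample", "ct"])
    return CTTable(
        records=table, housekeeping_genes=HOUSEKEEPING_GENES, condition_of=cond_of
    )
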