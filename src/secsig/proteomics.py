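"""Cytokine antibody-array densitometry stage.

Membranes are probed at several film exposures; each (condition, exposure)
grid holds duplicate target spots, positive-control reference spots, and
background spots, with volumes clipped at a saturation ceiling.  For each
target the shortest exposure with detectable, unsaturated signal is chosen;
the duplicate mean is background-subtracted and divided by the
background-subtracted positive-control mean of the *same* grid, which cancels
membrane-wide exposure gain.  Condition fold changes are then log2 ratios of
these normalized intensities.

Arrays are typically run at n = 1 per condition, so no test statistic is
attached here; downstream evidence integration applies an effect-size floor
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError

SPOT_CLASSES = ("target", "reference", "background")

ARRAY_COLUMNS = [
    "membrane",
    "condition",
    "exposure_s",
    "row",
    "col",
    "target",
    "spot_class",
    "volume",
]


@dataclass
class ArrayExperiment:
    """Long-format spot densitometry volumes across membranes and exposures."""

    spots: pd.DataFrame
    saturation_ceiling: float = 65535.0

    def __post_init__(self) -> None:
        missing = set(ARRAY_COLUMNS) - set(self.spots.columns)
        if missing:
            raise ConfigurationError(f"array table missing columns: {sorted(missing)}")
        if self.saturation_ceiling <= 0:
            raise ConfigurationError("saturation_ceiling must be > 0")
        if (~self.spots["spot_class"].isin(SPOT_CLASSES)).any():
            raise ConfigurationError(f"spot_class must be one of {SPOT_CLASSES}")
        if (self.spots["volume"] < 0).any():
            raise ConfigurationError("spot volumes must be non-negative")
        for (mem, exp), grid in self.spots.groupby(["membrane", "exposure_s"]):
            classes = set(grid["spot_class"])
            if "reference" not in classes or "background" not in classes:
                raise ConfigurationError(
                    f"grid ({mem}, {exp}s) lacks reference or background spots"
                )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.spots["condition"].unique())

    @property
    def targets(self) -> list[str]:
        t = self.spots.loc[self.spots["spot_class"] == "target", "target"]
        return sorted(t.unique())

    def exposures_for(self, condition: str) -> list[float]:
        sub = self.spots[self.spots["condition"] == condition]
        if sub.empty:
            raise AnalysisError(f"no membranes for condition {condition!r}")
        return sorted(sub["exposure_s"].unique())

    def grid(self, condition: str, exposure_s: float) -> pd.DataFrame:
        sub = self.spots[
            (self.spots["condition"] == condition)
            & (self.spots["exposure_s"] == exposure_s)
        ]
        if sub.empty:
            raise AnalysisError(f"no grid for ({condition!r}, {exposure_s}s)")
        return sub


@dataclass(frozen=True)
class ExposureSelection:
    exposure_s: float | None
    undetected: bool = False
    saturated_all_exposures: bool = False


@dataclass(frozen=True)
class ArrayProteinResult:
    target: str
    condition: str
    chosen_exposure_s: float | None
    normalized_intensity: float
    undetected: bool = False
    saturated_all_exposures: bool = False


def _spot_mean(grid: pd.DataFrame, spot_class: str, target: str | None = None) -> float:
    sel = grid[grid["spot_class"] == spot_class]
    if target is not None:
        sel = sel[sel["target"] == target]
    if sel.empty:
        raise AnalysisError(f"no {spot_class} spots" + (f" for target {target!r}" if target else ""))
    return float(sel["volume"].mean())


def select_exposure(
    x: ArrayExperiment,
    target: str,
    condition: str,
    detect_threshold: float | None = None,
) -> ExposureSelection:
    """Shortest exposure with detectable, unsaturated duplicate-mean signal.

    ``detect_threshold`` is an absolute volume; when None it defaults to
    3 x the mean background volume of each candidate grid (a conventional
    signal-to-noise rule).  If no exposure detects the target the result is
    flagged ``undetected``; if detection only ever occurs at saturation, the
    shortest saturated exposure is returned flagged
    ``saturated_all_exposures``.
    """
    if target not in x.targets:
        raise AnalysisError(f"unknown target {target!r}")
    shortest_saturated: float | None = None
    for exp in x.exposures_for(condition):
        grid = x.grid(condition, exp)
        mean_v = _spot_mean(grid, "target", target)
        thr = detect_threshold
        if thr is None:
            thr = 3.0 * _spot_mean(grid, "background")
        if mean_v > thr:
            if mean_v < x.saturation_ceiling:
                return ExposureSelection(exposure_s=exp)
            if shortest_saturated is None:
                shortest_saturated = exp
    if shortest_saturated is not None:
        return ExposureSelection(
            exposure_s=shortest_saturated, saturated_all_exposures=True
        )
    return ExposureSelection(exposure_s=None, undetected=True)


def quantify_target(
    x: ArrayExperiment,
    target: str,
    condition: str,
    detect_threshold: float | None = None,
) -> ArrayProteinResult:
    """Background-subtracted, positive-control-normalized intensity.

    intensity = max(0, target mean - background mean)
              / (reference mean - background mean), all on the chosen grid.
    Undetected targets get intensity 0.
    """
    sel = select_exposure(x, target, condition, detect_threshold)
    if sel.undetected:
        return ArrayProteinResult(
            target=target,
            condition=condition,
            chosen_exposure_s=None,
            normalized_intensity=0.0,
            undetected=True,
        )
    grid = x.grid(condition, sel.exposure_s)
    bg = _spot_mean(grid, "background")
    signal = max(0.0, _spot_mean(grid, "target", target) - bg)
    ref_net = _spot_mean(grid, "reference") - bg
    if ref_net <= 0:
        mem = grid["membrane"].iloc[0]
        raise AnalysisError(
            f"reference signal not above background on membrane {mem!r} "
            f"at {sel.exposure_s}s"
        )
    return ArrayProteinResult(
        target=target,
        condition=condition,
        chosen_exposure_s=sel.exposure_s,
        normalized_intensity=signal / ref_net,
        saturated_all_exposures=sel.saturated_all_exposures,
    )


def quantify_condition(
    x: ArrayExperiment, condition: str, detect_threshold: float | None = None
) -> pd.DataFrame:
    """Quantify every target for one condition; indexed by target."""
    rows = [
        quantify_target(x, t, condition, detect_threshold) for t in x.targets
    ]
    return pd.DataFrame(
        {
            "condition": [r.condition for r in rows],
            "chosen_exposure_s": [r.chosen_exposure_s for r in rows],
            "normalized_intensity": [r.normalized_intensity for r in rows],
            "undetected": [r.undetected for r in rows],
            "saturated_all_exposures": [r.saturated_all_exposures for r in rows],
        },
        index=pd.Index([r.target for r in rows], name="target"),
    )


def array_fold_changes(
    test, ref, pseudo: float = 0.01, dead_band: float = 0.0
) -> pd.DataFrame:
    """log2((test + pseudo) / (ref + pseudo)) per target with a direction call.

    ``test`` and ``ref`` map target -> normalized intensity over the same
    target universe.  The direction is "up"/"down" by sign outside a
    symmetric dead band (default 0: any nonzero ratio is directional).
    Zero intensities (undetected) are handled by the pseudocount; the result
    is always finite.
    """
    if pseudo <= 0:
        raise ConfigurationError("pseudo must be > 0")
    test = pd.Series(test, dtype=float)
    ref = pd.Series(ref, dtype=float)
    if set(test.index) != set(ref.index):
        raise ConfigurationError("test and ref must cover the same targets")
    ref = ref.loc[test.index]
    log2_ratio = np.log2((test + pseudo) / (ref + pseudo))
    direction = np.where(
        log2_ratio > dead_band, "up", np.where(log2_ratio < -dead_band, "down", "unchanged")
    )
    out = pd.DataFrame({"log2_ratio": log2_ratio, "direction": direction})
    out.index.name = "target"
    return out
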