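"""Multi-assay evidence integration into a secretome gene signature.

This is the core bespoke computation of the pipeline.  Candidate genes come
from a preliminary list (transcript differentially up, secretome member,
IFN-regulated).  Each candidate's support across assays is collected into an
evidence matrix: one record per (gene, assay, comparison) carrying a
direction, a magnitude (log2 where applicable) and a significance call.  The
final signature keeps a candidate only if, in addition to the preliminary
filter, it has (2) proteomic up-regulation in the resistant-vs-parental
comparison, (3) a decrease under the IFN-receptor knockdown, and (4)
confirmation by at least one transcriptomic and one proteomic method.  A
mirrored derivation with all directions flipped produces the down-regulated
signature; the two are disjoint by construction.

Each rule step can be toggled via :class:`RuleConfig`, and the derivation
log records every step's verdict per candidate so the evidence funnel is
auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .annotation import AnnotationDB, DEFAULT_TAU_IFN, is_ifn_regulated
from .errors import ConfigurationError
from .expression import DEFAULT_TAU_DE

ASSAYS = ("rnaseq", "qrtpcr", "array", "elisa", "western")
MODALITY_OF = {
    "rnaseq": "transcriptomic",
    "qrtpcr": "transcriptomic",
    "array": "proteomic",
    "elisa": "proteomic",
    "western": "proteomic",
}
COMPARISONS = ("PTR_vs_P", "KD_vs_PTR")
DIRECTIONS = ("up", "down", "unchanged")

#: |log2 ratio| floor standing in for significance on replicate-free assays
#: (~1.5-fold)
DEFAULT_EFFECT_FLOOR = 0.58

EVIDENCE_COLUMNS = ["gene", "assay", "comparison", "direction", "magnitude", "significant"]


@dataclass(frozen=True)
class EvidenceRecord:
    gene: str
    assay: str
    comparison: str
    direction: str
    magnitude: float
    significant: bool

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ConfigurationError(f"unknown assay {self.assay!r}")
        if self.comparison not in COMPARISONS:
            raise ConfigurationError(f"unknown comparison {self.comparison!r}")
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.direction == "unchanged" and self.significant:
            raise ConfigurationError("an 'unchanged' record cannot be significant")

    @property
    def modality(self) -> str:
        return MODALITY_OF[self.assay]


class EvidenceMatrix:
    """Evidence records indexed by (gene, assay, comparison); one per cell."""

    def __init__(self, records: list[EvidenceRecord] | None = None):
        self._cells: dict[tuple[str, str, str], EvidenceRecord] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: EvidenceRecord) -> None:
        key = (rec.gene, rec.assay, rec.comparison)
        if key in self._cells:
            raise ConfigurationError(f"duplicate evidence cell {key}")
        self._cells[key] = rec

    def __len__(self) -> int:
        return len(self._cells)

    def records(self) -> list[EvidenceRecord]:
        return [self._cells[k] for k in sorted(self._cells)]

    def records_for(self, gene: str) -> list[EvidenceRecord]:
        return [r for k, r in sorted(self._cells.items()) if k[0] == gene]

    def to_frame(self) -> pd.DataFrame:
        recs = self.records()
        return pd.DataFrame(
            {
                "gene": [r.gene for r in recs],
                "assay": [r.assay for r in recs],
                "comparison": [r.comparison for r in recs],
                "direction": [r.direction for r in recs],
                "magnitude": [r.magnitude for r in recs],
                "significant": [r.significant for r in recs],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceMatrix":
        return cls(
            [
                EvidenceRecord(
                    gene=str(row.gene),
                    assay=str(row.assay),
                    comparison=str(row.comparison),
                    direction=str(row.direction),
                    magnitude=float(row.magnitude),
                    significant=bool(row.significant),
                )
                for row in df.itertuples()
            ]
        )


@dataclass(frozen=True)
class RuleConfig:
    """Toggles and parameters of the integration rule steps."""

    require_preliminary: bool = True
    require_proteomic_up: bool = True
    require_kd_reversal: bool = True
    kd_any_modality: bool = True
    require_confirmation: bool = True
    confirmation_mode: str = "cross_modality"  # or "any_two"

    def __post_init__(self) -> None:
        if self.confirmation_mode not in ("cross_modality", "any_two"):
            raise ConfigurationError("confirmation_mode must be 'cross_modality' or 'any_two'")


@dataclass
class GeneSignature:
    name: str
    genes: list[str]
    derivation_log: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ConfigurationError("signature genes must be unique")


def build_preliminary_list(
    de: pd.DataFrame,
    db: AnnotationDB,
    tau_de: float = DEFAULT_TAU_DE,
    tau_ifn: float = DEFAULT_TAU_IFN,
    sense: str = "up",
) -> list[str]:
    """Candidate genes: differential in the requested sense, secretory, IFN-regulated.

    ``sense`` "up" keeps log2fc >= +tau_de; "down" keeps log2fc <= -tau_de.
    The returned list is sorted alphabetically; it may be empty.
    """
    if sense not in ("up", "down"):
        raise ConfigurationError("sense must be 'up' or 'down'")
    if sense == "up":
        directional = de["passes_de"] & (de["log2fc"] >= tau_de)
    else:
        directional = de["passes_de"] & (de["log2fc"] <= -tau_de)
    genes = list(de.index[directional])
    secretory = [g for g in genes if g in db.secretome]
    if not secretory:
        return []
    ifn = is_ifn_regulated(secretory, db, tau_ifn)
    return sorted(g for g in secretory if ifn[g])


def _direction_of(log2_value: float, floor: float) -> tuple[str, bool]:
    if log2_value >= floor:
        return "up", True
    if log2_value <= -floor:
        return "down", True
    return ("up" if log2_value > 0 else "down" if log2_value < 0 else "unchanged"), False


def assemble_evidence(
    de: pd.DataFrame | None = None,
    array_fc: dict[str, pd.DataFrame] | None = None,
    qpcr_fc: dict[str, pd.Series] | None = None,
    extra_assays: list[EvidenceRecord] | None = None,
    protein_gene_map: dict[str, str] | None = None,
    effect_floor: float = DEFAULT_EFFECT_FLOOR,
    tau_de: float = DEFAULT_TAU_DE,
) -> EvidenceMatrix:
    """Collate per-assay results into one evidence matrix.

    ``de`` is the RNA-seq differential table (PTR_vs_P).  ``array_fc`` and
    ``qpcr_fc`` map a comparison name to the per-target/per-gene log2 fold
    changes of that assay.  Array targets are translated to gene ids through
    ``protein_gene_map`` (identity by default); unmapped targets are skipped
    with a warning rather than silently mis-assigned.  Assays without
    replicate-based tests are called significant at |log2| >= ``effect_floor``.
    """
    ev = EvidenceMatrix()
    if de is not None:
        for gene, row in de.iterrows():
            direction, _ = _direction_of(row["log2fc"], tau_de)
            ev.add(
                EvidenceRecord(
                    gene=str(gene),
                    assay="rnaseq",
                    comparison="PTR_vs_P",
                    direction=direction,
                    magnitude=float(row["log2fc"]),
                    significant=bool(row["passes_de"]),
                )
            )
    mapping = protein_gene_map or {}
    for comparison, table in (array_fc or {}).items():
        for target, row in table.iterrows():
            gene = mapping.get(str(target), str(target) if not mapping else None)
            if gene is None:
                warnings.warn(f"array target {target!r} has no gene mapping; skipped", stacklevel=2)
                continue
            direction, significant = _direction_of(row["log2_ratio"], effect_floor)
            ev.add(
                EvidenceRecord(
                    gene=gene,
                    assay="array",
                    comparison=comparison,
                    direction=direction,
                    magnitude=float(row["log2_ratio"]),
                    significant=significant,
                )
            )
    for comparison, series in (qpcr_fc or {}).items():
        for gene, val in series.items():
            direction, significant = _direction_of(float(val), effect_floor)
            ev.add(
                EvidenceRecord(
                    gene=str(gene),
                    assay="qrtpcr",
                    comparison=comparison,
                    direction=direction,
                    magnitude=float(val),
                    significant=significant,
                )
            )
    for rec in extra_assays or []:
        ev.add(rec)
    return ev


_STEP_NAMES = ("preliminary", "proteomic_change", "kd_reversal", "confirmation")


def _flip(direction: str) -> str:
    return {"up": "down", "down": "up"}[direction]


def derive_signature(
    ev: EvidenceMatrix,
    prelim: list[str],
    rules: RuleConfig = RuleConfig(),
    sense: str = "up",
    name: str | None = None,
) -> GeneSignature:
    """Apply the integration rule to the candidate list.

    A candidate passes when every enabled step holds:

    1. membership in the preliminary (secretory, IFN-regulated, transcript
       differential) list;
    2. at least one significant proteomic record in the ``sense`` direction
       for PTR_vs_P;
    3. at least one significant record (any modality by default) in the
       opposite direction for KD_vs_PTR -- the knockdown-reversal check;
    4. confirmation overall by at least one transcriptomic and one proteomic
       record (or, in "any_two" mode, any two distinct assays) whose
       direction matches the expected pattern in either comparison.
    """
    if sense not in ("up", "down"):
        raise ConfigurationError("sense must be 'up' or 'down'")
    name = name or ("signature_up" if sense == "up" else "signature_down")
    candidates = sorted(set(prelim))
    log_rows = []
    members = []
    for gene in candidates:
        recs = ev.records_for(gene)
        expected_kd = _flip(sense)

        def confirming(r: EvidenceRecord) -> bool:
            return r.significant and (
                (r.comparison == "PTR_vs_P" and r.direction == sense)
                or (r.comparison == "KD_vs_PTR" and r.direction == expected_kd)
            )

        step1 = True  # candidates are drawn from the preliminary list
        step2 = any(
            r.modality == "proteomic"
            and r.comparison == "PTR_vs_P"
            and r.direction == sense
            and r.significant
            for r in recs
        )
        step3 = any(
            r.comparison == "KD_vs_PTR"
            and r.direction == expected_kd
            and r.significant
            and (rules.kd_any_modality or r.modality == "proteomic")
            for r in recs
        )
        confirming_recs = [r for r in recs if confirming(r)]
        if rules.confirmation_mode == "cross_modality":
            step4 = any(r.modality == "transcriptomic" for r in confirming_recs) and any(
                r.modality == "proteomic" for r in confirming_recs
            )
        else:
            step4 = len({r.assay for r in confirming_recs}) >= 2

        verdicts = {
            "preliminary": step1 if rules.require_preliminary else True,
            "proteomic_change": step2 if rules.require_proteomic_up else True,
            "kd_reversal": step3 if rules.require_kd_reversal else True,
            "confirmation": step4 if rules.require_confirmation else True,
        }
        passed = all(verdicts.values())
        log_rows.append({"gene": gene, **verdicts, "in_signature": passed})
        if passed:
            members.append(gene)

    log = pd.DataFrame(log_rows, columns=["gene", *_STEP_NAMES, "in_signature"])
    if not log_rows:
        log = pd.DataFrame(columns=["gene", *_STEP_NAMES, "in_signature"])
    return GeneSignature(name=name, genes=sorted(members), derivation_log=log.set_index("gene") if log_rows else log)


def derive_signature_down(
    ev: EvidenceMatrix,
    prelim_down: list[str],
    rules: RuleConfig = RuleConfig(),
    name: str = "signature_down",
) -> GeneSignature:
    """Mirror of :func:`derive_signature` with every direction flipped."""
    return derive_signature(ev, prelim_down, rules, sense="down", name=name)


def example_evidence_matrix() -> tuple[EvidenceMatrix, list[str]]:
    """Worked five-factor example with full cross-assay support, plus decoys.

    Encodes the canonical evidence pattern of a resistant-vs-parental
    secretome study: five secreted, IFN-regulated factors (Ccl2, Il1rn, Il6,
    Lcn2, Nos2) with transcript up-regulation, cytokine-array up-regulation,
    array decreases under the IFN-receptor knockdown, western blots for Lcn2
    and Nos2, ELISAs for Lcn2, Il6 and Ccl2, and qRT-PCR support for all
    five.  Two decoy candidates carry transcript-only or non-reversed
    support and must be rejected by the integration rule.  Returns the
    matrix and the candidate (preliminary) list.
    """
    five = ["CCL2", "IL1RN", "IL6", "LCN2", "NOS2"]
    records: list[EvidenceRecord] = []

    def rec(gene, assay, comparison, direction, magnitude=2.0, significant=True):
        records.append(
            EvidenceRecord(
                gene=gene,
                assay=assay,
                comparison=comparison,
                direction=direction,
                magnitude=magnitude,
                significant=significant,
            )
        )

    for g in five:
        rec(g, "rnaseq", "PTR_vs_P", "up", 3.0)
        rec(g, "array", "PTR_vs_P", "up", 1.9)
        rec(g, "array", "KD_vs_PTR", "down", -1.7)
        rec(g, "qrtpcr", "PTR_vs_P", "up", 2.5)
        rec(g, "qrtpcr", "KD_vs_PTR", "down", -2.0)
    for g in ("LCN2", "NOS2"):
        rec(g, "western", "PTR_vs_P", "up", 1.2)
    for g in ("LCN2", "IL6", "CCL2"):
        rec(g, "elisa", "PTR_vs_P", "up", 1.5)

    # decoy: transcript up but never confirmed at the protein level
    rec("CXCL10", "rnaseq", "PTR_vs_P", "up", 2.8)
    rec("CXCL10", "qrtpcr", "PTR_vs_P", "up", 2.1)
    # decoy: protein up but not decreased by the knockdown
    rec("SAA3", "rnaseq", "PTR_vs_P", "up", 2.2)
    rec("SAA3", "array", "PTR_vs_P", "up", 1.1)
    rec("SAA3", "array", "KD_vs_PTR", "up", 0.9)

    candidates = sorted(five + ["CXCL10", "SAA3"])
    return EvidenceMatrix(records), candidates
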