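"""Configuration and orchestration of the full analysis.

The pipeline runs ``simulate -> normalize/DE -> array -> qPCR -> evidence ->
signature -> enrichment/scoring`` and writes every intermediate artifact as
plain TSV/CSV plus a JSON manifest (seed, thresholds, per-stage record
counts, content hashes) so the evidence funnel is auditable and re-runs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import io as sio
from .annotation import AnnotationDB, summarize_ifn_regulation
from .enrichment import (
    EnrichmentConfig,
    EnrichmentResult,
    GeneSet,
    average_cpm_score,
    compare_scores,
    enrichment_table,
    gsea_preranked,
)
from .errors import ConfigurationError
from .expression import (
    CountMatrix,
    NormalizedExpression,
    RankedList,
    build_rank_list,
    differential_expression,
    filter_low_counts,
    upper_quartile_normalize,
)
from .proteomics import array_fold_changes, quantify_condition
from .qpcr import log2_fold_changes
from .signature import (
    EvidenceMatrix,
    GeneSignature,
    RuleConfig,
    assemble_evidence,
    build_preliminary_list,
    derive_signature,
    derive_signature_down,
)
from .synthetic import (
    SimulationConfig,
    simulate_annotation,
    simulate_array,
    simulate_counts,
    simulate_qpcr,
)


class PipelineConfig(BaseModel):
    """Validated thresholds and options for a full pipeline run.

    Unknown keys are rejected; all thresholds must be positive.  The
    ``simulation`` block holds :class:`SimulationConfig` keyword arguments
    plus ``n_planted``.
    """

    model_config = ConfigDict(extra="forbid")

    simulation: dict = Field(default_factory=dict)
    tau_de: float = 2.0
    tau_ifn: float = 1.5
    pseudocount: float = 1.0
    min_cpm: float = 1.0
    min_samples: int | None = None
    effect_floor: float = 0.58
    qpcr_convention: str = "standard"
    n_perm: int = 1000
    fdr_cutoff: float = 0.25
    weight_exponent: float = 1.0
    rules: dict = Field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None

    @field_validator("tau_de", "tau_ifn", "pseudocount", "fdr_cutoff")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @field_validator("n_perm")
    @classmethod
    def _n_perm(cls, v):
        if v < 1:
            raise ValueError("n_perm must be >= 1")
        return v

    @field_validator("qpcr_convention")
    @classmethod
    def _convention(cls, v):
        if v not in ("standard", "as_printed"):
            raise ValueError("qpcr_convention must be 'standard' or 'as_printed'")
        return v

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        n_planted = kwargs.pop("n_planted", 50)
        kwargs.setdefault("seed", self.seed)
        return SimulationConfig.default(n_planted=n_planted, **kwargs)

    def rule_config(self) -> RuleConfig:
        return RuleConfig(**self.rules)


def validate_config(raw) -> PipelineConfig:
    """Schema-check a raw JSON string or mapping into a PipelineConfig."""
    if isinstance(raw, (str, bytes)):
        raw = json.loads(raw)
    try:
        cfg = PipelineConfig.model_validate(raw)
    except Exception as exc:  # surface pydantic detail as a configuration error
        raise ConfigurationError(str(exc)) from exc
    if cfg.n_perm < 100:
        warnings.warn(
            f"n_perm={cfg.n_perm} is low; FDR estimates will be coarse", stacklevel=2
        )
    return cfg


@dataclass
class PipelineResult:
    """Everything a full in-memory run computes, stage by stage."""

    sim_config: SimulationConfig
    counts: CountMatrix
    filtered: CountMatrix
    normalized: NormalizedExpression
    de: pd.DataFrame
    rank: RankedList
    db: AnnotationDB
    ifn_summary: dict
    array_intensities: dict[str, pd.DataFrame]
    array_fc: dict[str, pd.DataFrame]
    qpcr_fc: dict[str, pd.Series]
    evidence: EvidenceMatrix
    prelim_up: list[str]
    prelim_down: list[str]
    signature_up: GeneSignature
    signature_down: GeneSignature
    enrichment: list[EnrichmentResult]
    scores: dict[str, pd.Series]
    score_comparison: tuple[float, float | None] | None


def analyze(cfg: PipelineConfig, run_gsea: bool = True) -> PipelineResult:
    """Run the whole synthetic-study analysis in memory."""
    sim = cfg.simulation_config()
    counts = simulate_counts(sim)
    db = simulate_annotation(sim)
    array = simulate_array(sim)
    ct = simulate_qpcr(sim)

    filtered = filter_low_counts(counts, cfg.min_cpm, cfg.min_samples)
    norm = upper_quartile_normalize(filtered)
    de = differential_expression(norm, ref="P", test="PTR", pseudocount=cfg.pseudocount, tau_de=cfg.tau_de)
    rank = build_rank_list(de)
    ifn_summary = summarize_ifn_regulation(de, db, cfg.tau_ifn)

    intensities = {c: quantify_condition(array, c) for c in array.conditions}
    array_fc = {
        "PTR_vs_P": array_fold_changes(
            intensities["PTR"]["normalized_intensity"],
            intensities["P"]["normalized_intensity"],
        ),
        "KD_vs_PTR": array_fold_changes(
            intensities["PTR_KD"]["normalized_intensity"],
            intensities["PTR"]["normalized_intensity"],
        ),
    }
    qpcr_fc = {
        "PTR_vs_P": log2_fold_changes(ct, "PTR", "P", cfg.qpcr_convention),
        "KD_vs_PTR": log2_fold_changes(ct, "PTR_KD", "PTR", cfg.qpcr_convention),
    }

    evidence = assemble_evidence(
        de=de,
        array_fc=array_fc,
        qpcr_fc=qpcr_fc,
        effect_floor=cfg.effect_floor,
        tau_de=cfg.tau_de,
    )
    rules = cfg.rule_config()
    prelim_up = build_preliminary_list(de, db, cfg.tau_de, cfg.tau_ifn, sense="up")
    prelim_down = build_preliminary_list(de, db, cfg.tau_de, cfg.tau_ifn, sense="down")
    sig_up = derive_signature(evidence, prelim_up, rules, sense="up")
    sig_down = derive_signature_down(evidence, prelim_down, rules)

    enrichment: list[EnrichmentResult] = []
    scores: dict[str, pd.Series] = {}
    comparison = None
    if sig_up.genes:
        gene_set = GeneSet(name=sig_up.name, genes=frozenset(sig_up.genes))
        if run_gsea:
            ecfg = EnrichmentConfig(
                weight_exponent=cfg.weight_exponent, n_perm=cfg.n_perm, fdr_cutoff=cfg.fdr_cutoff, seed=cfg.seed
            )
            enrichment = gsea_preranked(rank, [gene_set], ecfg)
        score = average_cpm_score(norm, gene_set)
        for cond in sim.conditions:
            scores[cond] = score.scores[norm.samples_in(cond)]
        comparison = compare_scores(scores["PTR"], scores["P"])

    return PipelineResult(
        sim_config=sim,
        counts=counts,
        filtered=filtered,
        normalized=norm,
        de=de,
        rank=rank,
        db=db,
        ifn_summary=ifn_summary,
        array_intensities=intensities,
        array_fc=array_fc,
        qpcr_fc=qpcr_fc,
        evidence=evidence,
        prelim_up=prelim_up,
        prelim_down=prelim_down,
        signature_up=sig_up,
        signature_down=sig_down,
        enrichment=enrichment,
        scores=scores,
        score_comparison=comparison,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Full run with every artifact written to ``out_dir``; returns the manifest."""
    out = Path(out_dir or cfg.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    result = analyze(cfg)
    sim = result.sim_config

    sio.write_counts(result.counts, out / "counts.tsv", out / "samples.tsv")
    sio.write_annotation(result.db, out / "secretome.txt", out / "interferome.tsv")
    sio.write_array(simulate_array(sim), out / "array.csv")
    ct = simulate_qpcr(sim)
    sio.write_ct_table(ct, out / "ct.tsv", out / "ct_samples.tsv")
    (out / "sim_config.json").write_text(sim.to_json() + "\n")

    result.de.to_csv(out / "differential.tsv", sep="\t")
    sio.write_rnk(result.rank, out / "ranking.rnk")
    (out / "ifn_summary.json").write_text(json.dumps(result.ifn_summary, indent=2) + "\n")
    for comp, table in result.array_fc.items():
        table.to_csv(out / f"array_fc_{comp}.tsv", sep="\t")
    for comp, series in result.qpcr_fc.items():
        series.rename_axis("gene").to_csv(out / f"qpcr_fc_{comp}.tsv", sep="\t")
    result.evidence.to_frame().to_csv(out / "evidence.tsv", sep="\t", index=False)
    for sig in (result.signature_up, result.signature_down):
        sig.derivation_log.to_csv(out / f"{sig.name}_derivation.tsv", sep="\t")
    sio.write_gmt(
        {
            result.signature_up.name: result.signature_up.genes,
            result.signature_down.name: result.signature_down.genes,
        },
        out / "signatures.gmt",
    )
    if result.enrichment:
        enrichment_table(result.enrichment).to_csv(out / "enrichment.tsv", sep="\t")
    if result.scores:
        pd.concat(result.scores.values()).rename_axis("sample").to_csv(
            out / "signature_scores.tsv", sep="\t"
        )

    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": cfg.seed,
        "thresholds": {
            "tau_de": cfg.tau_de,
            "tau_ifn": cfg.tau_ifn,
            "effect_floor": cfg.effect_floor,
            "fdr_cutoff": cfg.fdr_cutoff,
            "n_perm": cfg.n_perm,
        },
        "qpcr_convention": cfg.qpcr_convention,
        "stages": {
            "simulate": {"n_genes": sim.n_genes, "n_samples": len(sim.sample_ids)},
            "filter": {"n_genes_kept": len(result.filtered.gene_ids)},
            "differential": {"n_de": int(result.de["passes_de"].sum())},
            "preliminary": {"up": len(result.prelim_up), "down": len(result.prelim_down)},
            "evidence": {"n_records": len(result.evidence)},
            "signature": {
                "up": result.signature_up.genes,
                "down": result.signature_down.genes,
            },
            "enrichment": {"n_sets": len(result.enrichment)},
        },
        "files": {p.name: _sha256(p) for p in files},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
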