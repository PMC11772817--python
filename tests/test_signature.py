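"""Evidence assembly and the multi-step signature integration rule."""

import dataclasses

import pandas as pd
import pytest

from secsig import (
    ConfigurationError,
    EvidenceMatrix,
    EvidenceRecord,
    RuleConfig,
    assemble_evidence,
    build_preliminary_list,
    derive_signature,
    derive_signature_down,
)
from secsig.annotation import AnnotationDB


def _db(secretome, ifn_genes):
    table = pd.DataFrame(
        [(g, "I", 2.0, "up") for g in ifn_genes],
        columns=["gene", "ifn_type", "fold_change", "direction"],
    )
    return AnnotationDB(secretome=frozenset(secretome), interferome=table)


def _de(rows):
    df = pd.DataFrame(
        {"log2fc": [v for v in rows.values()]}, index=list(rows)
    )
    df["passes_de"] = df["log2fc"].abs() >= 2.0
    df["mean_cpm_ref"] = 10.0
    df["mean_cpm_test"] = 10.0
    return df


def _rec(gene, assay, comparison, direction, magnitude=2.0, significant=True):
    return EvidenceRecord(
        gene=gene,
        assay=assay,
        comparison=comparison,
        direction=direction,
        magnitude=magnitude,
        significant=significant,
    )


def _full_support(gene):
    """Evidence rows that satisfy every step of the UP rule."""
    return [
        _rec(gene, "rnaseq", "PTR_vs_P", "up", 3.0),
        _rec(gene, "array", "PTR_vs_P", "up", 1.8),
        _rec(gene, "array", "KD_vs_PTR", "down", -1.5),
    ]


class TestPreliminaryList:
    def test_rule_conjunction(self):
        db = _db(secretome={"g1"}, ifn_genes={"g1"})
        de = _de({"g1": 3.1})
        assert build_preliminary_list(de, db) == ["g1"]

    def test_non_secretory_excluded(self):
        db = _db(secretome=set("x"), ifn_genes={"g1"})
        de = _de({"g1": 3.1})
        assert build_preliminary_list(de, db) == []

    def test_not_ifn_regulated_excluded(self):
        db = _db(secretome={"g1"}, ifn_genes=set())
        de = _de({"g1": 3.1})
        assert build_preliminary_list(de, db) == []

    def test_threshold_above_all_fold_changes_empty(self):
        db = _db(secretome={"g1"}, ifn_genes={"g1"})
        de = _de({"g1": 3.1})
        assert build_preliminary_list(de, db, tau_de=5.0) == []

    def test_down_sense_mirrors(self):
        db = _db(secretome={"g1", "g2"}, ifn_genes={"g1", "g2"})
        de = _de({"g1": 3.1, "g2": -2.5})
        assert build_preliminary_list(de, db, sense="down") == ["g2"]


class TestAssembleEvidence:
    def test_rnaseq_only_closure(self):
        ev = assemble_evidence(de=_de({"g1": 3.0, "g2": 0.5}))
        assert {r.assay for r in ev.records()} == {"rnaseq"}
        assert len(ev) == 2

    def test_array_mapping_walkthrough(self):
        fc = pd.DataFrame({"log2_ratio": [1.9], "direction": ["up"]}, index=["Lipocalin-2"])
        ev = assemble_evidence(
            array_fc={"PTR_vs_P": fc}, protein_gene_map={"Lipocalin-2": "LCN2"}
        )
        (rec,) = ev.records()
        assert rec.gene == "LCN2" and rec.modality == "proteomic" and rec.direction == "up"
        assert rec.significant  # 1.9 above the 0.58 effect floor

    def test_unmapped_target_warns_and_skips(self):
        fc = pd.DataFrame({"log2_ratio": [1.9], "direction": ["up"]}, index=["mystery"])
        with pytest.warns(UserWarning, match="mystery"):
            ev = assemble_evidence(
                array_fc={"PTR_vs_P": fc}, protein_gene_map={"other": "OTHER"}
            )
        assert len(ev) == 0

    def test_duplicate_cell_errors(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            EvidenceMatrix([_rec("g", "elisa", "PTR_vs_P", "up"),
                            _rec("g", "elisa", "PTR_vs_P", "up", 1.0)])

    def test_unchanged_cannot_be_significant(self):
        with pytest.raises(ConfigurationError):
            _rec("g", "elisa", "PTR_vs_P", "unchanged", 0.0, significant=True)


class TestDeriveSignature:
    def test_empty_matrix_empty_signature(self):
        sig = derive_signature(EvidenceMatrix(), ["g1"])
        assert sig.genes == []
        assert not sig.derivation_log.loc["g1", "in_signature"]

    def test_full_support_included(self):
        ev = EvidenceMatrix(_full_support("g1"))
        assert derive_signature(ev, ["g1"]).genes == ["g1"]

    def test_no_proteomic_confirmation_excluded(self):
        ev = EvidenceMatrix(
            [
                _rec("g1", "rnaseq", "PTR_vs_P", "up", 3.0),
                _rec("g1", "qrtpcr", "PTR_vs_P", "up", 2.0),
                _rec("g1", "qrtpcr", "KD_vs_PTR", "down", -2.0),
            ]
        )
        sig = derive_signature(ev, ["g1"])
        assert sig.genes == []
        assert not sig.derivation_log.loc["g1", "proteomic_change"]

    def test_no_kd_reversal_excluded(self):
        ev = EvidenceMatrix(
            [
                _rec("g1", "rnaseq", "PTR_vs_P", "up", 3.0),
                _rec("g1", "array", "PTR_vs_P", "up", 1.8),
                _rec("g1", "array", "KD_vs_PTR", "up", 0.9),
            ]
        )
        sig = derive_signature(ev, ["g1"])
        assert sig.genes == []
        assert not sig.derivation_log.loc["g1", "kd_reversal"]

    @pytest.mark.parametrize(
        "toggle",
        ["require_preliminary", "require_proteomic_up", "require_kd_reversal", "require_confirmation"],
    )
    def test_disabling_any_step_never_shrinks(self, toggle):
        ev = EvidenceMatrix(
            _full_support("g1")
            + [
                _rec("g2", "rnaseq", "PTR_vs_P", "up", 3.0),
                _rec("g2", "array", "PTR_vs_P", "up", 1.8),
            ]
        )
        base = set(derive_signature(ev, ["g1", "g2"]).genes)
        relaxed = set(
            derive_signature(ev, ["g1", "g2"], RuleConfig(**{toggle: False})).genes
        )
        assert base <= relaxed

    def test_adding_evidence_never_removes_member(self):
        ev = EvidenceMatrix(_full_support("g1"))
        before = derive_signature(ev, ["g1"]).genes
        ev.add(_rec("g1", "elisa", "PTR_vs_P", "up", 1.2))
        after = derive_signature(ev, ["g1"]).genes
        assert set(before) <= set(after)

    def test_strict_proteomic_kd_mode(self):
        ev = EvidenceMatrix(
            [
                _rec("g1", "rnaseq", "PTR_vs_P", "up", 3.0),
                _rec("g1", "array", "PTR_vs_P", "up", 1.8),
                _rec("g1", "qrtpcr", "KD_vs_PTR", "down", -2.0),
            ]
        )
        assert derive_signature(ev, ["g1"]).genes == ["g1"]
        strict = RuleConfig(kd_any_modality=False)
        assert derive_signature(ev, ["g1"], strict).genes == []

    def test_deterministic_alphabetical_order(self):
        ev = EvidenceMatrix(_full_support("zeta") + _full_support("alpha"))
        assert derive_signature(ev, ["zeta", "alpha"]).genes == ["alpha", "zeta"]


class TestDownSignature:
    @staticmethod
    def _flip(rec: EvidenceRecord) -> EvidenceRecord:
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        return dataclasses.replace(
            rec, direction=flip[rec.direction], magnitude=-rec.magnitude
        )

    def test_sign_flip_maps_up_onto_down_exactly(self):
        up_records = _full_support("g1") + [
            _rec("g2", "rnaseq", "PTR_vs_P", "up", 2.5),
            _rec("g2", "array", "PTR_vs_P", "up", 1.1),
        ]
        ev_up = EvidenceMatrix(up_records)
        ev_down = EvidenceMatrix([self._flip(r) for r in up_records])
        up = derive_signature(ev_up, ["g1", "g2"])
        down = derive_signature_down(ev_down, ["g1", "g2"])
        assert up.genes == down.genes
        pd.testing.assert_frame_equal(up.derivation_log, down.derivation_log)

    def test_transcript_down_without_proteomic_excluded(self):
        ev = EvidenceMatrix([_rec("g1", "rnaseq", "PTR_vs_P", "down", -2.5)])
        assert derive_signature_down(ev, ["g1"]).genes == []

    def test_up_and_down_signatures_disjoint(self):
        ev = EvidenceMatrix(
            _full_support("g1")
            + [
                _rec("g2", "rnaseq", "PTR_vs_P", "down", -3.0),
                _rec("g2", "array", "PTR_vs_P", "down", -1.8),
                _rec("g2", "array", "KD_vs_PTR", "up", 1.5),
            ]
        )
        up = derive_signature(ev, ["g1", "g2"])
        down = derive_signature_down(ev, ["g1", "g2"])
        assert not (set(up.genes) & set(down.genes))
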