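"""Contaminant screen: significance gates, A/B validation, stage order."""

import pytest

from isotriage.screen import (
    CATEGORY_ORDER,
    ContaminantEvidence,
    ScreenThresholds,
    evidence_from_hits,
    run_screen,
    significant,
    validate,
)
from isotriage.seqio import TranscriptRecord
from tests.test_hits import make_hsp


def ev(qid="q", category="chloroplast", A=350.0, identity=85.0,
       evalue=1e-30, B=None):
    return ContaminantEvidence(
        qid=qid, category=category, bitscore_A=A, identity=identity,
        evalue=evalue, bitscore_B=B,
    )


class TestSignificant:
    @pytest.mark.parametrize(
        "A, identity, evalue, expected",
        [
            (350, 85, 1e-30, True),
            (250, 95, 1e-30, False),   # bit-score gate
            (400, 75, 1e-30, False),   # identity gate
            (400, 95, 1e-5, False),    # E-value gate
            (300, 80, 1e-10, True),    # all three boundaries inclusive
        ],
    )
    def test_three_gates(self, A, identity, evalue, expected):
        assert significant(ev(A=A, identity=identity, evalue=evalue)) is expected

    def test_boundary_enumeration(self):
        """All 8 combinations of pass/fail per gate at the boundary values."""
        for a_ok in (True, False):
            for i_ok in (True, False):
                for e_ok in (True, False):
                    e = ev(
                        A=300.0 if a_ok else 299.99,
                        identity=80.0 if i_ok else 79.99,
                        evalue=1e-10 if e_ok else 1.01e-10,
                    )
                    assert significant(e) is (a_ok and i_ok and e_ok)


class TestValidate:
    @pytest.mark.parametrize(
        "A, B, decision",
        [
            (350, 320, "discard"),  # A > B
            (350, 400, "keep"),     # A < B
            (350, 350, "keep"),     # equality keeps (rule is strict A > B)
            (350, None, "discard"),  # no rescuing general-database hit
        ],
    )
    def test_four_case_enumeration(self, A, B, decision):
        assert validate(ev(A=A, B=B)).decision == decision


class TestRunScreen:
    def records(self, n=10):
        return [TranscriptRecord(f"t{i}", "ACGT" * 100) for i in range(n)]

    def test_planted_mimics_removed(self):
        records = self.records(10)
        evidence = {
            "chloroplast": [ev(qid="t0", B=300.0), ev(qid="t1", B=None)],
        }
        result = run_screen(records, evidence)
        assert len(result.clean) == 8
        assert result.per_category_counts["chloroplast"] == 2
        assert all(result.per_category_counts[c] == 0 for c in CATEGORY_ORDER[1:])

    def test_no_significant_evidence_keeps_all(self):
        records = self.records(5)
        evidence = {"fungal": [ev(qid="t0", category="fungal", A=100.0)]}
        result = run_screen(records, evidence)
        assert [r.id for r in result.clean] == [r.id for r in records]

    def test_stage_order_attribution(self):
        """A sequence significant in two categories is removed at the
        earlier stage only."""
        records = self.records(3)
        evidence = {
            "chloroplast": [ev(qid="t1", category="chloroplast")],
            "fungal": [ev(qid="t1", category="fungal")],
        }
        result = run_screen(records, evidence)
        assert result.per_category_counts == {
            "chloroplast": 1, "mitochondrion": 0, "ribosomal": 0,
            "virus_viroid_prokaryote": 0, "fungal": 0,
        }
        decision = next(d for d in result.decisions if d.qid == "t1")
        assert decision.stage == "chloroplast"

    def test_conservation_and_single_decision(self):
        records = self.records(8)
        evidence = {
            "mitochondrion": [ev(qid="t2", category="mitochondrion")],
            "ribosomal": [ev(qid="t5", category="ribosomal", B=500.0)],
        }
        result = run_screen(records, evidence)
        discarded = sum(result.per_category_counts.values())
        assert len(result.clean) + discarded == len(records)
        assert len(result.decisions) == len(records)
        assert len({d.qid for d in result.decisions}) == len(records)

    def test_unknown_qid_warns_and_is_ignored(self):
        records = self.records(2)
        evidence = {"chloroplast": [ev(qid="ghost")]}
        with pytest.warns(UserWarning, match="ghost"):
            result = run_screen(records, evidence)
        assert len(result.clean) == 2


def test_evidence_from_hits_best_hsp_scores():
    category_hits = [
        make_hsp(qid="q1", sid="cp1", bitscore=400, pident=90),
        make_hsp(qid="q1", sid="cp2", bitscore=500, pident=88),
    ]
    validation_hits = [
        make_hsp(qid="q1", sid="nr1", bitscore=450),
        make_hsp(qid="q1", sid="nr2", bitscore=420),
    ]
    (evd,) = evidence_from_hits("chloroplast", category_hits, validation_hits)
    assert evd.bitscore_A == 500 and evd.identity == 88
    assert evd.bitscore_B == 450
    # A > B here, so the screen would discard
    assert validate(evd).decision == "discard"


def test_screen_recovers_planted_contaminants(small_dataset):
    ds = small_dataset
    evidence = {
        c: evidence_from_hits(c, ds.contaminant_hits[c], ds.validation_hits)
        for c in CATEGORY_ORDER
    }
    result = run_screen(ds.transcripts, evidence)
    truth = ds.truth
    planted = truth[truth.role == "contaminant"]
    assert sum(result.per_category_counts.values()) == len(planted)
    for category, group in planted.groupby("contaminant_category"):
        assert result.per_category_counts[category] == len(group)
    clean_ids = {r.id for r in result.clean}
    assert clean_ids == set(truth[truth.role != "contaminant"].qid)
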