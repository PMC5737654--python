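"""Ordered contaminant screen with bit-score validation.

Transcripts are screened against contaminant references in a fixed stage
order — chloroplast, mitochondrion, ribosomal, virus/viroid/prokaryote,
fungal — one stage after another. A contaminant-database hit is significant
when its bit score (A) >= 300, identity >= 80% and E-value <= 1e-10
(defaults, configurable). A significant hit is then validated against a
general database: with B the best general-database bit score, the sequence
is discarded when A > B (or when no B exists), and kept otherwise. A
sequence discarded at one stage never reaches later stages.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .hits import HspRecord
from .seqio import TranscriptRecord

__all__ = [
    "CATEGORY_ORDER",
    "ContaminantEvidence",
    "ScreenDecision",
    "ScreenThresholds",
    "ScreenResult",
    "significant",
    "validate",
    "evidence_from_hits",
    "run_screen",
]

#: Fixed screening order; earlier stages claim a sequence first.
CATEGORY_ORDER: Tuple[str, ...] = (
    "chloroplast",
    "mitochondrion",
    "ribosomal",
    "virus_viroid_prokaryote",
    "fungal",
)


@dataclass(frozen=True)
class ContaminantEvidence:
    """Best contaminant-database hit of one query in one category, with the
    best general-database (validation) bit score when one exists."""

    qid: str
    category: str
    bitscore_A: float
    identity: float
    evalue: float
    bitscore_B: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_ORDER:
            raise ValueError(f"unknown contaminant category {self.category!r}")
        if self.bitscore_A <= 0:
            raise ValueError(f"{self.qid}: bitscore_A must be positive")


@dataclass(frozen=True)
class ScreenDecision:
    qid: str
    decision: str  # discard | keep
    stage: str  # a category name, or "passed_all"
    reason: str


@dataclass(frozen=True)
class ScreenThresholds:
    min_bitscore: float = 300.0
    min_identity: float = 80.0
    max_evalue: float = 1e-10

    def __post_init__(self) -> None:
        if self.min_bitscore <= 0 or self.min_identity <= 0 or self.max_evalue <= 0:
            raise ValueError("screen thresholds must be positive")


@dataclass
class ScreenResult:
    clean: List[TranscriptRecord]
    decisions: List[ScreenDecision]
    per_category_counts: Dict[str, int]

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"qid": d.qid, "stage": d.stage, "decision": d.decision,
                 "reason": d.reason}
                for d in self.decisions
            ]
        )


def significant(
    evidence: ContaminantEvidence, thresholds: ScreenThresholds = ScreenThresholds()
) -> bool:
    """True iff the contaminant hit passes all three gates:
    bit score A >= min, identity >= min, E-value <= max."""
    return (
        evidence.bitscore_A >= thresholds.min_bitscore
        and evidence.identity >= thresholds.min_identity
        and evidence.evalue <= thresholds.max_evalue
    )


def validate(evidence: ContaminantEvidence) -> ScreenDecision:
    """A-vs-B validation of a significant contaminant hit.

    Discard when the contaminant bit score beats the general-database one
    (A > B) or when no general-database hit exists; equal scores keep.
    """
    if evidence.bitscore_B is None:
        return ScreenDecision(
            qid=evidence.qid,
            decision="discard",
            stage=evidence.category,
            reason="no general-database hit to rescue the sequence",
        )
    if evidence.bitscore_A > evidence.bitscore_B:
        return ScreenDecision(
            qid=evidence.qid,
            decision="discard",
            stage=evidence.category,
            reason=(
                f"contaminant bit score {evidence.bitscore_A:g} exceeds "
                f"general-database bit score {evidence.bitscore_B:g}"
            ),
        )
    return ScreenDecision(
        qid=evidence.qid,
        decision="keep",
        stage=evidence.category,
        reason=(
            f"general-database bit score {evidence.bitscore_B:g} >= "
            f"contaminant bit score {evidence.bitscore_A:g}"
        ),
    )


def evidence_from_hits(
    category: str,
    category_hits: Iterable[HspRecord],
    validation_hits: Iterable[HspRecord] = (),
) -> List[ContaminantEvidence]:
    """Build per-query evidence from raw hit tables.

    A and B are single best-HSP bit scores (the rule is stated on raw
    search scores, not aggregates); identity and E-value come from the
    best contaminant HSP.
    """
    best_a: Dict[str, HspRecord] = {}
    for h in category_hits:
        cur = best_a.get(h.qid)
        if cur is None or h.bitscore > cur.bitscore:
            best_a[h.qid] = h
    best_b: Dict[str, float] = {}
    for h in validation_hits:
        if h.qid not in best_b or h.bitscore > best_b[h.qid]:
            best_b[h.qid] = h.bitscore
    return [
        ContaminantEvidence(
            qid=qid,
            category=category,
            bitscore_A=h.bitscore,
            identity=h.pident,
            evalue=h.evalue,
            bitscore_B=best_b.get(qid),
        )
        for qid, h in sorted(best_a.items())
    ]


def run_screen(
    records: Sequence[TranscriptRecord],
    evidence_by_category: Mapping[str, Sequence[ContaminantEvidence]],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> ScreenResult:
    """Run the five screening stages in order.

    Returns the surviving records (input order preserved), one decision per
    input record, and per-category discard counts. Evidence naming a query
    absent from ``records`` is ignored with a warning.
    """
    unknown_categories = set(evidence_by_category) - set(CATEGORY_ORDER)
    if unknown_categories:
        raise ValueError(f"unknown screen categories: {sorted(unknown_categories)}")

    by_id = {r.id: r for r in records}
    active = set(by_id)
    decisions: Dict[str, ScreenDecision] = {}
    counts = {c: 0 for c in CATEGORY_ORDER}

    for category in CATEGORY_ORDER:
        for ev in evidence_by_category.get(category, ()):
            if ev.category != category:
                raise ValueError(
                    f"evidence for {ev.qid!r} labelled {ev.category!r} listed "
                    f"under stage {category!r}"
                )
            if ev.qid not in by_id:
                warnings.warn(
                    f"screen evidence for unknown query {ev.qid!r} ignored",
                    stacklevel=2,
                )
                continue
            if ev.qid not in active:
                continue  # already discarded at an earlier stage
            if not significant(ev, thresholds):
                continue
            decision = validate(ev)
            if decision.decision == "discard":
                active.discard(ev.qid)
                decisions[ev.qid] = decision
                counts[category] += 1

    clean = [r for r in records if r.id in active]
    for r in records:
        if r.id in active:
            decisions[r.id] = ScreenDecision(
                qid=r.id, decision="keep", stage="passed_all",
                reason="no validated contaminant hit at any stage",
            )
    ordered_decisions = [decisions[r.id] for r in records]
    return ScreenResult(
        clean=clean, decisions=ordered_decisions, per_category_counts=counts
    )
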