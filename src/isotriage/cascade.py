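"""Ordered annotation cascade with a count-conserving ledger.

Transcripts are searched against a protein database first; the no-hit
remainder goes to a general nucleotide database; that remainder to a
species-specific CDS+UTR / EST stage (a hit in either table counts); and
the final remainder to an ncRNA family stage. Whatever survives all four
stages is a novel-transcript candidate. At every stage
input = hits + no-hits, and the next stage's input is exactly the previous
stage's no-hit set, so counts are conserved end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from ._util import round_half_up
from .hits import HspRecord

__all__ = [
    "STAGE_ORDER",
    "DEFAULT_STAGE_CUTOFFS",
    "StageCount",
    "TriageLedger",
    "RfamHit",
    "run_cascade",
    "hits_to_stage_table",
    "percentage",
    "ledger_report",
]

#: Fixed stage order of the cascade.
STAGE_ORDER: Tuple[str, ...] = ("nr_plant", "nt", "coffee_db", "rfam")

#: Per-stage E-value cutoffs; the ncRNA family table is taken as-is.
DEFAULT_STAGE_CUTOFFS: Dict[str, Optional[float]] = {
    "nr_plant": 1e-10,
    "nt": 1e-10,
    "coffee_db": 1e-20,
    "rfam": None,
}

#: Terminal set name per stage; the remainder is the novel-candidate set.
_FINAL_SET_BY_STAGE: Dict[str, str] = {
    "nr_plant": "tiered",
    "nt": "nt_hit",
    "coffee_db": "coffee_db_hit",
    "rfam": "ncRNA",
}


@dataclass(frozen=True)
class RfamHit:
    """One ncRNA family assignment (family accession + biotype)."""

    qid: str
    family_accession: str
    biotype: str
    evalue: float


@dataclass(frozen=True)
class StageCount:
    name: str
    input_count: int
    hit_count: int
    nohit_count: int


@dataclass
class TriageLedger:
    """Per-stage counts and the five terminal query sets.

    The terminal sets (tiered, nt_hit, coffee_db_hit, ncRNA,
    novel_candidate) partition the input queries.
    """

    stages: List[StageCount]
    sets: Dict[str, Set[str]]
    total: int

    def validate(self) -> None:
        for st in self.stages:
            if st.input_count != st.hit_count + st.nohit_count:
                raise ValueError(f"stage {st.name}: input != hit + nohit")
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.input_count != prev.nohit_count:
                raise ValueError(
                    f"stage {cur.name}: input differs from {prev.name} no-hits"
                )
        union: Set[str] = set()
        size_sum = 0
        for name, ids in self.sets.items():
            union |= ids
            size_sum += len(ids)
        if size_sum != len(union) or len(union) != self.total:
            raise ValueError("terminal sets do not partition the queries")

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "stages": [
                    {"stage": s.name, "input": s.input_count, "hits": s.hit_count,
                     "no_hits": s.nohit_count}
                    for s in self.stages
                ],
                "set_sizes": {k: len(v) for k, v in self.sets.items()},
            },
            indent=2,
        )


def hits_to_stage_table(hsps: Iterable[HspRecord]) -> List[Tuple[str, float]]:
    """Reduce a raw HSP table to (query id, E-value) pairs for the cascade."""
    return [(h.qid, h.evalue) for h in hsps]


def run_cascade(
    queries: Iterable[str],
    stage_hits: Mapping[str, Iterable[Tuple[str, float]]],
    cutoffs: Optional[Mapping[str, Optional[float]]] = None,
) -> TriageLedger:
    """Route queries through the four stages in order.

    ``stage_hits`` maps stage name to (qid, evalue) pairs; a query is a hit
    at a stage when at least one of its rows passes that stage's cutoff
    (duplicate rows are harmless). Rows naming unknown queries warn and are
    ignored.
    """
    cutoffs = dict(DEFAULT_STAGE_CUTOFFS if cutoffs is None else cutoffs)
    unknown_stages = set(stage_hits) - set(STAGE_ORDER)
    if unknown_stages:
        raise ValueError(f"unknown cascade stage(s): {sorted(unknown_stages)}")

    universe = list(dict.fromkeys(queries))
    universe_set = set(universe)

    hit_sets: Dict[str, Set[str]] = {}
    for stage in STAGE_ORDER:
        cutoff = cutoffs.get(stage)
        passing: Set[str] = set()
        n_unknown = 0
        for qid, evalue in stage_hits.get(stage, ()):
            if qid not in universe_set:
                n_unknown += 1
                continue
            if cutoff is None or evalue <= cutoff:
                passing.add(qid)
        if n_unknown:
            warnings.warn(
                f"cascade stage {stage!r}: {n_unknown} hit row(s) referencing "
                "unknown queries ignored",
                stacklevel=2,
            )
        hit_sets[stage] = passing

    stages: List[StageCount] = []
    sets: Dict[str, Set[str]] = {}
    remaining = set(universe_set)
    for stage in STAGE_ORDER:
        hits_here = hit_sets[stage] & remaining
        stages.append(
            StageCount(
                name=stage,
                input_count=len(remaining),
                hit_count=len(hits_here),
                nohit_count=len(remaining) - len(hits_here),
            )
        )
        sets[_FINAL_SET_BY_STAGE[stage]] = hits_here
        remaining -= hits_here
    sets["novel_candidate"] = remaining

    ledger = TriageLedger(stages=stages, sets=sets, total=len(universe_set))
    ledger.validate()
    return ledger


def percentage(n: int, total: int) -> float:
    """Share of ``total`` as a percentage, 2 decimals, ties rounded up."""
    if total == 0:
        raise ValueError("percentage undefined for total == 0")
    if not (0 <= n <= total):
        raise ValueError("need 0 <= n <= total")
    return round_half_up(100.0 * n / total, 2)


def ledger_report(ledger: TriageLedger) -> pd.DataFrame:
    """Per-stage table (stage, input, hits, no-hits, % of total annotated
    at that stage) in cascade order, with a final novel-candidate row.
    Stages with zero traffic are rendered, not omitted."""
    rows = []
    for st in ledger.stages:
        rows.append(
            {
                "stage": st.name,
                "input": st.input_count,
                "hits": st.hit_count,
                "no_hits": st.nohit_count,
                "percent_of_total": percentage(st.hit_count, ledger.total),
            }
        )
    novel = ledger.sets["novel_candidate"]
    rows.append(
        {
            "stage": "novel_candidate",
            "input": len(novel),
            "hits": 0,
            "no_hits": len(novel),
            "percent_of_total": percentage(len(novel), ledger.total),
        }
    )
    return pd.DataFrame(rows)
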