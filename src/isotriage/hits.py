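"""Tabular similarity-search hits: parsing, per-subject HSP aggregation,
best-subject selection, and annotation-quality tiering.

A similarity search reports one row per HSP (high-scoring segment pair).
Annotation quality is judged per (query, subject) pair by pooling all of
the subject's HSPs:

* cumulative identity ``ID = sum(identity length) / sum(aligned length)``
  over the subject's HSPs, where the identity length of an HSP is the
  number of identical columns;
* query coverage ``qcovs`` = percentage of the query covered by the union
  of the subject's HSP query intervals.

Standard 12-column tabular output does not carry the identity length, so it
is reconstructed per HSP as round-half-up(pident x length / 100); a dialect
with an explicit ``nident`` column overrides the reconstruction.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._util import interval_union_length, round_half_up

__all__ = [
    "HspRecord",
    "SubjectAggregate",
    "AnnotationTier",
    "TierThresholds",
    "DEFAULT_DIALECT",
    "parse_hits",
    "aggregate_subject",
    "aggregate_by_subject",
    "best_subject",
    "best_subjects_per_query",
    "classify_tier",
    "classify_all",
    "limit_hits",
]

#: The 12 standard tabular columns plus query length and tool query coverage.
DEFAULT_DIALECT: Tuple[str, ...] = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qlen",
    "qcovs",
)

_KNOWN_COLUMNS = set(DEFAULT_DIALECT) | {"nident"}
_REQUIRED_COLUMNS = {
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "qstart",
    "qend",
    "evalue",
    "bitscore",
    "qlen",
}


@dataclass(frozen=True)
class HspRecord:
    """One high-scoring segment pair from a tabular search report."""

    qid: str
    sid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    qcovs: Optional[float] = None
    nident: Optional[int] = None

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(
                f"HSP {self.qid}/{self.sid}: qstart {self.qstart} > qend {self.qend}"
            )
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"HSP {self.qid}/{self.sid}: pident out of [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"HSP {self.qid}/{self.sid}: negative evalue")
        if self.bitscore <= 0:
            raise ValueError(f"HSP {self.qid}/{self.sid}: non-positive bitscore")

    @property
    def identity_length(self) -> int:
        """Identical columns in this HSP (exact if nident present)."""
        if self.nident is not None:
            return self.nident
        return int(round_half_up(self.pident * self.length / 100.0, 0))


@dataclass(frozen=True)
class SubjectAggregate:
    """All HSPs of one (query, subject) pair pooled into one record."""

    qid: str
    sid: str
    identity_len_sum: int
    aligned_len_sum: int
    cumulative_identity: float
    qcovs: float
    bitscore_sum: float
    best_evalue: float


@dataclass(frozen=True)
class AnnotationTier:
    """Annotation-quality tier of one query, with the values used."""

    qid: str
    tier: str  # high | medium | low | unannotated
    qcovs: Optional[float]
    cumulative_identity: Optional[float]
    qlen: Optional[int]
    sid: Optional[str] = None


@dataclass(frozen=True)
class TierThresholds:
    """Cutoffs for the three annotation-quality tiers.

    A query is *high* when qcovs >= qcovs_high and ID >= id_high, else
    *medium* at the medium cutoffs, else *low*; queries with no passing hit
    are *unannotated*. Optional minimum-query-length gates per tier are off
    by default.
    """

    qcovs_high: float = 80.0
    id_high: float = 0.80
    qcovs_med: float = 50.0
    id_med: float = 0.50
    min_qlen_high: Optional[int] = None
    min_qlen_med: Optional[int] = None

    def __post_init__(self) -> None:
        if self.qcovs_med > self.qcovs_high or self.id_med > self.id_high:
            raise ValueError(
                "medium-tier thresholds must not exceed high-tier thresholds"
            )


def parse_hits(
    path,
    dialect: Sequence[str] = DEFAULT_DIALECT,
    max_evalue: Optional[float] = 1e-10,
) -> List[HspRecord]:
    """Parse a tab-separated hit file into HspRecords.

    Rows with E-value above ``max_evalue`` are dropped with a counted
    warning (pass ``max_evalue=None`` to keep everything). Malformed rows
    raise with the 1-based line number.
    """
    dialect = tuple(dialect)
    unknown = set(dialect) - _KNOWN_COLUMNS
    if unknown:
        raise ValueError(f"unknown hit-table column(s): {sorted(unknown)}")
    missing = _REQUIRED_COLUMNS - set(dialect)
    if missing:
        raise ValueError(f"hit-table dialect missing column(s): {sorted(missing)}")

    try:
        frame = pd.read_csv(
            path, sep="\t", names=list(dialect), header=None, comment="#", dtype=str
        )
    except pd.errors.EmptyDataError:
        return []

    records: List[HspRecord] = []
    dropped = 0
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        values = dict(zip(dialect, row))
        try:
            if any(v is None or (isinstance(v, float) and pd.isna(v)) for v in values.values()):
                raise ValueError("missing field")
            rec = HspRecord(
                qid=values["qseqid"],
                sid=values["sseqid"],
                pident=float(values["pident"]),
                length=int(values["length"]),
                mismatch=int(values.get("mismatch", 0) or 0),
                gapopen=int(values.get("gapopen", 0) or 0),
                qstart=int(values["qstart"]),
                qend=int(values["qend"]),
                sstart=int(values.get("sstart", 0) or 0),
                send=int(values.get("send", 0) or 0),
                evalue=float(values["evalue"]),
                bitscore=float(values["bitscore"]),
                qlen=int(values["qlen"]),
                qcovs=float(values["qcovs"]) if "qcovs" in values else None,
                nident=int(values["nident"]) if "nident" in values else None,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed hit row at line {idx}: {exc}") from exc
        if max_evalue is not None and rec.evalue > max_evalue:
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        warnings.warn(
            f"{path}: dropped {dropped} hit row(s) with E-value above "
            f"{max_evalue:g}",
            stacklevel=2,
        )
    return records


def aggregate_subject(
    hsps: Sequence[HspRecord], trust_qcovs: bool = False
) -> SubjectAggregate:
    """Pool all HSPs of one (query, subject) pair.

    qcovs is recomputed from the union of HSP query intervals unless
    ``trust_qcovs`` is set and the tool column is present.
    """
    if not hsps:
        raise ValueError("cannot aggregate an empty HSP list")
    qids = {h.qid for h in hsps}
    sids = {h.sid for h in hsps}
    qlens = {h.qlen for h in hsps}
    if len(qids) != 1 or len(sids) != 1 or len(qlens) != 1:
        raise ValueError("aggregate_subject requires a single (qid, sid, qlen)")
    qlen = hsps[0].qlen
    identity_len_sum = sum(h.identity_length for h in hsps)
    aligned_len_sum = sum(h.length for h in hsps)
    if trust_qcovs and hsps[0].qcovs is not None:
        qcovs = float(hsps[0].qcovs)
    else:
        union = interval_union_length((h.qstart, h.qend) for h in hsps)
        qcovs = 100.0 * union / qlen
    return SubjectAggregate(
        qid=hsps[0].qid,
        sid=hsps[0].sid,
        identity_len_sum=identity_len_sum,
        aligned_len_sum=aligned_len_sum,
        cumulative_identity=identity_len_sum / aligned_len_sum,
        qcovs=qcovs,
        bitscore_sum=sum(h.bitscore for h in hsps),
        best_evalue=min(h.evalue for h in hsps),
    )


def aggregate_by_subject(
    hsps: Iterable[HspRecord], trust_qcovs: bool = False
) -> Dict[Tuple[str, str], SubjectAggregate]:
    """Group HSPs by (query, subject) and aggregate each group."""
    groups: Dict[Tuple[str, str], List[HspRecord]] = defaultdict(list)
    for h in hsps:
        groups[(h.qid, h.sid)].append(h)
    return {
        key: aggregate_subject(group, trust_qcovs=trust_qcovs)
        for key, group in groups.items()
    }


def best_subject(aggs: Sequence[SubjectAggregate]) -> SubjectAggregate:
    """The subject with maximal cumulative bit score; ties broken by lower
    best E-value, then lexicographically smaller subject id."""
    if not aggs:
        raise ValueError("best_subject of an empty aggregate list")
    return min(aggs, key=lambda a: (-a.bitscore_sum, a.best_evalue, a.sid))


def best_subjects_per_query(
    aggs: Iterable[SubjectAggregate],
) -> Dict[str, SubjectAggregate]:
    per_query: Dict[str, List[SubjectAggregate]] = defaultdict(list)
    for a in aggs:
        per_query[a.qid].append(a)
    return {qid: best_subject(group) for qid, group in per_query.items()}


def classify_tier(
    best: Optional[SubjectAggregate],
    qlen: Optional[int],
    thresholds: TierThresholds = TierThresholds(),
) -> AnnotationTier:
    """Assign one annotation-quality tier from the best subject aggregate."""
    if best is None:
        return AnnotationTier(
            qid="", tier="unannotated", qcovs=None, cumulative_identity=None, qlen=qlen
        )
    qc, ident = best.qcovs, best.cumulative_identity
    tier = "low"
    if qc >= thresholds.qcovs_high and ident >= thresholds.id_high:
        if thresholds.min_qlen_high is None or (
            qlen is not None and qlen >= thresholds.min_qlen_high
        ):
            tier = "high"
    if tier != "high" and qc >= thresholds.qcovs_med and ident >= thresholds.id_med:
        if thresholds.min_qlen_med is None or (
            qlen is not None and qlen >= thresholds.min_qlen_med
        ):
            tier = "medium"
    return AnnotationTier(
        qid=best.qid, tier=tier, qcovs=qc, cumulative_identity=ident,
        qlen=qlen, sid=best.sid,
    )


def classify_all(
    hsps: Iterable[HspRecord],
    all_qids: Optional[Iterable[str]] = None,
    thresholds: TierThresholds = TierThresholds(),
    trust_qcovs: bool = False,
) -> List[AnnotationTier]:
    """Tier every query; queries in ``all_qids`` with no hits come out
    unannotated. Each query receives exactly one tier."""
    hsps = list(hsps)
    qlens = {h.qid: h.qlen for h in hsps}
    best = best_subjects_per_query(
        aggregate_by_subject(hsps, trust_qcovs=trust_qcovs).values()
    )
    tiers: List[AnnotationTier] = []
    ordered = list(all_qids) if all_qids is not None else sorted(best)
    for qid in ordered:
        agg = best.get(qid)
        if agg is None:
            tiers.append(
                AnnotationTier(
                    qid=qid, tier="unannotated", qcovs=None,
                    cumulative_identity=None, qlen=None,
                )
            )
        else:
            tiers.append(classify_tier(agg, qlens.get(qid), thresholds))
    return tiers


def limit_hits(hsps: Sequence[HspRecord], max_subjects: int = 50) -> List[HspRecord]:
    """Keep at most ``max_subjects`` subjects per query, ranked by the
    subject's cumulative bit score (search tools cap reported hits the same
    way)."""
    aggs = aggregate_by_subject(hsps)
    keep: Dict[str, set] = defaultdict(set)
    per_query: Dict[str, List[SubjectAggregate]] = defaultdict(list)
    for agg in aggs.values():
        per_query[agg.qid].append(agg)
    for qid, group in per_query.items():
        ranked = sorted(group, key=lambda a: (-a.bitscore_sum, a.best_evalue, a.sid))
        keep[qid] = {a.sid for a in ranked[:max_subjects]}
    return [h for h in hsps if h.sid in keep[h.qid]]
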