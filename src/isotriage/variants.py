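"""Sub-genome (homeolog) assignment and intron-retention detection.

An allopolyploid transcript can derive from either progenitor sub-genome.
Assignment compares global alignment identity of the transcript to each
progenitor reference; the higher-identity progenitor wins unless the two
identities differ by less than a margin (in percentage points), in which
case the call is ambiguous. Global (not local) identity is used because
homeolog discrimination rests on full-length divergence.

Intron retention is called per intron of a reference gene model from the
genomic intervals the transcript covers: an intron covered over at least a
threshold fraction of its length is retained. Coverage need not be
contiguous, since single-molecule reads are gap-free over retained introns
anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from Bio import Align

from ._util import covered_length_within
from .seqio import GeneModel
from .utr import make_aligner

__all__ = [
    "SubgenomeCall",
    "RetentionCall",
    "global_identity",
    "assign_subgenome",
    "detect_retention",
]


@dataclass(frozen=True)
class SubgenomeCall:
    qid: str
    identity_to_A: float  # percent
    identity_to_B: float  # percent
    call: str  # A | B | ambiguous
    margin_used: float  # percentage points


@dataclass(frozen=True)
class RetentionCall:
    qid: str
    intron: Tuple[int, int]
    fraction_covered: float
    retained: bool


def global_identity(
    seq_a: str, seq_b: str, aligner: Optional[Align.PairwiseAligner] = None
) -> float:
    """Percent identity of a global alignment: identical columns divided by
    all alignment columns (gap columns included)."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner("global")
    alignments = aligner.align(seq_a, seq_b)
    if len(alignments) == 0:
        raise ValueError("global alignment failed")
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        raise ValueError("global alignment produced no columns")
    return 100.0 * counts.identities / columns


def assign_subgenome(
    qid: str,
    transcript: str,
    ref_a: str,
    ref_b: str,
    margin: float = 0.5,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> SubgenomeCall:
    """Call the progenitor sub-genome of one transcript.

    ``margin`` is the minimum identity difference (percentage points)
    required for an unambiguous call.
    """
    if aligner is None:
        aligner = make_aligner("global")
    id_a = global_identity(transcript, ref_a, aligner)
    id_b = global_identity(transcript, ref_b, aligner)
    if abs(id_a - id_b) < margin:
        call = "ambiguous"
    else:
        call = "A" if id_a > id_b else "B"
    return SubgenomeCall(
        qid=qid, identity_to_A=id_a, identity_to_B=id_b, call=call,
        margin_used=margin,
    )


def detect_retention(
    qid: str,
    covered_blocks: Sequence[Tuple[int, int]],
    model: GeneModel,
    threshold: float = 0.95,
) -> List[RetentionCall]:
    """One RetentionCall per intron of the gene model.

    ``covered_blocks`` are the 1-based inclusive genomic intervals the
    transcript covers, sorted and non-overlapping. The fraction of each
    intron covered decides retention; a model without introns yields an
    empty list.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("retention threshold must be in (0, 1]")
    blocks = list(covered_blocks)
    for (lo, hi) in blocks:
        if lo > hi:
            raise ValueError(f"{qid}: inverted coverage block {lo}-{hi}")
    for (a, b), (c, d) in zip(blocks, blocks[1:]):
        if c <= b:
            raise ValueError(f"{qid}: coverage blocks overlap or are unsorted")
    calls: List[RetentionCall] = []
    for intron in model.introns:
        lo, hi = intron
        intron_len = hi - lo + 1
        covered = covered_length_within(blocks, lo, hi)
        fraction = covered / intron_len
        calls.append(
            RetentionCall(
                qid=qid, intron=intron, fraction_covered=fraction,
                retained=fraction >= threshold,
            )
        )
    return calls
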