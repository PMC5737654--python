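"""UTR delimitation, uORF and polyadenylation-signal scanning, and
measurement of 5'/3' extensions relative to a reference mRNA.

Full-length cDNA reads routinely extend beyond previously deposited mRNA
sequences, especially at the 5' end. The extension of a transcript over a
reference is measured from a local pairwise alignment: the transcript bases
lying outside the aligned block at each end, minus any reference bases also
unaligned at that end.

An upstream ORF (uORF) is an ATG-initiated open reading frame, with its own
in-frame stop codon, whose start lies strictly 5' of the main ORF start.
uORFs can repress translation of the main ORF, so their count in a 5'
leader is of direct regulatory interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from Bio import Align

__all__ = [
    "UorfHit",
    "UtrAnnotation",
    "make_aligner",
    "find_main_orf",
    "measure_extension",
    "scan_uorfs",
    "scan_polya_signals",
    "annotate_utrs",
]

_STOPS = {"TAA", "TAG", "TGA"}

#: Default polyadenylation signal hexamer (DNA spelling of AAUAAA).
POLYA_MOTIF = "AATAAA"


@dataclass(frozen=True)
class UorfHit:
    """One upstream ORF, 1-based inclusive transcript coordinates
    (stop codon included)."""

    start: int
    end: int
    frame: int  # start position modulo 3 relative to the transcript
    overlaps_main: bool


@dataclass(frozen=True)
class UtrAnnotation:
    """Main ORF, UTR intervals, uORFs, poly(A) signals and extensions of
    one transcript. Coordinates are 1-based inclusive on the transcript;
    poly(A) signal positions are transcript coordinates of motif starts."""

    qid: str
    main_orf: Optional[Tuple[int, int]]
    utr5: Optional[Tuple[int, int]]
    utr3: Optional[Tuple[int, int]]
    extension5: Optional[int]
    extension3: Optional[int]
    uorfs: Tuple[UorfHit, ...]
    polya_signals: Tuple[int, ...]
    reference_id: Optional[str] = None


def make_aligner(
    mode: str = "local",
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> Align.PairwiseAligner:
    """Affine-gap pairwise aligner with the package's default scoring
    (match +2, mismatch -3, gap open 5, gap extend 2, given as penalties)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def find_main_orf(seq: str) -> Optional[Tuple[int, int]]:
    """Longest ATG-initiated ORF with an in-frame stop, as (start, end)
    1-based inclusive including the stop codon; ties go to the 5'-most
    start. None when the transcript holds no complete ORF."""
    seq = seq.upper()
    n = len(seq)
    best: Optional[Tuple[int, int]] = None
    best_len = 0
    # per frame, walk codons once and pair each ATG with the next stop
    for frame in range(3):
        open_starts: List[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                open_starts.append(i)
            elif codon in _STOPS:
                if open_starts:
                    start = open_starts[0]  # 5'-most open ATG gives longest ORF
                    length = i + 3 - start
                    if length > best_len or (
                        length == best_len and best is not None and start + 1 < best[0]
                    ):
                        best = (start + 1, i + 3)
                        best_len = length
                open_starts = []
    return best


def _aligned_block(
    transcript: str,
    reference: str,
    aligner: Optional[Align.PairwiseAligner],
) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """1-based inclusive aligned span on (transcript, reference)."""
    if aligner is None:
        aligner = make_aligner("local")
    alignments = aligner.align(transcript, reference)
    if len(alignments) == 0 or alignments.score <= 0:
        raise ValueError("reference does not align to the transcript")
    aln = alignments[0]
    t_blocks, r_blocks = aln.aligned
    if len(t_blocks) == 0:
        raise ValueError("reference does not align to the transcript")
    t_span = (int(t_blocks[0][0]) + 1, int(t_blocks[-1][1]))
    r_span = (int(r_blocks[0][0]) + 1, int(r_blocks[-1][1]))
    return t_span, r_span


def measure_extension(
    transcript: str,
    reference: str,
    alignment: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Tuple[int, int]:
    """(extension5, extension3): transcript bases beyond the reference ends.

    ``alignment`` may supply a precomputed aligned block as
    ((t_start, t_end), (r_start, r_end)), 1-based inclusive; otherwise a
    local alignment is computed with the default scoring. Extensions are
    clipped at zero: a transcript that starts inside the reference has no
    5' extension.
    """
    if alignment is None:
        t_span, r_span = _aligned_block(transcript, reference, aligner)
    else:
        t_span, r_span = alignment
    ext5 = max(0, (t_span[0] - 1) - (r_span[0] - 1))
    ext3 = max(0, (len(transcript) - t_span[1]) - (len(reference) - r_span[1]))
    return ext5, ext3


def scan_uorfs(
    seq: str,
    main_orf: Tuple[int, int],
    min_len_nt: int = 9,
    allow_overlap_main: bool = True,
) -> List[UorfHit]:
    """All uORFs starting strictly 5' of the main ORF start.

    Each ATG upstream of the main start that reaches an in-frame stop within
    the transcript, with total length (stop included) >= ``min_len_nt``,
    yields one hit. Hits whose stop lies at or beyond the main start are
    flagged as overlapping and dropped when ``allow_overlap_main`` is False.
    """
    seq = seq.upper()
    main_start = main_orf[0]
    hits: List[UorfHit] = []
    for i in range(main_start - 1):  # 0-based ATG candidates upstream of main
        if seq[i : i + 3] != "ATG":
            continue
        end = None
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in _STOPS:
                end = j + 3
                break
        if end is None:
            continue
        if end - i < min_len_nt:
            continue
        overlaps = end >= main_start
        if overlaps and not allow_overlap_main:
            continue
        hits.append(
            UorfHit(start=i + 1, end=end, frame=i % 3, overlaps_main=overlaps)
        )
    return hits


def scan_polya_signals(
    utr3_seq: str, motifs: Sequence[str] | str = POLYA_MOTIF
) -> List[int]:
    """1-based start positions of polyadenylation-signal motifs, ascending;
    overlapping occurrences are all reported."""
    if isinstance(motifs, str):
        motifs = [motifs]
    seq = utr3_seq.upper()
    positions: List[int] = []
    for motif in motifs:
        motif = motif.upper().replace("U", "T")
        start = seq.find(motif)
        while start != -1:
            positions.append(start + 1)
            start = seq.find(motif, start + 1)
    return sorted(set(positions))


def annotate_utrs(
    qid: str,
    seq: str,
    reference: Optional[str] = None,
    reference_id: Optional[str] = None,
    min_uorf_len: int = 9,
    allow_overlap_main: bool = True,
    polya_motifs: Sequence[str] | str = POLYA_MOTIF,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> UtrAnnotation:
    """Full per-transcript UTR annotation.

    Delimits the main ORF and UTRs, scans the leader for uORFs and the
    3' UTR for polyadenylation signals (positions reported in transcript
    coordinates), and, when a reference mRNA is given, measures the 5'/3'
    extensions over it.
    """
    orf = find_main_orf(seq)
    if orf is None:
        utr5 = utr3 = None
        uorfs: Tuple[UorfHit, ...] = ()
        polya: Tuple[int, ...] = ()
    else:
        start, end = orf
        utr5 = (1, start - 1) if start > 1 else None
        utr3 = (end + 1, len(seq)) if end < len(seq) else None
        uorfs = tuple(
            scan_uorfs(seq, orf, min_len_nt=min_uorf_len,
                       allow_overlap_main=allow_overlap_main)
        )
        if utr3 is not None:
            local = scan_polya_signals(seq[utr3[0] - 1 :], polya_motifs)
            polya = tuple(p + utr3[0] - 1 for p in local)
        else:
            polya = ()
    if reference is not None:
        ext5, ext3 = measure_extension(seq, reference, aligner=aligner)
    else:
        ext5 = ext3 = None
    return UtrAnnotation(
        qid=qid,
        main_orf=orf,
        utr5=utr5,
        utr3=utr3,
        extension5=ext5,
        extension3=ext3,
        uorfs=uorfs,
        polya_signals=polya,
        reference_id=reference_id,
    )
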