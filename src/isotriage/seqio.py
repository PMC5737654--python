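"""Sequence and gene-model I/O, plus the raw length filter.

Coordinate convention used throughout the package: 1-based inclusive
intervals, matching BLAST tabular output and the way gene structures are
reported in the literature. Any half-open arithmetic is internal only.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptRecord",
    "GeneModel",
    "DuplicateIdError",
    "read_fasta",
    "write_fasta",
    "length_filter",
    "load_gene_model",
]

_RNA_TO_DNA = str.maketrans("Uu", "Tt")


class DuplicateIdError(ValueError):
    """Raised when a FASTA file contains the same identifier twice."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One full-length isoform sequence.

    The sequence alphabet is DNA (U is mapped to T on read) and may include
    IUPAC ambiguity codes; ``length`` is always the number of characters.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of a reference locus, introns derived from the gaps.

    Exons are 1-based inclusive genomic intervals, stored sorted ascending
    regardless of strand. Consecutive exons must be separated by at least one
    intronic base.
    """

    id: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene model {self.id!r} has no exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        for lo, hi in exons:
            if lo > hi:
                raise ValueError(f"gene model {self.id!r}: exon {lo}-{hi} inverted")
        for (_, prev_hi), (lo, _) in zip(exons, exons[1:]):
            if lo <= prev_hi:
                raise ValueError(f"gene model {self.id!r}: exons overlap or are unsorted")
            if lo - prev_hi < 2:
                raise ValueError(
                    f"gene model {self.id!r}: adjacent exons leave no intron"
                )

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (prev_hi + 1, lo - 1)
            for (_, prev_hi), (lo, _) in zip(self.exons, self.exons[1:])
        )


def read_fasta(path: str | os.PathLike) -> List[TranscriptRecord]:
    """Read a FASTA file into TranscriptRecords, in file order.

    Sequences are uppercased and U mapped to T. Duplicate identifiers are an
    error; an empty file yields an empty list with a warning.
    """
    records: List[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().translate(_RNA_TO_DNA)
        records.append(TranscriptRecord(id=rec.id, seq=seq))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(
    records: Iterable[TranscriptRecord], path: str | os.PathLike, width: int = 60
) -> None:
    """Write records as multi-line FASTA wrapped at ``width`` columns."""
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(
            SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
        )


def length_filter(
    records: Sequence[TranscriptRecord], min_len: int = 300
) -> Tuple[List[TranscriptRecord], List[TranscriptRecord]]:
    """Partition records into (kept, removed) by minimum length.

    Records shorter than ``min_len`` are removed; a record of exactly
    ``min_len`` bases is kept. Input order is preserved in both outputs.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in records if r.length >= min_len]
    removed = [r for r in records if r.length < min_len]
    return kept, removed


def _gene_model_from_bed12(path: str | os.PathLike, locus_id: str) -> GeneModel:
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}: BED12 requires 12 columns, got {len(fields)}")
            name = fields[3]
            if name != locus_id:
                continue
            chrom_start = int(fields[1])
            strand = fields[5]
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(f"{path}: block columns disagree with blockCount")
            exons = tuple(
                (chrom_start + s + 1, chrom_start + s + sz)
                for s, sz in zip(starts, sizes)
            )
            return GeneModel(id=locus_id, strand=strand, exons=exons)
    raise KeyError(f"locus {locus_id!r} not found in {path}")


def _gene_model_from_gff3(path: str | os.PathLike, locus_id: str) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    exons = []
    strand = None
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent", [])
        if locus_id in parents:
            exons.append((feat.start, feat.end))
            strand = feat.strand
    if not exons:
        try:
            db[locus_id]
        except Exception:
            raise KeyError(f"locus {locus_id!r} not found in {path}") from None
        raise KeyError(f"locus {locus_id!r} has no exon children in {path}")
    exons.sort()
    return GeneModel(id=locus_id, strand=strand or "+", exons=tuple(exons))


def load_gene_model(
    path: str | os.PathLike, locus_id: str, fmt: Optional[str] = None
) -> GeneModel:
    """Load one locus from a GFF3 or BED12 file as a GeneModel.

    ``fmt`` is "gff3" or "bed12"; when omitted it is inferred from the file
    extension (.gff/.gff3 vs .bed).
    """
    if fmt is None:
        suffix = Path(path).suffix.lower()
        if suffix in {".gff", ".gff3"}:
            fmt = "gff3"
        elif suffix in {".bed", ".bed12"}:
            fmt = "bed12"
        else:
            raise ValueError(
                f"cannot infer gene-model format from {path}; pass fmt="
            )
    if fmt == "gff3":
        return _gene_model_from_gff3(path, locus_id)
    if fmt == "bed12":
        return _gene_model_from_bed12(path, locus_id)
    raise ValueError(f"unknown gene model format {fmt!r}")
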