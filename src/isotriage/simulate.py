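"""Seeded synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the statistical shape of a full-length isoform
dataset — transcript lengths spanning roughly 300 bp to 23 kb, GC near 41%,
a small admixture of organellar/ribosomal/fungal contaminant mimics with
matching hit tables, annotation hit tables whose per-subject aggregates
land on planted annotation tiers, and case-study transcripts carrying
planted 5' UTR extensions, uORFs, polyadenylation signals, retained
introns, and progenitor sub-genome copies.

Every planted feature is recorded in a ground-truth table so each pipeline
stage can be tested as a parameter-recovery loop. Case-study leaders and
UTR filler are drawn from a C/T alphabet, which makes planted ATG and
AATAAA counts exact by construction (no accidental motifs); divergence is
substitution-only by default so identity arithmetic stays exact.

All randomness flows from one integer seed; regenerating with the same
configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hits import HspRecord, DEFAULT_DIALECT
from .cascade import RfamHit
from .screen import CATEGORY_ORDER
from .seqio import GeneModel, TranscriptRecord, write_fasta

__all__ = [
    "SimConfig",
    "UtrCase",
    "RetentionCase",
    "SubgenomeCase",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_progenitor_pair",
    "mutate_sequence",
]

_BASES = np.array(list("ACGT"))
_CT = np.array(list("CT"))

#: One planted uORF: own start, one codon, own in-frame stop (9 nt).
UORF_UNIT = "ATGGCCTAA"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic dataset.

    Defaults mirror the dataset the pipeline is designed for: lengths
    301-23,335 bp, GC 41.4%, sequencing error 1% (99%-accuracy reads),
    progenitor divergences 0.01 and 0.10 substitutions/site, planted uORF
    counts 0..12, and two polyadenylation signals in the two-signal case.
    """

    seed: int = 0
    n_transcripts: int = 60
    length_range: Tuple[int, int] = (301, 23_335)
    gc_target: float = 41.4
    n_contaminants: Mapping[str, int] = field(
        default_factory=lambda: {
            "chloroplast": 2,
            "mitochondrion": 2,
            "ribosomal": 1,
            "virus_viroid_prokaryote": 0,
            "fungal": 1,
        }
    )
    n_nt_only: int = 3
    n_coffee_only: int = 2
    n_ncrna: int = 1
    n_novel: int = 2
    tier_fractions: Tuple[float, float, float] = (0.40, 0.15, 0.45)
    d_A: float = 0.01
    d_B: float = 0.10
    sequencing_error: float = 0.01
    uorf_counts: Tuple[int, ...] = tuple(range(13))
    extension5_case_bp: int = 136
    n_polya_signals: int = 2
    n_retention_cases: int = 2
    n_subgenome_cases: int = 6
    spurious_hit_rate: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 30 or hi <= lo:
            raise ValueError("length_range must satisfy 30 <= lo < hi")
        if not (0.0 < self.gc_target < 100.0):
            raise ValueError("gc_target is a percentage in (0, 100)")
        for rate in (self.d_A, self.d_B):
            if not (0.0 <= rate < 0.5):
                raise ValueError("divergence rates must lie in [0, 0.5)")
        if not (0.0 <= self.sequencing_error <= 1.0):
            raise ValueError("sequencing_error must lie in [0, 1]")
        if not (0.0 <= self.spurious_hit_rate <= 1.0):
            raise ValueError("spurious_hit_rate must lie in [0, 1]")
        unknown = set(self.n_contaminants) - set(CATEGORY_ORDER)
        if unknown:
            raise ValueError(f"unknown contaminant categories: {sorted(unknown)}")
        n_special = (
            sum(self.n_contaminants.values())
            + self.n_nt_only + self.n_coffee_only + self.n_ncrna + self.n_novel
        )
        if n_special > self.n_transcripts:
            raise ValueError(
                "n_transcripts too small for the planted contaminant and "
                "cascade-set counts"
            )
        for k in self.uorf_counts:
            if k < 0:
                raise ValueError("uORF counts must be non-negative")


@dataclass(frozen=True)
class UtrCase:
    """One planted case transcript with its reference and truth."""

    transcript: TranscriptRecord
    reference: TranscriptRecord
    extension5: int
    extension3: int
    n_uorfs: int
    utr5_len: int
    polya_positions: Tuple[int, ...]  # transcript coordinates
    main_orf: Tuple[int, int]


@dataclass(frozen=True)
class RetentionCase:
    qid: str
    model: GeneModel
    covered_blocks: Tuple[Tuple[int, int], ...]
    retained_introns: Tuple[bool, ...]


@dataclass(frozen=True)
class SubgenomeCase:
    qid: str
    ref_a: TranscriptRecord
    ref_b: TranscriptRecord
    transcript: TranscriptRecord
    origin: str  # A | B


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, plus the planted truth."""

    config: SimConfig
    transcripts: List[TranscriptRecord]
    contaminant_hits: Dict[str, List[HspRecord]]
    validation_hits: List[HspRecord]
    stage_hits: Dict[str, List[HspRecord]]
    rfam_hits: List[RfamHit]
    truth: pd.DataFrame
    utr_cases: List[UtrCase]
    retention_cases: List[RetentionCase]
    subgenome_cases: List[SubgenomeCase]

    def write(self, outdir: str | Path) -> None:
        """Write the dataset in the same dialects the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.transcripts, outdir / "transcripts.fasta")
        hits_dir = outdir / "hits"
        hits_dir.mkdir(exist_ok=True)
        for category, rows in self.contaminant_hits.items():
            _write_hits(rows, hits_dir / f"contam_{category}.tsv")
        _write_hits(self.validation_hits, hits_dir / "validation.tsv")
        for stage, rows in self.stage_hits.items():
            _write_hits(rows, hits_dir / f"stage_{stage}.tsv")
        with open(hits_dir / "stage_rfam.tsv", "w") as fh:
            for r in self.rfam_hits:
                fh.write(f"{r.qid}\t{r.family_accession}\t{r.biotype}\t{r.evalue:g}\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

        cases = outdir / "cases"
        cases.mkdir(exist_ok=True)
        if self.utr_cases:
            write_fasta([c.transcript for c in self.utr_cases], cases / "utr_transcripts.fasta")
            write_fasta([c.reference for c in self.utr_cases], cases / "utr_references.fasta")
            pd.DataFrame(
                [
                    {
                        "qid": c.transcript.id,
                        "reference_id": c.reference.id,
                        "extension5": c.extension5,
                        "extension3": c.extension3,
                        "n_uorfs": c.n_uorfs,
                        "utr5_len": c.utr5_len,
                        "polya_positions": ",".join(map(str, c.polya_positions)),
                    }
                    for c in self.utr_cases
                ]
            ).to_csv(cases / "utr_truth.tsv", sep="\t", index=False)
        if self.subgenome_cases:
            write_fasta([c.transcript for c in self.subgenome_cases], cases / "subgenome_transcripts.fasta")
            write_fasta(
                [c.ref_a for c in self.subgenome_cases]
                + [c.ref_b for c in self.subgenome_cases],
                cases / "subgenome_references.fasta",
            )
            pd.DataFrame(
                [
                    {"qid": c.qid, "ref_a": c.ref_a.id, "ref_b": c.ref_b.id,
                     "origin": c.origin}
                    for c in self.subgenome_cases
                ]
            ).to_csv(cases / "subgenome_truth.tsv", sep="\t", index=False)
        if self.retention_cases:
            _write_retention_cases(self.retention_cases, cases)
        manifest = {
            "seed": self.config.seed,
            "n_transcripts": self.config.n_transcripts,
            "length_range": list(self.config.length_range),
            "gc_target": self.config.gc_target,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _write_hits(rows: Sequence[HspRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for h in rows:
            fh.write(
                "\t".join(
                    [
                        h.qid, h.sid, f"{h.pident:.2f}", str(h.length),
                        str(h.mismatch), str(h.gapopen), str(h.qstart),
                        str(h.qend), str(h.sstart), str(h.send),
                        f"{h.evalue:g}", f"{h.bitscore:.1f}", str(h.qlen),
                        f"{h.qcovs:.1f}" if h.qcovs is not None else "0.0",
                    ]
                )
                + "\n"
            )


def _write_retention_cases(cases: Sequence[RetentionCase], outdir: Path) -> None:
    # GFF3 gene models and BED coverage blocks
    with open(outdir / "gene_models.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for c in cases:
            m = c.model
            span_lo = m.exons[0][0]
            span_hi = m.exons[-1][1]
            fh.write(
                f"chr1\tsim\tgene\t{span_lo}\t{span_hi}\t.\t{m.strand}\t.\tID={m.id}\n"
            )
            for i, (lo, hi) in enumerate(m.exons, 1):
                fh.write(
                    f"chr1\tsim\texon\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                    f"ID={m.id}.exon{i};Parent={m.id}\n"
                )
    with open(outdir / "coverage_blocks.bed", "w") as fh:
        for c in cases:
            for lo, hi in c.covered_blocks:
                fh.write(f"chr1\t{lo - 1}\t{hi}\t{c.qid}\n")
    pd.DataFrame(
        [
            {
                "qid": c.qid,
                "model_id": c.model.id,
                "intron_index": i,
                "retained": int(flag),
            }
            for c in cases
            for i, flag in enumerate(c.retained_introns)
        ]
    ).to_csv(outdir / "retention_truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence-level helpers


def _random_seq(rng: np.random.Generator, length: int, gc_percent: float) -> str:
    g = gc_percent / 200.0
    a = (100.0 - gc_percent) / 200.0
    return "".join(rng.choice(_BASES, size=length, p=[a, g, g, a]))


def _ct_filler(rng: np.random.Generator, length: int) -> str:
    """A/G-free filler: cannot contain ATG, stop codons or AATAAA."""
    if length <= 0:
        return ""
    return "".join(rng.choice(_CT, size=length))


def _orf_body(rng: np.random.Generator, n_codons: int) -> str:
    """ORF interior over {A,C,G}: T-free, hence free of internal ATG and
    stop codons in every reading frame."""
    return "".join(rng.choice(np.array(list("ACG")), size=3 * n_codons))


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    """Substitution-only mutation at the given per-site rate."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    if mask.any():
        for idx in np.nonzero(mask)[0]:
            choices = [b for b in "ACGT" if b != arr[idx]]
            arr[idx] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_progenitor_pair(
    ancestral_len: int,
    d_a: float,
    d_b: float,
    seed: int | np.random.Generator,
    sequencing_error: float = 0.01,
    gc_percent: float = 41.4,
) -> Tuple[str, str, str]:
    """(refA, refB, transcript-from-A) modelling an allopolyploid gene.

    refA and refB are independently mutated copies of one random ancestor
    at per-site rates ``d_a`` and ``d_b``; the transcript is a near-exact
    copy of refA carrying the sequencing-error rate.
    """
    if ancestral_len <= 0:
        raise ValueError("ancestral length must be positive")
    for rate in (d_a, d_b):
        if not (0.0 <= rate < 0.5):
            raise ValueError("divergence rates must lie in [0, 0.5)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ancestor = _random_seq(rng, ancestral_len, gc_percent)
    ref_a = mutate_sequence(ancestor, d_a, rng)
    ref_b = mutate_sequence(ancestor, d_b, rng)
    transcript = mutate_sequence(ref_a, sequencing_error, rng)
    return ref_a, ref_b, transcript


# ---------------------------------------------------------------------------
# hit-table construction


def _bitscore(rng: np.random.Generator, length: int, pident: float) -> float:
    """Monotone in length x identity with small additive noise; planted
    winners stay unambiguous because competitors differ by far more."""
    return round(1.8 * length * pident / 100.0 + float(rng.normal(0.0, 1.0)), 1)


def _tier_hsps(
    rng: np.random.Generator, qid: str, sid: str, qlen: int, tier: str
) -> List[HspRecord]:
    if tier == "high":
        # two HSPs, union covering ~92% of the query at ~96% identity
        b1 = (1, int(qlen * 0.55))
        b2 = (int(qlen * 0.50), int(qlen * 0.92))
        pident = 96.0
        blocks = [b1, b2]
    elif tier == "medium":
        blocks = [(1, int(qlen * 0.60))]
        pident = 65.0
    else:  # low
        blocks = [(1, max(30, int(qlen * 0.20)))]
        pident = 40.0
    out = []
    for qstart, qend in blocks:
        length = qend - qstart + 1
        out.append(
            HspRecord(
                qid=qid, sid=sid, pident=pident, length=length,
                mismatch=int(length * (100 - pident) / 100), gapopen=0,
                qstart=qstart, qend=qend, sstart=1, send=length,
                evalue=1e-50, bitscore=_bitscore(rng, length, pident),
                qlen=qlen,
            )
        )
    return out


def _simple_hit(
    rng: np.random.Generator, qid: str, sid: str, qlen: int,
    pident: float = 90.0, cover: float = 0.5, evalue: float = 1e-30,
) -> HspRecord:
    length = max(30, int(qlen * cover))
    return HspRecord(
        qid=qid, sid=sid, pident=pident, length=length,
        mismatch=int(length * (100 - pident) / 100), gapopen=0,
        qstart=1, qend=length, sstart=1, send=length,
        evalue=evalue, bitscore=_bitscore(rng, length, pident), qlen=qlen,
    )


# ---------------------------------------------------------------------------
# case-study construction


def _build_utr_case(
    rng: np.random.Generator,
    qid: str,
    ref_id: str,
    n_uorfs: int,
    ext5: Optional[int],
    ext3: int,
    n_polya: int,
) -> UtrCase:
    ref_utr5 = _ct_filler(rng, 60)
    body = _orf_body(rng, 149)  # 447 nt interior
    orf = "ATG" + body + "TAA"
    ref_utr3 = _ct_filler(rng, 90)
    reference = ref_utr5 + orf + ref_utr3

    # leader: planted uORF units separated by C/T filler
    parts = [_ct_filler(rng, 20)]
    for _ in range(n_uorfs):
        parts.append(UORF_UNIT)
        parts.append(_ct_filler(rng, int(rng.integers(5, 12))))
    leader = "".join(parts)
    if ext5 is not None:
        if ext5 < len(leader):
            raise ValueError(
                f"requested 5' extension {ext5} bp cannot hold {n_uorfs} uORFs"
            )
        leader = leader + _ct_filler(rng, ext5 - len(leader))

    # 3' extension with planted AATAAA signals
    tail_parts = [_ct_filler(rng, 25)]
    polya_local: List[int] = []
    for _ in range(n_polya):
        polya_local.append(sum(len(p) for p in tail_parts) + 1)
        tail_parts.append("AATAAA")
        tail_parts.append(_ct_filler(rng, int(rng.integers(8, 20))))
    tail = "".join(tail_parts)
    if ext3 > len(tail):
        tail = tail + _ct_filler(rng, ext3 - len(tail))
    transcript = leader + reference + tail

    orf_start = len(leader) + len(ref_utr5) + 1
    orf_end = orf_start + len(orf) - 1
    polya_transcript = tuple(
        len(leader) + len(reference) + p for p in polya_local
    )
    return UtrCase(
        transcript=TranscriptRecord(id=qid, seq=transcript),
        reference=TranscriptRecord(id=ref_id, seq=reference),
        extension5=len(leader),
        extension3=len(tail),
        n_uorfs=n_uorfs,
        utr5_len=orf_start - 1,
        polya_positions=polya_transcript,
        main_orf=(orf_start, orf_end),
    )


def _build_retention_case(
    rng: np.random.Generator, qid: str, index: int, retained: Tuple[bool, ...]
) -> RetentionCase:
    offset = 1 + 2000 * index
    exon_lens = (200, 150, 250)
    intron_lens = (100, 120)
    exons = []
    pos = offset
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    model = GeneModel(id=f"locus_{index}", strand="+", exons=tuple(exons))
    blocks: List[Tuple[int, int]] = []
    for i, exon in enumerate(model.exons):
        if blocks and retained[i - 1]:
            # previous intron retained: fuse with the previous block
            blocks[-1] = (blocks[-1][0], exon[1])
        else:
            blocks.append(exon)
    return RetentionCase(
        qid=qid, model=model, covered_blocks=tuple(blocks),
        retained_introns=tuple(retained),
    )


# ---------------------------------------------------------------------------
# main entry point


def simulate_dataset(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """Generate one complete synthetic dataset with ground truth.

    The main transcript set carries planted contaminants (with matching
    contaminant and validation hit tables) and planted annotation-cascade
    terminal sets (with matching per-stage hit tables); the case bundle
    carries planted UTR, retention and sub-genome features.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range

    n = config.n_transcripts
    roles: List[Tuple[str, Optional[str]]] = []
    for category in CATEGORY_ORDER:
        roles += [("contaminant", category)] * config.n_contaminants.get(category, 0)
    roles += [("nt_hit", None)] * config.n_nt_only
    roles += [("coffee_db_hit", None)] * config.n_coffee_only
    roles += [("ncRNA", None)] * config.n_ncrna
    roles += [("novel_candidate", None)] * config.n_novel
    n_tiered = n - len(roles)
    f_high, f_med, f_low = config.tier_fractions
    n_high = int(round(n_tiered * f_high))
    n_med = int(round(n_tiered * f_med))
    n_low = n_tiered - n_high - n_med
    roles += [("high", None)] * n_high + [("medium", None)] * n_med + [("low", None)] * n_low
    order = rng.permutation(len(roles))
    roles = [roles[i] for i in order]

    # log-uniform lengths within the configured range
    lengths = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=n)
    ).astype(int)
    lengths = np.clip(lengths, lo, hi)

    transcripts: List[TranscriptRecord] = []
    contaminant_hits: Dict[str, List[HspRecord]] = {c: [] for c in CATEGORY_ORDER}
    validation_hits: List[HspRecord] = []
    stage_hits: Dict[str, List[HspRecord]] = {"nr_plant": [], "nt": [], "coffee_db": []}
    rfam_hits: List[RfamHit] = []
    truth_rows = []

    for i, ((role, category), qlen) in enumerate(zip(roles, lengths)):
        qid = f"iso_{i:05d}"
        qlen = int(qlen)
        transcripts.append(
            TranscriptRecord(id=qid, seq=_random_seq(rng, qlen, config.gc_target))
        )
        tier = ""
        cascade_set = ""
        if role == "contaminant":
            hit_len = max(250, int(qlen * 0.6))
            pident = float(85.0 + rng.uniform(0, 10))
            a_score = max(320.0, _bitscore(rng, hit_len, pident))
            contaminant_hits[category].append(
                HspRecord(
                    qid=qid, sid=f"{category}_ref", pident=pident, length=hit_len,
                    mismatch=int(hit_len * (100 - pident) / 100), gapopen=0,
                    qstart=1, qend=min(hit_len, qlen), sstart=1, send=hit_len,
                    evalue=1e-80, bitscore=a_score, qlen=qlen,
                )
            )
            b_score = max(50.0, a_score - float(rng.uniform(20, 80)))
            validation_hits.append(
                HspRecord(
                    qid=qid, sid="general_db_subject", pident=80.0, length=hit_len,
                    mismatch=int(hit_len * 0.2), gapopen=0,
                    qstart=1, qend=min(hit_len, qlen), sstart=1, send=hit_len,
                    evalue=1e-40, bitscore=b_score, qlen=qlen,
                )
            )
        elif role in {"high", "medium", "low"}:
            tier = role
            cascade_set = "tiered"
            stage_hits["nr_plant"].extend(
                _tier_hsps(rng, qid, f"prot_{i:05d}", qlen, role)
            )
        elif role == "nt_hit":
            cascade_set = "nt_hit"
            stage_hits["nt"].append(
                _simple_hit(rng, qid, f"nt_{i:05d}", qlen, evalue=1e-30)
            )
        elif role == "coffee_db_hit":
            cascade_set = "coffee_db_hit"
            stage_hits["coffee_db"].append(
                _simple_hit(rng, qid, f"cds_{i:05d}", qlen, evalue=1e-40)
            )
        elif role == "ncRNA":
            cascade_set = "ncRNA"
            rfam_hits.append(
                RfamHit(qid=qid, family_accession="RF00012", biotype="snoRNA",
                        evalue=1e-12)
            )
        elif role == "novel_candidate":
            cascade_set = "novel_candidate"

        if config.spurious_hit_rate > 0 and rng.random() < config.spurious_hit_rate:
            # weak off-target row the parser must drop at the E-value gate
            stage_hits["nr_plant"].append(
                _simple_hit(
                    rng, qid, "spurious_subject", qlen, pident=30.0,
                    cover=0.05, evalue=1e-5,
                )
            )

        truth_rows.append(
            {
                "qid": qid,
                "length": qlen,
                "role": role,
                "contaminant_category": category or "",
                "screen_decision": "discard" if role == "contaminant" else "keep",
                "cascade_set": cascade_set,
                "tier": tier,
            }
        )

    # case bundle ----------------------------------------------------------
    utr_cases: List[UtrCase] = []
    for j, k in enumerate(config.uorf_counts):
        utr_cases.append(
            _build_utr_case(
                rng, qid=f"case_uorf_{k:02d}_{j}", ref_id=f"ref_uorf_{k:02d}_{j}",
                n_uorfs=k, ext5=None, ext3=40, n_polya=1,
            )
        )
    # the headline extension case: a long planted 5' leader, two signals
    utr_cases.append(
        _build_utr_case(
            rng, qid="case_ext5", ref_id="ref_ext5", n_uorfs=0,
            ext5=config.extension5_case_bp, ext3=60,
            n_polya=config.n_polya_signals,
        )
    )

    retention_cases: List[RetentionCase] = []
    for j in range(config.n_retention_cases):
        flags = (j % 2 == 0, False)  # alternate retained/not on intron 1
        retention_cases.append(
            _build_retention_case(rng, qid=f"case_ret_{j}", index=j, retained=flags)
        )

    subgenome_cases: List[SubgenomeCase] = []
    for j in range(config.n_subgenome_cases):
        origin = "A" if j % 2 == 0 else "B"
        ref_a, ref_b, _ = simulate_progenitor_pair(
            600, config.d_A, config.d_B, rng,
            sequencing_error=config.sequencing_error,
            gc_percent=config.gc_target,
        )
        source = ref_a if origin == "A" else ref_b
        transcript = mutate_sequence(source, config.sequencing_error, rng)
        subgenome_cases.append(
            SubgenomeCase(
                qid=f"case_sub_{j}",
                ref_a=TranscriptRecord(id=f"refA_{j}", seq=ref_a),
                ref_b=TranscriptRecord(id=f"refB_{j}", seq=ref_b),
                transcript=TranscriptRecord(id=f"case_sub_{j}", seq=transcript),
                origin=origin,
            )
        )

    return SimulatedDataset(
        config=config,
        transcripts=transcripts,
        contaminant_hits=contaminant_hits,
        validation_hits=validation_hits,
        stage_hits=stage_hits,
        rfam_hits=rfam_hits,
        truth=pd.DataFrame(truth_rows),
        utr_cases=utr_cases,
        retention_cases=retention_cases,
        subgenome_cases=subgenome_cases,
    )
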