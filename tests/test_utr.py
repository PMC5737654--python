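"""ORF finding, uORF and poly(A)-signal scanning, extension measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isotriage.utr import (
    annotate_utrs,
    find_main_orf,
    measure_extension,
    scan_polya_signals,
    scan_uorfs,
)

_STOPS = {"TAA", "TAG", "TGA"}


def brute_orfs(seq):
    """Exhaustive oracle: every (ATG, first in-frame stop) pair."""
    seq = seq.upper()
    orfs = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in _STOPS:
                orfs.append((i + 1, j + 3))
                break
    return orfs


def brute_main_orf(seq):
    orfs = brute_orfs(seq)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o[1] - o[0], -o[0]))


class TestFindMainOrf:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ATGAAATAA", (1, 9)),
            ("CCCCCC", None),
            # 30-mer ORF beats a 9-mer ORF downstream
            ("ATG" + "AAA" * 8 + "TAA" + "CC" + "ATGAAATAA", (1, 30)),
        ],
    )
    def test_examples(self, seq, expected):
        assert find_main_orf(seq) == expected

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(10, 2000))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert find_main_orf(seq) == brute_main_orf(seq)


class TestScanUorfs:
    def test_single_planted_uorf(self):
        seq = "ATGTAA" + "ATG" + "GGG" * 20 + "TAA"
        main = find_main_orf(seq)
        assert main == (7, 72)
        hits = scan_uorfs(seq, main, min_len_nt=6)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 6)

    def test_empty_leader_no_uorfs(self):
        seq = "ATG" + "GGG" * 20 + "TAA"
        assert scan_uorfs(seq, find_main_orf(seq)) == []

    def test_atg_without_stop_not_counted(self):
        # leader ATG has no in-frame stop anywhere in the transcript
        seq = "ATGCC" + "C" * 30 + "ATGGGGTAA"
        main = find_main_orf(seq)
        hits = scan_uorfs(seq, main, min_len_nt=6)
        assert all(h.start != 1 for h in hits)

    def test_min_length_gate(self):
        seq = "ATGTAA" + "CT" * 5 + "ATG" + "GGG" * 20 + "TAA"
        main = find_main_orf(seq)
        assert len(scan_uorfs(seq, main, min_len_nt=6)) == 1
        assert len(scan_uorfs(seq, main, min_len_nt=9)) == 0

    def test_overlap_flag_and_drop(self):
        # out-of-frame leader ATG whose first stop lies inside the main ORF
        seq = "CCATGCC" + "ATGGTAACAGGATAA"
        main = find_main_orf(seq)
        assert main == (8, 22)
        hits = scan_uorfs(seq, main, min_len_nt=6, allow_overlap_main=True)
        overlapping = [h for h in hits if h.overlaps_main]
        assert overlapping
        kept = scan_uorfs(seq, main, min_len_nt=6, allow_overlap_main=False)
        assert not any(h.overlaps_main for h in kept)

    @given(st.text(alphabet="CT", min_size=0, max_size=60))
    @settings(deadline=None)
    def test_count_monotone_under_leader_extension(self, prefix):
        """Extending the 5' leader never loses uORFs (C/T prefix keeps the
        main ORF and existing uORFs in place)."""
        base = "ATGTAACT" + "ATG" + "GGG" * 30 + "TAA"
        extended = prefix + base
        main_base = find_main_orf(base)
        main_ext = find_main_orf(extended)
        n_base = len(scan_uorfs(base, main_base, min_len_nt=6))
        n_ext = len(scan_uorfs(extended, main_ext, min_len_nt=6))
        assert n_ext >= n_base


class TestPolyaSignals:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("CCAATAAAGG", [3]),
            ("AATAAACCAATAAA", [1, 9]),
            ("CCCCCC", []),
            ("AATAAATAAA", [1, 5]),  # overlapping motifs reported at each start
        ],
    )
    def test_examples(self, seq, expected):
        assert scan_polya_signals(seq) == expected

    def test_rna_motif_spelling_accepted(self):
        assert scan_polya_signals("CCAATAAAGG", motifs="AAUAAA") == [3]


class TestMeasureExtension:
    def test_constructed_prefix_extension(self):
        ref = "ATGGCTGCTGCAGCAGGATAACCTCCT"
        transcript = "N" * 100 + ref
        assert measure_extension(transcript, ref) == (100, 0)

    def test_identity_property(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 400))))
            assert measure_extension(seq, seq) == (0, 0)

    def test_suffix_extension(self):
        ref = "ATGGCTGCTGCAGCAGGATAACCTCCT"
        transcript = ref + "N" * 55
        assert measure_extension(transcript, ref) == (0, 55)

    def test_precomputed_alignment_accepted(self):
        ext = measure_extension("A" * 200, "A" * 100,
                                alignment=((101, 200), (1, 100)))
        assert ext == (100, 0)

    def test_unalignable_reference_errors(self):
        with pytest.raises(ValueError):
            measure_extension("AAAAAAAAAA", "CCCCCCCCCC")


def test_annotate_utrs_full_report(small_dataset):
    """Planted case transcripts: ORF, uORF count, signals, extensions all
    recovered from sequence alone."""
    for case in small_dataset.utr_cases:
        ann = annotate_utrs(
            case.transcript.id, case.transcript.seq, case.reference.seq
        )
        assert ann.main_orf == case.main_orf
        assert len(ann.uorfs) == case.n_uorfs
        assert ann.polya_signals == case.polya_positions
        assert abs(ann.extension5 - case.extension5) <= 2
        assert abs(ann.extension3 - case.extension3) <= 2
        if ann.utr5:
            assert ann.utr5[1] == ann.main_orf[0] - 1
        if ann.utr3:
            assert ann.utr3[0] == ann.main_orf[1] + 1
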