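"""Hit parsing, HSP aggregation, best-subject selection, tiering."""

import pytest
from hypothesis import given, settings, strategies as st

from isotriage._util import interval_union_length
from isotriage.hits import (
    DEFAULT_DIALECT,
    HspRecord,
    TierThresholds,
    aggregate_by_subject,
    aggregate_subject,
    best_subject,
    classify_all,
    classify_tier,
    limit_hits,
    parse_hits,
)


def make_hsp(qid="q", sid="s", pident=90.0, length=100, qstart=1, qend=100,
             evalue=1e-50, bitscore=200.0, qlen=1000, **kw):
    return HspRecord(
        qid=qid, sid=sid, pident=pident, length=length, mismatch=0, gapopen=0,
        qstart=qstart, qend=qend, sstart=1, send=length, evalue=evalue,
        bitscore=bitscore, qlen=qlen, **kw,
    )


def hit_line(qid="q1", sid="s1", pident=97.5, length=100, qstart=1, qend=100,
             evalue="1e-50", bitscore=180.3, qlen=500, qcovs=20.0):
    return "\t".join(
        map(str, [qid, sid, pident, length, 2, 0, qstart, qend, 1, length,
                  evalue, bitscore, qlen, qcovs])
    )


class TestParseHits:
    def test_single_valid_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(hit_line() + "\n")
        records = parse_hits(p)
        assert len(records) == 1
        assert records[0].qid == "q1" and records[0].pident == 97.5

    def test_evalue_gate_drops_with_warning(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(hit_line(evalue="1e-5") + "\n" + hit_line() + "\n")
        with pytest.warns(UserWarning, match="dropped 1"):
            records = parse_hits(p, max_evalue=1e-10)
        assert len(records) == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        assert parse_hits(p) == []

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(hit_line() + "\nnot\ta\tvalid\trow\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_hits(p)

    def test_unknown_column_rejected(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(hit_line() + "\n")
        with pytest.raises(ValueError, match="unknown"):
            parse_hits(p, dialect=list(DEFAULT_DIALECT) + ["bogus"])


class TestAggregate:
    def test_cumulative_identity_hand_sums(self):
        hsps = [
            make_hsp(pident=90, length=100, qstart=1, qend=100),
            make_hsp(pident=90, length=50, qstart=200, qend=249),
        ]
        agg = aggregate_subject(hsps)
        assert agg.identity_len_sum == 135
        assert agg.aligned_len_sum == 150
        assert agg.cumulative_identity == pytest.approx(0.90)

    def test_single_perfect_hsp(self):
        agg = aggregate_subject([make_hsp(pident=100, length=100)])
        assert agg.cumulative_identity == 1.0

    def test_qcovs_from_interval_union(self):
        hsps = [
            make_hsp(qstart=1, qend=300, length=300),
            make_hsp(qstart=251, qend=500, length=250),
        ]
        agg = aggregate_subject(hsps)
        assert agg.qcovs == pytest.approx(50.0)  # union 500 of qlen 1000

    def test_nident_column_overrides_reconstruction(self):
        agg = aggregate_subject([make_hsp(pident=90, length=100, nident=93)])
        assert agg.identity_len_sum == 93

    def test_trust_qcovs_passthrough(self):
        agg = aggregate_subject([make_hsp(qcovs=42.0)], trust_qcovs=True)
        assert agg.qcovs == 42.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_subject([])

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=900),
                st.integers(min_value=1, max_value=100),
                st.floats(min_value=0, max_value=100),
            ),
            min_size=1,
            max_size=10,
        )
    )
    @settings(deadline=None)
    def test_cumulative_identity_is_length_weighted_mean(self, spans):
        hsps = [
            make_hsp(pident=p, length=ln, qstart=qs, qend=qs + ln - 1)
            for qs, ln, p in spans
        ]
        agg = aggregate_subject(hsps)
        # weighted-mean oracle, using the same per-HSP identity lengths
        weights = [h.length for h in hsps]
        idents = [h.identity_length / h.length for h in hsps]
        oracle = sum(w * x for w, x in zip(weights, idents)) / sum(weights)
        assert agg.cumulative_identity == pytest.approx(oracle)

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=900),
                st.integers(min_value=1, max_value=100),
            ),
            min_size=1,
            max_size=10,
        ),
        st.tuples(st.integers(min_value=1, max_value=900),
                  st.integers(min_value=1, max_value=100)),
    )
    @settings(deadline=None)
    def test_qcovs_monotone_under_added_hsp(self, spans, extra):
        def build(pairs):
            return [
                make_hsp(qstart=qs, qend=qs + ln - 1, length=ln)
                for qs, ln in pairs
            ]

        before = aggregate_subject(build(spans)).qcovs
        after = aggregate_subject(build(spans + [extra])).qcovs
        assert after >= before - 1e-12


class TestBestSubject:
    def test_max_bitscore_wins(self):
        aggs = list(aggregate_by_subject(
            [make_hsp(sid="s1", bitscore=500), make_hsp(sid="s2", bitscore=300)]
        ).values())
        assert best_subject(aggs).sid == "s1"

    def test_tie_broken_by_evalue_then_sid(self):
        aggs = list(aggregate_by_subject(
            [make_hsp(sid="s1", bitscore=300, evalue=1e-20),
             make_hsp(sid="s2", bitscore=300, evalue=1e-50)]
        ).values())
        assert best_subject(aggs).sid == "s2"
        tied = list(aggregate_by_subject(
            [make_hsp(sid="sb", bitscore=300), make_hsp(sid="sa", bitscore=300)]
        ).values())
        assert best_subject(tied).sid == "sa"


class TestTiers:
    def test_high_under_defaults(self):
        agg = aggregate_subject(
            [make_hsp(pident=95, length=900, qstart=1, qend=900, qlen=1000)]
        )
        assert classify_tier(agg, 1000).tier == "high"

    def test_low_when_sparse(self):
        agg = aggregate_subject(
            [make_hsp(pident=30, length=100, qstart=1, qend=100, qlen=1000)]
        )
        assert classify_tier(agg, 1000).tier == "low"

    def test_no_hit_is_unannotated(self):
        assert classify_tier(None, 500).tier == "unannotated"

    def test_inconsistent_thresholds_rejected(self):
        with pytest.raises(ValueError):
            TierThresholds(qcovs_high=50, qcovs_med=80)

    def test_tier_partition_counts(self, small_dataset):
        ds = small_dataset
        tiered_truth = ds.truth[ds.truth.tier != ""]
        tiers = classify_all(ds.stage_hits["nr_plant"])
        by_tier = {t.qid: t.tier for t in tiers}
        # every query with >=1 passing hit gets exactly one of the 3 tiers
        assert sum(t.tier in {"high", "medium", "low"} for t in tiers) == len(tiers)
        for row in tiered_truth.itertuples():
            assert by_tier[row.qid] == row.tier


def test_limit_hits_caps_subjects_per_query():
    hsps = [make_hsp(sid=f"s{i}", bitscore=100 + i) for i in range(10)]
    kept = limit_hits(hsps, max_subjects=3)
    assert {h.sid for h in kept} == {"s9", "s8", "s7"}


def brute_union(intervals):
    covered = set()
    for lo, hi in intervals:
        covered.update(range(lo, hi + 1))
    return len(covered)


@given(
    st.lists(
        st.tuples(st.integers(min_value=1, max_value=400),
                  st.integers(min_value=1, max_value=400)),
        max_size=12,
    )
)
@settings(deadline=None)
def test_interval_union_matches_enumeration(intervals):
    assert interval_union_length(intervals) == brute_union(
        [(min(a, b), max(a, b)) for a, b in intervals]
    )
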