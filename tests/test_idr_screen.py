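import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from galphase import (DisorderTrack, ProteinRecord, ScreenConfig, classify,
                      composition, extract_idrs, run_screen, summarize)
from galphase.core_io import AlignmentError
from galphase.idr_screen import (PROTEOME_AROMATIC_FREQS, PipelineError,
                                 ScreenClassification, round_percentage)


def brute_force_idrs(scores, threshold, min_len):
    """Oracle: maximal qualifying runs by checking every (start, end) pair."""
    n = len(scores)
    runs = []
    for i in range(n):
        for j in range(i, n):
            if all(scores[k] >= threshold for k in range(i, j + 1)) \
                    and (i == 0 or scores[i - 1] < threshold) \
                    and (j == n - 1 or scores[j + 1] < threshold) \
                    and (j - i + 1) > min_len:
                runs.append((i + 1, j + 1))
    return runs


def make_track(scores, seq=None):
    seq = seq or "G" * len(scores)
    record = ProteinRecord(id="t", sequence=seq)
    return DisorderTrack(record_id="t", scores=tuple(scores)), record


class TestExtractIdrs:
    def test_whole_sequence_run(self, record_with_track):
        record, track = record_with_track
        segs = extract_idrs(track, record)
        assert [(s.start, s.end) for s in segs] == [(1, 60)]
        assert segs[0].subsequence == record.sequence

    def test_all_low_scores_yield_nothing(self):
        track, record = make_track([0.0] * 80)
        assert extract_idrs(track, record) == []

    def test_strictly_greater_than_length_rule(self):
        # runs of exactly 50 and of 51 separated by one low residue
        scores = [1.0] * 50 + [0.0] + [1.0] * 51
        track, record = make_track(scores)
        segs = extract_idrs(track, record)
        assert [(s.start, s.end) for s in segs] == [(52, 102)]

    def test_misaligned_track_rejected(self):
        record = ProteinRecord(id="t", sequence="G" * 10)
        track = DisorderTrack(record_id="t", scores=(1.0,) * 9)
        with pytest.raises(AlignmentError):
            extract_idrs(track, record)

    def test_oracle_equivalence_on_random_tracks(self):
        """Fast scan equals brute-force maximal-run enumeration."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 120))
            scores = rng.random(n).round(2)
            thr = float(rng.choice([0.3, 0.5, 0.7]))
            min_len = int(rng.integers(1, 15))
            cfg = ScreenConfig(disorder_threshold=thr, min_idr_length=min_len)
            track, record = make_track(scores.tolist())
            got = [(s.start, s.end) for s in extract_idrs(track, record, cfg)]
            assert got == brute_force_idrs(scores.tolist(), thr, min_len)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.sampled_from([0.0, 0.4, 0.5, 0.6, 1.0]),
                min_size=1, max_size=150),
       st.integers(min_value=1, max_value=20))
def test_threshold_and_length_monotonicity(scores, min_len):
    """Raising the disorder cutoff never increases IDR coverage; raising
    the length cutoff never increases segment count."""
    track, record = make_track(scores)
    lo = extract_idrs(track, record, ScreenConfig(disorder_threshold=0.4,
                                                  min_idr_length=min_len))
    hi = extract_idrs(track, record, ScreenConfig(disorder_threshold=0.6,
                                                  min_idr_length=min_len))
    assert sum(len(s) for s in hi) <= sum(len(s) for s in lo)
    longer = extract_idrs(track, record,
                          ScreenConfig(disorder_threshold=0.4,
                                       min_idr_length=min_len + 5))
    assert len(longer) <= len(lo)


class TestComposition:
    def test_ntd_like_census(self):
        """100 residues, two Asp, nothing else charged or aromatic — the
        composition signature of galectin-3's N-terminal domain."""
        seq = "D" + "G" * 50 + "D" + "G" * 48
        prof = composition(seq)
        assert (prof.n_negative, prof.n_positive, prof.n_aromatic) == (2, 0, 0)
        assert prof.f_negative == pytest.approx(0.02)
        assert prof.net_charge == -2

    @pytest.mark.parametrize("seq,expect", [
        ("WFY", dict(n_aromatic=3, f_aromatic=1.0)),
        ("WW" + "G" * 18, dict(n_aromatic=2, f_aromatic=0.10)),
        ("XXGG", dict(n_total=4, n_aromatic=0)),  # X counted only in total
        ("HHKD", dict(n_his=2, n_positive=1, n_negative=1, net_charge=0)),
    ])
    def test_census_cases(self, seq, expect):
        prof = composition(seq)
        for key, value in expect.items():
            assert getattr(prof, key) == pytest.approx(value)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition("")

    @settings(max_examples=60, deadline=None)
    @given(st.text(st.sampled_from("ACDEFGHIKLMNPQRSTVWYX"),
                   min_size=1, max_size=200))
    def test_count_conservation(self, seq):
        """Class counts plus unclassified residues always sum to n_total."""
        prof = composition(seq)
        unclassified = sum(1 for a in seq if a not in "WFYKRDEH")
        assert (prof.n_aromatic + prof.n_positive + prof.n_negative
                + prof.n_his + unclassified) == prof.n_total


class TestClassify:
    def _segment_for(self, seq):
        record = ProteinRecord(id="t", sequence=seq)
        track = DisorderTrack(record_id="t", scores=(1.0,) * len(seq))
        return record, extract_idrs(track, record)

    def test_ntd_pattern_net_negative_and_sparse(self):
        seq = "D" + "G" * 50 + "D" + "G" * 48
        record, segs = self._segment_for(seq)
        cls = classify(record, segs)
        assert cls.charge_class == "net_negative"
        assert cls.negative_sparse is True
        assert cls.aromatic_rich is False

    def test_no_segments_leaves_flags_unset(self):
        record = ProteinRecord(id="t", sequence="G" * 10)
        cls = classify(record, [])
        assert cls.has_long_idr is False
        assert cls.aromatic_rich is None and cls.charge_class is None

    def test_equal_charges_is_balanced(self):
        seq = "K" * 5 + "D" * 5 + "G" * 90
        record, segs = self._segment_for(seq)
        assert classify(record, segs).charge_class == "balanced"

    def test_strict_boundaries_not_rich_not_sparse(self):
        # exactly 9/100 aromatic and exactly 3/100 negative sit on the
        # thresholds and must not qualify
        seq = "W" * 9 + "D" * 3 + "G" * 88  # f_arom = 0.09, f_neg = 0.03
        record, segs = self._segment_for(seq)
        cls = classify(record, segs)
        assert cls.aromatic_rich is False
        assert cls.negative_sparse is False

    def test_foreign_segment_rejected(self):
        record = ProteinRecord(id="a", sequence="G" * 60)
        other = ProteinRecord(id="b", sequence="G" * 60)
        track = DisorderTrack(record_id="b", scores=(1.0,) * 60)
        segs = extract_idrs(track, other)
        with pytest.raises(ValueError):
            classify(record, segs)


class TestSummarize:
    @staticmethod
    def _cls(i, charge_class, sparse=None, rich=False, idr=True):
        if not idr:
            return ScreenClassification(record_id=f"r{i}", has_long_idr=False)
        return ScreenClassification(record_id=f"r{i}", has_long_idr=True,
                                    aromatic_rich=rich,
                                    charge_class=charge_class,
                                    negative_sparse=sparse)

    def test_cohort_percentages_match_published_style(self):
        """720 net-negative of 1263 -> 57.0%; 480 sparse of 720 -> 66.7%."""
        cls = [self._cls(i, "net_negative", sparse=(i < 480))
               for i in range(720)]
        cls += [self._cls(720 + i, "net_positive") for i in range(300)]
        cls += [self._cls(1020 + i, "balanced") for i in range(243)]
        summary = summarize(cls)
        assert summary.n_long_idr == 1263
        assert summary.pct_net_negative == 57.0
        assert summary.pct_negative_sparse == 66.7
        assert (summary.n_net_negative + summary.n_net_positive
                + summary.n_balanced) == summary.n_long_idr

    def test_all_positive_cohort(self):
        summary = summarize([self._cls(i, "net_positive") for i in range(10)])
        assert summary.pct_net_negative == 0.0
        assert summary.pct_negative_sparse is None  # no negatives at all

    def test_zero_long_idr_percentages_undefined(self):
        summary = summarize([self._cls(0, None, idr=False)])
        assert summary.n_long_idr == 0
        assert summary.pct_net_negative is None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


def test_round_percentage_half_away_from_zero():
    assert round_percentage(1, 16) == 6.3  # 6.25 rounds up, not to even
    assert round_percentage(716, 1263) == 56.7


def test_aromatic_cutoff_is_sum_of_proteome_frequencies():
    """The 9% aromatic-richness cutoff is W 1.5% + Y 3.5% + F 4.0%."""
    assert ScreenConfig().aromatic_rich_threshold == pytest.approx(
        sum(PROTEOME_AROMATIC_FREQS.values()))
    assert ScreenConfig().aromatic_rich_threshold == pytest.approx(0.09)


class TestRunScreen:
    def test_records_without_tracks_skipped(self, record_with_track):
        record, track = record_with_track
        orphan = ProteinRecord(id="orphan", sequence="G" * 30)
        cls, summary, table = run_screen([record, orphan],
                                         {record.id: track})
        assert summary.n_screened == 1
        assert len(table) == 1

    def test_no_tracks_at_all_is_pipeline_error(self):
        record = ProteinRecord(id="a", sequence="G" * 30)
        with pytest.raises(PipelineError):
            run_screen([record], {})

    def test_rerun_is_deterministic(self, record_with_track):
        record, track = record_with_track
        out1 = run_screen([record], {record.id: track})
        out2 = run_screen([record], {record.id: track})
        assert out1[1] == out2[1] and out1[2] == out2[2]
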