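"""Epoch detection rules: peaks, widths, power gate, growth, masks, picks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seizefeat.detect import (
    DetectionParams,
    EpochSet,
    SeizureEpoch,
    detect,
    epoch_power,
    find_onset_peaks,
    grow_and_merge,
    make_mask,
    mask_to_epochs,
    picks_to_epochs,
    width_filter,
)
from seizefeat.feature import FeatureSignal, build_feature_signal

FS = 256.0


def make_feature(envelope, gain=300.0):
    """FeatureSignal from a constructed [0,1] envelope; filtered_avg scaled
    so that genuine onset peaks clear the default power threshold."""
    envelope = np.asarray(envelope, dtype=np.float64)
    return FeatureSignal(
        envelope=envelope,
        filtered_avg=envelope * gain,
        norm_factor=gain,
        fs=FS,
    )


def gaussian_bump(t_total_s, center_s, height=0.95, fwhm_s=1.0, base=0.0):
    t = np.arange(int(t_total_s * FS)) / FS
    sigma = fwhm_s / 2.35482
    return base + height * np.exp(-((t - center_s) ** 2) / (2 * sigma**2))


class TestFindOnsetPeaks:
    def test_flat_envelope_has_no_peaks(self):
        assert find_onset_peaks(make_feature(np.full(5000, 0.2))) == []

    def test_gaussian_bump_width_matches_fwhm(self):
        fx = make_feature(gaussian_bump(20, 10.0))
        cands = [c for c in find_onset_peaks(fx) if c.is_onset]
        assert len(cands) == 1
        assert cands[0].width_s == pytest.approx(1.0, rel=0.05)
        assert cands[0].height == pytest.approx(0.95, abs=0.01)

    def test_two_bumps_found_at_their_centers(self):
        env = gaussian_bump(30, 10.0) + gaussian_bump(30, 20.0)
        cands = [c for c in find_onset_peaks(make_feature(env)) if c.is_onset]
        centers = sorted(c.index / FS for c in cands)
        assert np.allclose(centers, [10.0, 20.0], atol=0.05)

    def test_sub_upper_peaks_kept_as_evidence_only(self):
        fx = make_feature(gaussian_bump(20, 10.0, height=0.5))
        cands = find_onset_peaks(fx)
        assert len(cands) == 1 and not cands[0].is_onset


class TestWidthFilter:
    @pytest.mark.parametrize(
        "width_s,kept", [(1.0, True), (0.3, False), (2.5, False), (0.5, True), (1.7, True)]
    )
    def test_duration_rule(self, width_s, kept):
        fx = make_feature(gaussian_bump(30, 15.0, fwhm_s=width_s))
        cands = width_filter(find_onset_peaks(fx))
        assert bool(cands) == kept


class TestEpochPower:
    def test_zero_signal(self):
        assert epoch_power(np.zeros(1000), 0, 1000, FS) == 0.0

    def test_constant_one_over_two_seconds(self):
        assert epoch_power(np.ones(512), 0, 512, FS) == pytest.approx(2.0)

    def test_unit_sine_over_two_seconds(self):
        t = np.arange(512) / FS
        x = np.sin(2 * np.pi * 4 * t)
        assert epoch_power(x, 0, 512, FS) == pytest.approx(1.0, rel=0.01)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            epoch_power(np.ones(100), 50, 50, FS)


class TestGrowAndMerge:
    def test_candidate_grows_to_supra_threshold_region(self):
        env = np.full(int(120 * FS), 0.02)
        lo, hi = int(40 * FS), int(80 * FS)  # 40 s plateau
        env[lo:hi] = 0.4
        env[int(41 * FS) : int(42 * FS)] = 1.0  # onset peak inside
        fx = make_feature(env)
        cands = [c for c in find_onset_peaks(fx) if c.is_onset]
        es = grow_and_merge(cands, fx)
        assert len(es) == 1
        assert es.epochs[0].start == pytest.approx(lo, abs=2)
        assert es.epochs[0].end == pytest.approx(hi, abs=2)

    def test_nearby_regions_merge(self):
        env = np.full(int(60 * FS), 0.02)
        env[int(20 * FS) : int(25 * FS)] = 0.4
        env[int(25.5 * FS) : int(30 * FS)] = 0.4  # 0.5 s gap < 1 s
        env[int(21 * FS) : int(21.5 * FS)] = 1.0
        env[int(26 * FS) : int(26.5 * FS)] = 1.0
        fx = make_feature(env)
        cands = [c for c in find_onset_peaks(fx) if c.is_onset]
        es = grow_and_merge(cands, fx)
        assert len(es) == 1
        assert es.epochs[0].end - es.epochs[0].start >= int(9.5 * FS)

    def test_region_shorter_than_minimum_discarded(self):
        env = np.full(int(30 * FS), 0.02)
        env[int(15 * FS) : int(15.5 * FS)] = 1.0  # 0.5 s < seizLinterval
        fx = make_feature(env)
        cands = [c for c in find_onset_peaks(fx) if c.is_onset]
        assert len(grow_and_merge(cands, fx)) == 0


class TestDetectEndToEnd:
    def test_all_zero_feature_detects_nothing(self):
        assert len(detect(make_feature(np.zeros(10000)))) == 0

    def test_injected_seizure_recovered(self, seizure_record, seizure_feature):
        _, ann = seizure_record
        es = detect(seizure_feature)
        assert len(es) == 1
        (a, b) = es.intervals_s()[0]
        e = ann.entries[0]
        assert a < e.end_s and e.onset_s < b

    def test_artefact_only_record_stays_clean(self, quiet_record):
        rec, _ = quiet_record
        es = detect(build_feature_signal(rec))
        assert len(es) == 0

    def test_monotone_in_amp_lower_and_aggressiveness(self, seizure_feature, quiet_record):
        feats = [seizure_feature, build_feature_signal(quiet_record[0])]
        for fx in feats:
            counts = [
                len(detect(fx, DetectionParams(amp_lower=v)))
                for v in (0.05, 0.075, 0.2, 0.5)
            ]
            assert counts == sorted(counts, reverse=True)
            counts = [
                len(detect(fx, DetectionParams(seizAggressiveness=v)))
                for v in (0.0, 200.0, 1e4, 1e9)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_shift_equivariance(self):
        env = gaussian_bump(60, 20.0)
        k = 500
        fx = make_feature(env)
        shifted = make_feature(np.concatenate([np.zeros(k), env[:-k]]))
        a = detect(fx).epochs
        b = detect(shifted).epochs
        assert len(a) == len(b) == 1
        assert b[0].start - a[0].start == k
        assert b[0].end - a[0].end == k

    def test_gain_invariance_with_power_gate_disabled(self, seizure_record, seizure_feature):
        rec, _ = seizure_record
        params = DetectionParams(seizAggressiveness=0.0)
        scaled = build_feature_signal(rec.copy_with(rec.data * 3.7))
        a = [(e.start, e.end) for e in detect(seizure_feature, params).epochs]
        b = [(e.start, e.end) for e in detect(scaled, params).epochs]
        assert a == b


class TestMask:
    def test_empty_epochs_give_zero_mask(self):
        es = EpochSet(epochs=[], n_samples=100, fs=FS)
        assert make_mask(es).sum() == 0

    def test_mask_counts_epoch_samples(self):
        es = EpochSet(
            epochs=[SeizureEpoch(10, 20, 1.0, 1.0, 0.0)], n_samples=30, fs=FS
        )
        mask = make_mask(es)
        assert mask.sum() == 10 and mask[9] == 0 and mask[10] == 1 and mask[19] == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 480), st.integers(1, 20)), min_size=0, max_size=6
        )
    )
    def test_mask_interval_roundtrip(self, raw):
        mask = np.zeros(500, dtype=np.int8)
        for start, length in raw:
            mask[start : start + length] = 1
        es = mask_to_epochs(mask, FS)
        assert np.array_equal(make_mask(es), mask)


class TestPicks:
    def picks_feature(self, dur_s=430.0):
        return make_feature(np.full(int(dur_s * FS), 0.1))

    def test_table_style_pick_pair_becomes_95s_epoch(self):
        es = picks_to_epochs([326.0, 421.0], self.picks_feature())
        assert len(es) == 1
        assert es.epochs[0].duration_s(FS) == pytest.approx(95.0, abs=0.01)

    def test_no_picks_no_epochs(self):
        assert len(picks_to_epochs([], self.picks_feature(10))) == 0

    def test_sub_duration_pick_flagged_not_a_seizure(self):
        assert len(picks_to_epochs([10.0, 10.2], self.picks_feature(20))) == 0

    def test_odd_or_unsorted_picks_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            picks_to_epochs([1.0, 2.0, 3.0], self.picks_feature(10))
        with pytest.raises(ValueError, match="ascending"):
            picks_to_epochs([5.0, 2.0], self.picks_feature(10))
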