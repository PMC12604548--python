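"""Pupil preprocessing contracts: blink handling, filtering, exclusion, PPD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aveffort.pupil import (
    EmptyDatasetError,
    PupilTrace,
    apply_exclusions,
    average_trace,
    baseline_correct,
    baseline_correct_stack,
    detect_blinks,
    interpolate_invalid,
    lowpass_filter,
    pad_and_stack,
    peak_pupil_dilation,
    process_pupil_trials,
)


def make_trace(samples, fs=1200.0, valid=None, meta=None):
    samples = np.asarray(samples, float)
    if valid is None:
        valid = np.ones(len(samples), bool)
    return PupilTrace(
        time_s=np.arange(len(samples)) / fs,
        samples=samples,
        fs=fs,
        valid_mask=valid,
        meta=meta or {"subject": "S01", "modality": "AO", "snr_db": -4.0},
    )


class TestDetectBlinks:
    def test_constant_trace_flags_nothing(self):
        tr = detect_blinks(make_trace(np.ones(1200)))
        assert tr.valid_mask.all()

    def test_single_spike_invalidates_361_samples_at_1200hz(self):
        """One extreme sample plus 150 ms padding on both sides at 1200 Hz is
        exactly 180 + 1 + 180 = 361 invalid samples (spike z-score ~34.6)."""
        x = np.ones(1200)
        x[600] = 100.0
        tr = detect_blinks(make_trace(x))
        assert (~tr.valid_mask).sum() == 361
        assert not tr.valid_mask[600 - 180 : 600 + 181].any()

    def test_nearby_spikes_merge_into_one_invalid_run(self):
        x = np.ones(2400)
        x[1000] = 50.0
        x[1120] = 50.0  # 100 ms later; +/-150 ms windows overlap
        tr = detect_blinks(make_trace(x))
        invalid = np.flatnonzero(~tr.valid_mask)
        assert np.all(np.diff(invalid) == 1)  # one contiguous run
        assert invalid[0] == 1000 - 180 and invalid[-1] == 1120 + 180

    def test_mean_and_sd_computed_over_whole_trial_once(self):
        # a modest outlier whose z-score w.r.t. the spike-inflated SD is < 3
        # must NOT be flagged, confirming the non-iterative single pass
        x = np.ones(1200)
        x[100] = 100.0  # huge spike inflates SD to ~2.86
        x[700] = 6.0  # |6 - 1.08| / 2.86 ~ 1.7 < 3
        tr = detect_blinks(make_trace(x))
        assert tr.valid_mask[700]

    def test_preexisting_invalid_samples_stay_invalid(self):
        valid = np.ones(1200, bool)
        valid[10:20] = False
        tr = detect_blinks(make_trace(np.ones(1200), valid=valid))
        assert not tr.valid_mask[10:20].any()

    def test_nan_with_zero_variance_rejected(self):
        x = np.ones(100)
        x[50] = np.nan
        with pytest.raises(ValueError, match="zero-variance"):
            detect_blinks(make_trace(x))


class TestInterpolation:
    def test_linear_fill_between_anchors(self):
        x = np.array([1.0, 0.0, 0.0, 0.0, 2.0])
        valid = np.array([True, False, False, False, True])
        tr = interpolate_invalid(make_trace(x, fs=10.0, valid=valid))
        assert np.allclose(tr.samples, [1.0, 1.25, 1.5, 1.75, 2.0])
        assert tr.interp_fraction == pytest.approx(3 / 5)

    def test_clean_trace_unchanged(self):
        tr = interpolate_invalid(make_trace(np.arange(10.0), fs=10.0))
        assert np.allclose(tr.samples, np.arange(10.0))
        assert tr.interp_fraction == 0.0

    def test_leading_run_filled_with_nearest_valid_constant(self):
        x = np.zeros(15)
        x[10:] = 2.0
        valid = np.zeros(15, bool)
        valid[10:] = True
        tr = interpolate_invalid(make_trace(x, fs=10.0, valid=valid))
        assert np.allclose(tr.samples[:10], 2.0)

    def test_all_invalid_trace_unusable(self):
        with pytest.raises(ValueError, match="unusable"):
            interpolate_invalid(make_trace(np.zeros(10), fs=10.0, valid=np.zeros(10, bool)))

    def test_detect_then_interpolate_idempotent_on_clean_trace(self):
        t = np.arange(1200) / 1200.0
        x = 3.5 + 0.1 * np.sin(2 * np.pi * 0.4 * t)
        once = interpolate_invalid(detect_blinks(make_trace(x)))
        twice = interpolate_invalid(detect_blinks(once))
        assert np.allclose(once.samples, twice.samples)
        assert twice.interp_fraction == once.interp_fraction


class TestLowpass:
    def test_dc_gain_unity(self):
        tr = lowpass_filter(make_trace(np.full(2400, 5.0)))
        assert np.allclose(tr.samples, 5.0, atol=1e-8)

    def test_slow_oscillation_preserved(self):
        t = np.arange(12000) / 1200.0
        tr = lowpass_filter(make_trace(np.sin(2 * np.pi * 0.1 * t)))
        mid = slice(2400, 9600)  # away from filtfilt edges
        assert np.abs(tr.samples[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_fast_oscillation_removed(self):
        t = np.arange(12000) / 1200.0
        tr = lowpass_filter(make_trace(np.sin(2 * np.pi * 30.0 * t)))
        mid = slice(2400, 9600)
        assert np.abs(tr.samples[mid]).max() < 0.01  # >99% attenuation

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(make_trace(np.ones(100), fs=4.0), cutoff_hz=3.0)


class TestPadAndStack:
    def test_padding_marked_and_zero(self):
        tr_short = make_trace(np.ones(6000))
        stack = pad_and_stack([tr_short], target_len=8400)
        assert stack.data.shape == (1, 8400)
        assert np.all(stack.data[0, 6000:] == 0.0)
        assert stack.padding_mask()[0, 6000:].all()
        assert not stack.padding_mask()[0, :6000].any()

    def test_equal_length_traces_identity(self):
        tr = make_trace(np.arange(100.0))
        stack = pad_and_stack([tr, tr])
        assert stack.data.shape == (2, 100)
        assert not stack.padding_mask().any()

    def test_trace_longer_than_target_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            pad_and_stack([make_trace(np.ones(100))], target_len=50)

    def test_average_ignores_padding(self):
        """At a time index where one of three trials is padding, the mean is
        over the two contributing trials only."""
        trs = [
            make_trace(np.full(100, 1.0)),
            make_trace(np.full(100, 3.0)),
            make_trace(np.full(60, 10.0)),
        ]
        stack = pad_and_stack(trs)
        mean, counts = average_trace(stack)
        assert mean[50] == pytest.approx((1 + 3 + 10) / 3)
        assert mean[80] == pytest.approx(2.0)
        assert counts[80] == 2


class TestExclusions:
    @staticmethod
    def stack_with_fractions(fracs, subjects=None):
        traces = []
        for i, f in enumerate(fracs):
            tr = make_trace(
                np.ones(100),
                meta={"subject": (subjects[i] if subjects else "S01"),
                      "modality": "AO", "snr_db": -4.0, "trial": i},
            )
            tr.interp_fraction = f
            traces.append(tr)
        return pad_and_stack(traces)

    def test_strictly_greater_than_threshold_semantics(self):
        stack = self.stack_with_fractions([0.41, 0.39, 0.40])
        kept, report = apply_exclusions(stack)
        assert kept.data.shape[0] == 2  # 0.40 exactly is kept
        assert [f for _, _, f in report.trials_excluded] == [pytest.approx(0.41)]

    def test_subject_with_41_percent_bad_trials_excluded(self):
        fracs = [0.5] * 41 + [0.0] * 59  # 41% of this subject's trials bad
        subjects = ["S01"] * 100 + ["S02"] * 10
        stack = self.stack_with_fractions(fracs + [0.0] * 10, subjects)
        kept, report = apply_exclusions(stack)
        assert report.subjects_excluded == ["S01"]
        assert all(m["subject"] == "S02" for m in kept.meta)

    def test_clean_dataset_empty_report(self):
        stack = self.stack_with_fractions([0.0, 0.1])
        kept, report = apply_exclusions(stack)
        assert kept.data.shape[0] == 2
        assert not report.trials_excluded and not report.subjects_excluded

    def test_everything_excluded_raises_with_report(self):
        stack = self.stack_with_fractions([0.9, 0.9])
        with pytest.raises(EmptyDatasetError) as err:
            apply_exclusions(stack)
        assert err.value.report.subjects_excluded == ["S01"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_lowering_trial_threshold_never_keeps_more(self, fracs):
        stack = self.stack_with_fractions(fracs)

        def n_kept(thresh):
            try:
                kept, _ = apply_exclusions(stack, trial_thresh=thresh)
                return kept.data.shape[0]
            except EmptyDatasetError:
                return 0

        assert n_kept(0.2) <= n_kept(0.4)


class TestBaselineAndPPD:
    def test_constant_trace_becomes_zero(self):
        tr = baseline_correct(make_trace(np.full(3600, 5.0)))
        assert np.allclose(tr.samples, 0.0)

    def test_baseline_window_mean_zero_after_correction(self):
        rng = np.random.default_rng(0)
        tr = baseline_correct(make_trace(3.5 + rng.normal(0, 0.1, 9600)))
        sel = (tr.time_s >= 1.0) & (tr.time_s <= 2.0)
        assert tr.samples[sel].mean() == pytest.approx(0.0, abs=1e-12)

    def test_peak_relative_to_baseline(self):
        x = np.full(9600, 3.1)
        x[6000] = 3.5
        tr = baseline_correct(make_trace(x))
        assert tr.samples.max() == pytest.approx(0.4)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(make_trace(np.ones(100), fs=1200.0))  # trace < 1 s

    def test_ppd_single_trial(self):
        x = np.zeros(9600)
        x[4800] = 0.12  # at t = 4 s
        stack = pad_and_stack([make_trace(x)])
        assert peak_pupil_dilation(stack) == pytest.approx(0.12)

    def test_ppd_ignores_global_max_outside_window(self):
        """A larger excursion at t = 1.5 s (inside the baseline) must not be
        reported; the PPD is the within-window maximum."""
        x = np.zeros(9600)
        x[1800] = 0.9  # t = 1.5 s
        x[4800] = 0.2  # t = 4 s
        stack = pad_and_stack([make_trace(x)])
        assert peak_pupil_dilation(stack) == pytest.approx(0.2)

    def test_ppd_of_two_trials_is_mean_peak(self):
        a = np.zeros(9600)
        b = np.zeros(9600)
        a[4800] = 0.1
        b[4800] = 0.3
        stack = pad_and_stack([make_trace(a), make_trace(b)])
        assert peak_pupil_dilation(stack) == pytest.approx(0.2)

    def test_ppd_window_restricted_to_nonpadding_support(self):
        stack = pad_and_stack([make_trace(np.ones(1200))], target_len=9600)
        with pytest.raises(ValueError, match="non-padding"):
            peak_pupil_dilation(stack, window=(2.0, 7.0))

    def test_baseline_stack_rejects_window_in_padding(self):
        stack = pad_and_stack([make_trace(np.ones(600))], target_len=9600)
        with pytest.raises(ValueError, match="padding"):
            baseline_correct_stack(stack)


class TestPipeline:
    def test_end_to_end_noiseless_ppd_within_one_percent(
        self, tiny_pupil_study, noiseless_params
    ):
        from aveffort.curves import effort_curve

        table, report = process_pupil_trials(tiny_pupil_study.pupil_traces)
        assert not report.trials_excluded
        cond = table[table["modality"] != "VO"]
        for _, row in cond.iterrows():
            planted = effort_curve(row.snr_db, row.modality, noiseless_params.pupil_curve)
            assert row.ppd == pytest.approx(planted, rel=0.01)

    def test_provenance_records_pipeline_order(self, tiny_pupil_study):
        from aveffort.pupil import (
            detect_blinks, interpolate_invalid, pad_and_stack, lowpass_filter_stack,
        )

        tr = interpolate_invalid(detect_blinks(tiny_pupil_study.pupil_traces[0]))
        stack = lowpass_filter_stack(pad_and_stack([tr]))
        steps = tr.provenance + stack.provenance
        names = [s.split("(")[0].split(":")[0] for s in steps]
        assert names == ["simulated", "detect_blinks", "interpolate_invalid",
                         "pad_and_stack", "lowpass_filter"]
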