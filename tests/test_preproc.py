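"""Trial rejection, channel screening, filtering, normalization, contrasts."""

import numpy as np
import pytest

import meglock as mg
from meglock.preproc import RejectionReport

A = ("averted", "brief")
B = ("direct", "brief")


def _flat_epochs(n_trials=10, n_rois=2, n_samples=60, sfreq=100.0):
    data = 0.1 * np.sin(np.linspace(0, 4 * np.pi, n_samples))[None, None, :] \
        * np.ones((n_trials, n_rois, 1))
    labels = [A if i % 2 == 0 else B for i in range(n_trials)]
    return mg.EpochSet("sub-000", data, sfreq, -0.2, labels, tuple(f"R{i}" for i in range(n_rois)))


class TestRejectTrials:
    def test_all_below_threshold_keeps_everything(self):
        es = _flat_epochs()
        out, rep = mg.reject_trials(es, mg.PreprocConfig(rejection_thresholds=1.0))
        assert out.n_trials == es.n_trials
        assert rep.causes == {} and rep.excluded_rois == []

    def test_single_spike_drops_exactly_that_trial(self):
        es = _flat_epochs()
        es.data[3, 1, 10] = 50.0
        out, rep = mg.reject_trials(es, mg.PreprocConfig(rejection_thresholds=1.0))
        assert rep.kept_trials == [i for i in range(10) if i != 3]
        assert list(rep.causes) == [3]
        roi, ptp, limit = rep.causes[3][0]
        assert roi == "R1" and ptp > limit == 1.0

    def test_bad_channel_excluded_under_twenty_percent_rule(self):
        es = _flat_epochs(n_trials=10)
        es.data[[0, 4], 0, 5] = 100.0  # R0 alone would reject 20% of epochs
        out, rep = mg.reject_trials(es, mg.PreprocConfig(rejection_thresholds=1.0))
        assert rep.excluded_rois == ["R0"]
        assert out.roi_names == ("R1",)
        assert out.n_trials == 10  # trials rescued by excluding the channel

    def test_rejection_is_idempotent(self):
        es = _flat_epochs()
        es.data[2, 0, 3] = 30.0
        cfg = mg.PreprocConfig(rejection_thresholds=1.0)
        once, _ = mg.reject_trials(es, cfg)
        twice, rep2 = mg.reject_trials(once, cfg)
        assert np.array_equal(once.data, twice.data)
        assert rep2.causes == {}

    def test_all_rejected_raises_with_subject_name(self):
        es = _flat_epochs()
        es.data += 100.0 * np.sin(np.arange(es.n_samples))
        with pytest.raises(ValueError, match="sub-000"):
            mg.reject_trials(es, mg.PreprocConfig(rejection_thresholds=1.0))


def _report_with_counts(counts: dict) -> RejectionReport:
    return RejectionReport("s", sum(counts.values()), [], {}, {}, [], condition_counts=counts)


class TestTrialBalance:
    def test_identical_counts_give_p_one_and_min(self):
        reports = [_report_with_counts({c: 60 for c in mg.CONDITIONS}) for _ in range(6)]
        bal = mg.check_trial_balance(reports)
        assert bal.min_count == 60
        assert all(p == 1.0 for p in bal.pairwise_p.values())

    def test_min_count_is_smallest_surviving_count(self):
        counts = [{c: 60 for c in mg.CONDITIONS} for _ in range(3)]
        counts[1][mg.CONDITIONS[2]] = 51
        bal = mg.check_trial_balance([_report_with_counts(c) for c in counts])
        assert bal.min_count == 51

    def test_planted_imbalance_detected(self):
        rng = np.random.default_rng(0)
        reports = []
        for _ in range(12):
            base = int(rng.integers(58, 64))
            counts = {c: base for c in mg.CONDITIONS}
            counts[A] = int(round(base * 0.7)) + int(rng.integers(0, 2))
            reports.append(_report_with_counts(counts))
        bal = mg.check_trial_balance(reports)
        assert min(p for (a, b), p in bal.pairwise_p.items() if A in (a, b)) < 0.05


class TestLowpass:
    def test_constant_signal_unchanged(self):
        es = _flat_epochs()
        es.data[:] = 3.0
        out = mg.lowpass_filter(es, 40.0)
        assert np.allclose(out.data, 3.0, atol=1e-8)

    @pytest.mark.parametrize("freq,check", [(60.0, "stop"), (10.0, "pass")])
    def test_attenuation_and_passband(self, freq, check):
        sfreq, n = 300.0, 900
        t = np.arange(n) / sfreq
        sig = np.sin(2 * np.pi * freq * t)
        es = mg.EpochSet("s", sig[None, None, :], sfreq, 0.0, [A], ("R0",))
        out = mg.lowpass_filter(es, 40.0)
        ratio = np.sqrt((out.data ** 2).mean() / (sig ** 2).mean())
        if check == "stop":
            assert ratio < 0.10
        else:
            assert abs(ratio - 1) < 0.05

    def test_filter_is_linear(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 1, 300))
        y = rng.standard_normal((2, 1, 300))
        mk = lambda d: mg.EpochSet("s", d, 300.0, 0.0, [A, B], ("R0",))
        f = lambda d: mg.lowpass_filter(mk(d), 40.0).data
        assert np.allclose(f(2 * x + 3 * y), 2 * f(x) + 3 * f(y), atol=1e-9)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            mg.lowpass_filter(_flat_epochs(sfreq=100.0), 50.0)


class TestBaselineNormalize:
    def _evoked(self, values, sfreq=100.0, tmin=-0.2):
        return mg.EvokedTimecourse(values, ("R0",), sfreq, tmin, 10, A)

    def test_unit_variance_baseline_roughly_identity(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((1, 150))
        out = mg.baseline_noise_normalize(self._evoked(vals), (-0.2, 0.0))
        sd = np.std(vals[0, :21], ddof=1)
        assert np.allclose(out.values, vals / sd)
        assert abs(sd - 1) < 0.5  # baseline genuinely near unit variance

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((2, 150))
        ev = mg.EvokedTimecourse(vals, ("R0", "R1"), 100.0, -0.2, 5, A)
        ev10 = mg.EvokedTimecourse(10 * vals, ("R0", "R1"), 100.0, -0.2, 5, A)
        a = mg.baseline_noise_normalize(ev, (-0.2, 0.0))
        b = mg.baseline_noise_normalize(ev10, (-0.2, 0.0))
        assert np.allclose(a.values, b.values)

    def test_deflection_divided_by_baseline_sd(self):
        baseline = np.tile([1.0, -1.0], 11)[:21]
        sd = np.std(baseline, ddof=1)
        vals = np.concatenate([baseline, np.full(80, 3.0 * sd)])[None, :]
        out = mg.baseline_noise_normalize(self._evoked(vals), (-0.2, 0.0))
        assert np.allclose(out.values[0, 30:], 3.0)

    def test_zero_baseline_variance_names_roi(self):
        vals = np.zeros((1, 150))
        with pytest.raises(ValueError, match="R0"):
            mg.baseline_noise_normalize(self._evoked(vals), (-0.2, 0.0))


class TestContrast:
    def test_identical_conditions_give_zero(self):
        es = _flat_epochs()
        waves = mg.evoked_and_contrast(es, A, A)
        assert all(np.allclose(w.values, 0) for w in waves.values())

    def test_constant_offset_recovered(self):
        es = _flat_epochs()
        es.data[es.trials_in(A)] += 2.5
        waves = mg.evoked_and_contrast(es, A, B)
        assert all(np.allclose(w.values, 2.5, atol=1e-9) for w in waves.values())

    def test_toy_two_trial_contrast_matches_hand_computation(self):
        data = np.zeros((4, 1, 3))
        data[0, 0] = [1.0, 2.0, 3.0]
        data[1, 0] = [3.0, 2.0, 1.0]
        data[2, 0] = [0.0, 1.0, 0.0]
        data[3, 0] = [2.0, 1.0, 2.0]
        es = mg.EpochSet("s", data, 100.0, 0.0, [A, A, B, B], ("R0",))
        w = mg.evoked_and_contrast(es, A, B)["R0"]
        assert np.allclose(w.values, [1.0, 1.0, 1.0])

    def test_contrast_antisymmetry(self, tiny_epochs):
        fwd = mg.evoked_and_contrast(tiny_epochs, A, B)
        rev = mg.evoked_and_contrast(tiny_epochs, B, A)
        for roi in fwd:
            assert np.array_equal(fwd[roi].values, -rev[roi].values)

    def test_empty_condition_named_in_error(self):
        es = _flat_epochs()
        only_a = mg.EpochSet("s", es.data[es.trials_in(A)], es.sfreq, es.tmin,
                             [A] * len(es.trials_in(A)), es.roi_names)
        with pytest.raises(ValueError, match="direct"):
            mg.evoked_and_contrast(only_a, A, B)
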