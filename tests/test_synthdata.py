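"""Synthetic-cohort generator tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import find_peaks

from nvcouple import aslactivation as aa
from nvcouple import aslkinetics as ak
from nvcouple import synthdata as sd


class TestContrastResponse:
    PARAMS = sd.ContrastResponseParams(r_max=1.0, c50=0.3, n_exp=2.0)

    def test_zero_contrast_is_floor(self):
        assert sd.contrast_response(0.0, self.PARAMS) == 0.0

    def test_semi_saturation(self):
        assert sd.contrast_response(0.3, self.PARAMS) == pytest.approx(0.5)

    def test_full_contrast_arithmetic(self):
        # 1 / (1 + 0.3^2) = 0.91743...
        assert sd.contrast_response(1.0, self.PARAMS) == pytest.approx(
            1 / 1.09, rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sd.contrast_response(1.2, self.PARAMS)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(r_max=st.floats(0.1, 100), c50=st.floats(0.05, 0.95),
           n_exp=st.floats(0.2, 5), floor=st.floats(0, 10))
    def test_monotone_nondecreasing(self, r_max, c50, n_exp, floor):
        p = sd.ContrastResponseParams(r_max, c50, n_exp, floor)
        c = np.linspace(0, 1, 50)
        r = sd.contrast_response(c, p)
        assert np.all(np.diff(r) >= -1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sd.ContrastResponseParams(r_max=-1, c50=0.3, n_exp=1)
        with pytest.raises(ValueError):
            sd.ContrastResponseParams(r_max=1, c50=1.5, n_exp=1)


class TestSchedule:
    @pytest.mark.parametrize("seed", [0, 1, 17, 123456])
    def test_composition_and_duration(self, seed):
        s = sd.make_schedule(seed, "left")
        assert len(s.entries) == 28
        assert s.total_duration == 840.0
        assert np.all(s.entries["duration"] == 30.0)
        counts = s.entries["condition"].value_counts()
        assert counts["rest"] == 8
        for c in sd.CONTRAST_LEVELS:
            assert counts[c] == 4

    def test_deterministic_in_seed(self):
        a = sd.make_schedule(7, "right")
        b = sd.make_schedule(7, "right")
        assert a.entries.equals(b.entries)

    def test_eyes_get_different_orders(self):
        a = sd.make_schedule(7, "left")
        b = sd.make_schedule(7, "right")
        assert not a.entries["condition"].equals(b.entries["condition"])

    def test_reversal_count(self):
        s = sd.make_schedule(0, "left")
        # 20 stimulus blocks x 30 s x 4 reversals/s
        assert len(s.reversal_times()) == 2400

    def test_invalid_eye_rejected(self):
        with pytest.raises(ValueError):
            sd.make_schedule(0, "both")


class TestSimulateMeg:
    def test_reproducible(self, control_truth):
        sched = sd.make_schedule(1, "left")
        a = sd.simulate_meg(control_truth, sched, seed=3, trials_per_block=2)
        b = sd.simulate_meg(control_truth, sched, seed=3, trials_per_block=2)
        assert np.array_equal(a.data, b.data)

    def test_trial_shape_and_labels(self, control_truth):
        sched = sd.make_schedule(1, "left")
        ep = sd.simulate_meg(control_truth, sched, seed=3,
                             trials_per_block=2)
        assert ep.data.shape == (56, 60, 600)
        assert (ep.labels["condition"] == "rest").sum() == 16
        assert ep.is_stimulus.sum() == 40

    def test_zero_signal_makes_stim_and_rest_identical(self, quiet_truth):
        t = quiet_truth
        t.gamma = sd.ContrastResponseParams(r_max=1e-12, c50=0.3, n_exp=1,
                                            floor=0.0)
        t.eye_gain = {"left": 0.0, "right": 0.0}
        sched = sd.make_schedule(1, "left")
        ep = sd.simulate_meg(t, sched, seed=3, trials_per_block=2)
        rms_stim = np.std(ep.data[ep.is_stimulus])
        rms_rest = np.std(ep.data[~ep.is_stimulus])
        assert rms_stim == pytest.approx(rms_rest, rel=1e-6)

    def test_four_reversal_locked_transients(self, quiet_truth):
        """A 1-s stimulus trial at 250-ms reversals carries 4 evoked bumps
        at the truth latency."""
        t = quiet_truth
        t.evoked_amp = 5e-9
        t.evoked_latency_ms = 110.0
        t.source_amp = 1e-15  # gamma negligible
        sched = sd.make_schedule(1, "left")
        ep = sd.simulate_meg(t, sched, seed=3, trials_per_block=1)
        trial = ep.data[ep.is_stimulus][0]
        ch = np.argmax(np.ptp(trial, axis=1))
        x = np.abs(trial[ch]) / np.abs(trial[ch]).max()
        peaks, _ = find_peaks(x, height=0.9)
        assert len(peaks) == 4
        expected = (np.arange(4) * 0.25 + 0.110) * 600
        assert np.allclose(peaks, expected, atol=3)

    def test_low_rate_rejected(self, control_truth):
        with pytest.raises(ValueError, match="rate"):
            sd.simulate_meg(control_truth, sd.make_schedule(0, "left"),
                            rate=400.0)

    def test_outside_dipole_rejected(self, control_truth, head):
        with pytest.raises(ValueError, match="conductor"):
            sd.simulate_meg(control_truth, sd.make_schedule(0, "left"),
                            source_loc=head.center + [0, 0.2, 0])


class TestSimulateAsl:
    def test_pair_count_gives_382_volumes(self, control_truth):
        sched = sd.make_schedule(1, "left")
        e1, e2 = sd.simulate_asl(control_truth, sched, shape=(4, 4, 2))
        assert e1.volumes.shape[-1] == 382
        assert e2.volumes.shape[-1] == 382
        assert e1.n_pairs == 191

    def test_parity_alternates(self, control_truth):
        sched = sd.make_schedule(1, "left")
        e1, _ = sd.simulate_asl(control_truth, sched, shape=(4, 4, 2))
        assert np.all(e1.parity[::2] == "tag")
        assert np.all(e1.parity[1::2] == "control")

    def test_no_modulation_no_noise_is_constant_after_surround(
            self, quiet_truth):
        t = quiet_truth
        t.bold_slope = t.cbf_slope = 0.0
        t.bold_intercept = t.cbf_intercept = 0.0
        sched = sd.make_schedule(1, "left")
        e1, e2 = sd.simulate_asl(t, sched, shape=(4, 4, 2))
        smoothed = aa.surround_average(e1)
        assert np.ptp(smoothed[..., 1:-1], axis=-1).max() < 1e-9

    def test_reproducible(self, control_truth):
        sched = sd.make_schedule(1, "left")
        a, _ = sd.simulate_asl(control_truth, sched, seed=5, shape=(4, 4, 2))
        b, _ = sd.simulate_asl(control_truth, sched, seed=5, shape=(4, 4, 2))
        assert np.array_equal(a.volumes, b.volumes)

    def test_invalid_config_rejected(self, control_truth):
        with pytest.raises(ValueError):
            sd.simulate_asl(control_truth, sd.make_schedule(1, "left"),
                            tr=-1.0)


class TestSimulateMultiTi:
    def test_noise_free_round_trip(self, quiet_truth):
        params = ak.KineticParams(m0_blood=sd.M0_BLOOD_DEFAULT)
        mt = sd.simulate_multiti(quiet_truth, shape=(4, 4, 2), params=params)
        roi = np.ones((4, 4, 2), bool)
        ti_eff, dm = mt.roi_points(roi)
        fit = ak.fit_baseline_cbf(ti_eff, dm, params)
        assert fit.cbf == pytest.approx(quiet_truth.baseline_cbf, abs=0.1)
        assert fit.arrival_time == pytest.approx(quiet_truth.arrival_time,
                                                 abs=0.01)

    def test_shapes_and_reproducibility(self, control_truth):
        mt1 = sd.simulate_multiti(control_truth, seed=2, shape=(4, 4, 2))
        mt2 = sd.simulate_multiti(control_truth, seed=2, shape=(4, 4, 2))
        assert mt1.dm.shape == (4, 4, 2, 9)
        assert np.array_equal(mt1.dm, mt2.dm)


class TestCohort:
    def test_sizes_and_groups(self):
        truths = sd.default_cohort(seed=0)
        groups = [t.group for t in truths]
        assert groups.count("control") == 10
        assert groups.count("patient") == 14

    def test_patient_gamma_deficit_grows_with_contrast(self):
        """Group-mean gamma difference increases with contrast (the
        generative group x contrast interaction)."""
        truths = sd.default_cohort(n_controls=40, n_patients=40, seed=1)
        diffs = []
        for c in sd.CONTRAST_LEVELS:
            ctl = np.mean([t.gamma_pct(c) for t in truths
                           if t.group == "control"])
            pat = np.mean([t.gamma_pct(c) for t in truths
                           if t.group == "patient"])
            diffs.append(ctl - pat)
        assert np.all(np.diff(diffs) > 0)

    def test_measurement_table_layout(self):
        truths = sd.default_cohort(2, 2, seed=0)
        meas = sd.simulate_measurements(truths, seed=0)
        assert len(meas) == 4 * 2 * 5  # subjects x eyes x contrasts
        assert set(meas["eye"]) == {"left", "right"}
        per_subj = meas.groupby("subject").size()
        assert (per_subj == 10).all()

    def test_cbf_quant_is_product_of_pct_and_baseline(self):
        truths = sd.default_cohort(2, 2, seed=0)
        meas = sd.simulate_measurements(truths, seed=0)
        assert np.allclose(meas["cbf_quant"],
                           meas["cbf_pct"] / 100.0 * meas["baseline_cbf"])
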