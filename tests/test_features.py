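"""Feature extraction: spike detection, step/BAC features, scoring."""

import numpy as np
import pytest

from dendrofit.cablesim import Trace
from dendrofit.features import (
    BAC_GROUPS_DEFAULT, FeatureReport, HARD_CONSTRAINT_SENTINEL,
    STEP_GROUPS_DEFAULT, bac_features, ca_spike_width, detect_spikes,
    feature_error, group_objectives, normalize_fi, spike_shapes,
    step_features,
)

from conftest import gaussian_train, triangle_train


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 100, 0.025)
        tr = Trace("V", "soma", 0.0, t, np.full_like(t, -80.0))
        assert len(detect_spikes(tr)) == 0

    def test_template_spikes_found_at_known_times(self):
        times = [20.0, 40.0, 60.0, 80.0, 100.0]
        tr = triangle_train(times, 130.0)
        det = detect_spikes(tr)
        assert len(det) == 5
        # triangular rise from -80 to +40 over 1 ms crosses -20 at 0.5 ms
        np.testing.assert_allclose(det, np.array(times) + 0.5, atol=0.03)

    def test_threshold_above_peaks_detects_nothing(self):
        tr = triangle_train([20.0, 40.0], 60.0, peak=40.0)
        assert len(detect_spikes(tr, threshold=50.0)) == 0

    def test_refractory_lockout(self):
        tr = triangle_train([20.0], 40.0)
        # a noisy double-crossing within 1 ms counts once
        v = tr.values.copy()
        i = np.searchsorted(tr.t, 20.4)
        v[i] = -30.0  # dip below threshold and recross
        tr2 = Trace("V", "soma", 0.0, tr.t, v)
        assert len(detect_spikes(tr2)) == 1


class TestStepFeatures:
    def test_regular_train_has_zero_cv_and_adaptation(self):
        times = list(np.arange(120.0, 520.0, 50.0))
        tr = triangle_train(times, 600.0)
        f = step_features(tr, onset=100.0, dur=450.0)
        assert f["isi_cv"] == pytest.approx(0.0, abs=1e-9)
        assert f["adaptation_index"] == pytest.approx(0.0, abs=1e-9)
        assert f["spike_frequency"] == pytest.approx(len(times) / 0.45)
        assert f["first_spike_latency"] == pytest.approx(20.5, abs=0.03)

    def test_isi_cv_closed_form(self):
        """ISIs {10, 20, 30} ms: population CV = sqrt(200/3)/20 = 0.4082."""
        times = [110.0, 120.0, 140.0, 170.0]
        tr = triangle_train(times, 300.0)
        f = step_features(tr, onset=100.0, dur=150.0)
        assert f["isi_cv"] == pytest.approx(np.sqrt(200.0 / 3.0) / 20.0,
                                            abs=1e-9)
        assert f["initial_burst_isi"] == pytest.approx(10.0, abs=1e-9)
        # adaptation: mean of (10/30, 10/50)
        assert f["adaptation_index"] == pytest.approx((1 / 3 + 0.2) / 2,
                                                      abs=1e-9)

    def test_triangle_half_width(self):
        """Linear flanks: width at half height is (rise + fall) / 2."""
        tr = triangle_train([50.0], 100.0, rise=1.0, fall=2.0)
        _, _, widths = spike_shapes(tr)
        assert widths[0] == pytest.approx(1.5, abs=0.03)

    def test_no_spikes_yields_nan_features(self):
        t = np.arange(0, 500, 0.025)
        tr = Trace("V", "soma", 0.0, t, np.full_like(t, -75.0))
        f = step_features(tr, onset=100.0, dur=300.0)
        assert f["spike_frequency"] == 0.0
        assert np.isnan(f["ap_peak"])
        assert np.isnan(f["isi_cv"])

    def test_resampling_invariance(self):
        """Halving dt changes every defined feature by < 1%."""
        times = [120.0, 135.0, 155.0, 180.0, 210.0, 245.0]
        f1 = step_features(gaussian_train(times, 400.0, dt=0.025), 100.0, 200.0)
        f2 = step_features(gaussian_train(times, 400.0, dt=0.0125), 100.0, 200.0)
        for k, v in f1.items():
            if np.isnan(v) or v == 0.0:
                continue
            assert abs(f2[k] - v) <= 0.01 * abs(v) + 1e-9, k

    def test_cross_check_against_naive_extractor(self):
        """Spike count and half-width agree with an independent, naive
        reference implementation on random synthetic trains."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(2, 8)
            times = np.sort(rng.uniform(30.0, 400.0, n))
            keep = np.concatenate([[True], np.diff(times) > 8.0])
            times = times[keep]
            tr = triangle_train(times, 450.0)
            det = detect_spikes(tr)
            # naive count: local maxima above threshold
            v = tr.values
            peaks_naive = np.sum((v[1:-1] > -20.0) & (v[1:-1] >= v[:-2])
                                 & (v[1:-1] > v[2:]))
            assert len(det) == peaks_naive
            # naive width: samples above half level, counted discretely
            _, _, widths = spike_shapes(tr)
            for w in widths:
                assert abs(w - 1.5) < 2 * tr.dt


class TestBacFeatures:
    def test_triangular_ca_spike_width(self):
        """A synthetic Ca2+ spike above -55 mV for exactly 30 ms."""
        t = np.arange(0, 200, 0.025)
        v = np.full_like(t, -70.0)
        up = (t >= 50.0) & (t < 65.0)
        v[up] = -70.0 + (t[up] - 50.0) * 2.0  # rises 30 mV over 15 ms
        down = (t >= 65.0) & (t < 80.0)
        v[down] = -40.0 - (t[down] - 65.0) * 2.0
        tr = Trace("V", "apical", 700.0, t, v)
        # crosses -55 at t=57.5 up and t=87.5- down: 15 ms up + 15 down
        assert ca_spike_width(tr) == pytest.approx(15.0, abs=0.1)

    def test_bac_counts_and_bap_amplitudes(self):
        soma_coinc = triangle_train([30.0, 40.0, 50.0], 150.0)
        soma_only = triangle_train([30.0], 150.0)
        hot = triangle_train([35.0], 150.0, peak=0.0, rise=10.0, fall=30.0,
                             rest=-65.0)
        d620 = triangle_train([31.0], 150.0, peak=-20.0, rest=-70.0)
        d800 = triangle_train([32.0], 150.0, peak=-40.0, rest=-68.0)
        f = bac_features(soma_coinc, hot, soma_only, d620, d800)
        assert f["ap_count_coincident"] == 3
        assert f["ap_count_soma_only"] == 1
        assert f["mean_ap_isi"] == pytest.approx(10.0, abs=1e-6)
        assert f["bap_amp_620"] == pytest.approx(50.0)
        assert f["bap_amp_800"] == pytest.approx(28.0)
        assert f["ca_spike_peak"] == pytest.approx(0.0)


class TestScoring:
    def test_error_in_sd_units(self):
        assert feature_error(5.0, 5.0, 2.0) == 0.0
        assert feature_error(9.0, 5.0, 2.0) == 2.0

    def test_hard_constraint_sentinel(self):
        assert feature_error(3.0, 3.0, 0.0) == 0.0
        assert feature_error(2.0, 3.0, 0.0) == HARD_CONSTRAINT_SENTINEL
        assert feature_error(float("nan"), 3.0, 1.0) == HARD_CONSTRAINT_SENTINEL

    def test_normalize_fi_linear_curve(self):
        """f = 0.03 Hz/pA * I: 15 Hz at 500 pA; amplitudes 390/500/950."""
        pts = [(i, 0.03 * i * 1000.0) for i in (0.1, 0.3, 0.4, 0.6, 0.8, 1.0)]
        out = normalize_fi(pts)
        assert out["i_ref"] == pytest.approx(0.5, rel=1e-9)
        assert out["amplitudes"]["low"] == pytest.approx(0.39, rel=1e-9)
        assert out["amplitudes"]["high"] == pytest.approx(0.95, rel=1e-9)
        # the ratios are fixed by definition
        assert out["amplitudes"]["low"] / out["i_ref"] == pytest.approx(0.78)
        assert out["amplitudes"]["high"] / out["i_ref"] == pytest.approx(1.90)

    def test_normalize_fi_requires_bracketing(self):
        with pytest.raises(ValueError):
            normalize_fi([(0.1, 2.0), (0.2, 6.0), (0.3, 10.0)])

    def test_group_objectives_shapes_and_zero(self, stats):
        values = {(s, f): m for s, f in stats.features("step")
                  for m in [stats.get(f, s)[0]]}
        report = FeatureReport.from_values(values, stats, "step")
        vec = group_objectives(report, "step")
        assert len(vec) == 8
        np.testing.assert_allclose(vec, 0.0, atol=1e-12)
        values_b = {(s, f): stats.get(f, s)[0] for s, f in stats.features("bac")}
        report_b = FeatureReport.from_values(values_b, stats, "bac")
        vec_b = group_objectives(report_b, "bac")
        assert len(vec_b) == 5
        np.testing.assert_allclose(vec_b, 0.0, atol=1e-12)

    def test_groups_cover_all_features(self):
        step_members = {f for g in STEP_GROUPS_DEFAULT for f in g}
        bac_members = {f for g in BAC_GROUPS_DEFAULT for f in g}
        assert len(step_members) == 10
        assert len(bac_members) == 10

    def test_acceptance_flag(self, stats):
        values = {(s, f): stats.get(f, s)[0] for s, f in stats.features("bac")}
        report = FeatureReport.from_values(values, stats, "bac")
        assert report.acceptable(3.0)
        # push one soft feature to 3.5 SD
        mean, sd = stats.get("ca_spike_peak", "bac")
        values[("bac", "ca_spike_peak")] = mean + 3.5 * sd
        report2 = FeatureReport.from_values(values, stats, "bac")
        assert not report2.acceptable(3.0)
        assert report2.acceptable(4.0)
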