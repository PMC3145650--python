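"""Cable solver: density rules, passive analytics, measurements."""

import numpy as np
import pytest

from dendrofit.cablesim import (
    BriefPulse, DensityRule, MeasurementInvalid, RmSigmoid, Step,
    StimulusProtocol, EpspLike, apply_density_rules, build_cell_model,
    default_rules, measure_input_resistance, set_ih_blocked, simulate,
    transfer_impedance,
)
from dendrofit.mechanisms import CHANNEL_NAMES
from dendrofit.moofit import TABLE3_PARAMS
from dendrofit.morphology import Morphology, Section, compartmentalize


@pytest.fixture(scope="module")
def passive_soma():
    m = Morphology([Section("soma", [[0, 0, 0]], [20.0], None)], "sphere")
    cell = compartmentalize(m)
    return build_cell_model(cell, {"s.g_leak": 0.3}, rules=[])


@pytest.fixture(scope="module")
def passive_cable_model(ref_cell):
    """The reference morphology with leak only (no active channels)."""
    return build_cell_model(ref_cell, {"s.g_leak": 0.3, "ax.g_leak": 0.3,
                                       "b.g_leak": 0.3, "a.g_leak": 0.3},
                            rules=[])


class TestDensityRules:
    def test_ih_base_density_is_1_at_soma(self, ref_cell):
        gbar = apply_density_rules(ref_cell, default_rules(TABLE3_PARAMS, ref_cell))
        ih = CHANNEL_NAMES.index("I_h")
        assert gbar[ih, 0] == pytest.approx(1.0)
        # exponential growth along the apical trunk
        i_mid = ref_cell.index_at("apical", 400.0)
        i_far = ref_cell.index_at("apical", 900.0)
        assert gbar[ih, i_far] > gbar[ih, i_mid] > gbar[ih, 0]

    def test_basal_ih_uniform(self, ref_cell):
        gbar = apply_density_rules(ref_cell, default_rules(TABLE3_PARAMS, ref_cell))
        ih = CHANNEL_NAMES.index("I_h")
        basal = gbar[ih, ref_cell.region_mask("basal")]
        assert np.allclose(basal, basal[0])

    def test_hot_zone_multipliers(self, ref_cell):
        gbar = apply_density_rules(ref_cell, default_rules(TABLE3_PARAMS, ref_cell))
        lva = CHANNEL_NAMES.index("Ca_LVA")
        hva = CHANNEL_NAMES.index("Ca_HVA")
        inside = ref_cell.index_at("apical", 700.0)
        outside = ref_cell.index_at("apical", 500.0)
        assert gbar[lva, inside] == pytest.approx(TABLE3_PARAMS["a.gbar_Ca_LVA"])
        assert gbar[lva, inside] == pytest.approx(100.0 * gbar[lva, outside])
        assert gbar[hva, inside] == pytest.approx(10.0 * gbar[hva, outside])

    def test_conflicting_rules_rejected(self, ref_cell):
        rules = [DensityRule("Na_t", "soma", "uniform", {"density": 1.0}),
                 DensityRule("Na_t", "soma", "uniform", {"density": 2.0})]
        with pytest.raises(ValueError, match="conflict"):
            apply_density_rules(ref_cell, rules)

    def test_hot_zone_unplaceable_on_short_apical(self):
        soma = Section("soma", [[0, 0, 0]], [15.0], None)
        apic = Section("apical", [[0, 0, 0], [0, 300, 0]], [2.0, 2.0], 0)
        cell = compartmentalize(Morphology([soma, apic]))
        with pytest.raises(ValueError, match="hot zone"):
            default_rules(TABLE3_PARAMS, cell)

    def test_dendritic_doubling_internal_only(self, ref_cell):
        model = build_cell_model(ref_cell, TABLE3_PARAMS)
        nat = CHANNEL_NAMES.index("Na_t")
        i_ap = ref_cell.index_at("apical", 300.0)
        # reported density is un-doubled; the solver conductance is 2x
        assert model.gbar_report[nat, i_ap] == pytest.approx(107.0)
        assert model.gbar_uS[nat, i_ap] == pytest.approx(
            2.0 * 107.0 * ref_cell.area[i_ap] * 1e-6)
        assert model.gbar_uS[nat, 0] == pytest.approx(
            TABLE3_PARAMS["s.gbar_Na_t"] * ref_cell.area[0] * 1e-6)
        # capacitance doubling goes with it
        assert model.cm_nF[i_ap] == pytest.approx(2.0 * ref_cell.area[i_ap] * 1e-5)
        assert model.cm_nF[0] == pytest.approx(1.0 * ref_cell.area[0] * 1e-5)

    def test_rm_sigmoid_profile(self, ref_cell):
        model = build_cell_model(ref_cell, TABLE3_PARAMS,
                                 rm_sigmoid=RmSigmoid())
        apical = ref_cell.region_mask("apical")
        g = model.g_leak_report[apical]
        x = ref_cell.path_dist[apical]
        # leak conductance rises distally (R_m falls), E_leak rises
        assert g[np.argmax(x)] > g[np.argmin(x)]
        e = model.e_leak[apical]
        assert e[np.argmax(x)] > -85.0
        assert model.e_leak[0] == pytest.approx(-90.0)
        # proximal value matches the somatic R_m with the area factor
        assert g[np.argmin(x)] == pytest.approx(1e4 * 1.16 / 34963.0, rel=0.05)


class TestPassiveAnalytics:
    def test_rest_equals_leak_reversal(self, passive_soma):
        res = simulate(passive_soma, StimulusProtocol([], 50.0),
                       recordings={"s": ("soma", 0.0)})
        np.testing.assert_allclose(res["s"].values, -90.0, atol=1e-9)

    def test_input_resistance_of_sphere(self, passive_soma):
        area = passive_soma.cell.total_area()
        expected = 1.0 / (0.3e-6 * area)  # MOhm
        rin = measure_input_resistance(passive_soma, amp=-0.01, dur=400.0)
        assert rin == pytest.approx(expected, rel=0.01)

    def test_membrane_time_constant(self, passive_soma):
        """Charging follows tau = R_m C_m = 33.3 ms for 0.3 pS/um^2 leak."""
        prot = StimulusProtocol([(("soma", 0.0), Step(-0.01, 10.0, 300.0))],
                                350.0)
        res = simulate(passive_soma, prot, recordings={"s": ("soma", 0.0)})
        v, t = res["s"].values, res["s"].t
        v0 = v[t < 10.0][-1]
        v_inf = v[(t > 280.0) & (t < 310.0)].mean()
        target = v0 + (1.0 - np.exp(-1.0)) * (v_inf - v0)
        sel = t >= 10.0
        tau = t[sel][np.argmax(v[sel] <= target)] - 10.0
        assert tau == pytest.approx(1e-3 / 0.3e-4, rel=0.01)  # 33.33 ms

    def test_subthreshold_linearity(self, passive_cable_model):
        def deflection(amp):
            prot = StimulusProtocol([(("soma", 0.0), Step(amp, 10.0, 150.0))],
                                    180.0)
            res = simulate(passive_cable_model, prot,
                           recordings={"s": ("soma", 0.0)})
            return res["s"].values - res["s"].values[0]

        d1, d2 = deflection(-0.01), deflection(-0.02)
        assert np.abs(d2 - 2 * d1).max() <= 0.01 * np.abs(d2).max()

    def test_charge_balance(self, passive_soma):
        """Injected charge equals capacitive plus leak charge."""
        amp, dur = -0.01, 100.0
        prot = StimulusProtocol([(("soma", 0.0), Step(amp, 10.0, dur))], 130.0,
                                dt=0.01)
        res = simulate(passive_soma, prot, recordings={"s": ("soma", 0.0)})
        v, t = res["s"].values, res["s"].t
        on = (t >= 10.0) & (t <= 10.0 + dur)
        c = passive_soma.cm_nF[0]
        g = passive_soma.g_leak_uS[0]
        q_inj = abs(amp) * dur  # nA*ms = pC
        q_cap = abs(c * (v[on][-1] - v[on][0]))
        q_leak = abs(np.trapezoid(g * (v[on] + 90.0), t[on]))
        assert abs(q_cap + q_leak - q_inj) / q_inj < 1e-3

    def test_transfer_impedance_reciprocity(self, passive_cable_model):
        a, b = ("soma", 0.0), ("apical", 600.0)
        k_ab = transfer_impedance(passive_cable_model, a, b, "steady")
        k_ba = transfer_impedance(passive_cable_model, b, a, "steady")
        assert k_ab == pytest.approx(k_ba, rel=0.005)

    def test_steady_state_initialization(self, ref_model):
        """No stimulus: the fully active model sits still after init."""
        res = simulate(ref_model, StimulusProtocol([], 50.0),
                       recordings={"s": ("soma", 0.0)})
        dvdt = np.abs(np.diff(res["s"].values)) / res["s"].dt
        assert dvdt.max() < 0.01  # mV/ms


class TestActiveModel:
    def test_resting_potential_rises_distally(self, ref_model):
        """I_h produces a depolarizing resting gradient along the apical
        tree, on the order of 10 mV/mm."""
        res = simulate(ref_model, StimulusProtocol([], 20.0),
                       recordings={"s": ("soma", 0.0), "d": ("apical", 900.0)})
        slope = (res["d"].values[-1] - res["s"].values[-1]) / 0.9  # mV/mm
        assert 3.0 < slope < 20.0

    def test_dt_convergence_of_ap_peak(self, ref_model):
        """In the convergent regime (dt <= 0.0125 ms) halving dt moves
        the somatic AP peak by < 0.5 mV; the coarse 0.025 ms default
        carries a known few-mV peak error, well below the experimental
        AP-peak SD."""
        peaks = {}
        for dt in (0.025, 0.0125, 0.00625):
            prot = StimulusProtocol([(("soma", 0.0), BriefPulse(1.9, 10.0))],
                                    60.0, dt=dt)
            res = simulate(ref_model, prot, recordings={"s": ("soma", 0.0)})
            peaks[dt] = res["s"].values.max()
        assert abs(peaks[0.0125] - peaks[0.00625]) < 0.5
        assert abs(peaks[0.025] - peaks[0.00625]) < 4.0

    def test_divergence_flagged(self, passive_soma):
        prot = StimulusProtocol([(("soma", 0.0), Step(1e5, 1.0, 10.0))], 20.0)
        res = simulate(passive_soma, prot, recordings={"s": ("soma", 0.0)},
                       raise_on_divergence=False)
        assert res.diverged

    def test_spike_invalidates_input_resistance(self, ref_model):
        with pytest.raises(MeasurementInvalid):
            measure_input_resistance(ref_model, amp=2.5, dur=100.0)

    def test_peak_somatic_na_current_order_of_magnitude(self, ref_model):
        """Peak Na_t current density at the soma during an AP is of
        order 50 pA/um^2 (within a factor of a few)."""
        prot = StimulusProtocol([(("soma", 0.0), BriefPulse(1.9, 10.0))], 60.0)
        res = simulate(ref_model, prot, recordings={"s": ("soma", 0.0)})
        peak = np.abs(res.inat_traces["s"].values).max()
        assert 15.0 < peak < 250.0


class TestIhBlock:
    def test_block_removes_sag(self, ref_model):
        def sag(model):
            prot = StimulusProtocol([(("soma", 0.0), Step(-0.05, 20.0, 200.0))],
                                    250.0)
            res = simulate(model, prot, recordings={"s": ("soma", 0.0)})
            v, t = res["s"].values, res["s"].t
            v0 = v[t < 20.0][-1]
            trough = v[(t > 20.0) & (t < 220.0)].min() - v0
            steady = v[(t > 200.0) & (t < 220.0)].mean() - v0
            return (trough - steady) / trough

        assert sag(ref_model) > 0.05
        assert sag(set_ih_blocked(ref_model)) < 0.01

    def test_block_idempotent_and_reversible(self, ref_model):
        blocked = set_ih_blocked(ref_model)
        twice = set_ih_blocked(blocked)
        np.testing.assert_array_equal(blocked.gbar_uS, twice.gbar_uS)
        restored = set_ih_blocked(twice, blocked=False)
        np.testing.assert_array_equal(restored.gbar_uS, ref_model.gbar_uS)
        np.testing.assert_array_equal(restored.gbar_report,
                                      ref_model.gbar_report)

    def test_epsp_peak_equals_nominal_amplitude(self):
        wf = EpspLike(0.5, onset=5.0)
        t = np.arange(0.0, 60.0, 0.001)
        assert wf.evaluate(t).max() == pytest.approx(0.5, rel=1e-4)
        assert np.all(wf.evaluate(t)[t < 5.0] == 0.0)
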