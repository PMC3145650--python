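"""Coincidence-detection window in Up versus Down states.

A brief somatic pulse (evoking one AP) and a distal EPSP-like current
are applied with a varying time difference dt.  The Down state is the
resting cell; the Up state is emulated by a 0.42 nA DC current at the
proximal apical dendrite.  The contiguous dt range whose peak distal
voltage shows the Ca2+ spike is the coincidence window; sustained
depolarization inactivates dendritic Na+ channels, depressing the BAP
and narrowing the window.
"""

from dendrofit.experiments import coincidence_window, reference_model

model = reference_model()
for state in ("down", "up"):
    r = coincidence_window(model, state)
    print(f"\n{state.upper()} state  (dt = t_EPSP - t_soma):")
    for d, p, n in zip(r["dt_grid"], r["peak_dend_v"], r["ap_counts"]):
        flag = " *" if r["ca_spike_mask"][list(r["dt_grid"]).index(d)] else ""
        print(f"  dt {d:+6.0f} ms   peak {p:7.1f} mV   APs {n}{flag}")
    print(f"  window: {r['window']}")
# The Down-state window brackets exact coincidence (dt = 0); under the
# Up-state DC the out-of-window BAP peak drops (Na_t inactivation) and
# the window shrinks or disappears - a prediction of increased temporal
# selectivity during depolarized network states.
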