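"""Spatiotemporal correlation entropy (SC) and neuromodulation intensity (NI)
of a resting-state recording, per frequency band.

SC summarizes how similar the channels' temporal entropy sequences are
(higher = more synchronized brain activity); NI estimates the fraction of
2-second segments occupied by sparse non-Gaussian transient activity.
"""

from docndf import (GroupParams, compute_sc_ni, common_average_reference,
                    butterworth_bandpass, generate_resting_recording)

params = GroupParams("MCS", synchrony=0.6, transient_prob=0.25)
rec = generate_resting_recording(params, n_channels=30, fs=500.0,
                                 duration_s=40.0, seed=7)
rec = butterworth_bandpass(common_average_reference(rec), 0.1, 45.0)

features = compute_sc_ni(rec, T=2.0)
full = compute_sc_ni(rec, bands=None, T=2.0)["full"]
truth = len(rec.meta["burst_windows"]) / rec.meta["n_burst_windows"]
print(f"{'band':>6}  {'SC (whole brain)':>17}  {'NI (whole brain)':>17}")
for band, bf in features.items():
    print(f"{band:>6}  {bf.sc.whole_brain:17.2f}  {bf.ni.whole_brain:17.3f}")
print(f"{'full':>6}  {full.sc.whole_brain:17.2f}  {full.ni.whole_brain:17.3f}")
print(f"\ninjected transient proportion (ground truth): {truth:.3f}")
# SC is bounded by n_channels * n_segments; NI is a proportion in [0, 1].
# The full-band NI tracks the injected burst proportion; narrow-band
# filtering symmetrizes the burst waveform, so per-band NI values sit near
# the 10% floor of the percentile grid.
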