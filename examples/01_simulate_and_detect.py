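"""Simulate a multi-frequency impedance recording and detect bead transits.

Builds a 60 s eight-channel trace at 100 pg/mL IL-6 with the frozen
synthetic preset, runs the running-median/MAD peak detector, and compares
the detected events with the injected ground truth.
"""

from impedquant import (DetectionParams, detect_peaks, match_to_truth,
                        assay_regime, simulate_trace)

config = assay_regime()
trace = simulate_trace(config, concentration=100.0, duration_s=60.0, seed=42)
print(f"trace: {trace.samples.shape[0]} samples x {trace.n_channels} channels "
      f"at {trace.sampling_rate_hz:g} Sa/s, {len(trace.truth)} injected beads")

peaks = detect_peaks(trace, DetectionParams())
result = match_to_truth(peaks, trace.truth, tolerance_s=0.010)
print(f"detected {len(peaks)} events | recall {result.recall:.3f}, "
      f"precision {result.precision:.3f}, amplitude RMSE "
      f"{result.amplitude_rmse * 1e3:.2f} mV")
# Recall/precision near 1 show every bead transit is recovered; the small
# RMSE is the documented ~2.8% peak attenuation of a 15 ms Gaussian pulse
# by the instrument's 100 Hz first-order demodulation filter.
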