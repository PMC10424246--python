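"""Ciliary beat frequency from a synthetic high-speed recording.

Simulates a 10 s recording (100 frames/s, 1024 frames) of cilia beating at
8.83 Hz with realistic noise, then recovers the frequency from three ROIs
by FFT with quadratic peak refinement, exactly as one would from a real
TIFF stack.
"""

from epidrop import cbf
from epidrop.synth import gen_cilia_stack

stack, truth = gen_cilia_stack(f0=8.83, frame_rate=100.0, n_frames=1024,
                               snr=5.0, shape=(32, 32), seed=42)
print(f"simulated beat frequency: {truth.parameters['f0']} Hz")

estimates = []
for roi in [(0, 0, 16, 16), (16, 0, 16, 16), (0, 16, 16, 16)]:
    trace = cbf.extract_roi_trace(stack, roi, frame_rate=100.0)
    est = cbf.cbf_fft(trace, band=(1.0, 20.0))
    estimates.append(est)
    print(f"ROI {roi}: {est.frequency:.3f} Hz "
          f"(dominant-peak power fraction {est.power_fraction:.2f})")

table = cbf.summarize_cbf({"50-pass": estimates})
print(table.round(3))
print()
print("The group median is the per-insert CBF readout; healthy airway cilia")
print("beat at roughly 6-16 Hz, so values in this range indicate function.")
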