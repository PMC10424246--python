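# epidrop

Quantitative analysis for droplet-bioprinted airway epithelial cultures.

Droplet-based bioprinting deposits progenitor nasal epithelial cells onto
Transwell inserts layer by layer ("passes"), after which air–liquid-interface
(ALI) culture differentiates them into a pseudostratified epithelium with
beating cilia, mucus-secreting goblet cells and tight junctions. `epidrop`
implements the measurements used to characterize such cultures, for
bioprinting and airway-biology labs that want them scripted, tested and
reproducible rather than clicked through ImageJ/FlowJo:

* **printability** — dimensionless jetting numbers for a fluid expelled
  from a nozzle of diameter *L* at velocity *U*:
  Oh = η/√(γρL) = √We/Re = 1/Z, We = ρU²L/γ, Re = ρUL/η, Fr = U/√(gL),
  Bo = ρgL²/γ and the splashing parameter K_sp = √(We·√Re). Droplet impacts
  with K_sp < 57.7 do not splash; Bo < 1 means gravity is negligible at
  droplet scale. Includes gravimetric droplet-volume calibration and
  least-squares droplet velocimetry.
* **cbf** — ciliary beat frequency from high-speed recordings: per-ROI mean
  intensity traces, detrended and Hann-windowed, FFT peak in a 1–20 Hz band
  refined by quadratic interpolation; plus manual cycle counting
  (CBF = n·frame_rate/frames) and per-condition median/IQR summaries.
* **imagequant** — tight-junction (ZO-1) peak-to-peak spacing along line
  profiles, marker area per 10⁵ µm² and percent area, LIVE/DEAD blob
  counting and viability, and flow-cytometry-style DAPI×GFP gating of
  per-cell intensity tables.
* **barrier** — transepithelial electrical resistance, (raw − blank)·area
  in Ω·cm², with time-course aggregation; FITC-dextran flux as the
  regression slope of basal accumulation, optionally normalized to the
  apical load.
* **seeding** — pass-number dosing plans (2200 cells/insert/pass; 10–50
  passes span one-tenth to one-half of the 2.2 × 10⁵-cell manual dose).
* **synth** — seeded generators for every input modality with ground-truth
  sidecars, so the whole pipeline is validated by parameter recovery.

## Worked example

Estimate beat frequency from a synthetic recording of cilia beating at
8.83 Hz (100 frames/s, 1024 frames, SNR 5):

```python
from epidrop import cbf
from epidrop.synth import gen_cilia_stack

stack, truth = gen_cilia_stack(f0=8.83, frame_rate=100.0, n_frames=1024,
                               snr=5.0, shape=(32, 32), seed=42)
trace = cbf.extract_roi_trace(stack, (0, 0, 16, 16), frame_rate=100.0)
est = cbf.cbf_fft(trace, band=(1.0, 20.0))
print(f"{est.frequency:.3f} Hz, power fraction {est.power_fraction:.2f}")
```

prints

```
8.831 Hz, power fraction 0.51
```

— the estimator recovers the simulated 8.83 Hz to within the raw FFT bin
width (~0.1 Hz) thanks to the quadratic peak refinement, and half of the
band's spectral power sits in the dominant bin, a confident peak (pure
noise stays below ~0.05). Healthy airway cilia beat at roughly 6–16 Hz.

The `examples/` directory holds one short narrative script per capability
(`printability_profile.py`, `cbf_estimation.py`, `junction_spacing.py`,
`viability_counting.py`, `infection_gating.py`, `barrier_function.py`,
`dosing_plan.py`); each builds a small input, runs the analysis and prints
what the numbers mean. A thin CLI mirrors the library for shell use:

```sh
epidrop printability --spec water.yaml --json report.json
epidrop simulate cilia --seed 1 --out sim/
epidrop cbf --stack sim/cilia_stack.tif --fps 100 --roi 0,0,16,16
```

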