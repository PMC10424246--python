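# Methods

This note records the models, numerical choices and validation logic behind
`epidrop`, in the order a user meets them.

## Printability physics

The printability module evaluates the standard dimensionless groups for a
Newtonian fluid (viscosity η, surface tension γ, density ρ) jetted from a
nozzle of inner diameter *L* at droplet velocity *U* under gravity *g*:

    Oh = η / √(γρL) = √We / Re = 1/Z
    We = ρU²L/γ        Re = ρUL/η       Fr = U/√(gL)
    Bo = ρgL²/γ        K_sp = √(We·√Re)

All quantities are SI internally; the YAML/JSON reader converts the lab
units these quantities are usually reported in (mPa·s, mN/m, g/ml, µm).
Two classification rules are applied: gravity is negligible during droplet
spreading when **Bo < 1** (strict), and an impact splashes significantly
when **K_sp ≥ 57.7** (the boundary itself counts as splashing). Both
computation routes for Oh are kept and cross-checked in tests to 1e−9
relative tolerance. Fr is reported without any threshold — no decision in
this pipeline depends on it.

The culture media used for cell jetting have essentially water-like
properties, so examples and tests ship a water-like default
(η = 1 mPa·s, γ = 72.8 mN/m, ρ = 998 kg/m³, L = 250 µm, U = 2 m/s). For
that configuration Oh ≈ 0.0074 (Z ≈ 135), K_sp ≈ 17.5 (non-splashing) and
Bo ≈ 0.008. Over the full plausible medium range (ρ 990–1010 kg/m³,
γ 30–73 mN/m) the worst-case Bo at a 250 µm nozzle is ≈ 0.02 — two orders
of magnitude below the gravity threshold, which is why droplet spreading at
this scale is capillary/inertia-driven.

Droplet volume is calibrated gravimetrically: the weighed mass of a counted
burst divided by (density × count), with the equivalent-sphere diameter
(6V/π)^(1/3). Droplet velocity is the least-squares slope of frame-by-frame
displacement versus time — robust to per-frame jitter, unlike a two-point
difference.

## Ciliary beat frequency

Beating cilia modulate pixel intensity, so the mean intensity of an ROI in
a high-speed recording oscillates at the beat frequency. The FFT estimator:

1. detrend (remove mean and linear trend — photobleaching and focus drift
   are approximately linear over a 10 s recording);
2. apply a Hann window against spectral leakage;
3. FFT, restrict to the analysis band (default 1–20 Hz, covering both
   cultured-epithelium values ~6–9 Hz and the 11–16 Hz healthy in-vivo
   range);
4. take the maximum-power bin and refine with a three-point parabola on
   log-power. At 100 frames/s and 1024 frames the raw bin width is
   ~0.098 Hz — too coarse to separate, say, 8.17 from 8.34 Hz — and the
   refinement resolves well below a bin;
5. report the fraction of band power in the dominant bin. If the dominant
   bin does not reach 3× the median band power, or the trace is numerically
   flat, a `NoPeakError` is raised instead of a number. Pure white noise
   typically yields power fractions below ~0.05 versus ~0.5 for a clean
   beat signal.

The estimate is invariant to affine intensity transforms (gain/offset) by
construction. A cycle-counting estimator is also provided:
CBF = n_cycles · frame_rate / frames_elapsed, i.e. cycles per second. The
formula printed in the source protocol carries an extra "×5 conversion per
beat cycle" factor in the denominator that is dimensionally inconsistent
with beat frequencies in Hz; this module uses the physically consistent
reading above, which agrees with the FFT estimator to within one bin on
clean tones.

Per-insert summaries pool the ROI estimates of a condition group (pooling,
not per-insert averaging, is the default — both are possible by how the
caller groups estimates) and report median and IQR.

## Tight-junction spacing

The measured quantity is the peak-to-peak distance of a junction-staining
(ZO-1) intensity profile along a drawn line. Line profiles are sampled at
one-pixel arc-length steps with bilinear interpolation, 0-based pixel
centers at integers. A wide-line option averages several parallel one-pixel
lines (the familiar wide "Plot Profile"), suppressing pixel noise without
shifting peaks. Peak detection uses prominence (default 10% of the
profile's dynamic range) with a minimum separation (default 2 µm, below any
epithelial cell diameter) after light Gaussian smoothing (σ = 1 px);
plateaus keep their leftmost sample. Positions are scaled by µm/pixel, so
spacing estimates are exactly equivariant under rescaling.

When no analyst line is supplied, `junction_spacing_field` samples N random
chords (default 25, wide-line width 5 px, smoothing σ = 1.5 px) and pools
the spacings. Random chords of a convex cell systematically under-sample
its diameter (Cauchy: mean chord = πA/P ≈ 0.79 d for hexagons), so three
summaries are reported: plain mean and median chord, and the
**length-weighted median** (the point-sampled intercept of classical
stereology — the chord containing a random point on the line), which is the
recommended cell-diameter estimate and recovers the generator's nominal
diameter to within ~7% on default synthetic fields.

## Marker area, counting, viability

Area fractions binarize the image with Otsu's threshold (or a fixed value;
a fixed threshold outside the intensity range yields an empty mask plus a
warning) and report percent-positive area (mucin convention) and absolute
positive area normalized per 10⁵ µm² of field (cilia convention — note the
reference region is 10⁵ **µm²**; a 10⁵ mm² field would exceed any
microscope's field of view by orders of magnitude). Cell counting is
Laplacian-of-Gaussian blob detection on the contrast-normalized channel;
viability is 100·live/(live+dead).

## Histocytometry gating

Per-cell mean intensities (DAPI, viral GFP) are gated with per-channel
thresholds. Auto-thresholds use Otsu on log10 intensities — fluorescence
intensities are positive and right-skewed, and mixtures are log-normal-like
— but Otsu is only meaningful on a bimodal channel. A valley test guards
it: the smoothed log-histogram must dip below 20% of its global maximum at
the Otsu cut. A unimodal channel carries no threshold information, so its
gate falls back to a stated polarity: DAPI defaults to all-positive (every
event in a segmented cell table is a nucleus), GFP to all-negative (a
reporter with no distinguishable bright population means no detectable
infection). Fixed thresholds are available whenever those assumptions do
not fit — e.g. a fully infected culture. The double-positive percentage is
monotone non-increasing in either threshold by construction.

## Barrier function

TEER: (raw − blank) × membrane area, in Ω·cm². The membrane area defaults
to 0.33 cm², the nominal growth area of a 6.5 mm Transwell insert, and is
configurable. Raw readings below their blank produce a negative value that
is returned with a warning, never clipped — near-zero barrier states should
stay visible. Time-course aggregation refuses mixed membrane areas within a
(condition, day) group, since their Ω·cm² values would not be commensurate.

Dextran flux: the least-squares slope of cumulative basal tracer amount
versus time (amount/h), with an optional normalization to the apical load
(concentration × apical volume → fraction of load per hour). No apparent
permeability coefficient (P_app) is computed — the readout here is a
relative flux comparison, and a P_app would require geometry assumptions
the data do not constrain; the slope is the documented extension point.
Conversion from plate-reader signal to concentration is a user-supplied
linear calibration.

## Dosing plans

One printed pass deposits 2200 cells per insert; dose is exactly linear in
passes, so 10–50 passes give 0.22–1.1 × 10⁵ cells, one-tenth to one-half
of the 2.2 × 10⁵-cell manual seeding reference. (A printed suspension
"density" figure sometimes quoted alongside these numbers is inconsistent
as a volumetric concentration; the per-insert-per-pass constant is the
operative quantity and reproduces every tabulated dose.) Print time is a
planning estimate (0.2 min/pass), never a benchmark. Volume and droplet
count per pass are not specified by the protocol, so cells-per-droplet is
deliberately not derived.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its parameters and a seed
(`numpy.random.default_rng`); identical seeds give bit-identical outputs,
and each output carries a ground-truth JSON sidecar. Defaults encode the
study conditions the analyses target.

* **Cilia stacks** — per-pixel baseline + A·sin(2πf₀t + φ(x)) with a 0.2A
  second harmonic (asymmetric power/recovery stroke) and a linear phase
  gradient across columns (metachronal-wave-like coherence); Gaussian noise
  with SNR = A/σ. Defaults: 100 frames/s, 1024 frames, SNR 5, f₀ in the
  6–9 Hz range. Not modeled: cilia hydrodynamics, optics/PSF, non-
  stationary beating.
* **Junction images** — hexagonal lattice of cell centers at the nominal
  diameter, Gaussian-jittered (SD = jitter × diameter) then relaxed by one
  Lloyd step toward a centroidal Voronoi tessellation, the standard
  geometric model of confluent epithelial packing; the lattice pins the
  mean center spacing to the requested diameter and the zero-jitter limit
  is the exact hexagonal tessellation. Boundaries are Gaussian ridges of
  the stated width; default field 512×512 px at 0.5 µm/px (a realistic 40×
  confocal frame). Not modeled: cell-size heterogeneity gradients, gaps in
  the junctional network, membrane-vs-junction background.
* **LIVE/DEAD fields** — non-overlapping Gaussian spots split between the
  two channels at an exact designed viability. Not modeled: overlapping
  cells, staining crosstalk.
* **Dextran series** — linear accumulation slope·t + Gaussian noise,
  hourly over 3 h.
* **Infection tables** — DAPI a single log-normal; GFP a two-component
  log-normal mixture with an exact designed infected count (recovery error
  is then gating error, not binomial noise).
* **TEER courses** — a rise-then-decline Ω·cm² template (peaking ~1000
  about a week after air-lift, relaxing to ~255 by day 28, the trajectory
  typical of differentiating airway cultures) converted back to raw
  chopstick readings (blank + value/area) plus replicate noise, so the
  analysis path exercises blank subtraction and area normalization.

Passing recovery tests therefore demonstrates that the estimators are
correct and unbiased *under these generative assumptions*; they cannot
certify performance on real microscopy, where segmentation errors, uneven
illumination and biological heterogeneity dominate.

## Validation strategy and problem sizes

The test suite checks hand-computed reference values for every closed-form
operation, property-based invariants (Oh route identity to 1e−9 over random
specs; K_sp monotone in U; Bo independent of U and η; affine invariance of
the CBF estimate; gating monotone in thresholds; spacing equivariance under
rescaling), and end-to-end parameter recovery: 200 seeded CBF replicates
per frequency at SNR 5 with ≥95% required within ±0.1 Hz; 50 seeded gating
tables at 10.6% and 2.8% infected within ±1.5/±1.0 points; 20 junction
fields within 15%; 20 dextran series within ±0.05/h; viability within ±2
points. Replicate stacks use small spatial footprints (8×8 px), since ROI
averaging makes the trace statistics independent of field size; these sizes
keep the full suite under half a minute while leaving the per-trace
statistics (1024 frames, SNR 5) at the study's recording conditions.

## Known limitations

* The auto-gate's unimodal fallback encodes polarity assumptions (DAPI
  positive, GFP negative); cultures that are uniformly infected need fixed
  thresholds.
* The junction-spacing estimator assumes a connected boundary network;
  sparse or broken networks reduce peak counts and widen the estimate.
* Blob counting undercounts at high spot density (overlap); the generator's
  non-overlap constraint sidesteps this regime rather than solving it.
* Flux normalization assumes the apical concentration stays approximately
  constant (short sampling window, small transported fraction).
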