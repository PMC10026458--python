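# Methods

## Relaxivity model

The recipe model assumes both relaxation rates are affine in the two
ingredient concentrations over the calibration range:
`R = r0 + r_ni·[Ni2+ mM] + r_ag·[agarose %w/v]`, with R in 1/s computed as
1000/T(ms). The two planes (R1, R2) are fitted independently by ordinary,
unweighted least squares; residual standard deviations are stored on the
model so that inadequacy of the pure plane (e.g. a neglected Ni–agarose
cross-term) stays visible rather than silent. Recipe design inverts the
2×2 slope matrix exactly; a design is rejected only when a solved
concentration is negative — no further physicality prior is imposed, so a
target with T2 > T1 merely warns.

Degenerate calibrations are classified by the rank of the *centered*
concentration matrix: rank 0 (all rows share one recipe) degrades to an
intercept-only fit with zero slopes; rank 1 (recipes on a line) is an
error, because the two slopes are then not identifiable.

The default fit excludes the outer-matrix row of the embedded calibration
table: the outer fill is a different formulation (HDPE-bead loaded) and is
not part of the tube recipe chemistry. On the embedded benchtop (1.4 T)
data the fitted R1 slope on one concentration column is ~−2.6e-4 1/s —
statistically indistinguishable from zero — so sign-based monotonicity
properties (e.g. "more Ni strictly shortens T1") are only guaranteed by
the clinical-field (1.5 T / 3 T) fits, where all four slopes are positive.

## Virtual phantom

Geometry: nine 24 mm disks on a 30 mm pitch inside a 100×100 mm body,
rasterized by pixel-centre point sampling (no partial-volume weighting —
partial volume is explicitly out of scope). The default pixel size is
1 mm; most tests use 2 mm for speed. Corner positions hold the
short/stable tubes, matching the physical device's layout convention, and
the QA corner group is fixed to tubes {A, B, F, I}.

Truth values default to the embedded calibration table at the chosen
field strength. The outer fill was characterised on the benchtop only;
its 1.4 T values are reused at clinical fields since it is not a QA
target.

Temperature is modelled per compartment as linear about the 22 °C
reference: slopes default to +0.8 %/°C for T1 and −0.4 %/°C for T2 of the
compartment's reference value — magnitudes typical of NiCl2/agarose gels
near room temperature, with the signs (T1 rises, T2 falls) and the
longer-tubes-drift-more property built in. Slopes are user-overridable but
must respect the sign constraints; results are clamped positive and a
sweep that would drive a relaxation time non-positive raises.

### Sequence simulators

Reference IR-GRE and single-echo SE are exact closed forms
(`|1 − 2e^(−TI/T1) + e^(−TR/T1)|` and `(1 − e^(−TR/T1)) e^(−TE/T2)`), with
the standard protocols: TI ∈ {20…2100} ms (11 values), TE ∈ {10…150} ms
(10 values), TR 10 s, evaluated per pixel.

MOLLI and T2-prepared bSSFP are event-chain Bloch simulations run once
per compartment (every pixel in a compartment shares T1/T2): RF pulses
are instantaneous rotations about x with alternating sign, separated by
exact on-resonance relaxation over one readout TR; inversions are ideal
(efficiency 1) with crushed transverse magnetization; T2 preparations
scale Mz by exp(−TEprep/T2) with the residual transverse spoiled. Readout
trains use a linear flip-angle ramp and record the echo of the centre
pulse (linear phase-encode ordering) with the TR/2 transverse decay
applied.

Defaults: T2-prep — TEprep {0, 25, 55} ms, FA 70°, 65 pulses at 2.8 ms
TR, 10-pulse ramp, 3 recovery beats at RR 900 ms. MOLLI — 5s(3s)3s read
as beats at RR 900 ms (second inversion at beat 8), FA 35° at 1.5 T / 20°
at 3 T, first TI 100 ms, second-train TI offset 80 ms, 32-pulse readout.
The shorter MOLLI train is a geometric necessity: with the centre pulse
in the middle of the train, a 65-pulse readout would place the k-space
centre 119 ms after the readout starts, which cannot realise a first
image at TI = 100 ms; 32 pulses put the centre at 74 ms. Effective TI
(inversion to k-space centre) is recorded as the frame parameter.

Two consequences of tracking the coherent transverse chain are worth
knowing. First, T1 recovery between the T2 preparation and the k-space
centre adds a TEprep-independent signal offset, which a 2-parameter
exponential fit converts into a *positive* T2 bias that grows as T1
shortens — the mechanism behind bSSFP mapping reading high against the
spin-echo reference, most severely for the short-T1 post-contrast tube.
This offset does not vanish with the flip angle; the true "weak-readout"
limit in which the signal becomes a pure exponential in TEprep requires a
short train as well (the test uses FA 5°, 4 pulses at 0.5 ms). Second,
the echo at the centre pulse is a T2-weighted running sum of earlier
tips, i.e. a linear filter on the inversion-recovery transient; the
filter's gain at the recovery rate differs slightly from its DC gain, so
B/A deviates from 2 and the Look-Locker correction is not exact even as
FA → 0 (≤1.5 % over T1 400–1300 ms in our tests). At the default 35°,
apparent T1* is depressed well below truth and the correction brings it
back to within a few percent, with the residual underestimation growing
with T1 — the familiar MOLLI behaviour.

Field-mapping acquisitions are closed forms: dual-echo complex frames
with phase 2π·Δf·TE and SE-like magnitude; double-angle frames
∝ sin(b1_rel·α) at long TR. Field conditions default to uniform Δf = 0
and b1_rel = 1; a radial-droop preset mimics the stronger relative-FA
variation seen at 3 T (centre ~0.66).

Noise is Rician on magnitude frames (complex Gaussian of SD σ per
channel, then magnitude) and additive complex Gaussian on field-mapping
frames; a seed fully determines the realisation and σ = 0 is the
identity.

### What the generator does and does not emulate

It emulates compartment geometry, sequence timing, readout-induced bias,
Rician statistics, B0/B1 inhomogeneity and temperature drift. It does not
emulate partial volume, motion, k-space/raw reconstruction, parallel
imaging, magnetization transfer, off-resonance inside the bSSFP passband,
variable RR triggering, or vendor-specific readout details. Passing tests
therefore demonstrate the correctness of the analysis chain and the
qualitative sequence physics (bias signs and orderings), not quantitative
agreement with any particular scanner's absolute bias.

## Map fitting

All models are single exponentials with linear nuisance parameters, so
fitting is by variable projection: for a fixed rate the linear
coefficients have closed-form least-squares solutions, reducing each
pixel to a 1-D profiled search over the rate. That search is a log-spaced
coarse grid (96 points over T ∈ [0.5 ms, 20 s] for T1, [0.5, 5000] ms for
T2) followed by four per-pixel zoom stages and a parabolic refinement —
deterministic, vectorized over pixels, immune to initialization failures,
and accurate to ~1e-5 relative on noiseless data (tests compare against
independent dense grid searches). Magnitude IR data is polarity-restored
by fitting every candidate flip index (frames 1..k negated) on the coarse
grid and refining the best; RSS ties break toward the smaller index.
Pixels with no positive signal, out-of-range rates, or B/A ≤ 1 (MOLLI
correction undefined) are flagged unconverged — values become NaN but
diagnostics (A, B, T1*, flip index) are retained. The T2 fit is
2-parameter by default; a 3-parameter offset variant is available since
product implementations differ.

## QA statistics

ROIs are circles of half the tube radius centred on the tube-mask
centroid (optional manual offsets; an ROI escaping its tube raises).
Statistics use arithmetic means and n−1 sample SDs throughout — including
two-point CoV, which is what reproduces the published 1.25 % maximum from
the 12-month table. Percent-difference denominators follow the benchmark
tables: the spin-echo reference for bias tables, the baseline scan for
reproducibility tables. Report rounding is half-away-from-zero at the
displayed precision (integers for ms, one decimal for %, one significant
figure for ppm) and is never applied to stored values. The qualification
threshold is CoV ≤ 2.7 %, boundary inclusive, adopted as published.

## Problem sizes and acceptance script

The acceptance script uses 2 mm rasterization (50×50) for the noiseless
recovery, bias, field-map and temperature checks, and the default 1 mm
rasterization for the short-term reproducibility experiment so the
half-radius ROIs carry their design pixel count (~110 pixels). SNR 100 is
defined against each sequence's peak clean signal. Reproducibility uses 3
repeats; all sub-seeds derive from the `--seed` argument.

## Known limitations

* The linear relaxivity plane ignores Ni–agarose interaction; residual
  SDs on the model quantify the cost on the embedded calibration data.
* The Bloch chains are on-resonance and single-compartment; bSSFP
  off-resonance banding is not modelled, so B0 conditions affect only the
  field-mapping sequences.
* Simulated absolute sequence biases depend on unpublished readout
  details (TEprep list, train length, ordering); only their signs and
  orderings are treated as meaningful.
* The temperature model is phenomenological and linear; real gels curve
  over wide ranges.
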