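# t2phantom

A virtual nickel-chloride/agarose phantom for the quality assurance of
cardiovascular MR T1/T2 mapping.

Quantitative myocardial T2 mapping lacks a standard reference object:
measured T2 varies with scanner, sequence and software, which hampers
multi-centre studies and longitudinal follow-up. A physical QA phantom for
this purpose is a 3×3 array of nine 24 mm agarose-gel tubes doped with
NiCl2, spanning the clinically relevant myocardial T2 range (~43–74 ms)
at both 1.5 T and 3 T, embedded in an HDPE-bead-loaded gel matrix inside a
10×10 cm body. This package implements the full computational chain around
such a device, so that every analysis step can be developed and tested
without scanner time:

* **Recipe design** (`t2phantom.recipe`) — both relaxation *rates* are
  modelled as linear in the ingredient concentrations,

  ```
  R1 = 1/T1 = r1_0 + r1_ni [Ni2+] + r1_ag [agarose]
  R2 = 1/T2 = r2_0 + r2_ni [Ni2+] + r2_ag [agarose]
  ```

  fitted by ordinary least squares to a benchtop calibration table; any
  target (T1, T2) pair then maps to a recipe by solving the 2×2 system.
* **Virtual phantom** (`t2phantom.phantom`, `t2phantom.simulate`) —
  rasterized tube geometry with per-compartment truth, Rician noise,
  B0/B1 field conditions, a linear temperature model, and Bloch-event
  simulators for every acquisition used to qualify the device: reference
  inversion-recovery gradient echo and single-echo spin echo (TR 10 s),
  MOLLI 5s(3s)3s T1 mapping, T2-prepared bSSFP T2 mapping, dual-echo B0
  mapping and double-angle B1 mapping.
* **Map fitting** (`t2phantom.fitting`) — pixel-wise mono-exponential T2,
  three-parameter inversion recovery `|A − B exp(−TI/T1)|` with polarity
  restoration, and MOLLI T1* with the Look-Locker correction
  `T1 = T1*(B/A − 1)`, all via a deterministic variable-projection search.
* **Field maps** (`t2phantom.fieldmaps`) — phase-difference off-resonance
  `Δf = ∠(S2 S1*)/(2π ΔTE)`, ppm conversion with γ = 42.576 MHz/T, the
  double-angle flip-angle map `arccos(S(2α)/2S(α))`, and the
  displacement-current ratio Q = ωε/σ.
* **QA statistics** (`t2phantom.qa`) — ROIs over the central 50 % of each
  tube radius, bias vs the spin-echo reference with corner/central group
  summaries, coefficients of variation, long-term reproducibility rows,
  temperature trends and the CoV ≤ 2.7 % qualification verdict.
* **Benchmark tables** (`t2phantom.tables`) — the device's published
  calibration (tube recipes and T1/T2 at 1.4/1.5/3 T), bSSFP-vs-SE
  comparison and 12-month reproducibility tables, embedded as fixtures.

## Worked example

Design a tube hitting T1 = 600 ms, T2 = 45 ms under the 1.4 T benchtop
calibration model:

```
$ t2phantom design --t1 600 --t2 45 --field 1.4T
agarose_pct: 1.9323
ni_mM: 2.7105
```

i.e. a gel with 1.93 % w/v agarose and 2.71 mM NiCl2. Feeding this recipe
back through the forward model reproduces (600, 45) exactly — the
forward/inverse pair is exact linear algebra.

Re-derive the published QA arithmetic from the embedded tables:

```
$ t2phantom reproduce-tables
PASS 1.5T mean |diff| ms: 6.3 (expected 6.3)
PASS 1.5T mean |diff| %: 12.5 (expected 12.5)
PASS 1.5T corner |diff| ms: 8.5 (expected 8.5)
...
all benchmark-table checks passed
```

The 6.3 ms [12.5 %] figure is the mean absolute deviation of T2-prepared
bSSFP mapping from the long-TR spin-echo reference over the nine tubes at
1.5 T; corner tubes deviate more (8.5 ms) because of the short-T1
post-contrast tube in the corner, whose bias (15 ms, 36.6 %) is a known
property of bSSFP readouts at short T1 — the simulators reproduce the sign
and ordering of that bias from the Bloch equations.

A full in-silico session (simulate → fit → QA):

```bash
t2phantom simulate --sequence se          --seed 1 --out ref.nii
t2phantom simulate --sequence t2prep_bssfp --seed 2 --out map.nii
t2phantom fit --input ref.nii --method t2_monoexp --threshold 1e-6 --out ref_t2.nii
t2phantom fit --input map.nii --method t2_monoexp --threshold 1e-6 --out map_t2.nii
t2phantom qa --mapped map_t2.nii --reference ref_t2.nii --out qa/
```

which writes a per-tube bias table (CSV) and a JSON summary of all-tube,
corner and central mean deviations.

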