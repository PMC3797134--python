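# aptcest

Quantitative amide proton transfer (APT) CEST MRI analysis: z-spectrum
assembly, pixel-wise B0 correction, MTR-asymmetry mapping, and
reference-normalized ROI group statistics — together with a Bloch-McConnell
exchange simulator that generates fully ground-truthed synthetic phantoms,
so every stage of the chain can be validated end to end.

It is written for researchers analysing saturation-transfer image stacks
(one image per saturation offset plus an unsaturated S0 control) from
small-animal tumor studies, and for anyone who wants a desk-scale, testable
model of the whole APT quantification chain.

## The quantities computed

A z-spectrum is the normalized water signal versus saturation offset,
Z(x) = S_sat(x)/S0, with x in ppm from water (downfield positive). The
package computes, per pixel and per ROI:

- **MTR** = 1 − S_sat/S0;
- **MTR_asym(x)** = MTR(+x) − MTR(−x) = Z(−x) − Z(+x); at x = 3.5 ppm (the
  backbone amide resonance) this is the APT-weighted value, and its
  per-pixel image is the APT-weighted map;
- **corrected MTR_asym** = tumor MTR_asym − spinal-cord MTR_asym, which
  removes the intrinsically asymmetric background MT/NOE contribution
  shared by the tissues (cord asymmetry is itself slightly negative);
- per-offset **two-sample pooled Student's t-tests** between animal groups.

B0 inhomogeneity shifts each pixel's apparent water centre; before any
asymmetry is computed the spectrum is fitted (Gaussian water well +
12th-order polynomials per offset sign side), the well minimum located on a
fine grid, and the spectrum re-sampled so the minimum sits at 0 ppm. See
`docs/methods.md` for the model, defaults and numerical choices.

## Worked example

```bash
aptcest demo --out demo --seed 1 --n-per-group 6
```

simulates a 12-animal study (two groups whose true corrected asymmetries
are 2.7 % and 7.8 % with 1.5 pp inter-animal spread), writes the stacks,
runs the full analysis and prints:

```
cohort of 12 animals written to demo/data
12 animals analyzed; 0 failed
corrected MTR_asym(3.5 ppm) A549: 2.6 ± 1.6 % (n=6)
corrected MTR_asym(3.5 ppm) LLC: 7.8 ± 0.9 % (n=6)
Student's t-test: t = -6.86, p = 0.0000 (significant at 0.05)
```

The recovered group means (2.6 % and 7.8 %) match the simulated truth
within sampling error, and the group difference is detected at the 0.05
level. `demo/results/` contains the per-animal APT and B0 maps (TIFF), the
per-animal ROI table, the per-offset group table and a JSON run report.

Published mean ± SD values can be checked directly without raw data:

```bash
aptcest stats 7.8 3.9 6 2.7 1.9 6
# t = 2.8796, p = 0.0164
```

The same functionality is available as a library:

```python
from aptcest import (PhantomSpec, generate_phantom_stack, build_apt_map,
                     phantom_rois)

stack, truth = generate_phantom_stack(PhantomSpec(seed=1))
apt = build_apt_map(stack)          # B0-corrected MTR_asym(3.5 ppm) map
print(truth.tissue_asym["tumor_a"]) # simulator ground truth for comparison
```

## CLI

- `aptcest simulate` — one phantom stack + schedule + ROIs + ground truth;
- `aptcest cohort` — a multi-animal synthetic study with analysis manifest;
- `aptcest analyze` — run the pipeline over a manifest of real or synthetic
  stacks (NIfTI or multi-page TIFF; exits non-zero if any animal fails);
- `aptcest stats` — pooled t-test from summary statistics;
- `aptcest demo` — the worked example above.

Conventions: pixel coordinates are 0-based row/col; schedule files list
offsets high-to-low (+6 → −6 ppm) as acquired; stacks store one image per
offset in schedule order with the S0 control last.

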