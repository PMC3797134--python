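# Methods

## The measurement being modelled

Amide proton transfer (APT) imaging is the CEST variant that targets
backbone amide protons of mobile proteins and peptides, resonating about
3.5 ppm downfield of water. A long off-resonance saturation pulse saturates
the amide protons; chemical exchange carries that saturation into bulk
water, depressing the water signal. Sweeping the saturation offset over
±6 ppm and normalizing by an unsaturated control image gives the z-spectrum
Z(x) = S_sat(x)/S0 per pixel. The APT-weighted quantity is the magnetization
transfer ratio asymmetry

    MTR_asym(x) = MTR(+x) − MTR(−x) = Z(−x) − Z(+x),

evaluated at x = 3.5 ppm. Because the background magnetization-transfer (MT)
and nuclear Overhauser contributions are not symmetric about water, tissue
MTR_asym carries a negative offset even without amide exchange; the pipeline
therefore also reports a *corrected* asymmetry, tumor minus a spinal-cord
reference ROI, which is the quantity compared between groups.

## Bloch-McConnell simulation

Pools (bulk water, amide, optional broad MT pool) exchange in a star
topology with water; detailed balance fixes the reverse rate as
`fraction × exchange_rate`. Under a continuous-wave block pulse the coupled
magnetizations obey a linear time-invariant ODE dM/dt = A M + c, which we
solve with the exact matrix exponential
M(t) = M_ss + expm(A t)(M0 − M_ss), M_ss = −A⁻¹c. Two independent routes
check it: a stiff ODE integration (Radau, rtol 1e-8) and the stationary
linear solve. The matrix-exponential solution is exact for this system, so
it is the default; the ODE route exists purely as a cross-check (it is slow
for long pulses because it tracks megacycles of off-resonance precession).

Default parameters (all configurable):

| parameter | default | units | note |
|---|---|---|---|
| field strength | 7 | T | small-animal scanner |
| B1 amplitude | 1.7 | µT | CW block pulse |
| saturation time | 4 | s | gating idealized as one uninterrupted pulse |
| offsets | +6…−6, step 0.5 | ppm | 25 offsets plus S0 control |
| water T1 / T2 | 1.8 / 0.05 | s | tissue at 7 T |
| amide T1 / T2 | 1.0 / 0.001 | s | see linewidth note below |
| amide shift | +3.5 | ppm | downfield positive |
| amide exchange rate | 100 | s⁻¹ | base-catalyzed amide exchange regime |
| amide fraction | 1e-3 (muscle/cord), 3e-3 (tumor) | — | tumors have elevated mobile protein |
| MT pool fraction / T2 / shift / rate | 0.05 / 60 µs / −2.4 ppm / 40 s⁻¹ | — | broad, slightly upfield |

**Amide linewidth.** The amide dip's width at 1.7 µT is roughly
√(ω1² + (R2b + k)²); with T2b = 1 ms and k = 100 s⁻¹ it is ~0.6 ppm, which
the 0.5 ppm acquisition grid samples adequately. A much slower/narrower
amide pool (e.g. T2b = 10 ms, k = 30 s⁻¹, dip ~0.25 ppm) produces a feature
that *no* interpolation from these offsets can resample reliably, and the
B0 round-trip accuracy targets below become unattainable for any
implementation of the stated correction; the defaults were chosen in the
adequately-sampled regime, which is also where in-vivo spectra (broadened by
overlapping resonances) live.

**MT pool.** A Lorentzian-broadened pool (T2 = 60 µs) centred at −2.4 ppm
reproduces the intrinsically negative reference-tissue asymmetry: cord
(amide fraction 1e-3 + MT) simulates to MTR_asym(3.5) = −2.4 %, inside the
−4…−1 % range reported for spinal cord and normal brain. Tumor tissue
(fraction 3e-3 + MT) simulates to +3.3 % raw, +5.8 % corrected. These
magnitudes — not real exchange biology, which is unreported for these cell
lines — are what the defaults are calibrated to. A true super-Lorentzian
semisolid lineshape is out of scope.

## Synthetic phantom and cohorts

The phantom is a single axial thorax slice: an elliptical muscle body, two
air lungs (near-zero S0, masked downstream), one or two tumor nodules inside
the lungs, a spinal-cord disk, a smooth B0 surface (peak ±0.3 ppm by
default, within the ±0.5 ppm design range), and additive zero-mean Gaussian
noise (σ = 1 % of muscle S0 by default, i.e. SNR ≈ 100 — a Rician floor
matters only in the air, which is masked, so the Gaussian model keeps the
oracles analytic). The local B0 value enters as a shift of the irradiation
offset; per-pixel spectra are shared between pixels of the same tissue and
quantized B0 value (step 0.005 ppm, an order of magnitude below the
correction's fine grid).

Cohorts draw each animal's *true corrected asymmetry* from a normal
distribution around the group mean (default A549 2.7 %, LLC 7.8 % — the
reported group means — with inter-animal SD 1.5 percentage points, at the
level of the less variable reported group), then invert the monotone
fraction→asymmetry map by bisection to get that animal's tumor amide
fraction. Working on the asymmetry scale makes the simulated group
difference exactly the quantity the pipeline must recover.

What the generator does **not** emulate: respiratory motion (the modelled
acquisition is gated), fast-spin-echo readout and echo-train blurring,
coil-sensitivity shading, Rician noise, partial-volume mixtures at tissue
boundaries, and B1 inhomogeneity. Passing tests therefore demonstrate
correctness of the analysis chain under ideal gated acquisition, not
robustness to those effects.

## Z-spectrum assembly and masking

Pixels are valid iff S0 exceeds 5× the background noise, estimated as the
standard deviation of the darkest corner patch (side/8 pixels) of the S0
image; with zero noise a tiny positive threshold still rejects exact-zero
air. Division at low S0 is handled by masking, never by clipping or
imputation. Spectra are stored ascending in offset; the acquisition
(high-to-low) order lives only in files.

## B0 correction

Per pixel: (1) a Gaussian well (amplitude, centre, width, baseline) is
fitted to the direct-saturation dip over |x| ≤ 2 ppm; its minimum on a
0.002 ppm grid is the B0 estimate. (2) 12th-order polynomials are fitted to
the positive- and negative-side points separately (0 ppm in both, Chebyshev
basis on the side rescaled to [−1, 1]) and serve as the interpolant.
(3) The corrected spectrum is the interpolant resampled at
(nominal offset + B0), putting the water minimum at 0 ppm; resampled points
beyond ±6 ppm are flagged extrapolations and the ±6 ppm offsets excluded
from ROI statistics when flagged.

Numerical rationale, established empirically during design:

- With 13 points per side, the order-12 fit is exact interpolation. Its
  argmin is *not* a usable centre estimator: the water line is nearly fully
  saturated over ~1 ppm and the interpolant oscillates between nodes at the
  well's foot, biasing the argmin by >0.1 ppm. The Gaussian centre recovers
  injected shifts to <0.01 ppm (noise-free).
- Subtracting the Gaussian before the polynomial fit makes matters worse:
  the well bottom is flat (fully saturated) where a Gaussian is curved, the
  nodal residuals alternate in sign, and the interpolant of that alternation
  rings with amplitude ~0.27 near |x| > 4 ppm. The polynomials therefore fit
  the raw spectrum.
- The fine grid is 0.002 ppm because the B0 estimate is snapped to it and a
  0.005 ppm snap error times the spectrum's slope asymmetry (~7 %/ppm)
  would consume most of the 0.1 pp map-error budget.
- Estimates are unreliable (pixel masked) when the well is shallower than
  5 % of the spectrum range, the centre hits the search boundary, or
  |B0| > 1 ppm.
- The whole-image path vectorizes the same computation; its Gaussian stage
  is Guo's iteratively reweighted log-linearization (3 iterations), which
  matches the per-spectrum nonlinear fit to a few 0.001 ppm noise-free.

Measured on the default noise-free phantom: B0 map RMS error 0.010 ppm;
APT-map worst-pixel error 0.094 pp; round-trip perturbation of the corrected
3.5 ppm value ≤0.05 pp over injected shifts in ±0.5 ppm.

## ROI statistics and group comparison

ROIs are circles (centre in 0-based row/col pixels, area in mm²; pixels
included iff centre distance ≤ radius, always keeping the centre pixel).
Synthetic-phantom ROIs sit at tissue centroids with a 2 mm² default area —
larger than the 0.34 mm² in-vivo protocol ROI because the phantom grid
(64 px over 30 mm) is coarser than a 256 matrix. Per animal, tumor ROI
asymmetry spectra are averaged unweighted; the corrected spectrum subtracts
the single cord ROI offset-wise (exact identity, tested to machine
precision). Groups are compared per offset with a two-sample two-tailed
pooled-variance Student's t-test at α = 0.05. Pooled (not Welch) matches the
convention of the study being reproduced, and the printed P = 0.01 for the
2 ppm comparison is consistent with the pooled computation. No
multiple-testing correction across the 12 offsets by default (per-frequency
testing convention); `holm=True` enables a Holm step-down adjustment. Exact
zero-variance groups short-circuit to t = 0, p = 1 (equal means) or a
flagged degenerate p = 0 (unequal means); "zero" is detected by range, not
variance, to dodge floating-point cancellation.

## Problem sizes in tests and the acceptance script

Simulation-heavy checks run on reduced grids chosen so each suite completes
in minutes on one core while keeping every ROI several pixels wide: 64 px
phantoms for map-accuracy checks, 48 px for noise-free cohort recovery,
32 px for the 100-replicate power study, 2000 replicates for the type-I
calibration. Sizes are configuration, not approximations baked into the
library.

## Known limitations

- The corrected spectrum is fit-resampled, so its values are only as good as
  polynomial interpolation of 0.5 ppm-spaced samples; features narrower than
  ~0.4 ppm are not faithfully recovered (see amide linewidth note).
- The B0 estimate is the *apparent* water-centre shift; asymmetric CEST/MT
  background pulls it a few 0.001 ppm away from the injected field. This is
  a property of the method, shared by any minimum-centring scheme.
- The reference subtraction assumes cord and tumor share the same background
  asymmetry; in the simulator they do by construction (same MT pool), in
  real tissue only approximately.
- Respiration, readout and B1 effects are outside the model (above).
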