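# Methods

## Signal model and conventions

All processing happens in the time domain. An FID is a complex series
sampled at the dwell time 1/bandwidth starting at t = 0; a resonance offset
of +f Hz from the carrier appears at `center_ppm + f/f0` on the ppm scale,
and spectra are displayed on a decreasing ppm axis aligned with the DFT bin
grid. The carrier sits on water at 4.7 ppm by default (the in vivo ppm
reference; configurable for phantom work referenced to DSS). FIDs are kept
unapodized throughout the pipeline; exponential line broadening exists only
as a display/diagnostic utility. Spectra are zero filled to 8192 points
(from 1024 acquired) for display and peak picking; the fits never need it.

Default acquisition blocks mirror a typical 3 T editing protocol:
MEGA-PRESS at TR/TE 2000/68 ms and PRESS at TR/TE 5000/30 ms, both with
2000 Hz bandwidth and 1024 complex points, f0 = 127.74 MHz.

## Synthetic data

The simulator emulates the *structure* of an interleaved editing
examination — 40 blocks, each one unsuppressed water reference followed by
4 ON/OFF pairs (320 edited transients), plus a separate reference scan —
with known ground truth. Metabolite signals are parametric multiplets (sums
of damped complex exponentials, Lorentzian envelope exp(−πWt) or Gaussian
exp(−(πWt)²/4ln2)); the edited metabolites enter only the ON transients, so
mean(ON) − mean(OFF) equals the weighted basis sum exactly in the noiseless
limit. Controlled imperfections: linear B0 drift per block (drift shape
beyond linear is not modelled), a global zero-order phase, residual water,
and i.i.d. complex Gaussian noise (`noise_sd` is the SD of each quadrature;
no autocorrelation). `amplitudes_for_concentrations` inverts the
quantification chain so that a simulated examination has a single known
C_GABA under every reference method.

What the simulator does *not* emulate — and what passing tests therefore do
not demonstrate about real data: true J-evolution lineshapes under the
editing pulses (the multiplets are phenomenological stand-ins for measured
in vitro basis spectra), frequency/phase jitter within a block, lipid and
broad macromolecule baselines, and subject motion. Multiplet positions use
standard chemical shifts (GABA pseudo-triplet at 3.01 ppm with J ≈ 7.3 Hz
satellites and a 2.28 ppm group, Glu 2.35/3.75, Gln 2.45, NAA 2.008 with
small aspartyl lines, NAAG as NAA shifted to 2.045 ppm; OFF singlets tCho
3.185, tCr 3.027, tNAA 2.008); relative amplitudes and linewidths in
`data/multiplets.json` are editable package choices.

The GABA+ basis member is built from the pure-GABA model by adding one
Lorentzian line (5 Hz FWHM) on the central component of the 3 ppm
pseudo-triplet, sized to make the central peak 1.10× the outer peaks —
an empirical macromolecule-contamination model. Since a multiplet carries
one common linewidth, the added line inherits the GABA model width when the
two differ; the t = 0 amplitude target is preserved exactly.

## Preprocessing

Fixed order: drift correction → eddy-current correction → averaging →
residual-water removal. Each block's offset is estimated once from its
water reference (dominant component of a low-order Hankel-SVD
decomposition) and applied to all transients of that block, mirroring the
acquisition structure. Eddy-current correction subtracts the water phase
sample-wise (Klose); whether it runs before or after drift correction is
immaterial to within the noise floor (regression-tested), and the order
above was fixed as a convention. Zero-order phase is *not* corrected here —
both fitting engines estimate it as a free parameter.

Residual water removal decomposes the averaged OFF FID into damped
sinusoids via Hankel SVD (state-space/Kung variant: SVD-truncated Hankel
matrix, poles from shift invariance of the left singular vectors,
amplitudes by linear least squares) and subtracts the components inside the
water band. Defaults: model order 25, band 4.4–5.0 ppm, Hankel matrix built
from at most 1024 points. Removal is idempotent to within 1 % energy and
preserves a 3.03 ppm singlet to within 1 %.

## Fitting

Both engines minimize the squared time-domain residual (stacked
real/imaginary) with bounded trust-region least squares.

*Singlet engine* (OFF spectrum): per peak an amplitude a ≥ 0, a frequency
bounded within ±`shift_tol_ppm` of the prior position, a linewidth within
prior bounds; one global zero-order phase. Initialized by linear projection
of the data onto the prior lineshapes. Analytic Jacobians are supplied to
the optimizer.

*Basis engine* (difference spectrum): nonnegative amplitude per basis
metabolite — nonnegativity is the conservative reading of "constrained"
basis fitting — plus a common frequency shift Δf ∈ [−20, 20] Hz, a common
extra damping (FWHM 0–25 Hz; Gaussian shape for GABA+, Lorentzian for the
rest) and a zero-order phase. The amplitudes are profiled out by NNLS
inside the 3-parameter outer problem; the outer optimisation is
multi-started at Δf ∈ {−5, 0, +5} Hz to escape local minima, short-circuited
when a start already reaches the numerical noise floor. No baseline is
fitted in the difference spectrum — a documented limitation; macromolecule
contamination is handled entirely by the GABA+ basis construction and
MM_cor. "Shape peak selection" as practised by some basis-fitting tools has
no published definition and is deliberately not implemented.

*Uncertainties*: the Fisher information F = (1/σ²)·Re(JᴴJ) is assembled
from analytic model derivatives over **all** free real parameters
(amplitudes, frequencies/shift, widths/damping, phase — parameter
correlations with the phase are therefore included), and the CRSD of an
amplitude is the square root of its diagonal entry of F⁻¹. σ is estimated
from the last 10 % of the fit residual (the FID has decayed into noise
there); a known σ can be supplied instead. The percentage fit error is
100·CRSD/amplitude, undefined (reported missing) at zero amplitude.
Monte-Carlo checks hold SD/CRSD within [0.8, 1.3] at SNR 20.

## Quantification

Equations and constants as in the README. Numerical decisions:

* The trailing factor of the water-reference concentration is a *division*
  by (1 − f_CSF): W_conc is expressed per kilogram of CSF-free tissue,
  the convention of the quantification literature this chain follows.
* The proton-count normalization of the water-referenced equation is
  2/N_GABA (= 1 for the two C4 protons); MM_cor/eff_GABA = 0.5/0.5
  contributes exactly 1 but both factors are carried explicitly and
  overridable.
* MM_cor applies identically in the water- and metabolite-referenced
  equations, as both contain the same edited-intensity numerator.
* Concentrations are molal (mol/kg wet weight) internally and reported in
  mmol/kg; no molarity conversion is offered.
* Default relaxation times (3 T literature values) and physical constants
  live in `data/relaxation_constants.json`; every value can be overridden
  through `RelaxationTable`/`QuantConstants`.
* Reference metabolite concentrations from the PRESS scan use the same
  W_conc water scaling evaluated at the reference sequence's TR/TE, with
  explicit metabolite attenuation correction (the long-TR/short-TE timing
  makes these corrections small, which is why that sequence anchors the
  reference concentrations).

Degenerate inputs fail loudly: all-zero tissue fractions, a pure-CSF voxel,
nonpositive water intensity or relaxation times, and unknown reference
metabolites all raise with specific messages; a singular Fisher information
reports the near-degenerate parameter pair.

## Problem sizes in the test suite

Simulation-backed tests run 3–8 blocks rather than the protocol's 40 (the
pipeline is linear in blocks, so block count affects only SNR, which the
tests set explicitly through `noise_sd`), 100–200 noise draws for
Monte-Carlo bias/CRSD calibration, and a 3 × 3 amplitude-by-SNR grid with
20 draws per cell (coverage of ±1.96·CRSD intervals pooled across the
grid). These sizes are the package's choice of study design for stable yet
quick statistical checks.

## Known limitations

* Parametric multiplets, not density-matrix simulation: editing efficiency
  is not emergent but enters as the constant eff_GABA, matching the
  structure of the quantification equations.
* No first-order phase fitting, no soft constraints between singlets, no
  spline/wavelet baselines.
* Drift correction assumes one offset per block (from its single water
  reference); intra-block drift is uncorrected.
* Transient-level outlier rejection and spectral-registration
  frequency/phase alignment are out of scope.
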