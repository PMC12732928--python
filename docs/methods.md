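# Methods

`oligostate` determines the oligomeric state of a self-associating protein by
reconciling four measurement modalities. Each analysis module implements the
standard reduction for its technique; a synthetic-data module generates
instrument-realistic inputs with known ground truth so the whole chain is
testable without instrument data. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## Study conditions

The default generator parameters describe the system the pipeline was built
around: a ~17.4 kDa, predominantly α-helical ice-binding protein that forms
elongated oligomers in solution.

* MALDI: protonated oligomer ladder at m/z = (n·M + z·m_H)/z, M = 17 413.8 Da,
  n = 1…7, z = 1–2, intensity halving per oligomer order, optional ppm jitter.
* AFM: four particle size classes (semi-major axis a1 classes I–IV:
  5–20, 17–27, 28–44, 44–60 nm) with Gaussian per-class parameters
  (a1 means 14.2/24.0/32.8/51.1 nm; heights 1.57/1.86/2.43/1.90 nm).
* SAXS: elliptical-cylinder scatterer (minor semi-axis 77 Å, axis ratio 1.2,
  thickness 16 Å; analytic Rg 60.3 Å), 2% relative noise.
* ITC: 20 injections, 300 s apart, with total dissociation heat increasing
  as temperature drops (defaults 300/200/100 µJ at 15/25/37 °C).

Instrument noise magnitudes are module choices exposed in the config (SAXS 2%
relative; AFM background roughness 0.05 nm; ITC 0.02 µW): realistic for
modern instruments, and every tolerance below was set against them.

## SAXS reductions (`oligostate.saxs`)

**Guinier fit.** Weighted linear regression of ln I vs q² on the largest
low-q window satisfying q·Rg ≤ 1.3 (community convention, configurable),
found by iterating fit → recompute Rg → shrink window to a fixed point;
Rg = √(−3·slope). The finite window carries a known truncation bias — on a
sphere it overestimates Rg by ≈2% — so the exact closed forms are checked
through the IFT route, and the package's own cross-check requires the two
routes to agree within 3%.

**Cross-sectional Guinier.** For rod-like particles, ln(qI) vs q² gives the
cross-sectional radius of gyration Rc = √(−2·slope); the equivalent uniform
rod diameter is 2·Rc·√2. The default window, when none is given, iterates
from [1/Rg, q_max] to [1/Rg, 1/Rc].

**Dimensionless Kratky.** (qRg)²·I/I0 vs qRg; a compact globular scatterer
peaks at (√3, 3/e ≈ 1.104), flexible chains plateau. The peak is located by
quadratic interpolation through the maximum sample and its neighbours;
boundary maxima are reported as "no interior peak".

**Indirect Fourier transform.** P(r) on an n_r = 101 grid over [0, Dmax]
solves a non-negative least-squares problem: min ‖A p − b‖² + α‖D₂ p‖² with
p ≥ 0, P(0) = P(Dmax) = 0, where A is the 4π·sinc(qr) kernel weighted by the
per-point σ and D₂ the second-difference operator. Non-negativity is imposed
exactly (NNLS on the augmented design) rather than by an after-the-fact
penalty — P(r) of a mass density is non-negative, and the hard constraint
removes a ~0.5 χ²/N misfit floor the soft penalty left behind. α is chosen
by maximising a Gaussian-evidence score, 0.5·ln det(αD₂ᵀD₂) − 0.5·ln det(H)
− χ²/2 − α‖D₂p‖²/2 with H = AᵀA + αD₂ᵀD₂, over a 50-point log grid from
1e−2 to 1e8. Reported χ²_red uses N − tr(H⁻¹AᵀA) effective degrees of
freedom. `scan_dmax` scores candidate supports by evidence minus an
endpoint-smoothness penalty ((p at the penultimate node / max P)²) and
breaks ties toward the smallest Dmax within 1% of the best score.

**Form factors.** Sphere (closed form), circular cylinder, and elliptical
cylinder: A(q,α,ψ) = [2J₁(u)/u]·sinc(qL·cosα/2), u = q·sinα·a·√(cos²ψ +
ν²sin²ψ), orientation-averaged by fixed-order Gauss–Legendre quadrature
(order 76 per axis; self-converged to <1e−6 against order 152, and equal to
the circular-cylinder closed form at ν = 1 to the same level). Fitting holds
any subset of shape parameters fixed (the study fixes the 16 Å thickness
measured by AFM), profiles the scale and constant background analytically at
every step, and multi-starts `scipy.optimize.least_squares` from a coarse
geometric grid (≥5 starts) to avoid local minima.

**Mass from volume.** MW[kDa] = V[nm³]·N_A/(v̄·10²¹·10³); at the protein
default v̄ = 0.73 cm³/g the divisor is 1.212 nm³/kDa, so 105 nm³ → 86.6 kDa.
Published mass figures often imply effective divisors of 1.24–1.31, so the
divisor is always printed next to the value. The fitted analytic envelope
volume (π·a·b·L) is reported only as an upper bound: a loosely packed
assembly fills a fraction of its envelope, and the excluded volume of a
bead-model reconstruction — outside this package's scope — is taken as a
study input where a mass is needed.

**Semi-axis interpretation.** The "minor axis ~77 Å" of the cylinder model
is interpreted as the semi-axis: only then does the model's closed-form Rg
(60.3 Å) match the measured Guinier/IFT Rg of ≈60 Å. The fit report records
this convention.

## MALDI oligomer series (`oligostate.maldi`)

Peaks are modelled as [nM + zH]^z+ with average (not monoisotopic) masses —
linear-mode MALDI at 17–120 kDa does not resolve isotopes; the proton term
(~60 ppm at 17 kDa) is configurable off to reproduce a bare n·M convention.
The monomer mass is the weighted least-squares solution of z·(mz − m_H) =
n·M over anchor peaks. Assignment enumerates all (n ≤ 10, z ≤ 3) within a
two-tier tolerance — 500 ppm for n ≤ 4 and 2000 ppm from n = 5 up, because
high-order oligomer peaks broaden (the ladder's own z = 1 vs z = 2 readings
of the same oligomer can disagree by ~0.1%) — and keeps every candidate:
primary = smallest z, then smallest n (MALDI yields mostly singly charged
ions), the rest flagged as alternatives. Every (n, z) has an algebraically
degenerate (2n, 2z) twin, so the stoichiometry census counts primaries only,
while degenerate readings are listed explicitly; internally inconsistent
charge pairs are reported, never reconciled.

## AFM morphometry (`oligostate.afm`)

Scan lines are flattened by per-row polynomial background subtraction with a
robust mask (pixels below median + 2·MAD of the detrended residuals,
re-iterated three times so a background slope cannot inflate the spread
estimate). Images are then smoothed with a σ = 1 px Gaussian: the height
statistic is the footprint maximum, and without smoothing it would be biased
upward by the extreme value of the pixel noise over the footprint (~+3σ_noise
for typical footprints).

Particles are pixels above the 0.5 nm detection threshold — chosen because
protein-free control surfaces show nothing above 0.5 nm — grown down to a
footprint level of 0.15 nm (3× the background roughness) by hysteresis
thresholding; regions smaller than 4 px or touching the border are dropped.
Each footprint's equivalent ellipse comes from the second central moments of
the binary mask (semi-axes = 2√eigenvalues of the pixel covariance). Two
model-based corrections follow, both exact for the paraboloid cap the
generator renders and second-order for any smooth single-maximum particle:
the axes are scaled by 1/√(1 − level/z) to undo truncation of the cap at the
footprint level, and the height is divided by 1 − s²(1/a1² + 1/a2²) to undo
the Gaussian smoothing of the peak. Without the axis correction the bare
0.5 nm mask censors a 1.9 nm-high particle's axes by −14%, well outside the
recovery targets. S = √area is reported from the raw mask area (S_mask,
uncorrected — what a grain-analysis tool reports) alongside the
ellipse-based S_ellipse = √(π·a1·a2); population comparisons use S_mask.

Size classes overlap by construction (I and II share 17–20 nm); a particle
joins every class containing its a1 and carries a multi-membership flag,
preserving the published class bounds instead of inventing an exclusive cut.
Per-class statistics are the maximum-likelihood Gaussian parameters (sample
mean/sd); a histogram curve fit is stored as a diagnostic only.

The generator draws (a1, a2) as a correlated Gaussian pair (ρ = 0.7, a2
resampled into (0, a1]) — large particles are large in both axes, and with
independent draws the mean axis ratio would overshoot the reference
populations. Even so, a reference table's mean ratio cannot in general be
reproduced exactly by any generator matching the axis marginals
(mean-of-ratios ≠ ratio-of-means; the class III reference is ~7% below the
value its own axis means imply), so recovery tests hold drawn parameters
(a1, a2, z) to 3 standard errors + 5% and derived parameters (ratio, S) to
10%.

No tip-convolution model is included: at tip radii of 1–3 nm against
10–50 nm particles the broadening is second order. Synthetic caps are rigid
and isolated; the tests therefore say nothing about soft-particle
deformation, multilayer stacking, or crowded fields with merging footprints.

## ITC heats (`oligostate.itc`)

Each injection's heat is the trapezoidal integral of baseline-subtracted
power over [t_inj, t_inj + 290 s] (spacing 300 s). The baseline line is
fitted to the trailing 20% of the two segments bracketing the peak — the end
of the preceding inter-injection segment and the end of the injection's own
segment, where the single-exponential response (τ = 15 s) has decayed to
~1e−7. Anchoring both sides makes the integral insensitive to noise in the
fitted slope; a one-sided extrapolation amplifies a ~1.5e−4 µW/s slope error
into several µJ per injection at the default noise. Energy closure on
synthetic data: 0.5% clean, 2% with default noise and drift.

The endpoint is deliberately qualitative: per-temperature total |Σ heats|
and a strict-monotonicity verdict (|Q| decreasing with temperature).
Overlapping oligomer equilibria make a single-constant fit meaningless, so
no ΔH/K_d estimation is attempted.

## Cross-technique reconciliation (`oligostate.consistency`)

Stoichiometry candidates are ranked by |MW/M − n| (ties toward smaller n).
The dimensional checks print their tolerance bands so the qualitative claims
are auditable: rod diameter vs the 12 Å α-helix diameter within ±25%
⇒ "consistent"; AFM full major axis 2·a1 vs SAXS Dmax within ±35%
⇒ "matching", within a further 10% ⇒ "borderline" (both numbers always
printed — whether a1 or 2·a1 corresponds to Dmax is itself a modelling
choice, so a1 is reported too). The report assembles whatever techniques are
present, lists the missing ones, and is byte-reproducible for identical
inputs.

## Problem sizes

Defaults were chosen so the complete test suite and the acceptance script
each run in a few minutes on one core: 240-point SAXS curves, 101-node P(r)
grids, 1000 particles per AFM class (the analysis drivers use 500/class),
20-injection thermograms at 1 Hz sampling. All are comfortably above the
resolution the statistics require; scaling them up changes nothing but
runtime.

## Known limitations

* No ab initio bead modelling, multiphase models, or structure-factor
  corrections; the analytic elliptical cylinder is the only shape fitted.
* The IFT evidence grid (1e−2…1e8) assumes intensities within a few orders
  of magnitude of unity; rescale extreme data or pass an explicit grid.
* MALDI module consumes centroided peak lists; no baseline/centroiding of
  raw spectra, no isotope deconvolution, no intensity quantitation.
* AFM reader ingests plain-text matrices and grayscale TIFF only, not
  instrument-native formats.
* The pipeline infers stoichiometry from masses and dimensions only; it
  cannot distinguish, e.g., a tetramer from a dimer-of-dimers pathway.
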