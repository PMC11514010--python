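# Methods

This note records the models implemented in `agphot`, their assumptions, the
parameters that matter, and the design choices made where more than one
reasonable convention exists.

## Emitter descriptors

All per-emitter inputs live in a YAML document (schema `emitter/v1`) with
fixed units: energies in eV as excitation energies above S0 at the stated
geometry, SOCME in cm⁻¹, rates in s⁻¹, NACME in atomic units, X-H frequencies
in cm⁻¹. Two geometry contexts are distinguished — `S0-opt` (vertical
absorption) and `S1-opt` (emission) — because the quantities that enter the
rate expressions are all taken at the relaxed S1 geometry. Validation is
strict: unknown keys are rejected, oscillator strengths are allowed only on
singlets, and every negative energy/coupling/rate is an error. Experimental
numbers are confined to a `reference` block that no computation reads, so
calculated and measured provenance can never mix.

Rates carried in a descriptor's `supplied_rates` block are tagged
`"supplied"`; anything the engine derives is tagged `"computed"`. For the
four packaged benchmark emitters the supplied block holds the full reference
rate set — including k_r, since k_r recomputed by Strickler–Berg from the
*rounded* tabulated emission energy and oscillator strength reproduces the
reference value only to ~1–2%, and yield percentages quoted at integer
precision are sensitive to that rounding. `compute_rates(...,
prefer_supplied=False)` forces the fully computed route for every channel.

## Radiative rate

Strickler–Berg in its vacuum single-transition form, k_r = ν̃² f / 1.499 with
ν̃ in cm⁻¹ and 1.499 cm⁻² s. No refractive-index factor is applied by
default: this convention reproduces the benchmark k_r values from their
printed E(S1) and f to better than 2%, so it is evidently the convention
those values were computed with. A medium correction (n² prefactor) is
available as an argument. Temperature dependence and vibronic band-shape
corrections to k_r are out of scope.

## Intersystem crossing

Golden rule, k_ISC = 4π²c · SOCME² · FCWD(ΔE), with the S1–T1 gap taken as
E(S1) − E(T1) at the S1-optimized geometry. Only the channels given are
rated; no attempt is made to guess additional triplet channels (a T2 near S1
at the absorbing geometry, as in the Ag16 emitters, is stored but not rated).

The FCWD is the Marcus–Levich–Jortner form: a Poisson progression
exp(−S)Sⁿ/n! over one effective high-frequency accepting mode of quantum
ħω (default 1400 cm⁻¹, the fingerprint-region skeletal stretches), each line
a Gaussian of variance 2λkT centred at λ + nħω, with λ the classical
low-frequency/solvent reorganization energy (default 800 cm⁻¹) and the
1/√(4πλkT) Marcus prefactor. kT uses 0.695035 cm⁻¹/K (default T = 298.15 K).
The density is normalized to 1 over the gap axis; negative gaps (inverted
regime) are valid inputs and are not clamped. The vibronic sum truncates at
`n_max` (default 100) with a warning whenever the discarded Poisson tail
exceeds 10⁻¹².

This functional form is a documented effective model, not a first-principles
vibronic calculation: its three shape parameters are meant to be pinned to
data. `calibrate_fcwd` minimizes Σ(ln k_model − ln k_obs)² over any subset of
{mode_energy, huang_rhys, reorg_low} in log10 space (positivity by
construction, bounded to physical ranges), via `scipy.optimize.least_squares`
from a deterministic starting point; points are canonically sorted first so
the fit is invariant to input order, underdetermined configurations raise,
and non-convergence is flagged on the returned fit object. Calibrated on the
four benchmark (SOCME, gap, k_ISC) triples, the model reproduces all four
rates within 6% and is monotone decreasing across the 0.23–0.39 eV gap range
— the energy-gap law the reduced rates k_ISC/SOCME² themselves display.

## Internal conversion

The X-H promoting-mode approximation: S1 → S0 conversion deposits the full
electronic gap into stretching overtones of the stiffest, most anharmonic
bonds available — C-H, N-H, O-H. Each mode class (count m, frequency ω,
Morse anharmonicity χ) absorbs n = round(gap/ω) quanta (at least one); the
Franck–Condon weight of that overtone is the m-fold convolution of
single-oscillator factors

  w(j) = exp(−s) sʲ/j! · Π_{k=1..j} (1 − kχ)⁻¹,

a displaced-oscillator Poisson factor with a per-bond Huang–Rhys parameter
`s_xh` (default 0.05, the weak X-H displacement typical when the electronic
transition is localized away from the X-H bonds) times a Morse enhancement
reflecting the compression of the anharmonic ladder. In the harmonic limit
χ → 0 the class weight reduces exactly to the analytic Poisson factor
exp(−mS)(mS)ⁿ/n!, which is the independent oracle the tests enforce. The
electronic matrix element is the nonadiabatic coupling; per class the
effective coupling is taken as NACME·ω (the promoting-mode quantum sets the
scale of the derivative coupling matrix element), so

  k_IC = 4π²c · NACME² · Σ_c ω_c F_c(n_c).

Thermal occupation of X-H stretches is negligible below ~1000 K
(ħω ≈ 3000 cm⁻¹ ≫ kT ≈ 207 cm⁻¹) and is not modeled. The model is
non-increasing in the gap (stepwise, through the integer quantum count) —
the energy-gap law. The default inventory (10 C-H at 2950 cm⁻¹, 4 N-H at
3400 cm⁻¹, 2 O-H at 3550 cm⁻¹, χ ≈ 0.02) with the generator's NACME of
5·10⁻⁴ a.u. places k_IC at 10⁴–10⁷ s⁻¹ over 1.2–2.2 eV gaps, orders of
magnitude below k_r for these bright emitters.

Because reference NACME values and mode inventories are rarely reported,
descriptors may instead carry k_IC directly; the engine computes from
NACME + modes when both are present and otherwise falls back to the supplied
value, never to a silent default.

## Yields and lifetimes

QYF = k_r/(k_r + k_ISC + k_IC), φ_ISC and φ_IC analogously, lifetime
τ = 1/(Σk). Missing channels count as zero; an all-zero rate set is an
error. Integer percentages round half away from zero (7.57 → 8, 33.70 → 34),
matching how such tables are conventionally printed; full precision is kept
in the machine-readable output.

## Spectra

Sticks are broadened on the energy axis with unit-area Gaussian (default,
FWHM 0.15 eV) or Lorentzian shapes on a default grid of 2000 points spanning
the lines ± 5 FWHM; the integrated curve equals the summed stick weight
(Lorentzian wing loss outside the grid is reported as `weight_captured`,
never hidden). Axis display in nm or cm⁻¹ is a pointwise relabel without
Jacobian reweighting — the common TD-DFT plotting convention — so peak
positions map exactly through the unit conversion. Vibronic band shapes and
fitting of measured spectra are out of scope.

## Structures

Subset RMSD uses the Kabsch algorithm (SVD with determinant sign correction,
so the rotation is always proper, including for reflection-favoring and
rank-deficient point sets, the latter flagged `degenerate`). Correspondence
is strictly positional; each named selection is superposed independently,
because cluster cores and ligand shells relax on very different scales and a
single global fit would conflate them. RMSD is unweighted (a mass-weighted
variant is a natural extension but not implemented). Bond tables and contact
reports use closed distance cutoffs (≤); hydrogen-bond angles are measured
at the hydrogen (D-H···A), with hydrogens assigned to donors within a 1.25 Å
covalent radius. XYZ files are written at 4 decimals (1e-4 Å round trip);
PDB parsing (Biopython) keeps the first alternate location with a warning and
retains chain/residue metadata for selection building.

## Synthetic fixtures

The generator manufactures descriptors in the regime of these emitters —
emission 1.6–2.6 eV, S1–T1 gaps 0.2–0.4 eV, SOCME 2–4.1 cm⁻¹, oscillator
strengths 0.8–1.35 — with supplied k_ISC values computed from a declared
`fcwd_truth`, so calibration can be verified closed-loop (recovery of the
generating parameters to <1% from noiseless points). Toy structure pairs
place a minimum-separation metal core inside a ligand shell and apply a known
rigid transform plus independent per-subset Gaussian jitter. All generation
derives from a single seeded `numpy` Generator (default seed 17) and is
byte-reproducible. The generator emulates the *bookkeeping* of a quantum
chemistry workflow, not its physics: energies and couplings are drawn
independently, with none of the correlations (gap–coupling, geometry–energy)
real emitters show, so passing closed-loop tests demonstrates the engine's
internal consistency, not predictive accuracy for new emitters.

## Problem sizes and numerics

All engine operations are closed-form or low-dimensional: the vibronic sum is
O(n_max), the X-H convolution is a short polynomial power, calibration is a
≤3-parameter least squares on a handful of points, and the structure tools
are O(n²) on hundreds of atoms. The test suite and the acceptance script run
in well under a minute on one CPU; tolerances asserted in tests (FCWD
normalization 1e-6, Franck–Condon oracle agreement 1e-8 relative, Kabsch
inversion 1e-8 Å, calibration recovery 1%) reflect the numerical headroom of
double precision for these sizes, not tuned margins.

## Known limitations

- The ISC/IC expressions are effective surrogates with calibrated parameters;
  reference k_ISC/k_IC values are treated as inputs to be matched within a
  factor-level bound, not reproduced ab initio.
- Only the channels described are modeled: no reverse ISC, no triplet decay
  kinetics, no S1 → T2 channels, no Herzberg–Teller corrections.
- Solvent enters only through the FCWD reorganization parameter and the
  optional refractive-index factor; explicit-water effects on gaps and
  couplings (known to matter for these emitters) are upstream of this
  package.
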