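# Methods

This note records the models implemented in `fractsans`, the defaults and
why they were chosen, the numerical decisions that affect results, and what
the synthetic benchmarks do and do not demonstrate.

## From atomic structure to excess scatterers

A PDB structure (ATOM and HETATM records; highest-occupancy altloc kept,
ties resolved towards "A"; waters and hetero compounds dropped by default
because the matched-out detergent and the solvent contribute no coherent
signal) is converted into point scatterers, one per heavy atom:

    b_excess = b_atom + sum(b_bound_H) - rho_solvent * V_excluded

* Coherent scattering lengths come from the shipped table
  (`data/neutron_scattering_lengths.tsv`, Sears compilation).  Excluded
  volumes are atomic van der Waals volumes (`data/vdw_volumes.tsv`, Bondi
  radii), plus one H volume per bound hydrogen.
* Deposited structures lack hydrogens, so bound H counts are attached from
  a residue template (`data/residue_hydrogens.tsv`), split into non-labile
  (carbon-bound) and labile (N/O/S-bound).  The template assumes pH ~7.5
  protonation: carboxylates and the C-terminal OXT deprotonated, Lys/Arg
  protonated, His neutral.
* A labile hydrogen contributes `b_H + ef * f_D2O * (b_D - b_H)`, with
  `f_D2O` the solvent D2O fraction and `ef` the exchange fraction.
  Defaults: pure D2O (`f_D2O = 1`) and `ef = 0.9`, the common
  accessible-exchange assumption for folded proteins.  Neither number is
  dictated by physics alone — solvent accessibility varies — so both are
  plain parameters.  The water molecular volume (30 A^3) is likewise a
  parameter, not a constant of nature.

Total excess scattering length is affine in the D2O fraction, which the
tests exploit as an invariant.

### Hydration shell

Proteins in solution carry a first hydration layer about 10% denser than
bulk water.  The layer is modelled as dummy beads, each standing for 4.13
water molecules, with excess scattering length
`0.10 * 4.13 * b_water(f_D2O)` — only the 10% density excess scatters,
because the displaced bulk is part of the background.  Placement is
deterministic: nodes of a cubic lattice (spacing `(4.13 * 30)^(1/3)` ~ 5 A,
anchored to the structure's bounding box) that lie between 1.4 A (a water
probe radius) and 4.4 A outside the van der Waals surface.  A
`MembraneSlab` (manual bounds along a stated axis) suppresses beads in the
detergent-embedded belt, where the corona replaces water.  Automatic
membrane-orientation lookup is out of scope; the slab is user-defined.

Note the sign structure in D2O: protein excess scattering lengths are
negative (protein SLD below D2O), shell beads positive.  Contrast-weighted
moments can then be indefinite; `radius_of_gyration` returns NaN with a
warning in that case rather than a complex number.

## Scattering from point sets

`P(q)` is the Debye double sum; above 600 points a distance-histogram
acceleration (0.02 A bins) is used, which matches the exact sum to ~1e-4
relative for q below ~1 1/A (asserted by a test).  `A00(q)` is the
zeroth-order spherical-harmonic amplitude about the excess-weighted
centroid — the centroid minimizes low-q truncation error of the order-zero
expansion, which is all the decoupling approximation needs.  `beta = A00^2/P`
is 1 at q = 0 and bounded by 1 everywhere (property-tested).

The theoretical p(r) is the `b_j b_k`-weighted pair-distance histogram
(default 1 A bins).  Because every atom pair enters, p(r) has a weak tail
out to the geometric maximum distance that no experiment can see; the
operational D_max is therefore the first r past the peak where p(r) drops
below 1% of its maximum (threshold exposed).  For transform-pair oracle
checks the tests use 0.05 A bins, since the discretization error of 1 A
bins (~q^2 * var/2) exceeds the 1e-3 tolerance at q = 0.3.

## Fractal oligomer model

Sparse, randomly oriented aggregates of the particle are described as mass
fractals: Teixeira structure factor S(q | D, r, xi) with

* D = 2 by default — dilute oligomer tails constrain the fractal geometry
  far too weakly to refine D;
* k = 1 in `N = k (R_g/r)^D`, consistent with D ~ 2;
* r fixed to the equivalent-sphere radius of the particle's summed vdW
  volume (implicit hydrogens included), ~47 A for a ~370 kDa particle;
* `xi = R_g sqrt(2/(D(D+1)))`, i.e. xi = R_g/sqrt(3) at D = 2.

q = 0 is evaluated through the analytic limit
`S(0) = 1 + Gamma(D+1)/(D-1) * (xi/r)^D` (the raw expression is 0/0), and
at D = 2 the whole expression collapses to
`1 + (2 xi^2/r^2) / (1 + q^2 xi^2)`, which the tests use as an independent
closed form.  Orientational decoupling gives `S' = 1 + beta (S - 1)`; since
beta is in [0, 1], S' is pinched between 1 and S pointwise.

Mixing is per-particle number fraction: a fraction g of particles in
oligomers contributes `g P S'` per particle, the rest `(1-g) P`.  This
normalization is pinned by two requirements: g = 0 must reduce model 2 to
model 1 exactly, and the forward intensity of the oligomer component must
equal `P(0) (1 + 2 xi^2/r^2)` at D = 2 (verified numerically).  N is kept
real-valued; it is a derived scale, not a particle count to round.

## Fitting and model comparison

Weighted least squares (trust-region reflective, bounded) on
`(I_model - I_exp)/sigma`.  Bounds: K in (0, 10], B in [-0.1, 0.1] 1/cm,
oligomer R_g in [10, 2000] A, g and a in [0, 1]; starts K = 1, B = 0,
g = 0.01, a = 0.1, R_g = 300 A.  Fits are deterministic given starts and
seeds; an optional seeded multistart guards against local minima (in the
regimes tested the optimum was global).  Resolution smearing is a Gaussian
quadrature (21-point Gauss-Legendre over +-3 sigma_q, weights renormalized
so constants are conserved exactly); the model is evaluated at |q'| of the
quadrature nodes, clamped to the tabulated component range at the edges.

Parameter uncertainties are local-curvature (Wald) by default.  The
oligomer fraction and oligomer R_g are strongly anticorrelated with a
distinctly non-quadratic likelihood — the fraction of particles in
oligomers and their size trade off almost freely at the percent level — so
`fit(..., profile=...)` additionally computes asymmetric profile-likelihood
intervals (delta chi2 crossings, re-minimizing the other parameters).  The
parameter-recovery benchmark uses the delta chi2 = 9 crossings, the exact
3-sigma statement for a non-quadratic profile; Wald 3-sigma boxes
under-cover there, which is a property of the statistics, not of the
optimizer.

F-tests are one-sided upper tail, in two modes: nested (extra-parameter
test on chi2 differences) and equal-parameter (variance ratio of reduced
chi2, for comparing the same model with two different input structures;
identical fits give P = 0.5 under this convention).  The type-I calibration
benchmark uses a nested pair whose extra parameter (the flat background) is
interior to its bounds, where the classical F null distribution is exact.
For extra parameters pinned at a physical boundary under the null (an
oligomer fraction of zero, a state fraction of zero) the F-test is
conservative — its true type-I rate is below nominal — which practitioners
should keep in mind when a borderline P value argues for a more complex
model.

## Indirect Fourier transform

p(r) on a 100-point grid from non-negative least squares with a
second-difference smoothness prior (endpoints softly pinned to zero) and a
co-fitted flat background (entered as a +-column pair so the problem stays
NNLS).  The data are scale-normalized internally so the smoothness weight
is dimensionless.  Candidates over a log-spaced alpha grid (1e-6 to 1e8)
and, when D_max is not given, a D_max grid around 3.2x the Guinier R_g, are
ranked as follows: candidates whose chi2 exceeds the best achievable by
more than max(9, 2%) are discarded (a ~3-sigma acceptability band), and the
Gaussian-approximation evidence picks the winner among the rest — in
effect, the smoothest and most compact p(r) still consistent with the data.
The pure evidence maximum was found to favour under-sized D_max at extreme
smoothness (the kernel-capacity Occam terms outgrow a modest chi2 penalty),
hence the acceptability band.  Reported D_max is the support of the
reconstructed p(r), R_g and I(0) come from its moments, and the chosen
alpha and background are attached to the result.

On a noise-free sphere curve the reconstruction matches the analytic p(r)
to ~0.2% normalized RMS and D_max to well under 1%.  At realistic noise
(2% + floor) D_max is biased low by up to ~10% — the familiar behaviour of
regularized IFT, since the p(r) tail is the least-determined feature.

## Guinier, Porod, molecular weights

* Guinier: iterative widest-window fit of ln I vs q^2 subject to
  `q_max R_g <= 1.3` (at least 5 points); curves with aggregation upturns
  yield no self-consistent window and are flagged invalid rather than
  returning an inflated R_g.
* Porod background: slope of q^4 I vs q^4 in a high-q window (default: the
  upper third of the measured range).
* Invariant `Q = int q^2 (I - B) dq`: trapezoid on the measured grid,
  low-q extension from the Guinier or p(r) model, optional q^-4 tail above
  q_max contributing A/q_max.  Estimators guard against degenerate input by
  requiring Q to exceed twice its propagated uncertainty.
* MW from I(0): exact evaluation of
  `MW = [I(0)/c] N_A rho_p^2 / delta_rho^2` with rho_p = 1.37 g/cm^3.
* Size-aware invariant MW ("Fischer-style"): Q truncated at
  `q_max = 8/R_g` — so particles of different size are integrated over
  comparable q R_g ranges — with the missing tail restored analytically
  from the Porod amplitude; V = 2 pi^2 I(0)/Q converted to mass with
  rho_p.  The truncation correction is derived (Porod tail), not an
  empirical coefficient table; on a constructed globular reference it
  recovers the built-in mass to ~1-2%.
* Porod-volume MW: V_porod / 1.6 A^3/Da, the widely used empirical rule.
  Note the two conventions disagree by a factor ~1.32 on an ideal uniform
  sphere: the 1.6 divisor is calibrated on real protein data where Porod
  volumes run large (hydration, disorder, finite contrast).  Both are
  reported; for large particles the size-aware estimator is the one to
  trust, which is why it leads the report.

All MW constants live in `data/mw_constants.tsv` with sources.

## Synthetic data: what it emulates and what it does not

The generator mirrors the study conditions of a dilute detergent-solubilized
tetrameric receptor: a three-layer mock (membrane slab plus two wider
extracellular layers, R_g ~ 56 A, D_max ~ 180 A; a splayed "open" variant
with R_g larger by ~8 A for two-state mixtures), ~0.5 uM number density in
D2O, q from 0.006 to 0.2 1/A, a resolution column sigma_q = 0.1 q/2.355
(10% FWHM wavelength spread rendered as a Gaussian width), and additive
Gaussian noise `sigma_i = 0.002 I_max + 0.02 I_i` (percent-scale counting
errors with a floor, the character of reduced SANS uncertainties).
Oligomer fixtures use gamma = 1.5%, the dilute regime of interest.

Not emulated: detergent-corona residual scattering (assumed perfectly
matched out), inter-particle structure factor at finite concentration,
instrument-specific resolution beyond the Gaussian width, correlated
errors from azimuthal averaging, and beam-time-varying backgrounds.
Passing benchmarks therefore demonstrate correctness of the mathematics
and estimators under the stated noise model, not robustness to every
artefact of real reduced data.

`corpus(seed, out_dir)` writes the fixture set (structures as pseudo-atom
PDBs, curves for all four models, a heavily aggregated no-valid-Guinier
case) with a manifest of true parameters; regeneration at the same seed is
byte-identical.

## Problem sizes

Benchmarks run at desk scale by design: 300-2000-point assemblies, 120-150
point curves, 20 recovery replicates, 200 F-test replicates.  These sizes
make every distribution-level claim (coverage, type-I rate) measurable in
minutes while keeping the statistical resolution of the asserted bands.

## Known limitations

* PDB only (no mmCIF); structures with exotic residues need template
  entries or `strict=False`.
* The hydration lattice is anchored to the bounding box, so beads are
  deterministic but not rotation-invariant; form factors shift by well
  under the shell discretization error.
* D and k of the fractal are fixed by default; polydisperse oligomer
  populations are not modelled.
* The IFT evidence is a Gaussian approximation ignoring the active
  non-negativity constraints; the acceptability band compensates in
  practice but the reported alpha is not a calibrated posterior mode.
* Merging curves without q overlap is only weakly constrained (joint
  smooth-p(r) criterion) and is flagged with a warning.
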