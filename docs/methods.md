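# Methods

This note records the models bindkit implements, the defaults it ships, and
the design choices made where more than one reasonable construction existed.

## Binding models

### Stern–Volmer quenching

The titration model is F = F₀ / (1 + K_SV·[L]) with multiplicative Gaussian
noise (relative, default 1%), because fluorescence error scales with
intensity on a photon-counting instrument. The fit is ordinary least squares
of F₀/F on [L] with a *free* intercept rather than one forced through 1: an
intercept far from 1 flags mixed static/dynamic quenching or baseline drift,
which a constrained fit would silently absorb into the slope. K_q = K_SV/τ
uses the tryptophan lifetime τ = 1.0×10⁻⁸ s; values above the ~10¹⁰ M⁻¹s⁻¹
diffusion limit indicate ground-state (static) complex formation.

### Quenching-derived dissociation constant

The double-log analysis regresses log₁₀((F₀−F)/F) on log₁₀[L]_free; the
intercept is log₁₀K_a and the slope the site exponent n. Because part of the
ligand is protein-bound, [L]_free is refined iteratively as
[L]_tot − n·((F₀−F)/F₀)·[P]_tot, floored at 10⁻³ of the smallest nonzero
dose to keep the logarithm defined, until the relative change in K_d = 1/K_a
falls below the tolerance (default 10⁻⁶, max 50 passes). The exact update
rule is fixed here — variants of this scheme circulate — and is isolated in
one function (`estimate_kd_quench`) so it can be swapped. With
[P]_tot = 0 the correction vanishes and a single pass is exact. Note that
K_d from this analysis and 1/K_SV agree only when n = 1 and ligand depletion
is negligible; they are different estimators in general.

### ITC one-set-of-sites

Displacement-cell dilution uses the standard factors
M_i = M₀·(1−v/2V₀)/(1+v/2V₀) and X_i = X_syr·(v/V₀)/(1+v/2V₀) (cumulative
injected volume v, cell volume V₀); the exact-exponential dilution
alternative differs by <0.5% at these volumes. The bound fraction Θ is the
smaller root of the Wiseman quadratic (the physical branch with Θ ≤ 1), and
injection heats are differences of cumulative heat Q_i = n·Θ_i·M_i·ΔH·V₀
plus the half-displaced-volume correction (ΔV_i/V₀)(Q_i+Q_{i−1})/2.

The fitter runs Levenberg–Marquardt over (n, log K_a, ΔH), subtracting a
supplied blank series or otherwise co-fitting a constant per-injection
dilution offset. Fitting K_a on a log scale keeps the parameter positive and
makes the linearized confidence interval asymmetric in K_d, as it should be;
the 95% CI uses the t-quantile at n_inj − p degrees of freedom because 20
injections is a small sample. A warning is raised when the Wiseman c-value
n·K_a·M₀ leaves the reliable [1, 1000] window. ΔG = RT·ln K_d (1 M standard
state, R = 1.98720×10⁻³ kcal mol⁻¹ K⁻¹ throughout, kcal units everywhere)
and TΔS = ΔH − ΔG hold identically for fitted values by construction.

### DSC deconvolution

The thermogram model is a sum of independent two-state peaks, each with its
own calorimetric (peak area) and van 't Hoff (peak width) enthalpy —
unequal values are what "non-two-state" means — on a linear baseline;
sigmoidal progress baselines are out of scope. Initialisation takes the
n highest local maxima of a Savitzky–Golay-smoothed trace (window 11,
order 3); requesting more transitions than detectable maxima is an error
rather than a silent overfit. The excess-Cp maximum sits slightly below T_m
(the 1/T² prefactor skews the peak by a few hundredths of a kelvin at these
enthalpies), which matters when comparing a fitted T_m against the argmax
of a trace. Interfaces accept Celsius and convert on entry; all equations
are in kelvin.

### IC₅₀

The 4PL is fitted on log₁₀ concentration with Levenberg–Marquardt. The 95%
CI is a residual bootstrap (default 1000 resamples) with two small-sample
corrections: residuals are inflated by √(n/(n−p)) to restore the degrees of
freedom absorbed by the 4-parameter fit, and the interval is the basic
(reflected) bootstrap interval on the log-IC₅₀ scale, which corrects
first-order estimator bias that the raw percentile interval ignores. With 8
doses and 4 parameters these corrections bring empirical coverage of the
nominal 95% interval to roughly 90%; the residual undercoverage is a known
small-sample effect of nonlinear regression, not a tunable.

## Pose post-processing

Poses from different receptor snapshots are made comparable by
Kabsch-superposing every snapshot onto the first (on a caller-chosen
reference selection) and applying each snapshot's rigid transform to its
poses; PCA is then computed on poses pooled across snapshots. PCA flattens
heavy-atom coordinates (hydrogens excluded; heavy = element ≠ H) to 3N
vectors and takes the top-2 right singular vectors, with the sign fixed so
each component's first nonzero loading is positive.

KDE selection uses a Gaussian product kernel with per-axis Scott bandwidth
sd·n^(−1/6), evaluated on a 100×100 grid padded by one bandwidth. Grid
local maxima (strict 8-neighbour inequality, so flat near-zero plateaus do
not spawn spurious modes) are ranked by density; each mode claims its
nearest not-yet-selected pose, and leftover slots are filled by the
unselected poses of highest density. Score selection takes the k lowest
scores with lexicographic (snapshot, conformer, pose-order) tie-breaking;
an input flag on the reader declares the score sign convention, since some
docking programs print negative-better affinities while others rank
"highest score". Both selections are fully deterministic.

MDCOM is the mean over all unordered pairs of unweighted heavy-atom
centroid distances within the combined (union) selection; a cross-set-only
variant (`pair_set="cross"`) and mass-weighted centroids are available by
flag. Small MDCOM relative to the candidate-site separation means the two
selection routes converge on one site; MDCOM approaching the separation
means they disagree — the pipeline's convergence diagnostic. Complex
assembly appends the pose atoms as one residue (PUN) on a dedicated chain,
so receptor atom names can never collide with ligand names and nothing is
renamed or dropped; atom counts and coordinates are conserved exactly.
Rescoring tables (externally computed end-point binding energies) are
consumed as-is; the ranking reports the best pose and its energy gap to the
runner-up, +∞ for a single-row table.

## Trajectory statistics

Superposition is Kabsch with the determinant correction enforcing a proper
rotation; near-collinear selections (second singular value ~0) are
rejected. Backbone means atom names N, CA, C, O. RMSD series superpose each
frame on a fit selection (default: the measured selection itself); passing
a rigid subdomain as the fit selection exposes relative motion of the rest.
RMSF superposes all frames to the average structure, iterated twice, then
reports per-residue CA fluctuations; for isotropic jitter of s.d. σ the
expected RMSF is σ√3.

SASA is Shrake–Rupley with van der Waals radii C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20 Å, water probe 1.4 Å, and a deterministic generalized-spiral
(golden-angle) point set (default 960 points) so results are
bit-reproducible; unknown elements are an error, never a default radius.
Rotational invariance therefore holds to quadrature resolution
(≲1% at 960 points), and the isolated-atom value matches the analytic
4π(r+probe)² to the same accuracy. Closest-distance series use a k-d tree
query that returns values identical to the brute-force double loop (kept as
the oracle path); selections may include hydrogens and must not overlap.
Snapshot sampling defaults to a uniform stride including frame 0; a greedy
max–min RMSD spread strategy is available and deterministic.

## Synthetic generators

The generators emulate the *structure* of the real data — Stern–Volmer
curvature, Wiseman isotherm shape with a constant per-injection dilution
heat (exposed so the blank-subtraction path is testable), two-transition
thermograms, 4PL dose–response over the 0.2–50 µM assay range, pose clusters
with uniformly random (quaternion) orientations, and a two-domain
hinge-closing trajectory whose closest interdomain gap interpolates linearly
from 15 to 4 Å with a probe atom that becomes buried at the interface. They
do not emulate photobleaching, baseline drift, injection-schedule artefacts,
real protein energetics, solvent, or docking physics; the hinge toy uses
carbon pseudo-atoms (one residue per atom, chains A/B) with no chemistry
implied. Passing tests therefore demonstrate correctness of the estimators
under the stated noise models, not robustness to every instrumental
pathology. Noise-free generator output is computed by the same forward-model
code the fitters use, so round trips are exact by construction at zero
noise — that identity is itself asserted bit-level in the tests. Instrument
noise magnitudes are not documented for the reference experiments; the
defaults (1% relative fluorescence, 0.05 µcal per injection, 3% of dynamic
range for activity) are plausible for the instrument classes involved and
are configurable. All randomness flows from one explicit integer seed per
call; there is no global RNG state.

## Problem sizes and reproduction

The acceptance script reports replicate-batch means for the stochastic
recoveries — 100 quenching titrations, 100 ITC titrations, 40
triplicate-averaged inhibition assays per IC₅₀ — mirroring how measured
values are reported (means over repeated experiments) and averaging out
single-run fit noise, whose relative s.d. is ~19% for a single ITC run at
0.05 µcal noise and ~11% for a single triplicate-averaged IC₅₀ assay. The
DSC recovery is deterministic (noise-free) and uses a 400-point grid over
300–345 K. Planted-cluster selection demonstrations use 200-pose ensembles;
the bookkeeping check builds the full 24,000- and 12,000-pose campaigns.

## Known limitations

- Single-wavelength quenching only; no spectral integration or inner-filter
  correction.
- One binding-site class in ITC; no sequential or multi-site models, and no
  raw power-curve peak integration (inputs are integrated heats).
- DSC baseline is linear; transitions are assumed independent.
- The KDE grid resolution (100×100) bounds mode localisation; modes closer
  than about one bandwidth merge.
- PDB is the only structure format (multi-model for trajectories and poses);
  no mmCIF or binary trajectory formats.
- Docking, scoring-function internals, end-point free-energy evaluation and
  conformer generation are out of scope by design — poses, scores and
  energies are inputs.
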