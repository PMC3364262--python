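# Methods

This note documents the models, defaults, numerical choices and known
limitations of the `furcula` package, in the spirit of a statistical
methods appendix.

## Outline standardization

Digitized curves (TPS or CSV) are oriented so the trace runs left to
right; a perfectly vertical curve is tie-broken by y (smaller first) and
logged. Resampling places `n_points` (default **100**) pseudolandmarks at
equal arc-length steps along the piecewise-linear source curve.
Interpolation is linear between digitized points; spline smoothing was
deliberately excluded so that the resampler has a closed-form oracle.
When landmarks are present, each landmark-bounded segment receives an
integer point budget proportional to its arc length by largest-remainder
rounding (minimum 2 per segment, shared boundary points counted once), so
the total count is exact and landmarks are retained verbatim. Image
`SCALE=` lines are ignored: the turning-angle transform is scale-free and
scale is not available for all specimens. TPS coordinates are treated as
y-up; a reader flag flips image-origin data.

Two consequences worth knowing: equal spacing is guaranteed in the arc
metric of the *source* polyline (chord lengths of the resampled curve
differ near corners), and resampling is idempotent only for curves whose
own chords are already equal.

## Eigenshape model

The φ-function is the open-curve turning-angle form: φᵢ is the signed
angle between successive segments, wrapped to (−π, π], length
`n_points − 2`. No closed-curve ramp subtraction is applied, matching the
open ramus traces. The specimen × variable matrix is centred by the mean
specimen; with the correlation option (default) each φ variable is also
scaled to unit variance across specimens — we standardize *variables*,
not specimens, and expose both choices because the classical
correlation-matrix phrasing is ambiguous. Zero-variance variables are
dropped with a warning and recorded on the model; reconstruction re-embeds
them at their mean values. Eigenvector signs are fixed by making each
axis's largest-magnitude loading positive, so scores and plots are
reproducible across BLAS implementations. The default retention rule
keeps the first three axes (configurable).

The extended fit computes φ per landmark-bounded segment and
concatenates, never taking an angle across a landmark; with zero landmarks
it reduces exactly to the standard fit. Multi-view fusion standardizes
the concatenated score matrices and decomposes them by a second SVD.
Outline reconstruction integrates φ with a fixed segment length from the
origin heading +x; extended models restart each segment's heading, which
reproduces segment shapes but not inter-segment orientation (that
information is not in the segmented φ).

## Trees, covariance and simulation

Trees are handled through dendropy; Newick round trips preserve topology
and lengths to 10 significant digits. `scale_to_dates` assigns branch
lengths from node/tip ages (Ma): undated internal nodes take, over their
dated descendants, the oldest age consistent with equal spacing of the
intervening branches, which keeps parent ≥ child on every path and
reduces to plain equal sharing on chains. Fossil tips default to the
midpoint when a range is supplied. Branch-length transforms: Grafen
(heights = descendant-tip counts − 1, normalized, power ρ), Pagel's
all-branches-equal, the Ornstein–Uhlenbeck depth transform
ℓ' = (1/2α)·e^(−2α(T−d₂))·(1 − e^(−2α(d₂−d₁))) (which approaches the
original lengths as α → 0), and per-branch power. The power exponent used
to coerce branch lengths toward Brownian conformance is chosen by
maximizing the BM likelihood of the focal trait over a 0.1–3.0 grid
(step 0.05); the classical description names the step but not the
criterion, so the criterion here is our choice and is stated as such.

Phylogenetic covariance **V** holds shared root-to-ancestor path lengths;
Pagel's λ multiplies off-diagonals only. Zero-length branches are floored
at 10⁻⁸ Ma before any covariance or contrast computation (the same floor
in both places, so simulated data and contrast standardization agree).
Brownian simulation draws tips from N(root, σ²**V**) via Cholesky with a
jitter fallback; polytomies are treated as hard.

## Signal statistics

Blomberg's K follows the standard ratio-of-MSE form with the GLS root
estimate; its permutation test ranks the observed variance of independent
contrasts among tip-label shuffles (contrasts are precomputed as a linear
map, so 999 permutations are a single matrix product). Abouheif's
proximity is 1/∏(direct-descendant counts of internal nodes on the tip
pair's path), row-normalized; the test is greater-tailed. All permutation
p-values use (r + 1)/(n_perm + 1) and a mandatory seed. Pagel's λ is
profiled analytically over σ² and root, maximized on a 21-point grid with
bounded refinement; the LRT against λ = 0 uses the 50:50 χ²₀:χ²₁ boundary
mixture; a profile flat to 10⁻⁷ (star tree) sets an `unidentifiable`
flag. PVR double-centres the patristic distance matrix directly (the
original PVR convention), retains positive-eigenvalue axes whose fraction
exceeds the broken-stick expectation bₖ = (1/n)·Σᵢ₌ₖⁿ 1/i (or a forward
stepwise-AIC subset), and reports OLS R², the F-test p, the retained ids
and their cumulative eigenvalue fraction.

## Simulation-null group tests

The (M)ANOVA statistic is classical (univariate F, or Wilks' Λ with Rao's
F approximation); the phylogenetic p-value is the (r + 1)/(n_sim + 1)
rank of the observed statistic among statistics recomputed on Brownian
datasets simulated with the GLS-estimated rate (full evolutionary rate
matrix in the multivariate case, so trait correlations are preserved).
The simulating scale cancels in F, so the rate estimate only matters for
numerical conditioning. Defaults are 999 simulations/permutations. The
phylogenetic Tukey HSD uses the Tukey–Kramer studentized range per pair
and compares each observed q against the simulated null distribution of
the *maximum* q, giving familywise control; the same GLS rate drives the
null. Pillai's trace is available as an alternative multivariate
statistic. Mardia's skewness/kurtosis tests and Box's M are provided as a
diagnostic report only — they never gate an analysis.

Evolutionary model fits (BM, OU, EB, white noise) profile σ² and the root
analytically and optimize the shape parameter (OU α on a log scale within
[10⁻⁶, 50]/T; EB decay within [ln 10⁻⁵/T, 0)) by bounded scalar search.
Parameter counts are 2/3/3/2 and AICc = −2logL + 2k + 2k(k+1)/(n−k−1)
exactly. The OU covariance uses the non-ultrametric generalization
(σ²/2α)·e^(−α dᵢⱼ)·(1 − e^(−2α sᵢⱼ)).

## pFDA

Whitening uses the symmetric eigendecomposition root **C**(λ)^(−1/2) —
unique, symmetric, and deterministic, unlike a Cholesky factor.
λ* maximizes the PGLS log-likelihood of the traits regressed on the class
indicators, both whitened; the Jacobian term −(q/2)·log det **C**(λ) is
included, without which likelihoods at different λ are not comparable.
The last indicator column is dropped to keep the design full rank. The
grid is 0–1 in steps of 0.01 with bounded refinement; a star tree yields
a flat profile (flagged) rather than an arbitrary argmax. By default λ is
optimized on training tips only; an option includes unknown tips'
phylogenetic positions in **C** during whitening, since the original
procedure is ambiguous on this point. Class priors are uniform by default
(survey-balanced training classes), proportional priors optional; the
subaqueous class is excluded from profile-view discriminant training by
default, matching the six-class published confusion matrix, while lateral
analyses may retain it.

Prediction whitens training and unknown rows jointly under **C**(λ*) over
the combined tip set and refits the discriminant on the whitened training
rows — centring is therefore handled inside the discriminant rather than
by a GLS ancestral estimate (the alternative the literature leaves
unspecified). Predictions whose maximum posterior falls below 0.5 carry a
low-confidence flag; λ-sweep stability is the modal-class fraction across
the grid. Percent-correct cells round half-up to integers, matching the
published display convention.

## Synthetic generator

The generator is the package's study system, standing in for undeposited
photographs. A profile outline is built in tangent-angle space: the right
ramus starts horizontal at a rounded symphysis (rounding window 12% of
the ramus), sweeps up to the chord direction (π/2 − θ/2 for
interclavicular angle θ), varies linearly along the ramus for
circular-arc-style bowing (tangent sweep 1.2·curvature, i.e. sag
0.3·curvature of the unit ramus length), and rotates its distal 20% by
the omal-flare term (±π/3 at full flare); the left ramus is an exact
mirror, so outlines are symmetric before noise. The rounded symphysis is
deliberate: it spreads the angle signal over many pseudolandmarks, as in
real bone, instead of a single corner variable. The hypocleideum is a
smooth Gaussian midline process (depth = `hypocleideum_frac` ramus
lengths, width 0.12). The lateral view is a bowed anterior edge (80% of
arc) plus an epicleideum segment whose curl follows the flare parameter,
with a landmark at the junction. Digitization/within-species noise is
*smooth*: a Gaussian-filtered (σ = 4 points) perpendicular displacement
field, tapered to zero at the curve ends, with sd expressed in ramus
lengths. Point-wise white noise is unrealistic for bone outlines and,
under per-variable standardization, would drown distributed shape signal.

Dataset simulation draws a pure-birth tree (depth scaled to 50 Ma),
assigns classes clade-wise (contiguous blocks in tip order, then a
fraction 1 − clustering of tips reshuffled; default clustering 0.8), and
sets per-specimen parameters to class mean + bm_fraction × (Brownian
deviation, unit tip variance) + (1 − bm_fraction) × i.i.d. deviation,
each scaled by the class SD and clipped to the valid range. Default class
means are qualitative translations of the reported form–function
relations (soarers ~115° and strongly U-shaped; bounders ~42° and
straight; divers strongly bowed anteroposteriorly; burst fliers nearly
flat laterally; theropod-grade "preflight" very wide-angled); only
rank-order relations among classes are asserted in tests, because true
magnitudes are unknowable. Default noise sd is 0.005 (0.5% of ramus
length) for datasets and 0.002 for single-parameter sweeps, chosen once
as plausible tracing precision.

What passing tests show — and don't. The generator produces smooth,
symmetric, cleanly labelled outlines with known class structure; real
furculae add asymmetry, taphonomic distortion, 2-D projection error from
3-D bone, ambiguous curve definitions and mislabelled behaviour classes.
Recovery rates measured here (e.g. leave-one-out accuracy ≥ 60% on five
classes) are therefore upper bounds on what comparable real data would
give, and the published empirical eigenvalue fractions and
misclassification rates are not reproducible from synthetic data.

## Analysis scales used in the shipped checks

The calibration and recovery studies run at sizes chosen to balance
Monte-Carlo error against desk-scale runtimes: type-I calibration uses
500 meta-replicates × 199 simulations on a 16-tip tree; K calibration 200
Brownian replicates; λ recovery 100 replicates at 64 tips; discriminant
recovery one 60-specimen, 5-class dataset; the morphometric sweep 40
specimens. The full test suite completes in well under a minute of CPU
apart from the property suites.

## Known limitations

- Reconstruction of extended (multi-segment) models loses inter-segment
  orientation by construction.
- The Abouheif proximity treats polytomies through raw direct-descendant
  counts; very unresolved trees dilute the statistic.
- The simulation-null MANOVA assumes a common within-group evolutionary
  rate matrix; rate heterogeneity between groups is not modelled.
- pFDA posteriors come from a linear discriminant in whitened space;
  strongly non-Gaussian whitened classes (e.g. far-outlying fossil
  morphologies) yield extrapolated posteriors, which is why the
  low-confidence flag exists.
- The packaged composite tree is a taxonomy-based synthetic stand-in with
  round-number node ages; it preserves clade structure, not published
  divergence-date estimates.
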