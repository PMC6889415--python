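# Methods

## The mechanistic model

The model is a closed mass-action reaction network (22 reactions, 14
species) describing insulin-driven, redox-modulated Akt activation at
the plasma membrane (PM). Four moieties are conserved exactly: the
insulin receptor (inactive/active), NADPH oxidase (NOX,
inactive/active), Akt (reduced/oxidized cytosolic, reduced/oxidized
PM-bound, phosphorylated PM-bound), and a generic substrate
(Sub/pSub). Insulin is a clamped input set by protocol events; ROS and
PIP3 are produced and cleared in open balance. Rate laws are mass
action, with two competitive-style divisors: the NOX inhibitor DPI
divides the NOX activation rate by `1 + [DPI]/dpi_ki`, and ROS divides
the substrate-phosphorylation rate by `1 + [ROS]/ros_ki`.

The ROS divisor is the one deliberate departure from pure mass action.
A single lumped phospho-Akt species cannot simultaneously rise (as
activation-loop phosphorylation does under oxidative stress) while its
substrate output falls, if substrate flux is strictly proportional to
it. Mechanistically the attenuation reflects oxidation of the Akt
kinase domain (the inhibitory C297–C311 disulfide); representing it as
an ROS-dependent inhibitory modifier of the catalytic step keeps the
species list small, preserves Sub-moiety conservation, and uses the
same functional form already adopted for DPI.

Assumptions worth keeping in mind:

* one lumped phospho-Akt species — the two activating sites (activation
  loop and hydrophobic motif) are not distinguished, and the
  oxidation state of phosphorylated Akt is not tracked;
  dephosphorylation returns Akt to the reduced PM pool;
* oxidized Akt binds PIP3 with a larger bimolecular on-rate than
  reduced Akt (`k_on_ox > k_on_red`) — the membrane-affinity mechanism;
* PIP3 appears as an explicit species with receptor-driven production
  and first-order clearance; there is no explicit PI3K/PTEN enzymology;
* concentrations are in arbitrary units with conserved totals
  normalized to 1; time is in minutes.

### Parameters

One rate constant per reaction plus the conserved totals and the two
perturbation constants (`dpi_ki`, in the same units as the DPI dose;
`bcnu_af_reduction_factor ∈ (0,1]`, applied to ROS clearance and both
Akt re-reduction rates). `reference_parameters()` is the package's
reference set. It was chosen, once, to place the system in the
physiologic regime: a basal oxidized-Akt fraction of ~0.5%, a few
percent oxidized under insulin's NOX-driven ROS rise, and a
majority-oxidized pool under BCNU/AF — the regime in which
oxidation-enhanced recruitment raises membrane Akt and pAkt while
kinase-domain inhibition suppresses substrate output, and in which NOX
inhibition dose-dependently lowers recruitment, pAkt and pSub. The
oxidized/reduced on-rate contrast (15 vs 0.3) and the substrate
inhibition constant (`ros_ki = 0.3`) are the load-bearing choices; the
remaining constants are order-one turnover rates on the minute
timescale.

### Simulation

Protocols are timed event lists (set insulin, set DPI, toggle BCNU/AF)
with events allowed at negative times (e.g. a 30-min DPI
pre-treatment before the insulin step at t = 0). Before the first
event the system is integrated to its basal steady state
(`‖dx/dt‖∞ < 1e-9`, expanding horizons up to 1e6 min); integration
between events uses LSODA at rtol 1e-8 / atol 1e-10. States are
clipped to zero below integrator noise (−10·atol triggers an error
instead). Moiety drift stays below 1e-6 relative on all shipped
protocols, and halving the grid spacing changes observables by less
than 1e-6 relative.

### Fitting

The objective is the SEM-weighted sum of squared residuals over all
(protocol, observable, time) points. Observables recorded in arbitrary
units are marked `"scaled"`: the linear factor mapping data into model
units is profiled out analytically, so the score is invariant to the
data's units. Points with missing or zero SEM receive the observable's
median positive SEM (weight 1 if none exists).

The optimizer is a real-coded genetic algorithm over log10-transformed
rate constants: tournament selection (size 3), SBX crossover (p = 0.9,
η = 10), per-gene Gaussian log-space mutation (p = 0.1, σ = 0.2),
elitism 2 (making the best-objective trace non-increasing), defaults
population 200 × 500 generations, all configurable; a Nelder–Mead
polish of the GA winner is on by default. Raw rate constants of this
network are structurally non-identifiable from recruitment and
phosphorylation curves alone; identifiable combinations such as the
oxidized/reduced membrane on-rate ratio are what recovery is judged
on. Multi-restart fitting keeps independent seeded runs sorted by
objective, and predictions are averaged pointwise across the kept
parameter sets with SEM = sd/√n_fits.

## The statistics

Pipeline order for real acquisitions: per-sample log2, median centring
and SD scaling within each (treatment, time) condition →
protein-abundance correction of late-time redox values (log2
subtraction of the matched protein's level at the same treatment and
time; peptides without a quantified protein are flagged and left
unadjusted) → imputation → moderated tests → BH → downstream
integration.

* **Normalization.** Scaling is per sample by the SD of observed values
  (ddof 1); a normalized-MAD alternative is exposed. Within-group
  pooled scaling was considered and rejected in favour of the
  per-sample convention; a degenerate column (all observed values
  equal) is returned as zeros with a warning. A second normalization
  call errors. Centring-based normalization is *biased when regulation
  is one-sided*: with 10% of features shifted up, treated-column
  medians rise and every null feature acquires a small negative
  logFC. This is inherent to centring (any median-centred workflow
  shows it identically) and is visible in a dedicated test. Generated
  matrices have no sample-loading offsets, so pipelines on synthetic
  data may use `log2_transform` (log2 without centring) instead.
* **kNN imputation** (k = 10): features missing less than 50% of cells
  have each missing cell replaced by the unweighted mean, over the k
  nearest feature rows, of that column's observed values; features at
  or above 50% are untouched. Distances are per-column-normalized
  Euclidean on jointly observed columns computed on the rows as-is, so
  neighbours share the feature's intensity level and borrowed values
  are on the right scale (the convention of the standard
  expression-matrix kNN imputers; verified to reproduce
  scikit-learn's KNNImputer exactly on sporadically missing data).
  A z-scored-row distance that matches on profile shape instead is
  available as an option. Ties break lexicographically by feature id.
* **Random-tail imputation** for on/off (condition-structured)
  missingness: within each treatment arm, a feature observed in ≥2
  replicates of one condition and none of the other has the empty
  condition drawn from `N(μ_s − 1.8σ_s, (0.3σ_s)²)` per sample column —
  the low-intensity tail. The width/downshift constants follow the
  convention of the standard proteomics environment for this
  procedure; both are configurable. Features partially observed in
  both conditions are left to the kNN path.
* **Moderated test.** Per feature, the pooled two-group variance is
  shrunk toward a scaled-F prior fitted by the closed-form method of
  moments on log variances (trigamma inversion by Newton's method).
  The implementation reproduces the reference empirical-Bayes
  implementation to at least six significant figures on a frozen
  heteroskedastic fixture (prior df, prior variance, moderated t and
  p). Underdispersed log-variances give an infinite prior df (normal
  reference distribution); the exactly-degenerate case (all variances
  equal) returns that common value as the point-mass prior. Features
  with fewer than two observations in either group are dropped with a
  log entry. BH adjustment is the step-up procedure (via statsmodels),
  cross-checked against a direct implementation.
* **Direction analysis.** Each contrast becomes a signed z-score
  `z = sign(logFC)·|Φ⁻¹(p/2)|`; two contrasts are integrated along a
  direction `(d₁,d₂) ∈ {±1}²` as `(d₁z₁+d₂z₂)/√2` with a one-sided
  upper-tail p (clipped away from 0 and 1). Concordant features are
  those whose z-signs agree; the combined z is invariant to swapping
  the contrasts for symmetric directions.
* **Substrate fidelity.** Per kinase substrate set (≥2 quantified
  members per condition): a one-sided Bartlett comparison of whether
  the later condition's variance of substrate changes exceeds the
  earlier's — Bartlett is natively omnibus, so the one-sided p is
  `p/2` when the later sample variance is larger and `1 − p/2`
  otherwise — plus a one-sided one-sample t of whether the later
  condition's mean change is below zero. Singletons are skipped with a
  log entry.
* **Probabilistic PCA.** The isotropic-noise latent-variable model
  fitted by EM, handling missing entries exactly by restricting each
  sample's E-step to its observed coordinates; log-likelihoods use the
  determinant lemma so cost scales with the latent dimension.
  Convergence at relative log-likelihood change < 1e-8 or 1000
  iterations (EM's linear tail can hit the iteration cap with the
  subspace already converged to < 1e-4 rad of the SVD solution).
  Reported loadings are orthogonalised by SVD of W.
* **Assays.** The Hill fit is nonlinear least squares with EC50 on the
  log scale, multi-start at the dose quartiles, asymptotes fitted by
  default (fixable); flat data are flagged unidentifiable. Redox
  fractions pool ions across 2–4 peptides before the ratio
  (abundance-weighted), not the mean of per-peptide fractions. The
  rank-sum comparison uses the exact null for combined n ≤ 20 without
  ties, the tie/continuity-corrected normal approximation otherwise.

## The synthetic-data generators

All generators draw from a single seeded PCG64 stream per call; a fixed
seed gives bit-identical output. Feature baselines are `N(20, 2²)` on
the log2 scale (MS-like dynamic range), group effects are additive in
log2, replicate noise is Gaussian with default sd 0.3 log2 units
(chosen to match a median replicate CV on the order of 10–20%,
typical of multiplexed redox quantification), and matrices are stored
as linear intensities. Designs default to four biological replicates
per (treatment, time) condition.

Missingness models: MCAR at a fixed rate; MNAR with
`P(missing) = expit(−slope·(log2 intensity − midpoint))`; and a
condition-structured model in which a stated fraction of features is
"insulin-only" (observed in ≥2 insulin replicates, in no basal
replicate) with the remainder thinned by the MNAR logistic. Features
that acquire the on/off pattern by thinning chance are broken by
restoring one cell, so the pattern set equals the planted set exactly.

Model time courses are generated by simulating protocols with the
reference parameters and adding multiplicative Gaussian noise of a
stated CV to pseudo-replicates, reporting mean and SEM = sd/√n as
experimental SEMs arise. The CV-noise form is a stand-in: the noise
structure of the fluorescence-microscopy and immunoblot data this
emulates is not characterised, so calibration claims should not be
read as statements about those instruments. Hill curves are evaluated
exactly at the six spotted amounts (100, 50, 25, 10, 5, 1 pmol) plus
optional additive noise.

What passing tests show — and don't. The generators reproduce the
replicate structure, effect structure and missingness structure the
statistics assume, but not sample-loading offsets, channel
interference, peptide-level correlation within proteins, or
heavy-tailed measurement error. Recovery and calibration results on
generated data therefore validate the implementations and their
contracts, not the end-to-end error rates of any real acquisition.

## Problem sizes

Shipped tests and the acceptance script run at desk scale by design:
1000-feature matrices for recovery, 200–300-feature nulls over 20
seeds for calibration, 60-min protocols on 241-point grids, and a
3-parameter GA recovery at population 36 × 30 generations with 3
restarts. All sizes are arguments; nothing in the implementation is
specific to them.

## Known limitations

* The reaction scheme is a canonical lumped network; the loader accepts
  alternative schemes (dropping/adding conservation-checked reactions)
  but no attempt is made to resolve individual phosphosites or the
  PH-domain/kinase-domain conformational cycle.
* GA fitting recovers identifiable parameter combinations, not raw
  rate constants; no posterior uncertainty is attached to fits beyond
  the across-restart SEM.
* Protein-abundance correction assumes the peptide→protein map is
  given; no inference of shared peptides is attempted.
* The moderated test assumes (approximately) Gaussian log intensities
  after preprocessing; imputation-induced correlation between cells is
  not propagated into the degrees of freedom.
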