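# Methods

## The three-state folding-and-activation model

An enzyme molecule is modelled as occupying one of three states: unfolded
and inactive (ui), folded and inactive (fi), and folded and active (fa).
Two free energies parameterise the equilibrium, both in kcal/mol:

- `dGf` — folding energy, ui → fi;
- `dGa` — activation energy of the folded enzyme, fi → fa.

With Boltzmann weights `w_fi = exp(-dGf/RT)` and
`w_fa = exp(-(dGf+dGa)/RT)` relative to the unfolded state, the fraction
of molecules that are folded (two-state, the abundance phenotype) and the
fraction folded *and* active (three-state, the activity phenotype) are

    p_f  = 1 / (1 + exp(dGf/RT))
    p_fa = w_fa / (1 + w_fi + w_fa)
         = 1 / (1 + exp(dGa/RT) (1 + exp(dGf/RT)))

The probability of an unfolded-but-active state is taken as negligible.
`dGa` is phenomenological: it absorbs every change in activity not
explained by the folded concentration (conformational equilibrium, kcat,
substrate positioning), so no physical calibration of its absolute value
is attempted.

Mutational effects are additive on the energy scale: a genotype's
energies are the wild-type energies plus the sum of the per-substitution
`ddGf` / `ddGa` values of its mutations.  Each experiment (assay ×
mutagenesis block) observes an affine transformation of the relevant
state probability, `fitness = intercept + slope * p`, which absorbs
assay-specific scale and offset.

Alternatives kept for model comparison: a two-state model in which both
phenotypes are driven by folding alone, and a four-state model in which
activity is the summed occupancy of two active conformations with
independent per-mutation energies.

**Constants.** `R = 0.001987 kcal/(mol K)` and `T = 303.15 K` (yeast
growth at 30 °C), so `RT ≈ 0.6025 kcal/mol`.  The temperature is not
measurable from fitness data; it sets the scale of all reported energies
and is configurable.  All state probabilities use log-sum-exp guards and
are exact for |dG|/RT up to several hundred.

## Fitting

The fit minimises the error-weighted squared loss
`sum_i (y_i - yhat_i)^2 / sigma_i^2` jointly across all experiments,
sharing energies while each (assay, block) has its own affine layer, with
no regularisation.  The optimiser is deterministic full-batch
trust-region least squares (scipy `least_squares`, TRF with the `lsmr`
sub-solver) with an analytic sparse Jacobian assembled from the genotype
indicator matrix; on noiseless synthetic data it recovers all energies to
machine precision.  We chose tolerance-based convergence of a
deterministic trust-region method over stochastic training with hold-out
early stopping: the model is a smooth least-squares problem of moderate
size, where full-batch methods are both faster and exactly reproducible.

Energy parameters are box-bounded at ±4 kcal/mol by default.  Outside
the dynamic window of a fitness assay the loss is flat in the energy, so
unbounded estimates of fully saturated effects perform an unguided random
walk with the noise (we observed estimates of 28 kcal/mol for a true 2.5
before the bound was added); the bound is a numerical guard, not a prior,
and affects only parameters the data cannot resolve anyway.  It is not an
L2 penalty — none is used.

Identifiability notes, from a Cramér–Rao analysis at the truth (the
Jacobian in `fitting.py` makes this a three-line computation):

- both assays are required for three- and four-state fits (the activation
  trait is otherwise free); `fit` raises `UnderIdentifiedError`;
- the energy scale is pinned by the Boltzmann nonlinearity at fixed RT,
  so no global sign or scale flip survives a multi-background design;
- when the observed folding-energy range is narrow, the activation trait
  can be nearly reparameterised as an affine function of the folding
  trait; a spread of destabilizing backgrounds breaks this degeneracy.

**Cross-validation** partitions the unique double mutants into k folds;
wild type and singles always stay in training, because singles are the
parameters of interest and each appears in many doubles.  Held-out R² is
computed on the doubles, pooled over assays.  **Uncertainty** (the "SD
kcal/mol" used by the classification z tests) is the standard deviation
of each parameter across the ensemble of per-fold refits.

**Explainable variance.** MEV = Var(fitness) − mean(sigma²), FEV =
MEV/Var(fitness), computed after discarding variants whose errors fall in
the top 15th percentile; model R² divided by FEV gives noise-normalised
performance.

## Statistics

Mutations are classified with one-sided z tests against a signed
boundary of ±0.5 kcal/mol (destabilizing/inactivating above +0.5,
stabilizing/activating below −0.5), Benjamini–Hochberg FDR per energy
across all tested mutations, cut at 0.1.  Sidedness follows the
direction-specific definition of the classes; testing two-sided against
zero would ignore the magnitude boundary.

Residue-level enrichments use Fisher's exact test with the rest of the
domain as background.  The odds ratio reported is the sample OR
(a·d)/(b·c), with ∞ on a zero denominator — the OR is descriptive, the
exact p carries the inference, so no Haldane correction is applied.
Major allosteric sites are non-active-site residues with OR > 2 and
FDR < 0.1 for enrichment in activity-modulating mutations; activating
sites use OR > 1, p < 0.05.  Per-residue mean ddGa is 1/sd²-weighted when
SDs are available (plain mean otherwise).

## Spatial analysis

Distances are minimum heavy-atom distances from each residue to the
active-site reference selections (ligand groups and/or catalytic
residues); residues inside the reference selections get distance 0, since
they anchor the decay intercept.  The decay of per-site mean |ddGa| is
fitted as `y = a·exp(k·d)` by nonlinear least squares, initialised from a
log-linear regression of `ln(y + 1e-6)` (the classic two-step), with the
95% CI of k from the asymptotic covariance.  The half-decay distance is
`d_half = ln 2/|k|` for every fit (one published (k, d_half) pair that
does not satisfy this identity is treated as a typographical
inconsistency; the identity is used throughout).

Directional decay measures displacements from the heavy-atom centroid of
the reference selections along the structure frame's axes, keeps residues
within a 10 Å slab on the two orthogonal axes, and fits the decay against
|axial displacement| separately for each signed direction.

The effect-size-matched comparison of inhibitory (ddGa > 0) and
activating (ddGa < 0) mutations subsamples the inhibitory set, with
replacement, to match the activating set's size and |ddGa| distribution
(decile bins of the activating magnitudes — the binning rule is ours, the
matching requirement is not), and fits a decay rate per subsample.  The
p-value is the fraction of subsamples decaying no more steeply than the
activating set (rate ≥ activating rate).  Within the subsampling loop the
rate estimator is the closed-form log-linear slope rather than a full
nonlinear fit: it is consistent under the exchangeability null, orders of
magnitude faster at 10⁴ subsamples, and its null distribution is well
calibrated (KS-uniform in the test suite).  Headline decay estimates
always use the full nonlinear fit.

Site clustering/connectivity tests compare the observed median pairwise
(or nearest-neighbour) Cα–Cα distance among sites against equal-sized
random residue subsets; p is the fraction of null medians ≤ observed.
Distance-corrected effects are lowess residuals (default span 0.75,
configurable; no published value exists).

## Contact dynamics

Only salt bridges, pi-cation interactions, and side-chain–side-chain /
side-chain–backbone hydrogen bonds are retained from getcontacts tables —
the types that differ between conformational states.  Duplicate
(pair, type) rows collapse to one contact; a pair annotated both sb and
hbss collapses to sb.  Per (residue, type), comparing partner sets
between the active and inactive structures yields active-only,
inactive-only, swapping, static or none; partners are compared at residue
granularity, matching how rearranging contacts are described at the
residue level.  Class effect-size comparisons use two-sided Wilcoxon
rank-sum tests on |ddGa| with BH adjustment.

## Pockets

Per-structure pockets are filtered at druggability ≥ 5, then clustered
agglomeratively on 1 − overlap coefficient (|A∩B|/min(|A|,|B|)) with
average linkage cut at 0.75 (linkage and cut are exposed; no published
values exist — the analysis is robust over a range of cuts).  Unique
pockets aggregate member summaries (mean/max/min of per-residue mean
ddGa; Fisher ORs for activating/inactivating enrichment vs the rest of
the domain) as medians across member structures, BH-FDR across unique
pockets, ranked by inactivating enrichment.

## Prediction and regulatory comparison

The ddGa predictor is ordinary least squares on one-hot categorical
features (wild-type and mutant residue, secondary-structure type and
element, contact class) plus rSASA and two transformed distances
`dtr = exp(k·d)` with k = −0.063 Å⁻¹ (the global inhibitory decay
constant), evaluated by 10-fold CV on held-out rows, active-site
mutations excluded.

The full-length vs domain-only comparison regresses FL ddGa on KD ddGa
(unweighted, as specified by the source procedure), takes residuals as
dddGa, computes z = residual/√(sdFL² + sdKD²), applies one-sided tests
per direction with BH-FDR within direction, and flags |dddGa| > 1
kcal/mol at FDR < 0.1.  Sites with ≥ 2 flagged mutations are clustered on
Cα–Cα distances (average linkage, default cut 10 Å, configurable).

## The synthetic-data generator

The generator emulates the statistical structure of a tiled
double-mutant kinase-domain scan: a contiguous partition of the domain
into 5 tiles, 10 genetic backgrounds per tile (wild type plus 9 singles
chosen at fixed quantile spacing of the true effects — ddGf quantiles
spread toward the destabilizing side, ddGa quantiles toward the
activating side, so backgrounds span weak-to-strong on both energies and
populate the sensitive region of both Boltzmann curves), every single
substitution of every tile position in every background, and two
phenotypes generated from the three-state model through per-experiment
affine layers with Gaussian noise.  Default domain size is 269 positions
(5111 possible singles); the test-suite and acceptance studies use 50
positions in 5 tiles so that a full fit takes seconds rather than hours —
the design (tiles, backgrounds, noise level) is unchanged, only the
number of positions is scaled.

Effect sizes are spike-and-slab by position class: neutral positions
N(0, 0.1) on ddGf and exactly 0 on ddGa; core positions (25%)
Gamma(2, 0.6) destabilizing ddGf truncated at 2.5 kcal/mol; allosteric
positions (25%) inhibitory ddGa whose per-position mean follows the
planted exponential law `a·exp(k·d)` exactly (a = 1.5 kcal/mol,
k = −0.07 Å⁻¹, lognormal within-site spread); activating positions (8%)
ddGa = −|N(0, 0.75)|, distance independent; the designated active-site
residues follow the inhibitory law at d = 0.  The truncation at 2.5
kcal/mol keeps all planted energies inside the ~3 kcal/mol window that a
two-phenotype assay at 10% noise can actually resolve — effects beyond it
saturate the fitness readout and are bounded, not measured, exactly as in
real scans.  The wild type sits at dGf = −1, dGa = 0 (mostly folded,
half-activated), the sensitive region of both curves.

Noise is Gaussian per experiment, with sd a configured fraction (default
10%) of the experiment's realised noiseless fitness range, and the
recorded per-variant sigma equals the generating sd.  Real
sequencing-derived fitness errors are count-dependent and heteroscedastic
per variant; the generator's heteroscedasticity is only per experiment,
and the error model is an assumption, not a reproduction of any
published pipeline.  Passing recovery tests therefore show that the
inference is correct *given* well-calibrated Gaussian errors; they do not
validate robustness to misspecified error estimates.

The toy structure is a compact self-avoiding Cα walk (3.8 Å steps,
origin-pulled, 3.4 Å clash radius) with 5 pseudo-atoms per residue and a
spatially clustered active-site selection near the centroid; it provides
realistic distance *distributions*, not a protein fold.  Contact tables,
overlapping pocket sets (with sub-threshold druggability decoys) and
per-residue rSASA/secondary-structure annotations are generated with the
qualitative properties the downstream analyses require.

A degenerate "dead" background (saturated, extremely narrow fitness
range) can be planted, and the fitter supports exclusion of backgrounds
by id, mirroring the removal of one such background in real data.

## Problem sizes and numerical choices

- Test-suite/acceptance studies: 5 tiles × 10 positions, 10 backgrounds
  (~17,000 observations, ~1,900 energy parameters); noiseless exactness
  checks use 2 tiles × 10 positions.  These sizes were chosen so the full
  suite exercises every stage end-to-end in minutes.
- TRF convergence: ftol = 1e-8, xtol = 1e-12, gtol = 1e-14, max 300
  residual evaluations (machine-precision convergence on noiseless data
  at these sizes).  A fit that exhausts the evaluation budget while its
  accepted-step loss improvements have fallen below 1e-5 (relative, per
  step) is classified as converged: bound-constrained saturated
  parameters can zigzag indefinitely without changing the estimates.
- Decay-fit initialisation eps = 1e-6 inside the log; flat data yields
  k ≈ 0 and a non-finite d_half rather than an error.
- Agglomeration tie-breaks: inputs sorted by (structure, pocket) id
  before clustering, making results order-invariant.
- Degenerate FET tables: OR = ∞ (or NaN when both diagonals vanish),
  exact p always defined.

## Known limitations

- Energies of fully saturated mutations are reported at the ±4 kcal/mol
  bound; their SDs from the CV ensemble can be near zero, so downstream
  z tests floor SDs at 1e-3 kcal/mol.
- The generator does not simulate sequencing counts, selection dynamics
  or error-model misspecification.
- The four-state model is identified only up to permutation of its two
  active states; it is used for model comparison, not interpretation.
- Directional decay uses residue heavy-atom centroids for axial
  displacement (a single well-defined origin and coordinate per residue);
  the global fit uses minimum heavy-atom distances, so the two agree only
  in the degenerate all-residue limit along one axis.
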