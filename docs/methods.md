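# Methods

## The kinetic model behind the simulator

Each gene follows the standard two-stage transcription model

    du/dt = α(t) − β·u        (unspliced pre-mRNA)
    ds/dt = β·u − γ·s         (spliced mRNA)

with transcription rate α(t) a function of a latent activation time
t ∈ [0, 1], splicing rate β and degradation rate γ (both per unit
latent time). Four α-profiles are supported: `flat` (constant),
`monotone_up` / `monotone_down` (saturating sigmoids), and `pulse`
(Gaussian bump). Integration uses the closed form for flat genes and
`scipy.integrate.solve_ivp` on a dense latent-time grid otherwise, with
the steady state under α(0) as the initial condition — so a flat gene
sits exactly at u\* = α/β, s\* = α/γ for every cell.

Counts are drawn per cell and gene from a gamma–Poisson (negative
binomial) observation model with dispersion φ (variance m + φm²;
φ = 0 gives Poisson; `count_model="none"` rounds the deterministic
mean). A per-cell capture-efficiency factor, lognormal with σ = 0.2,
scales both layers and creates the library-size variation that
depth normalization is designed to remove. Defaults: φ = 0.1, typical
of droplet UMI data.

**Population structure.** Latent times are drawn from a two-component
mixture: a quiescent mode (0.15 ± 0.05) and an activated mode
(0.75 ± 0.18), reproducing two discrete timepoint clusters joined by a
continuum of transiting cells. Label-retaining-cell (LRC) status is
assigned at the physiological fractions 35% (young) and 15% (aged),
with the count made exact by rounding.

**How age enters.** The age rate multiplier r (default: young 1.0,
aged 0.5) models a group traversing the *same* trajectory at r times
the reference speed. Two consequences are implemented:

1. *Kinetics.* In trajectory coordinates the ODE right-hand side is
   divided by r. This leaves every steady state — and hence the
   manifold of states — untouched, but scales the measurable
   disequilibrium β·u − γ·s (the RNA velocity) by ≈ r at matched
   positions. A slow traverser is closer to quasi-steady state
   everywhere.
2. *Occupancy.* The fraction of cells that have launched into
   activation by the fixed sampling time is scaled by (1 + r)/2, so a
   slower group has more cells still quiescent and a lower mean latent
   time, while both groups share full trajectory support. (An earlier
   design that compressed latent positions by r was rejected: it
   truncates the aged data mid-trajectory, and phase points then drift
   indefinitely past the data edge because no attractor exists in the
   aged field.)

**Default gene panel.** 30 up / 30 down / 20 pulse / 20 flat genes.
Rates are fast relative to the unit latent-time span (β = 24, γ ∈
[12, 20]; pulse genes β = 40, γ ∈ [20, 28]) and ramps/pulses complete
by latent time ≈ 0.5, for two reasons: cells at the expression extremes
are then genuinely at steady state, which is the regime the
steady-state γ estimator assumes, and the dense activated region is a
kinetic fixed point, giving the phase-point flow a real attractor.
Pulse-gene kinetics must be fast relative to the pulse width or the
spliced pool cannot track the transient and the γ fit for those genes
is badly biased (observed during design: γ̂/γ ≈ 0.6 with slow pulse
genes, recovering to ≈ 0.97 with fast ones).

**Motility tracks.** Two-state (immotile/motile) per-frame Markov
switching at the 6.5-minute frame interval; motile steps have
gamma-distributed lengths (mean 1 µm/frame, sd 0.3) and uniform
directions; immotile cells do not move. The immotile→motile rate ramps
linearly from `p_on_start` to `p_on_end` starting at the 10 h analysis
window open — activation during imaging. Defaults: young 0.01 → 0.40
(p_off 0.10), aged 0.01 → 0.08 (p_off 0.14). The ramp must begin at
the window open: occupancy equilibrates within ~1 h, so a ramp spread
over the whole recording produces nearly equal early→late occupancy
*changes* in both groups and no transition-magnitude contrast.

## Preprocessing

QC removes cells with mitochondrial fraction strictly > 0.10 or more
than 5000 detected genes, and drops the rRNA-contaminated transcripts
Gm42418 and AY036118 before normalization. Normalization scales each
cell to 10,000 counts and applies log1p. Highly variable genes are the
top n by variance-to-mean dispersion of the log-normalized values. PCA
is computed by SVD with a fixed sign convention (largest-magnitude
loading of each component positive) so embeddings are bit-reproducible.

Factor variance decomposition uses sequential (type-I) sums of squares
in caller-specified factor order, averaged over genes; aliased factors
get NaN with a warning. Type-I SS is an explicit stand-in — the
decomposition is order-dependent by construction, which the caller
must keep in mind with unbalanced designs.

## RNA velocity

Layers are normalized by a *common* per-cell size factor computed from
spliced totals (target 10,000). Using one factor for both layers
preserves each cell's u:s ratio; normalizing each layer to its own
total would deflate the unspliced signal of rising cells. Both layers
are then smoothed by kNN pooling (k = 30) over the embedding. When
group labels are supplied, pooling neighbors are restricted within
group: where groups share state-space support, unrestricted pooling
averages their layers together and erases exactly the kinetic contrast
under study.

γ̂ per gene is the origin-constrained least-squares slope of u on s over
the cells in the top and bottom 5% of s, clipped at zero. Velocity is
v = u − γ̂·s; the extrapolated future state is max(s + v·Δt, 0) with
dimensionless Δt = 1. For the embedding projection, current and future
spliced expression are both passed through log1p — the scale the
embedding was fit on — before applying the stored centering and
loadings; the embedded velocity is the coordinate difference per Δt.
`embed_velocity` itself is a pure linear projection of whatever
expression pair it is handed.

Known estimator biases, characterized on synthetic data: selection on
noisy pooled s attenuates γ̂ by a few percent (the top-quantile cells
are upper order statistics of the pooling noise), and genes violating
the steady-state-at-extremes assumption (slow relaxation, transient
peaks) can be off by tens of percent. The internal pooling PCA uses
log1p counts so that no single high-count gene's noise dominates the
neighbor graph.

The binned magnitude curve uses equal-width pseudotime bins (‖mean
vector‖ per bin), a centered rolling mean, and masks bins with fewer
than 10 cells; pass shared bin edges when comparing groups.

## Pseudotime, Δpseudotime, lineage regression

The built-in pseudotime fallback orders cells along PC1 (oriented so
activated-timepoint cells have larger values, shifted to start at 0);
it is adequate when the activation axis dominates variance, as in the
synthetic populations, and is replaced by externally computed
pseudotime on real data. The pseudotime map is a kNN regression
(k = 5, uniform weights) from embedding coordinates; its predictions
are bounded by the reference pseudotime range.

Δpseudotime is the map's prediction at x + v·Δt minus the observed
pseudotime. A cell is *regressing* when Δp < −m·σ with σ the sample
standard deviation (ddof 1) of Δp and m = 0.5 by default. The
threshold multiplier is configurable because the source material for
this definition is internally inconsistent about the sign and factor;
the operational "more than half a standard deviation below zero" form
is implemented. The regressing-frequency curve bins cells by observed
pseudotime, with Gaussian smoothing (σ = 1 bin) and binomial standard
errors per bin.

## Phase-point simulation

Phase points start from observed cell positions in the primitive
region of the activated timepoint (activated cells below that group's
25th pseudotime percentile — the source material names the region
without defining it; the rule is configurable). Each step moves every
point by step_size × (mean embedded velocity of its k = 30 nearest
cells in the group-restricted field), plus optional Gaussian jitter.
Velocities are pre-scaled to unit median magnitude; the default
step_size is 0.05 embedding units, chosen so a few hundred steps
resolve the traversal of a ~25-unit manifold (a full-manifold step of
1.0 would cross the trajectory in ~20 steps and alias the progression
curves). Runs are bit-reproducible given the seed. Densities are
accumulated on a 100×100 grid over the bounding box; terminal
positions and per-step mean inferred pseudotime support group
comparisons. For between-group comparisons, sample one shared set of
initial positions and pre-scale both fields by one common median.

**Attractor identifiability.** With noise-free fields, both groups'
phase points collapse onto the trajectory-end fixed point. With NB
count noise, each group's empirical field has its own attracting zero
inside the activated region, displaced by roughly the within-state
embedding scatter; measured young–aged terminal-centroid separations
are ~0.2–0.5 raw embedding units (0.04–0.2 in per-PC-standardized
units) at 2000 cells/group and dispersion 0.1. Terminal *regions*
coincide; terminal *points* agree only up to this noise floor. The
validation suite checks the separation at a 0.1-unit tolerance and
currently fails it for this reason; the directional comparisons (which
group progresses faster, and where) are unaffected.

## Population statistics

Differential expression filters first — |difference of mean log1p
expression| ≥ 0.15 (natural-log scale; the scale is a package choice)
and expressed (count > 0) in ≥ 10% of cells in at least one group —
then applies the two-sided Wilcoxon rank-sum test (exact for small
samples without ties) and Bonferroni correction over the genes
actually tested. Note a structural property of filter-then-correct:
when the fold-change filter binds under the null it preferentially
retains statistic-correlated genes while shrinking the Bonferroni
denominator, so family-wise error can exceed nominal; the type-I
validation therefore uses a null where the filters are pass-through.

Gene AUROC is computed from rank sums (ties at 0.5), which is exactly
U/(n₁n₂). DM overdispersion orders mean-filtered genes (mean ≥ 0.1) by
log10 mean and subtracts a 50-gene running median of log10 CV²
(window shrinking at the ends). The KL estimator cross-fits a
probabilistic classifier (regularized logistic regression by default;
gradient boosting optional) over 2 stratified folds, converts held-out
probabilities to density ratios with the training-fold prior
correction and probability clipping at 10⁻⁶, and averages log r over
held-out A-points. Incorporation tests use a logistic regression Wald
test; under perfect separation the odds ratio comes from an
L2-penalized fit and the p-value is reported as NaN with a flag.

## Sparse classification

A linear SVM with L1 penalty and squared-hinge loss is fitted per C on
a 20-value log grid over [10⁻³, 10], on a stratified 80/20 split with
features standardized using training statistics only. The reported
gene set is taken at the smallest C (strongest penalty) whose holdout
accuracy is within one binomial standard error of the best — the 1-SE
rule, used because the upstream analyses report gene-set sizes without
stating a selection rule.

## Behavior analysis

Features per track (within the 10–35 h window): total and net
distance, net/total ratio, mean/max/min speed (µm/min), linearity
(squared Pearson correlation of y on x — the one feature that is not
rotation-invariant, by its axis convention), progressivity (Spearman
correlation of distance-from-origin with time), mean cosine of turning
angles, and moving-time fraction (step length > 0.5 µm/frame by
default). Features are z-scored to population mean 0, variance 1.
Behavior states are Ward-linkage hierarchical clusters of the z-scored
features, relabeled by ascending mean speed so state 1 is least
motile. Transition vectors come from splitting the window into two
halves, embedding both halves' z-scored features in one 2-D PCA, and
subtracting earlier from later coordinates; a group's transition
magnitude is the norm of its mean vector with a 1000-resample
percentile bootstrap CI. State preference uses a χ² test without
continuity correction (Fisher fallback when an expected count is
zero) and, with a covariate, a logistic regression of state-1
membership with a Wald test on the age term. Per-feature age
comparisons use two-tailed t-tests with Holm–Bonferroni correction.

## Validation studies and problem sizes

The studies in `statekinetics.benchmarks` (run by the test suite and
`scripts/acceptance.py`):

* γ recovery: ratios {0.2, 0.5, 1.0} × 10 replicate flat genes + 30
  fillers, 500 cells, φ = 0.1, per-ratio median γ̂; replicates are used
  because a single gene's estimate at this size carries ~4% sampling
  scatter, which would dominate a recovery check.
* Kinetic delay: default panel, 2000 cells/group, aged rate 0.5×;
  binned-magnitude comparison on shared edges, and phase simulations
  with 1000 points × 2000 steps from one shared init set.
* Δpseudotime: 400 cells on a linear manifold, constructed ±velocities.
* KL: n = 10⁴/group 1-D Gaussians (closed form 0.5 nats) plus an
  identical-distribution control.
* DE null: 2000 × 400 N(10, 6) matrices with permuted labels (filters
  pass-through; see above), plus the exact 6-vs-6 p = 1/462 example.
* SVM: 20 informative of 1000 genes (1 SD shift), 1000 cells.
* Behavior: 300 cells/group tracks at the default regimes.

## What the synthetic data does and does not establish

The generator reproduces the statistical structure the estimators
assume: NB counts obeying the kinetic model, a 1-D activation manifold
with two sampling modes, group-wise kinetic scaling, and two-regime
motility. Passing tests therefore demonstrate correctness of the
machinery and recoverability under those assumptions — not performance
on real MuSC data, which adds batch effects, cell-cycle structure,
doublets, ambient RNA, multi-lineage contamination, segmentation
errors, and velocity-model violations (transcriptional bursting,
gene-specific capture) that the simulator deliberately omits. Absolute
magnitudes (velocity units, embedding units) are arbitrary; only
within-dataset contrasts are interpreted.
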