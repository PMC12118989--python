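# Methods

## Data model and assumptions

The input is a collection of expression cohorts x^{t} ∈ ℝ^{m×n(t)} observed at
strictly increasing times t₁ < … < t_N (N ≥ 2, n(t) ≥ 2). Sampling is
destructive: cohorts at different times share no cells, and any statement
about temporal change must be routed through an inferred correspondence
between cohorts. Values are raw non-negative counts or normalized expression;
the pipeline applies log(x+1) unless told the data are already transformed.
Continuous pseudotime can stand in for real time: cells are sorted and sliced
into quantile bins of near-equal size (ties always share a bin, going to the
lower bin at boundaries), and bin midpoints of the pseudotime ranges act as
time stamps in the finite differences unless real times are supplied.

## Couplings

For each consecutive pair of cohorts we solve the entropic fused
Gromov–Wasserstein problem over the transportation polytope Π(p, q):

- **Feature cost** D: pairwise Euclidean (optionally cosine) distances
  between cells across the two cohorts, divided by its maximum.
- **Structure costs** S, S̃: geodesic distances on the union-symmetrized
  k-nearest-neighbor graph within each cohort, k = max(1, ⌊min{50, 0.2 n(t),
  0.2 n(t̃)}⌋) — the formula references both cohort sizes, and we follow it
  literally even though each structure matrix involves only one cohort.
  Unreachable pairs are set to the largest finite geodesic (keeping the
  objective finite), then the matrix is max-normalized. The union rather than
  mutual-kNN graph is used because it disconnects less often.
- **Marginals** p, q: uniform by default. In `branch_reweighed` mode every
  branch receives total mass equal to its average proportion across the two
  time points, split uniformly within the branch — compensating for
  disproportionate branch representation so that under- or over-sampled
  lineages still map onto themselves.
- **Entropy**: the term ε Σ T log T is *added* to the minimized objective, so
  larger ε always yields more diffuse plans. Defaults α = 0.5, ε = 0.01.

### Solver

The GW term is quadratic in T; we iterate linearization: around the current
plan, the squared-difference loss factorizes into
`(S²p)1ᵀ + 1(S̃²q)ᵀ − 2 S T S̃ᵀ`, giving a linear cost whose entropic OT
subproblem is solved by Sinkhorn scaling (multiplicative for ε ≥ 5e−3,
log-domain below or on underflow; marginal tolerance 1e−9, warm-started
potentials). Outer iterations stop when the relative change of the entropic
objective falls below 1e−7 (cap 50); non-convergence returns the best iterate
with a warning, and the returned plan's marginal violation is polished below
1e−6. An absolute-difference GW loss is available via direct tensor
contraction for cohorts up to 200 cells.

Two numerical choices matter for solution quality and are deliberate:

1. **ε-annealing.** The entropic coefficient is lowered geometrically from
   0.1 to the target over the first 10 outer iterations. The continuation
   path avoids the poorest stationary points of the non-convex quadratic.
2. **Deterministic restarts.** On problems with ≤ 64 cells per side the loop
   additionally restarts from three fixed-seed Sinkhorn-projected random
   plans (besides the independent coupling pqᵀ) and keeps the best final
   entropic objective. Small-problem landscapes are the roughest — on random
   4×4 pure-GW instances, single-start linearization ends up to 13% above
   the best permutation plan, while the multi-start version stays within a
   fraction of a percent — and the extra solves are cheap there. Cohort-scale
   problems (hundreds of cells, fused with an informative feature term) are
   much better conditioned and use the single pqᵀ start. At α = 0 the
   problem is strictly convex and a single Sinkhorn run suffices. Everything
   is deterministic given the inputs.

Composition across longer lags converts each plan to a Markov kernel (rows
normalized; an all-zero row teleports to the plan's target marginal, with a
warning) and chains them: `diag(p) K₁ K₂ …`.

## Velocities

The barycentric projection 𝒯(x^{t,c}) = Σ_c̃ (T[c,c̃]/Σ_d̃ T[c,d̃]) x^{t̃,c̃}
predicts each cell's descendant (and, via Tᵀ, its ancestor — the backward map
reuses the forward coupling rather than re-solving). Velocities are finite
differences: forward at t₁, backward at t_N, and inside the spacing-weighted
centered combination

v_center(t_k) = (t_k−t_{k−1})/(t_{k+1}−t_{k−1}) · v_forward + (t_{k+1}−t_k)/(t_{k+1}−t_{k−1}) · v_backward,

which reduces to the plain average for equally spaced times. Each gene is then
scaled to unit *population* standard deviation pooled over all cells at all
time points (the convention only affects a recorded scale factor,
`gene_sds`); means are **not** subtracted because velocity signs carry the
activation/inhibition information. Zero-variance genes are left untouched and
recorded. Projected velocities (the column-normalized coupling average
carrying the past cohort's velocities onto present cells) are divided by the
same per-gene factors, since the regression mixes both.

A stimulus is encoded as an artificial gene with velocity exactly 1 at the
stimulus time point and 0 elsewhere; it bypasses normalization, is excluded
as a correlation target, and is predictor-only in the regression.

## GRN estimators

**Correlation (`corr`).** C^{(k)} = v(t_k) T^{t_k,t_{k+lag}} v(t_{k+lag})ᵀ and
C = (1/(N−lag)) Σ_k C^{(k)}. The prefactor is kept as an average in interval
restrictions too, so windows of different lengths are comparable. With one
cell per time and T ≡ 1 this is the classical lagged product-moment sum; with
unit-SD velocities and a probability coupling the matrix is unit-free. The
in–out degree deg(g) = Σ_{g̃≠g}|C[g̃,g]| / Σ_{g̃≠g}|C[g,g̃]| flags likely
regulators (< 1) versus targets (> 1), with ∞ and NaN sentinels for empty
denominators reported as such.

**Granger (`granger`).** Per interval, each gene's velocity at t_{k+1} is
regressed on all genes' projected past velocities at the same cells with the
standard elastic-net objective

1/(2n) ‖v_{g₂} − A[g₂,:] v̂‖² + λ ( r‖A[g₂,:]‖₁ + (1−r)/2 ‖A[g₂,:]‖₂² ),

no intercept, defaults λ = 1, r = 0.5. The printed form of the penalized
problem with unsquared norms is reconciled to this conventional scaling — it
is the objective standard solvers actually minimize, and λ, r retain their
usual meaning. λ = 0 is solved by least squares and r = 0 by the ridge
closed form; otherwise coordinate descent (scikit-learn). Coefficients are
stored rows-as-targets; the edge g₁→g₂ lives at the transposed position, and
all exported matrices are oriented regulator → target. The global network is
the exact elementwise sum of the interval matrices. Only first-order lags are
used; longer-lag compositions degrade and overparameterize.

**Branches.** In `split` mode the full pipeline runs once per branch (time
points where the branch has < 2 cells are dropped) and the per-branch
networks are combined either by summation (default) or by taking the
entrywise signed maximum absolute value (ties to the lowest branch index).
Both rules are legitimate summaries; summation favors consistently supported
edges, max-abs preserves branch-specific ones.

## Evaluation

Self-loops are excluded from predictions and truth alike; the random baseline
is the edge density over ordered off-diagonal pairs and the AUPRC ratio is
AUPRC/baseline. AUPRC is computed as average precision over the forced total
order (|weight| descending, ties broken by stable row-major index); AUROC by
rank-averaging over tied blocks (equivalent to trapezoidal integration).
Signed metrics zero every prediction whose sign contradicts the true sign of
a true edge before scoring — predictions on non-edges have no true sign and
are left untouched. Early precision uses k = min(#true edges, #nonzero
predictions); exact zeros count as "not predicted" for k but remain (ranked
last) in the AUPRC/AUROC ranking. An optional undirected mode symmetrizes by
the max-|weight| direction before scoring.

## Simulator

Each cell is an independent Euler–Maruyama path of

dx_g = ( β_g σ(Σ_h W[h,g] x_h + b_g + u_g) − γ_g x_g ) dt + η dB,  σ(z) = 1/(1+e^{−z}),

clipped at zero, started at the stimulus-off stationary state plus small
Gaussian jitter (σ = 0.05), with the stimulus input u switching on at t = 0.
For every observation time a fresh cohort is integrated and recorded once —
destructive sampling by construction. Branch-specific interaction matrices
take over after the branch time, with cells assigned to branches by
per-time-point proportions; optional Poisson counts and Bernoulli dropout are
applied last. All randomness flows from one seed through per-cohort
`SeedSequence` substreams, so cohorts are order-independent and datasets are
bit-reproducible. dt must be at most one tenth of the smallest observation
spacing; states above 1e6 abort with a request for a smaller dt.

This logistic-interaction SDE is a deliberately simple stand-in for bursty
transcription kinetics: it shares the observational structure that matters
for this pipeline (signed network ground truth, stimulus, branching,
independent cohorts) but not promoter switching, mRNA/protein layers, or
realistic count overdispersion. Passing recovery tests therefore demonstrate
that the method extracts planted temporal signal under destructive sampling —
not performance on any particular experimental platform.

### Fixture defaults

Canned benchmarks use interaction weight |W| = 4 on active edges (strongly
saturating), production β = 4, degradation γ = 1 (response time ≈ 1 time
unit), basal input b = −2 for silent genes (raised for inhibited targets so
repression is visible), stimulus input 4 on the root gene, diffusion
η = 0.3, dt = 0.05. `tiny2`/`tiny2_inh`: two genes, one planted ± edge,
3 time points × 30 cells. `fn4like`: four genes with a branch point and an
inhibition feedback loop, two branch variants, 6 × 60 cells. `tree8`: eight
genes wired as a tree under the stimulus (one inhibitory edge), 10 time
points × 200 cells — sized like a typical time-stamped benchmark cohort.
The tiny2 fixtures drive the regulator with a stimulus *input* (no stimulus
gene is added at inference) because a system resting at its fixed point has
no temporal signal at all.

## Known limitations

- The transport solver is a local method on a non-convex objective; the
  restart/annealing scheme makes small instances reliably near-optimal, but
  there is no global optimality guarantee at cohort scale.
- Moderate random dropout on the simulator's low-noise, continuous-valued
  fixtures does not necessarily reduce recovery — independent zeroing whitens
  shared-ancestry background correlations as much as it corrupts signal; on
  real count data with structured dropout the effect is typically harmful.
- Couplings are stored dense; cohorts beyond a few thousand cells per time
  point will be slow and memory-hungry.
- No unbalanced transport (growth/death), no splicing-based velocity, no
  cross-validation of (λ, r) — the defaults are used throughout.
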