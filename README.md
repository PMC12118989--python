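# otgrn

Signed, time-resolved gene regulatory network (GRN) inference from
**time-stamped single-cell expression cohorts**, via gene velocities estimated
with entropic **fused Gromov–Wasserstein optimal transport**.

## The problem

Single-cell RNA sequencing destroys the cell it measures: cohorts sampled at
times t₁ < … < t_N contain *different* cells, so no gene's trajectory is ever
observed directly. `otgrn` reconstructs the missing temporal links by solving,
for each consecutive pair of cohorts, the entropic fused Gromov–Wasserstein
problem

T = argmin_{T ∈ Π(p,q)} (1−α)⟨T, D⟩_F + α Σ L(S_{cd}, S̃_{c̃d̃}) T_{cc̃} T_{dd̃} + ε Σ T log T

where `D` compares cells across the two cohorts in expression space, `S`/`S̃`
are geodesic distances on within-cohort kNN graphs (so branching geometry is
preserved), `α` trades the two terms and `ε` controls the diffuseness of the
plan. The coupling `T[c, c̃]` estimates the probability that cell c̃ descended
from cell c.

From the couplings, each cell receives a **gene velocity** — the finite
difference between its barycentric descendant/ancestor predictions and its
observed state (forward at t₁, centered inside, backward at t_N, with
non-uniform-spacing weights). Velocities, normalized per gene to unit pooled
standard deviation, feed two GRN estimators:

- **corr** — OT-weighted time-lagged correlation:
  `C[g₁,g₂] = 1/(N−lag) Σ_k v_{g₁}(t_k) T^{t_k,t_{k+lag}} v_{g₂}(t_{k+lag})ᵀ`.
  Positive entries suggest activation of g₂ by g₁, negative inhibition.
- **granger** — per-interval elastic-net regression of current velocities on
  the projected past velocities of the same cells, summed over intervals into
  a sparse global network.

Both return per-interval decompositions (time-varying GRNs), support an
artificial *stimulus gene* (unit velocity at the stimulus time, source-only),
branch-aware marginals for unbalanced lineages, and signed/unsigned
AUPRC/AUROC/early-precision scoring against a ground-truth edge list. A
simulator generates destructively-sampled cohorts from known signed networks
(logistic-interaction SDE with branching, dropout and count noise) so the
whole pipeline is testable end to end.

## Worked example

```python
import otgrn

# 8-gene tree network rooted at a stimulus; 10 time points x 200 cells,
# every cohort an independent draw (destructive sampling)
dataset, truth = otgrn.make_fixture("tree8", seed=0)

model = otgrn.VelocityGRN(dataset, stimulus_time=0.0)
results = model.fit("granger")          # or "corr"; couplings are shared
print(results.summary(top=8))
print(results.evaluate(truth))
```

```
Velocity-GRN results (Granger elastic net)
==========================================
genes: 9   time points: 10   cells: 2000
params: method=granger, alpha=0.5, epsilon=0.01, lag=1, lam=1.0, ratio_r=0.5, ...
coupling diagnostics: max marginal violation 6.914e-10; outer iterations [21, 14, 13, ...]
nonzero off-diagonal weights: 14 / 72

top 8 edges by |weight|:
regulator target          weight sign interval
       g2     g3  0.292329071831    +   global
       g3     g2  0.281736717147    +   global
       g1     g3  0.233544442166    +   global
...

auprc: 0.274359          auroc: 0.667969
signed_auprc: 0.255963   auprc_ratio: 2.46923
random_baseline: 0.111111
```

The AUPRC ratio of ≈2.5 means the ranked edge list recovers the planted tree
about 2.5× better than a random classifier (ratio 1); the signed variant
zeroes predictions whose activation/inhibition sign contradicts the truth
before scoring.

The same pipeline runs from the shell:

```bash
otgrn simulate --fixture tree8 --out-dir data/
otgrn infer data/matrix.tsv data/metadata.tsv --out-dir out/ \
      --method corr --stimulus-time 0 --per-interval
otgrn eval out/grn_global.tsv data/truth.tsv --out report.json
```

## Layout

| module | contents |
|---|---|
| `otgrn.io` | dataset/network/config containers, delimited & MatrixMarket readers, quantile pseudotime binning, edge-list output |
| `otgrn.preprocess` | log1p, inter-cohort cost matrices, kNN-geodesic structure matrices, uniform & branch-reweighed marginals |
| `otgrn.coupling` | entropic fused-GW solver, Sinkhorn (standard + log-domain), coupling composition, barycentric projection |
| `otgrn.velocity` | finite-difference velocities, velocity projection, per-gene normalization, stimulus gene |
| `otgrn.correlation` | OT-weighted lagged correlation, per-interval networks, in-out degree |
| `otgrn.granger` | per-interval elastic-net regression, global aggregation, branch combination |
| `otgrn.evaluation` | signed/unsigned AUPRC, AUROC, AUPRC ratio, early precision |
| `otgrn.simulate` | SDE simulator with destructive sampling, branching, dropout; canned fixtures |
| `otgrn.model` | `VelocityGRN` / `GRNResults` (fit → summary/evaluate/export) |
| `otgrn.cli` | `otgrn simulate | infer | eval` |

See `docs/methods.md` for the model assumptions, parameter meanings and
numerical choices.
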