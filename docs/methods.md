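# Methods

## Model

`layerprop` scores nodes of a K-layer network by regularized label
propagation. Nodes are ordered layer by layer (declaration order within a
layer); the weight matrix `W` is block tri-diagonal: symmetric non-negative
intra-layer blocks on the diagonal (zero diagonal — no self-loops) and
non-negative rectangular inter-layer blocks only between consecutive layers.
Layer adjacency is the declared layer order; no other topology is inferred.

Matrix separation splits `W` into `W_intra` (block diagonal) and `W_inter`
(the band), reconstructing `W` exactly, entry for entry. Each part has an
unnormalized Laplacian `L = D − W` with `D = diag(row sums)`; both are
positive semidefinite, so for any trade-offs `μ_a, μ_b ≥ 0` the system
matrix `I + μ_a L_intra + μ_b L_inter` is symmetric positive definite and

```
f = (I + μ_a L_intra + μ_b L_inter)⁻¹ Y
```

uniquely minimizes `‖f − Y‖² + μ_a f'L_intra f + μ_b f'L_inter f`.

**Smoothness-term convention.** `f'Lf` equals *half* the double sum
`Σ_{i,j} W_ij (f_i − f_j)²` over ordered pairs. The quadratic form `f'Lf`
is taken as the canonical smoothness term here, so the closed-form solution
above minimizes the implemented cost exactly; writing the objective with the
unhalved double sum instead simply rescales `μ` by 2 and changes nothing
qualitative.

**Label encodings.** Theory sections conventionally use `Y ∈ {−1, 1}` for
labeled nodes; the co-occurrence experiment uses `{1, 0}` (presence
labeling). Both are supported: the solver is linear in `Y`. With `{0, 1}`
labels all scores stay in `[0, 1]`, because the system matrix is a
diagonally dominant M-matrix whose inverse is non-negative and maps the
all-ones vector to itself.

## Fast solver

The inter-layer Laplacian — typically sparse and effectively low-rank in a
layered network — is approximated by the Nyström method: sample `r` columns
`C` (uniformly without replacement), take the intersection block `Q`, and
use `Ĥ = C Q⁺ C'`. The solution then follows from the Woodbury identity
with `A = I + μ_a L_intra` (block diagonal, one Cholesky factorization per
layer) and core `B = μ_b Q⁺`. Only the inter-layer part is approximated;
approximating the intra-layer Laplacians would degrade each layer's own
structure for no asymptotic gain.

Numerical choices:

* **Core truncation.** Woodbury needs an invertible core, but `Q⁺` can be
  rank-deficient (zero columns, duplicated structure). `Q` is
  eigendecomposed and truncated at relative eigenvalue cutoff `1e-10`
  (configurable); with `Q = V diag(w) V'` restricted to retained
  eigenvalues, the factorization becomes `U diag(1/w) U'` with `U = CV`, and
  `B = μ_b diag(1/w)` is invertible on the retained space — the identity is
  exact for the approximation actually used. A sample whose numerical rank
  falls below `r` triggers a `RankDeficiencyWarning`.
* **Sampling.** The `r` indices are the first `r` entries of a seeded random
  permutation — still uniform without replacement, and nested across `r`
  for a fixed seed, which makes the agreement error between fast and direct
  solutions behave monotonically as `r` grows.
* **Symmetrization.** `C Q⁺ C'` is averaged with its transpose to suppress
  floating-point asymmetry before use.
* **Degenerate cases.** `μ_b = 0` delegates to the exact block-decoupled
  path; an all-zero sampled band (effective rank 0) reduces to `A f = Y`.
* Conditioning of the core and of the inner `r × r` Woodbury system is
  checked (condition number below `1e14`); failure raises rather than
  returning garbage.

At `r = N`, `Ĥ = H` to machine precision (`H H⁺ H = H` for PSD `H`) and the
fast solution matches the direct one to ~`1e-15` relative error; the tests
assert `≤ 1e-6`.

## Co-occurrence experiment

Protocol (per target disease, leave-one-target-out over all diseases with at
least one co-occurring partner):

1. label the target 1;
2. reveal a random 20% of its co-occurring diseases as prior labels
   (nearest-integer count, capped so at least one partner stays hidden);
3. label a fraction (0–100% in 20% steps) of its *related symptoms* — those
   sharing a non-zero inter-layer edge with it;
4. solve; rank all other diseases by score; compute the rank-based AUC
   (ties one half, identical to the Mann–Whitney statistic) against the
   co-occurrence truth, **excluding the target and the revealed priors**
   from the truth set — they were given to the solver, so counting them
   would leak;
5. repeat the label draws 10 times; at 0% symptom labels the inter-layer
   edges are dropped entirely and the disease layer is solved alone with
   trade-off `μ_a` (the single-layer reference).

Label draws are deterministic functions of the experiment seed (one
independent substream per fraction × repeat × target) and are shared across
the `(μ_a, μ_b)` grid, so grid points differ only in the solver. The default
grid is the 5 × 5 logarithmic grid over `{0.01, 0.1, 1, 10, 100}` with the
best pair chosen by overall mean AUC; the scripted analyses fix
`(μ_a, μ_b) = (1, 0.1)` instead — see below.

**Why `μ_b = 0.1`.** Labeled symptoms inject signal into the disease layer
at first order in `μ_b`, while the purely structural two-hop path
(target → symptom → candidate) enters at second order. A moderate `μ_b`
therefore keeps the benefit of the symptom layer *attributable to its
labels*, which is the phenomenon the sweep measures; at large `μ_b` the
two-hop flow saturates the ranking and the label fraction barely matters.

## Enrichment analysis

For each disease with at least one co-occurring and one non-co-occurring
partner, compute the difference between its mean shared-symptom count with
co-occurring and with non-co-occurring diseases (shared symptoms = common
inter-layer neighbors). The differences are tested with a paired one-sided
t-test (H1: mean difference > 0), `df = retained diseases − 1`. Zero
variance is reported as a degenerate result (`t = 0, p = 0.5` when the mean
is also zero; infinite `t` otherwise) instead of an error. A tier variant
bins diseases by associated-symptom count (`≥ high`, in between, `≤ low`;
default cutoffs 100/10) and tests each bin.

## Synthetic generator

The generator emulates a curated symptom–disease resource at desk scale.
Diseases are partitioned into equal co-occurrence modules (every
within-module pair co-occurs). Signal is planted through **both** layers:

* *proteins* — each module owns `n_proteins / n_modules` proteins; a member
  disease carries each with probability `protein_sharing_rate` (default
  0.12) against `background_protein_rate` (0.02) elsewhere. The disease
  intra block is the pairwise Tanimoto similarity of these bit profiles, so
  the disease layer alone carries moderate signal.
* *symptoms* — each module owns `n_symptoms / n_modules` symptoms; the
  disease–symptom link probability is `within_module_symptom_overlap`
  (default 0.4) on module symptoms and `background_symptom_rate` (0.02)
  elsewhere, every link an independent Bernoulli. The binary incidence
  matrix is the inter-layer block; the symptom intra block is the pairwise
  Tanimoto of symptom × disease incidence.

Defaults (200 diseases, 20 modules, 60 symptoms, 300 proteins) were chosen
so the experiment operates in the regime the method is designed for: a
single-layer reference AUC near 0.6, rising monotonically to ~0.72–0.75
with fully labeled symptoms, with full sweeps running in seconds. The
per-pair-independent link mechanism matters for calibration: when
`within_module_symptom_overlap == background_symptom_rate` the inter-layer
links are i.i.d. and the network is an *exact* null for the enrichment
test with respect to symptom structure, and under the default planting the
test rejects at `α = 0.001` in every seed. One caveat the tests make
explicit: the paired t-test treats the per-disease differences as
independent, but module partners average their shared-symptom counts over
the *same* set of co-occurring diseases, which correlates their differences
positively. The test is therefore mildly anti-conservative even under the
exact link-level null — rejection rates at `α = 0.05` run at roughly 5–10%
depending on the seed batch (≈8% over 1000 seeds) rather than exactly 5%.
The same caveat applies to any module-structured co-occurrence truth,
including real comorbidity data.

What the generator does **not** emulate: realistic symptom/disease degree
distributions (hubs like "pain"), overlapping or nested comorbidity modules,
partially observed co-occurrence truth, or similarity noise from shared
pathways outside modules. Passing tests therefore demonstrate the method's
correctness and its qualitative behavior under planted structure, not
performance on any real clinical resource.

## Problem sizes and tolerances

Test and script workloads use networks of 10–260 nodes — large enough to
exercise every code path (rank deficiency, rectangular blocks, tier binning)
while keeping the full suite under a minute of compute for the numerical
parts and a few minutes for the sweeps. Solver agreement is asserted at
`1e-8`–`1e-10` relative error (direct vs brute-force inversion, Woodbury vs
dense oracle), `1e-6` for fast-vs-direct at full rank; the achieved errors
are near machine precision. The AUC implementation is checked against an
exhaustive pairwise oracle, and the t-test against an independent
statistical library routine.

## Known limitations

* Dense block storage: fine for thousands of nodes, not for genome-scale
  layers; the Nyström/Woodbury structure would carry over to sparse
  intra-block factorizations but that path is not implemented.
* Uniform column sampling only; leverage-score sampling would improve the
  low-rank approximation at small `r`.
* The grid search reports all grid points and selects by the same AUC it
  reports — there is no inner/outer split; treat the selected pair as a
  descriptive optimum, not an unbiased performance estimate.
* Two-layer experiment code assumes one disease layer adjacent to one
  symptom layer; the solvers themselves handle any K.
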