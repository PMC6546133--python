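# Methods

This note documents the models implemented in `supnmf`, the algorithms
and their numerical details, the synthetic-data generator used for
validation, and the design decisions taken where several reasonable
choices existed.

## Problem setting

An MSI experiment yields a non-negative matrix `Y ∈ R≥0^{n×m}`: n spectra
(one per measured spot), m intensity channels on a common m/z axis.  Each
spectrum carries a binary class label `u_i ∈ {0,1}` (e.g. two tumor
subtypes) and a group identifier (the TMA slide / measurement batch it
came from).  The scientific difficulty is that class-discriminative
spectral features are typically much weaker than the dominant spectral
components, so a plain low-rank decomposition allocates its components to
the dominant structure and the discriminative signal is lost to the
downstream classifier.

## Models

All models factorize `Y ≈ KX` with `K ∈ R≥0^{n×p}`, `X ∈ R≥0^{p×m}` under
a Frobenius discrepancy, and differ in their penalties.

Unsupervised:

* **FR** — `½‖Y−KX‖²_F + λ‖X‖₁ + (μ/2)‖K‖²_F + (ν/2)‖X‖²_F`.  The l1
  term sparsifies the pseudo spectra; the l2 terms control scaling and
  conditioning.
* **FRO** — FR plus a *split* orthogonality penalty
  `(σ₁/2)‖I−XWᵀ‖²_F + (σ₂/2)‖W−X‖²_F` with an auxiliary non-negative
  `W` of the same shape as `X`.  Splitting avoids a quartic term in `X`
  while driving `XXᵀ → I` as `W → X`.
* **FO** — FRO with `λ = μ = ν = 0` (enforced at configuration time).

Supervised, coupling the factorization to the labels through the feature
map `F = YXᵀ`:

* **Flda / FRlda / FROlda** — add `(γ/2)‖u − YXᵀβ‖²` with `β ≥ 0`
  (length p, no intercept).  The labels are modeled as a non-negative
  superposition of the correlation images `YX_k,·ᵀ`, which is what makes
  the non-negativity constraint on `β` natural.
* **Flog** — add the logistic negative log-likelihood
  `(γ/n)(Σ_i log(1+e^{z_i}) − uᵀz)` with `z = [1|YXᵀ]β`.  Here
  `β ∈ R^{p+1}` (intercept first) must be allowed negative values to model
  probabilities below ½, so it cannot be updated multiplicatively.  No
  further l1/l2 terms are added to Flog; the logistic term itself acts as
  an effective regularizer of the decomposition.

## Algorithms

### Multiplicative MM sweeps (FR, FO, FRO, Flda family)

Each variable is updated by multiplying entrywise with the ratio of the
negative to the positive part of its partial gradient — the classical
majorize-minimization construction with a diagonal quadratic surrogate,
which preserves non-negativity and never increases the cost.  One sweep
updates `K`, then `X`, then `W` (when present), then `β` (when present),
each rule using the most recent values of the other variables:

```
K ← K ∘ YXᵀ / (KXXᵀ + μK)
X ← X ∘ (KᵀY + (σ₁+σ₂)W + γβuᵀY)
        / (KᵀKX + σ₁XWᵀW + σ₂X + γββᵀXYᵀY + νX + λ)
W ← W ∘ (σ₁+σ₂)X / (W(σ₁XᵀX + σ₂I))
β ← β ∘ XYᵀu / (XYᵀYXᵀβ)
```

The l1 weight λ enters the denominator as an entrywise constant (the
subgradient of `λ‖X‖₁` on the non-negative orthant).  Setting σ₁ = σ₂ = 0
recovers the FR rules and drops `W`; setting γ = 0 drops the supervision
terms.  The denominator product `ββᵀXYᵀY` is evaluated left-to-right as
`β((βX)Yᵀ)Y`, costing O(pnm) rather than O(m²) memory/time.

Numerical guards: every denominator receives an additive
`eps_div = 1e-12`.  This prevents 0/0 at zero entries and perturbs exact
fixed points by a relative `~eps_div` — far below test tolerances.  The
acceptance suite verifies cost monotonicity to within `1e-8 ×` the
initial cost over random instances, and fixed-point invariance of exact
factorizations to within `10 × eps_div`.

**Rescaling.**  With `D = diag(‖X_k,·‖₂)`, the transformation
`X ← D⁻¹X, K ← KD` leaves `KX` unchanged and gives the pseudo spectra
unit l2 norm (the orthogonality penalty itself implies l2 normalization,
which is why rescaling matters mostly for FR).  When a supervised Flda
model rescales, `β ← Dβ` keeps the supervision residual `u − YXᵀβ`
invariant as well.  Rescaling is applied once per sweep, after the
updates, when enabled; note that the l1/l2 penalty values are not
invariant under rescaling, so cost traces of rescaled fits need not be
monotone.  Flog applies no rescaling.

### ADADELTA for Flog

`K` keeps its multiplicative rule (the printed Flog K-rule carries no μ
term).  `X` and `β` take full-batch ADADELTA steps: per-entry squared
gradients and squared updates are accumulated with decay ρ, and the step
is the gradient scaled by the ratio of the two root-mean-squares,

```
E[g²] ← ρE[g²] + (1−ρ)g²
Δ      = −√(E[Δ²]+ε) / √(E[g²]+ε) ∘ g
E[Δ²] ← ρE[Δ²] + (1−ρ)Δ²
```

with the canonical ρ = 0.95, ε = 1e-6.  Full-batch gradients (no
minibatch sampling) keep every fit exactly reproducible from its seed.
The analytic gradients, with `Z = [1|YXᵀ]`, `s = σ(Zβ)`:

```
∂cost/∂β = (γ/n) Zᵀ(s − u)
∂cost/∂X = −Kᵀ(Y − KX) + (γ/n) β_{1:p} (s − u)ᵀ Y
```

are validated against central finite differences (relative error
< 1e-5).  Steps are sequential within a sweep — `X` first, then `β` at
the updated `X`.  After each `X` step, entries ≤ 0 are replaced by the
projection floor 1e-9.  `β` starts at zero (probability ½ for every
spectrum — a symmetric start); the Flda family's `β` starts strictly
positive uniform, like `K` and `X`.  The logistic softplus is computed
via `logaddexp`, so the cost stays finite for |z| of 1e3 and far beyond.

ADADELTA is not monotone; the suite asserts a net cost decrease over the
first sweeps rather than per-step descent.  Because early ADADELTA steps
are small (≈ √ε per entry), the supervision term needs a sizable weight
and enough sweeps to engage: the shipped Flog preset uses γ = 3000 and
1000 sweeps with a loose stopping tolerance (1e-10), which on the
synthetic benchmark reliably moves the factorization into the
discriminative subspace.  Smaller γ (≲ 300) or ~300 sweeps leave the fit
stuck near the unsupervised solution on some initializations.

### Initialization, stopping, determinism

`K`, `X` (and `W`) initialize uniform on (0,1], scaled so `mean(KX)`
matches `mean(Y)`; `p > min(n,m)` triggers a warning, not an error.
Fitting stops when the relative cost change between sweeps drops below
`rel_tol` (default 1e-6) or after `max_iter` sweeps (default 500).  A
non-finite cost raises a divergence error.  All randomness flows through
`numpy` Generators seeded from the configuration, so identical configs
give bitwise-identical fits.

## Classification

* **Feature map** — `F = YXᵀ` (linear, non-negative).
* **Fisher LDA** — `w = S_w⁻¹(m₁−m₀)` with pooled within-class scatter
  (ridge 1e-8) and equal priors (balanced accuracy is the target metric,
  so empirical priors would misalign the objective); the threshold is the
  midpoint of the projected class means.  Coinciding class means yield a
  majority-class fallback rule.
* **Logistic regression** — unregularized maximum likelihood with
  intercept, by Newton/IRLS (Hessian ridge 1e-10, at most 200
  iterations; separable data simply stops at the cap).  Both classifiers
  are checked against scikit-learn's implementations on random fixtures.
* **Integrated classifiers** — reuse the supervised NMF's `β`.  The Flda
  family scores `YXᵀβ` and picks the threshold maximizing training
  balanced accuracy; since the metric is piecewise constant in the
  threshold, the exact optimum is found among midpoints of consecutive
  sorted unique scores plus ±∞ sentinels, ties broken toward the smallest
  threshold (verified against exhaustive search).  Flog thresholds
  `σ([1|YXᵀ]β)` at 0.5.
* **Diagnostics** — the discriminatory pattern `x_β = Xᵀβ̂` (intercept
  dropped), and the *active-weight* count: entries with |β_k| above 10 %
  of the maximum |β| are active.  The Flog intercept is excluded from
  both the maximum and the count — it shifts the decision boundary rather
  than weighting a pseudo spectrum.

## Cross-validation

Leave-one-group-out on the grouping variable (one fold per TMA): each
fold fits the *entire* pipeline — NMF and classifier — on the other
groups and predicts the held-out group, so both the feature extraction
and the classification step are covered by the CV and the score reflects
robustness to between-batch variation.  Per-fold balanced accuracies and
the pooled balanced accuracy of the union of fold predictions are both
reported (a test group that happens to be single-class gets a NaN
per-fold entry; the pooled score is unaffected).  No within-group
splitting is offered — it would break the batch-robustness semantics.

## Synthetic data

The generator emulates the structure the supervised models target.  Each
pattern is a sum of 3–8 Gaussian peaks (width 2 channels) at random
positions, normalized to unit l2 norm; discriminative patterns are scaled
by `effect_ratio`.  Spectrum i in group g with label c is

```
y_i = b_g (Σ_k c_ik d_k + c Σ_j e_ij s_j) + noise,
```

with mixing coefficients `c_ik, e_ij ~ U(0.5, 1.5)`, a per-group batch
factor `b_g = exp(N(0, batch_sd²))` and Gaussian channel noise (the sum
truncated at zero).  Labels are Bernoulli(`class_balance`).

The "paper-shaped" preset — 8 groups × 100 spectra, m = 500, 8 dominant
and 2 discriminative patterns, `effect_ratio = 0.15`, `batch_sd = 0.15`,
`noise_sd = 0.01` — is a desk-scale stand-in for a TMA tumor-typing
dataset with two roughly balanced classes.  `batch_sd = 0.15` makes
group-level CV meaningfully harder than random splitting (group totals
differ by ~±15 %); `noise_sd = 0.01` puts per-channel noise at roughly a
fifth of the discriminative peak amplitude, so the class signal is
recoverable but well below the dominant structure.

What the generator does *not* emulate: isotope envelopes, m/z jitter,
baseline drift, peak-shape variation, spatial autocorrelation, and
label noise.  Passing recovery tests on this generator therefore shows
that the algorithms extract weak planted linear structure under batch
effects — not that they handle raw-spectrum artifacts, which are assumed
to be removed by upstream preprocessing (only total-ion-count
normalization is provided here).

## Validation experiments and problem sizes

The acceptance suite runs entirely on synthetic or random data, at sizes
chosen to finish in minutes on one CPU:

* **Recovery** — paper-shaped preset, 10 generator seeds: median pooled
  CV balanced accuracy of Flog_int at p = 5 must reach 0.9 and exceed
  FR_lda at equal p by 0.03.  Measured values are far clearer than the
  bounds (≈ 0.95+ vs ≈ 0.54).
* **Null calibration** — 20 seeds × all 13 schemes on a 4-group × 30
  spectra, m = 120 dataset with permuted labels; at least 95 % of pooled
  balanced accuracies must lie in [0.4, 0.6].  Iteration caps are reduced
  (300 Flog / 150 others) — chance level does not require convergence.
* **Active-weight concentration** — 4 groups × 100 spectra, m = 200,
  6 dominant + 2 discriminative patterns at `effect_ratio = 0.10`,
  5 fit seeds, p ∈ {5, 10, 20, 40}.  The subtle-signal regime is
  essential here: when the discriminative amplitude approaches the
  dominant one, *every* pseudo spectrum absorbs class signal and the
  active count tracks p for all models; at low amplitude the supervised
  model concentrates the signal in a few rows (median count range ≤ 2
  across the grid) while FR_log's median count keeps growing.  This
  count is intrinsically seed-noisy — individual fits can deviate by
  several weights, which is why medians over seeds are compared.
* **Orthogonality effect** — 20 random 30×40 matrices, p = 4: FRO with
  σ₁ = σ₂ = 5 reduces the off-diagonal Frobenius mass of the
  row-normalized Gram matrix `XXᵀ` by ≥ 50 % (median) relative to FR.
* **Numerical checks** — cost monotonicity (100 random instances,
  tolerance 1e-8 × initial cost), fixed-point invariance (10 × eps_div),
  gradient finite-difference error (< 1e-5), threshold-oracle agreement
  (1000 instances).

## Hyperparameter presets

The shipped per-model presets (see `supnmf/presets.py`) assume intensity
scales of order one:

| model | preset | rationale |
|---|---|---|
| FR/FRO | λ = μ = ν = 0.01, rescale on (FR) | mild sparsity/conditioning without distorting the fit |
| FO/FRO | σ₁ = σ₂ = 1 | orthogonality pressure comparable to the data term on desk-scale problems |
| Flda family | γ = 10 | supervision term comparable to the per-spectrum residual; multiplicative β rule converges fast |
| Flog | γ = 3000, 1000 sweeps, tol 1e-10 | ADADELTA needs both weight and sweeps for the logistic term to steer X (see above) |

These are starting points, not tuned optima; applications with different
intensity scales (e.g. TIC-normalized spectra, where intensities are
O(1/m)) should rescale γ accordingly, since the Frobenius term scales
with the squared intensities while the logistic term does not.

## Known limitations

* Binary classification only; the multi-class extension is out of scope.
* The MM sweeps converge linearly at best; tight factorizations can need
  thousands of sweeps (the multiplicative updates cannot set entries
  exactly to zero either — they approach zero geometrically).
* Flog's outcome depends on the interplay of γ, ε and the sweep budget;
  no automatic hyperparameter selection is provided.
* The active-weight count is a noisy diagnostic; compare medians over
  several fit seeds, not single runs.
* The imzML adapter bins by nearest m/z neighbor onto a fixed axis; no
  resampling or peak alignment is performed.
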