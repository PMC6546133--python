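# supnmf — supervised NMF for mass-spectrometry-imaging classification

`supnmf` implements supervised non-negative matrix factorization (NMF) for
binary tissue classification from mass-spectrometry-imaging (MSI) spectra,
together with the unsupervised baselines, NMF-based classifiers,
group-level cross-validation and diagnostics needed to compare them.

It is aimed at computational proteomics / MSI researchers who want to
extract *class-discriminative* spectral patterns from a spectra matrix —
patterns that are often far weaker than the dominant spectral components
and therefore get lost in a plain low-rank decomposition.

## The model

Given a non-negative spectra matrix `Y` (n spectra × m channels), NMF seeks
`K ≥ 0` (n × p) and `X ≥ 0` (p × m) with `Y ≈ K X`; the rows of `X` are
*pseudo spectra* and the columns of `K` their sample loadings.  The
regularized unsupervised models are

```
FR:   min ½‖Y − KX‖²_F + λ‖X‖₁ + (μ/2)‖K‖²_F + (ν/2)‖X‖²_F
FRO:  FR + (σ₁/2)‖I − XWᵀ‖²_F + (σ₂/2)‖W − X‖²_F     (W ≥ 0 auxiliary)
FO:   FRO with λ = μ = ν = 0
```

Supervision couples the factorization to binary labels `u ∈ {0,1}ⁿ`
through the feature map `f = y Xᵀ`:

```
Flda:  min ½‖Y − KX‖²_F + (γ/2)‖u − YXᵀβ‖²,   β ≥ 0
Flog:  min ½‖Y − KX‖²_F + (γ/n) Σᵢ [log(1 + exp(zᵢ)) − uᵢ zᵢ],
       z = [1 | YXᵀ] β,   β free sign
```

with regularized variants FRlda / FROlda.  The Flda family is solved by
multiplicative majorize-minimization sweeps (cost provably non-increasing,
non-negativity automatic); Flog alternates the multiplicative `K` rule
with full-batch ADADELTA gradient steps on `X` (positively projected) and
`β`.

Classifiers come in two flavors: *integrated* (`*_int`) reuse the NMF's
own `β` — thresholding `YXᵀβ` at the balanced-accuracy-optimal cut for the
Flda family, or the logistic probability at 0.5 for Flog — while
*optimized* (`*_lda`, `*_log`) refit a Fisher LDA or logistic regression
on the features `YXᵀ`.  Evaluation is leave-one-group-out cross-validation
(one fold per TMA/measurement batch) scored by balanced accuracy, the mean
of the two class sensitivities.

## Worked example

Simulate a synthetic MSI-like dataset (8 groups × 100 spectra, 500
channels, 8 dominant patterns shared by everyone plus 2 weak
class-discriminative patterns at 15 % relative amplitude, multiplicative
per-group batch effects), then cross-validate a supervised and an
unsupervised scheme:

```
$ supnmf simulate --preset paper-shaped --seed 1 --out demo/data
wrote 800 x 500 dataset to demo/data

$ supnmf cv --dataset demo/data/dataset.h5 --scheme Flog_int --p 5 --seed 1 --out demo/cv_flog
Flog_int p=5: pooled balanced accuracy 0.997 (folds 0.989-1.000)

$ supnmf cv --dataset demo/data/dataset.h5 --scheme FR_lda --p 5 --max-iter 300 --seed 1 --out demo/cv_fr
FR_lda p=5: pooled balanced accuracy 0.536 (folds 0.462-0.588)
```

With only 5 pseudo spectra the supervised logistic model recovers the weak
class signal almost perfectly on held-out groups (pooled balanced accuracy
0.997), while the unsupervised FR decomposition spends its 5 components on
the dominant shared patterns and the downstream LDA barely beats chance
(0.536).  Each run writes a per-fold table (`cv_folds.csv`), a summary
(`cv_summary.json`) and a manifest that makes the run reproducible.

The same pipeline is available as a library:

```python
from supnmf import SynthSpec, generate_dataset, run_cv
from supnmf.presets import preset_config

ds, truth = generate_dataset(SynthSpec(seed=1))
cv = run_cv(ds, "Flog_int", preset_config("Flog", p=5, seed=1))
print(cv.pooled_balanced_accuracy)      # 0.997
```

`supnmf diagnose` reports the number of *active* regression weights
(entries above 10 % of the maximum |β|) as the feature count grows — for
supervised Flog this stays near the number of planted discriminative
patterns, whereas for the two-step FR + logistic pipeline it keeps growing
— and exports the discriminatory pattern `x_β = Xᵀβ̂`.

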