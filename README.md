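# eegsev

Continuous prediction of clinical anxiety severity from resting-state EEG
functional connectivity, for researchers in computational psychiatry and
EEG biomarker development.

Severity assessment for generalized anxiety disorder still rests on
interviews and rating scales; this package operationalizes an objective
alternative: band-limited **Phase Lag Index (PLI)** connectivity features
feed a **convolutional gated-MLP (Conv_gMLP)** regressor that predicts the
HAM-A total score (0–56), and **Grad-RAM** gradient attribution identifies
which electrode pairs, regions, and frequency bands carry the prediction.
Because clinical EEG datasets of this kind are not public, the package
includes a first-class synthetic cohort generator with planted,
severity-linked phase coupling, so the entire pipeline is verifiable
against known ground truth.

## Method at a glance

For channels i, j with instantaneous phases Φ from the Hilbert transform
of band-limited epochs (theta 4–8, alpha1 8–10, alpha2 10–13, beta 13–30
Hz):

    PLI_ij = | ⟨ sign( sin(Φ_i(t) − Φ_j(t)) ) ⟩ |  ∈ [0, 1]

With 16 montage channels this yields 4 × C(16,2) = 480 features per
epoch.  The regressor lifts the 1×480 vector to d_channel×480 with a
kernel-1 convolution, passes it through N gMLP blocks — each a channel
projection U, GELU, a **Spatial Gating Unit** `u ⊗ (Wᵀv + b)` with the
480×480 spatial map W initialized near zero and b at one, and a channel
projection V with a residual shortcut — then average-pools and maps to a
scalar score.  Training minimizes MSE; evaluation is MAE under repeated
(3×) 5-fold cross-validation with subject-grouped folds.  Attribution
differentiates y_e = 1/((ŷ−y)² + 1e-9) with respect to the convolution
output and aggregates the rectified channel-weighted map over electrodes,
lobes, and bands.

The deep models run on a small numpy autodiff engine shipped with the
package (no GPU framework required); LightGBM/XGBoost comparators and a
self-contained Tree-structured Parzen Estimator for hyperparameter search
are included.

## Worked example

```python
from eegsev import (CohortSpec, generate_cohort, CVPlan, ModelSpec,
                    ConvGMLP, run_cv)
from eegsev.evaluation import features_from_recordings

# 12 synthetic subjects, 2 min each; beta fronto-temporal coupling
# strength rises linearly with the severity label
cohort = generate_cohort(CohortSpec(n_subjects=12, duration_s=120, seed=11))
X, y, groups = features_from_recordings(cohort, window_s=10.0)
print(X.shape)                     # one 480-vector per subject

spec = ModelSpec(d_channel=16, num_layers=2, d_ffn=64, norm="none",
                 learning_rate=1e-3, max_epochs=60, seed=0)
res = run_cv(X, y, lambda: ConvGMLP(spec), CVPlan(n_repeats=1, seed=0),
             groups=groups)
print(f"MAE {res.mean:.2f} ± {res.sd:.2f}")
```

Output:

```
(12, 480)
MAE 5.17 ± 2.35
```

Twelve subjects is enough to see the model beat chance (the train-mean
predictor sits near 14 on uniform labels) but not to saturate; at the
package's default study size (120 subjects, 10 minutes each) the same
pipeline reaches a test MAE near 1.5 — see below.  A command-line
interface wraps the same stages:

```
eegsev simulate --n-subjects 12 --seed 1 --out cohort
eegsev features cohort/manifest.csv --window-s 10 --average-epochs --out features
eegsev evaluate cohort/manifest.csv --model conv_gmlp --windows 10 --out results
eegsev train features --model conv_gmlp --norm none --out run
eegsev explain --checkpoint run --features features --out attribution
```

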