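# glnet

Tabular deep learning for student depression risk, with Shapley-value
factor attribution.

`glnet` is for researchers in psychiatric epidemiology and educational
health who want to (a) predict depression status from mixed-type survey
factors — demographic (age, gender, city), academic (CGPA, study
satisfaction, academic pressure), lifestyle (sleep duration, dietary
habits, work/study hours) and history (suicidal ideation, family history,
financial stress) — and (b) quantify how much each factor, and each
*level* of each categorical factor, contributes to every prediction,
globally and within subgroups (by gender, by educational level).

## The model

The classifier is a U-shaped residual network over the encoded survey
columns.  A linear embedding lifts the `d` encoded factors to 128 deep
features; four **global-and-local blocks** follow, each composing a
selective state-space (Mamba-style) scan along the feature sequence
(global context, linear time) with a kernel-3 1-D convolution (local
context), a leaky-ReLU, a fully connected resize and batch normalization:

    x_fc = f_fc(x)                             # d -> 128
    GLB(x) = BN(f_fc(β(f_conv(f_mamba(x)))))   # width x2 (up) or /2 (down)
    y = GLB_down(GLB_down(GLB_up(x_glb1)) + x_glb1),  x_glb1 = GLB_up(x_fc)

i.e. 128 → 256 → 512 → 256 → 128 → 2, with a residual joining the two
256-wide stages.  The selective scan updates a hidden state
`h_t = exp(Δ_t A) h_{t−1} + Δ_t B_t u_t`, `y_t = C_t·h_t + D u_t` with
input-dependent `Δ_t, B_t, C_t` (zero-order-hold discretization, `A < 0`
for stability).  Training uses inverse-frequency **weighted cross-entropy**
(`w_c = n/(2 n_c)`) against the ~59/41 class imbalance, 10% factor dropout
and 10% uniform data-shift augmentation, and the Ranger optimizer
(RAdam + Lookahead) at lr 1e-4 with cosine decay, batch 256.

Evaluation reports AUC, accuracy, sensitivity, specificity and F1 with
seeded percentile-bootstrap 95% CIs.  Attribution uses Shapley values
φ_i with the interventional value function (coalition complements imputed
from a training background sample): exact enumeration up to 15 columns,
antithetic permutation sampling beyond, positive φ pushing toward the
depressed class.  Everything — network, gradients, optimizer, bootstrap,
Shapley machinery — runs on numpy (the scan loops are numba-compiled);
gradients are hand-derived and finite-difference checked.

A synthetic survey generator with a known logistic ground truth (59%
prevalence, realistic effect magnitudes, planted CGPA×gender and
diet×degree interactions) makes the whole pipeline testable end to end
without any external data.

## Worked example

`examples/02_train_and_evaluate.py` trains a reduced-width network on
2,000 synthetic records and prints:

```
epochs run: 60  best epoch: 56
final train loss: 0.527
AUC   78.0% (95% CI 73.1-82.7)
ACC   72.2% (95% CI 67.5-76.9)
SEN   71.2% (95% CI 65.3-76.9)
SPE   73.7% (95% CI 66.8-80.3)
F1    74.9% (95% CI 70.3-79.3)
```

AUC far above the 50% of an uninformative classifier shows the network
recovers the planted risk structure even at demo scale (the full-size
study at n = 5,000 reaches AUC ≈ 0.93 on the held-out test set).
`examples/03_explain_factors.py` attributes a small model exactly and
prints the factor ranking:

```
estimator: exact   base value: 0.502
efficiency check, row 0: base + sum(phi) = 0.8222 vs prediction 0.8222

                          column  mean_abs_phi  phi_value_slope  rank
               academic_pressure      0.134729         0.160294     1
           suicidal_thoughts=Yes      0.107877         0.129440     2
              study_satisfaction      0.084559        -0.091034     3
sleep_duration=Less than 5 hours      0.054292         0.045788     4
```

Base value plus the per-factor φ reproduces the prediction exactly
(efficiency axiom); risk factors carry positive φ-vs-value slopes,
protective ones negative.  The other examples cover encoding/splitting
(`01`) and the end-to-end pipeline with subgroup contrasts (`04`).

## Command line

```bash
glnet simulate --n 5000 --seed 1 --out students.csv   # synthetic survey
glnet run-all config.yaml       # encode -> train -> evaluate -> explain
glnet subgroup runs/my-run --filter gender=Female
```

A run directory contains the schema, split, standardizer, checkpoint,
metrics report, attribution tables and subgroup summaries, plus a
manifest of content hashes; rerunning the same config and seed reproduces
every artifact byte for byte.

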