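"""Train the classifier on synthetic data and report test metrics.

Uses a reduced width (embed_dim=32) and a faster learning rate so the
example finishes in about a minute on 2,000 records; the full-size study
configuration (embed_dim=128, lr 1e-4, n >= 5,000) follows the same
recipe: weighted cross-entropy, 10% factor dropout, 10% data shift,
Ranger with cosine decay, batch 256, early stopping on validation loss.
"""

from glnet import (
    GLNetConfig,
    TrainConfig,
    apply_standardizer,
    encode_dataset,
    evaluate,
    fit_standardizer,
    split_dataset,
    train_model,
)
from glnet.synthetic import default_sdd_like_spec, generate

spec = default_sdd_like_spec()
df, _ = generate(spec, n=2000, seed=1)
ds = encode_dataset(df, spec.schema)
split = split_dataset(ds, seed=1)
ds = apply_standardizer(ds, fit_standardizer(ds, split.train))

model, history = train_model(
    ds, split,
    GLNetConfig(input_dim=len(ds.columns), embed_dim=32, ssm_state_dim=8, seed=1),
    TrainConfig(epochs=60, lr=1e-3, early_stop_patience=60, seed=1),
)
print(f"epochs run: {len(history.train_loss)}  best epoch: {history.best_epoch}")
print(f"final train loss: {history.train_loss[-1]:.3f}")

report = evaluate(model, ds, split.test, replicates=500, seed=1)
for name in ("auc", "acc", "sen", "spe", "f1"):
    lo, hi = report.ci[name]
    print(f"{name.upper():4s} {100 * report.point[name]:5.1f}% "
          f"(95% CI {100 * lo:.1f}-{100 * hi:.1f})")
print("AUC well above 50% shows the network recovers the planted risk "
      "structure; the bootstrap CIs quantify test-set uncertainty.")
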