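"""Select the hidden-layer width by stratified 5-fold cross-validation.

For each candidate width the network is initialized, trained and scored on
five folds; the selected width maximizes the mean-to-deviation ratio of the
fold accuracies, preferring stable as well as accurate configurations.
"""

from ckainit import SyntheticSpec, TrainConfig, generate, tune_hidden_size

spec = SyntheticSpec(
    group_sizes={"CV": 10, "SV": 8, "SA": 10, "TA": 10, "TS": 10},
    n_per_class=(80, 80, 80),
    informative_features=tuple(range(10, 16)),
    effect_size=2.0,
    seed=5,
)
ds = generate(spec)

result = tune_hidden_size(
    ds.X, ds.t, strategy="cka", grid=[4, 8, 14, 20], seed=5,
    train_cfg=TrainConfig(epochs=80, seed=5, early_stop_patience=10),
)

print("width  fold accuracies                      mean/sd ratio")
for m1 in result.grid:
    accs = ", ".join(f"{a:.2f}" for a in result.fold_accuracies[m1])
    print(f"  {m1:3d}  [{accs}]  {result.criterion[m1]:8.2f}")
print(f"\nselected hidden width: {result.selected_m1}")

# A high ratio needs both a high mean and low variability across folds;
# ties resolve to the smallest width, the more parsimonious model.
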