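# ckainit

Supervised pretraining of shallow neural classifiers by **centered kernel
alignment (CKA)**, with PCA and autoencoder baselines, feature-relevance
analysis and multiclass evaluation. The package targets tabular
morphometric data of the kind used in computer-aided dementia diagnosis —
a few hundred per-structure brain measurements per subject and three
diagnostic groups (normal controls, mild cognitive impairment, Alzheimer's
disease) — but works on any numeric feature table with integer class
labels.

## The method

A projection matrix `W ∈ R^{m1×D}` (`m1 ≤ D`) defines a Mahalanobis metric
`d_W(x_i,x_j)² = ‖Wx_i − Wx_j‖²` on the feature space. Passing these
distances through a Gaussian kernel gives a sample-similarity matrix
`K_W`; class labels give the binary kernel `B` with `b_ij = δ(t_i − t_j)`.
The projection is learned by maximizing the centered kernel alignment

```
ρ(K_W, B) = ⟨HK_WH, HBH⟩_F / (‖HK_WH‖_F ‖HBH‖_F),   H = I − N⁻¹11ᵀ,
```

via scale-normalized gradient ascent with backtracking (the accepted-ρ
trace is strictly increasing). `W*` then initializes the first layer of a
`D → m1 → C` sigmoid/softmax network trained by minibatch SGD; biases and
the output layer are randomly initialized. The column energies of `W*`,
`ϱ_d = (1/m1)Σ_u W_ud²`, rank input features by their contribution to the
learned embedding. Classifiers are compared with accuracy `α`, per-class
recall `τ^c` and one-vs-rest trapezoidal AUC `β^c` (class-size-weighted
mean `β`).

See `docs/methods.md` for the model details, the analytic gradient, the
synthetic-cohort generator and the package's design choices.

## Worked example

```python
import numpy as np
from ckainit import (SyntheticSpec, generate, fit_scaler,
                     fit_cka_projection, OptimizerConfig,
                     group_relevance, top_k_features)
from ckainit.simulate import group_index_map

spec = SyntheticSpec(n_per_class=(200, 200, 200), seed=0)
ds = generate(spec)                       # 600 x 324 morphometric-like table
Xs = fit_scaler(ds.X).transform(ds.X)
model = fit_cka_projection(Xs, ds.t, m1=14, cfg=OptimizerConfig(seed=0))
print(f"rho: {model.trace[0][1]:.4f} -> {model.rho:.4f}")
print(group_relevance(model.relevance, group_index_map(spec.group_sizes)))
```

prints (exactly, for this seed):

```
rho: 0.2426 -> 0.8233
{'CV': 0.080, 'SV': 0.274, 'SA': 0.082, 'TA': 0.075, 'TS': 0.083}
```

The alignment between the projected-feature kernel and the label kernel
rises from 0.24 at the PCA initialization to 0.82, and the relevance
concentrates on the SV (subcortical volume) block — the block that carries
the class signal in the generator — with 9 of the 10 top-ranked features
truly informative. The scripts in `examples/` walk through each
capability (simulation, projection fitting, training and evaluation,
hidden-size tuning, initialization comparison); each prints its numbers
with a note on what they mean. A thin CLI offers the same pipeline from a
shell:

```bash
ckainit simulate --seed 1 --n-per-class 200 200 200 --out data.csv
ckainit split data.csv --seed 1 --out-dir splits/
ckainit fit-projection splits/train.csv --m1 14 --out-dir proj/
ckainit train splits/train.csv --projection proj/projection.json --out-dir net/
ckainit evaluate net/network.json splits/test.csv --out-dir report/
```

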