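"""Learn the alignment-maximizing projection and read off feature relevance.

Fits the linear map W that maximizes the centered kernel alignment between
the Gaussian kernel of projected features and the class-label kernel, then
shows the optimization trace and which feature blocks the projection relies
on.
"""

import numpy as np

from ckainit import (
    OptimizerConfig,
    SyntheticSpec,
    fit_cka_projection,
    fit_scaler,
    generate,
    group_relevance,
    top_k_features,
)
from ckainit.simulate import group_index_map

spec = SyntheticSpec(n_per_class=(200, 200, 200), seed=0)
ds = generate(spec)
Xs = fit_scaler(ds.X).transform(ds.X)

model = fit_cka_projection(Xs, ds.t, m1=14, cfg=OptimizerConfig(seed=0))

print(f"alignment rho: {model.trace[0][1]:.4f} (init) -> {model.rho:.4f} "
      f"after {len(model.trace) - 1} accepted steps")

groups = group_index_map(spec.group_sizes)
print("\nmean relevance per feature block (max-normalized):")
for name, value in group_relevance(model.relevance, groups).items():
    print(f"  {name}: {value:.3f}")

top = top_k_features(model.relevance, 10)
hits = sum(1 for i in top if i in set(spec.resolved_informative()))
print(f"\ntop-10 relevant features, {hits}/10 in the truly informative set:")
print(" ", [ds.feature_names[i] for i in top])

# The SV (subcortical volume) block, which carries the class signal by
# construction, dominates the relevance; the trace is strictly increasing
# because the ascent only accepts uphill steps.
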