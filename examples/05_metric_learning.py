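"""Learn discriminative projections (RLDA and LDP) and compare distances.

Two 10-dimensional Gaussian classes differ only along axis 0. RLDA finds
the direction maximizing between-class over (ridge-regularized)
within-class scatter; LDP finds it from the covariances of within- vs
between-class sample differences. Both should recover axis 0 and enlarge
the between/within distance contrast.
"""

import numpy as np

from lesionbow.metrics import (
    fit_ldp,
    fit_rlda,
    make_distance_spec,
    pairwise_distances,
)

rng = np.random.default_rng(0)
n, d = 150, 10
a = rng.normal(0.0, 1.0, (n, d))
b = rng.normal(0.0, 1.0, (n, d))
b[:, 0] += 6.0  # 6-sigma separation on the first axis only
X = np.vstack([a, b])
y = np.array(["a"] * n + ["b"] * n)

rlda = fit_rlda(X, y, alpha=0.001)
Z = rlda.transform(X)[:, 0]
sep = abs(Z[:n].mean() - Z[n:].mean()) / np.sqrt(0.5 * (Z[:n].var() + Z[n:].var()))
print(f"RLDA: 1-D projection separates the class means by {sep:.1f} pooled sds")

ldp = fit_ldp(X, y, out_dim=3, seed=0)
w = ldp.matrix[:, 0]
print(f"LDP: |cosine| of leading direction with the true axis = "
      f"{abs(w[0]) / np.linalg.norm(w):.4f}")

for method in ("L2", "RLDA", "LDP"):
    spec = make_distance_spec(method, X, y, seed=0)
    D = pairwise_distances(spec, X, X)
    same = (y[:, None] == y[None, :]) & ~np.eye(len(y), dtype=bool)
    ratio = D[~same & ~np.eye(len(y), dtype=bool)].mean() / D[same].mean()
    print(f"{method:>4}: between-class / within-class mean distance = {ratio:.2f}")
print("\nRLDA's 1-D projection stretches the between/within contrast far beyond")
print("raw L2; LDP recovers the right axis but keeps 3 dimensions here, so its")
print("distance contrast stays near L2 until the extra dimensions are trimmed.")
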