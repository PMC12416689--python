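"""Rank features by mutual information with the class label.

MI is estimated from a joint histogram (equal-width bins for the feature,
labels used as-is) and reported in nats; a feature that mirrors the label
scores ln 2 ~ 0.693, an independent feature scores ~ 0.
"""

import numpy as np

from acgsfe import mutual_information, rank_features_by_mi

rng = np.random.default_rng(0)
n = 300
y = rng.integers(0, 2, n)

X = rng.standard_normal((n, 6))
X[:, 0] = y                                  # perfect copy of the label
X[:, 1] = y + 0.5 * rng.standard_normal(n)   # strong signal
X[:, 2] = y + 2.0 * rng.standard_normal(n)   # weak signal
# columns 3-5 are pure noise

for j in range(6):
    print(f"feature {j}: MI = {mutual_information(X[:, j], y, bins=10):.4f} nats")

order = rank_features_by_mi(np.arange(6), X, y, bins=10)
print(f"\nMI ranking (best first): {order.tolist()}")
print("The label copy tops the ranking at ~ln 2; noise features trail with "
      "small positive values (histogram estimation bias).")
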