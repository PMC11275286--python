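"""Compare two correlated classifiers' AUCs with the DeLong test.

Builds two score vectors over the same 200-sample labelled test set — one
clearly informative, one weaker and correlated with it — computes the
tie-aware Mann-Whitney AUC of each, and tests whether the AUC difference is
statistically significant. A p-value below 0.05 indicates the models'
discrimination genuinely differs on this test set.
"""

import numpy as np

from vaefusion.eval_stats import auc, delong_test

rng = np.random.default_rng(0)
labels = np.repeat([0, 1], 100)
shared = rng.normal(size=200)
strong = 1.2 * labels + shared + 0.5 * rng.normal(size=200)
weak = 0.4 * labels + shared + 0.5 * rng.normal(size=200)

roc_strong = auc(strong, labels)
roc_weak = auc(weak, labels)
result = delong_test(roc_strong, roc_weak)
print(f"AUC strong model: {roc_strong.auc:.3f}")
print(f"AUC weak model:   {roc_weak.auc:.3f}")
print(f"DeLong z = {result.z_stat:.2f}, two-sided p = {result.p_value:.4g}")
print("p < 0.05 -> the AUC difference is significant on this paired test set"
      if result.p_value < 0.05 else
      "p >= 0.05 -> no significant difference detected")
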