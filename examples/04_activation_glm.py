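"""Per-channel GLM activation and group contrasts with FDR correction.

Condition regressors are HRF-convolved boxcars (rest is the unmodeled
baseline). Per participant and channel the HbO series yields one beta per
condition; group one-sample t-tests per channel test each condition
against rest and private against inner, Benjamini-Hochberg corrected
across the 40 channels.
"""

import numpy as np

from fnirspeech.activation import ActivationBetas, activation_contrasts

rng = np.random.default_rng(0)
n, C = 16, 40

# betas as they would come out of the per-participant GLM stage: noise
# plus a planted outer-speech activation in three "motor" channels
beta = rng.normal(0, 0.03, (n, C, 3))
beta[:, [6, 7, 8], 2] += 0.05  # strong outer-speech effect, d ~ 1.7

res = activation_contrasts(
    ActivationBetas(beta, np.ones((n, C)), list(range(1, C + 1))),
    groups=["high"] * n,
)
tab = res["high/outer_gt_rest"]
sig = tab[tab.significant]
print("outer speech > rest, FDR q = 0.05:")
for _, row in sig.iterrows():
    print(f"  CH {int(row.channel):2d}: t({int(row.df)}) = {row.t:5.2f}, "
          f"corrected p = {row.p_fdr:.4f}")
print(f"{len(sig)} of {C} channels significant "
      f"(planted channels were 7, 8, 9)")

null_tab = res["high/private_gt_inner"]
print(f"private > inner (no planted difference): "
      f"{int(null_tab.significant.sum())} significant channels")
# A clean run detects the planted motor channels and nothing in the null
# contrast — the FDR correction holds false positives near zero.
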