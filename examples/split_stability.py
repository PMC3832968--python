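"""Stability of MAXFJ vs AFJ p-values under repeated random stage splits.

One synthetic cohort with a recessive effect is split into stage 1/stage 2
at pi=0.3 over and over; each split yields a joint p-value for both
analyses.  The scale-free spread (IQR / median of -log10 p) measures how
sensitive each analysis is to the arbitrary split.
"""

from maxfj import EffectSpec
from maxfj.simulate import SimConfig, gen_dataset, split_stability

cfg = SimConfig(n=2000, pi=0.3, maf=0.3, effect=EffectSpec("REC", 0.4), seed=1)
data = gen_dataset(cfg)
res = split_stability(data, pi=0.3, reps=200, seed=7)

q = res[["neglog10_p_maxfj", "neglog10_p_afj"]].quantile([0.25, 0.5, 0.75])
print(q.round(3).to_string())
for stat in ("maxfj", "afj"):
    col = f"neglog10_p_{stat}"
    rel = (q.loc[0.75, col] - q.loc[0.25, col]) / q.loc[0.5, col]
    print(f"{stat.upper():6s} relative spread of -log10 p: {rel:.3f}")
# MAXFJ sits at a stronger evidence level AND wobbles less relative to that
# level: the robust statistic is less sensitive to which subjects happened
# to land in stage 1.
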