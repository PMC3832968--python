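"""Power of the robust joint test (MAXFJ) versus the additive-only test (AFJ).

Under a recessive truth the additive statistic is badly mis-specified and
AFJ collapses, while the maximum over the three model statistics stays
powerful; under an additive truth AFJ is (by construction) slightly ahead.
"""

from maxfj import EffectSpec, PowerRequest, analytic_power

design = dict(n=2000, pi=0.4, maf=0.3, gamma=2e-4, alpha=0.05, m=5e5)

print("true model  beta1   AFJ power   MAXFJ power")
for model, beta1 in (("REC", 0.5), ("ADD", 0.3), ("DOM", 0.4)):
    row = []
    for stat in ("AFJ", "MAXFJ"):
        req = PowerRequest(
            effect=EffectSpec(model=model, beta1=beta1), statistic=stat, **design
        )
        row.append(analytic_power(req).power)
    print(f"{model:9s}  {beta1:5.2f}   {row[0]:9.3f}   {row[1]:11.3f}")
# The recessive row is the headline: the additive-only analysis retains
# ~0.09 power where the robust maximum keeps ~0.52.
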