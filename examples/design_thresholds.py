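"""Calibrate the two-stage cut-offs for one GWAS design.

A study of n subjects screens every marker on a fraction pi at stage 1;
markers with F1MAX above u1 (screen level gamma) are carried forward, and a
combined-data FJMAX above uJ is declared genome-wide significant at the
Bonferroni per-marker level alpha/m.  Both cut-offs are solved from the
asymptotic null of the six Z statistics with chi-square residual mixing.
"""

from maxfj import design_thresholds, hwe_expected_counts, prob_joint_exceeds

counts = hwe_expected_counts(n=2000, pi=0.4, maf=0.3)
thr = design_thresholds(gamma=2e-4, alpha_per_snp=1e-7, counts=counts)

print(f"stage-1 cutoff u1 = {thr.u1:.4f}  (Pr_H0(F1MAX > u1) = {thr.achieved_gamma:.3e})")
print(f"joint   cutoff uJ = {thr.uJ:.4f}  (joint null rate = {thr.achieved_alpha:.3e})")
print(
    "check: joint exceedance at (u1, uJ) =",
    f"{prob_joint_exceeds(thr.u1, thr.uJ, counts):.3e}",
)
# u1 is on the F(2-ish) scale: ~15.8 corresponds to a stage-1 p of 2e-4 for
# the maximum of the three model F statistics; uJ ~ 28 is the combined-data
# bar a selected marker must clear for genome-wide significance at 1e-7.
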