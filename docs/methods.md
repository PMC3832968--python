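# Methods

## Model and statistics

Subjects carry a biallelic marker with minor/high-risk allele G; genotype
g ∈ {gg, Gg, GG} is coded 0/1/2. The trait follows the one-way normal
model `y = β0 + code(g)·β1 + ε`, `ε ~ N(0, σ²)`, where `code` is the true
genetic model: REC = (0,0,1), ADD = (0,1,2), DOM = (0,1,1). A two-stage
design genotypes all markers on n1 = nπ subjects (stage 1) and carries
markers passing a screen to the remaining n2 = n(1−π).

For each candidate model k the test statistic is a modified F ratio: the
numerator is the squared contrast Z_k of genotype-group phenotype means
(normalised so Var(Z_k) = σ² under H0), and the denominator is the residual
mean square of the *saturated* group model — RSS1 over the three stage-1
genotype groups (df n1−3), or RSSJ over all six stage-by-genotype cells
(df n−6) for the combined-data joint statistic. Sharing the saturated
denominator across the three models is what makes the trivariate and
six-variate distribution theory tractable. The robust statistics are
F1MAX = max(F1R, F1A, F1D) and FJMAX = max(FJR, FJA, FJD); ties (measure
zero for continuous traits) resolve to the first maximum in the fixed
order REC, ADD, DOM.

Every Z is implemented as a linear contrast of cell means with
Var(cell mean) = σ²/count. That single construction yields, with no further
assumptions:

* the correlation matrices V1 (stage-1 triple), VJ (joint triple) and the
  3×3 cross-block ρ, assembled into the 6×6 Σ;
* the H1 mean vector μ, linear in β1 and proportional to β1/σ after
  standardisation — power depends on the design only through the genotype
  counts and β1/σ;
* the residual laws RSS1/σ² ~ χ²(n1−3) and RSS2/σ² ~ χ²(n2−3), independent
  of each other and of the Z vector, with RSSJ = RSS1 + RSS2.

Given genotype counts these facts are *exact* under normal errors, not
asymptotic; the "asymptotic" qualifier only covers treating the counts as
fixed and the error distribution as normal.

## Calibration numerics

The two cut-offs solve Pr_H0(F1MAX > u1) = γ and
Pr_H0(F1MAX > u1, FJMAX > uJ) = α/m; power is the same joint probability
under μ. The numerical difficulty is the 1e-7 scale of the joint tail:
complement forms such as `1 − P(A') − P(B') + P(A'B')` lose seven digits to
cancellation. The package never differences large probabilities:

* **Rank-2 reduction.** Each Z triple consists of three sum-to-zero
  contrasts of three group means, so V1 and VJ have rank 2 and Σ has rank
  4. We factor Z1/σ = B1·w + μ1 and ZJ/σ = M·w + L·v + μJ with w, v
  independent N2(0, I). The event {max_k |Z1k| ≤ a} is a hexagon
  (intersection of three bands) in the w-plane.
* **Stage-1 tail in closed form.** Along the ray at angle θ the hexagon
  ends at r = a/M(θ) with M(θ) = max_k |b_k·u(θ)|. Mixing over
  RSS1/σ² ~ χ²(df) with a² = u·S/df gives
  E[exp(−uS/(2 df M²))] = (1 + u/(df M²))^(−df/2), so
  Pr_H0(F1MAX > u) is a single smooth angular integral (8192-point grid);
  `solve_u1` brackets between the one-model and Bonferroni-of-three F
  cut-offs and is exact to root-finder tolerance.
* **Joint tail by region quadrature.** Pr(screen region ∧ FJMAX > aJ) is
  integrated over (S1, S2, θ, r): Gauss-Legendre on the chi-square
  probability scale (12 and 3 nodes; dfJ ≈ 2000 makes S2 a small
  correction), 48 angular panels × 4 nodes, and radial segments handled
  exactly-in-the-Gaussian-weight (an exponential-CDF substitution on the
  inner segment, Gauss-Laguerre on the outward tail). At each node the
  conditional joint event is 1 minus the N2 measure of the convex polygon
  {v : |M_l·w + L_l·v + μJ_l| ≤ aJ}, computed exactly by enumerating the
  band-pair vertices and summing signed origin-fan triangles, each an
  analytic 1-D angular integral (12 Gauss nodes per edge, ~1e-5 relative).
  Every term is a small positive quantity: relative accuracy survives at
  the 1e-7 scale. All nodes except the polygon half-width are independent
  of uJ, so root-finding for uJ re-evaluates only the polygon stage.
* **Additive-only comparator (AFJ).** Under H0, F1A is exactly F(1, n1−3)
  (independent numerator and saturated denominator), so its screen cut-off
  is a quantile call. The joint AFJ tail mixes, over (S1, S2), four signed
  bivariate-normal orthant probabilities with correlation ρ22, using a
  vectorised port of Genz's BVND algorithm (~1e-15 absolute, full relative
  accuracy in deep tails).

Default quadrature sizes give ~1e-3 relative accuracy on tail
probabilities (verified against 1e6–4e6-replicate Monte-Carlo oracles in
the test suite) and evaluate one joint probability in ~0.2 s; a
`plug_in` mode replaces RSS/df by σ² (the large-df limit) and is retained
as a fast approximation — at df ≈ 600 the mixing correction on a 1e-4 tail
is ~15%, so exact mixing is the default. The complement-differencing form
is kept only as a cross-check at relaxed levels. Probabilities are clipped
to [0, 1]; degenerate inputs (an empty genotype cell, n1 ≤ 3) raise
errors rather than returning NaN.

The joint p-value of an observed pair has two definitions, selectable by
flag: the design-conditional `Pr_H0(F1MAX > u1, FJMAX > fJ_obs)` (default
for the association scan; markers failing the screen get p = 1, and given
selection the p-value is uniform on (0, γ)), and the observed-pair
`Pr_H0(F1MAX > f1_obs, FJMAX > fJ_obs)`.

## Design parameters

| parameter | meaning | default / reference value |
|---|---|---|
| n | total cohort size | 2000 in the reference grids |
| π | stage-1 fraction | 0.3 / 0.4 / 0.5 |
| MAF | minor-allele frequency | 0.15 / 0.30 / 0.45 |
| γ | stage-1 screen level (p-value scale) | 1e-4, 2e-4 |
| α, m | family level and marker count | 0.05, 5e5 → α/m = 1e-7 |
| β1 | genetic effect (trait units) | 0.5 REC / 0.3 ADD / 0.4 DOM |
| σ | residual SD | 1 (power depends only on β1/σ) |

Analytic calibration uses *real-valued* Hardy-Weinberg expected counts
(n·π·((1−p)², 2p(1−p), p²) per stage); the simulator uses either
multinomial draws or rounded expected counts. The reference β1 values are
deliberately model-specific so the three true-model columns of the power
grid are visually comparable.

## Simulator

`gen_dataset` draws genotypes iid from HWE proportions (or fixes the
rounded expected composition), assigns stages by random permutation, and
adds N(0, σ²) noise to the coded mean. Monte-Carlo power/type-I routines
regenerate replicates with an empty stage-by-genotype cell (capped at 10×
the request, counted in the output) so the estimator stays a clean
binomial conditional on testability. What the generator does *not*
emulate: linkage disequilibrium between markers, genotyping error, missing
data, covariates, population stratification, or effect-size heterogeneity
between stages — agreement of analytic and simulated power therefore
validates the distribution theory and the calibration numerics, not
robustness to those real-data features.

The repeated-random-split experiment (`split_stability`) re-randomises the
stage labels of one cohort many times and records both analyses' joint
p-values. Two details matter:

* The combined-data Z statistics are invariant to the split (only RSSJ and
  the stage-1 statistics move), so the *observed-pair* p-value definition
  is the default here — with the design-conditional definition and no
  screen, the p-values would barely vary by construction.
* Stability is summarised by IQR/median of −log10 p rather than raw IQR.
  Under recessive truth MAXFJ's p-values sit at roughly twice AFJ's
  −log10 scale, where the same relative wobble produces more absolute
  spread; the scale-free ratio isolates split sensitivity from evidence
  level and shows the robust statistic to be the more stable one. The
  null-uniformity check runs with γ = 1 (no screen), where the
  design-conditional p-value is exactly uniform; with a screen its law is
  uniform on (0, γ) with an atom at 1, and a plain KS test against U(0,1)
  would wrongly reject.

## Open choices made here

* Tie-breaking in the maxima: fixed order REC, ADD, DOM (ties have
  probability zero).
* Genotype orientation is the caller's contract: the statistics are not
  re-oriented by allele frequency (REC/DOM are not invariant to swapping
  gg↔GG, ADD is).
* "RSS1 and RSSJ independent" is implemented as the only reading
  consistent with RSSJ = RSS1 + RSS2: RSS1 ⟂ RSS2, both ⟂ Z.
* The joint cut-off *increases* with γ at fixed α/m (a weaker screen
  admits more of the joint event), which the tests assert.

## Limitations

* No covariate adjustment; the contrasts act on raw group means.
* Calibration conditions on genotype counts; count randomness across
  replicates is a second-order effect the simulator quantifies.
* Very small cells (< ~5 subjects) strain the normal approximation for
  non-normal traits; the theory here is exact only under normal errors.
* H1 probabilities below ~1e-6 combined with extreme thresholds fall back
  on the same quadrature but have not been accuracy-profiled; the
  supported regime is power ≥ ~1e-3.
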