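"""Asymptotic moment structure of the six Z statistics.

Writing each Z as a contrast of the six stage-by-genotype cell means (cell
mean variance sigma^2 / count, cells independent), the vector

    Z = (Z1R, Z1A, Z1D, ZJR, ZJA, ZJD)'

is exactly Gaussian given the genotype counts:

    Z | H0 ~ N6(0, sigma^2 * Sigma),      Sigma = [[V1, rho], [rho', VJ]],
    Z | H1 ~ N6(mu, sigma^2 * Sigma),     mu linear in beta1,

with V1, VJ unit-diagonal by the contrast normalisation.  Each stage's Z
triple consists of three sum-zero contrasts of three group means, so V1 and
VJ have rank 2 and Sigma has rank 4 — structure the calibration module
exploits.  Residual sums of squares obey RSS1/sigma^2 ~ chi2(n1-3),
RSS2/sigma^2 ~ chi2(n2-3), RSSJ = RSS1 + RSS2, all independent of Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._contrasts import model_contrasts
from .data import GENO_CODES, EffectSpec, GenotypeCounts

__all__ = [
    "MomentStructure",
    "coefficient_matrix",
    "moment_structure",
    "corr_stage1",
    "corr_joint",
    "cross_corr",
    "mean_vector",
    "residual_laws",
    "hwe_expected_counts",
]


def coefficient_matrix(c: GenotypeCounts) -> np.ndarray:
    """6x6 matrix C with Z = C @ (six cell means), rows (Z1R..ZJD).

    Cell order is stage-major: (1,gg),(1,Gg),(1,GG),(2,gg),(2,Gg),(2,GG).
    Stage-1 rows load only stage-1 cells; joint rows distribute the pooled
    genotype-group contrast over the two stages with weights n_sj / N_j.
    """
    c.require_all()
    C = np.zeros((6, 6))
    s1 = c.stage1
    C[:3, :3] = model_contrasts(*s1)
    N = c.combined
    CJ = model_contrasts(*N)  # (3 models, 3 genotype groups)
    # pooled mean ybar_j = (n1j * ybar_1j + n2j * ybar_2j) / N_j
    C[3:, :3] = CJ * (s1 / N)
    C[3:, 3:] = CJ * (c.stage2 / N)
    return C


@dataclass(frozen=True)
class MomentStructure:
    """Moments of (Z1R, Z1A, Z1D, ZJR, ZJA, ZJD) given genotype counts."""

    counts: GenotypeCounts
    sigma6: np.ndarray  # 6x6 correlation matrix [[V1, rho], [rho', VJ]]
    mu: np.ndarray  # 6-vector of H1 means on the y scale (zero under H0)
    sigma2: float = 1.0

    @property
    def V1(self) -> np.ndarray:
        return self.sigma6[:3, :3]

    @property
    def VJ(self) -> np.ndarray:
        return self.sigma6[3:, 3:]

    @property
    def rho(self) -> np.ndarray:
        return self.sigma6[:3, 3:]

    @property
    def df1(self) -> float:
        return self.counts.df1

    @property
    def df2(self) -> float:
        return self.counts.df2

    @property
    def dfJ(self) -> float:
        return self.counts.dfJ

    @property
    def mu_standardized(self) -> np.ndarray:
        """Mean of Z / sigma — the scale on which power depends (beta1/sigma)."""
        return self.mu / np.sqrt(self.sigma2)

    def to_dict(self) -> dict:
        return {
            "V1": self.V1.tolist(),
            "VJ": self.VJ.tolist(),
            "rho": self.rho.tolist(),
            "mu": self.mu.tolist(),
            "sigma2": self.sigma2,
            "df1": self.df1,
            "df2": self.df2,
            "dfJ": self.dfJ,
            "counts": self.counts.cells.tolist(),
        }


def moment_structure(
    c: GenotypeCounts, effect: EffectSpec | None = None
) -> MomentStructure:
    """Build the 6-dimensional moment structure for the given counts.

    With ``effect`` supplied, ``mu`` is the H1 mean vector for that true
    generating model; otherwise ``mu`` is zero (H0).
    """
    C = coefficient_matrix(c)
    A = C / np.sqrt(c.cells)  # Cov(Z)/sigma^2 = A A'
    sigma6 = A @ A.T
    # exact unit diagonal by construction; tidy roundoff
    d = np.sqrt(np.diag(sigma6))
    sigma6 = sigma6 / np.outer(d, d)
    sigma6 = (sigma6 + sigma6.T) / 2.0
    if effect is None:
        mu = np.zeros(6)
        sigma2 = 1.0
    else:
        cell_codes = np.tile(GENO_CODES[effect.model], 2)
        mu = effect.beta1 * (C @ cell_codes)
        sigma2 = effect.sigma**2
    return MomentStructure(counts=c, sigma6=sigma6, mu=mu, sigma2=sigma2)


def corr_stage1(c: GenotypeCounts) -> np.ndarray:
    """V1: correlation matrix of (Z1R, Z1A, Z1D); rank 2, unit diagonal."""
    c.require_stage1()
    A = model_contrasts(*c.stage1) / np.sqrt(c.stage1)
    V = A @ A.T
    d = np.sqrt(np.diag(V))
    return (V / np.outer(d, d) + (V / np.outer(d, d)).T) / 2.0


def corr_joint(c: GenotypeCounts) -> np.ndarray:
    """VJ: correlation matrix of (ZJR, ZJA, ZJD) with combined counts."""
    c.require_all()
    A = model_contrasts(*c.combined) / np.sqrt(c.combined)
    V = A @ A.T
    d = np.sqrt(np.diag(V))
    return (V / np.outer(d, d) + (V / np.outer(d, d)).T) / 2.0


def cross_corr(c: GenotypeCounts) -> np.ndarray:
    """rho: 3x3 cross-correlation between the stage-1 and joint Z triples."""
    return moment_structure(c).rho


def mean_vector(effect: EffectSpec, c: GenotypeCounts) -> np.ndarray:
    """H1 mean of the six Z statistics (y scale); zero iff beta1 = 0."""
    return moment_structure(c, effect).mu


def residual_laws(c: GenotypeCounts) -> tuple[float, float, float]:
    """(df1, df2, dfJ) of the chi-square residual laws; dfJ = df1 + df2."""
    if not (c.n1 > 3 and c.n2 > 3 and c.n > 6):
        raise ValueError(
            f"need n1 > 3, n2 > 3 and n > 6; got n1={c.n1}, n2={c.n2}"
        )
    return c.df1, c.df2, c.dfJ


def hwe_expected_counts(
    n: float, pi: float, maf: float, rounded: bool = False
) -> GenotypeCounts:
    """Expected genotype counts under Hardy-Weinberg equilibrium.

    Stage 1 holds a fraction ``pi`` of the ``n`` subjects; genotype
    proportions are ((1-p)^2, 2p(1-p), p^2) at minor-allele frequency
    ``p = maf``.  Real-valued expected counts by default (for analytic
    calibration); ``rounded=True`` gives the nearest-integer variant used
    when simulating whole subjects.
    """
    if not 0 < pi < 1:
        raise ValueError(f"pi must be in (0, 1), got {pi}")
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    p = maf
    q = 1.0 - p
    props = np.array([q * q, 2 * p * q, p * p])
    c = GenotypeCounts(*(n * pi * props), *(n * (1 - pi) * props))
    return c.round() if rounded else c
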