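"""Threshold calibration and exceedance probabilities for the two-stage design.

The design is calibrated by two cut-offs on the F scale:

* ``u1`` — stage-1 screen, Pr_H0(F1MAX > u1) = gamma;
* ``uJ`` — joint cut-off, Pr_H0(F1MAX > u1, FJMAX > uJ) = alpha/m
  (Bonferroni per-marker level for m markers at family level alpha).

Power is the same joint exceedance under the H1 mean vector.  All
probabilities are computed deterministically: the chi-square residual laws
(RSS1 ~ sigma^2 chi2(n1-3), RSS2 ~ sigma^2 chi2(n2-3), RSSJ = RSS1 + RSS2)
are mixed by Gaussian quadrature on the probability scale, and the
conditional Gaussian events are evaluated exactly on the rank-2 planes of
the two Z triples (see ``_geometry``).  The stage-1 H0 exceedance has a
closed form (a single angular integral), so ``solve_u1`` is essentially
exact.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import f as f_dist

from ._geometry import (
    TWOPI,
    _gl,
    _glag,
    band_polygon_prob,
    bvn_upper,
    chi2_prob_nodes,
    fmax_tail_h0,
    plane_factor,
)
from .asymptotics import moment_structure
from .data import EffectSpec, GenotypeCounts

__all__ = [
    "CalibSettings",
    "Thresholds",
    "prob_f1max_exceeds",
    "prob_fjmax_exceeds",
    "solve_u1",
    "prob_joint_exceeds",
    "prob_joint_eq12",
    "solve_uJ",
    "design_thresholds",
    "joint_pvalue",
    "afj_solve_u1",
    "afj_prob_joint_exceeds",
    "afj_solve_uJ",
    "afj_design_thresholds",
]


@dataclass(frozen=True)
class CalibSettings:
    """Quadrature resolution knobs (defaults balance ~1e-3 relative accuracy
    on tail probabilities against sub-second evaluation)."""

    n_s1: int = 12  # chi2(df1) mixing nodes
    n_s2: int = 3  # chi2(df2) mixing nodes (dfJ ~ 2000: tiny correction)
    n_arc: int = 48  # angular panels on [0, 2pi)
    n_theta: int = 4  # Gauss-Legendre nodes per angular panel
    n_rad_upper: int = 8  # Gauss-Laguerre nodes on the outward ray segment
    n_rad_lower: int = 4  # Gauss-Legendre nodes on the inner ray segment
    edge_nodes: int = 12  # nodes per polygon edge
    n_theta_closed: int = 8192  # angular grid for the closed-form stage-1 tail
    plug_in: bool = False  # replace RSS/df by sigma^2 (large-df approximation)


@dataclass(frozen=True)
class Thresholds:
    """Calibrated cut-offs with the levels they achieve and method metadata."""

    u1: float
    uJ: float
    gamma: float
    alpha_per_snp: float
    counts: GenotypeCounts
    statistic: str = "MAXFJ"
    achieved_gamma: float = float("nan")
    achieved_alpha: float = float("nan")
    metadata: dict = field(default_factory=dict)


class JointCalibrator:
    """Rank-reduced Gaussian representation of (Z1, ZJ)/sigma for one marker.

    Z1/sigma = B1 w + mu1 and ZJ/sigma = M w + L v + muJ with w, v
    independent N2(0, I); B1, M, L are 3x2 factors determined by the
    genotype counts, and (mu1, muJ) is the standardised H1 mean (zero under
    H0).  Every exceedance probability is an integral over (w, S1, S2).
    """

    def __init__(
        self,
        counts: GenotypeCounts,
        effect: EffectSpec | None = None,
        settings: CalibSettings | None = None,
    ):
        self.counts = counts
        self.settings = settings or CalibSettings()
        ms = moment_structure(counts, effect)
        self.ms = ms
        self.B1 = plane_factor(ms.V1)
        BtB = self.B1.T @ self.B1
        self.M = ms.sigma6[3:, :3] @ self.B1 @ np.linalg.inv(BtB)
        resid = ms.VJ - self.M @ self.M.T
        self.L = plane_factor(resid)
        mu = ms.mu_standardized
        self.mu1 = mu[:3]
        self.muJ = mu[3:]
        self.df1 = counts.df1
        self.df2 = counts.df2
        self.dfJ = counts.dfJ
        self.BJ = plane_factor(ms.VJ)

    # -- stage-1 / joint marginals --------------------------------------
    def f1max_tail(self, u: float) -> float:
        """Pr(F1MAX > u) under the calibrator's mean (closed form when centred)."""
        st = self.settings
        df1 = np.inf if st.plug_in else self.df1
        if not np.any(self.mu1):
            return fmax_tail_h0(self.B1, u, df1, st.n_theta_closed)
        s_nodes, s_w = self._chi2(self.df1)
        a1 = np.sqrt(u * s_nodes / self.df1)
        c = np.tile(self.mu1, (len(a1), 1))
        inside = band_polygon_prob(self.B1, c, a1, st.edge_nodes)
        return float(np.dot(s_w, 1.0 - inside))

    def fjmax_tail(self, u: float) -> float:
        """Pr(FJMAX > u) marginally."""
        st = self.settings
        dfJ = np.inf if st.plug_in else self.dfJ
        if not np.any(self.muJ):
            return fmax_tail_h0(self.BJ, u, dfJ, st.n_theta_closed)
        s_nodes, s_w = self._chi2(self.dfJ)
        a = np.sqrt(u * s_nodes / self.dfJ)
        c = np.tile(self.muJ, (len(a), 1))
        inside = band_polygon_prob(self.BJ, c, a, st.edge_nodes)
        return float(np.dot(s_w, 1.0 - inside))

    def _chi2(self, df: float):
        """Mixing nodes for S ~ chi2(df); a single node S = df in plug-in mode."""
        if self.settings.plug_in:
            return np.array([df]), np.array([1.0])
        return chi2_prob_nodes(df, self.settings.n_s1)

    # -- joint event ----------------------------------------------------
    def region_nodes(self, u1: float, region: str = "outside") -> "_RegionNodes":
        """Precompute (w, S1) quadrature nodes over the stage-1 region.

        ``outside`` integrates over {F1MAX > u1} (screen passed),
        ``inside`` over its complement.  Nodes are reused across uJ values
        during root finding — only the joint polygon half-width changes.
        """
        return _RegionNodes(self, u1, region)

    def prob_joint(self, u1: float, uJ: float) -> float:
        return self.region_nodes(u1, "outside").joint_exceed(uJ)


class _RegionNodes:
    """Quadrature nodes over (S1, w) restricted to a stage-1 region."""

    def __init__(self, cal: JointCalibrator, u1: float, region: str):
        st = cal.settings
        self.cal = cal
        self.u1 = float(u1)
        self.region = region

        if st.plug_in:
            s1_nodes, s1_w = np.array([cal.df1]), np.array([1.0])
            s2_nodes, s2_w = np.array([cal.df2]), np.array([1.0])
        else:
            s1_nodes, s1_w = chi2_prob_nodes(cal.df1, st.n_s1)
            s2_nodes, s2_w = chi2_prob_nodes(cal.df2, st.n_s2)
        self.s2_nodes, self.s2_w = s2_nodes, s2_w

        # angular panels with Gauss-Legendre nodes; weights carry 1/(2pi)
        edges = np.linspace(0.0, TWOPI, st.n_arc + 1)
        xg, wg = _gl(st.n_theta)
        half = (edges[1:] - edges[:-1]) / 2.0
        mid = (edges[1:] + edges[:-1]) / 2.0
        theta = (mid[:, None] + half[:, None] * xg[None, :]).ravel()
        th_w = (half[:, None] * wg[None, :]).ravel() / TWOPI

        udir = np.stack([np.cos(theta), np.sin(theta)], axis=-1)  # (T, 2)
        g = udir @ cal.B1.T  # (T, 3): band slopes along each ray
        mu1 = cal.mu1

        t_lag, w_lag = _glag(st.n_rad_upper)
        x_low, w_low = _gl(st.n_rad_lower)

        rs, wts, cJs, s1s = [], [], [], []
        for s1, w1 in zip(s1_nodes, s1_w):
            a1 = np.sqrt(self.u1 * s1 / cal.df1) if self.u1 > 0 else 0.0
            lo, hi, nonempty = _ray_interval(g, mu1, a1)
            # hexagon segment on the ray, clipped to r >= 0
            seg_lo = np.where(nonempty, np.maximum(lo, 0.0), 0.0)
            seg_hi = np.where(nonempty, np.maximum(hi, 0.0), 0.0)
            has_seg = nonempty & (seg_hi > seg_lo)

            if region == "outside":
                # inner segment [0, seg_lo] in q = r^2/2 coordinates
                qn, qw = _exp_seg_nodes(
                    np.zeros_like(seg_lo),
                    np.where(has_seg, seg_lo**2 / 2.0, 0.0),
                    x_low, w_low,
                )
                r_in = np.sqrt(2.0 * qn)
                # outward segment [r_u, inf), r_u = seg_hi (0 if no hexagon)
                r_u = np.where(has_seg, seg_hi, 0.0)
                r_out = np.sqrt(r_u[:, None] ** 2 + 2.0 * t_lag[None, :])
                ow = np.exp(-0.5 * r_u[:, None] ** 2) * w_lag[None, :]
                r_all = np.concatenate([r_in, r_out], axis=1)
                w_all = np.concatenate([qw, ow], axis=1)
            elif region == "inside":
                qa = np.where(has_seg, seg_lo**2 / 2.0, 0.0)
                qb = np.where(has_seg, seg_hi**2 / 2.0, 0.0)
                qn, w_all = _exp_seg_nodes(qa, qb, x_low, w_low)
                r_all = np.sqrt(2.0 * qn)
            else:  # pragma: no cover
                raise ValueError(f"unknown region {region!r}")

            w_node = w1 * th_w[:, None] * w_all  # (T, R)
            keep = w_node.ravel() > 0
            r_flat = r_all.ravel()[keep]
            th_idx = np.repeat(np.arange(len(theta)), r_all.shape[1])[keep]
            w_pts = r_flat[:, None] * udir[th_idx]  # (K, 2)
            rs.append(w_pts)
            wts.append(w_node.ravel()[keep])
            cJs.append(w_pts @ cal.M.T + cal.muJ)
            s1s.append(np.full(keep.sum(), s1))

        self.w_pts = np.concatenate(rs) if rs else np.zeros((0, 2))
        self.weights = np.concatenate(wts) if wts else np.zeros(0)
        self.cJ = np.concatenate(cJs) if cJs else np.zeros((0, 3))
        self.s1 = np.concatenate(s1s) if s1s else np.zeros(0)

    @property
    def region_prob(self) -> float:
        """Quadrature mass of the stage-1 region (= Pr of the region)."""
        return float(self.weights.sum())

    def joint_exceed(self, uJ: float) -> float:
        """Pr(region AND FJMAX > uJ)."""
        cal = self.cal
        st = cal.settings
        total = 0.0
        for s2, w2 in zip(self.s2_nodes, self.s2_w):
            sJ = self.s1 + s2
            aJ = np.sqrt(uJ * sJ / cal.dfJ) if uJ > 0 else np.zeros_like(sJ)
            inside = band_polygon_prob(cal.L, self.cJ, aJ, st.edge_nodes)
            total += w2 * float(np.dot(self.weights, 1.0 - inside))
        return min(max(total, 0.0), 1.0)

    def joint_within(self, uJ: float) -> float:
        """Pr(region AND FJMAX <= uJ)."""
        cal = self.cal
        st = cal.settings
        total = 0.0
        for s2, w2 in zip(self.s2_nodes, self.s2_w):
            sJ = self.s1 + s2
            aJ = np.sqrt(uJ * sJ / cal.dfJ) if uJ > 0 else np.zeros_like(sJ)
            inside = band_polygon_prob(cal.L, self.cJ, aJ, st.edge_nodes)
            total += w2 * float(np.dot(self.weights, inside))
        return min(max(total, 0.0), 1.0)


def _exp_seg_nodes(qa: np.ndarray, qb: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Nodes/weights for int_qa^qb exp(-q) g(q) dq, vectorised over rays.

    Uses the exponential CDF as integration variable, so a constant g is
    integrated exactly regardless of segment length.
    """
    ea = np.exp(-qa)
    mass = ea - np.exp(-qb)
    xi = (x[None, :] + 1.0) / 2.0
    inner = np.maximum(ea[:, None] - xi * mass[:, None], 1e-300)
    qn = -np.log(inner)
    qw = mass[:, None] * w[None, :] / 2.0
    return qn, qw


def _ray_interval(g: np.ndarray, mu: np.ndarray, a: float):
    """Per-ray r-interval where all three bands |g_k r + mu_k| <= a hold.

    g: (T, 3) slopes, mu: (3,) offsets.  Returns (lo, hi, nonempty) over T.
    """
    eps = 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (-a - mu[None, :]) / g
        e2 = (a - mu[None, :]) / g
    lo_k = np.minimum(e1, e2)
    hi_k = np.maximum(e1, e2)
    flat = np.abs(g) <= eps
    ok_flat = np.abs(mu[None, :]) <= a
    lo_k = np.where(flat, np.where(ok_flat, -np.inf, np.inf), lo_k)
    hi_k = np.where(flat, np.where(ok_flat, np.inf, -np.inf), hi_k)
    lo = lo_k.max(axis=1)
    hi = hi_k.min(axis=1)
    return lo, hi, hi > lo


# ---------------------------------------------------------------------------
# functional API
# ---------------------------------------------------------------------------


def _mu_effect(counts, mu):
    """Accept a standardised 6-vector or None; EffectSpec handled upstream."""
    if mu is None:
        return None
    mu = np.asarray(mu, float)
    if mu.shape != (6,):
        raise ValueError("mu must be a 6-vector (standardised Z means)")
    return mu


def _calibrator(counts, mu=None, settings=None) -> JointCalibrator:
    cal = JointCalibrator(counts, settings=settings)
    m = _mu_effect(counts, mu)
    if m is not None:
        cal.mu1 = m[:3]
        cal.muJ = m[3:]
    return cal


def prob_f1max_exceeds(
    u: float,
    counts: GenotypeCounts,
    mu=None,
    settings: CalibSettings | None = None,
) -> float:
    """Pr(F1MAX > u) under N6 mean ``mu`` (standardised; None/zero = H0)."""
    if u <= 0:
        return 1.0
    return _calibrator(counts, mu, settings=settings).f1max_tail(u)


def prob_fjmax_exceeds(
    u: float,
    counts: GenotypeCounts,
    mu=None,
    settings: CalibSettings | None = None,
) -> float:
    """Pr(FJMAX > u) under N6 mean ``mu`` (standardised; None/zero = H0)."""
    if u <= 0:
        return 1.0
    return _calibrator(counts, mu, settings=settings).fjmax_tail(u)


def solve_u1(
    gamma: float,
    counts: GenotypeCounts,
    settings: CalibSettings | None = None,
) -> float:
    """Stage-1 cut-off with Pr_H0(F1MAX > u1) = gamma.

    The H0 tail is a closed-form angular integral, so the root is found to
    near machine precision.  Bracket: the single-model F cut-off from below
    (max of three >= one) and the Bonferroni-of-three cut-off from above.
    """
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    counts.require_stage1()
    cal = JointCalibrator(counts, settings=settings)
    lo = f_dist.isf(gamma, 1, counts.df1)
    hi = f_dist.isf(gamma / 3.0, 1, counts.df1)
    fun = lambda u: np.log(cal.f1max_tail(u)) - np.log(gamma)
    # tails are monotone; expand bracket defensively against quadrature slack
    flo, fhi = fun(lo), fun(hi)
    while flo < 0:
        lo *= 0.5
        flo = fun(lo)
    while fhi > 0:
        hi *= 1.5
        fhi = fun(hi)
    return float(brentq(fun, lo, hi, xtol=1e-10, rtol=1e-12))


def prob_joint_exceeds(
    u1: float,
    uJ: float,
    counts: GenotypeCounts,
    mu=None,
    settings: CalibSettings | None = None,
) -> float:
    """Pr(F1MAX > u1 AND FJMAX > uJ) under N6 mean ``mu`` (None = H0)."""
    counts.require_all()
    cal = _calibrator(counts, mu, settings=settings)
    return cal.region_nodes(u1, "outside").joint_exceed(uJ)


def prob_joint_eq12(
    u1: float,
    uJ: float,
    counts: GenotypeCounts,
    mu=None,
    settings: CalibSettings | None = None,
) -> float:
    """Joint exceedance by complement differencing (cross-check form).

    1 - Pr(F1MAX<=u1) - Pr(FJMAX<=uJ) + Pr(F1MAX<=u1, FJMAX<=uJ).  Loses
    relative precision at extreme tails (use only at relaxed levels).
    """
    cal = _calibrator(counts, mu, settings=settings)
    pA = cal.f1max_tail(u1)
    pB = cal.fjmax_tail(uJ)
    both_within = cal.region_nodes(u1, "inside").joint_within(uJ)
    return 1.0 - (1.0 - pA) - (1.0 - pB) + both_within


def solve_uJ(
    alpha_per_snp: float,
    u1: float,
    counts: GenotypeCounts,
    settings: CalibSettings | None = None,
) -> float:
    """Joint cut-off with Pr_H0(F1MAX > u1, FJMAX > uJ) = alpha_per_snp."""
    cal = JointCalibrator(counts, settings=settings)
    nodes = cal.region_nodes(u1, "outside")
    gamma_eff = nodes.region_prob
    if not 0 < alpha_per_snp < gamma_eff:
        raise ValueError(
            f"alpha_per_snp={alpha_per_snp} must lie in (0, Pr(F1MAX>u1)="
            f"{gamma_eff:.3g}); the joint event is nested in the screen"
        )
    hi = f_dist.isf(alpha_per_snp / 3.0, 1, counts.dfJ)
    fun = lambda u: np.log(max(nodes.joint_exceed(u), 1e-300)) - np.log(
        alpha_per_snp
    )
    fhi = fun(hi)
    while fhi > 0:
        hi *= 1.5
        fhi = fun(hi)
    return float(brentq(fun, 0.0, hi, xtol=1e-8, rtol=8.9e-16))


def design_thresholds(
    gamma: float,
    alpha_per_snp: float,
    counts: GenotypeCounts,
    settings: CalibSettings | None = None,
) -> Thresholds:
    """Solve (u1, uJ) and report the achieved levels and method metadata."""
    settings = settings or CalibSettings()
    u1 = solve_u1(gamma, counts, settings)
    uJ = solve_uJ(alpha_per_snp, u1, counts, settings)
    cal = JointCalibrator(counts, settings=settings)
    ach_g = cal.f1max_tail(u1)
    ach_a = cal.region_nodes(u1, "outside").joint_exceed(uJ)
    return Thresholds(
        u1=u1,
        uJ=uJ,
        gamma=gamma,
        alpha_per_snp=alpha_per_snp,
        counts=counts,
        statistic="MAXFJ",
        achieved_gamma=ach_g,
        achieved_alpha=ach_a,
        metadata={"settings": asdict(settings)},
    )


def joint_pvalue(
    f1_obs: float,
    fJ_obs: float,
    u1: float,
    counts: GenotypeCounts,
    definition: str = "design",
    settings: CalibSettings | None = None,
) -> tuple[float, bool]:
    """Joint p-value of an observed (F1MAX, FJMAX) pair.

    ``design`` (default): Pr_H0(F1MAX > u1, FJMAX > fJ_obs) — consistent
    with the threshold calibration; markers failing the screen get p = 1.
    ``observed``: Pr_H0(F1MAX > f1_obs, FJMAX > fJ_obs).
    Returns (p, selected).
    """
    selected = f1_obs > u1
    if definition == "design":
        if not selected:
            return 1.0, False
        p = prob_joint_exceeds(u1, fJ_obs, counts, settings=settings)
    elif definition == "observed":
        p = prob_joint_exceeds(f1_obs, fJ_obs, counts, settings=settings)
    else:
        raise ValueError(f"unknown p-value definition {definition!r}")
    return float(min(max(p, 0.0), 1.0)), bool(selected)


# ---------------------------------------------------------------------------
# additive-model-only comparator (AFJ)
# ---------------------------------------------------------------------------


def afj_solve_u1(gamma: float, counts: GenotypeCounts) -> float:
    """Stage-1 cut-off for the additive-only screen: F1A ~ F(1, n1-3) under H0."""
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    return float(f_dist.isf(gamma, 1, counts.df1))


def afj_prob_joint_exceeds(
    u1: float,
    uJ: float,
    counts: GenotypeCounts,
    mu2=(0.0, 0.0),
    settings: CalibSettings | None = None,
) -> float:
    """Pr(F1A > u1 AND FJA > uJ); (Z1A, ZJA) bivariate normal with corr rho22.

    Chi-square mixing by probability-scale quadrature; the conditional
    two-sided rectangle is summed from four signed orthant probabilities
    (no complement differencing, so small tails keep relative accuracy).
    """
    settings = settings or CalibSettings()
    counts.require_all()
    rho = float(moment_structure(counts).rho[1, 1])
    m1, mJ = float(mu2[0]), float(mu2[1])
    if settings.plug_in:
        s1n, s1w = np.array([counts.df1]), np.array([1.0])
        s2n, s2w = np.array([counts.df2]), np.array([1.0])
    else:
        s1n, s1w = chi2_prob_nodes(counts.df1, max(settings.n_s1, 16))
        s2n, s2w = chi2_prob_nodes(counts.df2, max(settings.n_s2, 8))
    S1, S2 = np.meshgrid(s1n, s2n, indexing="ij")
    W = np.outer(s1w, s2w)
    a1 = np.sqrt(np.maximum(u1, 0.0) * S1 / counts.df1)
    aJ = np.sqrt(np.maximum(uJ, 0.0) * (S1 + S2) / counts.dfJ)
    total = np.zeros_like(a1)
    for s in (1.0, -1.0):
        for t in (1.0, -1.0):
            total += bvn_upper(a1 - s * m1, aJ - t * mJ, s * t * rho)
    return float(np.clip((W * total).sum(), 0.0, 1.0))


def afj_solve_uJ(
    alpha_per_snp: float,
    u1: float,
    counts: GenotypeCounts,
    settings: CalibSettings | None = None,
) -> float:
    """Joint cut-off for the additive-only analysis."""
    gamma_eff = afj_prob_joint_exceeds(u1, 0.0, counts, settings=settings)
    if not 0 < alpha_per_snp < gamma_eff:
        raise ValueError(
            f"alpha_per_snp={alpha_per_snp} not in (0, Pr(F1A>u1)={gamma_eff:.3g})"
        )
    hi = float(f_dist.isf(alpha_per_snp, 1, counts.dfJ)) * 1.5
    fun = lambda u: np.log(
        max(afj_prob_joint_exceeds(u1, u, counts, settings=settings), 1e-300)
    ) - np.log(alpha_per_snp)
    while fun(hi) > 0:
        hi *= 1.5
    return float(brentq(fun, 0.0, hi, xtol=1e-8, rtol=8.9e-16))


def afj_design_thresholds(
    gamma: float,
    alpha_per_snp: float,
    counts: GenotypeCounts,
    settings: CalibSettings | None = None,
) -> Thresholds:
    settings = settings or CalibSettings()
    u1 = afj_solve_u1(gamma, counts)
    uJ = afj_solve_uJ(alpha_per_snp, u1, counts, settings)
    return Thresholds(
        u1=u1,
        uJ=uJ,
        gamma=gamma,
        alpha_per_snp=alpha_per_snp,
        counts=counts,
        statistic="AFJ",
        achieved_gamma=gamma,
        achieved_alpha=afj_prob_joint_exceeds(u1, uJ, counts, settings=settings),
        metadata={"settings": asdict(settings)},
    )
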