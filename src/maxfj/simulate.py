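"""Synthetic two-stage GWAS data and Monte-Carlo verification.

Generates subject-level data under the quantitative-trait model
``y = beta0 + code(g) * beta1 + N(0, sigma^2)`` with genotypes drawn from
Hardy-Weinberg proportions at a given minor-allele frequency, provides
vectorised Monte-Carlo estimates of power and type-I error for the
calibrated two-stage tests, and implements the repeated-random-split
p-value stability experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._contrasts import z_from_group_stats
from ._geometry import fmax_tail_h0, plane_factor
from .asymptotics import hwe_expected_counts, moment_structure
from .calibration import (
    CalibSettings,
    JointCalibrator,
    Thresholds,
    afj_prob_joint_exceeds,
    afj_solve_u1,
    joint_pvalue,
    solve_u1,
)
from .data import GENO_CODES, EffectSpec, GenotypeCounts
from .fstats import summarize

__all__ = [
    "SimConfig",
    "PowerEstimate",
    "gen_dataset",
    "empirical_power",
    "empirical_type1",
    "split_stability",
]


@dataclass(frozen=True)
class SimConfig:
    """Design and effect settings for replicate generation."""

    n: int
    pi: float
    maf: float
    effect: EffectSpec
    reps: int = 1
    seed: int = 0
    counts_policy: str = "multinomial"  # or "fixed_expected"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.pi < 1:
            raise ValueError("pi must be in (0, 1)")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.counts_policy not in ("multinomial", "fixed_expected"):
            raise ValueError(f"unknown counts_policy {self.counts_policy!r}")

    @property
    def n1(self) -> int:
        return int(round(self.n * self.pi))

    @property
    def geno_probs(self) -> np.ndarray:
        p, q = self.maf, 1.0 - self.maf
        return np.array([q * q, 2 * p * q, p * p])


@dataclass(frozen=True)
class PowerEstimate:
    estimate: float
    se: float
    reps: int
    regenerated: int = 0
    seed: int = 0


def _draw_genotypes(rng, cfg: SimConfig, reps: int) -> np.ndarray:
    """(reps, n) genotype matrix, iid HWE or fixed expected composition."""
    if cfg.counts_policy == "multinomial":
        u = rng.random((reps, cfg.n))
        cum = np.cumsum(cfg.geno_probs)
        return (u > cum[0]).astype(np.int8) + (u > cum[1]).astype(np.int8)
    # fixed expected rounded counts, positions shuffled within each replicate
    exp = hwe_expected_counts(cfg.n, cfg.pi, cfg.maf, rounded=True)
    base1 = np.repeat(np.arange(3, dtype=np.int8), exp.stage1.astype(int))
    base2 = np.repeat(np.arange(3, dtype=np.int8), exp.stage2.astype(int))

    def _fit(base: np.ndarray, size: int) -> np.ndarray:
        if len(base) >= size:
            return base[:size]
        return np.concatenate([base, np.zeros(size - len(base), np.int8)])

    g = np.concatenate([_fit(base1, cfg.n1), _fit(base2, cfg.n - cfg.n1)])
    g = np.tile(g, (reps, 1))
    for row in g:  # per-replicate within-stage shuffles
        rng.shuffle(row[: cfg.n1])
        rng.shuffle(row[cfg.n1:])
    return g


def gen_dataset(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """One subject-level replicate as a stage/genotype/phenotype table.

    Stage labels are assigned by random permutation of subjects; genotype
    effects follow the true model coding of ``cfg.effect``.  Fully
    deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    g = _draw_genotypes(rng, cfg, 1)[0]
    eff = cfg.effect
    y = (
        eff.beta0
        + GENO_CODES[eff.model][g] * eff.beta1
        + eff.sigma * rng.standard_normal(cfg.n)
    )
    order = rng.permutation(cfg.n)
    stage = np.ones(cfg.n, dtype=np.int64)
    stage[order[cfg.n1:]] = 2
    return pd.DataFrame({"stage": stage, "genotype": g.astype(np.int64),
                         "phenotype": y})


def _batch_cell_stats(rng, cfg: SimConfig, reps: int):
    """Vectorised sufficient statistics for ``reps`` replicates.

    Returns (counts, mean, ss) with shape (reps, 6), cells stage-major.
    Replicates with any empty stage-by-genotype cell are redrawn (hard cap
    10x the request) and counted.
    """
    eff = cfg.effect
    code = GENO_CODES[eff.model]
    need = reps
    out_c = np.empty((reps, 6))
    out_m = np.empty((reps, 6))
    out_s = np.empty((reps, 6))
    filled = 0
    regenerated = 0
    attempts = 0
    while need > 0:
        attempts += need
        if attempts > 10 * reps + 100:
            raise RuntimeError(
                "too many degenerate replicates (empty genotype cells); "
                "increase n or maf"
            )
        g = _draw_genotypes(rng, cfg, need)
        y = (
            eff.beta0
            + code[g] * eff.beta1
            + eff.sigma * rng.standard_normal((need, cfg.n))
        )
        cell = np.where(np.arange(cfg.n)[None, :] < cfg.n1, 0, 3) + g
        flat = (np.arange(need)[:, None] * 6 + cell).ravel()
        cnt = np.bincount(flat, minlength=need * 6).reshape(need, 6)
        tot = np.bincount(flat, weights=y.ravel(), minlength=need * 6).reshape(
            need, 6
        )
        tot2 = np.bincount(
            flat, weights=(y * y).ravel(), minlength=need * 6
        ).reshape(need, 6)
        good = np.all(cnt > 0, axis=1)
        k = int(good.sum())
        regenerated += need - k
        mean = tot[good] / cnt[good]
        ss = np.maximum(tot2[good] - tot[good] * mean, 0.0)
        out_c[filled : filled + k] = cnt[good]
        out_m[filled : filled + k] = mean
        out_s[filled : filled + k] = ss
        filled += k
        need -= k
    return out_c, out_m, out_s, regenerated


def _fmax_from_stats(cnt, mean, ss):
    """(f1max, fJmax) per replicate from cell sufficient statistics."""
    c1 = cnt[:, :3]
    N = cnt[:, :3] + cnt[:, 3:]
    pooled = (cnt[:, :3] * mean[:, :3] + cnt[:, 3:] * mean[:, 3:]) / N
    z1 = z_from_group_stats(
        c1[:, 0], c1[:, 1], c1[:, 2], mean[:, 0], mean[:, 1], mean[:, 2]
    )
    zJ = z_from_group_stats(
        N[:, 0], N[:, 1], N[:, 2], pooled[:, 0], pooled[:, 1], pooled[:, 2]
    )
    n1 = c1.sum(axis=1)
    n = cnt.sum(axis=1)
    rss1 = ss[:, :3].sum(axis=1)
    rssJ = ss.sum(axis=1)
    f1 = z1**2 / (rss1 / (n1 - 3))[:, None]
    fJ = zJ**2 / (rssJ / (n - 6))[:, None]
    return f1.max(axis=1), fJ.max(axis=1)


def empirical_power(
    cfg: SimConfig,
    thresholds: Thresholds,
    batch: int = 2000,
) -> PowerEstimate:
    """Monte-Carlo joint rejection rate of the calibrated two-stage test.

    For the MAXFJ thresholds the rejection event is {F1MAX > u1 and
    FJMAX > uJ}; AFJ thresholds apply to the additive-model statistics.
    """
    rng = np.random.default_rng(cfg.seed)
    afj = thresholds.statistic == "AFJ"
    hits = 0
    regen = 0
    done = 0
    while done < cfg.reps:
        b = min(batch, cfg.reps - done)
        cnt, mean, ss, rg = _batch_cell_stats(rng, cfg, b)
        regen += rg
        if afj:
            f1m, fJm = _f_additive_from_stats(cnt, mean, ss)
        else:
            f1m, fJm = _fmax_from_stats(cnt, mean, ss)
        hits += int(np.sum((f1m > thresholds.u1) & (fJm > thresholds.uJ)))
        done += b
    p = hits / cfg.reps
    se = float(np.sqrt(max(p * (1 - p), 1e-300) / cfg.reps))
    return PowerEstimate(
        estimate=p, se=se, reps=cfg.reps, regenerated=regen, seed=cfg.seed
    )


def _f_additive_from_stats(cnt, mean, ss):
    """(F1A, FJA) per replicate (additive statistic, saturated denominator)."""
    f1, fJ = _fmax_from_stats_components(cnt, mean, ss)
    return f1[:, 1], fJ[:, 1]


def _fmax_from_stats_components(cnt, mean, ss):
    c1 = cnt[:, :3]
    N = cnt[:, :3] + cnt[:, 3:]
    pooled = (cnt[:, :3] * mean[:, :3] + cnt[:, 3:] * mean[:, 3:]) / N
    z1 = z_from_group_stats(
        c1[:, 0], c1[:, 1], c1[:, 2], mean[:, 0], mean[:, 1], mean[:, 2]
    )
    zJ = z_from_group_stats(
        N[:, 0], N[:, 1], N[:, 2], pooled[:, 0], pooled[:, 1], pooled[:, 2]
    )
    n1 = c1.sum(axis=1)
    n = cnt.sum(axis=1)
    rss1 = ss[:, :3].sum(axis=1)
    rssJ = ss.sum(axis=1)
    f1 = z1**2 / (rss1 / (n1 - 3))[:, None]
    fJ = zJ**2 / (rssJ / (n - 6))[:, None]
    return f1, fJ


def empirical_type1(
    cfg: SimConfig,
    thresholds: Thresholds,
    batch: int = 2000,
) -> PowerEstimate:
    """Monte-Carlo type-I error: same pipeline with the effect nulled out."""
    eff = cfg.effect
    null = EffectSpec(model=eff.model, beta1=0.0, sigma=eff.sigma, beta0=eff.beta0)
    cfg0 = SimConfig(
        n=cfg.n, pi=cfg.pi, maf=cfg.maf, effect=null, reps=cfg.reps,
        seed=cfg.seed, counts_policy=cfg.counts_policy,
    )
    return empirical_power(cfg0, thresholds, batch)


# ---------------------------------------------------------------------------
# repeated-random-split p-value stability
# ---------------------------------------------------------------------------

_SPLIT_SETTINGS = CalibSettings(
    n_s1=6, n_s2=2, n_arc=24, n_theta=3, n_rad_upper=6, n_rad_lower=3,
    edge_nodes=8, n_theta_closed=2048,
)


def split_stability(
    data: pd.DataFrame,
    pi: float,
    reps: int,
    seed: int = 0,
    definition: str = "observed",
    gamma: float = 1.0,
    settings: CalibSettings | None = None,
) -> pd.DataFrame:
    """Joint p-values of MAXFJ and AFJ under repeated random stage splits.

    Each replicate assigns a random ``pi`` fraction of subjects to stage 1
    and the rest to stage 2, recomputes both statistics, and evaluates their
    joint p-values.  Definitions:

    * ``observed`` (default, the stability experiment):
      p = Pr_H0(F1MAX > f1_obs, FJMAX > fJ_obs) at the observed pair — the
      combined-data Z statistics are invariant to the split, so the spread
      of these p-values isolates the stage-1 re-randomisation.
    * ``design``: the threshold-conditional p-value at screen level
      ``gamma`` (markers failing the screen get p = 1).  With ``gamma=1``
      there is no screen and p reduces to the marginal combined-data tail
      Pr_H0(FJMAX > fJ_obs), which is exactly uniform under H0.

    Returns a frame with per-replicate columns ``p_maxfj``, ``p_afj``,
    their -log10 transforms and selection flags; degenerate splits (an
    empty cell) give NaN p-values, and more than 10% of them is an error.
    """
    from scipy.stats import f as f_dist

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if definition not in ("observed", "design"):
        raise ValueError(f"unknown p-value definition {definition!r}")
    settings = settings or _SPLIT_SETTINGS
    rng = np.random.default_rng(seed)
    n = len(data)
    n1 = int(round(n * pi))
    if n1 < 4 or n - n1 < 4:
        raise ValueError("split sizes too small for the statistics")
    geno = data["genotype"].to_numpy()
    y = data["phenotype"].to_numpy().astype(float)

    from .fstats import analyze

    rows = []
    bad = 0
    for _ in range(reps):
        order = rng.permutation(n)
        stage = np.ones(n, dtype=np.int64)
        stage[order[n1:]] = 2
        df = pd.DataFrame({"stage": stage, "genotype": geno, "phenotype": y})
        s = summarize(df)
        if s.empty_cells:
            bad += 1
            rows.append(
                {"p_maxfj": np.nan, "p_afj": np.nan,
                 "selected_maxfj": False, "selected_afj": False}
            )
            continue
        res = analyze(df)
        counts = s.counts
        f1a, fJa = res.f1[1], res.fJ[1]

        if definition == "observed":
            cal = JointCalibrator(counts, settings=settings)
            p_max = cal.region_nodes(res.f1max, "outside").joint_exceed(res.fJmax)
            p_afj = afj_prob_joint_exceeds(f1a, fJa, counts, settings=settings)
            sel_max = sel_afj = True
        elif gamma >= 1.0:
            # no screen: joint p-value is the marginal combined-data tail
            BJ = plane_factor(moment_structure(counts).VJ)
            p_max = fmax_tail_h0(BJ, res.fJmax, counts.dfJ,
                                 settings.n_theta_closed)
            p_afj = float(f_dist.sf(fJa, 1, counts.dfJ))
            sel_max = sel_afj = True
        else:
            u1 = solve_u1(gamma, counts, settings)
            p_max, sel_max = joint_pvalue(
                res.f1max, res.fJmax, u1, counts, settings=settings
            )
            u1a = afj_solve_u1(gamma, counts)
            sel_afj = f1a > u1a
            p_afj = (
                afj_prob_joint_exceeds(u1a, fJa, counts, settings=settings)
                if sel_afj
                else 1.0
            )
        rows.append(
            {"p_maxfj": float(p_max), "p_afj": float(p_afj),
             "selected_maxfj": bool(sel_max), "selected_afj": bool(sel_afj)}
        )
    if bad > 0.1 * reps:
        raise RuntimeError(
            f"{bad}/{reps} splits were degenerate (empty genotype cells)"
        )
    out = pd.DataFrame(rows)
    with np.errstate(divide="ignore"):
        out["neglog10_p_maxfj"] = -np.log10(out["p_maxfj"])
        out["neglog10_p_afj"] = -np.log10(out["p_afj"])
    out.attrs["seed"] = seed
    out.attrs["degenerate_splits"] = bad
    return out
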