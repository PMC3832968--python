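"""Analytic power of the two-stage joint analyses (MAXFJ and AFJ).

Power is Pr_H1(F1MAX > u1, FJMAX > uJ) with thresholds calibrated under H0
for the same genotype counts.  For planning, genotype counts are the
Hardy-Weinberg expected counts at the design (n, pi, MAF); the H1 mean
vector is linear in the standardised effect beta1/sigma and depends on the
true genetic model through the genotype coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .asymptotics import hwe_expected_counts, moment_structure
from .calibration import (
    CalibSettings,
    JointCalibrator,
    Thresholds,
    afj_prob_joint_exceeds,
    afj_solve_u1,
    afj_solve_uJ,
    design_thresholds,
)
from .data import EffectSpec, GenotypeCounts

__all__ = ["PowerRequest", "PowerResult", "analytic_power", "power_table"]

#: standardised effect sizes used for the reference power grids
DEFAULT_BETA1 = {"REC": 0.5, "ADD": 0.3, "DOM": 0.4}


@dataclass(frozen=True)
class PowerRequest:
    """Design + effect specification for a power computation."""

    n: float
    pi: float
    maf: float
    gamma: float
    alpha: float
    m: float
    effect: EffectSpec
    statistic: str = "MAXFJ"
    counts_mode: str = "expected_real"  # or "expected_rounded"

    @property
    def alpha_per_snp(self) -> float:
        return self.alpha / self.m

    def counts(self) -> GenotypeCounts:
        if self.counts_mode not in ("expected_real", "expected_rounded"):
            raise ValueError(f"unknown counts_mode {self.counts_mode!r}")
        return hwe_expected_counts(
            self.n, self.pi, self.maf, rounded=self.counts_mode == "expected_rounded"
        )


@dataclass(frozen=True)
class PowerResult:
    power: float
    thresholds: Thresholds
    request: PowerRequest
    metadata: dict = field(default_factory=dict)


def analytic_power(
    req: PowerRequest,
    settings: CalibSettings | None = None,
    thresholds: Thresholds | None = None,
) -> PowerResult:
    """Power of the requested two-stage analysis at the requested design.

    Pipeline: HWE expected counts -> solve u1 at gamma -> solve uJ at
    alpha/m -> joint exceedance under the H1 mean for the true model.
    Pre-computed ``thresholds`` (same design and statistic) are reused.
    """
    settings = settings or CalibSettings()
    counts = req.counts()
    eff = req.effect
    if req.statistic == "MAXFJ":
        if thresholds is None:
            thresholds = design_thresholds(
                req.gamma, req.alpha_per_snp, counts, settings
            )
        cal = JointCalibrator(counts, effect=eff, settings=settings)
        pw = cal.region_nodes(thresholds.u1, "outside").joint_exceed(thresholds.uJ)
    elif req.statistic == "AFJ":
        if thresholds is None:
            u1 = afj_solve_u1(req.gamma, counts)
            uJ = afj_solve_uJ(req.alpha_per_snp, u1, counts, settings)
            thresholds = Thresholds(
                u1=u1,
                uJ=uJ,
                gamma=req.gamma,
                alpha_per_snp=req.alpha_per_snp,
                counts=counts,
                statistic="AFJ",
            )
        mu = moment_structure(counts, eff).mu_standardized
        pw = afj_prob_joint_exceeds(
            thresholds.u1, thresholds.uJ, counts, mu2=(mu[1], mu[4]),
            settings=settings,
        )
    else:
        raise ValueError(f"statistic must be MAXFJ or AFJ, got {req.statistic!r}")
    return PowerResult(
        power=float(pw), thresholds=thresholds, request=req,
        metadata={"beta1_over_sigma": eff.beta1 / eff.sigma},
    )


def power_table(
    n: float = 2000,
    pis=(0.3, 0.4, 0.5),
    mafs=(0.15, 0.30, 0.45),
    models=("REC", "ADD", "DOM"),
    gamma: float = 1e-4,
    alpha: float = 0.05,
    m: float = 5e5,
    beta1_map: dict | None = None,
    sigma: float = 1.0,
    settings: CalibSettings | None = None,
) -> pd.DataFrame:
    """Long-format power grid over pi x MAF x true model for AFJ and MAXFJ.

    Thresholds depend only on the design, so each (pi, MAF) cell is
    calibrated once and evaluated under all true models.
    """
    settings = settings or CalibSettings()
    beta1_map = dict(DEFAULT_BETA1 if beta1_map is None else beta1_map)
    rows = []
    for pi, maf in product(pis, mafs):
        counts = hwe_expected_counts(n, pi, maf)
        thr_max = design_thresholds(gamma, alpha / m, counts, settings)
        u1a = afj_solve_u1(gamma, counts)
        uJa = afj_solve_uJ(alpha / m, u1a, counts, settings)
        thr_afj = Thresholds(
            u1=u1a, uJ=uJa, gamma=gamma, alpha_per_snp=alpha / m,
            counts=counts, statistic="AFJ",
        )
        for model in models:
            eff = EffectSpec(model=model, beta1=beta1_map[model], sigma=sigma)
            req_max = PowerRequest(
                n=n, pi=pi, maf=maf, gamma=gamma, alpha=alpha, m=m,
                effect=eff, statistic="MAXFJ",
            )
            req_afj = PowerRequest(
                n=n, pi=pi, maf=maf, gamma=gamma, alpha=alpha, m=m,
                effect=eff, statistic="AFJ",
            )
            p_max = analytic_power(req_max, settings, thr_max).power
            p_afj = analytic_power(req_afj, settings, thr_afj).power
            rows.append(
                {
                    "pi": pi, "maf": maf, "model": model,
                    "beta1": beta1_map[model],
                    "afj_power": p_afj, "maxfj_power": p_max,
                }
            )
    return pd.DataFrame(rows)
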