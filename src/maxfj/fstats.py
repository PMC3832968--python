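"""Model-robust modified F statistics for two-stage quantitative-trait data.

For a biallelic marker tested on a two-stage cohort, the association
statistic under each genetic model (recessive / additive / dominant) is an
F ratio whose numerator is the squared model contrast ``Z^2`` of
genotype-group means and whose denominator is the residual mean square of
the *saturated* genotype-group model — a common denominator shared by the
three models:

    F1_k = Z1_k^2 / (RSS1 / (n1 - 3)),      k in {REC, ADD, DOM}
    FJ_k = ZJ_k^2 / (RSSJ / (n - 6)),

where RSS1 sums within-group squared deviations over the three stage-1
genotype groups and RSSJ over all six stage-by-genotype cells.  The robust
statistics are the maxima F1MAX = max_k F1_k and FJMAX = max_k FJ_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._contrasts import z_from_group_stats
from .data import (
    MODELS,
    DegenerateMarkerError,
    GenotypeCounts,
    StageSummaries,
    validate_subject_table,
)

__all__ = [
    "summarize",
    "stage1_z",
    "joint_z",
    "residual_ss",
    "f_statistics",
    "fmax",
    "analyze",
    "TestResult",
]


@dataclass(frozen=True)
class TestResult:
    """Per-marker two-stage test summary (triples ordered REC, ADD, DOM)."""

    z1: np.ndarray
    zJ: np.ndarray
    rss1: float
    rssJ: float
    f1: np.ndarray
    fJ: np.ndarray
    f1max: float
    fJmax: float
    model1: str
    modelJ: str


def summarize(data: pd.DataFrame) -> StageSummaries:
    """Reduce a subject-level table to per-cell counts, means and SS.

    ``data`` must have columns ``stage`` (1|2), ``genotype`` (0|1|2) and
    ``phenotype`` (float).  Cells with no subjects are flagged in
    ``empty_cells`` (statistics requiring them will refuse to compute).
    """
    data = validate_subject_table(data)
    stage = data["stage"].to_numpy().astype(np.int64)
    geno = data["genotype"].to_numpy().astype(np.int64)
    y = data["phenotype"].to_numpy().astype(float)

    idx = (stage - 1) * 3 + geno
    cnt = np.bincount(idx, minlength=6).astype(float)
    tot = np.bincount(idx, weights=y, minlength=6)
    tot2 = np.bincount(idx, weights=y * y, minlength=6)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, tot / np.where(cnt > 0, cnt, 1.0), np.nan)
        ss = np.where(cnt > 0, tot2 - tot * mean_safe(tot, cnt), 0.0)
    ss = np.maximum(ss, 0.0)  # clip roundoff negatives

    counts = GenotypeCounts(*cnt)
    empty = tuple(
        (s + 1, j) for s in range(2) for j in range(3) if cnt[s * 3 + j] == 0
    )
    return StageSummaries(
        counts=counts,
        cell_mean=mean.reshape(2, 3),
        cell_ss=ss.reshape(2, 3),
        empty_cells=empty,
    )


def mean_safe(tot: np.ndarray, cnt: np.ndarray) -> np.ndarray:
    return tot / np.where(cnt > 0, cnt, 1.0)


def stage1_z(s: StageSummaries) -> np.ndarray:
    """Stage-1 Z triple (Z1R, Z1A, Z1D) from the summaries."""
    s.counts.require_stage1()
    m = s.counts.stage1
    mu = s.stage1_means()
    return z_from_group_stats(m[0], m[1], m[2], mu[0], mu[1], mu[2])


def joint_z(s: StageSummaries) -> np.ndarray:
    """Combined-stage Z triple (ZJR, ZJA, ZJD) using pooled genotype means."""
    s.counts.require_all()
    N = s.counts.combined
    mu = s.combined_means()
    return z_from_group_stats(N[0], N[1], N[2], mu[0], mu[1], mu[2])


def residual_ss(s: StageSummaries) -> tuple[float, float]:
    """(RSS1, RSSJ): saturated-model residual sums of squares.

    RSS1 is the within-group SS over the three stage-1 genotype groups;
    RSSJ adds the stage-2 within-group SS (the joint saturated design is
    block-diagonal over the six stage-by-genotype cells), so
    RSSJ = RSS1 + RSS2 exactly.
    """
    rss1 = float(s.cell_ss[0].sum())
    rssJ = float(s.cell_ss.sum())
    return rss1, rssJ


def f_statistics(z: np.ndarray, rss: float, df: float) -> np.ndarray:
    """F triple from a Z triple and the shared residual mean square."""
    if not df > 0:
        raise ValueError(f"residual degrees of freedom must be > 0, got {df}")
    if not rss > 0:
        raise DegenerateMarkerError(
            f"residual sum of squares must be > 0 (got {rss}); "
            "the saturated fit is perfect/degenerate"
        )
    z = np.asarray(z, float)
    return z * z / (rss / df)


def fmax(f: np.ndarray) -> tuple[float, str]:
    """Maximum of the F triple and the first maximising model (REC < ADD < DOM)."""
    f = np.asarray(f, float)
    if not np.all(np.isfinite(f)):
        raise ValueError(f"F triple must be finite, got {f}")
    k = int(np.argmax(f))  # argmax returns the first maximum: the tie rule
    return float(f[k]), MODELS[k]


def analyze(data: pd.DataFrame) -> TestResult:
    """Full per-marker pipeline: summaries -> Z, RSS, F triples, maxima."""
    s = summarize(data)
    s.counts.require_all()
    z1 = stage1_z(s)
    zJ = joint_z(s)
    rss1, rssJ = residual_ss(s)
    f1 = f_statistics(z1, rss1, s.counts.df1)
    fJ = f_statistics(zJ, rssJ, s.counts.dfJ)
    f1m, m1 = fmax(f1)
    fJm, mJ = fmax(fJ)
    return TestResult(
        z1=z1, zJ=zJ, rss1=rss1, rssJ=rssJ, f1=f1, fJ=fJ,
        f1max=f1m, fJmax=fJm, model1=m1, modelJ=mJ,
    )
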