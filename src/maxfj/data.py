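"""Domain containers for two-stage quantitative-trait association data.

A *two-stage* design genotypes all markers on a fraction ``pi`` of the
cohort (stage 1) and carries promising markers forward to the remaining
subjects (stage 2).  Everything downstream is driven by the per-stage
genotype cell counts and per-cell phenotype summaries collected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODELS = ("REC", "ADD", "DOM")

#: genotype -> mean-shift coding under each true generating model
GENO_CODES = {
    "REC": np.array([0.0, 0.0, 1.0]),
    "ADD": np.array([0.0, 1.0, 2.0]),
    "DOM": np.array([0.0, 1.0, 1.0]),
}


class DegenerateMarkerError(ValueError):
    """Raised when a genotype cell required by a statistic is empty."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-stage genotype counts (gg, Gg, GG) for a biallelic marker.

    Counts may be real-valued: analytic calibration uses Hardy-Weinberg
    *expected* counts, which are generally non-integer.
    """

    n10: float
    n11: float
    n12: float
    n20: float
    n21: float
    n22: float

    def __post_init__(self) -> None:
        for name in ("n10", "n11", "n12", "n20", "n21", "n22"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"count {name}={v!r} must be finite and >= 0")

    # -- derived totals -------------------------------------------------
    @property
    def n1(self) -> float:
        return self.n10 + self.n11 + self.n12

    @property
    def n2(self) -> float:
        return self.n20 + self.n21 + self.n22

    @property
    def n(self) -> float:
        return self.n1 + self.n2

    @property
    def N0(self) -> float:
        return self.n10 + self.n20

    @property
    def N1(self) -> float:
        return self.n11 + self.n21

    @property
    def N2(self) -> float:
        return self.n12 + self.n22

    @property
    def stage1(self) -> np.ndarray:
        return np.array([self.n10, self.n11, self.n12])

    @property
    def stage2(self) -> np.ndarray:
        return np.array([self.n20, self.n21, self.n22])

    @property
    def combined(self) -> np.ndarray:
        return self.stage1 + self.stage2

    @property
    def cells(self) -> np.ndarray:
        """All six cell counts, stage-major: (1,gg),(1,Gg),(1,GG),(2,gg),(2,Gg),(2,GG)."""
        return np.concatenate([self.stage1, self.stage2])

    @property
    def df1(self) -> float:
        return self.n1 - 3

    @property
    def df2(self) -> float:
        return self.n2 - 3

    @property
    def dfJ(self) -> float:
        return self.n - 6

    # -- validation -----------------------------------------------------
    def require_stage1(self) -> None:
        if np.any(self.stage1 < 1) or self.df1 <= 0:
            raise DegenerateMarkerError(
                f"stage-1 genotype cells {tuple(self.stage1)} must all be >= 1 "
                f"with n1 - 3 > 0"
            )

    def require_all(self) -> None:
        if np.any(self.cells < 1) or self.df1 <= 0 or self.dfJ <= 0:
            raise DegenerateMarkerError(
                f"all six genotype cells {tuple(self.cells)} must be >= 1 "
                f"with n1 - 3 > 0 and n - 6 > 0"
            )

    def round(self) -> "GenotypeCounts":
        """Integer-rounded variant (for simulation with whole subjects)."""
        r = [int(np.rint(v)) for v in self.cells]
        return GenotypeCounts(*r)


@dataclass(frozen=True)
class EffectSpec:
    """True generating model for the phenotype: y = beta0 + code(g)*beta1 + N(0, sigma^2)."""

    model: str
    beta1: float
    sigma: float = 1.0
    beta0: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma!r}")

    @property
    def codes(self) -> np.ndarray:
        return GENO_CODES[self.model]


@dataclass
class StageSummaries:
    """Sufficient statistics of a subject table for the two-stage F statistics.

    ``cell_mean[s, j]`` / ``cell_ss[s, j]`` are the phenotype mean and the
    within-cell sum of squared deviations for stage ``s+1``, genotype ``j``.
    Cells with zero count carry mean NaN and ss 0.
    """

    counts: GenotypeCounts
    cell_mean: np.ndarray  # (2, 3)
    cell_ss: np.ndarray  # (2, 3)
    empty_cells: tuple = field(default_factory=tuple)

    # pooled means over combined stages (count-weighted)
    def combined_means(self) -> np.ndarray:
        """Pooled phenotype means per genotype over both stages (ybar_0, ybar_1, ybar_2)."""
        num = np.nansum(
            np.where(
                np.array([self.counts.stage1, self.counts.stage2]) > 0,
                self.cell_mean * np.array([self.counts.stage1, self.counts.stage2]),
                0.0,
            ),
            axis=0,
        )
        return num / self.counts.combined

    def stage1_means(self) -> np.ndarray:
        return self.cell_mean[0]


def validate_subject_table(data: pd.DataFrame) -> pd.DataFrame:
    """Validate a subject-level table with columns stage, genotype, phenotype."""
    required = {"stage", "genotype", "phenotype"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if len(data) == 0:
        raise ValueError("subject table is empty")
    stage = data["stage"].to_numpy()
    geno = data["genotype"].to_numpy()
    pheno = data["phenotype"].to_numpy()
    bad = ~np.isin(stage, (1, 2))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"record {i}: stage must be 1 or 2, got {stage[i]!r}")
    bad = ~np.isin(geno, (0, 1, 2))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"record {i}: genotype must be 0, 1 or 2, got {geno[i]!r}")
    if not np.all(np.isfinite(pheno.astype(float))):
        i = int(np.flatnonzero(~np.isfinite(pheno.astype(float)))[0])
        raise ValueError(f"record {i}: phenotype is not finite")
    for s in (1, 2):
        if not np.any(stage == s):
            raise ValueError(f"no records in stage {s}")
    return data
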