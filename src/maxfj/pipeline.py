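"""Per-marker association scan over a long-format multi-marker table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import CalibSettings, joint_pvalue, solve_u1
from .data import DegenerateMarkerError
from .fstats import analyze, summarize

__all__ = ["association_scan"]


def association_scan(
    data: pd.DataFrame,
    gamma: float,
    alpha_per_snp: float,
    settings: CalibSettings | None = None,
) -> pd.DataFrame:
    """Two-stage scan: stage-1 screen at gamma, joint test for survivors.

    ``data`` has columns snp_id (optional for a single marker), stage,
    genotype, phenotype.  Selection uses the F1MAX threshold u1 solved per
    marker (equivalent to the stage-1 p < gamma rule); selected markers get
    the design-conditional joint p-value and a genome-wide significance
    flag at ``alpha_per_snp``.  Degenerate markers are flagged untestable.
    """
    if "snp_id" not in data.columns:
        data = data.assign(snp_id="snp1")
    rows = []
    for snp, sub in data.groupby("snp_id", sort=True):
        row: dict = {"snp_id": snp}
        try:
            s = summarize(sub)
            s.counts.require_all()
            res = analyze(sub)
            u1 = solve_u1(gamma, s.counts, settings)
            p, selected = joint_pvalue(
                res.f1max, res.fJmax, u1, s.counts, settings=settings
            )
            row.update(
                f1max=res.f1max, model1=res.model1,
                fJmax=res.fJmax, modelJ=res.modelJ,
                u1=u1, selected=selected,
                joint_p=p, significant=bool(selected and p < alpha_per_snp),
                status="ok",
            )
        except (DegenerateMarkerError, ValueError) as exc:
            row.update(
                f1max=np.nan, model1="", fJmax=np.nan, modelJ="",
                u1=np.nan, selected=False, joint_p=np.nan,
                significant=False, status=f"untestable: {exc}",
            )
        rows.append(row)
    return pd.DataFrame(rows)
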