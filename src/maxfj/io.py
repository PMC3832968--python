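"""Delimited-text readers/writers for subject tables and per-marker results."""

from __future__ import annotations

import io as _io
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd

__all__ = ["read_subject_table", "write_results", "write_table"]

_REQUIRED = ("stage", "genotype", "phenotype")


def read_subject_table(path) -> pd.DataFrame:
    """Read a subject-level TSV/CSV with columns stage, genotype, phenotype.

    An optional ``snp_id`` column allows long-format multi-marker tables.
    Malformed records are reported with their 1-based data line number.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col, allowed in (("stage", (1, 2)), ("genotype", (0, 1, 2))):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin(allowed)
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(
                f"{path}, line {line}: {col} must be in {allowed}, "
                f"got {df[col][bad].iloc[0]!r}"
            )
        df[col] = vals.astype(np.int64)
    pheno = pd.to_numeric(df["phenotype"], errors="coerce")
    bad = ~np.isfinite(pheno)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(
            f"{path}, line {line}: phenotype is not a finite number "
            f"({df['phenotype'][bad].iloc[0]!r})"
        )
    df["phenotype"] = pheno.astype(float)
    return df


def _fmt(v):
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    return str(v)


def write_results(results: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write per-marker results as TSV with ``#``-prefixed metadata lines.

    Floats are rendered at 6 significant digits; output bytes are a
    deterministic function of the inputs.
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    buf = _io.StringIO()
    meta = dict(metadata or {})
    for k in sorted(meta):
        v = meta[k]
        if is_dataclass(v):
            v = asdict(v)
        buf.write(f"# {k}: {v}\n")
    buf.write("\t".join(results.columns) + "\n")
    for _, row in results.iterrows():
        buf.write("\t".join(_fmt(v) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
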