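"""Model-specific contrast coefficients on genotype-group phenotype means.

Each Z statistic is a linear contrast ``sum_j c_j * ybar_j`` of the three
genotype-group means, with coefficients normalised so that Var(Z) = sigma^2
when Var(ybar_j) = sigma^2 / m_j and the groups are independent.  That
normalisation pins down every statistic unambiguously and is the single
source from which the correlation matrices and noncentrality means of the
whole package are derived.

All functions broadcast over leading dimensions of the count arrays.
"""

from __future__ import annotations

import numpy as np


def model_contrasts(m0, m1, m2):
    """Contrast coefficients for the REC, ADD, DOM statistics.

    Parameters
    ----------
    m0, m1, m2 : array_like
        Genotype-group sizes (gg, Gg, GG); broadcastable, real-valued.

    Returns
    -------
    ndarray, shape (..., 3, 3)
        ``out[..., k, j]`` is the coefficient of group-``j`` mean in the
        statistic for model ``k`` (order REC, ADD, DOM).  Rows sum to zero
        and satisfy ``sum_j c_kj^2 / m_j = 1``.
    """
    m0, m1, m2 = np.broadcast_arrays(
        np.asarray(m0, float), np.asarray(m1, float), np.asarray(m2, float)
    )
    M = m0 + m1 + m2
    out = np.empty(m0.shape + (3, 3))

    # recessive: contrast of pooled (gg, Gg) mean against GG mean
    s = np.sqrt((m0 + m1) * m2 / M)
    out[..., 0, 0] = s * m0 / (m0 + m1)
    out[..., 0, 1] = s * m1 / (m0 + m1)
    out[..., 0, 2] = -s

    # additive: allele-dosage trend contrast
    K = m0 * (m1 + 4.0 * m2) + m1 * m2
    denom = np.sqrt(M * K)
    out[..., 1, 0] = m0 * (m1 + 2.0 * m2) / denom
    out[..., 1, 1] = -m1 * (m0 - m2) / denom
    out[..., 1, 2] = -m2 * (2.0 * m0 + m1) / denom

    # dominant: contrast of gg mean against pooled (Gg, GG) mean
    s = np.sqrt(m0 * (m1 + m2) / M)
    out[..., 2, 0] = s
    out[..., 2, 1] = -s * m1 / (m1 + m2)
    out[..., 2, 2] = -s * m2 / (m1 + m2)
    return out


def z_from_group_stats(m0, m1, m2, mean0, mean1, mean2):
    """Z triple (REC, ADD, DOM) from group counts and group phenotype means."""
    C = model_contrasts(m0, m1, m2)
    means = np.stack(np.broadcast_arrays(
        np.asarray(mean0, float), np.asarray(mean1, float), np.asarray(mean2, float)
    ), axis=-1)
    return np.einsum("...kj,...j->...k", C, means)
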