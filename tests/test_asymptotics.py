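"""Moment-structure tests: printed correlation/mean formulas, HWE counts,
positive semidefiniteness, and empirical (simulation) verification."""

import numpy as np
import pytest

from maxfj.asymptotics import (
    coefficient_matrix,
    corr_joint,
    corr_stage1,
    cross_corr,
    hwe_expected_counts,
    mean_vector,
    moment_structure,
    residual_laws,
)
from maxfj.data import EffectSpec, GenotypeCounts


def _v_entries(m0, m1, m2):
    """Correlation entries of a Z triple as published (independent typing)."""
    K = m0 * (m1 + 4 * m2) + m1 * m2
    v12 = (2 * m0 + m1) * np.sqrt(m2 / ((m0 + m1) * K))
    v13 = np.sqrt(m0 * m2 / ((m0 + m1) * (m1 + m2)))
    v23 = (2 * m2 + m1) * np.sqrt(m0 / ((m1 + m2) * K))
    return v12, v13, v23


def _rho_entries(c: GenotypeCounts):
    n10, n11, n12 = c.stage1
    N0, N1, N2 = c.combined
    n1, n = c.n1, c.n
    K1 = n10 * (n11 + 4 * n12) + n11 * n12
    KJ = N0 * (N1 + 4 * N2) + N1 * N2
    rho = np.empty((3, 3))
    rho[0, 0] = np.sqrt(n * (n10 + n11) * n12 / (n1 * (N0 + N1) * N2))
    rho[0, 1] = np.sqrt(n / (n1 * (n10 + n11) * KJ)) * n12 * (2 * n10 + n11)
    rho[0, 2] = np.sqrt(n * n12 * n10 / (n1 * (n10 + n11) * N0 * (N1 + N2))) * np.sqrt(n12)
    rho[1, 0] = np.sqrt(n / (n1 * K1 * (N0 + N1) * N2)) * n12 * (2 * n10 + n11)
    rho[1, 1] = np.sqrt(n * K1 / (n1 * KJ))
    rho[1, 2] = np.sqrt(n / (n1 * K1 * N0 * (N1 + N2))) * n10 * (n11 + 2 * n12)
    rho[2, 0] = np.sqrt(n * n10 * n12 / (n1 * (n11 + n12) * (N0 + N1) * N2)) * np.sqrt(n12)
    rho[2, 1] = np.sqrt(n / (n1 * (n11 + n12) * KJ)) * n10 * (n11 + 2 * n12)
    rho[2, 2] = np.sqrt(n * n10 * (n11 + n12) / (n1 * N0 * (N1 + N2)))
    return rho


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_correlations_match_published_formulas(seed):
    rng = np.random.default_rng(seed)
    c = GenotypeCounts(*rng.integers(5, 500, size=6).astype(float))
    V1 = corr_stage1(c)
    v12, v13, v23 = _v_entries(*c.stage1)
    np.testing.assert_allclose(np.diag(V1), 1.0, atol=1e-12)
    np.testing.assert_allclose(
        [V1[0, 1], V1[0, 2], V1[1, 2]], [v12, v13, v23], rtol=1e-12
    )
    VJ = corr_joint(c)
    v12j, v13j, v23j = _v_entries(*c.combined)
    np.testing.assert_allclose(
        [VJ[0, 1], VJ[0, 2], VJ[1, 2]], [v12j, v13j, v23j], rtol=1e-12
    )


def test_cross_correlation_diagonal_formulas():
    rng = np.random.default_rng(5)
    for _ in range(3):
        c = GenotypeCounts(*rng.integers(5, 500, size=6).astype(float))
        rho = cross_corr(c)
        oracle = _rho_entries(c)
        # the three same-model diagonal entries (unambiguous rendering)
        np.testing.assert_allclose(np.diag(rho), np.diag(oracle), rtol=1e-12)
        assert np.all(rho > 0) and np.all(rho <= 1 + 1e-12)


def test_cross_corr_worked_example():
    c = GenotypeCounts(10, 20, 10, 10, 20, 10)
    rho = cross_corr(c)
    assert rho[2, 2] == pytest.approx(np.sqrt(0.5), rel=1e-12)
    assert rho[0, 0] == pytest.approx(np.sqrt(0.5), rel=1e-12)


def test_equal_counts_v13_is_half():
    c = GenotypeCounts(7, 7, 7, 3, 3, 3)
    assert corr_stage1(c)[0, 2] == pytest.approx(0.5, rel=1e-12)
    ceq = GenotypeCounts(5, 5, 5, 5, 5, 5)
    assert corr_joint(ceq)[0, 2] == pytest.approx(0.5, rel=1e-12)


def test_mean_vector_formulas_and_scaling():
    rng = np.random.default_rng(9)
    c = GenotypeCounts(*rng.integers(10, 400, size=6).astype(float))
    n10, n11, n12 = c.stage1
    N0, N1, N2 = c.combined
    b1 = 0.37
    mu = mean_vector(EffectSpec("REC", b1), c)
    assert mu[0] == pytest.approx(-np.sqrt((n10 + n11) * n12 / c.n1) * b1)
    K1 = n10 * (n11 + 4 * n12) + n11 * n12
    assert mu[1] == pytest.approx(-n12 * (2 * n10 + n11) * b1 / np.sqrt(c.n1 * K1))
    assert mu[3] == pytest.approx(-np.sqrt((N0 + N1) * N2 / c.n) * b1)
    muA = mean_vector(EffectSpec("ADD", b1), c)
    assert muA[1] == pytest.approx(-np.sqrt(K1 / c.n1) * b1)
    muD = mean_vector(EffectSpec("DOM", b1), c)
    assert muD[2] == pytest.approx(-np.sqrt(n10 * (n11 + n12) / c.n1) * b1)
    # zero iff beta1 = 0; linear in beta1
    assert np.all(mean_vector(EffectSpec("ADD", 0.0), c) == 0)
    np.testing.assert_allclose(
        mean_vector(EffectSpec("DOM", 2 * b1), c), 2 * muD, rtol=1e-12
    )
    # standardisation: power depends on beta1/sigma only
    ms = moment_structure(c, EffectSpec("DOM", b1, sigma=2.0))
    np.testing.assert_allclose(ms.mu_standardized, muD / 2.0, rtol=1e-12)


def test_identical_stage_compositions_joint_equals_pooled():
    c = GenotypeCounts(12, 30, 8, 12, 30, 8)
    mu = mean_vector(EffectSpec("ADD", 0.4), c)
    pooled = GenotypeCounts(24, 60, 16, 1, 1, 1)  # stage-1 part = combined
    mu1_pooled = mean_vector(EffectSpec("ADD", 0.4), pooled)[:3]
    np.testing.assert_allclose(mu[3:], mu1_pooled, rtol=1e-12)


def test_sigma6_psd_random_grid(random_counts_factory):
    for _ in range(30):
        c = random_counts_factory()
        ms = moment_structure(c)
        w = np.linalg.eigvalsh(ms.sigma6)
        assert w.min() >= -1e-10
        assert np.all(np.abs(ms.sigma6) <= 1 + 1e-12)
        np.testing.assert_allclose(np.diag(ms.sigma6), 1.0, atol=1e-12)


def test_residual_laws():
    c = hwe_expected_counts(2000, 0.3, 0.3)
    df1, df2, dfJ = residual_laws(c)
    assert (df1, df2, dfJ) == (597, 1397, 1994)
    assert dfJ == df1 + df2
    with pytest.raises(ValueError):
        residual_laws(GenotypeCounts(1, 1, 1, 5, 5, 5))


def test_hwe_expected_counts():
    c = hwe_expected_counts(2000, 0.4, 0.3)
    np.testing.assert_allclose(c.stage1, [392, 336, 72], rtol=1e-12)
    np.testing.assert_allclose(c.combined, [980, 840, 180], rtol=1e-12)
    assert c.n1 == pytest.approx(800) and c.n2 == pytest.approx(1200)
    c5 = hwe_expected_counts(100, 0.5, 0.5)
    np.testing.assert_allclose(c5.stage1 / c5.n1, [0.25, 0.5, 0.25], rtol=1e-12)
    r = hwe_expected_counts(2000, 0.4, 0.3, rounded=True)
    assert all(float(v).is_integer() for v in r.cells)
    with pytest.raises(ValueError):
        hwe_expected_counts(100, 0.0, 0.3)
    with pytest.raises(ValueError):
        hwe_expected_counts(100, 0.4, 0.7)


def _simulate_z(rng, c, effect, reps):
    """Data-level simulation of the six Z's and the two RSS (fixed counts)."""
    from maxfj._contrasts import z_from_group_stats

    cells = c.cells.astype(int)
    code = np.tile(effect.codes, 2)
    means = np.empty((reps, 6))
    rss = np.zeros((reps, 2))
    for j, m in enumerate(cells):
        y = (
            effect.beta1 * code[j]
            + effect.sigma * rng.standard_normal((reps, m))
        )
        means[:, j] = y.mean(axis=1)
        rss[:, 0 if j < 3 else 1] += (
            (y - means[:, j][:, None]) ** 2
        ).sum(axis=1)
    c1 = cells[:3]
    N = cells[:3] + cells[3:]
    pooled = (cells[:3] * means[:, :3] + cells[3:] * means[:, 3:]) / N
    z1 = z_from_group_stats(
        c1[0], c1[1], c1[2], means[:, 0], means[:, 1], means[:, 2]
    )
    zJ = z_from_group_stats(
        N[0], N[1], N[2], pooled[:, 0], pooled[:, 1], pooled[:, 2]
    )
    return np.hstack([z1, zJ]), rss


@pytest.mark.parametrize("model", ["REC", "ADD", "DOM"])
def test_empirical_moments_match_structure(model):
    """Simulated Z mean/covariance match mu and sigma6 within 4 MC SE."""
    rng = np.random.default_rng(hash(model) % 2**31)
    c = hwe_expected_counts(400, 0.4, 0.3, rounded=True)
    eff = EffectSpec(model, 0.4)
    reps = 30_000
    Z, rss = _simulate_z(rng, c, eff, reps)
    ms = moment_structure(c, eff)
    se_mean = 1.0 / np.sqrt(reps)
    assert np.all(np.abs(Z.mean(axis=0) - ms.mu) < 4 * se_mean + 4e-3)
    emp_cov = np.cov(Z.T)
    se_cov = 2.5 / np.sqrt(reps)  # conservative entrywise SE for unit-scale cov
    assert np.max(np.abs(emp_cov - ms.sigma6)) < 4 * se_cov
    # independence of Z's and residual sums of squares
    for k in range(6):
        for j in range(2):
            r = np.corrcoef(Z[:, k], rss[:, j])[0, 1]
            assert abs(r) < 4 / np.sqrt(reps)
    # residual chi-square means
    assert rss[:, 0].mean() == pytest.approx(c.df1, rel=0.02)
    assert rss[:, 1].mean() == pytest.approx(c.df2, rel=0.02)
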