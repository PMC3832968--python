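"""Threshold calibration tests: round-trips, monotonicity, Monte-Carlo
agreement at relaxed levels, p-value contracts, and the AFJ comparator."""

import numpy as np
import pytest
from scipy.stats import f as f_dist

from maxfj.asymptotics import coefficient_matrix, hwe_expected_counts, moment_structure
from maxfj.calibration import (
    CalibSettings,
    afj_prob_joint_exceeds,
    afj_solve_u1,
    afj_solve_uJ,
    design_thresholds,
    joint_pvalue,
    prob_f1max_exceeds,
    prob_fjmax_exceeds,
    prob_joint_exceeds,
    prob_joint_eq12,
    solve_u1,
    solve_uJ,
)
from maxfj.data import EffectSpec

COUNTS = hwe_expected_counts(2000, 0.4, 0.3)


def _mc_joint(u1, uJ, counts, mu=np.zeros(6), reps=1_000_000, seed=1, afj=False):
    """Plug-in Monte-Carlo on the asymptotic law (chi-square mixed)."""
    rng = np.random.default_rng(seed)
    A = coefficient_matrix(counts) / np.sqrt(counts.cells)
    hits_a = hits_j = 0
    B = 4
    for _ in range(B):
        x = rng.standard_normal((reps // B, 6))
        Z = x @ A.T + mu
        S1 = rng.chisquare(counts.df1, reps // B)
        S2 = rng.chisquare(counts.df2, reps // B)
        F1 = Z[:, :3] ** 2 / (S1 / counts.df1)[:, None]
        FJ = Z[:, 3:] ** 2 / ((S1 + S2) / counts.dfJ)[:, None]
        if afj:
            f1m, fJm = F1[:, 1], FJ[:, 1]
        else:
            f1m, fJm = F1.max(axis=1), FJ.max(axis=1)
        hits_a += np.sum(f1m > u1)
        hits_j += np.sum((f1m > u1) & (fJm > uJ))
    return hits_a / reps, hits_j / reps


def test_solve_u1_roundtrip_and_bracket():
    for gamma in (0.05, 1e-3, 1e-4):
        u1 = solve_u1(gamma, COUNTS)
        p = prob_f1max_exceeds(u1, COUNTS)
        assert abs(p - gamma) / gamma < 1e-3
        # max of three >= any single model statistic
        assert u1 > f_dist.isf(gamma, 1, COUNTS.df1)
        assert u1 < f_dist.isf(gamma / 3, 1, COUNTS.df1)


def test_u1_monotone_decreasing_in_gamma():
    gammas = [0.2, 0.05, 0.01, 1e-3]
    us = [solve_u1(g, COUNTS) for g in gammas]
    assert all(a < b for a, b in zip(us, us[1:]))
    assert solve_u1(0.999, COUNTS) < 0.01  # near-certain screen -> tiny cutoff


def test_prob_f1max_boundaries_and_monotone():
    assert prob_f1max_exceeds(0.0, COUNTS) == 1.0
    vals = [prob_f1max_exceeds(u, COUNTS) for u in (1.0, 5.0, 10.0, 20.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 1e-3


def test_joint_roundtrip_and_mc_relaxed():
    """gamma=0.01, alpha=0.001: round-trips and 1e6-rep MC within 3 SE."""
    gamma, alpha = 0.01, 1e-3
    u1 = solve_u1(gamma, COUNTS)
    uJ = solve_uJ(alpha, u1, COUNTS)
    pj = prob_joint_exceeds(u1, uJ, COUNTS)
    assert abs(pj - alpha) / alpha < 1e-3
    ea, ej = _mc_joint(u1, uJ, COUNTS)
    assert abs(ea - gamma) < 3 * np.sqrt(gamma * (1 - gamma) / 1e6)
    assert abs(ej - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / 1e6)


def test_joint_nested_in_marginals():
    u1 = solve_u1(0.01, COUNTS)
    for uJ in (2.0, 8.0, 15.0):
        pj = prob_joint_exceeds(u1, uJ, COUNTS)
        assert pj <= prob_f1max_exceeds(u1, COUNTS) + 1e-9
        assert pj <= prob_fjmax_exceeds(uJ, COUNTS) + 1e-4
    # uJ = 0 reduces to the stage-1 exceedance
    assert prob_joint_exceeds(u1, 0.0, COUNTS) == pytest.approx(0.01, rel=1e-3)
    assert prob_joint_exceeds(0.0, 0.0, COUNTS) == pytest.approx(1.0, rel=1e-6)


def test_uj_monotone_and_nesting_in_gamma():
    alpha = 1e-3
    uJs = []
    for gamma in (0.005, 0.02, 0.08):
        u1 = solve_u1(gamma, COUNTS)
        uJs.append(solve_uJ(alpha, u1, COUNTS))
    # weaker screen (larger gamma) admits more of the joint event, so the
    # joint cutoff must rise to hold the same alpha
    assert all(a <= b + 1e-9 for a, b in zip(uJs, uJs[1:]))
    u1 = solve_u1(0.01, COUNTS)
    ua = [solve_uJ(a, u1, COUNTS) for a in (2e-4, 1e-3, 5e-3)]
    assert all(x > y for x, y in zip(ua, ua[1:]))


def test_solve_uj_rejects_bad_alpha():
    u1 = solve_u1(0.01, COUNTS)
    with pytest.raises(ValueError):
        solve_uJ(0.02, u1, COUNTS)  # alpha above the screen level


def test_eq12_crosscheck_relaxed():
    st = CalibSettings(n_s1=20, n_s2=5, n_arc=72, n_theta=5, n_rad_upper=10,
                       n_rad_lower=8, edge_nodes=14)
    gamma, alpha = 0.05, 0.005
    u1 = solve_u1(gamma, COUNTS, st)
    uJ = solve_uJ(alpha, u1, COUNTS, st)
    direct = prob_joint_exceeds(u1, uJ, COUNTS, settings=st)
    via12 = prob_joint_eq12(u1, uJ, COUNTS, settings=st)
    assert via12 == pytest.approx(direct, rel=0.05)


def test_h1_stage1_exceedance_matches_mc():
    """Stage-1 F1MAX exceedance under a nonzero mean vector vs simulation."""
    mu = moment_structure(COUNTS, EffectSpec("DOM", 0.15)).mu_standardized
    rng = np.random.default_rng(31)
    A = coefficient_matrix(COUNTS) / np.sqrt(COUNTS.cells)
    reps = 400_000
    Z = rng.standard_normal((reps, 6)) @ A.T + mu
    S1 = rng.chisquare(COUNTS.df1, reps)
    f1m = (Z[:, :3] ** 2 / (S1 / COUNTS.df1)[:, None]).max(axis=1)
    for u in (6.0, 10.0):
        p = prob_f1max_exceeds(u, COUNTS, mu=mu)
        b = (f1m > u).mean()
        assert p == pytest.approx(b, abs=4 * np.sqrt(b * (1 - b) / reps))


def test_h1_joint_matches_mc():
    mu = moment_structure(COUNTS, EffectSpec("REC", 0.2)).mu_standardized
    u1 = solve_u1(0.01, COUNTS)
    uJ = solve_uJ(1e-3, u1, COUNTS)
    p = prob_joint_exceeds(u1, uJ, COUNTS, mu=mu)
    _, ej = _mc_joint(u1, uJ, COUNTS, mu=mu, seed=7)
    assert p == pytest.approx(ej, abs=4 * np.sqrt(ej * (1 - ej) / 1e6))


def test_joint_pvalue_contracts():
    gamma = 1e-3
    u1 = solve_u1(gamma, COUNTS)
    # marker failing the screen
    p, sel = joint_pvalue(u1 * 0.5, 30.0, u1, COUNTS)
    assert p == 1.0 and not sel
    # boundary: fJ_obs = 0 recovers the screen level
    p0, sel = joint_pvalue(u1 * 2, 0.0, u1, COUNTS)
    assert sel and p0 == pytest.approx(gamma, rel=1e-3)
    # monotone decreasing in fJ_obs
    ps = [joint_pvalue(u1 * 2, fj, u1, COUNTS)[0] for fj in (5.0, 10.0, 20.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))
    # consistency: p at fJ_obs = uJ equals alpha_per_snp
    uJ = solve_uJ(1e-4, u1, COUNTS)
    p_at_uJ, _ = joint_pvalue(u1 * 2, uJ, u1, COUNTS)
    assert p_at_uJ == pytest.approx(1e-4, rel=1e-3)
    # observed-pair definition monotone in f1_obs as well
    pa = joint_pvalue(u1 * 1.5, 10.0, u1, COUNTS, definition="observed")[0]
    pb = joint_pvalue(u1 * 3.0, 10.0, u1, COUNTS, definition="observed")[0]
    assert pa > pb


def test_afj_u1_below_maxfj_u1():
    for gamma in (0.01, 1e-3):
        assert afj_solve_u1(gamma, COUNTS) < solve_u1(gamma, COUNTS)
    assert afj_solve_u1(0.9999, COUNTS) < 1e-4


def test_afj_joint_roundtrip_and_mc():
    gamma, alpha = 0.01, 1e-3
    u1 = afj_solve_u1(gamma, COUNTS)
    uJ = afj_solve_uJ(alpha, u1, COUNTS)
    p = afj_prob_joint_exceeds(u1, uJ, COUNTS)
    assert abs(p - alpha) / alpha < 1e-3
    ea, ej = _mc_joint(u1, uJ, COUNTS, afj=True, seed=3)
    assert abs(ea - gamma) < 3 * np.sqrt(gamma / 1e6)
    assert abs(ej - alpha) < 3 * np.sqrt(alpha / 1e6)
    # H1 means
    mu = moment_structure(COUNTS, EffectSpec("ADD", 0.1)).mu_standardized
    ph1 = afj_prob_joint_exceeds(u1, uJ, COUNTS, mu2=(mu[1], mu[4]))
    _, ejh1 = _mc_joint(u1, uJ, COUNTS, mu=mu, afj=True, seed=5)
    assert ph1 == pytest.approx(ejh1, abs=4 * np.sqrt(ejh1 * (1 - ejh1) / 1e6))


def test_design_thresholds_metadata():
    thr = design_thresholds(0.01, 1e-3, COUNTS)
    assert thr.u1 > 0 and thr.uJ > 0
    assert thr.achieved_gamma == pytest.approx(0.01, rel=1e-3)
    assert thr.achieved_alpha == pytest.approx(1e-3, rel=1e-3)
    assert "settings" in thr.metadata


def test_plug_in_mode_close_at_large_df():
    st = CalibSettings(plug_in=True)
    u1 = solve_u1(0.01, COUNTS)
    p_exact = prob_joint_exceeds(u1, 8.0, COUNTS)
    p_plug = prob_joint_exceeds(u1, 8.0, COUNTS, settings=st)
    assert p_plug == pytest.approx(p_exact, rel=0.15)
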