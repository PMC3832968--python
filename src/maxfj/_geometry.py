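"""Low-dimensional Gaussian geometry kernels for tail calibration.

Each stage's Z triple consists of three sum-to-zero contrasts of three
group means, so it lives on a 2-plane: Z/sigma = B w (+ mean), w ~ N2(0, I)
with B a 3x2 factor.  Consequently

* ``max_k |Z_k| > a`` is the event that w falls outside a (centred or
  shifted) hexagon — the intersection of three bands ``|b_k . w + c_k| <= a``;
* every exceedance probability reduces to 1-D angular integrals and 2-D
  Gaussian measures of convex polygons.

These kernels are exact up to quadrature error and remain well conditioned
at the 1e-7 probability scale, where differencing large rectangle
probabilities would lose every significant digit.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import ndtr
from scipy.stats import chi2

TWOPI = 2.0 * np.pi


@lru_cache(maxsize=None)
def _gl(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on [-1, 1]."""
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


@lru_cache(maxsize=None)
def _glag(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Laguerre nodes/weights for integral of exp(-t) g(t) on (0, inf)."""
    x, w = np.polynomial.laguerre.laggauss(n)
    return x, w


def plane_factor(V: np.ndarray) -> np.ndarray:
    """Rank-2 factor B (3x2) with V = B B' for a unit-diagonal rank-2 matrix."""
    lam, U = np.linalg.eigh(np.asarray(V, float))
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order[:2]], 0.0, None)
    return U[:, order[:2]] * np.sqrt(lam)


def max_coef(B: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """M(theta) = max_k |b_k . u(theta)| for directions u = (cos, sin)."""
    u = np.stack([np.cos(theta), np.sin(theta)], axis=-1)  # (..., 2)
    return np.max(np.abs(u @ np.asarray(B, float).T), axis=-1)


def centered_max_tail(B: np.ndarray, a: float, n_theta: int = 4096) -> float:
    """P(max_k |b_k . w| > a), w ~ N2(0, I), for a centred band triple.

    Along the ray at angle theta the complement (all three bands hold) is
    r <= a / M(theta); integrating the radial Gaussian tail gives an exact
    1-D angular integral.  M has period pi.
    """
    theta = (np.arange(n_theta) + 0.5) * (np.pi / n_theta)
    M = max_coef(B, theta)
    return float(np.mean(np.exp(-0.5 * (a / M) ** 2)))


def fmax_tail_h0(B: np.ndarray, u: float, df: float, n_theta: int = 8192) -> float:
    """P(max_k Z_k^2 / (S/df) > u) under H0 with S ~ chi2(df) independent.

    The chi-square mixture integrates in closed form:
    E[exp(-u S / (2 df M^2))] = (1 + u / (df M^2))^(-df/2), leaving a single
    angular quadrature.  ``df=inf`` gives the plug-in (S/df == 1) limit.
    """
    if u <= 0:
        return 1.0
    theta = (np.arange(n_theta) + 0.5) * (np.pi / n_theta)
    M2 = max_coef(B, theta) ** 2
    if np.isinf(df):
        vals = np.exp(-0.5 * u / M2)
    else:
        vals = np.exp(-0.5 * df * np.log1p(u / (df * M2)))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Gaussian measure of the intersection of three bands (a convex polygon)
# ---------------------------------------------------------------------------

_PAIRS = ((0, 1), (0, 2), (1, 2))
_SIGNS = ((1, 1), (1, -1), (-1, 1), (-1, -1))


def band_polygon_prob(
    G: np.ndarray, c: np.ndarray, a: np.ndarray, edge_nodes: int = 12
) -> np.ndarray:
    """P(|G_l . v + c_l| <= a for l = 0, 1, 2), v ~ N2(0, I), vectorised.

    Parameters
    ----------
    G : (3, 2) array — band normals, shared across samples, pairwise
        linearly independent (the intersection is then a bounded convex
        polygon with at most six vertices).
    c : (N, 3) array — band centre offsets per sample.
    a : (N,) array or scalar — band half-width per sample (>= 0).

    The polygon vertices are intersections of band boundary lines; the
    Gaussian measure is a signed fan of origin-anchored triangles, each an
    exact 1-D angular integral evaluated by Gauss-Legendre.
    """
    G = np.asarray(G, float)
    c = np.atleast_2d(np.asarray(c, float))
    N = c.shape[0]
    a = np.broadcast_to(np.asarray(a, float), (N,)).astype(float)

    # boundary-line intersections: 3 pairs x 4 sign combinations
    inv = np.empty((3, 2, 2))
    ok_pair = np.empty(3, dtype=bool)
    for p, (l, m) in enumerate(_PAIRS):
        A2 = np.array([G[l], G[m]])
        det = A2[0, 0] * A2[1, 1] - A2[0, 1] * A2[1, 0]
        ok_pair[p] = abs(det) > 1e-12 * (np.abs(A2).max() ** 2 + 1e-300)
        inv[p] = (
            np.array([[A2[1, 1], -A2[0, 1]], [-A2[1, 0], A2[0, 0]]]) / det
            if ok_pair[p]
            else np.zeros((2, 2))
        )
    if ok_pair.sum() < 2:
        raise ValueError("band normals are collinear; polygon machinery needs rank 2")

    cand = np.empty((N, 12, 2))
    valid = np.zeros((N, 12), dtype=bool)
    k = 0
    for p, (l, m) in enumerate(_PAIRS):
        for s1, s2 in _SIGNS:
            rhs = np.stack([s1 * a - c[:, l], s2 * a - c[:, m]], axis=-1)
            cand[:, k] = rhs @ inv[p].T
            valid[:, k] = ok_pair[p]
            k += 1

    # keep candidates satisfying all three bands (tolerant: a missed true
    # vertex corrupts the polygon, an extra near-boundary one adds ~0 area)
    tol = 1e-7 * (1.0 + a)[:, None, None]
    resid = np.abs(np.einsum("lk,nik->nil", G, cand) + c[:, None, :])
    valid &= np.all(resid <= a[:, None, None] + tol, axis=-1)

    nv = valid.sum(axis=1)
    out = np.zeros(N)
    use = nv >= 3
    if not np.any(use):
        return out if out.shape != () else float(out)

    candu = cand[use]
    validu = valid[use]
    # order vertices by angle around the centroid of the feasible set
    cent = np.where(
        validu[:, :, None], candu, 0.0
    ).sum(axis=1) / nv[use][:, None]
    ang = np.arctan2(
        candu[:, :, 1] - cent[:, None, 1], candu[:, :, 0] - cent[:, None, 0]
    )
    ang = np.where(validu, ang, np.inf)
    order = np.argsort(ang, axis=1)
    idx = np.arange(len(candu))[:, None]
    verts = candu[idx, order]  # invalid ones pushed to the end
    V = nv[use]

    xg, wg = _gl(edge_nodes)
    maxv = 6  # three bands -> at most six polygon vertices
    total = np.zeros(len(candu))
    Vc = np.minimum(V, maxv)
    for i in range(maxv):
        has = Vc > i
        p0 = verts[:, i]
        nxt = np.where(has, (i + 1) % Vc, 0)
        p1 = verts[idx[:, 0], nxt]
        seg = p1 - p0
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        good = has & (seglen > 1e-12)
        th0 = np.arctan2(p0[:, 1], p0[:, 0])
        th1 = np.arctan2(p1[:, 1], p1[:, 0])
        dth = th1 - th0
        dth = (dth + np.pi) % TWOPI - np.pi  # wrap to (-pi, pi]
        # edge line in normal form: nrm . x = d
        nrm = np.stack([-seg[:, 1], seg[:, 0]], axis=-1) / np.maximum(
            seglen, 1e-300
        )[:, None]
        d = np.einsum("nj,nj->n", nrm, p0)
        theta = th0[:, None] + dth[:, None] * (xg[None, :] + 1.0) / 2.0
        cosproj = nrm[:, 0, None] * np.cos(theta) + nrm[:, 1, None] * np.sin(theta)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            R2 = (d[:, None] / cosproj) ** 2
        f = np.exp(-0.5 * np.where(np.isfinite(R2), R2, np.inf))
        integral = (dth / 2.0) * np.einsum("nk,k->n", f, wg)
        total += np.where(good, (dth - integral) / TWOPI, 0.0)

    out[use] = np.clip(total, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# bivariate normal upper orthant (Genz / Drezner-Wesolowsky)
# ---------------------------------------------------------------------------

_BVN_X = np.array([
    0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
    0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
    0.5108670019508271, 0.3737060887154195, 0.2277858511416451,
    0.07652652113349734,
])
_BVN_W = np.array([
    0.01761400713915212, 0.04060142980038694, 0.06267204833410907,
    0.08327674157670475, 0.10193011981724044, 0.11819453196151842,
    0.13168863844917663, 0.14209610931838205, 0.14917298647260375,
    0.15275338713072585,
])


def bvn_upper(h, k, r):
    """P(X > h, Y > k) for standard bivariate normal with correlation r.

    Vectorised port of Genz's BVND (20-point Gauss-Legendre branch for
    |r| < 0.925, asymptotic-expansion branch otherwise); absolute accuracy
    about 1e-15 — small orthant tails come out with full relative accuracy,
    which is what makes 1e-7-scale joint levels computable.
    """
    h, k, r = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(r, float)
    )
    shape = h.shape
    h, k, r = h.ravel(), k.ravel(), r.ravel()
    out = np.zeros_like(h)

    x = np.concatenate([1.0 - _BVN_X, 1.0 + _BVN_X]) / 2.0  # nodes in (0,1)
    w = np.concatenate([_BVN_W, _BVN_W]) / 2.0

    lo = np.abs(r) < 0.925
    if np.any(lo):
        hh, kk, rr = h[lo], k[lo], r[lo]
        hs = (hh * hh + kk * kk) / 2.0
        hk = hh * kk
        asr = np.arcsin(rr)
        sn = np.sin(asr[:, None] * x[None, :])
        vals = np.exp((sn * hk[:, None] - hs[:, None]) / (1.0 - sn * sn))
        out[lo] = (asr / TWOPI) * (vals @ w) + ndtr(-hh) * ndtr(-kk)

    hi = ~lo
    if np.any(hi):
        hh, kk, rr = h[hi].copy(), k[hi].copy(), r[hi]
        neg = rr < 0
        kk[neg] = -kk[neg]
        hk = hh * kk
        bvn = np.zeros_like(hh)
        ninf = np.abs(rr) < 1.0
        if np.any(ninf):
            hn, kn, rn = hh[ninf], kk[ninf], np.abs(rr[ninf])
            hkn = hn * kn
            as_ = (1.0 - rn) * (1.0 + rn)
            aa = np.sqrt(as_)
            bs = (hn - kn) ** 2
            cc = (4.0 - hkn) / 8.0
            dd = (12.0 - hkn) / 16.0
            asr = -(bs / as_ + hkn) / 2.0
            b = np.zeros_like(hn)
            m = asr > -100.0
            b[m] = (
                aa[m]
                * np.exp(asr[m])
                * (
                    1.0
                    - cc[m] * (bs[m] - as_[m]) * (1.0 - dd[m] * bs[m] / 5.0) / 3.0
                    + cc[m] * dd[m] * as_[m] * as_[m] / 5.0
                )
            )
            m = -hkn < 100.0
            sb = np.sqrt(bs)
            b[m] -= (
                np.exp(-hkn[m] / 2.0)
                * np.sqrt(TWOPI)
                * ndtr(-sb[m] / aa[m])
                * sb[m]
                * (1.0 - cc[m] * bs[m] * (1.0 - dd[m] * bs[m] / 5.0) / 3.0)
            )
            ah = aa / 2.0
            xs = (ah[:, None] * x[None, :] * 2.0) ** 2
            rs = np.sqrt(1.0 - xs)
            asr2 = -(bs[:, None] / xs + hkn[:, None]) / 2.0
            with np.errstate(over="ignore"):
                term = np.where(
                    asr2 > -100.0,
                    ah[:, None]
                    * np.exp(asr2)
                    * (
                        np.exp(-hkn[:, None] * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
                        - (1.0 + cc[:, None] * xs * (1.0 + dd[:, None] * xs))
                    ),
                    0.0,
                )
            b += 2.0 * (term @ w)
            bvn[ninf] = -b / TWOPI
        pos = ~neg
        bvn[pos] += ndtr(-np.maximum(hh[pos], kk[pos]))
        if np.any(neg):
            bvn[neg] = -bvn[neg] + np.maximum(
                0.0, ndtr(-hh[neg]) - ndtr(-kk[neg])
            )
        out[hi] = bvn

    out = np.clip(out, 0.0, 1.0).reshape(shape)
    return float(out) if out.ndim == 0 else out


def chi2_prob_nodes(df: float, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights for E[g(S)], S ~ chi2(df), on the probability scale."""
    if np.isinf(df):
        return np.array([1.0]), np.array([1.0])  # plug-in sentinel: S/df == 1
    xg, wg = _gl(n_nodes)
    t = (xg + 1.0) / 2.0
    return chi2.ppf(t, df), wg / 2.0
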