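"""Variograms and ordinary kriging (point, moving-neighbourhood and global).

Semivariogram models use the *practical range* convention (the distance at
which the model reaches ~95% of its sill), as in geoR / gstools:

* spherical:   gamma(h) = n + p * (1.5 h/a - 0.5 (h/a)^3), h < a; n + p beyond
* exponential: gamma(h) = n + p * (1 - exp(-3 h / a))
* gaussian:    gamma(h) = n + p * (1 - exp(-3 (h/a)^2))

with nugget ``n``, partial sill ``p`` and practical range ``a``.

Ordinary kriging solves, per target location, the bordered system

    [Gamma  1] [lambda]   [gamma_0]
    [1^T    0] [  mu  ] = [   1   ]

with estimate ``lambda^T z`` and variance ``lambda^T gamma_0 + mu``.  Global
kriging of a domain mean replaces ``gamma_0`` by point-to-domain mean
semivariances and subtracts the within-domain mean semivariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass
class VariogramModel:
    """Bounded semivariogram model gamma(h)."""

    family: str
    nugget: float
    psill: float
    range_: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("nugget/psill must be >= 0 and range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = h / self.range_
        if self.family == "spherical":
            struct = np.where(r < 1.0, 1.5 * r - 0.5 * r**3, 1.0)
        elif self.family == "exponential":
            struct = 1.0 - np.exp(-3.0 * r)
        else:
            struct = 1.0 - np.exp(-3.0 * r**2)
        g = self.nugget + self.psill * struct
        return np.where(h > 0, g, 0.0)


def empirical_variogram(
    xy: np.ndarray,
    values: np.ndarray,
    n_lags: int = 15,
    max_lag: float | None = None,
    axis: int | None = None,
    angle_tol_deg: float = 22.5,
):
    """Matheron semivariance estimator, binned by lag distance.

    ``axis`` restricts pairs to displacements within ``angle_tol_deg`` of a
    coordinate axis (0 = first axis, 1 = second) for anisotropy diagnostics.
    Returns ``(lag_centers, gamma, counts)``.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least two points")
    d = pdist(xy)
    if np.all(d == 0):
        raise ValueError("all points share one location; no pairs")
    sq = pdist(values[:, None], metric="sqeuclidean")
    if axis is not None:
        dx = pdist(xy[:, [0]])
        frac = np.divide(dx, d, out=np.zeros_like(d), where=d > 0)
        ang = np.degrees(np.arccos(np.clip(frac, 0, 1)))  # angle to first axis
        keep = ang <= angle_tol_deg if axis == 0 else (90 - ang) <= angle_tol_deg
        d, sq = d[keep], sq[keep]
    if max_lag is None:
        max_lag = float(d.max()) / 2
    edges = np.linspace(0, max_lag, n_lags + 1)
    idx = np.digitize(d, edges) - 1
    gamma = np.full(n_lags, np.nan)
    counts = np.zeros(n_lags, dtype=int)
    for k in range(n_lags):
        sel = idx == k
        counts[k] = int(sel.sum())
        if counts[k]:
            gamma[k] = 0.5 * sq[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, gamma, counts


def fit_variogram(
    lags: np.ndarray,
    gamma: np.ndarray,
    counts: np.ndarray | None = None,
    family: str | None = None,
) -> VariogramModel:
    """Weighted least-squares fit; weights are pair counts.

    When ``family`` is None the spherical, exponential and gaussian models
    are all fitted and the one with the lowest weighted residual is kept.
    """
    lags = np.asarray(lags, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    ok = np.isfinite(gamma)
    lags, gamma = lags[ok], gamma[ok]
    w = np.ones_like(lags) if counts is None else np.sqrt(np.asarray(counts, float)[ok])
    if len(lags) < 3:
        raise ValueError("need at least three non-empty lag bins")
    s0 = max(gamma.max(), 1e-12)
    x0 = np.array([min(gamma[0], 0.5 * s0), s0, lags[-1] / 2])
    lo = np.array([0.0, 1e-12, 1e-6])
    hi = np.array([s0 * 2, s0 * 3, lags[-1] * 4])

    def solve(fam):
        def resid(p):
            m = VariogramModel(fam, *np.clip(p, lo, hi))
            return w * (m(lags) - gamma)

        res = least_squares(resid, x0, bounds=(lo, hi))
        return res.cost, VariogramModel(fam, *res.x)

    families = FAMILIES if family is None else (family,)
    best = min((solve(f) for f in families), key=lambda t: t[0])
    return best[1]


def _dedupe(xy: np.ndarray, z: np.ndarray):
    """Drop duplicate locations (keep the first), warning when any exist."""
    _, idx = np.unique(np.round(xy, 9), axis=0, return_index=True)
    if len(idx) < len(xy):
        warnings.warn(f"dropped {len(xy) - len(idx)} duplicate data location(s)")
        idx = np.sort(idx)
        return xy[idx], z[idx]
    return xy, z


def ordinary_kriging(
    xy: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
    n_neighbors: int | None = 32,
):
    """Moving-neighbourhood ordinary kriging at target locations.

    Uses the nearest ``n_neighbors`` data points per target (all points when
    None or when fewer are available).  Returns ``(estimates, variances)``.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    xy, values = _dedupe(xy, values)
    n = len(xy)
    k = n if n_neighbors is None else min(n_neighbors, n)
    tree = cKDTree(xy)
    _, nbrs = tree.query(targets, k=k)
    nbrs = np.atleast_2d(nbrs)
    if k == 1:
        nbrs = nbrs.reshape(-1, 1)

    est = np.empty(len(targets))
    var = np.empty(len(targets))
    # Group targets sharing a neighbour set to factorise the system once.
    order = np.lexsort(nbrs.T)
    sorted_nbrs = nbrs[order]
    start = 0
    for i in range(1, len(targets) + 1):
        if i < len(targets) and np.array_equal(sorted_nbrs[i], sorted_nbrs[start]):
            continue
        group = order[start:i]
        idx = nbrs[group[0]]
        pts = xy[idx]
        m = len(idx)
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = model(squareform(pdist(pts))) if m > 1 else 0.0
        A[m, :m] = 1.0
        A[:m, m] = 1.0
        A[m, m] = 0.0
        d0 = np.linalg.norm(pts[None, :, :] - targets[group][:, None, :], axis=2)
        B = np.empty((m + 1, len(group)))
        B[:m] = model(d0).T
        B[m] = 1.0
        try:
            sol = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(A, B, rcond=None)[0]
        lam, mu = sol[:m], sol[m]
        est[group] = lam.T @ values[idx]
        var[group] = np.maximum(np.einsum("ij,ij->j", lam, B[:m]) + mu, 0.0)
        start = i
    return est, var


def global_kriging(
    xy: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    domain_points: np.ndarray,
):
    """Ordinary-kriging estimate of the mean of a domain.

    The domain is discretised to ``domain_points``; returns
    ``(mean_estimate, estimation_variance)``.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    domain_points = np.asarray(domain_points, dtype=float)
    if len(domain_points) == 0:
        raise ValueError("domain discretisation is empty")
    xy, values = _dedupe(xy, values)
    n = len(xy)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model(squareform(pdist(xy))) if n > 1 else 0.0
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    d = np.linalg.norm(xy[:, None, :] - domain_points[None, :, :], axis=2)
    b = np.empty(n + 1)
    b[:n] = model(d).mean(axis=1)
    b[n] = 1.0
    # within-domain mean semivariance (subsample for very fine grids)
    dp = domain_points
    if len(dp) > 1500:
        step = len(dp) // 1500 + 1
        dp = dp[::step]
    gvv = float(model(squareform(pdist(dp))).mean()) if len(dp) > 1 else 0.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
    lam, mu = sol[:n], sol[n]
    mean = float(lam @ values)
    var = float(max(lam @ b[:n] + mu - gvv, 0.0))
    return mean, var


def cross_validate(xy: np.ndarray, values: np.ndarray, model: VariogramModel):
    """Leave-one-out kriging; returns (predictions, kriging variances)."""
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(xy)
    pred = np.empty(n)
    kv = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        e, v = ordinary_kriging(xy[keep], values[keep], model, xy[i][None, :],
                                n_neighbors=None)
        pred[i], kv[i] = e[0], v[0]
    return pred, kv
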