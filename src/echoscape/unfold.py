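"""Unfolding of an annular island survey domain onto a rectangle.

An island survey domain is an annulus bounded by the coastline (inner) and an
offshore boundary (outer).  Geographic axes are meaningless for describing
correlation in such a domain: the natural directions are along-coast and
cross-shore.  The domain is therefore covered by a closed chain of trapezes,
each with an inner base on the coastline and an outer base on the offshore
boundary.  Within a trapeze, bilinear coordinates give

* ``t`` — cross-shore coordinate, 0 on the coastline, 1 on the offshore
  boundary;
* ``s`` — along-coast coordinate, the cumulative length of inner bases up to
  the trapeze plus the within-trapeze base fraction, ranging from 0 to the
  total base length of the chain.

The mapping is bijective, so points, grids and kriged estimates can be moved
back and forth between geographic and unfolded space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep


class OutOfDomainError(ValueError):
    """A point falls outside every trapeze of the chain."""


@dataclass(frozen=True)
class Trapeze:
    """One quadrilateral of the chain.

    Corners are ordered ``a0`` (coast, start), ``a1`` (coast, end),
    ``b1`` (offshore, end), ``b0`` (offshore, start); consecutive trapezes
    share the edge ``a1–b1`` / ``a0–b0``.
    """

    a0: np.ndarray
    a1: np.ndarray
    b0: np.ndarray
    b1: np.ndarray

    @property
    def inner_base_length_m(self) -> float:
        return float(np.hypot(*(self.a1 - self.a0)))

    @property
    def polygon(self) -> Polygon:
        return Polygon([self.a0, self.a1, self.b1, self.b0])


@dataclass
class TrapezeChain:
    """Ordered closed ring of trapezes around an island."""

    trapezes: list[Trapeze]
    annulus: Polygon | None = None
    cumulative_base_m: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lengths = [tz.inner_base_length_m for tz in self.trapezes]
        self.cumulative_base_m = np.concatenate([[0.0], np.cumsum(lengths)])
        self._polys = [tz.polygon for tz in self.trapezes]
        self._prepared = [prep(p) for p in self._polys]
        self._annulus_prep = prep(self.annulus) if self.annulus is not None else None

    @property
    def total_base_m(self) -> float:
        return float(self.cumulative_base_m[-1])

    @property
    def mean_width_m(self) -> float:
        """Mean coast-to-offshore extent, used to scale ``t`` to metres."""
        widths = [
            np.hypot(*((tz.b0 + tz.b1) / 2 - (tz.a0 + tz.a1) / 2))
            for tz in self.trapezes
        ]
        return float(np.mean(widths))

    def locate(self, x: float, y: float, tol: float | None = None) -> int:
        """Index of the trapeze covering (x, y); ties go to the lower index.

        Trapeze edges are chords of the curved boundaries, so lenses of the
        annulus lie just outside every trapeze; a point inside the stored
        annulus, or within ``tol`` (default 10% of the mean annulus width)
        of a trapeze, is assigned to the nearest trapeze — the bilinear
        coordinates extrapolate smoothly and stay bijective there.
        """
        pt = Point(x, y)
        for k, prepared in enumerate(self._prepared):
            if prepared.intersects(pt):
                return k
        tol = 0.1 * self.mean_width_m if tol is None else tol
        dists = [p.distance(pt) for p in self._polys]
        k = int(np.argmin(dists))
        in_annulus = self._annulus_prep is not None and self._annulus_prep.intersects(pt)
        if in_annulus or dists[k] <= tol:
            return k
        raise OutOfDomainError(f"point ({x:.1f}, {y:.1f}) outside the trapeze chain")

    def locate_many(self, xy: np.ndarray, tol: float | None = None) -> np.ndarray:
        """Vectorised :meth:`locate`; -1 marks out-of-domain points."""
        xy = np.asarray(xy, dtype=float)
        out = np.full(len(xy), -1, dtype=int)
        remaining = np.arange(len(xy))
        for k, prepared in enumerate(self._prepared):
            if remaining.size == 0:
                break
            hit = np.fromiter(
                (prepared.intersects(Point(*xy[i])) for i in remaining),
                dtype=bool,
                count=remaining.size,
            )
            out[remaining[hit]] = k
            remaining = remaining[~hit]
        tol = 0.1 * self.mean_width_m if tol is None else tol
        for i in remaining:
            pt = Point(*xy[i])
            dists = [p.distance(pt) for p in self._polys]
            k = int(np.argmin(dists))
            in_annulus = self._annulus_prep is not None and self._annulus_prep.intersects(pt)
            if in_annulus or dists[k] <= tol:
                out[i] = k
        return out


def _cross(v: np.ndarray, w: np.ndarray) -> float:
    return v[0] * w[1] - v[1] * w[0]


def build_chain(coastline: Polygon, offshore_boundary: Polygon, n_trapezes: int) -> TrapezeChain:
    """Cover the annulus between two closed boundaries with a trapeze ring.

    Inner corners partition the coastline into ``n_trapezes`` arcs of equal
    length; each is matched to the nearest point of the offshore boundary
    (nearest-normal projection).  If the projections are not monotone along
    the outer ring (strongly irregular shapes) the match falls back to rays
    from the coastline centroid.
    """
    if n_trapezes < 1:
        raise ValueError("n_trapezes must be >= 1")
    if not offshore_boundary.contains(coastline):
        raise ValueError("offshore boundary must strictly contain the coastline")

    coast = coastline.exterior
    outer = offshore_boundary.exterior
    # Orient both rings counter-clockwise so bases run the same way.
    if not coastline.exterior.is_ccw:
        coast = Polygon(list(coastline.exterior.coords)[::-1]).exterior
    if not offshore_boundary.exterior.is_ccw:
        outer = Polygon(list(offshore_boundary.exterior.coords)[::-1]).exterior

    from shapely.geometry import LineString

    fracs = np.arange(n_trapezes) / n_trapezes
    inner_pts = [np.asarray(coast.interpolate(f, normalized=True).coords[0]) for f in fracs]
    far = 10 * max(offshore_boundary.bounds[2] - offshore_boundary.bounds[0],
                   offshore_boundary.bounds[3] - offshore_boundary.bounds[1])

    def ray_hit(p, d):
        d = d / np.hypot(*d)
        hit = LineString([p, p + far * d]).intersection(outer)
        if hit.is_empty:
            return None
        pts = getattr(hit, "geoms", [hit])
        best = min(pts, key=lambda g: Point(*p).distance(g))
        return np.asarray(best.coords[0])

    outer_pts = []
    eps = 1e-4
    for f, p in zip(fracs, inner_pts):
        # outward coast normal (interior lies left of a CCW ring)
        ahead = np.asarray(coast.interpolate((f + eps) % 1.0, normalized=True).coords[0])
        behind = np.asarray(coast.interpolate((f - eps) % 1.0, normalized=True).coords[0])
        tx, ty = ahead - behind
        q = ray_hit(p, np.array([ty, -tx]))
        if q is None:  # nearest-point projection fallback
            q = np.asarray(outer.interpolate(outer.project(Point(*p))).coords[0])
        outer_pts.append(q)

    # outer corners must run monotonically around the ring; if the normals
    # cross (strong concavities) fall back to centroid rays throughout
    params = np.array([outer.project(Point(*q), normalized=True) for q in outer_pts])
    rel = np.mod(params - params[0], 1.0)
    if not np.all(np.diff(rel) > 0):
        c = np.asarray(coastline.centroid.coords[0])
        outer_pts = []
        for p in inner_pts:
            q = ray_hit(p, p - c)
            if q is None:
                raise ValueError("centroid ray misses the offshore boundary")
            outer_pts.append(q)

    trapezes = []
    for k in range(n_trapezes):
        k1 = (k + 1) % n_trapezes
        tz = Trapeze(a0=inner_pts[k], a1=inner_pts[k1], b0=outer_pts[k], b1=outer_pts[k1])
        poly = tz.polygon
        if (not poly.is_valid) or poly.area <= 0:
            raise ValueError(
                f"trapeze {k} is degenerate or self-intersecting; reduce n_trapezes"
            )
        trapezes.append(tz)
    return TrapezeChain(trapezes, annulus=offshore_boundary.difference(coastline))


def fold(s: float, t: float, chain: TrapezeChain) -> np.ndarray:
    """Map an unfolded point (s, t) back to geographic coordinates."""
    total = chain.total_base_m
    s = float(np.mod(s, total))
    k = int(np.searchsorted(chain.cumulative_base_m, s, side="right") - 1)
    k = min(k, len(chain.trapezes) - 1)
    tz = chain.trapezes[k]
    base = tz.inner_base_length_m
    u = (s - chain.cumulative_base_m[k]) / base
    return _bilinear(tz, u, t)


def _bilinear(tz: Trapeze, u: float, t: float) -> np.ndarray:
    inner = (1 - u) * tz.a0 + u * tz.a1
    outer = (1 - u) * tz.b0 + u * tz.b1
    return (1 - t) * inner + t * outer


def _inverse_bilinear(tz: Trapeze, p: np.ndarray) -> tuple[float, float]:
    """Invert the bilinear map of one trapeze; returns (u, t)."""
    a = tz.a1 - tz.a0
    b = tz.b0 - tz.a0
    c = (tz.b1 - tz.b0) - (tz.a1 - tz.a0)
    q = np.asarray(p, dtype=float) - tz.a0
    # cross(q - t*b, a + t*c) = 0  ->  quadratic in t
    A = -_cross(b, c)
    B = _cross(q, c) - _cross(b, a)
    C = _cross(q, a)
    if abs(A) < 1e-12 * (abs(B) + 1e-30):
        roots = [-C / B] if B != 0 else [0.0]
    else:
        disc = max(B * B - 4 * A * C, 0.0)
        r = np.sqrt(disc)
        roots = [(-B + r) / (2 * A), (-B - r) / (2 * A)]

    def solve_u(t):
        d = a + t * c
        denom = float(d @ d)
        return float((q - t * b) @ d) / denom if denom > 0 else 0.0

    # Both roots can be admissible in skewed quadrilaterals; keep the one
    # whose forward image actually returns to p.
    best = None
    for t in roots:
        u = solve_u(t)
        err = float(np.hypot(*(_bilinear(tz, u, t) - np.asarray(p, dtype=float))))
        pen = err + 1e3 * (max(0.0, -t, t - 1) + max(0.0, -u, u - 1))
        if best is None or pen < best[0]:
            best = (pen, u, t)
    return best[1], float(best[2])


def unfold(p, chain: TrapezeChain) -> tuple[float, float]:
    """Map a geographic point into unfolded (s, t) coordinates.

    ``t`` is 0 on the coastline and 1 on the offshore boundary; ``s`` is the
    cumulative inner-base offset of the containing trapeze plus the
    within-trapeze base fraction.
    """
    p = np.asarray(p, dtype=float)
    k = chain.locate(p[0], p[1])
    tz = chain.trapezes[k]
    u, t = _inverse_bilinear(tz, p)
    s = chain.cumulative_base_m[k] + u * tz.inner_base_length_m
    return float(s), float(t)


def unfold_many(xy: np.ndarray, chain: TrapezeChain) -> np.ndarray:
    """Unfold an array of points; returns an (n, 2) array of (s, t)."""
    xy = np.asarray(xy, dtype=float)
    ks = chain.locate_many(xy)
    if np.any(ks < 0):
        bad = int(np.sum(ks < 0))
        raise OutOfDomainError(f"{bad} point(s) outside the trapeze chain")
    out = np.empty_like(xy)
    for k in np.unique(ks):
        tz = chain.trapezes[k]
        idx = np.where(ks == k)[0]
        for i in idx:
            u, t = _inverse_bilinear(tz, xy[i])
            out[i, 0] = chain.cumulative_base_m[k] + u * tz.inner_base_length_m
            out[i, 1] = t
    return out


def wrap_pad(st: np.ndarray, values: np.ndarray, chain: TrapezeChain):
    """Duplicate first/last trapeze data across the chain seam.

    Points in the last trapeze are copied to ``s - total`` and points in the
    first trapeze to ``s + total`` so that interpolation near ``s = 0`` also
    sees the data from the other end of the ring.  Returns the padded
    ``(st, values)`` pair (originals first).
    """
    st = np.asarray(st, dtype=float)
    values = np.asarray(values, dtype=float)
    total = chain.total_base_m
    cum = chain.cumulative_base_m
    in_first = st[:, 0] < cum[1]
    in_last = st[:, 0] >= cum[-2]
    pads = []
    vals = []
    if np.any(in_last):
        p = st[in_last].copy()
        p[:, 0] -= total
        pads.append(p)
        vals.append(values[in_last])
    if np.any(in_first):
        p = st[in_first].copy()
        p[:, 0] += total
        pads.append(p)
        vals.append(values[in_first])
    if not pads:
        warnings.warn("wrap_pad: no points in first or last trapeze; nothing padded")
        return st, values
    return np.vstack([st] + pads), np.concatenate([values] + vals)
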