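"""Two-frequency echogram classification and NASC echo-integration.

An echogram is a ping x depth-bin matrix of volume backscattering strength
Sv (dB re 1 m^-1).  Swimbladdered fish, well beyond swimbladder resonance,
return a high and frequency-homogeneous Sv at 70 and 200 kHz, whereas
gelatinous and crustacean scatterers show a marked inter-frequency contrast.
Classification therefore thresholds (i) Sv itself, (ii) the bi-frequency sum
Sv70 + Sv200, (iii) the local variance of Sv, and the inter-frequency
difference |Sv70 - Sv200|.

Echo-integration converts the classified linear backscatter into the
Nautical Area Scattering Coefficient

    s_A = 4 pi 1852^2 * sum(10^(Sv/10)) * dz    [m^2 nmi^-2]

per ping, then averages per-ping s_A over consecutive 25-m along-track
elementary sampling distance units (ESDU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

#: 4 pi 1852^2 — spherical spreading times square nautical mile, the factor
#: turning depth-integrated linear backscatter (m^2 m^-2) into NASC units.
NASC_FACTOR = 4.0 * np.pi * 1852.0**2

#: Table of echotype labels: ten assemblages plus the two triggerfish
#: species identifiable from their characteristic shoal shapes.
ASSEMBLAGE_LABELS = (
    "bottom small fish school",
    "bottom weak fish detection",
    "C. sufflamen",
    "individual demersal fish",
    "loose school",
    "M. niger",
    "mix reef fish",
    "sand fish",
    "shelf-break large fish",
    "shelf-break school",
    "small pelagics school",
    "small pelagics and predators",
)


class AlignmentError(ValueError):
    """The two frequency channels are not on the same ping x depth grid."""


@dataclass
class Echogram:
    """Single-frequency Sv matrix with ping geometry.

    ``sv`` is (n_ping, n_depth); NaN marks "no data" (e.g. below the
    detected bottom).  Depth bins are half-open [top, bottom): a bin belongs
    to the water column while its *top* edge is above the bottom line minus
    one bin (the bottom-line cell itself is excluded from integration).
    """

    sv: np.ndarray
    depth_bin_m: float
    ping_x: np.ndarray
    ping_y: np.ndarray
    ping_times: np.ndarray  # seconds since survey start
    bottom_depth: np.ndarray  # metres, positive down, per ping
    frequency_khz: float

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv, dtype=float)
        if self.depth_bin_m <= 0:
            raise ValueError("depth_bin_m must be positive")
        n = self.sv.shape[0]
        for name in ("ping_x", "ping_y", "ping_times", "bottom_depth"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per ping")
            setattr(self, name, arr)
        if np.any(np.diff(self.ping_times) < 0):
            raise ValueError("pings must be time-ordered")

    @property
    def n_pings(self) -> int:
        return self.sv.shape[0]

    @property
    def n_bins(self) -> int:
        return self.sv.shape[1]

    @property
    def depth_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.depth_bin_m

    def water_column(self) -> np.ndarray:
        """Boolean matrix of bins above the bottom (bottom cell excluded)."""
        tops = np.arange(self.n_bins) * self.depth_bin_m
        return tops[None, :] < (self.bottom_depth[:, None] - self.depth_bin_m)


@dataclass
class ClassMask:
    """Disjoint fish-like / no-fish boolean masks on the echogram grid."""

    fish_like: np.ndarray
    no_fish: np.ndarray

    def __post_init__(self) -> None:
        if self.fish_like.shape != self.no_fish.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.fish_like & self.no_fish):
            raise ValueError("fish_like and no_fish masks overlap")


@dataclass
class ThresholdConfig:
    """Thresholds of the two-frequency classification.

    Defaults were calibrated on the synthetic echogram generator; real-data
    values are survey-specific and should be tuned on scrutinised echograms.
    """

    sv_min_db: float = -70.0
    bifreq_sum_bounds_db: tuple[float, float] = (-160.0, -20.0)
    sv_variance_bounds: tuple[float, float] = (0.0, np.inf)
    frequency_homogeneity_db: float = 3.0
    variance_window: int = 5

    def __post_init__(self) -> None:
        for lo, hi in (self.bifreq_sum_bounds_db, self.sv_variance_bounds):
            if not lo < hi:
                raise ValueError("interval bounds must satisfy lo < hi")
        if self.variance_window < 3 or self.variance_window % 2 == 0:
            raise ValueError("variance window must be odd and >= 3")


def _local_variance(sv: np.ndarray, w: int, fill: float) -> np.ndarray:
    x = np.where(np.isfinite(sv), sv, fill)
    m = uniform_filter(x, size=w, mode="nearest")
    m2 = uniform_filter(x * x, size=w, mode="nearest")
    return np.maximum(m2 - m * m, 0.0)


def classify_echoes(e70: Echogram, e200: Echogram, cfg: ThresholdConfig | None = None) -> ClassMask:
    """Split echogram cells into fish-like and no-fish scatter.

    A water-column cell whose stronger channel exceeds ``sv_min_db`` is a
    scatterer; it is *fish-like* when the bi-frequency sum lies inside its
    bounds, the inter-frequency difference is within the homogeneity
    threshold, and the local Sv variance (both channels) is inside its
    bounds; otherwise it is *no-fish*.  Cells below the bottom line belong
    to neither class.
    """
    cfg = cfg or ThresholdConfig()
    if e70.sv.shape != e200.sv.shape:
        raise AlignmentError("frequency channels have different grids")
    if not np.allclose(e70.bottom_depth, e200.bottom_depth):
        raise AlignmentError("bottom lines differ between channels")
    if not np.all(np.isfinite(e70.bottom_depth)):
        raise ValueError("bottom line missing")

    water = e70.water_column()
    valid = water & np.isfinite(e70.sv) & np.isfinite(e200.sv)
    strong = np.fmax(e70.sv, e200.sv) >= cfg.sv_min_db
    candidate = valid & strong

    bisum = e70.sv + e200.sv
    in_sum = (bisum >= cfg.bifreq_sum_bounds_db[0]) & (bisum <= cfg.bifreq_sum_bounds_db[1])
    homog = np.abs(e70.sv - e200.sv) <= cfg.frequency_homogeneity_db
    lo, hi = cfg.sv_variance_bounds
    v70 = _local_variance(e70.sv, cfg.variance_window, cfg.sv_min_db)
    v200 = _local_variance(e200.sv, cfg.variance_window, cfg.sv_min_db)
    var_ok = (v70 >= lo) & (v70 <= hi) & (v200 >= lo) & (v200 <= hi)

    fish = candidate & in_sum & homog & var_ok
    nofish = candidate & ~fish
    return ClassMask(fish_like=fish, no_fish=nofish)


def nasc_per_ping(e: Echogram, mask: np.ndarray) -> np.ndarray:
    """Per-ping NASC (m^2 nmi^-2) of the masked cells, water column only."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != e.sv.shape:
        raise ValueError("mask shape must match the echogram")
    lin = np.where(mask & np.isfinite(e.sv) & e.water_column(), 10.0 ** (e.sv / 10.0), 0.0)
    return NASC_FACTOR * lin.sum(axis=1) * e.depth_bin_m


def esdu_segments(e: Echogram, esdu_length_m: float = 25.0) -> np.ndarray:
    """ESDU index per ping, by cumulative along-track distance.

    Segmentation restarts nowhere: the track is cut every ``esdu_length_m``
    of cumulative distance from its start; a final short segment is merged
    into its predecessor when shorter than half an ESDU.
    """
    if esdu_length_m <= 0:
        raise ValueError("esdu_length_m must be positive")
    steps = np.hypot(np.diff(e.ping_x), np.diff(e.ping_y))
    dist = np.concatenate([[0.0], np.cumsum(steps)])
    idx = np.floor(dist / esdu_length_m).astype(int)
    if idx.max() > 0:
        last_len = dist[-1] - idx.max() * esdu_length_m
        if last_len < esdu_length_m / 2:
            idx[idx == idx.max()] = idx.max() - 1
    return idx


def echo_integrate(
    e: Echogram, mask: np.ndarray, esdu_length_m: float = 25.0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Echo-integrate masked cells to per-ping and per-ESDU NASC.

    Per-ESDU NASC is the *mean* of the per-ping NASC over the ESDU's pings,
    keeping units comparable across ESDU lengths and ping rates.  Returns
    ``(per_ping_nasc, esdu_table)``; the table carries mid positions, times,
    bottom depths and the first/last bottom depth used for the local slope.
    """
    per_ping = nasc_per_ping(e, mask)
    idx = esdu_segments(e, esdu_length_m)
    df = pd.DataFrame(
        {
            "esdu_id": idx,
            "sa": per_ping,
            "x": e.ping_x,
            "y": e.ping_y,
            "t": e.ping_times,
            "bottom": e.bottom_depth,
        }
    )
    g = df.groupby("esdu_id")
    out = g.agg(
        sa=("sa", "mean"),
        x=("x", "mean"),
        y=("y", "mean"),
        t=("t", "mean"),
        bottom_depth_m=("bottom", "mean"),
        depth_first=("bottom", "first"),
        depth_last=("bottom", "last"),
        n_pings=("sa", "size"),
    ).reset_index()
    out["esdu_length_m"] = esdu_length_m
    return per_ping, out


def compute_slope(depth_first, depth_last, esdu_length_m: float = 25.0, n_valid: int = 2):
    """Local bottom slope of an ESDU, in percent.

    ``|first depth - last depth| / ESDU length x 100``; with fewer than two
    valid bottom depths the slope is missing (NaN), not zero.
    """
    depth_first = np.asarray(depth_first, dtype=float)
    depth_last = np.asarray(depth_last, dtype=float)
    slope = np.abs(depth_first - depth_last) / esdu_length_m * 100.0
    n_valid = np.asarray(n_valid)
    return np.where(
        (n_valid >= 2) & np.isfinite(depth_first) & np.isfinite(depth_last), slope, np.nan
    )


def partition_by_label(
    e: Echogram,
    mask: ClassMask,
    polygons: list[tuple[str, Polygon]],
    esdu_length_m: float = 25.0,
) -> pd.DataFrame:
    """Allocate fish-like NASC among assemblage labels per ESDU.

    ``polygons`` are (label, polygon) pairs in (ping time s, depth m)
    coordinates, as drawn on an echogram.  Every fish-like cell takes the
    label of the first listed polygon containing its (time, depth-centre)
    point; list order is the precedence for overlaps (a warning is issued).
    Cells in no polygon are reported under ``"unlabelled"``.
    """
    times = e.ping_times
    depths = e.depth_centers
    fish = mask.fish_like
    cell_label = np.full(fish.shape, -1, dtype=int)
    prepared = [(i, prep(poly)) for i, (_, poly) in enumerate(polygons)]
    overlap = False
    pi, di = np.nonzero(fish)
    for p, d in zip(pi, di):
        pt = Point(times[p], depths[d])
        hits = [i for i, pr in prepared if pr.intersects(pt)]
        if hits:
            if len(hits) > 1:
                overlap = True
            cell_label[p, d] = hits[0]
    if overlap:
        warnings.warn("overlapping label polygons; precedence = list order")

    idx = esdu_segments(e, esdu_length_m)
    esdu_ids = np.unique(idx)
    labels = [lab for lab, _ in polygons] + ["unlabelled"]
    rows = {}
    for j, lab in enumerate(labels):
        sel = (cell_label == j) if lab != "unlabelled" else (fish & (cell_label == -1))
        per_ping = nasc_per_ping(e, sel)
        rows[lab] = pd.Series(per_ping).groupby(idx).mean().reindex(esdu_ids).to_numpy()
    out = pd.DataFrame(rows, index=pd.Index(esdu_ids, name="esdu_id"))
    # merge duplicate label names (several polygons, one assemblage)
    return out.T.groupby(level=0, sort=False).sum().T


def build_esdu_table(
    e70: Echogram,
    e200: Echogram,
    cfg: ThresholdConfig | None = None,
    esdu_length_m: float = 25.0,
    survey_id: str = "S1",
    polygons: list[tuple[str, Polygon]] | None = None,
) -> pd.DataFrame:
    """Classify, integrate and assemble the per-ESDU record table.

    Only the 70-kHz channel is integrated and propagated downstream (the two
    frequencies are strongly correlated once classified).  Columns follow
    the ESDU record layout: ``sa_fish``, ``sa_nofish``, ``log_sa_fish`` =
    log10(sa_fish + 1), ``slope_pct`` and per-label columns ``sa_<label>``
    when polygons are given.
    """
    mask = classify_echoes(e70, e200, cfg)
    _, tab = echo_integrate(e70, mask.fish_like, esdu_length_m)
    _, tab_nf = echo_integrate(e70, mask.no_fish, esdu_length_m)
    tab = tab.rename(columns={"sa": "sa_fish"})
    tab["sa_nofish"] = tab_nf["sa"].to_numpy()
    tab["log_sa_fish"] = np.log10(tab["sa_fish"] + 1.0)
    tab["slope_pct"] = compute_slope(
        tab["depth_first"], tab["depth_last"], esdu_length_m, tab["n_pings"]
    )
    tab["survey_id"] = survey_id
    if polygons:
        part = partition_by_label(e70, mask, polygons, esdu_length_m)
        part = part.rename(columns=lambda c: f"sa_{c}")
        tab = tab.merge(part, left_on="esdu_id", right_index=True, how="left")
    return tab
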