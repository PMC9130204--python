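"""Synthetic island survey scenes: geometry, fields, echograms, video.

The generator emulates a small-boat acoustic survey around an oceanic
island: an elliptical (optionally irregular) coastline inside an offshore
boundary, a shelf + shelf-break bathymetry, radial transects sailed at
~2.5 m/s with 1-s pings, a zero-inflated log-Gaussian areal backscatter
(s_A) field enriched on the windward side, two-frequency echograms holding
fish schools (frequency-homogeneous) and a non-fish scattering layer
(frequency-contrasting) over a noise floor, and Poisson video annotation
streams.  Every draw is fixed by the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .echo import NASC_FACTOR, Echogram

#: ground-truth class codes of synthetic echogram cells
TRUTH_NONE, TRUTH_FISH, TRUTH_LAYER = 0, 1, 2


class ConfigurationError(ValueError):
    """Invalid scene configuration (e.g. island larger than the domain)."""


@dataclass(frozen=True)
class SceneConfig:
    """All knobs of the synthetic survey; the seed fixes every draw."""

    seed: int = 0
    # island geometry (projected metres, island centre at the origin)
    coast_a: float = 1500.0
    coast_b: float = 1000.0
    offshore_a: float = 3500.0
    offshore_b: float = 2800.0
    irregularity: float = 0.0  # harmonic radius perturbation, fraction
    # bathymetry: linear shelf to shelf_depth at shelf_break_t, steeper beyond
    coast_depth_m: float = 5.0
    shelf_depth_m: float = 60.0
    max_depth_m: float = 120.0
    shelf_break_t: float = 0.6
    # true s_A field (m^2 nmi^-2)
    median_sa: float = 200.0
    log_sill: float = 1.0  # variance of ln(s_A) where present
    range_m: float = 400.0  # practical range of the log field
    presence_range_m: float = 500.0
    presence_prob: float = 0.4  # zero inflation: P(fish present)
    windward_factor: float = 3.0
    # echogram signal model
    school_thickness_m: float = 5.0
    school_center_frac: float = 0.6  # school centre depth / bottom depth
    layer_band_m: tuple[float, float] = (4.0, 12.0)
    layer_sv_db: float = -60.0
    freq_offset_db: float = 12.0  # Sv200 - Sv70 of the non-fish layer
    fish_offset_db: float = 0.0
    noise_floor_db: float = -90.0
    noise_sigma_db: float = 0.5
    depth_bin_m: float = 0.5
    # survey design
    n_transects: int = 24
    speed_m_s: float = 2.5
    ping_interval_s: float = 1.0
    esdu_length_m: float = 25.0
    max_range_m: float = 100.0
    intertransect_gap_s: float = 300.0
    # MPA sector (fraction of the coastline, from start angle, to 50 m depth)
    mpa_coast_fraction: float = 0.7
    mpa_start_angle: float = np.pi / 4
    grid_res_m: float = 50.0

    def __post_init__(self) -> None:
        if min(self.coast_a, self.coast_b, self.offshore_a, self.offshore_b) <= 0:
            raise ConfigurationError("all geometry axes must be positive")
        if self.coast_a >= self.offshore_a or self.coast_b >= self.offshore_b:
            raise ConfigurationError("island must be strictly inside the domain")
        if not 0 <= self.presence_prob <= 1:
            raise ConfigurationError("presence_prob must be in [0, 1]")
        for name in ("range_m", "presence_range_m", "depth_bin_m", "grid_res_m"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def _radius(theta, a, b, irregularity):
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if irregularity:
        r = r * (1 + irregularity * (0.6 * np.sin(3 * theta + 1.0) + 0.4 * np.cos(5 * theta)))
    return r


@dataclass
class IslandScene:
    """Geometry and environment of one synthetic island."""

    config: SceneConfig
    coastline: Polygon = field(init=False)
    offshore_boundary: Polygon = field(init=False)
    mpa_polygon: Polygon = field(init=False)

    def __post_init__(self) -> None:
        c = self.config
        th = np.linspace(0, 2 * np.pi, 361)[:-1]
        rc = _radius(th, c.coast_a, c.coast_b, c.irregularity)
        ro = _radius(th, c.offshore_a, c.offshore_b, c.irregularity)
        self.coastline = Polygon(np.c_[rc * np.cos(th), rc * np.sin(th)])
        self.offshore_boundary = Polygon(np.c_[ro * np.cos(th), ro * np.sin(th)])
        if not self.offshore_boundary.contains(self.coastline):
            raise ConfigurationError("offshore boundary does not contain the coastline")
        # MPA: angular sector of the coast out to the 50-m isobath
        t50 = self._t_of_depth(50.0)
        th_m = c.mpa_start_angle + np.linspace(0, 2 * np.pi * c.mpa_coast_fraction, 181)
        r_in = _radius(th_m, c.coast_a, c.coast_b, c.irregularity)
        r_o = _radius(th_m, c.offshore_a, c.offshore_b, c.irregularity)
        r_out = r_in + t50 * (r_o - r_in)
        ring = np.vstack(
            [
                np.c_[r_in * np.cos(th_m), r_in * np.sin(th_m)],
                np.c_[r_out * np.cos(th_m), r_out * np.sin(th_m)][::-1],
            ]
        )
        self.mpa_polygon = Polygon(ring)

    @property
    def annulus(self) -> Polygon:
        return self.offshore_boundary.difference(self.coastline)

    @property
    def domain_diameter_m(self) -> float:
        x0, y0, x1, y1 = self.offshore_boundary.bounds
        return float(np.hypot(x1 - x0, y1 - y0))

    def _t_of_depth(self, depth: float) -> float:
        c = self.config
        return c.shelf_break_t * (depth - c.coast_depth_m) / (c.shelf_depth_m - c.coast_depth_m)

    def radial_fraction(self, x, y) -> np.ndarray:
        """Cross-shore fraction: 0 at the coastline, 1 at the offshore boundary."""
        c = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        th = np.arctan2(y, x)
        r = np.hypot(x, y)
        rc = _radius(th, c.coast_a, c.coast_b, c.irregularity)
        ro = _radius(th, c.offshore_a, c.offshore_b, c.irregularity)
        return (r - rc) / (ro - rc)

    def bathymetry(self, x, y) -> np.ndarray:
        """Bottom depth (m, positive down): linear shelf, steeper shelf-break."""
        c = self.config
        t = np.clip(self.radial_fraction(x, y), 0.0, 1.0)
        tb = c.shelf_break_t
        shelf = c.coast_depth_m + (c.shelf_depth_m - c.coast_depth_m) * np.minimum(t, tb) / tb
        brk = (c.max_depth_m - c.shelf_depth_m) * (np.maximum(t - tb, 0.0) / (1 - tb)) ** 1.5
        return shelf + brk

    def side(self, x, y=None) -> np.ndarray:
        """'windward' (east, x >= 0 — ties go windward) or 'leeward'."""
        x = np.asarray(x, dtype=float)
        return np.where(x >= 0, "windward", "leeward")


@dataclass
class Track:
    """One transect: ping positions and clock times."""

    transect_id: int
    x: np.ndarray
    y: np.ndarray
    t_seconds: np.ndarray


def _grf(shape, res_m, range_m, rng) -> np.ndarray:
    """Unit-variance Gaussian random field (Gaussian covariance, wrap mode)."""
    white = rng.standard_normal(shape)
    sigma_pix = range_m / (2 * np.sqrt(3)) / res_m
    f = gaussian_filter(white, sigma=sigma_pix, mode="wrap")
    return (f - f.mean()) / f.std()


@dataclass
class TrueField:
    """Ground-truth expected s_A surface of one scene realisation.

    ``intensity = exp(mu + sigma G1) * [G2 < z_p] * windward multiplier``
    with two independent Gaussian random fields sampled on a regular grid
    and interpolated bilinearly in between.
    """

    scene: IslandScene
    _xs: np.ndarray = field(init=False, repr=False)
    _ys: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        c = self.scene.config
        rng = np.random.default_rng(c.seed)
        x0, y0, x1, y1 = self.scene.offshore_boundary.bounds
        pad = 2 * c.grid_res_m
        self._xs = np.arange(x0 - pad, x1 + pad, c.grid_res_m)
        self._ys = np.arange(y0 - pad, y1 + pad, c.grid_res_m)
        shape = (len(self._ys), len(self._xs))
        g1 = _grf(shape, c.grid_res_m, c.range_m, rng)
        g2 = _grf(shape, c.grid_res_m, c.presence_range_m, rng)
        self._i1 = RegularGridInterpolator(
            (self._ys, self._xs), g1, bounds_error=False, fill_value=0.0
        )
        self._i2 = RegularGridInterpolator(
            (self._ys, self._xs), g2, bounds_error=False, fill_value=0.0
        )
        from scipy.stats import norm

        self._z_presence = norm.ppf(c.presence_prob)

    def presence(self, x, y) -> np.ndarray:
        pts = np.c_[np.ravel(y), np.ravel(x)]
        return (self._i2(pts) < self._z_presence).reshape(np.shape(x))

    def intensity(self, x, y) -> np.ndarray:
        """Expected s_A (m^2 nmi^-2) at positions; zero where fish absent."""
        c = self.scene.config
        pts = np.c_[np.ravel(y), np.ravel(x)]
        g1 = self._i1(pts).reshape(np.shape(x))
        base = np.exp(np.log(c.median_sa) + np.sqrt(c.log_sill) * g1)
        mult = np.where(np.asarray(x) >= 0, c.windward_factor, 1.0)
        return base * self.presence(x, y) * mult

    def polygon_mean_sa(self, polygon: Polygon) -> float:
        """Mean intensity over a polygon, by grid quadrature."""
        import shapely

        gx, gy = np.meshgrid(self._xs, self._ys)
        inside = shapely.contains_xy(polygon, gx, gy)
        if not inside.any():
            raise ValueError("polygon contains no field grid points")
        return float(self.intensity(gx[inside], gy[inside]).mean())

    def biomass_in(self, polygon: Polygon, weight_g: float = 485.0, ts_db: float = -39.3) -> float:
        """Tonnes implied by the intensity surface over ``polygon``."""
        from .biomass import estimate_biomass

        return estimate_biomass(self.polygon_mean_sa(polygon), polygon.area,
                                weight_g, ts_db).biomass_t

    @property
    def total_biomass_t(self) -> float:
        return self.biomass_in(self.scene.annulus)


def generate_scene(config: SceneConfig) -> tuple[IslandScene, TrueField]:
    """Build a reproducible island scene and its ground-truth s_A field."""
    scene = IslandScene(config)
    return scene, TrueField(scene)


def generate_transects(scene: IslandScene, n: int | None = None) -> list[Track]:
    """Radial coast-to-offshore transects at equally spaced bearings.

    Ping spacing is speed x ping interval; each transect starts after the
    previous one plus a fixed inter-transect steaming gap, giving a single
    monotone survey clock.
    """
    c = scene.config
    n = c.n_transects if n is None else n
    if n < 1:
        raise ValueError("need at least one transect")
    spacing = c.speed_m_s * c.ping_interval_s
    tracks = []
    clock = 0.0
    for k in range(n):
        th = 2 * np.pi * k / n
        rc = _radius(th, c.coast_a, c.coast_b, c.irregularity)
        ro = _radius(th, c.offshore_a, c.offshore_b, c.irregularity)
        r0, r1 = rc + 0.02 * (ro - rc), rc + 0.98 * (ro - rc)
        rr = np.arange(r0, r1, spacing)
        x, y = rr * np.cos(th), rr * np.sin(th)
        t = clock + np.arange(len(rr)) * c.ping_interval_s
        tracks.append(Track(transect_id=k, x=x, y=y, t_seconds=t))
        clock = t[-1] + c.intertransect_gap_s
    return tracks


def generate_echogram(
    track: Track, scene: IslandScene, true_field: TrueField, config: SceneConfig | None = None
) -> tuple[Echogram, Echogram, np.ndarray]:
    """Render the two-frequency echograms of one transect.

    Fish schools are fixed-thickness bands centred at a fixed fraction of
    the bottom depth whose linear sv integrates exactly to the true field's
    s_A at the ping; they respond near-identically at both frequencies.  The
    non-fish layer occupies a fixed depth band with a configured
    inter-frequency offset.  Gaussian dB noise rides on everything above an
    additive noise floor.  Returns ``(echo70, echo200, truth)`` where truth
    codes cells 0 = background, 1 = fish, 2 = non-fish layer.
    """
    c = config or scene.config
    rng = np.random.default_rng((c.seed, 7, track.transect_id))
    n_bins = int(round(c.max_range_m / c.depth_bin_m))
    edges = np.arange(n_bins) * c.depth_bin_m
    centers = edges + c.depth_bin_m / 2
    n_ping = len(track.x)

    bottom = np.minimum(scene.bathymetry(track.x, track.y), c.max_range_m)
    sa = true_field.intensity(track.x, track.y)

    sv70 = np.zeros((n_ping, n_bins))
    truth = np.zeros((n_ping, n_bins), dtype=np.int8)
    offset = np.zeros((n_ping, n_bins))

    water = edges[None, :] < (bottom[:, None] - c.depth_bin_m)
    lo, hi = c.layer_band_m
    layer = water & (centers[None, :] >= lo) & (centers[None, :] < hi)

    for j in range(n_ping):
        if sa[j] <= 0:
            continue
        mid = c.school_center_frac * bottom[j]
        lo_f = max(mid - c.school_thickness_m / 2, 0.0)
        hi_f = min(mid + c.school_thickness_m / 2, bottom[j] - c.depth_bin_m)
        rows = np.nonzero(water[j] & (centers >= lo_f) & (centers < hi_f))[0]
        if rows.size == 0:
            continue
        thickness = rows.size * c.depth_bin_m
        sv_lin = sa[j] / (NASC_FACTOR * thickness)
        sv70[j, rows] = 10 * np.log10(sv_lin)
        truth[j, rows] = TRUTH_FISH
        offset[j, rows] = c.fish_offset_db

    layer_only = layer & (truth == TRUTH_NONE)
    sv70[layer_only] = c.layer_sv_db
    truth[layer_only] = TRUTH_LAYER
    offset[layer_only] = c.freq_offset_db

    signal = truth != TRUTH_NONE

    def channel(sv_signal_db):
        lin = np.where(signal, 10 ** (sv_signal_db / 10), 0.0) + 10 ** (c.noise_floor_db / 10)
        sv = 10 * np.log10(lin) + rng.normal(0, c.noise_sigma_db, lin.shape)
        return np.where(water, sv, np.nan)

    e70 = Echogram(
        sv=channel(sv70),
        depth_bin_m=c.depth_bin_m,
        ping_x=track.x,
        ping_y=track.y,
        ping_times=track.t_seconds,
        bottom_depth=bottom,
        frequency_khz=70.0,
    )
    e200 = Echogram(
        sv=channel(sv70 + offset),
        depth_bin_m=c.depth_bin_m,
        ping_x=track.x,
        ping_y=track.y,
        ping_times=track.t_seconds,
        bottom_depth=bottom,
        frequency_khz=200.0,
    )
    truth = np.where(water, truth, TRUTH_NONE)
    return e70, e200, truth


from .video import SEDIMENT_CODES  # noqa: E402  (shared annotation vocabulary)


def generate_video_stream(
    track: Track,
    scene: IslandScene,
    taxa_rates: dict[str, float],
    mean_count: float = 3.0,
    seed: int | None = None,
    video_id: str | None = None,
) -> pd.DataFrame:
    """Poisson video annotation stream along one transect.

    Each taxon fires events at its rate (events per second) over the track
    duration, with per-event counts 1 + Poisson(mean_count - 1); sediment is
    a piecewise-constant sequence of segments with codes drawn from the
    nine-code vocabulary.  Returns the annotation table (one row per event
    or sediment segment).
    """
    for tax, lam in taxa_rates.items():
        if lam < 0:
            raise ValueError(f"negative rate for {tax!r}")
    c = scene.config
    rng = np.random.default_rng((c.seed if seed is None else seed, 11, track.transect_id))
    t0, t1 = float(track.t_seconds[0]), float(track.t_seconds[-1])
    duration = t1 - t0
    vid = video_id or f"V{track.transect_id:03d}"
    rows = []
    for taxon, lam in sorted(taxa_rates.items()):
        n = rng.poisson(lam * duration)
        times = np.sort(rng.uniform(t0, t1, n))
        counts = 1 + rng.poisson(max(mean_count - 1.0, 0.0), n)
        for t, k in zip(times, counts):
            rows.append((vid, "towed", t, t, "taxon", taxon, int(k)))
    t = t0
    while t < t1:
        seg = min(float(rng.exponential(60.0)) + 5.0, t1 - t)
        code = SEDIMENT_CODES[rng.integers(len(SEDIMENT_CODES))]
        rows.append((vid, "towed", t, t + seg, "sediment", code, 1))
        t += seg
    df = pd.DataFrame(
        rows, columns=["video_id", "video_type", "t_start", "t_end", "kind", "value", "count"]
    )
    return df.sort_values(["kind", "t_start"], ignore_index=True)


def sample_esdu_table(
    scene: IslandScene,
    true_field: TrueField,
    survey_id: str = "S1",
    seed: int = 0,
    noise_log10: float = 0.15,
    pass_times_s: tuple[float, ...] = (0.0,),
    n_transects: int | None = None,
    log_shift: float = 0.0,
    jitter_m: float = 30.0,
) -> pd.DataFrame:
    """Sample the true field at ESDU midpoints along radial transects.

    A fast survey emulator that skips the echogram stage: observed s_A is
    the field intensity times multiplicative lognormal observation noise
    (``noise_log10`` is the SD of log10 s_A between repeat passes).  Each
    entry of ``pass_times_s`` produces one full pass over the same
    transects, offset by that many seconds — the ingredient needed for
    intra-survey variability checks.  ``log_shift`` adds a constant to
    log10(s_A + 1) (calibration-offset scenarios).  Each pass's track is
    offset by a random lateral ``jitter_m``-scale shift — repeat passes
    never steam exactly the same line, so same-pixel records also differ by
    the field's within-pixel variability.  Returns an ESDU table with the
    columns downstream modules expect.
    """
    c = scene.config
    rng = np.random.default_rng((c.seed, 23, seed))
    tracks = generate_transects(scene, n_transects)
    per_esdu = max(int(c.esdu_length_m / (c.speed_m_s * c.ping_interval_s)), 1)
    frames = []
    for pass_k, t_off in enumerate(pass_times_s):
        for tr in tracks:
            dx, dy = rng.normal(0.0, jitter_m, 2)
            idx = np.arange(len(tr.x)) // per_esdu
            mids = pd.DataFrame(
                {"x": tr.x + dx, "y": tr.y + dy, "t": tr.t_seconds + t_off}
            ).groupby(idx).mean()
            sa = true_field.intensity(mids["x"].to_numpy(), mids["y"].to_numpy())
            sa_obs = sa * 10 ** rng.normal(0.0, noise_log10, len(sa))
            log_sa = np.log10(sa_obs + 1.0) + log_shift
            sa_obs = 10**log_sa - 1.0
            frames.append(
                pd.DataFrame(
                    {
                        "survey_id": survey_id,
                        "transect_id": tr.transect_id,
                        "pass_id": pass_k,
                        "x": mids["x"].to_numpy(),
                        "y": mids["y"].to_numpy(),
                        "t": mids["t"].to_numpy(),
                        "sa_fish": sa_obs,
                        "log_sa_fish": log_sa,
                        "bottom_depth_m": scene.bathymetry(
                            mids["x"].to_numpy(), mids["y"].to_numpy()
                        ),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def with_seed(config: SceneConfig, seed: int) -> SceneConfig:
    """Copy of a config with a new seed."""
    return replace(config, seed=seed)
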