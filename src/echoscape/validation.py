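"""End-to-end validation studies on synthetic surveys.

Each function runs one self-contained study — simulate, estimate, measure —
and returns plain numbers.  They are the package's own evidence that the
pipeline recovers known ground truth: classification performance on
simulated echograms, estimator coverage on simulated fields, bijectivity of
the unfolding, decorrelation of the MAF transform, agreement of the kriging
solver with a dense reference solve, and the behaviour of the survey-merge
rule.  The same functions back the test suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm
from shapely.geometry import Point

from .biomass import compute_maf, estimate_biomass, global_krige_maf, indicator_code, recombine
from .echo import NASC_FACTOR, classify_echoes, nasc_per_ping
from .kriging import VariogramModel, ordinary_kriging
from .merge import inter_survey_differences, intra_survey_differences, merge_decision, pixelize
from .scene import (
    TRUTH_FISH,
    TRUTH_LAYER,
    IslandScene,
    SceneConfig,
    generate_echogram,
    generate_scene,
    generate_transects,
    sample_esdu_table,
)
from .unfold import build_chain, fold, unfold


def _simulate_point_survey(
    rng: np.random.Generator,
    n_transects: int = 10,
    esdu_m: float = 25.0,
    side_m: float = 2000.0,
    range_m: float = 300.0,
    presence_range_m: float = 400.0,
    log_sill: float = 1.0,
    median_sa: float = 200.0,
    presence: float = 0.5,
    n_grid: int = 24,
):
    """Joint draw of a zero-inflated lognormal s_A field at survey points
    and at a dense polygon grid (the ground truth), via Cholesky."""
    xs = (np.arange(n_transects) + 0.5) / n_transects * side_m
    ys = np.arange(esdu_m / 2, side_m, esdu_m * 2)
    data_xy = np.array([(x, y) for x in xs for y in ys])
    gx = (np.arange(n_grid) + 0.5) / n_grid * side_m
    grid_xy = np.array([(x, y) for x in gx for y in gx])
    allp = np.vstack([data_xy, grid_xy])
    d = cdist(allp, allp)

    def draw(corr_range):
        C = np.exp(-3 * d / corr_range) + 1e-8 * np.eye(len(d))
        return np.linalg.cholesky(C) @ rng.standard_normal(len(d))

    g_value = draw(range_m)
    g_presence = draw(presence_range_m)
    present = g_presence < norm.ppf(presence)
    sa = np.exp(np.log(median_sa) + np.sqrt(log_sill) * g_value) * present
    n = len(data_xy)
    return data_xy, sa[:n], grid_xy, sa[n:]


def biomass_coverage_study(n_replicates: int = 100, seed: int = 0,
                           surface_m2: float = 4e6) -> dict:
    """Coverage of the indicator->MAF->global-kriging biomass estimator.

    Each replicate simulates a fresh field, runs the full non-linear
    estimation over the survey square and counts whether the realised
    polygon-mean biomass lies inside the estimate +/- 2 estimated SD.
    """
    rng = np.random.default_rng((seed, 101))
    covered = 0
    cvs, rel_err = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_replicates):
            data_xy, sa, grid_xy, sa_grid = _simulate_point_survey(rng)
            truth_sa = sa_grid.mean()
            coding = indicator_code(sa)
            maf = compute_maf(coding.indicators, data_xy)
            F = maf.factors(coding.indicators)
            means, variances, _ = global_krige_maf(F, data_xy, grid_xy)
            mean_sa, var, _ = recombine(means, variances, maf, coding)
            est = estimate_biomass(mean_sa, surface_m2, mean_sa_variance=var)
            truth_t = estimate_biomass(truth_sa, surface_m2).biomass_t
            sd_t = est.biomass_t * est.cv
            if abs(est.biomass_t - truth_t) <= 2 * sd_t:
                covered += 1
            cvs.append(est.cv)
            rel_err.append((est.biomass_t - truth_t) / truth_t)
    return {
        "n_replicates": n_replicates,
        "covered": covered,
        "coverage_pct": 100.0 * covered / n_replicates,
        "mean_cv_pct": 100.0 * float(np.mean(cvs)),
        "mean_rel_bias_pct": 100.0 * float(np.mean(rel_err)),
    }


def classification_study(seed: int = 0, class_offset_db: float = 6.0,
                         snr_db: float = 10.0, n_transects: int = 6) -> dict:
    """Echo classification against simulator ground truth.

    ``snr_db`` is the margin between the school Sv at the median field
    intensity and the detection threshold; ``class_offset_db`` is the
    non-fish layer's inter-frequency contrast.  True fish NASC is the
    integration of the ground-truth fish mask on the same echogram, so the
    comparison isolates classification error.
    """
    thickness = 5.0
    sv_min = -70.0
    median_sa = 10 ** ((sv_min + snr_db + 10 * np.log10(NASC_FACTOR * thickness)) / 10)
    cfg = SceneConfig(
        seed=seed, median_sa=median_sa, freq_offset_db=class_offset_db,
        school_thickness_m=thickness, n_transects=n_transects,
    )
    scene, field = generate_scene(cfg)
    tracks = generate_transects(scene)
    fish_hit = fish_tot = layer_hit = layer_tot = 0
    nasc_est = nasc_true = 0.0
    for tr in tracks:
        e70, e200, truth = generate_echogram(tr, scene, field)
        mask = classify_echoes(e70, e200)
        fish_cells = truth == TRUTH_FISH
        layer_cells = truth == TRUTH_LAYER
        fish_hit += int((mask.fish_like & fish_cells).sum())
        fish_tot += int(fish_cells.sum())
        layer_hit += int((mask.no_fish & layer_cells).sum())
        layer_tot += int(layer_cells.sum())
        nasc_est += float(nasc_per_ping(e70, mask.fish_like).sum())
        nasc_true += float(nasc_per_ping(e70, fish_cells).sum())
    return {
        "fish_recall_pct": 100.0 * fish_hit / fish_tot,
        "layer_recall_pct": 100.0 * layer_hit / layer_tot,
        "nasc_rel_error_pct": 100.0 * (nasc_est - nasc_true) / nasc_true,
    }


def unfold_roundtrip_study(seed: int = 0, n_points: int = 10000) -> dict:
    """fold(unfold(p)) error over three island geometries."""
    geoms = {
        "circle": SceneConfig(coast_a=1000.0, coast_b=1000.0, offshore_a=3000.0, offshore_b=3000.0),
        "ellipse": SceneConfig(),
        "irregular": SceneConfig(irregularity=0.12),
    }
    out = {}
    rng = np.random.default_rng((seed, 5))
    for name, cfg in geoms.items():
        scene = IslandScene(cfg)
        chain = build_chain(scene.coastline, scene.offshore_boundary, 24)
        x0, y0, x1, y1 = scene.offshore_boundary.bounds
        errs = []
        while len(errs) < n_points:
            x, y = rng.uniform(x0, x1), rng.uniform(y0, y1)
            if not scene.annulus.contains(Point(x, y)):
                continue
            s, t = unfold((x, y), chain)
            p = fold(s, t, chain)
            errs.append(np.hypot(p[0] - x, p[1] - y))
        out[name] = float(np.max(errs) / scene.domain_diameter_m)
    out["max_rel_error"] = max(out.values())
    return out


def maf_decorrelation_study(seed: int = 0, n: int = 600) -> dict:
    """Factor correlation at lag 0 (exact) and at the short lag (empirical)."""
    rng = np.random.default_rng((seed, 7))
    n_transects = int(np.ceil(n / 40))  # 40 sampled ESDU midpoints per transect
    data_xy, sa, _, _ = _simulate_point_survey(rng, n_transects=n_transects)
    coding = indicator_code(sa)
    maf = compute_maf(coding.indicators, data_xy)
    F = maf.factors(coding.indicators)
    corr0 = np.corrcoef(F.T)
    lag0 = float(np.abs(corr0 - np.eye(len(corr0))).max())
    from .biomass import _lag_pairs

    pairs = _lag_pairs(data_xy, maf.h, maf.h_tol)
    d = F[pairs[:, 0]] - F[pairs[:, 1]]
    corr_h = np.corrcoef(d.T)
    lag_h = float(np.abs(corr_h - np.eye(len(corr_h))).max())
    return {"n": len(F), "lag0_max_abs_corr": lag0, "shortlag_max_abs_corr": lag_h}


def kriging_reference_study(seed: int = 0) -> dict:
    """Moving-neighbourhood OK vs a dense full-system solve, plus exactness."""
    rng = np.random.default_rng((seed, 13))
    worst = 0.0
    for n in (5, 12, 24, 32):
        pts = rng.uniform(0, 100, (n, 2))
        z = rng.normal(0, 1, n)
        m = VariogramModel("spherical", 0.1, 1.0, 70.0)
        tgt = rng.uniform(0, 100, (10, 2))
        est, var = ordinary_kriging(pts, z, m, tgt, n_neighbors=32)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = m(cdist(pts, pts))
        A[n, :n] = A[:n, n] = 1.0
        for j, t in enumerate(tgt):
            b = np.r_[m(cdist(pts, t[None, :])).ravel(), 1.0]
            sol = np.linalg.solve(A, b)
            e0 = sol[:n] @ z
            v0 = sol[:n] @ b[:n] + sol[n]
            scale = max(1.0, abs(e0))
            worst = max(worst, abs(est[j] - e0) / scale, abs(var[j] - v0) / max(1.0, v0))
    # exact interpolation, zero nugget
    pts = rng.uniform(0, 100, (20, 2))
    z = rng.normal(0, 1, 20)
    m0 = VariogramModel("exponential", 0.0, 1.0, 60.0)
    est, var = ordinary_kriging(pts, z, m0, pts, n_neighbors=None)
    exact = float(max(np.abs(est - z).max(), np.abs(var).max()))
    return {"max_rel_error_vs_dense": float(worst), "max_exact_interp_error": exact}


def merge_study(seed: int = 0) -> dict:
    """Poolability of two same-field surveys; rejection of a shifted one."""
    cfg = SceneConfig(seed=(seed % 2**16) + 19, presence_prob=0.7)
    scene, field = generate_scene(cfg)
    a = sample_esdu_table(scene, field, "A", seed=1, pass_times_s=(0.0, 7200.0))
    b = sample_esdu_table(scene, field, "B", seed=2)
    pixels = pixelize(pd.concat([a, b], ignore_index=True), 100.0)
    inter = inter_survey_differences(pixels)["diff"].to_numpy()
    intra = intra_survey_differences(a, 100.0)
    decision = merge_decision(inter, intra)
    se = 1.2533 * float(inter.std(ddof=1)) / np.sqrt(len(inter))

    b_shift = sample_esdu_table(scene, field, "B", seed=3, log_shift=0.5)
    pixels_s = pixelize(pd.concat([a, b_shift], ignore_index=True), 100.0)
    inter_s = inter_survey_differences(pixels_s)["diff"].to_numpy()
    decision_s = merge_decision(inter_s, intra)
    return {
        "median_inter": float(np.median(inter)),
        "median_se": se,
        "median_within_2se": bool(abs(np.median(inter)) <= 2 * se),
        "approved": bool(decision.approved),
        "shifted_median": float(np.median(inter_s)),
        "shifted_rejected": bool(not decision_s.approved),
    }
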