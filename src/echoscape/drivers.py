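"""Environmental covariates and univariate group comparisons.

Each ESDU record is enriched with the factors used to explain acoustic
biomass: wind/current exposure side (windward vs leeward), no-take MPA
membership, a five-stratum bottom-depth scheme spanning the euphotic
(0–40 m) and mesophotic (40–100 m) zones, and the local bottom slope.
Group differences of log10(s_A + 1) are tested with the Kruskal–Wallis
omnibus rank test followed by pairwise Wilcoxon rank-sum tests with Holm
adjustment (acoustic densities are far from normal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: depth strata (name, lower, upper); half-open [lo, hi) except the last,
#: closed at 100 m.  Bottom depths beyond 100 m fall out of the scheme.
DEFAULT_STRATA = (
    ("upper euphotic", 0.0, 20.0),
    ("lower euphotic", 20.0, 40.0),
    ("upper mesophotic", 40.0, 60.0),
    ("mid-mesophotic", 60.0, 80.0),
    ("lower mesophotic", 80.0, 100.0),
)

OUT_OF_SCHEME = "out-of-scheme"


@dataclass(frozen=True)
class StratumScheme:
    """Contiguous bottom-depth strata covering 0–100 m."""

    strata: tuple = DEFAULT_STRATA

    def __post_init__(self) -> None:
        for (_, _, hi), (_, lo2, _) in zip(self.strata, self.strata[1:]):
            if hi != lo2:
                raise ValueError("strata must be contiguous and non-overlapping")

    def assign(self, depths) -> np.ndarray:
        depths = np.asarray(depths, dtype=float)
        out = np.full(depths.shape, OUT_OF_SCHEME, dtype=object)
        for name, lo, hi in self.strata:
            last = (name, lo, hi) == self.strata[-1]
            sel = (depths >= lo) & ((depths <= hi) if last else (depths < hi))
            out[sel] = name
        return out


def assign_covariates(
    esdu: pd.DataFrame,
    scene,
    scheme: StratumScheme | None = None,
    mpa_max_depth_m: float = 50.0,
) -> pd.DataFrame:
    """Attach side, MPA flag, depth stratum and the MPA-comparison subset.

    ``side`` splits the domain by the windward axis (points on the axis are
    windward by convention); ``mpa`` is point-in-polygon membership of the
    no-take area; ``mpa_subset`` marks records usable for the in/out MPA
    comparison (bottom depth <= 50 m, the depth range the MPA spans).
    """
    scheme = scheme or StratumScheme()
    out = esdu.copy()
    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    out["side"] = scene.side(x, y)
    out["mpa"] = np.where(shapely.contains_xy(scene.mpa_polygon, x, y), "in", "out")
    out["stratum"] = scheme.assign(out["bottom_depth_m"].to_numpy(float))
    out["mpa_subset"] = out["bottom_depth_m"] <= mpa_max_depth_m
    return out


@dataclass
class GroupTestReport:
    """Omnibus + pairwise rank tests of one factor on one response."""

    factor: str
    response: str
    levels: pd.DataFrame  # per-level n, mean, median
    statistic: float | None
    p_value: float | None
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "response": self.response,
            "levels": self.levels.to_dict(orient="index"),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def group_compare(
    enriched: pd.DataFrame,
    factor: str,
    response: str = "log_sa_fish",
    adjust: str = "holm",
) -> GroupTestReport:
    """Kruskal–Wallis omnibus test plus Holm-adjusted pairwise Wilcoxon tests.

    Levels with fewer than two records are excluded; with a single usable
    level only the per-level summaries are reported.
    """
    df = enriched[[factor, response]].dropna()
    if factor == "stratum":
        df = df[df[factor] != OUT_OF_SCHEME]
    summary = (
        df.groupby(factor)[response].agg(n="size", mean="mean", median="median")
    )
    groups = {k: g[response].to_numpy() for k, g in df.groupby(factor) if len(g) >= 2}
    if len(groups) < 2:
        return GroupTestReport(factor, response, summary, None, None)
    stat, p = stats.kruskal(*groups.values())
    rows = []
    for a, b in combinations(sorted(groups), 2):
        if np.array_equal(groups[a], groups[b]):
            praw = 1.0
        else:
            praw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
        rows.append({"level_a": a, "level_b": b, "p_raw": float(praw)})
    pair = pd.DataFrame(rows)
    pair["p_adjusted"] = multipletests(pair["p_raw"], method=adjust)[1]
    return GroupTestReport(factor, response, summary, float(stat), float(p), pair)


MANDATORY_COLUMNS = ("log_sa_fish", "sa_nofish", "side", "stratum", "mpa", "slope_pct")


def export_tree_table(enriched: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Flat analysis-ready tables for regression-tree packages.

    Returns the ``full`` variant (response + side, stratum, MPA, slope and
    no-fish biomass) and, when a sediment column is present, the
    ``sediment`` variant restricted to rows with an observed sediment code.
    Row count of the full variant equals the input.
    """
    cols = [c for c in MANDATORY_COLUMNS if c in enriched.columns]
    missing = set(MANDATORY_COLUMNS) - set(cols)
    if missing:
        raise KeyError(f"enriched table lacks mandatory columns: {sorted(missing)}")
    out = {"full": enriched[cols].copy()}
    if "sediment_code" in enriched.columns:
        sed = enriched[cols + ["sediment_code"]].dropna(subset=["sediment_code"])
        out["sediment"] = sed
    return out
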