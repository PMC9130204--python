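"""Survey poolability: inter- vs intra-survey local differences.

Surveys run in different seasons/years can be pooled into one spatial
dataset only if, locally, their acoustic densities agree to within the
variability seen *within* a survey.  Records are gridded to pixels (100 m by
default); in pixels visited by several surveys, the differences of pixel
means of log10(s_A + 1) between surveys are compared against differences
between same-pixel records taken at least an hour apart within one survey.
Pooling is approved when the inter-survey differences are centred on zero
and no wider than the intra-survey ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


def pixelize(
    esdu: pd.DataFrame,
    pixel_m: float = 100.0,
    value_col: str = "log_sa_fish",
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Grid ESDU records to square pixels and summarise per (pixel, survey).

    The grid is anchored at ``origin`` (default: the data bounding-box
    corner, snapped to a pixel multiple).  Returns one row per
    (pixel, survey) with the mean of ``value_col``, record count and the
    first/last record times.
    """
    if pixel_m <= 0:
        raise ValueError("pixel_m must be positive")
    x = esdu["x"].to_numpy(float)
    y = esdu["y"].to_numpy(float)
    if origin is None:
        origin = (np.floor(x.min() / pixel_m) * pixel_m, np.floor(y.min() / pixel_m) * pixel_m)
    ix = np.floor((x - origin[0]) / pixel_m).astype(int)
    iy = np.floor((y - origin[1]) / pixel_m).astype(int)
    df = esdu.assign(pixel_ix=ix, pixel_iy=iy)
    out = (
        df.groupby(["pixel_ix", "pixel_iy", "survey_id"])
        .agg(
            mean_log_sa=(value_col, "mean"),
            n_records=(value_col, "size"),
            t_first=("t", "min"),
            t_last=("t", "max"),
        )
        .reset_index()
    )
    return out


def inter_survey_differences(pixels: pd.DataFrame) -> pd.DataFrame:
    """Pairwise survey differences of pixel means, in shared pixels.

    For each pixel holding >= 2 surveys and each ordered pair (A, B) with
    A < B by survey id, the difference mean(A) - mean(B) is emitted.
    """
    rows = []
    for (ix, iy), grp in pixels.groupby(["pixel_ix", "pixel_iy"]):
        if grp["survey_id"].nunique() < 2:
            continue
        means = grp.set_index("survey_id")["mean_log_sa"]
        for a, b in combinations(sorted(means.index), 2):
            rows.append((ix, iy, a, b, means[a] - means[b]))
    if not rows:
        warnings.warn("no pixels shared by two or more surveys")
        return pd.DataFrame(columns=["pixel_ix", "pixel_iy", "survey_a", "survey_b", "diff"])
    return pd.DataFrame(rows, columns=["pixel_ix", "pixel_iy", "survey_a", "survey_b", "diff"])


def intra_survey_differences(
    esdu: pd.DataFrame,
    pixel_m: float = 100.0,
    value_col: str = "log_sa_fish",
    min_gap_hours: float = 1.0,
    origin: tuple[float, float] | None = None,
) -> np.ndarray:
    """Same-pixel, same-survey differences between records >= a time gap apart."""
    x = esdu["x"].to_numpy(float)
    y = esdu["y"].to_numpy(float)
    if origin is None:
        origin = (np.floor(x.min() / pixel_m) * pixel_m, np.floor(y.min() / pixel_m) * pixel_m)
    ix = np.floor((x - origin[0]) / pixel_m).astype(int)
    iy = np.floor((y - origin[1]) / pixel_m).astype(int)
    df = esdu.assign(pixel_ix=ix, pixel_iy=iy)
    gap_s = min_gap_hours * 3600.0
    diffs = []
    for _, grp in df.groupby(["pixel_ix", "pixel_iy", "survey_id"]):
        if len(grp) < 2:
            continue
        t = grp["t"].to_numpy(float)
        v = grp[value_col].to_numpy(float)
        order = np.argsort(t)
        t, v = t[order], v[order]
        dt = np.abs(t[:, None] - t[None, :])
        i, j = np.nonzero(np.triu(dt >= gap_s, k=1))
        diffs.append(v[i] - v[j])
    return np.concatenate(diffs) if diffs else np.array([])


def _iqr(a: np.ndarray) -> float:
    return float(np.subtract(*np.percentile(a, [75, 25])))


@dataclass
class MergeReport:
    """Outcome of the poolability check."""

    approved: bool
    median_inter: float
    iqr_inter: float
    iqr_intra: float
    n_inter: int
    n_intra: int
    k: float
    m: float

    def to_dict(self) -> dict:
        return {
            "approved": bool(self.approved),
            "median_inter": self.median_inter,
            "iqr_inter": self.iqr_inter,
            "iqr_intra": self.iqr_intra,
            "n_inter": self.n_inter,
            "n_intra": self.n_intra,
            "k": self.k,
            "m": self.m,
        }


def merge_decision(
    inter: np.ndarray | pd.DataFrame,
    intra: np.ndarray,
    k: float = 0.5,
    m: float = 1.5,
) -> MergeReport:
    """Approve pooling iff inter-survey differences are centred and narrow.

    Approval requires |median(inter)| <= k * IQR(intra) and
    IQR(inter) <= m * IQR(intra).  Raises on empty inputs (undecidable).
    """
    if isinstance(inter, pd.DataFrame):
        inter = inter["diff"].to_numpy(float)
    inter = np.asarray(inter, dtype=float)
    intra = np.asarray(intra, dtype=float)
    if inter.size == 0 or intra.size == 0:
        raise ValueError("merge decision undecidable: empty difference distribution")
    med = float(np.median(inter))
    iqr_inter = _iqr(inter)
    iqr_intra = _iqr(intra)
    approved = (abs(med) <= k * iqr_intra) and (iqr_inter <= m * iqr_intra)
    return MergeReport(
        approved=approved,
        median_inter=med,
        iqr_inter=iqr_inter,
        iqr_intra=iqr_intra,
        n_inter=int(inter.size),
        n_intra=int(intra.size),
        k=k,
        m=m,
    )
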