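"""MaxN-family abundance metrics and sediment summaries from video annotations.

Underwater video census counts are conservative: per video, the abundance
index of a taxon is MaxN, the maximum number of individuals visible
simultaneously.  Stations use the per-frame MaxN directly (avoids double
counting of individuals swimming through); transects use the MaxN over
non-overlapping 3-s windows.  Across videos the per-taxon abundance is
TMaxN, the sum of per-video MaxN values.

Annotation tables carry one row per event with columns ``video_id``,
``video_type`` (towed | transducer | vertical | rov), ``t_start``,
``t_end``, ``kind`` (taxon | sediment), ``value`` and ``count``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: the nine sediment composition codes of the annotation vocabulary
SEDIMENT_CODES = (
    "Sa", "LrAl", "SaUn", "SaAl", "SaStAl", "SaLrAl", "SaRhAl", "SaCoRhAl", "SaStCoRhAl",
)

#: packaged taxon vocabulary (species, genus or family level) observed in
#: tropical island video censuses; unknown taxa pass with a warning.
TAXON_VOCABULARY = frozenset({
    "Holocentrus adscensionis", "Harengula sp.", "Acanthurus coeruleus",
    "Acanthurus chirurgus", "Caranx crysos", "Caranx latus", "Caranx lugubris",
    "Caranx ruber", "Caranx spp.", "Decapterus macarellus", "Elagatis bipinnulata",
    "Seriola spp.", "Gobiidae sp.", "Haemulon chrysargyreum", "Makaira nigricans",
    "Kyphosus sectatrix", "Halichoeres radiatus", "Thalassoma noronhanum",
    "Lutjanus jocu", "Malacanthus plumieri", "Pseudupeneus maculatus",
    "Abudefduf saxatilis", "Chromis multilineata", "Stegastes rocasensis",
    "Cephalopholis fulva", "Paranthias furcifer", "Bothidae sp.",
    "Sparisoma amplum", "Acanthocybium solandri", "Thunnus albacares",
    "Thunnus spp.", "Sphyraena barracuda", "Dactylopterus volitans",
    "Balistes vetula", "Canthidermis sufflamen", "Melichthys niger",
    "Aluterus scriptus", "Cantherhines macrocerus", "Lactophrys trigonus",
    "Ostraciidae sp.", "Carcharhinus falciformis", "Carcharhinus perezi",
    "Sphyrna lewini", "Hypanus americanus", "Aetobatus narinari",
    "Ginglymostoma cirratum", "Stenella longirostris", "Chelonia mydas",
})

#: video types treated as transects (windowed MaxN) vs stations (per frame)
TRANSECT_TYPES = ("towed", "transducer")
STATION_TYPES = ("vertical", "rov")


def _taxon_events(df: pd.DataFrame) -> pd.DataFrame:
    if "kind" in df.columns:
        df = df[df["kind"] == "taxon"]
    unknown = set(df["value"]) - TAXON_VOCABULARY
    if unknown:
        warnings.warn(f"taxa outside the packaged vocabulary: {sorted(unknown)}")
    return df


def maxn(events: pd.DataFrame, mode: str = "per_frame", window_s: float = 3.0) -> pd.Series:
    """Per-taxon MaxN of a single video.

    ``per_frame``: counts of the same taxon annotated at the same instant
    are summed (individuals visible together in one frame), then the
    maximum over frames is taken.  ``windowed``: time is cut into
    non-overlapping ``window_s`` bins anchored at the video start, and MaxN
    is the maximum over bins of the per-bin maximum count.
    """
    if mode not in ("per_frame", "windowed"):
        raise ValueError("mode must be 'per_frame' or 'windowed'")
    if len(events) == 0:
        return pd.Series(dtype=int)
    events = _taxon_events(events)
    if len(events) == 0:
        return pd.Series(dtype=int)
    if np.any(events["count"].to_numpy() < 1):
        raise ValueError("event counts must be >= 1")
    df = events.sort_values("t_start")
    if mode == "per_frame":
        frame = df.groupby(["value", "t_start"])["count"].sum()
        return frame.groupby("value").max().astype(int)
    t0 = df["t_start"].min()
    bins = np.floor((df["t_start"] - t0) / window_s).astype(int)
    per_bin = df.groupby(["value", bins])["count"].max()
    return per_bin.groupby("value").max().astype(int)


def tmaxn(annotations: pd.DataFrame, window_s: float = 3.0) -> pd.DataFrame:
    """Census table across videos: per-taxon TMaxN and occurrence.

    Transect videos (towed, transducer) use windowed MaxN; station videos
    (vertical, rov) use per-frame MaxN.  TMaxN is the sum over videos of
    each video's MaxN; occurrence is the number of videos where the taxon
    was seen.
    """
    events = _taxon_events(annotations)
    per_video = []
    for vid, grp in events.groupby("video_id"):
        vtypes = grp["video_type"].unique()
        mode = "windowed" if vtypes[0] in TRANSECT_TYPES else "per_frame"
        m = maxn(grp, mode=mode, window_s=window_s)
        per_video.append(m.rename(vid))
    if not per_video:
        return pd.DataFrame(columns=["tmaxn", "n_videos"])
    wide = pd.concat(per_video, axis=1).fillna(0).astype(int)
    out = pd.DataFrame({"tmaxn": wide.sum(axis=1), "n_videos": (wide > 0).sum(axis=1)})
    out.index.name = "taxon"
    return out.sort_values("tmaxn", ascending=False)


def relative_abundance(census: pd.DataFrame | pd.Series, total: float | None = None) -> pd.Series:
    """Percentages of TMaxN per taxon, rounded to one decimal.

    ``total`` defaults to the census sum; it must be positive.
    """
    t = census["tmaxn"] if isinstance(census, pd.DataFrame) else census
    total = float(t.sum()) if total is None else float(total)
    if total <= 0:
        raise ValueError("total abundance must be positive")
    return (t / total * 100).round(1)


def sediment_profile(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-video time fraction of each sediment code, plus the dominant code.

    Sediment rows are piecewise-constant segments (t_start, t_end); the
    fraction is segment time over the video's annotated time span.
    Fractions sum to <= 1 (gaps are unclassified).  Unknown codes raise.
    """
    sed = annotations[annotations["kind"] == "sediment"] if "kind" in annotations.columns else annotations
    bad = set(sed["value"]) - set(SEDIMENT_CODES)
    if bad:
        rows = sed.index[sed["value"].isin(bad)].tolist()
        raise ValueError(f"unknown sediment code(s) {sorted(bad)} at rows {rows[:5]}")
    out = []
    for vid, grp in annotations.groupby("video_id"):
        span = float(grp["t_end"].max() - grp["t_start"].min())
        g = sed[sed["video_id"] == vid]
        fr = {code: 0.0 for code in SEDIMENT_CODES}
        for _, row in g.iterrows():
            fr[row["value"]] += max(float(row["t_end"] - row["t_start"]), 0.0) / span if span > 0 else 0.0
        dominant = max(fr, key=fr.get) if any(v > 0 for v in fr.values()) else None
        out.append({"video_id": vid, **fr, "dominant": dominant})
    return pd.DataFrame(out).set_index("video_id")


def dominant_sediment(annotations: pd.DataFrame) -> pd.Series:
    """Dominant sediment code per video (convenience accessor)."""
    return sediment_profile(annotations)["dominant"]
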