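"""Kriged maps of log10(s_A + 1) on the unfolded island domain.

High-level driver tying the pieces together: build the trapeze chain,
unfold the ESDU records, duplicate the seam trapezes, fit a variogram in
unfolded coordinates (cross-shore axis scaled to metres by the mean annulus
width), krige a regular 55 m x 44 m geographic grid through its unfolded
cell centres with a moving neighbourhood, and return the folded map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.geometry import Polygon

from .kriging import VariogramModel, empirical_variogram, fit_variogram, ordinary_kriging
from .unfold import TrapezeChain, build_chain, unfold_many, wrap_pad


@dataclass
class KrigedMap:
    """Folded kriging result on the regular geographic grid."""

    dataset: xr.Dataset
    chain: TrapezeChain
    variogram: VariogramModel

    @property
    def estimate(self) -> xr.DataArray:
        return self.dataset["estimate"]

    @property
    def variance(self) -> xr.DataArray:
        return self.dataset["variance"]


def krige_map(
    esdu: pd.DataFrame,
    coastline: Polygon,
    offshore_boundary: Polygon,
    value_col: str = "log_sa_fish",
    n_trapezes: int = 24,
    cell_x_m: float = 55.0,
    cell_y_m: float = 44.0,
    variogram: VariogramModel | None = None,
    n_neighbors: int = 32,
    chain: TrapezeChain | None = None,
) -> KrigedMap:
    """Ordinary kriging of an ESDU value on the unfolded annulus.

    Cells of the 55 x 44 m geographic grid outside the annulus are masked.
    The variogram, unless supplied, is fitted by weighted least squares on
    the unfolded (seam-padded) data.
    """
    chain = chain or build_chain(coastline, offshore_boundary, n_trapezes)
    xy = esdu[["x", "y"]].to_numpy(float)
    z = esdu[value_col].to_numpy(float)
    ok = np.isfinite(z)
    xy, z = xy[ok], z[ok]
    st = unfold_many(xy, chain)
    st_pad, z_pad = wrap_pad(st, z, chain)
    # scale the cross-shore axis to metres so one distance applies to both
    width = chain.mean_width_m
    data = np.c_[st_pad[:, 0], st_pad[:, 1] * width]

    if variogram is None:
        lags, gamma, counts = empirical_variogram(data, z_pad, n_lags=15)
        variogram = fit_variogram(lags, gamma, counts)

    annulus = offshore_boundary.difference(coastline)
    x0, y0, x1, y1 = annulus.bounds
    xs = np.arange(x0 + cell_x_m / 2, x1, cell_x_m)
    ys = np.arange(y0 + cell_y_m / 2, y1, cell_y_m)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(annulus, gx, gy)
    est = np.full(gx.shape, np.nan)
    var = np.full(gx.shape, np.nan)
    if inside.any():
        cells = np.c_[gx[inside], gy[inside]]
        ks = chain.locate_many(cells)
        usable = ks >= 0
        if usable.any():
            st_cells = unfold_many(cells[usable], chain)
            targets = np.c_[st_cells[:, 0], st_cells[:, 1] * width]
            e, v = ordinary_kriging(data, z_pad, variogram, targets, n_neighbors=n_neighbors)
            tmp_e = np.full(len(cells), np.nan)
            tmp_v = np.full(len(cells), np.nan)
            tmp_e[usable] = e
            tmp_v[usable] = v
            est[inside] = tmp_e
            var[inside] = tmp_v
    ds = xr.Dataset(
        {
            "estimate": (("y", "x"), est),
            "variance": (("y", "x"), var),
        },
        coords={"x": xs, "y": ys},
        attrs={
            "value": value_col,
            "cell_x_m": cell_x_m,
            "cell_y_m": cell_y_m,
            "variogram_family": variogram.family,
            "variogram_nugget": variogram.nugget,
            "variogram_psill": variogram.psill,
            "variogram_range": variogram.range_,
        },
    )
    return KrigedMap(dataset=ds, chain=chain, variogram=variogram)
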