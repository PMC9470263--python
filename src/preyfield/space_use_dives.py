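"""Kernel utilization distributions, vertical prey profiles, dive histograms.

Core foraging ranges are the 75% contours of a bivariate Gaussian kernel
utilization distribution (UD) of HMM-classified foraging locations, with the
normal-reference bandwidth h = 1.06 sigma n^(-1/5) per axis.  Vertical
profiles summarize mean kriged acoustic density per 1 m depth bin over the
whole domain or inside the UD contour, for comparison with the distribution of
maximum dive depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from skimage import measure

from .kriging import KrigedField

logger = logging.getLogger(__name__)

__all__ = [
    "UtilizationDistribution",
    "kernel_ud",
    "vertical_profile",
    "dive_depth_distribution",
    "coast_distance",
]


@dataclass
class UtilizationDistribution:
    """Gridded UD: probability mass per cell plus the highest-density region.

    ``contour_cells`` is the minimal set of highest-density cells whose mass
    reaches ``level``; membership tests use the cell set (exact w.r.t. the
    grid), ``polygons`` are a marching-squares rendering for reporting.
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    pmf: np.ndarray              # (nx, ny), sums to 1
    bandwidth: tuple[float, float]
    level: float
    contour_cells: np.ndarray    # (nx, ny) bool
    polygons: list[Polygon]

    @property
    def contour_mass(self) -> float:
        return float(self.pmf[self.contour_cells].sum())

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # nearest-center cell assignment; exact w.r.t. the UD grid
        ix = np.clip(np.rint(
            (np.asarray(x, float) - self.x_centers[0])
            / (self.x_centers[1] - self.x_centers[0])), 0,
            len(self.x_centers) - 1).astype(int)
        iy = np.clip(np.rint(
            (np.asarray(y, float) - self.y_centers[0])
            / (self.y_centers[1] - self.y_centers[0])), 0,
            len(self.y_centers) - 1).astype(int)
        inside_grid = (
            (np.asarray(x, float) >= self.x_centers[0] - (self.x_centers[1] - self.x_centers[0]) / 2)
            & (np.asarray(x, float) <= self.x_centers[-1] + (self.x_centers[1] - self.x_centers[0]) / 2)
            & (np.asarray(y, float) >= self.y_centers[0] - (self.y_centers[1] - self.y_centers[0]) / 2)
            & (np.asarray(y, float) <= self.y_centers[-1] + (self.y_centers[1] - self.y_centers[0]) / 2)
        )
        return inside_grid & self.contour_cells[ix, iy]


def kernel_ud(points: np.ndarray, n_grid: int = 150, pad_bw: float = 3.0,
              level: float = 0.75) -> UtilizationDistribution:
    """Bivariate Gaussian KDE with per-axis normal-reference bandwidth.

    The grid spans the data padded by ``pad_bw`` bandwidths; the ``level``
    region accumulates cells by descending density until the mass is reached.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) array of locations")
    n = pts.shape[0]
    sx = float(np.std(pts[:, 0], ddof=1))
    sy = float(np.std(pts[:, 1], ddof=1))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in a coordinate: KDE undefined")
    hx = 1.06 * sx * n ** (-0.2)
    hy = 1.06 * sy * n ** (-0.2)
    xc = np.linspace(pts[:, 0].min() - pad_bw * hx,
                     pts[:, 0].max() + pad_bw * hx, n_grid)
    yc = np.linspace(pts[:, 1].min() - pad_bw * hy,
                     pts[:, 1].max() + pad_bw * hy, n_grid)
    # separable Gaussian products: density = Gx @ Gy^T / n
    gx = np.exp(-0.5 * ((xc[:, None] - pts[None, :, 0]) / hx) ** 2) / hx
    gy = np.exp(-0.5 * ((yc[:, None] - pts[None, :, 1]) / hy) ** 2) / hy
    dens = (gx @ gy.T) / (2 * np.pi * n)
    pmf = dens / dens.sum()

    order = np.argsort(pmf.ravel())[::-1]
    csum = np.cumsum(pmf.ravel()[order])
    k = int(np.searchsorted(csum, level)) + 1
    cells = np.zeros(pmf.size, dtype=bool)
    cells[order[:k]] = True
    cells = cells.reshape(pmf.shape)
    thr = float(pmf.ravel()[order[k - 1]])

    polys: list[Polygon] = []
    dxc = xc[1] - xc[0]
    dyc = yc[1] - yc[0]
    for contour in measure.find_contours(pmf, thr):
        cx = xc[0] + contour[:, 0] * dxc
        cy = yc[0] + contour[:, 1] * dyc
        if len(contour) >= 4:
            ring = Polygon(np.column_stack([cx, cy]))
            if ring.is_valid and ring.area > 0:
                polys.append(ring)
    return UtilizationDistribution(x_centers=xc, y_centers=yc, pmf=pmf,
                                   bandwidth=(hx, hy), level=level,
                                   contour_cells=cells, polygons=polys)


def vertical_profile(field: KrigedField, selection=None,
                     z_cap: float = 30.0) -> pd.DataFrame:
    """Mean and SD of kriged S_v per 1 m depth bin over selected columns.

    ``selection`` is None (whole domain), a shapely polygon, or a
    UtilizationDistribution (columns inside the contour).
    """
    g = field.grid
    X, Y = np.meshgrid(g.x_centers, g.y_centers, indexing="ij")
    if selection is None:
        colsel = np.ones(X.shape, dtype=bool)
    elif isinstance(selection, UtilizationDistribution):
        colsel = selection.contains(X.ravel(), Y.ravel()).reshape(X.shape)
    else:
        colsel = shapely.contains_xy(selection, X.ravel(), Y.ravel()
                                     ).reshape(X.shape)
    if not colsel.any():
        raise ValueError("selection contains no grid columns")
    zsel = g.z_centers <= z_cap
    rows = []
    for iz in np.where(zsel)[0]:
        layer = field.sv_db[:, :, iz]
        ok = colsel & field.mask[:, :, iz]
        vals = layer[ok]
        rows.append({
            "z": g.z_centers[iz],
            "mean_sv_db": float(vals.mean()) if vals.size else np.nan,
            "sd_sv_db": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            "n_cells": int(vals.size),
        })
    return pd.DataFrame(rows)


def dive_depth_distribution(dives: pd.DataFrame,
                            fixes: pd.DataFrame | None = None,
                            ud: UtilizationDistribution | None = None,
                            bin_m: float = 1.0, z_cap: float = 70.0,
                            max_dt_s: float = 150.0) -> pd.DataFrame:
    """Normalized histogram of maximum dive depths, optionally inside the UD.

    For the UD-conditional histogram each dive is matched to the regularized
    fix nearest in time (within +/- ``max_dt_s``, half the regular interval);
    unmatched dives are excluded and counted in the log.
    """
    d = dives.copy()
    if ud is not None:
        if fixes is None:
            raise ValueError("UD selection needs the regularized fixes")
        keep = np.zeros(len(d), dtype=bool)
        unmatched = 0
        for animal, grp in d.groupby("id"):
            fx = fixes[fixes["id"] == animal].sort_values("t")
            if fx.empty:
                unmatched += len(grp)
                continue
            ft = fx["t"].to_numpy(dtype=float)
            dt_idx = np.searchsorted(ft, grp["start_t"].to_numpy(dtype=float))
            dt_idx = np.clip(dt_idx, 1, len(ft) - 1)
            lo = dt_idx - 1
            pick = np.where(
                np.abs(ft[dt_idx] - grp["start_t"].to_numpy()) <
                np.abs(ft[lo] - grp["start_t"].to_numpy()), dt_idx, lo)
            dt = np.abs(ft[pick] - grp["start_t"].to_numpy())
            ok = dt <= max_dt_s
            unmatched += int((~ok).sum())
            xin = fx["x"].to_numpy()[pick]
            yin = fx["y"].to_numpy()[pick]
            inside = ud.contains(xin, yin)
            keep[d.index.get_indexer(grp.index)] = ok & inside
        if unmatched:
            logger.info("dive matching: %d dives without a fix within +/-%ss",
                        unmatched, max_dt_s)
        d = d[keep]
    edges = np.arange(0.0, z_cap + bin_m / 2, bin_m)
    counts, _ = np.histogram(d["max_depth_m"].to_numpy(dtype=float), bins=edges)
    total = counts.sum()
    if total == 0:
        logger.warning("no dives in the selection: empty histogram")
        freq = np.zeros_like(counts, dtype=float)
    else:
        freq = counts / total
    return pd.DataFrame({"z_lo": edges[:-1], "z_hi": edges[1:],
                         "count": counts, "freq": freq})


def coast_distance(fixes: np.ndarray, coastline: LineString
                   ) -> tuple[np.ndarray, float]:
    """Euclidean point-to-coastline distance (km) per fix, and the mean."""
    pts = np.atleast_2d(np.asarray(fixes, dtype=float))
    d = np.array([coastline.distance(shapely.points(x, y))
                  for x, y in pts]) / 1000.0
    return d, float(d.mean())
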