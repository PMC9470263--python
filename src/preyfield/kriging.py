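"""3-D ordinary kriging of acoustic backscatter with a normal-score transform.

Acoustic surveys measure mean volume backscattering strength (S_v, dB re 1 m^-1)
along transects; the prey field between transects is reconstructed by

1. mapping the dB values to standard-normal scores (rank transform),
2. fitting a variogram (nugget + Gaussian + cubic structures) to the scores,
3. ordinary kriging onto a regular 3-D grid (200 x 200 x 1 m by default) with an
   anisotropic moving neighbourhood (horizontal search radius 50 km, vertical
   20 m, 3-10 neighbours) and a penalization of the outermost neighbours to
   avoid map discontinuities,
4. back-transforming the kriged scores to dB through the inverse rank map.

Vertical distances are scaled by ``h_radius / v_radius`` (2500 by default) so a
single scaled metric serves both the variogram and the neighbourhood search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.special import ndtri
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec3D",
    "NormalScoreMap",
    "VariogramStructure",
    "VariogramModel",
    "Neighbourhood",
    "KrigedField",
    "dedupe_samples",
    "normal_score",
    "empirical_variogram",
    "fit_variogram",
    "krige_points",
    "krige",
    "back_transform",
    "krige_samples_to_field",
]


# --------------------------------------------------------------------------
# grids
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec3D:
    """Regular 3-D grid; ``(x0, y0, z0)`` is the lower edge of the first cell.

    z is depth, positive down, in metres.
    """

    x0: float
    y0: float
    z0: float
    dx: float
    dy: float
    dz: float
    nx: int
    ny: int
    nz: int

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("cell sizes must be positive")
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + self.dx * (np.arange(self.nx) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + self.dy * (np.arange(self.ny) + 0.5)

    @property
    def z_centers(self) -> np.ndarray:
        return self.z0 + self.dz * (np.arange(self.nz) + 0.5)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    def cell_centers(self) -> np.ndarray:
        """All cell centers as an ``(nx*ny*nz, 3)`` array (x fastest-varying last)."""
        X, Y, Z = np.meshgrid(self.x_centers, self.y_centers, self.z_centers,
                              indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


# --------------------------------------------------------------------------
# normal-score transform
# --------------------------------------------------------------------------

@dataclass
class NormalScoreMap:
    """Monotone value <-> Gaussian-score lookup built from the data ranks.

    ``values``/``scores`` are strictly increasing (ties collapsed to a single
    entry carrying the tie-averaged score).  Inverse mapping interpolates
    linearly between data quantiles and clamps beyond the data range.
    """

    values: np.ndarray
    scores: np.ndarray

    def forward(self, v: np.ndarray) -> np.ndarray:
        return np.interp(v, self.values, self.scores)

    def inverse(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.scores, self.values)


def normal_score(values: np.ndarray) -> tuple[np.ndarray, NormalScoreMap]:
    """Rank-based transform of ``values`` to standard-normal scores.

    Uses plotting position ``(r - 0.5) / n`` with tie-averaged ranks; returns
    the transformed values and the invertible map.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be 1-D")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    distinct = np.unique(values)
    if distinct.size == 1:
        raise ValueError("normal-score transform undefined: all values identical")
    if distinct.size < 10:
        raise ValueError("need at least 10 distinct values for a stable transform")
    n = values.size
    ranks = rankdata(values, method="average")
    scores = ndtri((ranks - 0.5) / n)
    order = np.argsort(values, kind="mergesort")
    v_sorted = values[order]
    s_sorted = scores[order]
    keep = np.empty(n, dtype=bool)
    keep[0] = True
    keep[1:] = np.diff(v_sorted) > 0
    nsmap = NormalScoreMap(values=v_sorted[keep], scores=s_sorted[keep])
    return scores, nsmap


# --------------------------------------------------------------------------
# variograms
# --------------------------------------------------------------------------

def _gamma_gaussian(d: np.ndarray, sill: float, rng: float) -> np.ndarray:
    return sill * (1.0 - np.exp(-3.0 * (d / rng) ** 2))


def _gamma_cubic(d: np.ndarray, sill: float, rng: float) -> np.ndarray:
    h = np.minimum(np.asarray(d, dtype=float) / rng, 1.0)
    return sill * (7 * h**2 - 8.75 * h**3 + 3.5 * h**5 - 0.75 * h**7)


_STRUCTURES = {"gaussian": _gamma_gaussian, "cubic": _gamma_cubic}


@dataclass(frozen=True)
class VariogramStructure:
    kind: str
    sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.kind not in _STRUCTURES:
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if self.sill < 0 or self.range_m <= 0:
            raise ValueError("structure needs sill >= 0 and range > 0")

    def gamma(self, d: np.ndarray) -> np.ndarray:
        return _STRUCTURES[self.kind](d, self.sill, self.range_m)


@dataclass(frozen=True)
class VariogramModel:
    """Nested variogram: nugget plus bounded structures, on scaled distance.

    Distances are ``sqrt(dx^2 + dy^2 + (r_aniso * dz)^2)``; r_aniso folds the
    vertical anisotropy into one metric.
    """

    nugget: float = 0.0
    structures: tuple[VariogramStructure, ...] = ()
    r_aniso: float = 2500.0

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.total_sill <= 0:
            raise ValueError("total sill must be positive")

    @property
    def total_sill(self) -> float:
        return self.nugget + sum(s.sill for s in self.structures)

    def scaled_distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        diff[..., 2] *= self.r_aniso
        return np.sqrt((diff**2).sum(axis=-1))

    def gamma(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = np.where(d > 0, self.nugget, 0.0)
        for s in self.structures:
            out = out + s.gamma(d)
        return out

    def covariance(self, d: np.ndarray) -> np.ndarray:
        """Stationary covariance ``C(d) = total_sill - gamma(d)``."""
        return self.total_sill - self.gamma(d)


def empirical_variogram(
    coords: np.ndarray,
    scores: np.ndarray,
    bin_edges: np.ndarray,
    r_aniso: float = 2500.0,
    max_pairs: int = 2_000_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Method-of-moments semivariance per scaled-distance bin.

    Returns a DataFrame with ``lag`` (bin center), ``gamma`` and ``n_pairs``;
    empty bins are flagged with ``n_pairs == 0`` and NaN gamma, never
    fabricated.  For more than ``max_pairs`` point pairs a random subset of
    pairs is used.
    """
    coords = np.asarray(coords, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if coords.shape[0] != scores.shape[0]:
        raise ValueError("coords and scores length mismatch")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    n_all = n * (n - 1) // 2
    if n_all <= max_pairs:
        i, j = np.triu_indices(n, k=1)
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n, size=max_pairs)
        ok = i != j
        i, j = i[ok], j[ok]

    diff = coords[i] - coords[j]
    diff[:, 2] *= r_aniso
    d = np.sqrt((diff**2).sum(axis=1))
    sq = 0.5 * (scores[i] - scores[j]) ** 2

    idx = np.digitize(d, bin_edges) - 1
    nb = len(bin_edges) - 1
    ok = (idx >= 0) & (idx < nb)
    counts = np.bincount(idx[ok], minlength=nb)
    sums = np.bincount(idx[ok], weights=sq[ok], minlength=nb)
    with np.errstate(invalid="ignore"):
        gam = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return pd.DataFrame({"lag": centers, "gamma": gam, "n_pairs": counts})


def fit_variogram(
    empirical: pd.DataFrame,
    structures: tuple[str, ...] = ("gaussian", "cubic"),
    r_aniso: float = 2500.0,
    weighting: str = "cressie",
) -> VariogramModel:
    """Weighted least-squares fit of a nugget + structures model.

    ``weighting='cressie'`` (default) uses Cressie's n / gamma^2 weights,
    which keep the heavily-populated plateau bins from buying nugget bias at
    the short lags; ``'npairs'`` weights by raw pair counts.  Non-negativity
    of the nugget and sills is enforced through the optimizer bounds.
    """
    if weighting not in ("cressie", "npairs"):
        raise ValueError(f"unknown weighting {weighting!r}")
    emp = empirical[empirical["n_pairs"] > 0]
    lags = emp["lag"].to_numpy(dtype=float)
    gam = emp["gamma"].to_numpy(dtype=float)
    w = np.sqrt(emp["n_pairs"].to_numpy(dtype=float))
    if lags.size < 4:
        raise ValueError("need at least 4 non-empty bins to fit a variogram")

    max_lag = lags.max()
    g_max = max(gam.max(), 1e-12)
    n_struct = len(structures)

    def unpack(x: np.ndarray) -> VariogramModel:
        c0 = x[0]
        structs = tuple(
            VariogramStructure(kind=k, sill=x[1 + 2 * s], range_m=x[2 + 2 * s])
            for s, k in enumerate(structures)
        )
        return VariogramModel(nugget=c0, structures=structs, r_aniso=r_aniso)

    def resid(x: np.ndarray) -> np.ndarray:
        c0 = x[0]
        g = np.full_like(lags, c0)
        for s, k in enumerate(structures):
            g = g + _STRUCTURES[k](lags, x[1 + 2 * s], x[2 + 2 * s])
        r = w * (g - gam)
        if weighting == "cressie":
            r = r / np.maximum(g, 1e-9)
        return r

    x0 = [0.25 * gam[0] if gam[0] > 0 else 0.01 * g_max]
    for s in range(n_struct):
        x0 += [g_max / n_struct, max_lag / (2.0 + s)]
    lb = [0.0] + [0.0, 1e-6 * max_lag] * n_struct
    ub = [2 * g_max] + [2 * g_max, 10 * max_lag] * n_struct
    try:
        sol = least_squares(resid, x0=np.asarray(x0), bounds=(lb, ub),
                            x_scale="jac")
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise RuntimeError(f"variogram fit failed: {exc}") from exc
    if not sol.success:
        logger.warning("variogram optimizer did not report success: %s", sol.message)
    x = np.maximum(sol.x, 0.0)
    if x[0] + sum(x[1 + 2 * s] for s in range(n_struct)) <= 0:
        # degenerate flat fit; fall back to pure nugget at the data variance
        x[0] = g_max
    return unpack(x)


# --------------------------------------------------------------------------
# ordinary kriging
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Neighbourhood:
    """Anisotropic moving search neighbourhood."""

    h_radius: float = 50_000.0
    v_radius: float = 20.0
    n_min: int = 3
    n_max: int = 10

    def __post_init__(self) -> None:
        if self.h_radius <= 0 or self.v_radius <= 0:
            raise ValueError("search radii must be positive")
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError("need 1 <= n_min <= n_max")

    @property
    def ratio(self) -> float:
        return self.h_radius / self.v_radius


def dedupe_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Merge duplicated coordinates, averaging S_v in the linear domain."""
    df = samples.copy()
    lin = 10.0 ** (df["sv_db"].to_numpy(dtype=float) / 10.0)
    df = df.assign(_lin=lin)
    out = (
        df.groupby(["x_m", "y_m", "depth_m"], as_index=False)["_lin"].mean()
    )
    out["sv_db"] = 10.0 * np.log10(out.pop("_lin"))
    return out


def _edge_taper(d: np.ndarray, radius: float) -> np.ndarray:
    """Down-weight the outermost neighbours (scaled distance > 0.8 R).

    Linear taper from 1 at 0.8 R to 0.5 at the search boundary; a smooth
    stand-in for neighbourhood-edge penalization that prevents abrupt weight
    changes as points enter/leave the moving neighbourhood.
    """
    t = np.ones_like(d)
    outer = d > 0.8 * radius
    t[outer] = 1.0 - 0.5 * (d[outer] - 0.8 * radius) / (0.2 * radius)
    return np.clip(t, 0.5, 1.0)


def krige_points(
    coords: np.ndarray,
    scores: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
    neighbourhood: Neighbourhood = Neighbourhood(),
    edge_penalization: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging of ``scores`` at arbitrary target points.

    Per target: gather samples within the anisotropic search ellipsoid, keep
    the ``n_max`` nearest by scaled distance, solve the ordinary-kriging
    system (weights constrained to sum to 1).  Targets with fewer than
    ``n_min`` neighbours get NaN estimate and variance.
    """
    coords = np.asarray(coords, dtype=float)
    scores = np.asarray(scores, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    nb = neighbourhood
    ratio = nb.ratio

    sc = coords.copy()
    sc[:, 2] *= ratio
    tc = targets.copy()
    tc[:, 2] *= ratio

    k = min(nb.n_max, coords.shape[0])
    tree = cKDTree(sc)
    dist, idx = tree.query(tc, k=k, distance_upper_bound=nb.h_radius)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    valid = np.isfinite(dist)
    counts = valid.sum(axis=1)

    est = np.full(targets.shape[0], np.nan)
    var = np.full(targets.shape[0], np.nan)
    sill = model.total_sill

    for kk in np.unique(counts):
        if kk < nb.n_min:
            continue
        rows = np.where(counts == kk)[0]
        nidx = idx[rows, :kk]
        ndist = dist[rows, :kk]
        pts = sc[nidx]  # (m, kk, 3) already-scaled coords
        dmat = np.sqrt(
            ((pts[:, :, None, :] - pts[:, None, :, :]) ** 2).sum(axis=-1)
        )
        m = rows.size
        A = np.zeros((m, kk + 1, kk + 1))
        A[:, :kk, :kk] = sill - model.gamma(dmat)
        A[:, :kk, :kk] += 1e-10 * np.eye(kk)
        A[:, kk, :kk] = 1.0
        A[:, :kk, kk] = 1.0
        b = np.ones((m, kk + 1))
        c0 = sill - model.gamma(ndist)
        if edge_penalization:
            c0 = c0 * _edge_taper(ndist, nb.h_radius)
        b[:, :kk] = c0
        try:
            sol = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.full((m, kk + 1), np.nan)
            for r in range(m):
                try:
                    sol[r] = np.linalg.solve(A[r], b[r])
                except np.linalg.LinAlgError:
                    sol[r], *_ = np.linalg.lstsq(A[r], b[r], rcond=None)
        w = sol[:, :kk]
        nu = sol[:, kk]
        est[rows] = (w * scores[nidx]).sum(axis=1)
        var[rows] = np.maximum(sill - (w * c0).sum(axis=1) - nu, 0.0)
    return est, var


def krige(
    coords: np.ndarray,
    scores: np.ndarray,
    model: VariogramModel,
    grid: GridSpec3D,
    neighbourhood: Neighbourhood = Neighbourhood(),
    edge_penalization: bool = True,
    chunk_size: int = 20_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Krige onto the grid; returns (score estimates, variance, estimated mask)."""
    centers = grid.cell_centers()
    est = np.empty(centers.shape[0])
    var = np.empty(centers.shape[0])
    for lo in range(0, centers.shape[0], chunk_size):
        hi = min(lo + chunk_size, centers.shape[0])
        e, v = krige_points(coords, scores, model, centers[lo:hi],
                            neighbourhood, edge_penalization)
        est[lo:hi] = e
        var[lo:hi] = v
    est3 = est.reshape(grid.shape)
    var3 = var.reshape(grid.shape)
    mask = np.isfinite(est3)
    n_masked = int((~mask).sum())
    if n_masked:
        logger.info("kriging: %d of %d cells below n_min neighbours (masked)",
                    n_masked, mask.size)
    return est3, var3, mask


@dataclass
class KrigedField:
    """Back-transformed kriged acoustic field plus kriging variance.

    ``sv_db`` is NaN on masked (un-estimable) cells; ``variance`` is in score
    space.
    """

    grid: GridSpec3D
    sv_db: np.ndarray
    variance: np.ndarray
    mask: np.ndarray
    neighbourhood: Neighbourhood = field(default_factory=Neighbourhood)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "sv_db": (("x", "y", "z"), self.sv_db),
                "variance": (("x", "y", "z"), self.variance),
                "mask": (("x", "y", "z"), self.mask.astype(np.int8)),
            },
            coords={
                "x": self.grid.x_centers,
                "y": self.grid.y_centers,
                "z": self.grid.z_centers,
            },
            attrs={
                "dx": self.grid.dx, "dy": self.grid.dy, "dz": self.grid.dz,
                "h_radius": self.neighbourhood.h_radius,
                "v_radius": self.neighbourhood.v_radius,
                "n_min": self.neighbourhood.n_min,
                "n_max": self.neighbourhood.n_max,
            },
        )

    def save(self, path: str) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def load(cls, path: str) -> "KrigedField":
        ds = xr.load_dataset(path, engine="scipy")
        x = ds["x"].values
        y = ds["y"].values
        z = ds["z"].values
        dx, dy, dz = float(ds.attrs["dx"]), float(ds.attrs["dy"]), float(ds.attrs["dz"])
        grid = GridSpec3D(
            x0=float(x[0] - dx / 2), y0=float(y[0] - dy / 2), z0=float(z[0] - dz / 2),
            dx=dx, dy=dy, dz=dz, nx=x.size, ny=y.size, nz=z.size,
        )
        nb = Neighbourhood(
            h_radius=float(ds.attrs["h_radius"]), v_radius=float(ds.attrs["v_radius"]),
            n_min=int(ds.attrs["n_min"]), n_max=int(ds.attrs["n_max"]),
        )
        return cls(grid=grid, sv_db=ds["sv_db"].values,
                   variance=ds["variance"].values,
                   mask=ds["mask"].values.astype(bool), neighbourhood=nb)


def back_transform(score_grid: np.ndarray, nsmap: NormalScoreMap) -> np.ndarray:
    """Inverse normal-score map; scores beyond the data range clamp to the data
    min/max (conservative tails)."""
    out = np.full(score_grid.shape, np.nan)
    ok = np.isfinite(score_grid)
    out[ok] = nsmap.inverse(score_grid[ok])
    return out


def krige_samples_to_field(
    samples: pd.DataFrame,
    grid: GridSpec3D,
    neighbourhood: Neighbourhood = Neighbourhood(),
    variogram: VariogramModel | None = None,
    n_lag_bins: int = 15,
    edge_penalization: bool = True,
    seed: int | None = None,
) -> tuple[KrigedField, VariogramModel, NormalScoreMap]:
    """Full reconstruction: dedupe -> normal score -> (fit) variogram -> krige
    -> back-transform.

    ``samples`` needs columns x_m, y_m, depth_m, sv_db.  If ``variogram`` is
    None an empirical variogram of the scores is computed on scaled distances
    and a nugget+gaussian+cubic model fitted to it.
    """
    df = dedupe_samples(samples)
    coords = df[["x_m", "y_m", "depth_m"]].to_numpy(dtype=float)
    scores, nsmap = normal_score(df["sv_db"].to_numpy(dtype=float))
    ratio = neighbourhood.ratio
    if variogram is None:
        sc = coords.copy()
        sc[:, 2] *= ratio
        span = np.linalg.norm(sc.max(axis=0) - sc.min(axis=0))
        edges = np.linspace(0.0, 0.6 * span, n_lag_bins + 1)
        emp = empirical_variogram(coords, scores, edges, r_aniso=ratio, seed=seed)
        variogram = fit_variogram(emp, r_aniso=ratio)
    est, var, mask = krige(coords, scores, variogram, grid, neighbourhood,
                           edge_penalization)
    sv = back_transform(est, nsmap)
    fieldk = KrigedField(grid=grid, sv_db=sv, variance=var, mask=mask,
                         neighbourhood=neighbourhood)
    return fieldk, variogram, nsmap
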