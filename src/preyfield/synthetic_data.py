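"""Synthetic seascapes, prey fields, acoustic surveys, tracks, dives, masses.

Every downstream stage of the pipeline is testable without field data: this
module generates inputs with known ground truth under a local planar frame
(metres; origin at the coastline corner of the survey box, coast along x = 0,
water at x > 0).  The emulated study design is a central-place forager breeding
on an island ~9 km offshore, surveyed by cross-shelf acoustic transects spaced
3.5 km apart, with a patchy prey field carrying an inshore hotspot.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.fft import fftn, ifftn, next_fast_len
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import LineString, Point, Polygon, mapping

from .kriging import GridSpec3D, VariogramModel, VariogramStructure

__all__ = [
    "SeascapeConfig",
    "Seascape",
    "HotspotSpec",
    "PreyFieldTruth",
    "SyntheticTrackSpec",
    "DiveDepthSpec",
    "make_seascape",
    "default_variogram",
    "simulate_prey_field",
    "sample_transects",
    "simulate_observed_tracks",
    "simulate_informed_tracks",
    "simulate_dives",
    "simulate_masses",
    "write_fixes_csv",
    "write_dives_csv",
    "write_acoustic_csv",
    "write_masses_csv",
    "write_seascape_geojson",
]


# --------------------------------------------------------------------------
# seascape
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeascapeConfig:
    """Survey-box geometry: straight north-south coast at x = 0, water x > 0."""

    alongshore_extent_m: float = 31_000.0
    offshore_extent_m: float = 14_000.0
    transect_spacing_m: float = 3_500.0
    n_transects: int = 9
    transect_length_m: float = 12_000.0
    colony_offshore_m: float = 9_000.0
    land_depth_m: float = 2_000.0


@dataclass
class Seascape:
    domain_polygon: Polygon
    land_polygon: Polygon
    colony: tuple[float, float]
    transects: list[LineString]
    transect_spacing_m: float
    crs_note: str = ("local planar metres; origin at the southern end of the "
                     "coastline, x offshore, y alongshore")


def make_seascape(config: SeascapeConfig = SeascapeConfig(),
                  seed: int | None = None) -> Seascape:
    """Build a synthetic survey box with coast-perpendicular transects.

    Transects run offshore (along +x) at constant y, spaced
    ``transect_spacing_m`` apart and centred alongshore; the colony sits
    offshore of the coast at the alongshore midpoint.  Rejects configurations
    whose transects would exceed the domain.
    """
    c = config
    if c.transect_spacing_m <= 0:
        raise ValueError("transect spacing must be positive")
    if c.n_transects < 1:
        raise ValueError("need at least one transect")
    span = (c.n_transects - 1) * c.transect_spacing_m
    if span > c.alongshore_extent_m:
        raise ValueError("transects exceed the alongshore extent")
    if c.transect_length_m > c.offshore_extent_m:
        raise ValueError("transects exceed the offshore extent")
    if not (0 < c.colony_offshore_m < c.offshore_extent_m):
        raise ValueError("colony must be offshore inside the domain")
    y0 = (c.alongshore_extent_m - span) / 2.0
    transects = [
        LineString([(0.0, y0 + i * c.transect_spacing_m),
                    (c.transect_length_m, y0 + i * c.transect_spacing_m)])
        for i in range(c.n_transects)
    ]
    domain = Polygon([
        (0.0, 0.0), (c.offshore_extent_m, 0.0),
        (c.offshore_extent_m, c.alongshore_extent_m), (0.0, c.alongshore_extent_m),
    ])
    land = Polygon([
        (-c.land_depth_m, -c.land_depth_m), (0.0, -c.land_depth_m),
        (0.0, c.alongshore_extent_m + c.land_depth_m),
        (-c.land_depth_m, c.alongshore_extent_m + c.land_depth_m),
    ])
    colony = (c.colony_offshore_m, c.alongshore_extent_m / 2.0)
    if not domain.contains(Point(colony)):
        raise ValueError("colony outside the survey domain")
    return Seascape(domain_polygon=domain, land_polygon=land, colony=colony,
                    transects=transects, transect_spacing_m=c.transect_spacing_m)


# --------------------------------------------------------------------------
# prey field truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HotspotSpec:
    """Additive radially decaying (Gaussian-profile) dB anomaly."""

    center_x: float
    center_y: float
    radius_m: float
    amplitude_db: float


@dataclass
class PreyFieldTruth:
    grid: GridSpec3D
    sv_db: np.ndarray
    variogram: VariogramModel
    hotspot: HotspotSpec | None
    seed: int | None


def default_variogram(ratio: float = 2500.0) -> VariogramModel:
    """Patchiness used for synthetic prey fields: 2 dB-SD Gaussian patches with
    a 2 km horizontal range (~8 m vertically at the default anisotropy) plus a
    small nugget."""
    return VariogramModel(
        nugget=0.5,
        structures=(VariogramStructure("gaussian", sill=4.0, range_m=2_000.0),),
        r_aniso=ratio,
    )


def grid_for_seascape(seascape: Seascape, dx: float = 200.0, dy: float = 200.0,
                      dz: float = 1.0, nz: int = 30,
                      buffer_m: float = 1_250.0) -> GridSpec3D:
    """Grid covering coast to the transect margins plus a buffer."""
    xs = [pt for t in seascape.transects for pt in t.xy[0]]
    ys = [pt for t in seascape.transects for pt in t.xy[1]]
    x1 = max(xs) + buffer_m
    ylo, yhi = min(ys) - buffer_m, max(ys) + buffer_m
    nx = int(math.ceil(x1 / dx))
    ny = int(math.ceil((yhi - ylo) / dy))
    return GridSpec3D(x0=0.0, y0=ylo, z0=0.0, dx=dx, dy=dy, dz=dz,
                      nx=nx, ny=ny, nz=nz)


def _grf_fft(grid: GridSpec3D, model: VariogramModel, rng) -> np.ndarray:
    """Stationary Gaussian random field on the grid by circulant embedding.

    The structured covariance (nugget excluded) is embedded in a padded
    periodic domain; negative embedding eigenvalues, if any, are clipped to
    zero, slightly shrinking the realized variance (checked by the recovery
    tests).  Nugget noise is added independently.
    """
    struct_sill = sum(s.sill for s in model.structures)
    if struct_sill <= 0:
        f = np.zeros(grid.shape)
    else:
        np_ = [next_fast_len(2 * n) for n in grid.shape]
        ax = [np.minimum(np.arange(m), m - np.arange(m)) * d
              for m, d in zip(np_, (grid.dx, grid.dy, grid.dz))]
        LX, LY, LZ = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij", sparse=True)
        d = np.sqrt(LX**2 + LY**2 + (model.r_aniso * LZ) ** 2)
        kern = struct_sill - (model.gamma(d) - np.where(d > 0, model.nugget, 0.0))
        lam = np.real(fftn(kern))
        lam = np.clip(lam, 0.0, None)
        w = rng.standard_normal(kern.shape)
        f = np.real(ifftn(np.sqrt(lam) * fftn(w)))
        f = f[: grid.nx, : grid.ny, : grid.nz]
    if model.nugget > 0:
        f = f + rng.normal(0.0, math.sqrt(model.nugget), size=grid.shape)
    return f


def simulate_prey_field(seascape: Seascape, base_mean_db: float = -75.0,
                        variogram: VariogramModel | None = None,
                        hotspot: HotspotSpec | None = None,
                        grid: GridSpec3D | None = None,
                        seed: int | None = None) -> PreyFieldTruth:
    """Gaussian random field with the requested covariance plus hotspot bump.

    The hotspot adds ``amplitude_db * exp(-0.5 (d / radius)^2)`` at horizontal
    distance d from its centre, uniformly over depth.  Deterministic for a
    fixed seed.
    """
    if variogram is None:
        variogram = default_variogram()
    if grid is None:
        grid = grid_for_seascape(seascape)
    rng = np.random.default_rng(seed)
    f = _grf_fft(grid, variogram, rng) + base_mean_db
    if hotspot is not None and hotspot.amplitude_db != 0:
        X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
        d2 = (X - hotspot.center_x) ** 2 + (Y - hotspot.center_y) ** 2
        bump = hotspot.amplitude_db * np.exp(-0.5 * d2 / hotspot.radius_m**2)
        f = f + bump[:, :, None]
    if not np.all(np.isfinite(f)):
        raise RuntimeError("non-finite values in simulated prey field")
    return PreyFieldTruth(grid=grid, sv_db=f, variogram=variogram,
                          hotspot=hotspot, seed=seed)


def sample_transects(truth: PreyFieldTruth, seascape: Seascape,
                     along_step_m: float = 200.0, noise_sd_db: float = 0.5,
                     seed: int | None = None) -> pd.DataFrame:
    """Acoustic samples along the transects: trilinear reads of the truth plus
    Gaussian dB noise, at every (along-step x 1 m depth-bin) node."""
    if along_step_m <= 0:
        raise ValueError("along_step_m must be positive")
    rng = np.random.default_rng(seed)
    g = truth.grid
    interp = RegularGridInterpolator(
        (g.x_centers, g.y_centers, g.z_centers), truth.sv_db,
        bounds_error=True)
    rows = []
    for ti, tr in enumerate(seascape.transects):
        (xa, ya), (xb, yb) = tr.coords[0], tr.coords[-1]
        length = math.hypot(xb - xa, yb - ya)
        n_along = int(length // along_step_m) + 1
        for j in range(n_along):
            frac = j * along_step_m / length
            x = xa + frac * (xb - xa)
            y = ya + frac * (yb - ya)
            x = min(max(x, g.x_centers[0]), g.x_centers[-1])
            y = min(max(y, g.y_centers[0]), g.y_centers[-1])
            for z in g.z_centers:
                rows.append((x, y, z))
    pts = np.asarray(rows)
    try:
        vals = interp(pts)
    except ValueError as exc:
        raise ValueError(f"transect exits the truth grid: {exc}") from exc
    if noise_sd_db > 0:
        vals = vals + rng.normal(0.0, noise_sd_db, size=vals.size)
    return pd.DataFrame({"x_m": pts[:, 0], "y_m": pts[:, 1],
                         "depth_m": pts[:, 2], "sv_db": vals})


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTrackSpec:
    """Observation model for synthetic GPS tracks.

    A latent two-state 5-min track is thinned (each fix dropped independently
    with ``dropout_fraction``) and jittered with isotropic Gaussian noise of SD
    ``obs_noise_sd_m`` (default 5 m, the nominal GPS error).
    """

    hmm: "HMMParams"
    n_tracks: int = 10
    n_fixes: int = 140
    fix_interval_s: float = 300.0
    obs_noise_sd_m: float = 5.0
    dropout_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_fraction < 1):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.n_fixes < 3:
            raise ValueError("need n_fixes >= 3")


def _observe(latent: pd.DataFrame, noise_sd: float, dropout: float, rng,
             jitter_times: bool = True) -> pd.DataFrame:
    n = len(latent)
    keep = rng.random(n) >= dropout
    keep[0] = keep[-1] = True  # anchor trip endpoints
    obs = latent.loc[keep, ["t", "x", "y"]].reset_index(drop=True)
    if noise_sd > 0:
        obs["x"] += rng.normal(0, noise_sd, size=len(obs))
        obs["y"] += rng.normal(0, noise_sd, size=len(obs))
    if jitter_times and dropout > 0:
        obs["t"] = obs["t"] + np.concatenate([
            [0.0], rng.uniform(-20, 20, size=len(obs) - 1)])
        obs = obs.sort_values("t").reset_index(drop=True)
    return obs


def simulate_observed_tracks(spec: SyntheticTrackSpec, seascape: Seascape,
                             seed: int | None = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent two-state tracks thinned and jittered into irregular GPS fixes.

    Tracks start at the colony.  Returns (observed fixes, latent truth with
    state labels); both carry an ``id`` column.
    """
    from .movement_hmm import simulate_hmm_track

    if bool(shapely.contains_xy(seascape.land_polygon, *seascape.colony)):
        raise ValueError("start position is on land")
    rng = np.random.default_rng(seed)
    obs_l, truth_l = [], []
    for i in range(spec.n_tracks):
        sub = int(rng.integers(0, 2**31 - 1))
        latent = simulate_hmm_track(spec.hmm, spec.n_fixes, seascape.colony,
                                    seascape.land_polygon, spec.fix_interval_s,
                                    seed=sub)
        latent.insert(0, "id", f"tr{i:04d}")
        obs = _observe(latent, spec.obs_noise_sd_m, spec.dropout_fraction, rng)
        obs.insert(0, "id", f"tr{i:04d}")
        obs_l.append(obs)
        truth_l.append(latent)
    return (pd.concat(obs_l, ignore_index=True),
            pd.concat(truth_l, ignore_index=True))


def simulate_informed_tracks(hmm: "HMMParams", n_tracks: int, n_fixes: int,
                             seascape: Seascape,
                             attractor: tuple[float, float],
                             attract_radius_m: float,
                             p_attract: float = 0.7,
                             interval_s: float = 300.0,
                             seed: int | None = None) -> list[pd.DataFrame]:
    """Prey-seeking tracks: HMM movement biased towards an attractor.

    Outside ``attract_radius_m`` of the attractor each step's heading is, with
    probability ``p_attract``, redrawn as the bearing to the attractor plus
    von Mises(kappa=2) noise; inside the radius movement follows the plain HMM
    kernel.  Used as the 'informed forager' arm of synthetic experiments.
    """
    rng = np.random.default_rng(seed)
    shape = tuple((m / s) ** 2 for m, s in zip(hmm.step_mean, hmm.step_sd))
    scale = tuple(s * s / m for m, s in zip(hmm.step_mean, hmm.step_sd))
    G = np.asarray(hmm.tmat)
    land = seascape.land_polygon
    out = []
    for k in range(n_tracks):
        x = np.empty(n_fixes)
        y = np.empty(n_fixes)
        x[0], y[0] = seascape.colony
        heading = rng.uniform(-math.pi, math.pi)
        s = int(rng.choice(2, p=np.asarray(hmm.delta)))
        states = np.zeros(n_fixes, dtype=int)
        for i in range(1, n_fixes):
            if i > 1:
                s = int(rng.choice(2, p=G[s]))
            for attempt in range(1000):
                step = max(float(rng.gamma(shape[s], scale[s])), 1.0)
                dx, dy = attractor[0] - x[i - 1], attractor[1] - y[i - 1]
                outside = math.hypot(dx, dy) > attract_radius_m
                if attempt >= 200:
                    # shore-pressed fallback: broaden the heading proposal
                    h_prop = rng.uniform(-math.pi, math.pi)
                elif outside and rng.random() < p_attract:
                    h_prop = math.atan2(dy, dx) + float(rng.vonmises(0.0, 2.0))
                elif i == 1:
                    h_prop = rng.uniform(-math.pi, math.pi)
                else:
                    h_prop = heading + float(
                        rng.vonmises(hmm.turn_mean[s], hmm.turn_kappa[s]))
                nx = x[i - 1] + step * math.cos(h_prop)
                ny = y[i - 1] + step * math.sin(h_prop)
                if not bool(shapely.contains_xy(land, nx, ny)):
                    break
            else:
                raise RuntimeError(f"land rejection exhausted at fix {i}")
            heading = h_prop
            x[i], y[i] = nx, ny
            states[i] = s
        states[0] = states[1]
        from .track_processing import steps_and_turns
        step_arr, turn_arr = steps_and_turns(x, y)
        df = pd.DataFrame({"t": interval_s * np.arange(n_fixes), "x": x, "y": y,
                           "state": states, "step_m": step_arr,
                           "turn_rad": turn_arr})
        df.insert(0, "id", f"real{k:04d}")
        out.append(df)
    return out


# --------------------------------------------------------------------------
# dives & masses
# --------------------------------------------------------------------------

@dataclass
class DiveDepthSpec:
    """Maximum-dive-depth distribution with a sub-threshold contamination.

    ``dist`` is a frozen scipy distribution with support in (0, 70] m, a
    constant (point mass), or a (depths, probs) pair.  With probability
    ``subthreshold_fraction`` a dive is replaced by one failing the 2 m / 5 s
    filter, to exercise QC.  The default emulates shallow foragers: depth =
    2 + Exponential(mean 8 m) truncated at 70 m, putting ~63% of dives above
    10 m depth.
    """

    dist: object = None
    subthreshold_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.dist is None:
            from scipy.stats import truncexpon
            self.dist = truncexpon(b=(70.0 - 2.0) / 8.0, loc=2.0, scale=8.0)
        if not (0 <= self.subthreshold_fraction < 1):
            raise ValueError("subthreshold_fraction must be in [0, 1)")

    def draw(self, n: int, rng) -> np.ndarray:
        if np.isscalar(self.dist):
            d = np.full(n, float(self.dist))
        elif isinstance(self.dist, tuple):
            depths, probs = self.dist
            d = rng.choice(np.asarray(depths, float), size=n,
                           p=np.asarray(probs, float))
        else:
            d = np.asarray(self.dist.rvs(size=n, random_state=rng), dtype=float)
        if np.any((d <= 0) | (d > 70)):
            raise ValueError("depth distribution must have support in (0, 70] m")
        return d


def simulate_dives(track: pd.DataFrame, spec: DiveDepthSpec = None,
                   seed: int | None = None) -> pd.DataFrame:
    """One dive per fix: depth from the spec, duration = 2 x depth + Exp(10 s)."""
    if spec is None:
        spec = DiveDepthSpec()
    rng = np.random.default_rng(seed)
    n = len(track)
    depth = spec.draw(n, rng)
    dur = 2.0 * depth + rng.exponential(10.0, size=n)
    if spec.subthreshold_fraction > 0:
        bad = rng.random(n) < spec.subthreshold_fraction
        shallow = rng.random(n) < 0.5
        depth = np.where(bad & shallow, rng.uniform(0.2, 1.9, size=n), depth)
        dur = np.where(bad & shallow, 2.0 * depth + rng.exponential(10.0, size=n), dur)
        dur = np.where(bad & ~shallow, rng.uniform(1.0, 4.9, size=n), dur)
    out = pd.DataFrame({
        "start_t": track["t"].to_numpy(dtype=float),
        "max_depth_m": depth,
        "duration_s": dur,
    })
    if "id" in track.columns:
        out.insert(0, "id", track["id"].to_numpy())
    return out


def simulate_masses(n_per_sex_year: int,
                    sex_year_effects_g: dict,
                    sd_g: float = 60.0,
                    baselines_g: dict | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Deployment masses: sex baseline + year effect + Gaussian noise.

    ``sex_year_effects_g`` maps sex -> {year: effect in grams}.
    """
    if sd_g < 0:
        raise ValueError("sd_g must be >= 0")
    if baselines_g is None:
        baselines_g = {"F": 1000.0, "M": 1100.0}
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for sex in sorted(sex_year_effects_g):
        for year in sorted(sex_year_effects_g[sex]):
            eff = sex_year_effects_g[sex][year]
            mass = baselines_g[sex] + eff + rng.normal(0, sd_g, size=n_per_sex_year)
            for m in mass:
                rows.append((f"p{i:05d}", sex, int(year), float(m)))
                i += 1
    return pd.DataFrame(rows, columns=["id", "sex", "year", "mass_g"])


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_fixes_csv(fixes: pd.DataFrame, path: str,
                    epoch: str = "2017-10-01T00:00:00") -> None:
    df = fixes.copy()
    if "timestamp" not in df.columns:
        df["timestamp"] = (pd.Timestamp(epoch)
                           + pd.to_timedelta(df["t"], unit="s"))
    cols = ["id", "timestamp"] + [c for c in ("lon", "lat") if c in df.columns]
    if "lon" not in df.columns:
        cols += ["x", "y"]
    df[cols].to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def write_dives_csv(dives: pd.DataFrame, path: str) -> None:
    dives.to_csv(path, index=False)


def write_acoustic_csv(samples: pd.DataFrame, path: str) -> None:
    samples[["x_m", "y_m", "depth_m", "sv_db"]].to_csv(path, index=False)


def write_masses_csv(masses: pd.DataFrame, path: str) -> None:
    masses[["id", "sex", "year", "mass_g"]].to_csv(path, index=False)


def write_seascape_geojson(seascape: Seascape, path: str) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": "domain"},
             "geometry": mapping(seascape.domain_polygon)},
            {"type": "Feature", "properties": {"name": "land"},
             "geometry": mapping(seascape.land_polygon)},
            {"type": "Feature", "properties": {"name": "colony"},
             "geometry": mapping(Point(seascape.colony))},
        ] + [
            {"type": "Feature", "properties": {"name": f"transect{i}"},
             "geometry": mapping(t)}
            for i, t in enumerate(seascape.transects)
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)
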