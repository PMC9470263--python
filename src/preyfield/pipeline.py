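"""Configuration, orchestration, and the canonical synthetic experiments.

``run_pipeline`` composes the whole per-year analysis on file inputs:
track QC -> CTCRW regularization -> HMM classification -> null-track
simulation -> 3-D kriging -> depth-weighted encounter bootstrap -> space-use
and mass summaries, with one master seed deterministically deriving every
stage seed.

The ``*_experiment`` helpers build fully synthetic scenarios with known ground
truth (an inshore prey hotspot sampled along transects, prey-seeking
'informed' foragers vs a random-movement ensemble) and recover the generating
parameters; they back both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import encounter_analysis as enc
from . import kriging as kg
from . import mass_condition as mc
from . import movement_hmm as mh
from . import space_use_dives as su
from . import synthetic_data as sd
from . import track_processing as tp

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "derive_seed",
    "default_hmm_params",
    "regularize_tracks",
    "run_pipeline",
    "encounter_experiment",
    "hmm_recovery_experiment",
    "ctcrw_recovery_experiment",
    "ctcrw_linear_limit",
    "variogram_recovery_experiment",
    "bootstrap_null_calibration",
    "ud_coverage_experiment",
    "mass_calibration_experiment",
    "run_acceptance_experiment",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study constants."""

    # track processing
    interval_s: float = 300.0
    vmax_ms: float = 20.0
    tau_obs_m: float = 5.0
    colony_radius_m: float = 500.0
    # dive filter
    min_dive_depth_m: float = 2.0
    min_dive_duration_s: float = 5.0
    # kriging
    grid_dx_m: float = 200.0
    grid_dy_m: float = 200.0
    grid_dz_m: float = 1.0
    grid_nz: int = 30
    grid_buffer_m: float = 1250.0
    h_radius_m: float = 50_000.0
    v_radius_m: float = 20.0
    n_min_neighbours: int = 3
    n_max_neighbours: int = 10
    # HMM / simulation
    hmm_restarts: int = 10
    n_per_year_subset: int = 10
    n_sim_tracks: int = 5000
    max_outside_fraction: float = 0.20
    # encounter
    n_draws: int = 100_000
    z_cap_m: float = 30.0
    encounter_mode: str = "all_fixes"
    # space use
    ud_level: float = 0.75
    # master seed
    seed: int = 0

    def validate(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not (0 < self.ud_level < 1):
            raise ValueError("ud_level must be in (0, 1)")
        if not (0 <= self.max_outside_fraction <= 1):
            raise ValueError("max_outside_fraction must be in [0, 1]")
        if self.interval_s <= 0 or self.vmax_ms <= 0 or self.tau_obs_m <= 0:
            raise ValueError("interval, vmax and tau must be positive")
        if min(self.grid_dx_m, self.grid_dy_m, self.grid_dz_m) <= 0:
            raise ValueError("grid cell sizes must be positive")
        if not (1 <= self.n_min_neighbours <= self.n_max_neighbours):
            raise ValueError("need 1 <= n_min <= n_max neighbours")
        if self.encounter_mode not in ("all_fixes", "foraging_only"):
            raise ValueError("unknown encounter mode")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    @property
    def neighbourhood(self) -> kg.Neighbourhood:
        return kg.Neighbourhood(h_radius=self.h_radius_m, v_radius=self.v_radius_m,
                                n_min=self.n_min_neighbours,
                                n_max=self.n_max_neighbours)


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed: SeedSequence over (master, crc32(stage))."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF,
                                 zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def default_hmm_params() -> mh.HMMParams:
    """Two-state movement kernel used by the synthetic study conditions:
    area-restricted search (150 m mean steps, diffuse turns) vs directed
    transit (700 m steps, turns concentrated at zero), sticky states."""
    return mh.HMMParams(
        step_mean=(150.0, 700.0), step_sd=(100.0, 300.0),
        turn_mean=(0.0, 0.0), turn_kappa=(0.5, 8.0),
        tmat=((0.9, 0.1), (0.1, 0.9)), delta=(0.5, 0.5),
    )


# --------------------------------------------------------------------------
# shared building blocks
# --------------------------------------------------------------------------

def regularize_tracks(fixes: pd.DataFrame, config: RunConfig,
                      ) -> list[pd.DataFrame]:
    """Per animal: speed filter, CTCRW fit, 5-min smoothed predictions."""
    out = []
    for animal, df in fixes.groupby("id", sort=True):
        df = df.sort_values("t").reset_index(drop=True)
        df = tp.filter_speed(df, vmax_ms=config.vmax_ms)
        if df.attrs.get("unusable") or len(df) < 10:
            logger.warning("track %s unusable after QC; skipped", animal)
            continue
        params, _ = tp.fit_ctcrw(df, tau_obs=config.tau_obs_m)
        reg = tp.predict_regular(df, params, interval_s=config.interval_s)
        reg.attrs["ctcrw"] = params
        out.append(reg)
    return out


def _decode_states(tracks: list[pd.DataFrame], params: mh.HMMParams
                   ) -> list[pd.DataFrame]:
    out = []
    for tr in tracks:
        seq = mh.decode(tr, params)
        tr = tr.copy()
        states = np.empty(len(tr), dtype=int)
        states[1:] = seq.states
        states[0] = seq.states[0]
        tr["state"] = states
        out.append(tr)
    return out


# --------------------------------------------------------------------------
# file-based pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, paths: dict, out_dir: str) -> dict:
    """End-to-end run on CSV/GeoJSON inputs; writes per-year reports.

    ``paths`` needs keys fixes, dives, acoustic, masses, seascape.  Fixes may
    carry lon/lat (projected about the colony) or planar x/y.  A ``year``
    column groups the analysis; absent that, everything is one year.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import shapely.geometry as sgeom

    with open(paths["seascape"]) as fh:
        gj = json.load(fh)
    geoms = {f["properties"]["name"]: sgeom.shape(f["geometry"])
             for f in gj["features"]}
    domain = geoms["domain"]
    land = geoms.get("land")
    colony = (geoms["colony"].x, geoms["colony"].y)
    transects = [g for n, g in geoms.items() if n.startswith("transect")]

    fixes = pd.read_csv(paths["fixes"], parse_dates=["timestamp"])
    if "lon" in fixes.columns:
        fixes = tp.project_to_plane(fixes, origin=colony)
    fixes["t"] = fixes["timestamp"].astype("int64") / 1e9
    fixes["year"] = fixes.get("year", fixes["timestamp"].dt.year)

    dives = pd.read_csv(paths["dives"])
    dives = tp.filter_dives(dives, config.min_dive_depth_m,
                            config.min_dive_duration_s)
    acoustic = pd.read_csv(paths["acoustic"])
    masses = pd.read_csv(paths["masses"])

    grid_xy = [p for t in transects for p in np.asarray(t.coords)]
    xs = [p[0] for p in grid_xy]
    ys = [p[1] for p in grid_xy]
    b = config.grid_buffer_m
    grid = kg.GridSpec3D(
        x0=0.0, y0=min(ys) - b, z0=0.0,
        dx=config.grid_dx_m, dy=config.grid_dy_m, dz=config.grid_dz_m,
        nx=int(math.ceil((max(xs) + b) / config.grid_dx_m)),
        ny=int(math.ceil((max(ys) - min(ys) + 2 * b) / config.grid_dy_m)),
        nz=config.grid_nz,
    )

    reports = {}
    years = sorted(fixes["year"].unique())
    # HMM on a per-year random subset of regularized tracks
    reg_by_year: dict = {}
    for year in years:
        reg_by_year[year] = regularize_tracks(fixes[fixes["year"] == year], config)
    hmm_params, hmm_ll, chosen = mh.fit_on_subset(
        reg_by_year, n_per_year=config.n_per_year_subset,
        seed=derive_seed(config.seed, "hmm_subset"),
        n_restarts=config.hmm_restarts)
    hmm_params.to_json(str(out / "hmm_params.json"))

    for year in years:
        real = _decode_states(reg_by_year[year], hmm_params)
        real = mh.filter_in_domain(real, domain, config.max_outside_fraction)
        if not real:
            logger.warning("year %s: no tracks inside the survey domain", year)
            continue
        lengths = np.array([len(tr) for tr in real])
        sims = mh.simulate_ensemble(
            hmm_params, config.n_sim_tracks, lengths, colony, land,
            config.interval_s, seed=derive_seed(config.seed, f"ensemble{year}"))
        sims = mh.filter_in_domain(sims, domain, config.max_outside_fraction)

        ac = acoustic[acoustic["year"] == year] if "year" in acoustic.columns \
            else acoustic
        fieldk, vario, nsmap = kg.krige_samples_to_field(
            ac, grid, config.neighbourhood,
            seed=derive_seed(config.seed, f"vario{year}"))
        fieldk.save(str(out / f"kriged_{year}.nc"))

        dv = dives[dives["id"].isin(fixes.loc[fixes["year"] == year, "id"])] \
            if "id" in dives.columns else dives
        rep = enc.run_year(real, sims, fieldk, dv, n_draws=config.n_draws,
                           z_cap=config.z_cap_m, mode=config.encounter_mode,
                           seed=derive_seed(config.seed, f"boot{year}"))
        boot = rep.pop("bootstrap")
        np.savetxt(out / f"anomaly_draws_{year}.csv.gz", boot.anomalies)

        forage_pts = np.concatenate([
            tr.loc[tr["state"] == hmm_params.foraging_state, ["x", "y"]]
            .to_numpy(dtype=float) for tr in real])
        if forage_pts.shape[0] >= 2 and np.std(forage_pts, axis=0).min() > 0:
            ud = su.kernel_ud(forage_pts, level=config.ud_level)
            prof_all = su.vertical_profile(fieldk, None, config.z_cap_m)
            prof_ud = su.vertical_profile(fieldk, ud, config.z_cap_m)
            prof_all.to_csv(out / f"profile_all_{year}.csv", index=False)
            prof_ud.to_csv(out / f"profile_ud_{year}.csv", index=False)
        reports[int(year)] = rep

    anoms, summary = mc.mass_anomaly(masses)
    coefs = []
    for sex in ("F", "M"):
        if (anoms["sex"] == sex).any():
            cf = mc.fit_year_model(anoms, sex=sex)
            cf.insert(0, "sex", sex)
            coefs.append(cf)
    if coefs:
        pd.concat(coefs).to_csv(out / "mass_year_models.csv", index=False)
    summary.to_csv(out / "mass_anomaly_summary.csv", index=False)

    manifest = {
        "config": asdict(config),
        "stage_seeds": {s: derive_seed(config.seed, s)
                        for s in ["hmm_subset"] +
                        [f"ensemble{y}" for y in years] +
                        [f"boot{y}" for y in years]},
        "hmm_loglik": hmm_ll,
        "hmm_subset": {str(k): v for k, v in chosen.items()},
        "reports": reports,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


# --------------------------------------------------------------------------
# synthetic end-to-end experiment
# --------------------------------------------------------------------------

def encounter_experiment(seed: int, hotspot_amplitude_db: float = 12.0,
                         n_real: int = 15, n_sim: int = 500,
                         n_fixes: int = 140, n_draws: int = 10_000,
                         hmm_restarts: int = 6,
                         _cache: dict | None = None) -> dict:
    """Hotspot signal-detection experiment through the full pipeline.

    An inshore prey hotspot (Gaussian bump, 5 km radius) is planted in a patchy
    3-D field, sampled along 9 transects, and reconstructed by kriging.
    'Informed' foragers biased towards the hotspot play the real animals; an
    HMM fitted to their regularized tracks drives a random-movement ensemble.
    Returns the per-year style report plus scenario metadata.  Passing the
    dict returned under ``"reuse"`` as ``_cache`` re-scores the SAME tracks
    against a field with a different hotspot amplitude (the negative control).
    """
    config = RunConfig(seed=seed, n_sim_tracks=n_sim, n_draws=n_draws,
                       hmm_restarts=hmm_restarts)
    seascape = sd.make_seascape()
    grid = sd.grid_for_seascape(seascape)
    ratio = config.neighbourhood.ratio
    vario_truth = sd.default_variogram(ratio)
    # hotspot centred on the third transect, 2.5 km offshore
    ty = seascape.transects[2].coords[0][1]
    hotspot = sd.HotspotSpec(center_x=2500.0, center_y=ty, radius_m=5000.0,
                             amplitude_db=hotspot_amplitude_db)

    if _cache is None:
        hmm_truth = default_hmm_params()
        real_latent = sd.simulate_informed_tracks(
            hmm_truth, n_real, n_fixes, seascape,
            attractor=(hotspot.center_x, hotspot.center_y),
            attract_radius_m=hotspot.radius_m, p_attract=0.7,
            seed=derive_seed(seed, "informed"))
        rng = np.random.default_rng(derive_seed(seed, "observe"))
        obs = []
        for tr in real_latent:
            o = sd._observe(tr, noise_sd=5.0, dropout=0.2, rng=rng)
            o.insert(0, "id", tr["id"].iloc[0])
            obs.append(o)
        real_reg = regularize_tracks(pd.concat(obs, ignore_index=True), config)
        hmm_fit, _ = mh.fit_hmm(real_reg, seed=derive_seed(seed, "hmmfit"),
                                n_restarts=hmm_restarts)
        real_reg = _decode_states(real_reg, hmm_fit)
        lengths = np.array([len(tr) for tr in real_reg])
        sims = mh.simulate_ensemble(
            hmm_fit, n_sim, lengths, seascape.colony, seascape.land_polygon,
            seed=derive_seed(seed, "ensemble"))
        real_reg = mh.filter_in_domain(real_reg, seascape.domain_polygon, 0.20)
        sims = mh.filter_in_domain(sims, seascape.domain_polygon, 0.20)
        dives = pd.concat([
            sd.simulate_dives(tr, sd.DiveDepthSpec(subthreshold_fraction=0.1),
                              seed=derive_seed(seed, f"dives{i}"))
            for i, tr in enumerate(real_latent)], ignore_index=True)
        dives = tp.filter_dives(dives)
    else:
        hmm_truth = _cache["hmm_truth"]
        real_reg, sims, dives = (_cache["real_reg"], _cache["sims"],
                                 _cache["dives"])

    truth = sd.simulate_prey_field(
        seascape, base_mean_db=-75.0, variogram=vario_truth,
        hotspot=hotspot, grid=grid,
        seed=derive_seed(seed, f"field{hotspot_amplitude_db}"))
    samples = sd.sample_transects(truth, seascape, along_step_m=200.0,
                                  noise_sd_db=0.5,
                                  seed=derive_seed(seed, "survey"))
    fieldk, vario_fit, _ = kg.krige_samples_to_field(
        samples, grid, config.neighbourhood,
        seed=derive_seed(seed, "variofit"))

    rep = enc.run_year(real_reg, sims, fieldk, dives, n_draws=n_draws,
                       z_cap=30.0, seed=derive_seed(seed, "boot"))
    rep.pop("bootstrap")
    rep["hotspot_amplitude_db"] = hotspot_amplitude_db
    rep["n_samples"] = len(samples)

    # field-recovery skill: kriging vs nearest-neighbour baseline on cells
    # near the transects (within one spacing), depth-averaged truth vs estimate
    from scipy.interpolate import NearestNDInterpolator
    est = fieldk.sv_db
    ok = fieldk.mask & np.isfinite(truth.sv_db)
    coords = samples[["x_m", "y_m", "depth_m"]].to_numpy()
    sc = coords.copy()
    sc[:, 2] *= ratio
    nn = NearestNDInterpolator(sc, samples["sv_db"].to_numpy())
    centers = grid.cell_centers()
    centers_sc = centers.copy()
    centers_sc[:, 2] *= ratio
    ty_all = np.array([t.coords[0][1] for t in seascape.transects])
    near = np.min(np.abs(centers[:, 1][:, None] - ty_all[None, :]), axis=1) \
        <= seascape.transect_spacing_m / 2
    near &= centers[:, 0] <= max(t.coords[-1][0] for t in seascape.transects)
    sel = near.reshape(grid.shape) & ok
    nn_vals = nn(centers_sc[near.ravel()])
    rmse_k = float(np.sqrt(np.nanmean((est[sel] - truth.sv_db[sel]) ** 2)))
    tr_near = truth.sv_db.reshape(-1)[near.ravel()]
    rmse_nn = float(np.sqrt(np.nanmean((nn_vals - tr_near) ** 2)))
    rep["kriging_rmse_db"] = rmse_k
    rep["nearest_neighbour_rmse_db"] = rmse_nn
    rep["reuse"] = {"hmm_truth": hmm_truth, "real_reg": real_reg,
                    "sims": sims, "dives": dives}
    return rep


# --------------------------------------------------------------------------
# recovery / calibration experiments
# --------------------------------------------------------------------------

def hmm_recovery_experiment(seed: int, n_tracks: int = 50, n_fixes: int = 140,
                            n_restarts: int = 10) -> dict:
    """Simulate from the known two-state kernel, refit, decode; report the
    worst relative parameter error and the decoding accuracy."""
    truth = default_hmm_params()
    rng = np.random.default_rng(derive_seed(seed, "hmmrec"))
    tracks = [mh.simulate_hmm_track(truth, n_fixes, (0.0, 0.0),
                                    seed=int(rng.integers(2**31 - 1)))
              for _ in range(n_tracks)]
    fit, _ = mh.fit_hmm(tracks, seed=derive_seed(seed, "hmmrecfit"),
                        n_restarts=n_restarts)
    rel = {}
    for name, tv, fv in [
        ("step_mean", truth.step_mean, fit.step_mean),
        ("step_sd", truth.step_sd, fit.step_sd),
        ("turn_kappa", truth.turn_kappa, fit.turn_kappa),
        ("tmat_diag", (truth.tmat[0][0], truth.tmat[1][1]),
         (fit.tmat[0][0], fit.tmat[1][1])),
    ]:
        rel[name] = max(abs(f - t) / t for t, f in zip(tv, fv))
    correct = total = 0
    for tr in tracks:
        seq = mh.decode(tr, fit)
        truth_states = tr["state"].to_numpy()[1:]
        correct += int((seq.states == truth_states).sum())
        total += truth_states.size
    return {"max_rel_err": max(rel.values()), "rel_err": rel,
            "decode_accuracy": correct / total,
            "n_tracks": n_tracks, "n_fixes": n_fixes}


def ctcrw_recovery_experiment(seed: int, n_tracks: int = 20, n_obs: int = 2000,
                              beta: float = 0.01, sigma: float = 0.2) -> dict:
    """Median relative error of (beta, sigma) over simulated irregular tracks."""
    rng = np.random.default_rng(derive_seed(seed, "ctcrwrec"))
    true = tp.CtcrwParams(beta=beta, sigma=sigma, tau_obs=5.0)
    errs_b, errs_s = [], []
    for _ in range(n_tracks):
        times = np.cumsum(rng.uniform(30.0, 90.0, size=n_obs))
        tr = tp.simulate_ctcrw_track(true, times,
                                     seed=int(rng.integers(2**31 - 1)))
        fit, _ = tp.fit_ctcrw(tr, tau_obs=5.0)
        errs_b.append(abs(fit.beta - beta) / beta)
        errs_s.append(abs(fit.sigma - sigma) / sigma)
    return {"beta_median_rel_err": float(np.median(errs_b)),
            "sigma_median_rel_err": float(np.median(errs_s)),
            "n_tracks": n_tracks, "n_obs": n_obs}


def ctcrw_linear_limit(n_obs: int = 121, speed: float = 1.5,
                       dt: float = 60.0) -> float:
    """Max deviation (m) of 5-min predictions from linear interpolation on a
    noiseless constant-velocity track."""
    t = dt * np.arange(n_obs)
    track = pd.DataFrame({"t": t, "x": speed * t, "y": 0.5 * speed * t})
    params, _ = tp.fit_ctcrw(track, tau_obs=5.0)
    reg = tp.predict_regular(track, params, interval_s=300.0)
    lin_x = np.interp(reg["t"], t, track["x"])
    lin_y = np.interp(reg["t"], t, track["y"])
    return float(np.hypot(reg["x"] - lin_x, reg["y"] - lin_y).max())


def variogram_recovery_experiment(seed: int, n_lines: int = 16,
                                  n_along: int = 200,
                                  extent_m: float = 80_000.0,
                                  nugget: float = 0.1, sill: float = 0.9,
                                  range_m: float = 5_000.0) -> dict:
    """Simulate a 2-D Gaussian field on a line survey (dense Cholesky), fit
    the empirical variogram, and report relative parameter errors.

    Sampling mimics a transect survey — dense along-line spacing pins the
    nugget, line separation and domain extent carry the range and sill.
    """
    rng = np.random.default_rng(derive_seed(seed, "variorec"))
    ys = (np.arange(n_lines) + 0.5) * extent_m / n_lines
    xs = (np.arange(n_along) + 0.5) * extent_m / n_along
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    n_points = pts.shape[0]
    d = np.sqrt(((pts[:, None, :2] - pts[None, :, :2]) ** 2).sum(-1))
    C = sill - kg._gamma_gaussian(d, sill, range_m)
    C[np.diag_indices_from(C)] += nugget + 1e-8
    L = np.linalg.cholesky(C)
    z = L @ rng.standard_normal(n_points)
    # dense short lags anchor the nugget; coarser bins carry sill and range
    edges = np.concatenate([np.linspace(0, 0.3 * range_m, 7),
                            np.linspace(0.45 * range_m, 3 * range_m, 12)])
    emp = kg.empirical_variogram(pts, z, edges, r_aniso=1.0, seed=0)
    fit = kg.fit_variogram(emp, structures=("gaussian",), r_aniso=1.0)
    g = fit.structures[0]
    return {
        "nugget_rel_err": abs(fit.nugget - nugget) / nugget,
        "sill_rel_err": abs(g.sill - sill) / sill,
        "range_rel_err": abs(g.range_m - range_m) / range_m,
        "fit": fit, "n_points": n_points,
    }


def bootstrap_null_calibration(seed: int, n_reps: int = 50,
                               n_draws: int = 10_000, n_real: int = 10,
                               n_sim: int = 100, n_fixes: int = 100) -> dict:
    """Real and simulated tracks from the SAME kernel scored on one field.

    With exchangeable arms p_better should average 0.5 and the anomaly 0;
    returns the replicate means and the Monte-Carlo SE of the anomaly mean.
    """
    seascape = sd.make_seascape()
    truth = sd.simulate_prey_field(seascape, seed=derive_seed(seed, "nullfield"))
    w = enc.DepthWeights(weights=np.full(30, 1 / 30),
                         bin_edges=np.arange(31.0))
    fieldk = kg.KrigedField(grid=truth.grid, sv_db=truth.sv_db,
                            variance=np.zeros(truth.grid.shape),
                            mask=np.ones(truth.grid.shape, dtype=bool))
    f2d = enc.collapse_field(fieldk, w)
    hmm = default_hmm_params()
    rng = np.random.default_rng(derive_seed(seed, "nullreps"))
    p_vals, anoms = [], []
    for _ in range(n_reps):
        tracks = [mh.simulate_hmm_track(hmm, n_fixes, seascape.colony,
                                        seascape.land_polygon,
                                        seed=int(rng.integers(2**31 - 1)))
                  for _ in range(n_real + n_sim)]
        E = np.array([enc.encounter_index(tr, f2d).E for tr in tracks])
        boot = enc.bootstrap_compare(E[:n_real], E[n_real:], n_draws=n_draws,
                                     seed=int(rng.integers(2**31 - 1)))
        p_vals.append(boot.p_better)
        anoms.append(boot.anomaly_mean)
    anoms = np.asarray(anoms)
    return {
        "mean_p_better": float(np.mean(p_vals)),
        "mean_anomaly": float(anoms.mean()),
        "anomaly_se": float(anoms.std(ddof=1) / math.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def ud_coverage_experiment(seed: int, n: int = 5000, level: float = 0.75
                           ) -> dict:
    """Fraction of an isotropic Gaussian sample inside its own UD contour."""
    rng = np.random.default_rng(derive_seed(seed, "udcov"))
    pts = rng.standard_normal((n, 2))
    ud = su.kernel_ud(pts, level=level)
    frac = float(ud.contains(pts[:, 0], pts[:, 1]).mean())
    return {"coverage": frac, "contour_mass": ud.contour_mass, "n": n}


def mass_calibration_experiment(seed: int, n_reps: int = 500,
                                n_years: int = 5, n_per_year: int = 15,
                                sd_g: float = 40.0,
                                planted_g: float = -60.0) -> dict:
    """Type-I rate of the per-year tests under the null, and recovery of a
    planted single-year effect.

    Because anomalies are deviations from the pooled per-sex mean, a planted
    effect e in one of k balanced years implies a year anomaly of e (1 - 1/k);
    recovery is scored against that implied value.
    """
    rng = np.random.default_rng(derive_seed(seed, "masscal"))
    years = {2015 + i: 0.0 for i in range(n_years)}
    n_sig = n_tests = 0
    for _ in range(n_reps):
        m = sd.simulate_masses(n_per_year, {"F": years, "M": years}, sd_g=sd_g,
                               seed=int(rng.integers(2**31 - 1)))
        anoms, _ = mc.mass_anomaly(m)
        res = mc.fit_year_model(anoms, sex="F")
        n_sig += int((res["p_value"] < 0.05).sum())
        n_tests += len(res)
    planted = dict(years)
    planted[2017] = planted_g
    m = sd.simulate_masses(n_per_year, {"F": planted, "M": years}, sd_g=sd_g,
                           seed=derive_seed(seed, "massplant"))
    anoms, _ = mc.mass_anomaly(m)
    res = mc.fit_year_model(anoms, sex="F").set_index("year")
    implied = planted_g * (1 - 1 / n_years)
    z = float((res.loc[2017, "coef_g"] - implied) / res.loc[2017, "se_g"])
    return {"type1_rate": n_sig / n_tests, "n_tests": n_tests,
            "planted_recovery_z": z, "implied_anomaly_g": implied,
            "recovered_g": float(res.loc[2017, "coef_g"])}


# --------------------------------------------------------------------------
# acceptance experiment
# --------------------------------------------------------------------------

def run_acceptance_experiment(seed: int, n_draws: int = 10_000) -> dict:
    """Run every synthetic calibration and the hotspot/negative-control
    experiment; returns a flat metrics dict (all values computed at run time)."""
    metrics: dict = {}

    sig = encounter_experiment(seed, hotspot_amplitude_db=12.0,
                               n_draws=n_draws)
    cache = sig.pop("reuse")
    null = encounter_experiment(seed, hotspot_amplitude_db=0.0,
                                n_draws=n_draws, _cache=cache)
    null.pop("reuse")
    metrics["hotspot_p_better"] = {"value": sig["p_better"],
                                   "n": sig["n_real"] + sig["n_sim"]}
    metrics["hotspot_anomaly_db"] = {"value": sig["anomaly_db"],
                                     "n": sig["n_draws"]}
    metrics["flat_field_p_better"] = {"value": null["p_better"],
                                      "n": null["n_real"] + null["n_sim"]}
    metrics["kriging_rmse_db"] = {"value": sig["kriging_rmse_db"],
                                  "n": sig["n_samples"]}
    metrics["nearest_neighbour_rmse_db"] = {
        "value": sig["nearest_neighbour_rmse_db"], "n": sig["n_samples"]}

    hmm = hmm_recovery_experiment(seed)
    metrics["hmm_max_param_rel_err_pct"] = {
        "value": 100 * hmm["max_rel_err"],
        "n": hmm["n_tracks"] * hmm["n_fixes"]}
    metrics["hmm_decode_accuracy_pct"] = {
        "value": 100 * hmm["decode_accuracy"],
        "n": hmm["n_tracks"] * (hmm["n_fixes"] - 1)}

    ct = ctcrw_recovery_experiment(seed)
    metrics["ctcrw_beta_median_rel_err_pct"] = {
        "value": 100 * ct["beta_median_rel_err"], "n": ct["n_tracks"]}
    metrics["ctcrw_sigma_median_rel_err_pct"] = {
        "value": 100 * ct["sigma_median_rel_err"], "n": ct["n_tracks"]}
    metrics["ctcrw_linear_limit_max_dev_m"] = {
        "value": ctcrw_linear_limit(), "n": 121}

    vg = variogram_recovery_experiment(seed)
    metrics["variogram_max_rel_err_pct"] = {
        "value": 100 * max(vg["nugget_rel_err"], vg["sill_rel_err"],
                           vg["range_rel_err"]),
        "n": vg["n_points"]}

    bn = bootstrap_null_calibration(seed)
    metrics["bootstrap_null_mean_p_better"] = {
        "value": bn["mean_p_better"], "n": bn["n_reps"]}
    metrics["bootstrap_null_anomaly_z"] = {
        "value": bn["mean_anomaly"] / bn["anomaly_se"], "n": bn["n_reps"]}

    ud = ud_coverage_experiment(seed)
    metrics["ud75_point_coverage"] = {"value": ud["coverage"], "n": ud["n"]}

    mcal = mass_calibration_experiment(seed)
    metrics["mass_type1_rate"] = {"value": mcal["type1_rate"],
                                  "n": mcal["n_tests"]}
    metrics["mass_planted_recovery_z"] = {"value": mcal["planted_recovery_z"],
                                          "n": 5 * 15}
    return metrics
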