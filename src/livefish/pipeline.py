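"""End-to-end orchestration: simulate -> detect -> register -> analyze.

A run is driven by a single RunConfig (YAML-serializable).  Every stage
writes plain-text artifacts (TIFF movies, CSV tables, JSON models) into the
output directory and the run closes with a manifest listing each artifact
with its SHA-256 hash, the resolved configuration and the per-stage seeds,
so that identical (config, seed) runs are byte-identical and each stage can
be re-run from its predecessors' serialized outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig
from .detect import localize_stack
from .distances import pair_loci, summarize_distances
from .dynamics import (Trajectory, compute_msd, ensemble_alpha,
                       ensemble_velocity_acf, estimate_msd_loc_error,
                       fit_power_law, link_trajectories)
from .fbm import simulate_fbm_trajectory
from .register import fit_warp, match_fiducials
from .simulate import render_movie, simulate_bead_field
from .warp import QuadraticWarp


@dataclass
class RunConfig:
    """Fully-resolved parameters of one pipeline run."""

    seed: int = 0
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    loci: list = field(default_factory=lambda: [
        dict(alpha=0.5, d_app=1e4, channels=[1, 2], origin=[10240.0, 10240.0]),
    ])
    warp: dict = field(default_factory=lambda: dict(
        kind="random", shift=1.0, linear_dev=1e-3, quad=1e-6))
    beads: dict = field(default_factory=lambda: dict(
        n_beads=100, loc_noise_nm=10.0, noise_ref_nm=10.0))
    detect: dict = field(default_factory=lambda: dict(
        low_sigma_px=1.0, high_sigma_px=4.0, threshold=None,
        roi_halfwidth_px=4))
    register: dict = field(default_factory=lambda: dict(max_dist_px=2.0))
    distances: dict = field(default_factory=lambda: dict(
        max_pair_nm=1500.0, thresholds_nm=[200.0, 300.0]))
    dynamics: dict = field(default_factory=lambda: dict(
        max_disp_nm=800.0, max_gap_frames=2, deltas=[1, 2, 4],
        fit_range_s=[0.33, 10.0]))

    def sim_config(self, seed: int | None = None) -> SimConfig:
        d = dict(self.sim)
        if seed is not None:
            d["seed"] = seed
        return SimConfig.from_dict(d)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        merged = {}
        for f in dataclasses.fields(cls):
            default = getattr(base, f.name)
            if f.name in d:
                if isinstance(default, dict) and isinstance(d[f.name], dict):
                    merged[f.name] = {**default, **d[f.name]}
                else:
                    merged[f.name] = d[f.name]
            else:
                merged[f.name] = default
        return cls(**merged)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        problems = []
        if not isinstance(self.seed, int):
            problems.append("seed must be an integer")
        try:
            self.sim_config()
        except (TypeError, ValueError) as exc:
            problems.append(f"sim: {exc}")
        for i, locus in enumerate(self.loci):
            if not (0 < locus.get("alpha", 0.5) <= 1):
                problems.append(f"loci[{i}]: alpha must be in (0, 1]")
            if locus.get("d_app", 0.0) < 0:
                problems.append(f"loci[{i}]: d_app must be >= 0")
        if self.beads.get("n_beads", 0) < 6:
            problems.append("beads: n_beads must be >= 6")
        lo, hi = self.dynamics.get("fit_range_s", [0.33, 10.0])
        if not (0 < lo < hi):
            problems.append("dynamics: fit_range_s must satisfy 0 < lo < hi")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in dependency order; return the run manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_df(df: pd.DataFrame, name: str) -> Path:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.6f")
        artifacts.append(p)
        return p

    def save_json(obj, name: str) -> Path:
        p = outdir / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
        artifacts.append(p)
        return p

    # one global seed expanded into independent per-stage streams
    streams = np.random.SeedSequence(config.seed).spawn(4)
    stage_seeds = {
        name: int(ss.generate_state(1)[0] % (2 ** 31))
        for name, ss in zip(("trajectories", "movie", "beads", "noise"), streams)
    }

    # ---- stage 1: simulate -----------------------------------------------
    sim = config.sim_config(seed=stage_seeds["movie"])
    wk = dict(config.warp)
    if wk.get("kind", "random") == "identity":
        warp_gt = QuadraticWarp.identity()
    else:
        warp_gt = QuadraticWarp.random(
            np.random.default_rng(stage_seeds["beads"]),
            shift=wk.get("shift", 1.0), linear_dev=wk.get("linear_dev", 1e-3),
            quad=wk.get("quad", 1e-6))
    traj_rng = np.random.default_rng(stage_seeds["trajectories"])
    h, w = sim.image_shape
    loci = []
    for i, locus_cfg in enumerate(config.loci):
        origin = locus_cfg.get("origin")
        if origin is None:
            origin = [w / 2 * sim.pixel_size_nm, h / 2 * sim.pixel_size_nm]
        loci.append(simulate_fbm_trajectory(
            alpha=locus_cfg.get("alpha", 0.5), d_app=locus_cfg.get("d_app", 1e4),
            n_steps=sim.n_frames, dt=sim.frame_interval_s, rng=traj_rng,
            locus_id=i, origin=origin,
            channels=tuple(locus_cfg.get("channels", [1]))))
    movies, truth = render_movie(loci, warp_gt, sim)
    for c, stack in movies.items():
        p = outdir / f"movie_ch{c}.tif"
        stack.save_tiff(p)
        artifacts.append(p)
    save_df(truth, "ground_truth.csv")
    p = outdir / "warp_ground_truth.json"
    warp_gt.to_json(p)
    artifacts.append(p)
    cfg_path = outdir / "run_config.yaml"
    config.to_yaml(cfg_path)
    artifacts.append(cfg_path)

    # ---- stage 2: detect + localize --------------------------------------
    loc_tables = {}
    for c, stack in movies.items():
        locs = localize_stack(
            stack, low_sigma_px=config.detect["low_sigma_px"],
            high_sigma_px=config.detect["high_sigma_px"],
            threshold=config.detect["threshold"],
            roi_halfwidth_px=config.detect["roi_halfwidth_px"])
        loc_tables[c] = locs
        save_df(locs, f"localizations_ch{c}.csv")

    # ---- stage 3: register ------------------------------------------------
    beads = simulate_bead_field(
        n_beads=config.beads["n_beads"], warp=warp_gt,
        loc_noise_nm=config.beads["loc_noise_nm"], config=sim,
        seed=stage_seeds["beads"],
        noise_ref_nm=config.beads.get("noise_ref_nm", 0.0))
    save_df(pd.DataFrame({
        "ref_x_px": beads.ref_xy_px[:, 0], "ref_y_px": beads.ref_xy_px[:, 1],
        "mov_x_px": beads.mov_xy_px[:, 0], "mov_y_px": beads.mov_xy_px[:, 1],
    }), "beads.csv")
    pairs_fid = match_fiducials(beads.ref_xy_px, beads.mov_xy_px,
                                max_dist=config.register["max_dist_px"])
    warp_model, qc = fit_warp(pairs_fid)
    p = outdir / "warp_model.json"
    warp_model.to_json(p, qc=qc)
    artifacts.append(p)

    # ---- stage 4: distances (needs both channels) -------------------------
    summary_dict = None
    if 2 in loc_tables and len(loc_tables[2]) and len(loc_tables.get(1, [])):
        ch2 = loc_tables[2].copy()
        ch2_px = ch2[["x_px", "y_px"]].to_numpy()
        warped_px = warp_model.transform(ch2_px)
        ch2["x_nm"] = warped_px[:, 0] * sim.pixel_size_nm
        ch2["y_nm"] = warped_px[:, 1] * sim.pixel_size_nm
        pairs = pair_loci(loc_tables[1], ch2,
                          max_pair_nm=config.distances["max_pair_nm"])
        save_df(pairs, "distance_pairs.csv")
        if len(pairs):
            summary = summarize_distances(
                pairs, thresholds_nm=config.distances["thresholds_nm"])
            summary_dict = summary.to_dict()
            save_json(summary_dict, "distance_summary.json")

    # ---- stage 5: dynamics (reference channel) ----------------------------
    dyn_result = None
    if 1 in loc_tables and len(loc_tables[1]):
        trajs = link_trajectories(
            loc_tables[1], max_disp_nm=config.dynamics["max_disp_nm"],
            max_gap_frames=config.dynamics["max_gap_frames"],
            frame_interval_s=sim.frame_interval_s, channel=1)
        trajs = [t for t in trajs if len(t) >= 4]
        if trajs:
            rows = []
            for t in trajs:
                for f, (x, y) in zip(t.frames, t.xy_nm):
                    rows.append(dict(locus_id=t.locus_id, frame=int(f),
                                     x_nm=x, y_nm=y))
            save_df(pd.DataFrame(rows), "trajectories_ch1.csv")
            curves = [compute_msd(t) for t in trajs]
            msd_rows = []
            for t, c in zip(trajs, curves):
                for lag, raw, n in zip(c.lags_s, c.msd_raw_nm2, c.counts):
                    msd_rows.append(dict(locus_id=t.locus_id, lag_s=lag,
                                         msd_raw_nm2=raw, n_pairs=n))
            save_df(pd.DataFrame(msd_rows), "msd_ch1.csv")
            fits = []
            lo, hi = config.dynamics["fit_range_s"]
            for c in curves:
                try:
                    fits.append(fit_power_law(c, lag_range_s=(lo, hi),
                                              use_corrected=False))
                except ValueError:
                    pass
            if fits:
                mean_a, se_a = ensemble_alpha(fits)
                dyn_result = dict(
                    n_trajectories=len(trajs), n_fits=len(fits),
                    alpha_mean=mean_a, alpha_se=se_a,
                    per_locus_alpha=[f.alpha for f in fits])
                save_json(dyn_result, "dynamics_fits.json")
            long = [t for t in trajs
                    if len(t) >= 3 * max(config.dynamics["deltas"])]
            if long:
                acf_rows = []
                for delta in config.dynamics["deltas"]:
                    acf = ensemble_velocity_acf(long, delta)
                    for lag, cv, n in zip(acf.lags_s, acf.cv, acf.counts):
                        acf_rows.append(dict(delta_s=acf.delta_s, lag_s=lag,
                                             cv_nm2_s2=cv, n=n))
                save_df(pd.DataFrame(acf_rows), "velocity_acf_ch1.csv")

    manifest = {
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": config.to_dict(),
        "registration_qc": qc.to_dict(),
        "distance_summary": summary_dict,
        "dynamics": dyn_result,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
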