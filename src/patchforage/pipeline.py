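"""End-to-end orchestration: simulate -> detect -> features -> classify ->
covariates -> fit -> residence -> report.

A run is configured by a ``RunConfig`` (YAML-loadable), executed stage by
stage into a run directory, and summarized in a manifest that records the
master seed, per-stage sub-seeds, row counts, and a SHA-256 hash of every
output file; re-running with the same config and seed reproduces identical
hashes for the deterministic stages. Completed stages whose inputs are
unchanged are skipped on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, detection, glm, kinematics, permutation, synthetic
from .geometry import PatchMap

__all__ = ["RunConfig", "run_pipeline", "StageError"]

log = logging.getLogger("patchforage")

STAGES = ("simulate", "detect", "features", "classify", "covariates", "fit", "residence", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulate
    n_worms: int = 10
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    # detect
    detection: dict = field(default_factory=dict)  # DetectionConfig overrides
    tracks_path: str | None = None  # skip simulation, read these instead
    patches_path: str | None = None
    # classify
    alpha_grid: tuple[float, ...] = classify.DEFAULT_ALPHA_GRID
    gmm_cv_reps: int = 3
    qda_reps: int = 100
    # fit
    covariates: tuple[str, ...] = ("rho_k", "tau_s", "rho_h", "rho_e")
    n_encounter_reps: int = 20
    n_worm_reps: int = 25
    ridge_lam: float = 0.0
    acclimation_density: float = 200.0
    # residence
    n_perm: int = 200
    n_bins: int = 30

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        for key in ("stages", "alpha_grid", "covariates"):
            if key in obj and isinstance(obj[key], list):
                obj[key] = tuple(obj[key])
        return cls(**obj)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"seed": cfg.seed, "stages": {}, "files": {}}
    if manifest_path.exists():
        try:
            manifest = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            pass
    cfg_hash = hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True, default=str).encode()).hexdigest()
    if manifest.get("config_hash") not in (None, cfg_hash):
        manifest = {"seed": cfg.seed, "stages": {}, "files": {}}
    manifest["config_hash"] = cfg_hash
    manifest["seed"] = cfg.seed

    seeds = {s: int(v) for s, v in zip(
        STAGES, np.random.SeedSequence(cfg.seed).generate_state(len(STAGES)) % (2**31)
    )}
    manifest["stage_seeds"] = seeds

    def done(stage: str) -> bool:
        info = manifest["stages"].get(stage)
        if not info:
            return False
        return all(
            Path(f).exists() and _sha256(Path(f)) == manifest["files"].get(f)
            for f in info.get("outputs", [])
        )

    def record(stage: str, outputs: list[Path], **info) -> None:
        for f in outputs:
            manifest["files"][str(f)] = _sha256(f)
        manifest["stages"][stage] = {"outputs": [str(f) for f in outputs], **info}
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        log.info("stage %s done: %s", stage, info)

    try:
        if "simulate" in cfg.stages and not done("simulate"):
            sim_cfg = synthetic.SimConfig(seed=seeds["simulate"], **cfg.sim)
            track, patch_map, gt = synthetic.simulate_tracks(sim_cfg, cfg.n_worms)
            _write_csv(track, out / "tracks.csv")
            patch_map.to_json(out / "patches.json")
            _write_csv(gt.encounters, out / "ground_truth.csv")
            record("simulate", [out / "tracks.csv", out / "patches.json", out / "ground_truth.csv"],
                   n_worms=cfg.n_worms, n_true_encounters=len(gt.encounters))

        if "detect" in cfg.stages and not done("detect"):
            tracks_path = Path(cfg.tracks_path or out / "tracks.csv")
            patches_path = Path(cfg.patches_path or out / "patches.json")
            for pth in (tracks_path, patches_path):
                if not pth.exists():
                    raise StageError("detect", f"missing input {pth}")
            track = pd.read_csv(tracks_path)
            patch_map = PatchMap.from_json(patches_path)
            det_cfg = detection.DetectionConfig(**cfg.detection)
            enc = detection.detect_encounters(track, patch_map, det_cfg)
            _write_csv(enc, out / "encounters.csv")
            record("detect", [out / "encounters.csv"], n_encounters=len(enc))

        if "features" in cfg.stages and not done("features"):
            track = pd.read_csv(Path(cfg.tracks_path or out / "tracks.csv"))
            enc = pd.read_csv(out / "encounters.csv")
            feats = kinematics.encounter_features(track, enc)
            _write_csv(feats, out / "encounter_features.csv")
            record("features", [out / "encounter_features.csv"], n_encounters=len(feats))

        if "classify" in cfg.stages and not done("classify"):
            feats = pd.read_csv(out / "encounter_features.csv")
            patch_map = PatchMap.from_json(Path(cfg.patches_path or out / "patches.json"))
            dens = patch_map.densities()
            feats["density"] = dens[feats["patch_id"].to_numpy(dtype=int)]
            if len(feats) < 20:
                raise StageError("classify", f"only {len(feats)} encounters; need >= 20")
            Z = feats[["log_duration", "log_mean_velocity"]].to_numpy()
            ex = classify.fit_exploit_gmm(Z, cfg.alpha_grid, n_reps=cfg.gmm_cv_reps,
                                          seed=seeds["classify"])
            feats["p_exploit"] = ex.p_exploit
            W = feats[["min_velocity", "deceleration", "max_delta_velocity"]].to_numpy()
            neg = feats["density"].to_numpy() == 0
            if not neg.any():
                # no bacteria-free patches in this run: seed negatives from the
                # clearest non-responders (fast minimum velocity)
                neg = W[:, 0] > np.nanpercentile(W[:, 0], 90)
            sp = classify.fit_sensing_qda(W, neg, ex.p_exploit, n_reps=cfg.qda_reps,
                                          seed=seeds["classify"])
            p_sensed = sp.p_sensed.copy()
            for i in np.flatnonzero(sp.marginalized):
                p_sensed[i] = classify.marginalize_censored_sensing(W[i, 0], sp, W)
            feats["p_sensed"] = p_sensed
            drop = classify.near_miss_mask(feats["max_signed_distance_mm"].to_numpy(), p_sensed)
            feats = feats.loc[~drop].reset_index(drop=True)
            s, m, e = classify.compose_states(feats["p_sensed"], feats["p_exploit"])
            feats["p_search"], feats["p_sample"], feats["p_exploit_final"] = s, m, e
            feats["q"] = feats["p_exploit"]
            _write_csv(feats, out / "classified.csv")
            model_json = {"gmm_alpha": ex.alpha, "gmm_means": ex.means.tolist(),
                          "gmm_weights": ex.weights.tolist(), "qda_replicates": sp.n_replicates}
            (out / "models.json").write_text(json.dumps(model_json, indent=1))
            record("classify", [out / "classified.csv", out / "models.json"],
                   n_near_miss_removed=int(drop.sum()), gmm_alpha=ex.alpha)

        if "covariates" in cfg.stages and not done("covariates"):
            feats = pd.read_csv(out / "classified.csv")
            feats = feats[feats["density"] > 0]
            rows = glm.build_covariates(
                feats.rename(columns={"entry_frame": "k"}), cfg.acclimation_density
            )
            _write_csv(rows, out / "covariates.csv")
            record("covariates", [out / "covariates.csv"], n_rows=len(rows))

        if "fit" in cfg.stages and not done("fit"):
            feats = pd.read_csv(out / "classified.csv")
            feats = feats[feats["density"] > 0].reset_index(drop=True)
            feats["k"] = feats.groupby("worm_id").cumcount()
            fit = glm.fit_replicated(
                feats, cfg.acclimation_density, covariates=cfg.covariates,
                n_encounter_reps=cfg.n_encounter_reps, n_worm_reps=cfg.n_worm_reps,
                ridge_lam=cfg.ridge_lam, seed=seeds["fit"],
            )
            _write_csv(pd.DataFrame(fit.beta, columns=list(fit.coef_names)), out / "beta_replicates.csv")
            fit.summary().to_json(out / "fit_summary.json", orient="records", indent=1)
            record("fit", [out / "beta_replicates.csv", out / "fit_summary.json"],
                   n_replicates=fit.n_replicates, n_failed=fit.n_failed)

        if "residence" in cfg.stages and not done("residence"):
            track = pd.read_csv(Path(cfg.tracks_path or out / "tracks.csv"))
            patch_map = PatchMap.from_json(Path(cfg.patches_path or out / "patches.json"))
            res = permutation.run_residence_analysis(
                track, patch_map, n_bins=cfg.n_bins, n_perm=cfg.n_perm, seed=seeds["residence"],
            )
            df = pd.DataFrame({
                "bin_start_s": res.bin_edges_s[:-1],
                "observed": res.observed,
                "permuted_mean": res.permuted_mean,
                "p_value": res.p_values,
                "significant": res.significant,
            })
            _write_csv(df, out / "residence.csv")
            record("residence", [out / "residence.csv"], n_significant=int(res.significant.sum()))

        if "report" in cfg.stages and not done("report"):
            summary = {}
            for name in ("encounters", "classified", "covariates"):
                f = out / f"{name}.csv"
                if f.exists():
                    summary[name] = int(len(pd.read_csv(f)))
            fsum = out / "fit_summary.json"
            if fsum.exists():
                summary["fit"] = json.loads(fsum.read_text())
            (out / "report.json").write_text(json.dumps(summary, indent=1))
            record("report", [out / "report.json"])
    except StageError:
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    except Exception as exc:  # tag the failing stage for the caller
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        stage = next((s for s in cfg.stages if s not in manifest["stages"]), "unknown")
        raise StageError(stage, str(exc)) from exc

    return manifest
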