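import numpy as np
import pandas as pd
import pytest

from patchforage import synthetic as syn
from patchforage.detection import (
    CalibrationError,
    DetectionConfig,
    calibrate_thresholds,
    detect_encounters,
)
from patchforage.geometry import Patch, PatchMap, signed_distances
from tests.conftest import straight_track


def bruteforce_encounters(track, patch_map, cfg):
    """Frame-by-frame reference state machine for encounter detection."""
    out = []
    for worm_id, grp in track.groupby("worm_id"):
        xy = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        t = grp["time_s"].to_numpy(dtype=float)
        d, pid = signed_distances(xy, patch_map)
        n = len(t)
        raw = []
        i = 0
        while i < n:
            if d[i] >= -cfg.encounter_threshold:
                j = i
                while j + 1 < n and d[j + 1] >= -cfg.encounter_threshold:
                    j += 1
                deepest = i + int(np.argmax(d[i : j + 1]))
                raw.append({"a": i, "b": j, "patch": int(pid[deepest]), "max_d": d[deepest]})
                i = j + 1
            else:
                i += 1
        raw = [r for r in raw if r["max_d"] >= -cfg.near_miss_threshold]
        merged = []
        for r in raw:
            if merged and merged[-1]["patch"] == r["patch"]:
                prev = merged[-1]
                p = patch_map.patches[r["patch"]]
                gap = xy[prev["b"] + 1 : r["a"]]
                gd = p.radius - np.hypot(gap[:, 0] - p.center[0], gap[:, 1] - p.center[1])
                # a single-frame gap has zero distance variability by definition
                if (np.std(gd) if len(gd) > 1 else 0.0) < cfg.merge_sd_threshold:
                    prev["b"] = r["b"]
                    continue
            merged.append(dict(r))
        for r in merged:
            out.append({
                "worm_id": worm_id, "patch_id": r["patch"],
                "entry_time_s": t[r["a"]], "exit_time_s": t[r["b"]],
                "left_censored": r["a"] == 0, "right_censored": r["b"] == n - 1,
            })
    return pd.DataFrame(out)


class TestDetectEncounters:
    def test_straight_crossing_matches_line_circle_intersection(self, single_patch_map):
        """Entry/exit equal the crossings of a circle of radius r + threshold."""
        cfg = DetectionConfig()
        fps = 10.0
        track = straight_track((-5.0, 0.0), 0.0, 0.2, 110.0, fps=fps)
        enc = detect_encounters(track, single_patch_map, cfg)
        assert len(enc) == 1
        r_eff = 0.9 + cfg.encounter_threshold
        t_entry = (10.0 - r_eff) / 0.2
        t_exit = (10.0 + r_eff) / 0.2
        assert enc["entry_time_s"].iloc[0] == pytest.approx(t_entry, abs=1 / fps)
        assert enc["exit_time_s"].iloc[0] == pytest.approx(t_exit, abs=1 / fps)
        assert not enc["left_censored"].iloc[0] and not enc["right_censored"].iloc[0]

    def test_tangential_near_miss_excluded(self, single_patch_map):
        """Closest approach 0.35 mm outside the edge: raw interval, then dropped."""
        cfg = DetectionConfig()
        y_off = 0.9 + 0.35
        track = straight_track((-5.0, y_off), 0.0, 0.2, 110.0, fps=10.0)
        track["x_mm"] += 10.0  # pass over the patch at x=5
        enc = detect_encounters(track, single_patch_map, cfg)
        assert len(enc) == 0
        # sanity: it would have been a raw interval at the outer threshold
        loose = DetectionConfig(near_miss_threshold=0.36)
        assert len(detect_encounters(track, single_patch_map, loose)) == 1

    def test_low_variability_excursion_merged(self, single_patch_map):
        """An outstretched-posture excursion (distance SD < 0.22221) is one encounter."""
        cfg = DetectionConfig()
        fps = 5.0
        # dwell near the edge, drift just past the threshold with tiny wobble, return
        t = np.arange(0, 60, 1 / fps)
        x = np.full_like(t, 5.9)  # on the edge
        drift = (t >= 20) & (t < 40)
        x[drift] = 5.9 + 0.9 + cfg.encounter_threshold + 0.05 + 0.02 * np.sin(t[drift])
        track = pd.DataFrame({"worm_id": 0, "time_s": t, "x_mm": x, "y_mm": 0.0})
        enc = detect_encounters(track, single_patch_map, cfg)
        assert len(enc) == 1
        assert enc["merged_from"].iloc[0] == 2
        # a wild excursion is a true leaving event: two encounters
        x2 = x.copy()
        x2[drift] = 5.9 + 2.0 + 1.5 * np.sin(3 * t[drift])
        track2 = pd.DataFrame({"worm_id": 0, "time_s": t, "x_mm": x2, "y_mm": 0.0})
        assert len(detect_encounters(track2, single_patch_map, cfg)) == 2

    def test_censoring_flags_at_recording_bounds(self, single_patch_map):
        track = straight_track((5.0, 0.0), 0.0, 0.05, 120.0, fps=5.0)  # starts on patch
        enc = detect_encounters(track, single_patch_map, DetectionConfig())
        assert len(enc) == 1
        assert enc["left_censored"].iloc[0]
        assert not enc["right_censored"].iloc[0]

    def test_unordered_timestamps_rejected(self, single_patch_map):
        track = straight_track((0, 0), 0.0, 0.1, 10.0)
        track.loc[3, "time_s"] = track.loc[5, "time_s"]
        with pytest.raises(ValueError, match="increasing"):
            detect_encounters(track, single_patch_map, DetectionConfig())

    def test_nan_positions_drop_or_error(self, single_patch_map):
        track = straight_track((-5.0, 0.0), 0.0, 0.2, 110.0, fps=5.0)
        track.loc[10:20, "x_mm"] = np.nan
        enc = detect_encounters(track, single_patch_map, DetectionConfig(), on_nan="drop")
        assert len(enc) == 1
        with pytest.raises(ValueError, match="NaN"):
            detect_encounters(track, single_patch_map, DetectionConfig(), on_nan="error")

    def test_mostly_missing_worm_rejected(self, single_patch_map):
        track = straight_track((-5.0, 0.0), 0.0, 0.2, 110.0, fps=5.0)
        track.loc[: int(0.3 * len(track)), "x_mm"] = np.nan
        enc = detect_encounters(track, single_patch_map, DetectionConfig())
        assert len(enc) == 0  # worm excluded: tracked <75% of the video

    def test_matches_bruteforce_oracle_on_random_tracks(self, grid_map):
        cfg = DetectionConfig()
        mismatches = 0
        for seed in range(25):
            sim = syn.SimConfig(duration=900, seed=seed, state_probs=(0.5, 0.3, 0.2),
                                patch_centers=[p.center for p in grid_map.patches])
            track, pm, _ = syn.simulate_track(sim, worm_id=seed)
            got = detect_encounters(track, pm, cfg)
            want = bruteforce_encounters(track, pm, cfg)
            assert len(got) == len(want), f"seed {seed}: {len(got)} vs {len(want)}"
            if len(got):
                got = got.sort_values("entry_time_s").reset_index(drop=True)
                want = want.sort_values("entry_time_s").reset_index(drop=True)
                assert np.allclose(got["entry_time_s"], want["entry_time_s"])
                assert np.allclose(got["exit_time_s"], want["exit_time_s"])
                assert (got["patch_id"].to_numpy() == want["patch_id"].to_numpy()).all()
        assert mismatches == 0

    def test_threshold_monotonicity(self, grid_map):
        """A wider encounter threshold never yields fewer raw encounters."""
        sim = syn.SimConfig(duration=1200, seed=99,
                            patch_centers=[p.center for p in grid_map.patches])
        track, pm, _ = syn.simulate_track(sim)
        counts = []
        for thr in (0.3, 0.46024, 0.7, 1.0):
            cfg = DetectionConfig(encounter_threshold=thr, near_miss_threshold=0.29 * thr / 0.46)
            raw = detect_encounters(track, pm, DetectionConfig(thr, thr * 0.999, 1e-9))
            counts.append(len(raw))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_ground_truth_recovered_within_one_frame(self):
        """Detection with matching thresholds recovers every synthetic encounter."""
        sim = syn.SimConfig(duration=1200, seed=5, state_probs=(0.4, 0.3, 0.3))
        track, pm, gt = syn.simulate_track(sim)
        enc = detect_encounters(track, pm, DetectionConfig(merge_sd_threshold=1e-9))
        dt = 1.0 / sim.frame_rate
        truth = gt.encounters[~gt.encounters["near_miss"]]
        assert len(truth) > 0
        for _, row in truth.iterrows():
            err = np.abs(enc["entry_time_s"] - row["entry_time_s"]).min()
            assert err <= dt + 1e-9


class TestCalibration:
    @staticmethod
    def _highres_tracks(half_length=0.46, seed=0):
        """Worm of fixed head-to-midpoint distance crossing a patch repeatedly."""
        rng = np.random.default_rng(seed)
        pm = PatchMap(arena_radius=12.0, patches=[Patch(center=(0.0, 0.0), radius=2.0)])
        rows = []
        for w in range(6):
            t = np.arange(0, 240, 1 / 8)
            x_head = -6.0 + 0.1 * t + rng.normal(0, 0.002, len(t))
            y = np.full_like(t, 0.0)
            x_mid = x_head - half_length
            rows.append(pd.DataFrame({
                "worm_id": w, "time_s": t, "x_mm": x_mid, "y_mm": y,
                "head_x_mm": x_head, "head_y_mm": y,
            }))
            # off-patch excursions with bimodal variability for the merge GMM
            t2 = t[-1] + 1 + np.arange(0, 40, 1 / 8)
            wob = 0.05 if w % 2 == 0 else 1.2
            x2 = -6.0 + wob * np.sin(t2) + rng.normal(0, 0.01, len(t2))
            rows.append(pd.DataFrame({
                "worm_id": w, "time_s": t2, "x_mm": x2, "y_mm": y[: len(t2)],
                "head_x_mm": x2 + half_length, "head_y_mm": y[: len(t2)],
            }))
        return pd.concat(rows, ignore_index=True), pm

    def test_recovers_constructed_half_length(self):
        tracks, pm = self._highres_tracks(half_length=0.46)
        cfg = calibrate_thresholds(tracks, pm)
        assert cfg.encounter_threshold == pytest.approx(0.46, abs=0.02)

    def test_single_cluster_sd_data_errors(self):
        tracks, pm = self._highres_tracks()
        # make every off-patch excursion identical in variability
        from patchforage.detection import _merge_threshold_from_sds
        with pytest.raises(CalibrationError):
            _merge_threshold_from_sds(np.full(50, 0.1) + np.random.default_rng(0).normal(0, 1e-4, 50))

    def test_paper_defaults_when_calibration_skipped(self):
        cfg = DetectionConfig()
        assert (cfg.encounter_threshold, cfg.near_miss_threshold, cfg.merge_sd_threshold) == (
            0.46024, 0.28758, 0.22221,
        )
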