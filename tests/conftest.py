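import numpy as np
import pandas as pd
import pytest

from patchforage.geometry import Patch, PatchMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_patch_map():
    return PatchMap(arena_radius=15.0, patches=[Patch(center=(5.0, 0.0), radius=0.9, rel_density=10.0)])


@pytest.fixture
def grid_map():
    centers = [(-4.0, -4.0), (4.0, -4.0), (-4.0, 4.0), (4.0, 4.0), (0.0, 0.0)]
    return PatchMap(
        arena_radius=15.0,
        patches=[Patch(center=c, radius=0.9, rel_density=d) for c, d in zip(centers, (1, 5, 10, 5, 10))],
    )


def straight_track(start, heading, speed_mm_s, duration_s, fps=10.0, worm_id=0):
    """Constant-velocity straight-line track used by geometry-oracle tests."""
    n = int(round(duration_s * fps)) + 1
    t = np.arange(n) / fps
    x = start[0] + speed_mm_s * t * np.cos(heading)
    y = start[1] + speed_mm_s * t * np.sin(heading)
    return pd.DataFrame({"worm_id": worm_id, "frame": np.arange(n), "time_s": t, "x_mm": x, "y_mm": y})
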