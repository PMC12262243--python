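"""Is on-patch residence above chance? Patch-permutation null over time.

Semi-randomly re-places the patch constellation (uniform feasible placements
with overlap rejection), recomputes residence per time bin, and tests observed
against permuted with a one-tailed Fisher's exact test, BH-corrected across
bins. On the simulated cohort, worms genuinely dwell on patches, so late time
bins should exceed the null.
"""

import pandas as pd
from pathlib import Path

from patchforage import permutation as perm
from patchforage.geometry import PatchMap

OUT = Path("results/analysis")


def main() -> None:
    track = pd.read_csv(OUT / "tracks.csv")
    patch_map = PatchMap.from_json(OUT / "patches.json")
    res = perm.run_residence_analysis(track, patch_map, n_bins=24, n_perm=300, seed=0)
    df = pd.DataFrame({
        "bin_start_s": res.bin_edges_s[:-1],
        "observed": res.observed,
        "permuted_mean": res.permuted_mean,
        "p_value": res.p_values,
        "significant": res.significant,
    })
    df.to_csv(OUT / "residence.csv", index=False)
    print(f"{int(res.significant.sum())}/{len(res.p_values)} time bins exceed the "
          f"permuted null (one-tailed Fisher, BH at 0.05, {res.n_perm} permutations)")
    print(df.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
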