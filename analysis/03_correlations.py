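"""Correlation structure of body metrics and body weight, overall and by age.

Computes the Pearson matrix over the herd, splits the herd into age
quartiles, and runs Mantel tests between every pair of quartile
correlation matrices. Small Mantel p-values mean the metric-weight
correlation structure is stable across growth — the premise behind
forecasting later weight from early body metrics.
"""

import json
from pathlib import Path

import pandas as pd

from calfdepth.correlation import mantel, pearson_matrix, quartile_groups
from calfdepth.depth_io import read_observations

SEED = 20230109
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    herd = read_observations(OUT / "herd_observations.csv")
    overall = pearson_matrix(herd)
    mat = pd.DataFrame(overall.values, index=overall.labels, columns=overall.labels)
    mat.to_csv(OUT / "correlation_overall.csv")
    print(f"overall (n={overall.n}):")
    print(f"  volume-BW  r = {overall[('volume_mm_px2', 'bw_lb')]:.3f}")
    print(f"  area-BW    r = {overall[('contour_area_px2', 'bw_lb')]:.3f}")

    groups = quartile_groups(herd)
    mats = [(label, pearson_matrix(sub)) for label, sub in groups]
    payload = {"quartiles": {}, "mantel": {}}
    for label, m in mats:
        payload["quartiles"][label] = {"n": m.n, "area_bw_r": m[("contour_area_px2", "bw_lb")]}
        print(f"age {label} d (n={m.n}): area-BW r = {m[('contour_area_px2', 'bw_lb')]:.3f}")
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            r, p = mantel(mats[i][1], mats[j][1], n_perm=999, seed=SEED)
            key = f"{mats[i][0]} vs {mats[j][0]}"
            payload["mantel"][key] = {"r": r, "p": p}
            print(f"Mantel {key}: r = {r:.3f}, p = {p:.3f}")
    with open(OUT / "correlation_quartiles.json", "w") as fh:
        json.dump(payload, fh, indent=1)


if __name__ == "__main__":
    main()
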