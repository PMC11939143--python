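"""Single-time-point body-weight prediction under calf-grouped 5-fold CV.

Compares ordinary least squares against gradient-boosted trees (randomized
hyperparameter search) with fold assignment at the calf level, repeated
with fresh random calf reassignments. Writes per-repetition metrics and
the per-metric model comparison under results/.
"""

import json
from pathlib import Path

from calfdepth.bw_predict import SearchSpace, fit_gbt, fit_linear, repeat_cv
from calfdepth.depth_io import read_observations

SEED = 20230109
OUT = Path(__file__).resolve().parents[1] / "results"
N_REP = 20  # repetitions of the grouped 5-fold CV
SEARCH = SearchSpace(n_estimators=(50, 200), n_iterations=8)


def main() -> None:
    herd = read_observations(OUT / "herd_observations.csv")
    models = {
        "linear": lambda tr, sp, sd: fit_linear(tr, sp),
        "gbt": lambda tr, sp, sd: fit_gbt(tr, sp, space=SEARCH, seed=sd),
    }
    report = repeat_cv(herd, models=models, k=5, n_rep=N_REP, seed=SEED)
    report["per_repetition"].to_csv(OUT / "cv_per_repetition.csv", index=False)
    payload = {}
    for metric, r in report["metrics"].items():
        payload[metric] = {k: r[k] for k in ("means", "sds", "p", "eta_sq", "letters")}
        means = {k: round(v, 3) for k, v in r["means"].items()}
        sds = {k: round(v, 3) for k, v in r["sds"].items()}
        print(f"{metric}: {means} (SD {sds}), ANOVA p = {r['p']:.3g}")
    with open(OUT / "cv_summary.json", "w") as fh:
        json.dump(payload, fh, indent=1)


if __name__ == "__main__":
    main()
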