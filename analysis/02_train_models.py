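#!/usr/bin/env python
"""Train and compare the four selector-PLS models on the simulated study.

Loads results/dataset.csv (run 01 first), splits it 2:1 stratified by
day, runs GA / SA / ACO / CARS wrapper selection around PLS at desk-scale
search budgets, refits a PLS model per selection and reports Rc, RMSEC,
Rp and RMSEP per model.  Artifacts (comparison.csv, per-model JSON, the
best model as warning_model.json) land under results/.
"""

from pathlib import Path

import spoilwarn as sw
from spoilwarn.io import read_dataset
from spoilwarn.pipeline import cmd_train
from spoilwarn.selection import test_scale_selector_configs

OUT = Path(__file__).resolve().parent.parent / "results"
DATA_DIR = Path(__file__).resolve().parent.parent / "scratch"
SEED = 1


def main() -> None:
    dataset_path = DATA_DIR / "dataset.csv"
    if not dataset_path.exists():
        raise SystemExit("run analysis/01_simulate_warehouses.py first")
    dataset = read_dataset(dataset_path)
    cv = sw.CVConfig(n_folds=5, shuffle_seed=SEED, max_components=10)
    result = cmd_train(
        dataset,
        test_scale_selector_configs(seed=SEED),
        cv,
        OUT,
        split_ratio=2 / 3,
        split_seed=SEED,
    )
    print(result["table"].round(3).to_string(index=False))
    best = result["best"]
    report = result["trained"][best].report
    print(f"\nbest model: {best}-PLS  (Rp={report.r_prediction:.3f}, "
          f"RMSEP={report.rmse_prediction:.3f} days)")
    print(f"artifacts in {OUT}")


if __name__ == "__main__":
    main()
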