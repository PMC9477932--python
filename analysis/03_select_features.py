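#!/usr/bin/env python
"""Split the development cohort 3/1 (stratified) and run the selection
cascade on the training rows.

The cascade — near-zero-variance filter, |r| >= 0.9 correlation filter,
stepwise forward selection under 5-fold cross-validated AUC with a strict
0.005 improvement threshold — sees only the training split and only the
radiomics pool (TBR_mean/TBR_max are reserved for the conventional model).
Writes the split assignment, the per-stage elimination log, and the
retained feature names to results/.
"""

import argparse
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from fetrad.model import CONVENTIONAL_FEATURES  # noqa: E402
from fetrad.selection import (FeatureTable, run_selection_cascade,  # noqa: E402
                              split_cohort)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--corr", type=float, default=0.9)
    parser.add_argument("--folds", type=int, default=5)
    parser.add_argument("--delta", type=float, default=0.005)
    args = parser.parse_args()

    results = ROOT / "results"
    table = FeatureTable.from_csv(results / "features_dev.csv")
    train, val = split_cohort(table, ratio=0.25, seed=args.seed)
    split = table.frame[["label"]].copy()
    split["split"] = ["validation" if i in val.frame.index else "train"
                      for i in table.frame.index]
    split.to_csv(results / "split_assignment.csv")

    pool = [c for c in train.feature_names if c not in CONVENTIONAL_FEATURES]
    retained, log = run_selection_cascade(
        train.subset_features(pool), corr_threshold=args.corr,
        k_folds=args.folds, delta=args.delta, seed=args.seed)

    stages = ("near_zero_variance", "correlation", "forward_cv")
    for stage, res in zip(stages, log):
        res.to_json(results / f"selection_{stage}.json")
        print(f"{stage}: {len(res.eliminated)} eliminated, "
              f"{len(res.retained)} retained")
    (results / "selected_features.txt").write_text("\n".join(retained) + "\n")
    print(f"cascade selected: {retained}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
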