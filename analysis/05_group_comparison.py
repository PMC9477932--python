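#!/usr/bin/env python
"""Descriptive group comparison of the conventional PET parameters.

Reports per-class mean +- SD of TBR_mean and TBR_max over the development
cohort with Mann-Whitney U p-values, and a Fisher's exact test of the
classifier's confusion table at the validation cutoff.  Writes
results/group_comparison.csv.
"""

import argparse
import json
import sys
import warnings
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from fetrad.evaluate import fisher_exact, mann_whitney  # noqa: E402


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    results = ROOT / "results"
    dev = pd.read_csv(results / "features_dev.csv", index_col=0)
    tp = dev[dev["label"] == 1]
    trc = dev[dev["label"] == 0]

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for param in ("tbr_mean", "tbr_max"):
            _, p = mann_whitney(tp[param], trc[param])
            rows.append({
                "parameter": param,
                "TP mean+-SD": f"{tp[param].mean():.2f} +- {tp[param].std():.2f}",
                "TRC mean+-SD": f"{trc[param].mean():.2f} +- {trc[param].std():.2f}",
                "Mann-Whitney p": f"{p:.2e}"})
    frame = pd.DataFrame(rows)
    frame.to_csv(results / "group_comparison.csv", index=False)
    print(frame.to_string(index=False))

    report_path = results / "study_report.json"
    split_path = results / "split_assignment.csv"
    if report_path.exists() and split_path.exists():
        report = json.loads(report_path.read_text())
        combined = report["models"]["combined"]["validation"]
        sens = combined["sensitivity_pct"] / 100.0
        spec = combined["specificity_pct"] / 100.0
        split = pd.read_csv(split_path, index_col=0)
        val = split[split["split"] == "validation"]
        n_tp = int((val["label"] == 1).sum())
        n_trc = int((val["label"] == 0).sum())
        confusion = [[round(sens * n_tp), n_tp - round(sens * n_tp)],
                     [n_trc - round(spec * n_trc), round(spec * n_trc)]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact(confusion)
        print(f"\ncombined-model validation confusion {confusion}: "
              f"Fisher exact p = {p:.3g}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
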