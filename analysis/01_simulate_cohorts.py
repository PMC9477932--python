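#!/usr/bin/env python
"""Simulate the two synthetic PET cohorts and write them to disk.

Development cohort: 93 tumor-progression (TP) and 31 treatment-related-
changes (TRC) phantoms with class TBR distributions 2.1+-0.3 / 1.9+-0.3
(TBR_mean) and 3.7+-0.9 / 2.8+-0.7 (TBR_max) and class-specific lesion
texture.  Test cohort: 21 TP / 6 TRC phantoms with higher voxel noise,
standing in for a second scanner.  Volumes and masks go to scratch/ (NIfTI);
the manifests (subject id, label, seed, per-subject targets, paths) go to
results/.
"""

import argparse
import sys
from dataclasses import replace
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from fetrad.experiments import DEV_COHORT, TEST_COHORT  # noqa: E402
from fetrad.phantom import generate_cohort, save_cohort  # noqa: E402


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "cohorts")
    args = parser.parse_args()

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name, spec in (("dev", DEV_COHORT), ("test", TEST_COHORT)):
        cohort = generate_cohort(replace(spec, seed=args.seed * 10 + len(name)))
        manifest = save_cohort(cohort, args.outdir / name)
        manifest.to_csv(results / f"cohort_{name}_manifest.csv", index=False)
        n_tp = sum(s.label for s in cohort)
        print(f"{name}: wrote {len(cohort)} subjects "
              f"({n_tp} TP / {len(cohort) - n_tp} TRC) to {args.outdir / name}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
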