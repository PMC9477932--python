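#!/usr/bin/env python
"""Quantify every simulated subject and extract the radiomics features.

For each subject: read the SUV volume and background mask (NIfTI), take the
background mean, auto-contour the lesion at TBR >= 1.6 in the hottest
transversal slice, compute TBR_mean/TBR_max, and extract the five feature
families.  The test cohort is first smoothed with the 2.5 mm Gaussian
harmonization filter (it emulates a different scanner).  Writes one feature
table CSV per cohort to results/.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from fetrad.features import FeatureConfig, extract_features  # noqa: E402
from fetrad.quantify import (PETVolume, autocontour_lesion,  # noqa: E402
                             background_mean, compute_tbr, harmonize)


def extract_cohort(manifest: pd.DataFrame, fwhm_mm: float | None) -> pd.DataFrame:
    config = FeatureConfig()
    rows = []
    for rec in manifest.itertuples():
        vol = PETVolume.from_nifti(rec.suv_path, units="SUV")
        if fwhm_mm:
            vol = harmonize(vol, fwhm_mm)
        import nibabel as nib

        roi = np.asanyarray(nib.load(rec.bgroi_path).dataobj) > 0
        bg = background_mean(vol, roi)
        seg = autocontour_lesion(vol, bg)
        if seg is None:
            print(f"  {rec.subject_id}: no supra-threshold lesion, skipped")
            continue
        tbr = compute_tbr(seg, vol, bg)
        row = {"subject_id": rec.subject_id, "label": rec.label,
               "tbr_mean": tbr.tbr_mean, "tbr_max": tbr.tbr_max}
        row.update(extract_features(vol, seg, bg, config))
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--harmonize-test-fwhm", type=float, default=2.5)
    args = parser.parse_args()

    results = ROOT / "results"
    for name, fwhm in (("dev", None), ("test", args.harmonize_test_fwhm)):
        manifest = pd.read_csv(results / f"cohort_{name}_manifest.csv")
        table = extract_cohort(manifest, fwhm)
        out = results / f"features_{name}.csv"
        table.to_csv(out)
        n_feat = table.shape[1] - 1
        print(f"{name}: {len(table)} subjects x {n_feat} features -> {out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
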