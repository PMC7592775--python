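"""Optional validation against the original study's raw data.

The study's per-subject waveform data is distributed only as a supplementary
spreadsheet alongside the article and is not bundled here.  Once obtained and
exported to a feature table (one row per subject with columns ``csa_mean``,
``lag20`` ... ``lag360`` and the measured ``cvp_mean``; the ``jvp features``
command produces exactly this layout from per-subject trace files), this
script recomputes the published model-fit statistics: the in-sample r^2 and
mean absolute error of the refit on the published predictor set, and their
10-fold cross-validated counterparts.

Usage:
    python scripts/validate_raw_data.py --features <feature_table.csv> [--seed N]
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from jvpulse.cvp_model import cross_validate, fit_metrics, fit_ols, predict_published
from jvpulse.published import PUBLISHED_PREDICTORS


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", required=True, help="feature table CSV with cvp_mean column")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    path = Path(args.features)
    if not path.exists():
        print(
            f"raw data not available: {path} not found.\n"
            "This validation needs the study's supplementary raw data, which is "
            "not redistributable with the package; export it to a feature table "
            "(jvp features) and re-run.",
            file=sys.stderr,
        )
        return 2

    table = pd.read_csv(path)
    y = table["cvp_mean"].to_numpy(dtype=float)

    refit = fit_ols(table, y, list(PUBLISHED_PREDICTORS))
    cv = cross_validate(table, y, list(PUBLISHED_PREDICTORS), k=10, seed=args.seed)
    r2_pub, mae_pub = fit_metrics(y, predict_published(table))

    print(f"n_subjects\t{len(table)}")
    print(f"refit_r_squared\t{refit.r_squared:.3f}")
    print(f"refit_mae_cmh2o\t{refit.mae:.3f}")
    print(f"cv10_r_squared\t{cv.r_squared_cv:.3f}")
    print(f"cv10_mae_cmh2o\t{cv.mae_cv:.3f}")
    print(f"published_coeff_r_squared\t{r2_pub:.3f}")
    print(f"published_coeff_mae_cmh2o\t{mae_pub:.3f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
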