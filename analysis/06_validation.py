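"""Reduced-size validation experiments: oracle equivalence, recovery,
calibration.

A quick-look version of the full validation in scripts/acceptance.py
(smaller replicate counts so it runs in seconds), reporting closed-form
oracle agreement of the logistic estimator, recovery of a planted
OR=1.95, and the null rejection rates of both tests.
"""

import json
from pathlib import Path

from sscpgx.experiments import (
    mw_null_calibration,
    or_oracle_check,
    recover_planted_or,
    wald_null_calibration,
)

SEED = 7
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    oracle = or_oracle_check(SEED, n_tables=50)
    recovery = recover_planted_or(SEED, n_subjects=2000, n_replicates=60)
    wald = wald_null_calibration(SEED, n_replicates=300)
    mw = mw_null_calibration(SEED, n_replicates=300)
    report = {
        "oracle_max_or_rel_err": oracle["max_or_rel_err"],
        "recovered_or_planted_1.95": recovery["recovered_or"],
        "ci_coverage": recovery["coverage"],
        "wald_null_rejection_rate": wald["rejection_rate"],
        "mw_null_rejection_rate": mw["rejection_rate"],
    }
    ROOT.mkdir(exist_ok=True)
    (ROOT / "validation_quicklook.json").write_text(json.dumps(report, indent=2) + "\n")
    for k, v in report.items():
        print(f"{k}: {v:.4g}")
    print("\n(full-size versions of these experiments run via "
          "scripts/acceptance.py)")


if __name__ == "__main__":
    main()
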