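#!/usr/bin/env python
"""Calibration of the ±3SD classification rule on artifact-free data.

Two numbers justify the correction factor: a Gaussian region keeps 99.7% of
its voxels inside mean±3SD, so ~0.3% of perfectly normal voxels are always
misclassified as artifacts.  This script measures that rate on >10^6
simulated artifact-free voxels and compares it with the closed form 2·Φ(−3).
"""

import json
from pathlib import Path

from maraq.experiments import misclassification_percent
from maraq.metrics import expected_inlier_percent, expected_misclassified_percent

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260929


def main() -> None:
    OUT.mkdir(exist_ok=True)
    measured = misclassification_percent(n_voxels=2_000_000, seed=SEED)
    payload = {
        "misclassified_percent_measured": round(measured, 3),
        "misclassified_percent_analytic": round(expected_misclassified_percent(3), 3),
        "coverage_percent_analytic": round(expected_inlier_percent(3), 1),
        "n_voxels": 2_000_000,
    }
    (OUT / "calibration.json").write_text(json.dumps(payload, indent=2))
    print(json.dumps(payload, indent=2))
    print(f"\n±3SD misclassifies {measured:.2f}% of normal voxels "
          f"(rounds to {round(measured, 1)}%); interval covers "
          f"{expected_inlier_percent(3):.1f}% of normal tissue.")


if __name__ == "__main__":
    main()
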