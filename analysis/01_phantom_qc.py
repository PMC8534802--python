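#!/usr/bin/env python
"""Stage 1 — synthetic angio-CT phantoms and segmentation QC.

Generates ten phantom volumes at the clinical image-quality regime
(BI ~ 27.9, CNR ~ 3.65), segments each by region growing + per-slice
hole filling, and scores the result against the generator's ground
truth.  Writes results/qc_report.json and results/qc_per_phantom.csv.

Finding to look for: the maximum relative volume error stays well below
the 5% radiologist-agreement bound, and the measured BI/CNR match the
regime the phantoms were tuned to.
"""

import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from aortoflow.pipeline import run_qc  # noqa: E402

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    report = run_qc(n_phantoms=10, base_seed=1)
    pd.DataFrame(report["per_phantom"]).to_csv(
        os.path.join(RESULTS, "qc_per_phantom.csv"), index=False
    )
    with open(os.path.join(RESULTS, "qc_report.json"), "w") as fh:
        json.dump({k: v for k, v in report.items() if k != "per_phantom"}, fh, indent=1)
    print(
        f"segmentation QC over 10 phantoms: max volume error "
        f"{report['max_volume_error_pct']:.2f}% (bound 5%), "
        f"BI {report['mean_bi']:.2f}, CNR {report['mean_cnr']:.2f}"
    )


if __name__ == "__main__":
    main()
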