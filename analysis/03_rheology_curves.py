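#!/usr/bin/env python
"""Stage 3 — blood viscosity curves for the two study hematocrits.

Tabulates the Quemada apparent viscosity mu(gamma) at Hct = 40% and 50%
(printed form) over 1e-3..1e4 1/s and writes
results/viscosity_curves.csv plus a log-log figure.

Finding to look for: shear thinning at both hematocrits and a uniformly
higher curve at Hct 50%.
"""

import os
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from aortoflow.rheology import BloodProperties, tabulate_viscosity_curve  # noqa: E402

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    frames = []
    fig, ax = plt.subplots(figsize=(5, 4))
    for hct in (0.40, 0.50):
        props = BloodProperties(hct=hct)
        gamma, mu = tabulate_viscosity_curve(props)
        frames.append(pd.DataFrame({"gamma_1_s": gamma, "mu_Pa_s": mu, "hct": hct}))
        ax.loglog(gamma, 1e3 * mu, label=f"Hct = {int(hct * 100)}%")
        print(
            f"Hct {hct:.2f}: mu({props.gamma_floor:.2g}/s) = {1e3 * mu[0]:.2f} mPa s, "
            f"mu(1e4/s) = {1e3 * mu[-1]:.2f} mPa s"
        )
    pd.concat(frames).to_csv(os.path.join(RESULTS, "viscosity_curves.csv"), index=False)
    ax.set_xlabel("shear rate (1/s)")
    ax.set_ylabel("apparent viscosity (mPa s)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(RESULTS, "viscosity_curves.png"), dpi=150)


if __name__ == "__main__":
    main()
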