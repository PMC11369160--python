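"""Photobleaching-recovery fitting across mobile fractions.

Simulates noisy recovery series over a grid of mobile fractions and rate
constants, fits each with the double-normalization + exponential model,
and tabulates recovered half-times and percentage recovery.

Finding: recovered PR tracks the planted mobile fraction linearly and the
immobile condition reports essentially zero recovery over the 15-minute
window, the signature of a static assembly.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spirocell.frap import FrapSeries, analyze_series
from spirocell.synthgen import FrapTruth, simulate_frap_series

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for mf in [0.0, 0.25, 0.5, 0.75, 1.0]:
        for r in [0.15, 0.35, 0.7]:
            for seed in range(10):
                truth = FrapTruth(mobile_fraction=mf, rate_constant=r,
                                  noise_sd=0.02)
                fit = analyze_series(FrapSeries.from_frame(
                    simulate_frap_series(truth, seed=seed)))
                rows.append({
                    "mobile_fraction": mf, "rate_true_per_min": r,
                    "seed": seed, "rate_fit": fit.rate,
                    "t_half_min": fit.t_half, "pr_pct": fit.percent_recovery,
                    "amplitude": fit.amplitude, "baseline": fit.baseline,
                })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "frap_fits.csv", index=False)

    summary = df.groupby("mobile_fraction")["pr_pct"].mean()
    print("mean recovered PR by mobile fraction:")
    print(summary.round(1).to_string())
    mobile = df[df["mobile_fraction"] > 0]
    th_err = np.abs(mobile["t_half_min"]
                    / (np.log(2) / mobile["rate_true_per_min"]) - 1)
    print(f"\nmedian |t_half error| (mobile conditions): "
          f"{100 * th_err.median():.1f}%")
    print("table -> results/frap_fits.csv")


if __name__ == "__main__":
    main()
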