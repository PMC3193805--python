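#!/usr/bin/env python
"""Group-level statistics: summaries, t-tests and cross-endpoint correlations.

Merges the kinetic endpoints (02) with the growth endpoints (03), then
writes summary.csv, group_means.csv, tests.csv and correlations.csv.  The
key readout is the correlation table across the five arm means — in
particular hypoxic fraction versus the change in the amplitude parameter A,
which the synthetic cohort couples negatively by construction.
"""

from pathlib import Path

import pandas as pd

from brixflow.pipeline import cohort_statistics

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    endpoints = pd.read_csv(RESULTS / "endpoints.csv")
    growth = pd.read_csv(RESULTS / "growth_endpoints.csv")
    merged = endpoints.merge(
        growth[["tumor_id", "delta_volume_pct", "time_to_3x_days", "censored"]],
        on="tumor_id", how="left",
    )
    out = cohort_statistics(merged, control_group="Control")
    for name in ("summary", "group_means", "correlations", "tests"):
        out[name].to_csv(RESULTS / f"{name}.csv", index=False)

    print("group means:")
    cols = [c for c in ("group", "delta_A_pct", "delta_kel_pct",
                        "hypoxic_fraction_pct", "delta_volume_pct")
            if c in out["group_means"].columns]
    print(out["group_means"][cols].round(1).to_string(index=False))
    print("\ncorrelations across arm means:")
    print(out["correlations"].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
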