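#!/usr/bin/env python
"""Dose-volume metrics per definition and plan (the dose-comparison table).

Reads the persisted cohort DVHs, computes V30/V40/V50/V60 (cc), Dmean and
Dmax (Gy) for every patient x definition x plan, and writes the long-format
metric table to results/metrics.csv.
"""

from pathlib import Path

from esontcp import read_dvh_file
from esontcp.pipeline import compute_metric_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    dvhs = read_dvh_file(ROOT / "results" / "cohort" / "dvh.csv")
    print(f"loaded {len(dvhs)} DVH blocks")
    metrics = compute_metric_table(dvhs)
    out = ROOT / "results" / "metrics.csv"
    metrics.to_csv(out, index=False)
    means = metrics.pivot_table(index=["plan", "metric"], columns="definition",
                                values="value")
    print("cohort means per definition:")
    print(means.round(1).to_string())
    print(f"wrote {len(metrics)} records to {out}")


if __name__ == "__main__":
    main()
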