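#!/usr/bin/env python
"""Esophageal toxicity predictions per definition and plan.

Converts every DVH to EQD2 at each model's alpha/beta (10 Gy acute, 3 Gy
late) and evaluates the four registered NTCP models — two logistic V50 acute
models, the Wijsman LKB acute model and the Chen LKB late model — writing
percent predictions to results/ntcp.csv.
"""

from pathlib import Path

from esontcp import read_dvh_file, registry_from_yaml
from esontcp.pipeline import compute_ntcp_table
from esontcp.radbio import FractionationScheme

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    dvhs = read_dvh_file(ROOT / "results" / "cohort" / "dvh.csv")
    registry = registry_from_yaml(ROOT / "analysis" / "config" / "models.yaml")
    schemes = {
        "SIB": FractionationScheme(64.8, 28),
        "SD": FractionationScheme(50.4, 28),
    }
    ntcp = compute_ntcp_table(dvhs, registry, schemes)
    out = ROOT / "results" / "ntcp.csv"
    ntcp.to_csv(out, index=False)
    means = ntcp.pivot_table(index=["plan", "metric"], columns="definition",
                             values="value")
    print("mean predicted complication probability (%) per definition:")
    print(means.to_string(float_format=lambda v: f"{v:.3g}"))
    print(f"wrote {len(ntcp)} records to {out}")


if __name__ == "__main__":
    main()
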