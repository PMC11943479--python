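#!/usr/bin/env python
"""Group-comparison statistics over the colony feature table.

Runs the statistics layer on the output of 04_colony_features.py (or on
freshly simulated data if that file is absent): assumption checks with
log-transform fallback, one-way ANOVA + Dunnett at the final time point,
and the two-way (time x treatment) analysis locating each group's first
significant departure from control.

Writes results/stats_report.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mentholtox import group_stats as gs
from mentholtox import synthetic as syn


def load_features(out: Path, seed: int) -> pd.DataFrame:
    path = out / "colony_features.csv"
    if path.exists():
        return pd.read_csv(path)
    # fall back to a fresh simulation matching 04's conditions
    import subprocess, sys
    subprocess.run([sys.executable, str(Path(__file__).parent / "04_colony_features.py"),
                    "--seed", str(seed), "--out", str(out)], check=True)
    return pd.read_csv(path)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    features = load_features(args.out, args.seed)
    tidy = features.rename(columns={"normalized_area": "value",
                                    "condition": "group", "time_h": "time"})
    tidy = tidy[tidy["time"] > 0][["value", "group", "time"]]

    data = gs.GroupedData(tidy, control_group="control")
    checked, transform_report = gs.check_and_transform(data)
    print("log transform applied:", transform_report.transformed,
          "| trigger:", transform_report.trigger)

    final_t = tidy["time"].max()
    final = gs.GroupedData(tidy[tidy["time"] == final_t].drop(columns="time"),
                           "control")
    oneway = gs.anova_dunnett(final)
    print(f"final time point ({final_t} h) Dunnett vs control:")
    print(oneway.to_string(index=False))

    twoway = gs.two_way_anova_dunnett(checked)
    print("first significant time per group:", twoway.first_significant_time)

    report = {
        "transform": {"applied": transform_report.transformed,
                      "trigger": transform_report.trigger},
        "final_time_dunnett": oneway.to_dict(orient="records"),
        "two_way_anova": {str(k): {"F": float(v["F"]), "p": float(v["PR(>F)"])}
                          for k, v in twoway.anova_table.iterrows()
                          if str(k) != "Residual"},
        "first_significant_time": twoway.first_significant_time,
    }
    (args.out / "stats_report.json").write_text(json.dumps(report, indent=2) + "\n")


if __name__ == "__main__":
    main()
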