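#!/usr/bin/env python
"""Compare vehicle vs chronic-diazepam synapse metrics.

Applies the study's statistical policy to the per-synapse tables from
02_localization_pipeline.py: optional Grubbs outlier removal, the four-test
normality gate, then an unpaired t-test or Mann-Whitney per variable.
Writes the report table and prints it.
"""

import argparse
from pathlib import Path

import pandas as pd

from nanoorg.stats_report import ComparisonPolicy, compare_table

parser = argparse.ArgumentParser()
parser.add_argument("--metrics", type=Path, default=Path("results/synapse_metrics.csv"))
parser.add_argument("--out", type=Path, default=Path("results/group_comparison.csv"))
args = parser.parse_args()

df = pd.read_csv(args.metrics)
variables = ["total_area", "loc_density", "n_ssd", "mean_ssd_area",
             "ssd_to_synapse_area"]
reports = []
for ch, label in (("scaffold", "gephyrin"), ("receptor", "gamma2")):
    tidy = (df[df.channel == ch]
            .melt(id_vars=["group"], value_vars=variables,
                  var_name="variable", value_name="value")
            .dropna(subset=["value"]))
    rep = compare_table(tidy, policy=ComparisonPolicy(remove_outliers=True))
    rep.insert(0, "channel", label)
    reports.append(rep)

report = pd.concat(reports, ignore_index=True)
args.out.parent.mkdir(parents=True, exist_ok=True)
report.to_csv(args.out, index=False)
pd.set_option("display.width", 200)
cols = ["channel", "variable", "test_used", "p_value", "n_dzp", "n_vehicle"]
print(report[cols].to_string(index=False))
print(f"\nwrote {args.out}")
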