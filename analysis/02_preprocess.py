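"""Preprocess raw records into the hourly modelling series.

Applies the <0.002 g food-event exclusion, aggregates to 5-min blocks and
then to per-mouse hourly values, and labels study blocks (days 0.5-6.5,
6.5-12.5, 12.5-17.5).
"""
import argparse
from pathlib import Path

from circagest.cohort import read_cohort
from circagest.preprocess import aggregate, filter_food_events, to_five_min

p = argparse.ArgumentParser()
p.add_argument("--results", type=Path, default=Path("results"))
args = p.parse_args()

records = read_cohort(args.results / "raw_records.csv")
filtered = filter_food_events(records)
to_five_min(filtered).to_csv(args.results / "five_min_blocks.csv", index=False)
hourly = aggregate(records)
hourly.to_csv(args.results / "hourly.csv", index=False)
n_missing = hourly["value"].isna().sum()
print(f"{len(records) - len(filtered):,} food events excluded; "
      f"{len(hourly):,} hourly values ({n_missing} missing) -> {args.results/'hourly.csv'}")
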