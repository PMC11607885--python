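"""Posterior peak inference across the five circadian windows.

For each behaviour x window x block: share of posterior draws with a local
maximum, peak time/amplitude summaries, and pregnant-minus-nonpregnant
differences (conditional on joint presence) with 95% credible intervals.
"""
import argparse
from pathlib import Path

import pandas as pd

from circagest.model import PosteriorCurves
from circagest.peaks import peak_table

p = argparse.ArgumentParser()
p.add_argument("--results", type=Path, default=Path("results"))
args = p.parse_args()

tables = []
for npz in sorted(args.results.glob("draws_*.npz")):
    curves = PosteriorCurves.load(npz)
    pt = peak_table(curves, force=True)
    pt.to_csv(args.results / f"peaks_{curves.behaviour}.csv", index=False)
    tables.append(pt)
    sig = pt[[c for c in pt.columns if c.endswith("_significant")]].sum().sum()
    print(f"{curves.behaviour}: {int(sig)} significant contrasts of {2*len(pt)}")
pd.concat(tables, ignore_index=True).to_csv(args.results / "peak_tables.csv", index=False)
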