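#!/usr/bin/env python
"""Does the systematic ILIS selection prefer retention-time-close surrogates?

Runs the selection experiment (one orphan analyte, one near candidate at
|dRT| 0.07 min vs three distant ones, soils S1-S5) across independently
seeded batches.  Because matrix-effect and recovery-shock correlations
decay with |dRT|, the nearest candidate should compensate best and win the
band-count/dispersion ranking in most runs.
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from soilmrm.pipeline import assignment_experiment

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-runs", type=int, default=200)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

res = assignment_experiment(n_runs=args.n_runs, base_seed=args.seed)
counts = Counter(res["chosen_ids"])
table = pd.DataFrame(
    sorted(counts.items()), columns=["ilis_id", "n_selected"]
)
args.out_dir.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out_dir / "ilis_selection_experiment.csv", index=False)

print(table.to_string(index=False))
print(f"\nnearest-RT candidate selected in "
      f"{res['n_nearest_selected']}/{res['n_runs']} runs "
      f"({100 * res['fraction_nearest_selected']:.1f}%)")
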