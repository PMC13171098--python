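"""Run the desk-scale savings study: growing up, NF1/FF1/NF2/FF2, and the
opposite-field control, for a 5-seed ensemble.

Writes results/study.pkl (full records for the downstream analyses),
results/curves_<condition>.csv (per-batch learning curves, field-direction
sign) and the array-archive record files.
"""

import pathlib
import pickle
import sys
import time

import numpy as np
import pandas as pd

from curladapt.fixtures import tiny_config
from curladapt.protocol import PHASE_ORDER, run_full_study

OUT = pathlib.Path(sys.argv[1] if len(sys.argv) > 1 else "results")
OUT.mkdir(parents=True, exist_ok=True)

config = tiny_config()
print(f"Desk-scale study: {config.n_units} units, seeds {list(config.seeds)}, "
      f"growing up {config.gu_batches} batches, phases {config.phase_batches}")

t0 = time.time()
study = run_full_study(config)
print(f"completed in {time.time() - t0:.0f} s")

with open(OUT / "study.pkl", "wb") as fh:
    pickle.dump(study, fh)

for cond, rec in study.items():
    rows = []
    for ph in PHASE_ORDER:
        cf = rec.curves_field(ph)
        for s in range(rec.n_seeds):
            rows.append(pd.DataFrame(dict(
                condition=cond, phase=ph, seed=config.seeds[s],
                batch=np.arange(cf.shape[0]), deviation_m=cf[:, s])))
    pd.concat(rows).to_csv(OUT / f"curves_{cond}.csv", index=False)
    rec.save(OUT / f"{cond}")
    print(f"[{cond}] batch-0 deviation (mm): "
          + ", ".join(f"{ph} {1000 * rec.batch0_deviation(ph).mean():+.1f}"
                      for ph in PHASE_ORDER))

print(f"wrote {OUT}/study.pkl and per-condition curves/records")
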