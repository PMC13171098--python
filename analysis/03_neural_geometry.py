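"""Preparatory-activity geometry: TDR ring and uniform-shift persistence.

Reads results/study.pkl; writes results/tdr_ring.csv (per-seed, per-phase
2-D coordinates of the 8 preparatory states in the force-predictive plane)
and results/uniform_shift.csv (normalized projections per phase), and prints
whether the washed-out state retains part of the shift (the candidate memory
trace) along with a one-sample t test of the NF2 projection against zero.
"""

import pathlib
import pickle
import sys

import numpy as np
import pandas as pd
from scipy import stats

from curladapt import neural_analysis as na
from curladapt.protocol import PHASE_ORDER

OUT = pathlib.Path(sys.argv[1] if len(sys.argv) > 1 else "results")
study = pickle.load(open(OUT / "study.pkl", "rb"))
rec = study["main"]

ring_rows, proj_rows = [], []
for s in range(rec.n_seeds):
    mats = rec.prep_matrices(s)
    tdr = na.fit_tdr(mats["NF1"], rec.force_matrix(s))
    gm = na.global_mean(mats.values())
    us = na.compute_uniform_shift(mats["FF1"], mats["NF1"], tdr)
    proj = na.project_and_normalize(mats, us, gm)
    for ph in PHASE_ORDER:
        xy = na.project_onto_tdr(mats[ph], tdr, gm)
        for k in range(xy.shape[0]):
            ring_rows.append(dict(seed=rec.config.seeds[s], phase=ph, target=k,
                                  x=xy[k, 0], y=xy[k, 1]))
        proj_rows.append(dict(seed=rec.config.seeds[s], phase=ph,
                              projection=proj[ph],
                              shift_norm=np.linalg.norm(us.us)))

pd.DataFrame(ring_rows).to_csv(OUT / "tdr_ring.csv", index=False)
pdf = pd.DataFrame(proj_rows)
pdf.to_csv(OUT / "uniform_shift.csv", index=False)

wide = pdf.pivot(index="seed", columns="phase", values="projection")
print("normalized uniform-shift projections (NF1 = 0, FF1 = 1 by construction):")
print(wide.round(3).to_string())
nf2 = wide["NF2"].to_numpy()
t, p = stats.ttest_1samp(nf2, 0.0)
print(f"\nNF2 residual: mean {nf2.mean():.3f}, one-sample t({len(nf2)-1}) = {t:.3f}, "
      f"p = {p:.3g}")
frac = np.mean((nf2 > 0) & (nf2 < 1))
print(f"fraction of seeds with NF2 projection strictly inside (0, 1): {frac:.0%}")
print(f"wrote {OUT}/tdr_ring.csv and uniform_shift.csv")
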