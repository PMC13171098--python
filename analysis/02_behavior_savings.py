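"""Behavioral analysis: adaptation, after-effect, washout, savings.

Reads results/study.pkl; writes results/savings.csv (per-seed fits and
flags) and results/savings_summary.csv, and prints the headline statistics:
batch-0 deviations, exponential learning rates, savings percentages with
Wilson CIs, and the paired t comparisons between first and second exposure.
"""

import pathlib
import pickle
import sys

import pandas as pd

from curladapt import behavior
from curladapt.behavior import LearningCurve, fit_learning_curve

OUT = pathlib.Path(sys.argv[1] if len(sys.argv) > 1 else "results")
study = pickle.load(open(OUT / "study.pkl", "rb"))

rows = []
for cond, rec in study.items():
    for s in range(rec.n_seeds):
        fits = {ph: fit_learning_curve(LearningCurve(rec.curves_field(ph)[:, s], ph))
                for ph in ("FF1", "FF2")}
        d1, d2 = rec.batch0_deviation("FF1")[s], rec.batch0_deviation("FF2")[s]
        rate_sav, dev_sav = behavior.classify_savings(fits["FF1"], fits["FF2"], d1, d2)
        rows.append(dict(
            condition=cond, seed=rec.config.seeds[s],
            nf1_end_m=rec.curves_field("NF1")[-20:, s].mean(),
            ff1_b0_m=d1, ff2_b0_m=d2,
            nf2_b0_m=rec.batch0_deviation("NF2")[s],
            nf2_end_m=rec.curves_field("NF2")[-20:, s].mean(),
            r_ff1=fits["FF1"].r, r_ff2=fits["FF2"].r,
            alpha_ff1=fits["FF1"].alpha, alpha_ff2=fits["FF2"].alpha,
            rate_savings=rate_sav, deviation_savings=dev_sav))
df = pd.DataFrame(rows)
df.to_csv(OUT / "savings.csv", index=False)

summary = []
for cond, g in df.groupby("condition"):
    dev_pct, dev_ci = behavior.savings_rate(g.deviation_savings.tolist())
    rate_pct, rate_ci = behavior.savings_rate(g.rate_savings.tolist())
    t_dev, df_dev, p_dev = behavior.paired_t(g.ff1_b0_m, g.ff2_b0_m)
    t_r, df_r, p_r = behavior.paired_t(g.r_ff2, g.r_ff1)
    summary.append(dict(condition=cond,
                        deviation_savings_pct=dev_pct,
                        deviation_savings_ci_lo=dev_ci[0], deviation_savings_ci_hi=dev_ci[1],
                        rate_savings_pct=rate_pct,
                        rate_savings_ci_lo=rate_ci[0], rate_savings_ci_hi=rate_ci[1],
                        t_dev=t_dev, df_dev=df_dev, p_dev=p_dev,
                        t_rate=t_r, df_rate=df_r, p_rate=p_r))
    print(f"\n[{cond}]")
    print(f"  NF1 end {1000 * g.nf1_end_m.mean():+.2f} mm | "
          f"FF1 b0 {1000 * g.ff1_b0_m.mean():+.1f} mm | "
          f"NF2 b0 (after-effect) {1000 * g.nf2_b0_m.mean():+.1f} mm | "
          f"NF2 end {1000 * g.nf2_end_m.mean():+.2f} mm | "
          f"FF2 b0 {1000 * g.ff2_b0_m.mean():+.1f} mm")
    print(f"  learning rate r: FF1 {g.r_ff1.mean():.1f} -> FF2 {g.r_ff2.mean():.1f}")
    print(f"  deviation savings {dev_pct:.0f}% (95% CI {dev_ci[0]:.0f}-{dev_ci[1]:.0f}), "
          f"rate savings {rate_pct:.0f}%")
    print(f"  paired t (FF1 b0 vs FF2 b0): t({df_dev}) = {t_dev:.3f}, p = {p_dev:.2g}")
pd.DataFrame(summary).to_csv(OUT / "savings_summary.csv", index=False)
print(f"\nwrote {OUT}/savings.csv and savings_summary.csv")
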