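"""Clinical grading of BP predictions: BHS letters, AAMI verdict,
Bland-Altman limits of agreement.

Simulates a predictor with ~4 mmHg error on systolic pressure and grades it
the way a cuff-less device would be judged.
"""

import numpy as np

from dsrunet.evaluation import aami_check, bhs_grade, bland_altman, metrics

rng = np.random.default_rng(0)
true_sbp = rng.uniform(90.0, 175.0, size=500)
pred_sbp = true_sbp + rng.normal(0.5, 4.0, size=500)

m = metrics(true_sbp, pred_sbp)
print(f"ME {m.me:+.2f}  MAE {m.mae:.2f}  RMSE-style STD {m.std_eq20:.2f}  "
      f"error dispersion {m.sd_diff:.2f}  R2 {m.r2:.3f}  r {m.r:.3f}")

bhs = bhs_grade(abs_errors=np.abs(pred_sbp - true_sbp))
print(f"BHS: {bhs.pct_within[0]:.1f}% / {bhs.pct_within[1]:.1f}% / "
      f"{bhs.pct_within[2]:.1f}% within 5/10/15 mmHg -> grade {bhs.grade} "
      f"(worst of per-threshold grades {bhs.per_threshold})")

aami = aami_check(m.me, m.sd_diff, n_subjects=500)
print(f"AAMI: |ME| <= 5 and SD <= 8 over >= 85 subjects -> "
      f"{'PASS' if aami.passed else 'FAIL'}")

ba = bland_altman(true_sbp, pred_sbp)
print(f"Bland-Altman: mean diff {ba.mean_diff:+.2f} mmHg, "
      f"95% limits of agreement [{ba.loa[0]:+.2f}, {ba.loa[1]:+.2f}] "
      f"({100 * ba.frac_within_loa:.1f}% of points inside)")
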