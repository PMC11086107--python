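"""Small end-to-end run: synthesize, preprocess, train, predict, grade.

Uses a reduced dataset and few epochs so it finishes in a couple of minutes
on one CPU; scale n_records / max_epochs up for a more faithful run.
"""

import numpy as np

from dsrunet.evaluation import evaluate_run
from dsrunet.nn.model import build_dsrunet, variant_config
from dsrunet.preprocess import PreprocessConfig, preprocess_records
from dsrunet.synth import SynthConfig, generate_dataset
from dsrunet.training import TrainConfig, predict, train

records, _ = generate_dataset(SynthConfig(n_records=16, duration_s=512.0, seed=2))
splits, _ = preprocess_records(records, PreprocessConfig(seed=2))
print(f"segments: train {len(splits['train'])}, val {len(splits['val'])}, "
      f"test {len(splits['test'])}")

net = build_dsrunet(variant_config("dsrunet", base_channels=12, se_reduction=4),
                    seed=2)
cfg = TrainConfig.desk(max_epochs=6, early_stop_patience=5, seed=2)
_, history = train(net, splits["train"], splits["val"], cfg)
print(f"trained {history.n_epochs} epochs ({history.stop_reason})")
print("validation MAE per epoch (standardized units):",
      [round(v, 3) for v in history.val_mae])

preds = predict(net, splits["test"])                      # mmHg
targets = np.stack([s.abp_mmhg() for s in splits["test"]])
report = evaluate_run(preds, targets, make_plots=False)

print(f"\nheld-out waveform: MAE {report.waveform.mae:.2f} mmHg, "
      f"RMSE {report.waveform.std_eq20:.2f} mmHg, R2 {report.waveform.r2:.3f}")
for p in ("sbp", "dbp", "mbp"):
    m = report.per_parameter[p]
    print(f"{p.upper()}: MAE {m.mae:5.2f} mmHg  BHS {report.bhs[p].grade}  "
          f"AAMI {'pass' if report.aami[p].passed else 'fail'}")
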