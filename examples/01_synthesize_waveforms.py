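"""Generate one synthetic paired PPG/ABP record and inspect its ground truth.

The arterial pulse is a two-Gaussian shape (systolic peak + dicrotic wave)
whose per-beat maximum/minimum hit the drawn SBP/DBP exactly before
corruption; the PPG channel is a delayed monotone warp of the same trace.
"""

import numpy as np

from dsrunet.synth import SynthConfig, generate_record

cfg = SynthConfig(duration_s=60.0, seed=0)
record, truth = generate_record(cfg, np.random.default_rng(0), record_id="demo#0")

print(f"record {record.record_id}: {record.n_samples} samples "
      f"({record.duration_s:.0f} s at {record.fs:.0f} Hz)")
print(f"beats: {truth.n_beats}")
print(f"SBP  mean {truth.sbp.mean():6.1f}  range [{truth.sbp.min():.1f}, {truth.sbp.max():.1f}] mmHg")
print(f"DBP  mean {truth.dbp.mean():6.1f}  range [{truth.dbp.min():.1f}, {truth.dbp.max():.1f}] mmHg")
print(f"MBP  mean {truth.mbp.mean():6.1f} mmHg   (MBP = (SBP + 2*DBP)/3)")
print()
print("first beats (onset sample, SBP, DBP):")
for i in range(3):
    print(f"  beat {i}: onset {truth.onsets[i]:5d}  "
          f"SBP {truth.sbp[i]:6.1f}  DBP {truth.dbp[i]:6.1f}")
# The per-beat truth is what the evaluation stage later tries to recover
# from predicted waveforms.
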