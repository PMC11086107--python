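"""Run the conditioning chain on synthetic records and inspect the output.

Chain: duration filter -> FFT baseline removal -> 0.5-8 Hz zero-phase
Butterworth band-pass (PPG; ABP gets the low-pass branch only) -> 3-sigma
peak clipping -> per-record PPG z-score -> 1024-sample segmentation ->
6:2:2 random split -> global ABP standardization from the training split.
"""

from dsrunet.preprocess import PreprocessConfig, preprocess_records
from dsrunet.synth import SynthConfig, generate_dataset

records, _ = generate_dataset(SynthConfig(n_records=4, duration_s=500.0, seed=1))
splits, attrs = preprocess_records(records, PreprocessConfig(seed=1))

total = sum(len(v) for v in splits.values())
print(f"{len(records)} records -> {total} segments of 1024 samples")
for name in ("train", "val", "test"):
    print(f"  {name:5s}: {len(splits[name]):4d} segments")
print(f"ABP standardization: mu = {attrs['abp_mu']:.2f} mmHg, "
      f"sigma = {attrs['abp_sigma']:.2f} mmHg (stored for inversion)")

seg = splits["train"][0]
print(f"\nexample segment from {seg.record_id} at offset {seg.offset}:")
print(f"  ppg: mean {seg.ppg.mean():+.3f}, std {seg.ppg.std():.3f} (z-scored)")
print(f"  abp: mean {seg.abp.mean():+.3f} standardized "
      f"-> {seg.abp_mmhg().mean():.1f} mmHg after inversion")
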