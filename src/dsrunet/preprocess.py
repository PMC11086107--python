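"""Signal conditioning pipeline for paired PPG/ABP records.

The chain mirrors common practice for the UCI cuff-less blood-pressure
container: short records are dropped, slow baseline wander is removed in the
Fourier domain, a fourth-order Butterworth band-pass (0.5–8 Hz at 125 Hz)
removes out-of-band noise, outlier peaks are clipped back by linear
interpolation against a mean ± k·std threshold, PPG is z-scored per record,
and the result is cut into non-overlapping 1024-sample windows which are
randomly partitioned 6:2:2 into train/validation/test sets.

ABP carries an absolute pressure level (mmHg), which a 0.5 Hz high-pass
would destroy.  By default only the 8 Hz low-pass branch is applied to ABP
(``abp_filter="lowpass"``); ``"bandpass"`` reproduces a strict
both-signals-band-passed variant and ``"none"`` leaves ABP untouched.
ABP is standardized with training-set global statistics (stored per segment
for inversion) so predictions are reported in mmHg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .records import RawRecord, RecordSet, SegmentPair

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "filter_records",
    "remove_baseline_fft",
    "bandpass_butterworth",
    "lowpass_butterworth",
    "clip_peaks",
    "zscore",
    "segment",
    "split",
    "preprocess_records",
]


@dataclass
class PreprocessConfig:
    """All tunables of the conditioning chain.

    Defaults follow the protocol described in the module docstring: 8-minute
    minimum record duration, 0.5–8 Hz fourth-order band-pass, 1024-sample
    windows, 6:2:2 split.  ``clip_k`` (threshold multiplier for peak
    clipping) and the baseline-removal taper are implementation choices.
    """

    min_duration_s: float = 480.0
    band_low: float = 0.5
    band_high: float = 8.0
    butter_order: int = 4
    clip_k: float = 3.0
    window_len: int = 1024
    split_ratios: tuple[float, float, float] = (6.0, 2.0, 2.0)
    seed: int = 0
    zscore_abp: bool = True
    abp_filter: str = "lowpass"  # "lowpass" | "bandpass" | "none"
    baseline_cutoff_hz: float = 0.5
    baseline_taper_hz: float = 0.1

    def validate(self, fs: float = 125.0) -> None:
        if not (0 < self.band_low < self.band_high < fs / 2):
            raise ValueError("require 0 < band_low < band_high < fs/2")
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if sum(self.split_ratios) <= 0 or any(r < 0 for r in self.split_ratios):
            raise ValueError("split ratios must be nonnegative with positive sum")
        if self.abp_filter not in ("lowpass", "bandpass", "none"):
            raise ValueError(f"unknown abp_filter {self.abp_filter!r}")


def filter_records(rs: RecordSet, min_duration_s: float) -> RecordSet:
    """Drop records shorter than ``min_duration_s`` (boundary inclusive)."""
    kept = [r for r in rs if r.duration_s >= min_duration_s]
    logger.info(
        "duration filter (>= %.0f s): kept %d of %d records",
        min_duration_s, len(kept), len(rs),
    )
    return RecordSet(records=kept, source=rs.source)


def remove_baseline_fft(
    x: np.ndarray,
    fs: float,
    cutoff_hz: float = 0.5,
    taper_hz: float = 0.1,
) -> np.ndarray:
    """Remove baseline wander by zeroing low-frequency Fourier bins.

    The linear trend is removed first (a non-periodic trend leaks across
    the whole spectrum of a finite window), then all bins with
    |f| < ``cutoff_hz`` (including DC) are zeroed; a raised-cosine ramp of
    width ``taper_hz`` just above the cutoff avoids ringing from a
    brick-wall edge.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("input must be a 1-D sequence of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    x = scipy.signal.detrend(x, type="linear")
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    gain = np.ones_like(freqs)
    gain[freqs < cutoff_hz] = 0.0
    if taper_hz > 0:
        ramp = (freqs >= cutoff_hz) & (freqs < cutoff_hz + taper_hz)
        gain[ramp] = 0.5 * (1 - np.cos(np.pi * (freqs[ramp] - cutoff_hz) / taper_hz))
    return np.fft.irfft(spectrum * gain, n=len(x))


def _butter_sos(fs, low, high, order, btype):
    if btype == "bandpass":
        return scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return scipy.signal.butter(order, high, btype="lowpass", fs=fs, output="sos")


def bandpass_butterworth(
    x: np.ndarray, fs: float, low: float = 0.5, high: float = 8.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward–backward application)."""
    x = np.asarray(x, dtype=float)
    sos = _butter_sos(fs, low, high, order, "bandpass")
    padlen = 3 * (2 * order + 1)
    if len(x) <= padlen:
        raise ValueError(f"sequence of length {len(x)} too short for filter warm-up ({padlen})")
    return scipy.signal.sosfiltfilt(sos, x)


def lowpass_butterworth(
    x: np.ndarray, fs: float, high: float = 8.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; used for ABP to preserve its DC level."""
    x = np.asarray(x, dtype=float)
    sos = _butter_sos(fs, None, high, order, "lowpass")
    padlen = 3 * (2 * order + 1)
    if len(x) <= padlen:
        raise ValueError(f"sequence of length {len(x)} too short for filter warm-up ({padlen})")
    return scipy.signal.sosfiltfilt(sos, x)


def clip_peaks(x: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Replace outlier peaks by linear interpolation.

    Samples with ``|x - mean| > k*std`` (mean/std of the input) are replaced
    by linear interpolation between the nearest unflagged neighbors; flagged
    runs touching the sequence edges are filled with the nearest valid value.
    A constant signal (std = 0) is returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    mu = float(np.mean(x))
    sd = float(np.std(x))
    if sd == 0.0:
        return x.copy()
    flagged = np.abs(x - mu) > k * sd
    if not flagged.any():
        return x.copy()
    if flagged.all():
        raise ValueError("all samples exceed the clipping threshold (degenerate signal)")
    idx = np.arange(len(x))
    good = ~flagged
    out = x.copy()
    out[flagged] = np.interp(idx[flagged], idx[good], x[good])
    return out


def zscore(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize to zero mean / unit variance (population convention).

    Returns ``(z, mu, sigma)`` so that ``x == z * sigma + mu``.
    """
    x = np.asarray(x, dtype=float)
    mu = float(np.mean(x))
    sigma = float(np.std(x))
    if sigma == 0.0:
        raise ValueError("zero-variance input cannot be z-scored")
    return (x - mu) / sigma, mu, sigma


def segment(
    x_ppg: np.ndarray,
    x_abp: np.ndarray,
    window_len: int = 1024,
    record_id: str = "",
) -> list[SegmentPair]:
    """Cut paired signals into non-overlapping windows; remainder dropped."""
    x_ppg = np.asarray(x_ppg, dtype=float)
    x_abp = np.asarray(x_abp, dtype=float)
    if len(x_ppg) != len(x_abp):
        raise ValueError("ppg and abp must have equal length")
    n = len(x_ppg) // window_len
    return [
        SegmentPair(
            ppg=x_ppg[i * window_len:(i + 1) * window_len].copy(),
            abp=x_abp[i * window_len:(i + 1) * window_len].copy(),
            record_id=record_id,
            offset=i * window_len,
        )
        for i in range(n)
    ]


def _apportion(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items by the given ratios."""
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    sizes = [math.floor(q) for q in quotas]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - sizes[i], reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def split(
    segments: list[SegmentPair],
    ratios: tuple[float, float, float] = (6.0, 2.0, 2.0),
    seed: int = 0,
) -> tuple[list[SegmentPair], list[SegmentPair], list[SegmentPair]]:
    """Seeded uniform random partition into (train, val, test).

    Sizes follow largest-remainder apportionment of the ratios; the same
    seed always yields the same membership.  With fewer than 3 segments
    everything goes to train (with a warning).
    """
    segments = list(segments)
    if len(segments) < 3:
        if segments:
            logger.warning("only %d segments: all assigned to train", len(segments))
        return segments, [], []
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(segments))
    n_train, n_val, n_test = _apportion(len(segments), ratios)
    train = [segments[i] for i in perm[:n_train]]
    val = [segments[i] for i in perm[n_train:n_train + n_val]]
    test = [segments[i] for i in perm[n_train + n_val:]]
    return train, val, test


def _condition_record(rec: RawRecord, cfg: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    """Apply the per-record signal chain; returns (ppg_z, abp_mmhg)."""
    ppg = remove_baseline_fft(
        rec.ppg, rec.fs, cfg.baseline_cutoff_hz, cfg.baseline_taper_hz
    )
    ppg = bandpass_butterworth(ppg, rec.fs, cfg.band_low, cfg.band_high, cfg.butter_order)
    if cfg.abp_filter == "bandpass":
        abp = bandpass_butterworth(rec.abp, rec.fs, cfg.band_low, cfg.band_high, cfg.butter_order)
    elif cfg.abp_filter == "lowpass":
        abp = lowpass_butterworth(rec.abp, rec.fs, cfg.band_high, cfg.butter_order)
    else:
        abp = np.asarray(rec.abp, dtype=float)
    ppg = clip_peaks(ppg, cfg.clip_k)
    abp = clip_peaks(abp, cfg.clip_k)
    ppg, _, _ = zscore(ppg)
    return ppg, abp


def preprocess_records(
    rs: RecordSet, cfg: PreprocessConfig, fs: float | None = None
) -> tuple[dict[str, list[SegmentPair]], dict[str, float]]:
    """Run the full chain on a record set.

    Returns ``(splits, attrs)`` where ``splits`` maps train/val/test to
    segment lists and ``attrs`` carries the training-set ABP normalization
    constants (also stored on every segment for inversion).
    """
    if fs is None:
        fs = rs.records[0].fs if len(rs) else 125.0
    cfg.validate(fs)
    rs = filter_records(rs, cfg.min_duration_s)
    segments: list[SegmentPair] = []
    for rec in rs:
        ppg, abp = _condition_record(rec, cfg)
        segments.extend(segment(ppg, abp, cfg.window_len, rec.record_id))
    train, val, test = split(segments, cfg.split_ratios, cfg.seed)
    attrs = {"abp_mu": 0.0, "abp_sigma": 1.0}
    if cfg.zscore_abp and train:
        flat = np.concatenate([s.abp for s in train])
        mu = float(np.mean(flat))
        sigma = float(np.std(flat))
        if sigma == 0.0:
            raise ValueError("training-set ABP has zero variance")
        for s in train + val + test:
            s.abp = (s.abp - mu) / sigma
            s.norm_mu, s.norm_sigma = mu, sigma
        attrs = {"abp_mu": mu, "abp_sigma": sigma}
    logger.info(
        "preprocessed %d records -> %d segments (train %d / val %d / test %d)",
        len(rs), len(segments), len(train), len(val), len(test),
    )
    return {"train": train, "val": val, "test": test}, attrs
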