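"""Core data containers for paired PPG/ABP signals.

A :class:`RawRecord` holds one subject's synchronized photoplethysmogram
(PPG, arbitrary units) and arterial blood pressure (ABP, mmHg) traces at a
common sampling rate (125 Hz throughout the pipeline).  Records are grouped
into a :class:`RecordSet`; after preprocessing they are cut into fixed-length
:class:`SegmentPair` windows that the network consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["RawRecord", "RecordSet", "SegmentPair"]


@dataclass
class RawRecord:
    """One subject record: synchronized PPG and ABP traces.

    Parameters
    ----------
    record_id : str
        Unique identifier (e.g. ``"Part_1.mat#17"``).
    ppg : ndarray
        PPG samples, arbitrary units.
    abp : ndarray
        ABP samples, mmHg; same length as ``ppg``.
    fs : float
        Sampling rate in Hz (default 125).
    """

    record_id: str
    ppg: np.ndarray
    abp: np.ndarray
    fs: float = 125.0

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.ppg.ndim != 1 or self.abp.ndim != 1:
            raise ValueError("ppg and abp must be 1-D sample sequences")
        if len(self.ppg) != len(self.abp):
            raise ValueError(
                f"record {self.record_id!r}: ppg has {len(self.ppg)} samples "
                f"but abp has {len(self.abp)}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.ppg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class RecordSet:
    """Ordered collection of records with unique ids."""

    records: list[RawRecord] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record_ids must be unique within a RecordSet")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RawRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> RawRecord:
        return self.records[i]


@dataclass
class SegmentPair:
    """One fixed-length PPG input window paired with its ABP target window.

    ``norm_mu``/``norm_sigma`` store the standardization applied to the ABP
    channel (identity: mu=0, sigma=1) so predictions can be mapped back to
    mmHg.
    """

    ppg: np.ndarray
    abp: np.ndarray
    record_id: str = ""
    offset: int = 0
    norm_mu: float = 0.0
    norm_sigma: float = 1.0

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.ppg.shape != self.abp.shape or self.ppg.ndim != 1:
            raise ValueError("ppg/abp windows must be 1-D and equally long")
        if self.norm_sigma <= 0:
            raise ValueError("norm_sigma must be positive")

    @property
    def window_len(self) -> int:
        return len(self.ppg)

    def abp_mmhg(self) -> np.ndarray:
        """ABP window mapped back to mmHg (inverts the stored z-scoring)."""
        return self.abp * self.norm_sigma + self.norm_mu


def stack_segments(segments: Sequence[SegmentPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a segment collection into (ppg, abp) arrays of shape [n, L]."""
    if not segments:
        return np.empty((0, 0)), np.empty((0, 0))
    ppg = np.stack([s.ppg for s in segments])
    abp = np.stack([s.abp for s in segments])
    return ppg, abp
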