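"""Readers and writers for physiological record containers.

Three storage formats are supported:

* the UCI cuff-less blood-pressure container layout — MATLAB ``.mat`` files
  (v5 or v7.3/HDF5 dialect) holding one cell array of records, each cell a
  2-D array with one signal channel per row;
* plain CSV with ``ppg`` and ``abp`` columns for a single record;
* the package's internal HDF5 segment store with ``/train``, ``/val`` and
  ``/test`` groups.

Readers never resample or rescale: the sampling rate is metadata and sample
values are passed through bit-exactly.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io

from .records import RawRecord, RecordSet, SegmentPair

logger = logging.getLogger(__name__)

__all__ = [
    "read_ucibp_container",
    "read_csv_records",
    "write_dataset",
    "read_dataset",
]

#: Conventional channel ordering of the UCI container (ECG row ignored).
DEFAULT_CHANNEL_MAP: Mapping[str, int] = {"ppg": 0, "abp": 1}

UCIBP_FS = 125.0


class FormatError(ValueError):
    """Raised when a container does not have the expected layout."""


def _cells_from_mat_v5(path: str) -> list[np.ndarray]:
    mat = scipy.io.loadmat(path, squeeze_me=False)
    for name, value in mat.items():
        if name.startswith("__"):
            continue
        if isinstance(value, np.ndarray) and value.dtype == object:
            return [np.atleast_2d(np.asarray(c)) for c in value.ravel(order="F")]
    raise FormatError(f"{path}: no cell array variable found")


def _cells_from_mat_v73(path: str) -> list[np.ndarray]:
    cells: list[np.ndarray] = []
    with h5py.File(path, "r") as f:
        var = None
        for name, node in f.items():
            if name == "#refs#":
                continue
            if isinstance(node, h5py.Dataset) and node.dtype == h5py.ref_dtype:
                var = node
                break
        if var is None:
            raise FormatError(f"{path}: no cell array variable found")
        for ref in var[()].ravel():
            # MATLAB writes arrays column-major, so a channels-by-samples
            # cell appears transposed on disk.
            cells.append(np.atleast_2d(np.asarray(f[ref][()]).T))
    return cells


def read_ucibp_container(
    path: str | os.PathLike,
    channel_map: Mapping[str, int] | None = None,
    fs: float = UCIBP_FS,
) -> RecordSet:
    """Read one UCI blood-pressure container file into a :class:`RecordSet`.

    Each cell of the container's cell array becomes one record with
    ``record_id = "<filename>#<cell index>"``.  Cells with fewer rows than
    the channel map requires are skipped with a logged warning.

    Parameters
    ----------
    path : path
        A MATLAB ``.mat`` file (v5 or v7.3 dialect).
    channel_map : mapping, optional
        Role → row index; defaults to ``{"ppg": 0, "abp": 1}``.
    """
    path = os.fspath(path)
    cmap = dict(DEFAULT_CHANNEL_MAP if channel_map is None else channel_map)
    if h5py.is_hdf5(path):  # v7.3 dialect is an HDF5 container
        cells = _cells_from_mat_v73(path)
    else:
        cells = _cells_from_mat_v5(path)

    needed = max(cmap.values()) + 1
    fname = os.path.basename(path)
    records: list[RawRecord] = []
    n_skipped = 0
    for i, cell in enumerate(cells):
        if cell.shape[0] < needed:
            n_skipped += 1
            logger.warning(
                "%s cell %d has %d rows (< %d required); skipped",
                fname, i, cell.shape[0], needed,
            )
            continue
        records.append(
            RawRecord(
                record_id=f"{fname}#{i}",
                ppg=np.asarray(cell[cmap["ppg"]], dtype=float),
                abp=np.asarray(cell[cmap["abp"]], dtype=float),
                fs=fs,
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d malformed cells", fname, n_skipped)
    return RecordSet(records=records, source=path)


def read_csv_records(path: str | os.PathLike, fs: float = UCIBP_FS) -> RecordSet:
    """Read a single paired record from a CSV with ``ppg`` and ``abp`` columns."""
    path = os.fspath(path)
    df = pd.read_csv(path)
    for col in ("ppg", "abp"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    rec = RawRecord(
        record_id=os.path.basename(path),
        ppg=df["ppg"].to_numpy(dtype=float),
        abp=df["abp"].to_numpy(dtype=float),
        fs=fs,
    )
    return RecordSet(records=[rec], source=path)


_SPLITS = ("train", "val", "test")


def write_dataset(
    splits: Mapping[str, Sequence[SegmentPair]],
    path: str | os.PathLike,
    fs: float = UCIBP_FS,
    attrs: Mapping[str, float] | None = None,
) -> None:
    """Write segment splits to the internal HDF5 store.

    Layout: groups ``/train``, ``/val``, ``/test``; per group 2-D datasets
    ``ppg``/``abp`` of shape [n_segments, window_len] plus per-segment
    ``record_id``, ``offset``, ``norm_mu``, ``norm_sigma``.  Root attributes
    carry ``fs`` and any normalization constants passed via ``attrs``.
    """
    with h5py.File(os.fspath(path), "w") as f:
        f.attrs["fs"] = float(fs)
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        for split in _SPLITS:
            segs = list(splits.get(split, []))
            g = f.create_group(split)
            if not segs:
                continue
            g.create_dataset("ppg", data=np.stack([s.ppg for s in segs]))
            g.create_dataset("abp", data=np.stack([s.abp for s in segs]))
            g.create_dataset(
                "record_id",
                data=np.array([s.record_id for s in segs], dtype=h5py.string_dtype()),
            )
            g.create_dataset("offset", data=np.array([s.offset for s in segs], dtype=np.int64))
            g.create_dataset("norm_mu", data=np.array([s.norm_mu for s in segs]))
            g.create_dataset("norm_sigma", data=np.array([s.norm_sigma for s in segs]))


def read_dataset(path: str | os.PathLike) -> tuple[dict[str, list[SegmentPair]], dict]:
    """Read the internal HDF5 store back; inverse of :func:`write_dataset`."""
    splits: dict[str, list[SegmentPair]] = {}
    try:
        with h5py.File(os.fspath(path), "r") as f:
            attrs = dict(f.attrs)
            for split in _SPLITS:
                segs: list[SegmentPair] = []
                if split in f and "ppg" in f[split]:
                    g = f[split]
                    ppg = g["ppg"][()]
                    abp = g["abp"][()]
                    rid = [s.decode() if isinstance(s, bytes) else str(s) for s in g["record_id"][()]]
                    off = g["offset"][()]
                    mu = g["norm_mu"][()]
                    sig = g["norm_sigma"][()]
                    for i in range(ppg.shape[0]):
                        segs.append(
                            SegmentPair(
                                ppg=ppg[i], abp=abp[i], record_id=rid[i],
                                offset=int(off[i]), norm_mu=float(mu[i]),
                                norm_sigma=float(sig[i]),
                            )
                        )
                splits[split] = segs
    except OSError as e:
        raise IOError(f"cannot read dataset store {path}: {e}") from e
    return splits, attrs
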