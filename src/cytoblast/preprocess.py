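"""Event ingestion and the arcsinh / min-max preprocessing pipeline.

The pipeline is ``raw -> arcsinh -> scaled``: per-channel inverse hyperbolic
sine with a marker-specific cofactor (``asinh(x / c)``), then per-channel
min-max scaling fitted on training data only and reused unchanged on
validation/test data.  Values outside the training range are deliberately
not clipped, so downstream models may see values outside [0, 1].
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcs import read_fcs
from .matrix import CellMatrix
from .panel import MarkerPanel, PanelError


class PanelMismatchError(KeyError):
    """An input file does not provide all panel channels."""


def _file_rng(seed: int, name: str) -> np.random.Generator:
    # One stream per file keyed by (seed, file name): subsampling is then
    # independent of the order in which files are read.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def read_events(
    path,
    panel: MarkerPanel,
    max_events: int = 10_000,
    seed: int = 0,
    sample_id: str | None = None,
) -> CellMatrix:
    """Read an FCS 3.x or delimited event table and subsample events.

    At most ``max_events`` rows are retained, sampled uniformly without
    replacement with an RNG keyed by ``(seed, basename)``; when the file has
    fewer events all are kept.  Columns are reordered to panel order.
    """
    if max_events < 1:
        raise ValueError("max_events must be positive")
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith(".fcs"):
        frame, _ = read_fcs(path)
    elif lower.endswith(".tsv") or lower.endswith(".txt"):
        frame = pd.read_csv(path, sep="\t")
    else:
        frame = pd.read_csv(path)

    missing = [c for c in panel.channels if c not in frame.columns]
    if missing:
        raise PanelMismatchError(
            f"file {path!r} lacks panel channel(s): {', '.join(missing)}"
        )
    frame = frame[panel.channels]

    n = len(frame)
    if n > max_events:
        rng = _file_rng(seed, os.path.basename(path))
        keep = np.sort(rng.choice(n, size=max_events, replace=False))
        frame = frame.iloc[keep]

    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    return CellMatrix(
        values=frame.to_numpy(dtype=np.float64),
        channels=list(panel.channels),
        state="raw",
        sample_id=sample_id,
    )


def arcsinh_transform(m: CellMatrix, panel: MarkerPanel) -> CellMatrix:
    """Apply ``asinh(x / cofactor)`` per channel to a raw matrix."""
    m.require_state("raw")
    if m.channels != list(panel.channels):
        raise PanelError("matrix channels do not match panel")
    cof = np.asarray(panel.cofactor_array(), dtype=np.float64)
    if np.any(cof <= 0):
        raise PanelError("cofactors must be strictly positive")
    return CellMatrix(
        values=np.arcsinh(m.values / cof),
        channels=list(m.channels),
        state="arcsinh",
        sample_id=m.sample_id,
    )


@dataclass
class MinMaxScaler:
    """Per-channel min/max fitted on training data.

    Scaling maps ``x`` to ``(x - min) / (max - min)``; a constant channel
    (max == min) maps to 0 by convention.
    """

    channels: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.maxs = np.asarray(self.maxs, dtype=np.float64)
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in scaler")

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        return cls(channels=list(d["channels"]), mins=d["mins"], maxs=d["maxs"])


def fit_minmax(train: CellMatrix) -> MinMaxScaler:
    """Fit per-channel extrema on an arcsinh-state training matrix."""
    train.require_state("arcsinh")
    if train.n_cells == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    return MinMaxScaler(
        channels=list(train.channels),
        mins=train.values.min(axis=0),
        maxs=train.values.max(axis=0),
    )


def apply_minmax(scaler: MinMaxScaler, m: CellMatrix) -> CellMatrix:
    """Scale an arcsinh-state matrix with a previously fitted scaler.

    Held-out values outside the training range fall outside [0, 1] and are
    not clipped.
    """
    m.require_state("arcsinh")
    if list(m.channels) != list(scaler.channels):
        raise ValueError("scaler/matrix channel mismatch")
    span = scaler.maxs - scaler.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (m.values - scaler.mins) / safe
    scaled[:, span == 0] = 0.0
    return CellMatrix(
        values=scaled,
        channels=list(m.channels),
        state="scaled",
        sample_id=m.sample_id,
    )


def preprocess(
    m: CellMatrix, panel: MarkerPanel, scaler: MinMaxScaler | None = None
) -> tuple[CellMatrix, CellMatrix, MinMaxScaler]:
    """Run raw -> arcsinh -> scaled; fit the scaler here unless one is given.

    Returns the arcsinh matrix, the scaled matrix and the scaler used.
    """
    a = arcsinh_transform(m, panel)
    if scaler is None:
        scaler = fit_minmax(a)
    return a, apply_minmax(scaler, a), scaler


def save_matrix(m: CellMatrix, path, panel: MarkerPanel | None = None,
                scaler: MinMaxScaler | None = None) -> None:
    """Write a matrix as CSV plus a JSON sidecar recording provenance."""
    m.to_frame().to_csv(path, index=False)
    sidecar = {
        "state": m.state,
        "sample_id": m.sample_id,
        "n_cells": m.n_cells,
        "channels": list(m.channels),
    }
    if panel is not None:
        sidecar["panel"] = panel.to_dict()
    if scaler is not None:
        sidecar["scaler"] = scaler.to_dict()
    with open(os.fspath(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
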