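"""Core in-memory containers: per-cell event matrices and sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed processing states, in pipeline order.
STATES = ("raw", "arcsinh", "scaled")


class StateError(ValueError):
    """Raised when an operation receives a matrix in the wrong state."""


@dataclass
class CellMatrix:
    """An ``n_cells x n_channels`` intensity table with a processing state.

    The ``state`` flag tracks where the matrix sits in the preprocessing
    pipeline (``raw`` fluorescence intensities, ``arcsinh``-transformed, or
    min-max ``scaled``); operations check it so that, e.g., the arcsinh
    transform cannot be applied twice.
    """

    values: np.ndarray
    channels: list[str]
    state: str = "raw"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.channels)} channel names"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.state not in STATES:
            raise StateError(f"unknown state {self.state!r}")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in matrix")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]

    def subset(self, rows) -> "CellMatrix":
        """A new matrix with the given rows (same channels/state)."""
        return CellMatrix(
            values=self.values[rows],
            channels=list(self.channels),
            state=self.state,
            sample_id=self.sample_id,
        )

    def require_state(self, state: str) -> None:
        if self.state != state:
            raise StateError(f"expected state {state!r}, got {self.state!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channels)


def concat(matrices: list[CellMatrix]) -> CellMatrix:
    """Row-concatenate matrices sharing channels and state."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.channels != first.channels:
            raise ValueError("channel mismatch in concat")
        if m.state != first.state:
            raise StateError("state mismatch in concat")
    return CellMatrix(
        values=np.vstack([m.values for m in matrices]),
        channels=list(first.channels),
        state=first.state,
        sample_id="",
    )


@dataclass
class SampleMeta:
    """Per-sample metadata with optional per-cell ground-truth annotation.

    ``timepoint`` is one of {"diagnosis", "remission", "relapse"}.  For
    synthetic cohorts ``stage`` holds the true developmental stage per cell
    and ``is_blast`` the planted blast flag; ``extra`` carries additional
    per-cell arrays (e.g. subclone membership).
    """

    sample_id: str
    patient_id: str
    timepoint: str
    stage: np.ndarray | None = None
    is_blast: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in ("diagnosis", "remission", "relapse"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.stage is not None:
            self.stage = np.asarray(self.stage)
        if self.is_blast is not None:
            self.is_blast = np.asarray(self.is_blast, dtype=bool)
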