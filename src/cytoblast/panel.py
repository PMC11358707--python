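"""Marker panel definition for the 23-channel myeloid cytometry panel.

A :class:`MarkerPanel` bundles, per channel, the arcsinh cofactor used for
variance stabilisation, the positivity threshold (in arcsinh space) used for
gating and marker-dynamics accounting, and a coarse lineage role tag.  The
default panel covers 21 antibody markers spanning myeloid differentiation and
lymphoid lineage exclusion, plus forward and side scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Antibody channels of the default panel, in panel order.
ANTIBODY_CHANNELS: tuple[str, ...] = (
    "CD45", "CD19", "CD3", "CD4", "CD8", "CD56", "CD34", "CD45RA",
    "HLA-DR", "CD117", "CD38", "CD33", "CD35", "CD13", "CD123", "CD64",
    "CD11b", "CD11c", "CD14", "CD203c", "CD71",
)

#: Scatter channels appended after the antibodies.
SCATTER_CHANNELS: tuple[str, ...] = ("FSC", "SSC")

DEFAULT_ANTIBODY_COFACTOR = 1_000.0
DEFAULT_SCATTER_COFACTOR = 10_000.0

# Positivity thresholds in arcsinh space: midway between the negative and
# positive population levels of the bundled synthetic trajectory model.
_DEFAULT_THRESHOLDS: dict[str, float] = {
    "CD45": 1.8, "CD19": 1.5, "CD3": 1.5, "CD4": 1.0, "CD8": 1.5,
    "CD56": 1.6, "CD34": 2.0, "CD45RA": 2.0, "HLA-DR": 2.0, "CD117": 1.8,
    "CD38": 1.5, "CD33": 2.2, "CD35": 1.6, "CD13": 2.0, "CD123": 1.8,
    "CD64": 2.0, "CD11b": 2.0, "CD11c": 1.8, "CD14": 2.2, "CD203c": 1.5,
    "CD71": 2.0, "FSC": 2.0, "SSC": 2.0,
}

_LINEAGE_ROLES: dict[str, str] = {
    **{c: "myeloid" for c in (
        "CD45", "CD4", "CD34", "CD45RA", "HLA-DR", "CD117", "CD38", "CD33",
        "CD35", "CD13", "CD123", "CD64", "CD11b", "CD11c", "CD14",
        "CD203c", "CD71",
    )},
    **{c: "lymphoid" for c in ("CD19", "CD3", "CD8", "CD56")},
    **{c: "scatter" for c in SCATTER_CHANNELS},
}


class PanelError(ValueError):
    """Raised for inconsistent panel configuration."""


@dataclass
class MarkerPanel:
    """Ordered channel list with per-channel cofactors and thresholds.

    Parameters
    ----------
    channels
        Ordered, unique channel names.
    cofactors
        Per-channel arcsinh cofactor ``c`` (strictly positive); the transform
        applied is ``asinh(x / c)``.
    positivity_thresholds
        Per-channel threshold in arcsinh space; a cell is *positive* for a
        marker when its arcsinh value is strictly above this.
    lineage_role
        Per-channel tag in {"myeloid", "lymphoid", "scatter", "other"}.
    """

    channels: list[str]
    cofactors: dict[str, float]
    positivity_thresholds: dict[str, float]
    lineage_role: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise PanelError("channel names must be unique")
        for name in self.channels:
            c = self.cofactors.get(name)
            if c is None or c <= 0:
                raise PanelError(f"cofactor for {name!r} must be strictly positive")
            if name not in self.positivity_thresholds:
                raise PanelError(f"missing positivity threshold for {name!r}")
            self.lineage_role.setdefault(name, "other")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def cofactor_array(self) -> list[float]:
        return [self.cofactors[c] for c in self.channels]

    def threshold(self, channel: str) -> float:
        try:
            return self.positivity_thresholds[channel]
        except KeyError:
            raise PanelError(f"no positivity threshold for channel {channel!r}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "cofactors": dict(self.cofactors),
            "positivity_thresholds": dict(self.positivity_thresholds),
            "lineage_role": dict(self.lineage_role),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(
            channels=list(d["channels"]),
            cofactors={k: float(v) for k, v in d["cofactors"].items()},
            positivity_thresholds={
                k: float(v) for k, v in d["positivity_thresholds"].items()
            },
            lineage_role=dict(d.get("lineage_role", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_panel(
    antibody_cofactor: float = DEFAULT_ANTIBODY_COFACTOR,
    scatter_cofactor: float = DEFAULT_SCATTER_COFACTOR,
    cofactor_overrides: dict[str, float] | None = None,
) -> MarkerPanel:
    """The default 23-channel panel (21 antibodies + FSC/SSC).

    Cofactors default to 1,000 for antibody channels and 10,000 for scatter;
    both are overridable per channel, covering the range typical of spectral
    cytometry panels tuned per marker.
    """
    channels = list(ANTIBODY_CHANNELS) + list(SCATTER_CHANNELS)
    cofactors = {c: antibody_cofactor for c in ANTIBODY_CHANNELS}
    cofactors.update({c: scatter_cofactor for c in SCATTER_CHANNELS})
    if cofactor_overrides:
        cofactors.update(cofactor_overrides)
    return MarkerPanel(
        channels=channels,
        cofactors=cofactors,
        positivity_thresholds=dict(_DEFAULT_THRESHOLDS),
        lineage_role=dict(_LINEAGE_ROLES),
    )
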