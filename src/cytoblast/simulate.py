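"""Synthetic bone-marrow cohorts with ground truth.

The generator emulates the monocytic arm of myelopoiesis as a continuous
pseudotime axis: every marker follows a monotone logistic response curve in
arcsinh space (rise or fall between a low and a high plateau), Gaussian noise
is added in arcsinh space (the variance-stabilised scale on which cytometry
noise is approximately homoscedastic), and raw intensities are recovered with
``cofactor * sinh(value)`` so the real preprocessing path is exercised
end-to-end.  Pseudotime is uniform on [0, 1]; the four developmental stages
(early HSPC, monoblast/myeloblast, promonocyte, monocyte) are defined by
cutpoints on that axis, and stage structure emerges from the plateaus of the
response curves rather than from discrete clusters.

Blast populations are healthy cells anchored at one developmental stage with
aberration shifts planted on top: CD56 gain, CD45 or CD33 loss, or an
asynchronous combination (CD117 overexpression with CD34 absence and CD4
gain) — the classic leukemia-associated immunophenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import CellMatrix, SampleMeta
from .panel import MarkerPanel, default_panel

STAGES = ("early HSPC", "monoblast/myeloblast", "promonocyte", "monocyte")


@dataclass(frozen=True)
class MarkerCurve:
    """Monotone logistic response in arcsinh space.

    ``value(t) = low + (high - low) * sigmoid((t - midpoint) / width)``;
    a falling marker simply has ``high < low``.
    """

    low: float
    high: float
    midpoint: float = 0.5
    width: float = 0.15

    def __call__(self, t: np.ndarray) -> np.ndarray:
        z = (np.asarray(t, dtype=np.float64) - self.midpoint) / self.width
        return self.low + (self.high - self.low) / (1.0 + np.exp(-z))


# Response curves of the default trajectory: start level -> end level along
# HSPC -> monocyte differentiation.  Levels are plausible arcsinh units.
_DEFAULT_CURVES: dict[str, MarkerCurve] = {
    "CD45": MarkerCurve(2.5, 4.0, 0.5, 0.15),
    "CD19": MarkerCurve(0.3, 0.3),
    "CD3": MarkerCurve(0.3, 0.3),
    "CD4": MarkerCurve(0.3, 1.8, 0.75, 0.08),     # monocytes are dim-positive
    "CD8": MarkerCurve(0.3, 0.3),
    "CD56": MarkerCurve(0.3, 0.3),
    "CD34": MarkerCurve(4.5, 0.4, 0.30, 0.08),    # progenitor marker, lost early
    "CD45RA": MarkerCurve(3.0, 1.0, 0.5, 0.12),
    "HLA-DR": MarkerCurve(3.8, 3.8),
    "CD117": MarkerCurve(3.5, 0.4, 0.35, 0.08),   # c-kit, lost after blast stage
    "CD38": MarkerCurve(2.0, 3.2, 0.4, 0.2),
    "CD33": MarkerCurve(1.5, 4.0, 0.30, 0.10),
    "CD35": MarkerCurve(0.5, 3.0, 0.70, 0.08),
    "CD13": MarkerCurve(1.0, 3.5, 0.40, 0.12),
    "CD123": MarkerCurve(1.2, 2.6, 0.5, 0.15),
    "CD64": MarkerCurve(0.5, 4.0, 0.60, 0.10),
    "CD11b": MarkerCurve(0.5, 4.0, 0.70, 0.08),
    "CD11c": MarkerCurve(0.5, 3.5, 0.65, 0.10),
    "CD14": MarkerCurve(0.3, 4.5, 0.80, 0.06),    # definitive monocyte marker
    "CD203c": MarkerCurve(0.3, 0.3),
    "CD71": MarkerCurve(1.0, 1.0),
    "FSC": MarkerCurve(1.8, 2.3, 0.5, 0.3),
    "SSC": MarkerCurve(1.5, 2.2, 0.5, 0.3),
}

DEFAULT_NOISE_SD = 0.35
SCATTER_NOISE_SD = 0.15


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TrajectoryModel:
    """Developmental trajectory over a marker panel.

    ``stage_cutpoints`` are three strictly increasing pseudotime boundaries
    splitting [0, 1] into the four stages of :data:`STAGES`.
    """

    panel: MarkerPanel
    curves: dict[str, MarkerCurve]
    noise_sd: dict[str, float]
    stage_cutpoints: tuple[float, float, float] = (0.25, 0.50, 0.75)

    def __post_init__(self) -> None:
        cuts = self.stage_cutpoints
        if not (0.0 < cuts[0] < cuts[1] < cuts[2] < 1.0):
            raise GeneratorConfigError("cutpoints must be strictly increasing in (0,1)")
        for name in self.panel.channels:
            if name not in self.curves:
                raise GeneratorConfigError(f"no response curve for channel {name!r}")
            sd = self.noise_sd.get(name, 0.0)
            if sd <= 0:
                raise GeneratorConfigError(f"noise_sd for {name!r} must be > 0")
            c = self.curves[name]
            for level in (c.low, c.high):
                if not (0.0 <= level <= 8.0):
                    raise GeneratorConfigError(
                        f"curve level {level} for {name!r} outside plausible arcsinh range [0, 8]"
                    )

    def stage_of(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.stage_cutpoints), t, side="right")
        return np.asarray(STAGES)[idx]

    def expression(self, t: np.ndarray) -> np.ndarray:
        """Noise-free arcsinh expression for pseudotimes ``t`` (n x channels)."""
        return np.column_stack([self.curves[c](t) for c in self.panel.channels])


def default_trajectory(panel: MarkerPanel | None = None,
                       noise_sd: float = DEFAULT_NOISE_SD) -> TrajectoryModel:
    panel = panel or default_panel()
    sds = {c: (SCATTER_NOISE_SD if panel.lineage_role.get(c) == "scatter" else noise_sd)
           for c in panel.channels}
    return TrajectoryModel(panel=panel, curves=dict(_DEFAULT_CURVES), noise_sd=sds)


@dataclass(frozen=True)
class Aberration:
    """One planted marker shift: mode gain/loss/asynchronous, arcsinh units."""

    marker: str
    mode: str  # gain | loss | asynchronous
    magnitude: float

    def shift(self) -> float:
        return self.magnitude if self.mode in ("gain", "asynchronous") else -self.magnitude


@dataclass(frozen=True)
class AberrationSpec:
    """A blast population's aberration profile.

    ``anchor_pseudotime`` is the developmental stage the blasts mimic;
    ``penetrance`` is the fraction of blasts carrying the shifts.
    """

    name: str
    aberrations: tuple[Aberration, ...]
    anchor_pseudotime: float = 0.30
    penetrance: float = 1.0
    anchor_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if not self.aberrations:
            raise GeneratorConfigError("at least one aberration per blast population")
        if not (0.0 < self.penetrance <= 1.0):
            raise GeneratorConfigError("penetrance must be in (0, 1]")
        if not (0.0 <= self.anchor_pseudotime <= 1.0):
            raise GeneratorConfigError("anchor_pseudotime must be in [0, 1]")


def default_aberration_catalog() -> tuple[AberrationSpec, ...]:
    """The default leukemia-associated immunophenotype catalog.

    One entry per classic aberrancy class: NK-marker gain (CD56), leukocyte
    or myeloid marker loss (CD45, CD33) and an asynchronous precursor pattern
    (CD117 overexpression without CD34 but with CD4).
    """
    return (
        AberrationSpec("CD56_gain", (Aberration("CD56", "gain", 3.0),)),
        AberrationSpec("CD45_loss", (Aberration("CD45", "loss", 2.5),)),
        AberrationSpec("CD33_loss", (Aberration("CD33", "loss", 2.8),)),
        AberrationSpec(
            "asynchronous_CD117_CD34_CD4",
            (
                Aberration("CD117", "asynchronous", 2.5),
                Aberration("CD34", "loss", 2.5),
                Aberration("CD4", "asynchronous", 2.0),
            ),
        ),
    )


def _to_raw(arcsinh_values: np.ndarray, panel: MarkerPanel) -> np.ndarray:
    cof = np.asarray(panel.cofactor_array())
    return cof * np.sinh(arcsinh_values)


def simulate_healthy(
    n_cells: int, model: TrajectoryModel, seed: int = 0
) -> tuple[CellMatrix, np.ndarray]:
    """Draw healthy cells along the trajectory; returns raw matrix + stages."""
    if n_cells < 1:
        raise GeneratorConfigError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_cells)
    expr = model.expression(t)
    sds = np.asarray([model.noise_sd[c] for c in model.panel.channels])
    expr = expr + rng.normal(0.0, 1.0, size=expr.shape) * sds
    m = CellMatrix(
        values=_to_raw(expr, model.panel),
        channels=list(model.panel.channels),
        state="raw",
    )
    return m, model.stage_of(t)


def simulate_blasts(
    n_cells: int, model: TrajectoryModel, ab: AberrationSpec, seed: int = 0
) -> tuple[CellMatrix, np.ndarray]:
    """Draw blasts anchored at one stage with planted aberrations.

    Returns the raw matrix and an all-True blast flag vector.
    """
    if n_cells < 1:
        raise GeneratorConfigError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.clip(
        ab.anchor_pseudotime + rng.normal(0.0, ab.anchor_jitter_sd, size=n_cells),
        0.0, 1.0,
    )
    expr = model.expression(t)
    sds = np.asarray([model.noise_sd[c] for c in model.panel.channels])
    expr = expr + rng.normal(0.0, 1.0, size=expr.shape) * sds
    affected = rng.uniform(size=n_cells) < ab.penetrance
    for a in ab.aberrations:
        j = model.panel.channels.index(a.marker)
        expr[affected, j] += a.shift()
    m = CellMatrix(
        values=_to_raw(expr, model.panel),
        channels=list(model.panel.channels),
        state="raw",
    )
    return m, np.ones(n_cells, dtype=bool)


@dataclass(frozen=True)
class RelapseShift:
    """Plant a minority diagnosis subclone that dominates relapse.

    A fraction ``subclone_frac`` of each diagnosis blast compartment is drawn
    from the relapse anchor phenotype; the relapse sample is drawn entirely
    from it.  Used to exercise the surviving-cell analysis.
    """

    subclone_frac: float = 0.05
    anchor_pseudotime: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 < self.subclone_frac < 1.0):
            raise GeneratorConfigError("subclone_frac must be in (0, 1)")


@dataclass
class SyntheticCohort:
    """Samples plus full ground truth and the generating configuration."""

    samples: list[tuple[CellMatrix, SampleMeta]]
    model: TrajectoryModel
    patient_aberrations: dict[str, AberrationSpec]
    seed: int
    config: dict = field(default_factory=dict)

    def by_timepoint(self, timepoint: str) -> list[tuple[CellMatrix, SampleMeta]]:
        return [(m, meta) for m, meta in self.samples if meta.timepoint == timepoint]


def simulate_cohort(
    n_patients: int = 10,
    blast_frac_dx: float = 0.5,
    blast_frac_rel: float = 0.5,
    relapse_shift: RelapseShift | None = None,
    remission_patients: int = 5,
    cells_per_sample: int = 10_000,
    model: TrajectoryModel | None = None,
    catalog: tuple[AberrationSpec, ...] | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate a longitudinal cohort with ground truth.

    Each of ``n_patients`` contributes a diagnosis and a relapse sample that
    mix healthy trajectory cells with planted blasts at the stated fractions
    (blast counts are exact by construction).  ``remission_patients``
    additional samples are healthy-only and serve as the reference class.
    Patients are individualised by cycling through the aberration catalog
    with per-patient anchor jitter.
    """
    if not (0.0 <= blast_frac_dx < 1.0 and 0.0 <= blast_frac_rel < 1.0):
        raise GeneratorConfigError("blast fractions must be in [0, 1)")
    if cells_per_sample < 2:
        raise GeneratorConfigError("cells_per_sample too small")
    model = model or default_trajectory()
    catalog = catalog or default_aberration_catalog()
    root = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    child_seeds = root.generate_state(4 * (n_patients + 1) * 4 + remission_patients)
    rng_assign = np.random.default_rng(child_seeds[0])

    samples: list[tuple[CellMatrix, SampleMeta]] = []
    patient_aberrations: dict[str, AberrationSpec] = {}
    s = 1

    for p in range(n_patients):
        pid = f"P{p + 1}"
        base = catalog[p % len(catalog)]
        # Individualise: jitter the anchor so patients are distinguishable.
        anchor = float(np.clip(base.anchor_pseudotime + rng_assign.normal(0, 0.05), 0.05, 0.95))
        ab = replace(base, anchor_pseudotime=anchor)
        patient_aberrations[pid] = ab

        for timepoint, frac in (("diagnosis", blast_frac_dx), ("relapse", blast_frac_rel)):
            n_blast = int(round(frac * cells_per_sample))
            n_healthy = cells_per_sample - n_blast
            parts, stages, flags, subclone = [], [], [], []
            if n_healthy:
                hm, hstage = simulate_healthy(n_healthy, model, seed=int(child_seeds[s]) & 0x7FFFFFFF)
                s += 1
                parts.append(hm.values)
                stages.append(hstage)
                flags.append(np.zeros(n_healthy, dtype=bool))
                subclone.append(np.zeros(n_healthy, dtype=bool))
            if n_blast:
                if relapse_shift is not None:
                    shifted = replace(ab, anchor_pseudotime=relapse_shift.anchor_pseudotime)
                    if timepoint == "relapse":
                        blast_specs = [(shifted, n_blast, True)]
                    else:
                        n_sub = max(1, int(round(relapse_shift.subclone_frac * n_blast)))
                        blast_specs = [(ab, n_blast - n_sub, False), (shifted, n_sub, True)]
                else:
                    blast_specs = [(ab, n_blast, False)]
                for spec_i, (bspec, n_b, is_sub) in enumerate(blast_specs):
                    if n_b == 0:
                        continue
                    bm, _ = simulate_blasts(n_b, model, bspec, seed=int(child_seeds[s]) & 0x7FFFFFFF)
                    s += 1
                    parts.append(bm.values)
                    stages.append(model.stage_of(np.full(n_b, bspec.anchor_pseudotime)))
                    flags.append(np.ones(n_b, dtype=bool))
                    subclone.append(np.full(n_b, is_sub))
            sid = f"{pid}_{timepoint}"
            matrix = CellMatrix(
                values=np.vstack(parts), channels=list(model.panel.channels),
                state="raw", sample_id=sid,
            )
            meta = SampleMeta(
                sample_id=sid, patient_id=pid, timepoint=timepoint,
                stage=np.concatenate(stages), is_blast=np.concatenate(flags),
                extra={"subclone": np.concatenate(subclone),
                       "aberration": ab.name},
            )
            samples.append((matrix, meta))

    for r in range(remission_patients):
        pid = f"R{r + 1}"
        sid = f"{pid}_remission"
        hm, hstage = simulate_healthy(cells_per_sample, model, seed=int(child_seeds[s]) & 0x7FFFFFFF)
        s += 1
        matrix = CellMatrix(values=hm.values, channels=list(model.panel.channels),
                            state="raw", sample_id=sid)
        meta = SampleMeta(
            sample_id=sid, patient_id=pid, timepoint="remission",
            stage=hstage, is_blast=np.zeros(cells_per_sample, dtype=bool),
        )
        samples.append((matrix, meta))

    config = {
        "n_patients": n_patients, "blast_frac_dx": blast_frac_dx,
        "blast_frac_rel": blast_frac_rel, "remission_patients": remission_patients,
        "cells_per_sample": cells_per_sample,
        "relapse_shift": None if relapse_shift is None else {
            "subclone_frac": relapse_shift.subclone_frac,
            "anchor_pseudotime": relapse_shift.anchor_pseudotime,
        },
    }
    return SyntheticCohort(samples=samples, model=model,
                           patient_aberrations=patient_aberrations,
                           seed=seed, config=config)
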