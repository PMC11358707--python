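"""Marker-positivity dynamics and the individuality score.

Positivity is evaluated on arcsinh-transformed, unscaled values against the
panel's marker-specific thresholds (strict ``>``).  Diagnosis-to-relapse
change accounting flags a marker as gained/lost for a patient when the
positive fraction moves by strictly more than ±delta (default 5 percentage
points).  The individuality score is an inverse-class-size-corrected
posterior over classes computed from each cell's k nearest neighbors,
measuring how self-contained the classes are in expression space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .matrix import CellMatrix
from .panel import MarkerPanel


def positive_fraction(
    m: CellMatrix, mask, panel: MarkerPanel, markers=None
) -> pd.Series:
    """Fraction of masked cells strictly above each marker's threshold."""
    m.require_state("arcsinh")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != m.n_cells:
        raise ValueError("mask does not align with cells")
    if not mask.any():
        raise ValueError("mask selects no cells")
    markers = list(markers) if markers is not None else list(m.channels)
    out = {}
    for mk in markers:
        out[mk] = float((m.column(mk)[mask] > panel.threshold(mk)).mean())
    return pd.Series(out, name="fraction_positive")


def positivity_table(
    samples: list[tuple[CellMatrix, np.ndarray, str]],
    panel: MarkerPanel,
    markers=None,
) -> pd.DataFrame:
    """Per-sample marker positivity over the masked cells.

    ``samples`` is a list of (arcsinh matrix, cell mask, sample_id); the
    mask typically selects predicted blasts.  Returns a samples x markers
    table plus an ``n_cells`` column.
    """
    rows = {}
    counts = {}
    for m, mask, sid in samples:
        rows[sid] = positive_fraction(m, mask, panel, markers=markers)
        counts[sid] = int(np.asarray(mask, dtype=bool).sum())
    table = pd.DataFrame(rows).T
    table["n_cells"] = pd.Series(counts)
    return table


@dataclass
class ChangeMatrix:
    """Diagnosis-to-relapse positivity deltas with gained/lost flags."""

    delta: pd.DataFrame    # patients x markers, relapse - diagnosis
    gained: pd.DataFrame   # boolean, delta > +threshold (strict)
    lost: pd.DataFrame     # boolean, delta < -threshold (strict)
    threshold: float

    def counts(self) -> pd.DataFrame:
        """Per-marker number of patients with a gain / loss."""
        return pd.DataFrame({
            "gained": self.gained.sum(axis=0).astype(int),
            "lost": self.lost.sum(axis=0).astype(int),
        })


def change_table(
    dx: pd.DataFrame, rel: pd.DataFrame, delta: float = 0.05
) -> ChangeMatrix:
    """Per-patient positivity change between matched diagnosis/relapse rows.

    Index values of ``dx`` and ``rel`` are patient identifiers; unmatched
    patients are excluded with a warning.  ``delta`` is strict: a change of
    exactly ±delta counts as neither gained nor lost.
    """
    dxv = dx.drop(columns=["n_cells"], errors="ignore")
    relv = rel.drop(columns=["n_cells"], errors="ignore")
    common = dxv.index.intersection(relv.index)
    unmatched = set(dxv.index).symmetric_difference(set(relv.index))
    if unmatched:
        warnings.warn(f"excluding unmatched patient(s): {sorted(map(str, unmatched))}")
    if len(common) == 0:
        raise ValueError("no matched patients")
    diff = relv.loc[common] - dxv.loc[common]
    return ChangeMatrix(delta=diff, gained=diff > delta, lost=diff < -delta,
                        threshold=delta)


@dataclass
class IndividualityResult:
    """kNN class posteriors per cell plus per-class means."""

    posterior: pd.DataFrame  # n_cells x C
    class_sizes: pd.Series
    k: int
    per_class_mean: pd.DataFrame  # own-class mean posterior per class


def individuality(
    m: CellMatrix, class_labels, k: int = 15, normalize: bool = True
) -> IndividualityResult:
    """Inverse-class-size-corrected kNN posterior per cell.

    For each cell the k nearest neighbors (Euclidean distance, excluding the
    cell itself) are counted per class; counts are weighted by the inverse
    class size and, under the default normalised form, rescaled so each
    cell's posterior sums to 1.  ``normalize=False`` instead divides every
    weighted count by the constant ``sum_j 1/n_class_j`` (a literal
    fixed-denominator variant whose rows do not sum to 1).
    """
    labels = np.asarray(class_labels)
    if labels.shape[0] != m.n_cells:
        raise ValueError("labels do not align with cells")
    classes, class_counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if k >= m.n_cells:
        raise ValueError("k must be smaller than the number of cells")
    small = classes[class_counts < k]
    if small.size:
        warnings.warn(f"class(es) smaller than k={k}: {list(map(str, small))}")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(m.values)
    _, idx = nn.kneighbors(m.values)
    neigh = idx[:, 1:]  # drop self

    sizes = pd.Series(class_counts, index=classes, dtype=float)
    counts = np.zeros((m.n_cells, len(classes)))
    lab_codes = np.searchsorted(classes, labels)
    for j in range(len(classes)):
        counts[:, j] = (lab_codes[neigh] == j).sum(axis=1)
    weighted = counts / sizes.to_numpy()
    if normalize:
        rowsum = weighted.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        post = weighted / rowsum
    else:
        post = weighted / (1.0 / sizes.to_numpy()).sum()
    posterior = pd.DataFrame(post, columns=classes)

    own = {c: float(posterior.loc[lab_codes == j, c].mean())
           for j, c in enumerate(classes)}
    per_class = pd.DataFrame({"mean_own_posterior": pd.Series(own)})
    return IndividualityResult(posterior=posterior, class_sizes=sizes.astype(int),
                               k=k, per_class_mean=per_class)
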