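"""Latent-space developmental mapping and the surviving-cell analysis.

The remission cells' latent encoding, labeled with their developmental
stage, forms a reference map of healthy myelopoiesis.  Query cells (e.g.
predicted blasts) are staged by majority vote among their k nearest
reference cells; per-sample stage composition vectors quantify the
developmental make-up, and single-Gaussian fits to diagnosis and relapse
encodings identify cells whose phenotype "survives" therapy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.neighbors import NearestNeighbors

from .simulate import STAGES


@dataclass
class ReferenceMap:
    """Latent coordinates of remission cells with their stage labels."""

    latent: np.ndarray
    stage_labels: np.ndarray

    def __post_init__(self) -> None:
        self.latent = np.asarray(self.latent, dtype=np.float64)
        self.stage_labels = np.asarray(self.stage_labels)
        if self.latent.shape[0] != len(self.stage_labels):
            raise ValueError("labels do not align with latent rows")


def knn_assign_stage(ref: ReferenceMap, query: np.ndarray, k: int = 5) -> np.ndarray:
    """Majority vote among each query's k nearest reference cells.

    Distances are Euclidean in latent space.  Ties break to the label with
    the smaller summed neighbor distance, then lexicographically — the
    assignment is fully deterministic.
    """
    query = np.asarray(query, dtype=np.float64)
    if query.ndim != 2 or query.shape[1] != ref.latent.shape[1]:
        raise ValueError("latent dimensionality mismatch")
    if k > ref.latent.shape[0]:
        raise ValueError(f"k={k} exceeds the {ref.latent.shape[0]} reference cells")
    if query.shape[0] == 0:
        return np.asarray([], dtype=ref.stage_labels.dtype)
    nn = NearestNeighbors(n_neighbors=k).fit(ref.latent)
    dist, idx = nn.kneighbors(query)
    out = []
    for d_row, i_row in zip(dist, idx):
        labs = ref.stage_labels[i_row]
        candidates = {}
        for lab, d in zip(labs, d_row):
            cnt, sd = candidates.get(lab, (0, 0.0))
            candidates[lab] = (cnt + 1, sd + float(d))
        # max count; ties -> min summed distance -> lexicographic label
        best = min(candidates.items(), key=lambda kv: (-kv[1][0], kv[1][1], str(kv[0])))
        out.append(best[0])
    return np.asarray(out, dtype=ref.stage_labels.dtype)


@dataclass
class CompositionVector:
    """Per-stage fractions; entries sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")

    def as_array(self, stage_order=None) -> np.ndarray:
        order = list(stage_order) if stage_order is not None else sorted(self.fractions)
        return np.asarray([self.fractions[s] for s in order])


def composition(labels, stages=STAGES) -> CompositionVector:
    """Fraction of cells per developmental stage."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    fracs = {s: float((labels == s).mean()) for s in stages}
    extra = set(np.unique(labels)) - set(stages)
    for s in extra:
        fracs[str(s)] = float((labels == s).mean())
    return CompositionVector(fractions=fracs)


def composition_distance(a: CompositionVector, b: CompositionVector) -> float:
    """Euclidean distance between two stage-fraction vectors."""
    if set(a.fractions) != set(b.fractions):
        raise ValueError("composition vectors cover different stage sets")
    order = sorted(a.fractions)
    return float(np.linalg.norm(a.as_array(order) - b.as_array(order)))


@dataclass
class FittedGaussian:
    """Maximum-likelihood mean and covariance in latent space."""

    mean: np.ndarray
    covariance: np.ndarray

    def log_density(self, X: np.ndarray) -> np.ndarray:
        return multivariate_normal.logpdf(
            np.asarray(X), mean=self.mean, cov=self.covariance,
            allow_singular=False,
        )


def fit_gaussian(latent: np.ndarray, reg: float = 1e-6) -> FittedGaussian:
    """ML Gaussian fit (a single-component GMM) with diagonal regularisation.

    ``reg`` is added to the covariance diagonal so small samples in few
    latent dimensions still yield an invertible covariance.
    """
    X = np.asarray(latent, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("latent must be 2-d")
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more cells ({n}) than latent dimensions ({d})")
    mean = X.mean(axis=0)
    centered = X - mean
    cov = centered.T @ centered / n  # ML (biased) estimator
    cov = (cov + cov.T) / 2.0 + reg * np.eye(d)
    return FittedGaussian(mean=mean, covariance=cov)


def label_surviving(
    diag_latent: np.ndarray, rel_latent: np.ndarray, diagonal: bool = False
) -> dict[str, np.ndarray]:
    """Flag diagnosis cells that look like relapse and vice versa.

    One Gaussian is fitted per timepoint; a diagnosis cell is flagged
    ``diagnosis_like_relapse`` iff its log-density under the relapse
    Gaussian strictly exceeds that under the diagnosis Gaussian (equal
    log-likelihood resolves to not flagged), and symmetrically for relapse
    cells.  ``diagonal`` constrains both covariances to their diagonals.
    """
    g_dx = fit_gaussian(diag_latent)
    g_rel = fit_gaussian(rel_latent)
    if diagonal:
        g_dx = FittedGaussian(g_dx.mean, np.diag(np.diag(g_dx.covariance)))
        g_rel = FittedGaussian(g_rel.mean, np.diag(np.diag(g_rel.covariance)))
    dx_flag = g_rel.log_density(diag_latent) > g_dx.log_density(diag_latent)
    rel_flag = g_dx.log_density(rel_latent) > g_rel.log_density(rel_latent)
    return {
        "diagnosis_like_relapse": np.asarray(dx_flag, dtype=bool),
        "relapse_like_diagnosis": np.asarray(rel_flag, dtype=bool),
        "diagnosis_gaussian": g_dx,
        "relapse_gaussian": g_rel,
    }
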