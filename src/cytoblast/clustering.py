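"""Clustering-stability selection and rule-based cluster annotation.

The clustering backend is pluggable (a callable ``backend(X, k, seed) ->
labels``): stability selection repeats it with different random
initialisations, scores every run by its average adjusted Rand index (ARI)
against its sibling repeats, and keeps the most reproducible run.  Cluster
profiles (per-channel medians in arcsinh space) are then matched against
cell-type signatures or flagged as blasts when any leukemia-associated
aberrancy criterion fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .matrix import CellMatrix
from .panel import MarkerPanel
from .simulate import STAGES


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions.

    1 for identical partitions (up to label permutation), ~0 for independent
    ones; computed from the pair-counting contingency table.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-d and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 elements")
    return float(adjusted_rand_score(a, b))


@dataclass
class Clustering:
    """A selected clustering run with its stability score."""

    labels: np.ndarray
    k_param: int
    repeat_index: int
    mean_pairwise_ari: float


def kmeans_backend(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Default clustering backend (k-means); swap in SOM/graph backends freely."""
    return KMeans(n_clusters=int(k), n_init=4, random_state=int(seed)).fit_predict(X)


def stability_select(
    m: CellMatrix,
    backend=kmeans_backend,
    k_values=(8,),
    n_repeats: int = 10,
    seed: int = 0,
    pooled: bool = False,
) -> Clustering:
    """Repeat clustering and keep the most stable run.

    For each ``k`` the backend is run ``n_repeats`` times with distinct
    seeds; each run is scored by its mean ARI against the sibling repeats of
    the same ``k`` (or against all runs of all ``k`` when ``pooled``).  The
    run with the highest mean is returned; ties break to the lowest ``k``,
    then the lowest repeat index.  Seeds are derived from ``(seed, k,
    repeat)`` so the result is invariant to the order of ``k_values``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 (no pairs to compare otherwise)")
    X = m.values
    runs: list[tuple[int, int, np.ndarray]] = []  # (k, repeat, labels)
    for k in k_values:
        for r in range(n_repeats):
            child = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(k), r])
            labels = np.asarray(backend(X, k, int(child.generate_state(1)[0] & 0x7FFFFFFF)))
            if labels.shape[0] != X.shape[0]:
                raise ValueError("backend returned wrong number of labels")
            runs.append((int(k), r, labels))

    best: Clustering | None = None
    for i, (k, r, labels) in enumerate(runs):
        if pooled:
            siblings = [lab for j, (_, _, lab) in enumerate(runs) if j != i]
        else:
            siblings = [lab for j, (kk, _, lab) in enumerate(runs) if kk == k and j != i]
        mean_ari = float(np.mean([adjusted_rand_index(labels, s) for s in siblings]))
        cand = Clustering(labels=labels, k_param=k, repeat_index=r,
                          mean_pairwise_ari=mean_ari)
        if (
            best is None
            or mean_ari > best.mean_pairwise_ari + 1e-15
            or (abs(mean_ari - best.mean_pairwise_ari) <= 1e-15
                and (k, r) < (best.k_param, best.repeat_index))
        ):
            best = cand
    assert best is not None
    return best


@dataclass
class ClusterProfile:
    cluster_id: int
    median_expression: dict[str, float]
    size: int


def profile_clusters(m: CellMatrix, labels) -> list[ClusterProfile]:
    """Per-cluster per-channel medians (arcsinh space), ordered by cluster id."""
    labels = np.asarray(labels)
    if labels.shape[0] != m.n_cells:
        raise ValueError("labels do not align with matrix rows")
    profiles = []
    for cid in np.unique(labels):
        rows = m.values[labels == cid]
        med = np.median(rows, axis=0)
        profiles.append(ClusterProfile(
            cluster_id=int(cid),
            median_expression=dict(zip(m.channels, med.tolist())),
            size=int(rows.shape[0]),
        ))
    return profiles


# --------------------------------------------------------------------------
# Rule-based annotation


@dataclass(frozen=True)
class Condition:
    """One predicate on a cluster's median: marker above/below a threshold."""

    marker: str
    op: str  # "above" | "below"
    threshold: float

    def holds(self, median: dict[str, float]) -> bool:
        v = median[self.marker]
        return v > self.threshold if self.op == "above" else v < self.threshold


@dataclass
class AnnotationRuleSet:
    """Cell-type signatures plus blast aberrancy criteria.

    ``signatures`` map a cell-type name to high/low expectations per marker
    (evaluated against the panel's positivity thresholds).  A cluster is a
    blast when *any* criterion (a conjunction of :class:`Condition`) is fully
    satisfied; otherwise it gets the best-matching signature, or ``debris``
    when every lineage marker is low.
    """

    signatures: dict[str, dict[str, str]]
    blast_criteria: dict[str, tuple[Condition, ...]]
    panel: MarkerPanel
    debris_markers: tuple[str, ...] = ("CD45", "CD34", "CD33", "CD64", "HLA-DR", "CD71")
    debris_threshold: float = 1.0

    def __post_init__(self) -> None:
        markers = set(self.panel.channels)
        for sig in self.signatures.values():
            unknown = set(sig) - markers
            if unknown:
                raise ValueError(f"signature references unknown markers {unknown}")
        for conds in self.blast_criteria.values():
            for c in conds:
                if c.marker not in markers:
                    raise ValueError(f"blast criterion references unknown marker {c.marker!r}")

    def to_dict(self) -> dict:
        return {
            "signatures": {k: dict(v) for k, v in self.signatures.items()},
            "blast_criteria": {
                name: [{"marker": c.marker, "op": c.op, "threshold": c.threshold}
                       for c in conds]
                for name, conds in self.blast_criteria.items()
            },
            "debris_markers": list(self.debris_markers),
            "debris_threshold": self.debris_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict, panel: MarkerPanel) -> "AnnotationRuleSet":
        return cls(
            signatures={k: dict(v) for k, v in d["signatures"].items()},
            blast_criteria={
                name: tuple(Condition(c["marker"], c["op"], float(c["threshold"]))
                            for c in conds)
                for name, conds in d["blast_criteria"].items()
            },
            panel=panel,
            debris_markers=tuple(d.get("debris_markers",
                                       ("CD45", "CD34", "CD33", "CD64", "HLA-DR", "CD71"))),
            debris_threshold=float(d.get("debris_threshold", 1.0)),
        )

    @classmethod
    def from_yaml(cls, path, panel: MarkerPanel) -> "AnnotationRuleSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), panel)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_rules(panel: MarkerPanel) -> AnnotationRuleSet:
    """Default myeloid signatures and the three aberrancy criteria.

    Criteria: (a) aberrant NK-marker CD56 expression, (b) abnormally low
    CD33 or CD45, (c) asynchronous precursor pattern — CD117 overexpressed
    without CD34 but with CD4.  Thresholds are arcsinh-space defaults tuned
    to the synthetic trajectory; override for real panels.
    """
    signatures = {
        "early HSPC": {"CD34": "high", "CD117": "high", "CD14": "low",
                       "CD11b": "low", "CD64": "low"},
        "monoblast/myeloblast": {"CD33": "high", "CD13": "high", "CD34": "low",
                                 "CD14": "low", "CD64": "low"},
        "promonocyte": {"CD64": "high", "CD33": "high", "CD14": "low", "CD34": "low"},
        "monocyte": {"CD14": "high", "CD64": "high", "CD11b": "high", "CD34": "low"},
    }
    blast_criteria = {
        "aberrant_CD56": (Condition("CD56", "above", panel.threshold("CD56")),),
        "low_CD33": (Condition("CD33", "below", 0.8),),
        "low_CD45": (Condition("CD45", "below", 1.5),),
        "asynchronous_CD117_CD34_CD4": (
            Condition("CD117", "above", 4.0),
            Condition("CD34", "below", 1.0),
            Condition("CD4", "above", 1.5),
        ),
    }
    return AnnotationRuleSet(signatures=signatures, blast_criteria=blast_criteria,
                             panel=panel)


def annotate_clusters(
    profiles: list[ClusterProfile], rules: AnnotationRuleSet
) -> dict[int, str]:
    """Label each cluster as a cell type, ``blast`` or ``debris``.

    A cluster matching any blast criterion is a blast; otherwise debris when
    all lineage markers are below the debris threshold; otherwise the
    signature with the highest fraction of satisfied expectations (ties
    break in canonical stage order).
    """
    if not profiles:
        raise ValueError("no cluster profiles to annotate")
    order = {s: i for i, s in enumerate(STAGES)}
    out: dict[int, str] = {}
    for p in profiles:
        med = p.median_expression
        # debris first: a cluster low in every lineage marker is not a cell
        # population, so the aberrancy criteria (e.g. low CD45) do not apply
        if all(med[mk] < rules.debris_threshold for mk in rules.debris_markers):
            out[p.cluster_id] = "debris"
            continue
        if any(all(c.holds(med) for c in conds)
               for conds in rules.blast_criteria.values()):
            out[p.cluster_id] = "blast"
            continue
        best_name, best_score = None, -1.0
        for name, sig in rules.signatures.items():
            hits = 0
            for marker, expect in sig.items():
                thr = rules.panel.threshold(marker)
                ok = med[marker] > thr if expect == "high" else med[marker] <= thr
                hits += ok
            score = hits / len(sig)
            better = score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12
                and order.get(name, 99) < order.get(best_name, 99)
            )
            if better:
                best_name, best_score = name, score
        out[p.cluster_id] = best_name
    return out
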