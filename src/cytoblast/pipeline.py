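"""End-to-end orchestration: cohort -> autoencoder -> classifier -> staging.

Mirrors the full workflow: remission cells are split into an autoencoder
training pool and a held-out remission-test pool; the autoencoder is trained
on the former, SRE features are computed for the latter and for all
annotated non-remission cells; a balanced leave-one-patient-out classifier
is selected and retrained; predictions are evaluated on annotated cells that
never entered classifier training; and the latent reference map assigns
developmental stages.

Default problem sizes are desk-scale (tens of thousands of cells, a
classifier pool of a few thousand per class) — large enough for stable
estimates on the synthetic cohorts, small enough to run on one CPU in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify
from .autoencoder import AEConfig, TrainedAutoencoder, encode, sre, train_autoencoder
from .classify import (
    BLAST, HEALTHY, FittedClassifier, LabeledSRESet, build_lopo_splits,
    cd45low_gate, evaluate_predictions, predict_blasts, train_select_classifier,
)
from .latent import ReferenceMap, composition, knn_assign_stage, label_surviving
from .matrix import CellMatrix, SampleMeta, concat
from .preprocess import apply_minmax, arcsinh_transform, fit_minmax
from .simulate import SyntheticCohort

DEFAULT_AE_CONFIG = AEConfig(layer_widths=(23, 16, 8), latent_dim=4,
                             activation="relu", learning_rate=1e-3,
                             epochs=30, batch_size=256)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    autoencoder: TrainedAutoencoder
    classifier: FittedClassifier
    reference: ReferenceMap
    sre_metrics: dict
    gate_metrics: dict
    stage_recovery: float
    blast_compositions: dict
    nonremission_truth: np.ndarray
    nonremission_pred: np.ndarray
    holdout_mask: np.ndarray
    extras: dict = field(default_factory=dict)


def _split_remission(remission: CellMatrix, stages: np.ndarray, seed: int,
                     test_frac: float = 0.5):
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    n = remission.n_cells
    perm = rng.permutation(n)
    n_test = int(round(test_frac * n))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    return train_idx, test_idx


def run_blast_pipeline(
    cohort: SyntheticCohort,
    seed: int = 0,
    ae_config: AEConfig | None = None,
    ae_train_cap: int = 20_000,
    classifier_pool: int = 6_000,
    n_trials: int = 6,
    model_space: list | None = None,
    knn_k: int = 5,
) -> PipelineResult:
    """Run the full blast-identification workflow on a synthetic cohort.

    ``classifier_pool`` caps the remission-test cells entering the
    classifier (per class, before the 19/20 : 1/20 fold split);
    ``model_space`` defaults to the fast families (logistic regression and
    random forest) — pass :func:`cytoblast.classify._default_model_space`
    for the full set including SVM and MLP.
    """
    panel = cohort.model.panel
    ae_config = ae_config or DEFAULT_AE_CONFIG

    # --- reference (remission) pool --------------------------------------
    rem = cohort.by_timepoint("remission")
    if not rem:
        raise ValueError("cohort has no remission samples")
    rem_matrix = concat([m for m, _ in rem])
    rem_stages = np.concatenate([meta.stage for _, meta in rem])
    rem_arc = arcsinh_transform(rem_matrix, panel)

    train_idx, test_idx = _split_remission(rem_arc, rem_stages, seed)
    ae_train_arc = rem_arc.subset(train_idx)
    if ae_train_arc.n_cells > ae_train_cap:
        sub = np.random.default_rng(seed).choice(
            ae_train_arc.n_cells, size=ae_train_cap, replace=False)
        ae_train_arc = ae_train_arc.subset(sub)
    scaler = fit_minmax(ae_train_arc)
    ae_train = apply_minmax(scaler, ae_train_arc)

    cfg = AEConfig(**{**ae_config.__dict__, "seed": seed,
                      "layer_widths": (panel.n_channels,) + tuple(ae_config.layer_widths[1:])})
    model = train_autoencoder(ae_train, cfg, scaler=scaler)

    rem_test_arc = rem_arc.subset(test_idx)
    rem_test = apply_minmax(scaler, rem_test_arc)
    rem_test_stages = rem_stages[test_idx]

    # --- SRE features for classifier training -----------------------------
    if classifier_pool and rem_test.n_cells > classifier_pool:
        pool_idx = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, 13])
        ).choice(rem_test.n_cells, size=classifier_pool, replace=False)
    else:
        pool_idx = np.arange(rem_test.n_cells)
    rem_pool = rem_test.subset(pool_idx)
    rem_pool_sre = sre(model, rem_pool)

    nonrem = [s for s in cohort.samples if s[1].timepoint != "remission"]
    nonrem_arc = [arcsinh_transform(m, panel) for m, _ in nonrem]
    nonrem_scaled = [apply_minmax(scaler, a) for a in nonrem_arc]
    nonrem_sre = [sre(model, s) for s in nonrem_scaled]

    blast_vals, blast_pids, blast_global = [], [], []
    offset = 0
    for (m, meta), sr in zip(nonrem, nonrem_sre):
        mask = meta.is_blast
        blast_vals.append(sr.values[mask])
        blast_pids.extend([meta.patient_id] * int(mask.sum()))
        blast_global.append(offset + np.flatnonzero(mask))
        offset += m.n_cells
    n_nonrem = offset
    blast_vals = np.vstack(blast_vals)
    blast_global = np.concatenate(blast_global)

    labeled = LabeledSRESet(
        sre=classify.SREMatrix(
            values=np.vstack([rem_pool_sre.values, blast_vals]),
            channels=list(panel.channels),
        ),
        labels=np.asarray([HEALTHY] * rem_pool.n_cells + [BLAST] * len(blast_pids)),
        patient_ids=np.asarray(
            ["remission"] * rem_pool.n_cells + blast_pids),
        origin=np.asarray(
            ["remission_test"] * rem_pool.n_cells
            + ["annotated_nonremission"] * len(blast_pids)),
    )
    plan = build_lopo_splits(labeled, seed=seed)
    clf = train_select_classifier(plan, labeled, model_space=model_space,
                                  n_trials=n_trials, seed=seed)

    # --- evaluation on annotated cells never used in training -------------
    used_blast_rows = clf.retrain_indices[clf.retrain_indices >= rem_pool.n_cells]
    used_global = set(blast_global[used_blast_rows - rem_pool.n_cells].tolist())
    holdout = np.ones(n_nonrem, dtype=bool)
    if used_global:
        holdout[np.fromiter(used_global, dtype=int)] = False

    all_sre = classify.SREMatrix(
        values=np.vstack([sr.values for sr in nonrem_sre]),
        channels=list(panel.channels))
    pred = predict_blasts(clf, all_sre)
    truth = np.where(np.concatenate([meta.is_blast for _, meta in nonrem]),
                     BLAST, HEALTHY)
    sre_metrics = evaluate_predictions(pred.labels[holdout], truth[holdout])

    gate_all = np.concatenate([
        cd45low_gate(a, panel.threshold("CD45")) for a in nonrem_arc])
    gate_metrics = evaluate_predictions(gate_all[holdout], truth[holdout])

    # --- latent reference map and staging ---------------------------------
    reference = ReferenceMap(latent=encode(model, rem_test),
                             stage_labels=rem_test_stages)
    healthy_nonrem = ~np.concatenate([meta.is_blast for _, meta in nonrem])
    all_scaled_vals = np.vstack([s.values for s in nonrem_scaled])
    healthy_latent = model.encode_values(all_scaled_vals[healthy_nonrem])
    healthy_truth = np.concatenate([meta.stage for _, meta in nonrem])[healthy_nonrem]
    healthy_assigned = knn_assign_stage(reference, healthy_latent, k=knn_k)
    stage_recovery = float((healthy_assigned == healthy_truth).mean())

    blast_compositions = {}
    offset = 0
    for (m, meta), s_scaled in zip(nonrem, nonrem_scaled):
        sel = pred.blast_mask[offset:offset + m.n_cells]
        offset += m.n_cells
        if sel.sum() == 0:
            continue
        latent = model.encode_values(s_scaled.values[sel])
        stages = knn_assign_stage(reference, latent, k=knn_k)
        blast_compositions[meta.sample_id] = composition(stages)

    return PipelineResult(
        autoencoder=model, classifier=clf, reference=reference,
        sre_metrics=sre_metrics, gate_metrics=gate_metrics,
        stage_recovery=stage_recovery, blast_compositions=blast_compositions,
        nonremission_truth=truth, nonremission_pred=pred.labels,
        holdout_mask=holdout,
        extras={"scaler": scaler, "plan": plan},
    )


def surviving_analysis(
    model: TrainedAutoencoder, cohort: SyntheticCohort, patient_id: str
) -> dict:
    """Diagnosis/relapse Gaussian comparison for one patient's blasts.

    Encodes the patient's ground-truth blasts at both timepoints, runs the
    surviving-cell labeling, and reports the flagged fraction within the
    planted relapse-like subclone and within the majority diagnosis
    population (when subclone ground truth is present).
    """
    panel = cohort.model.panel
    if model.scaler is None:
        raise ValueError("autoencoder carries no scaler")

    def blasts_of(timepoint: str) -> tuple[np.ndarray, SampleMeta]:
        for m, meta in cohort.samples:
            if meta.patient_id == patient_id and meta.timepoint == timepoint:
                scaled = apply_minmax(model.scaler, arcsinh_transform(m, panel))
                return scaled.values[meta.is_blast], meta
        raise KeyError(f"no {timepoint} sample for patient {patient_id!r}")

    dx_vals, dx_meta = blasts_of("diagnosis")
    rel_vals, _ = blasts_of("relapse")
    dx_latent = model.encode_values(dx_vals)
    rel_latent = model.encode_values(rel_vals)
    out = label_surviving(dx_latent, rel_latent)

    result = {
        "flags": out,
        "diagnosis_flagged_fraction": float(out["diagnosis_like_relapse"].mean()),
        "relapse_flagged_fraction": float(out["relapse_like_diagnosis"].mean()),
    }
    if "subclone" in dx_meta.extra:
        sub = np.asarray(dx_meta.extra["subclone"])[dx_meta.is_blast]
        flags = out["diagnosis_like_relapse"]
        if sub.any():
            result["subclone_flagged_fraction"] = float(flags[sub].mean())
        result["majority_flagged_fraction"] = float(flags[~sub].mean())
    return result
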