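"""End-to-end phantom experiments.

These functions reproduce, at phantom scale, the study designs the toolkit
is built for: a balanced detection task (20% breast-level malignancy) with
heat-map explainability scoring, an imbalanced screening task (~1.85%
prevalence after known-cancer exclusion) comparing the anomaly detector with
a conventional classifier at fixed-sensitivity operating points, and the
random-classifier AUPR/AUC baselines at given class counts.

Problem sizes default to a desk scale that trains in minutes on one CPU:
64x64 phantoms, a light backbone (8/16/32/32 channels), and around ten
epochs. All randomness derives from one experiment seed via named child
seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detector import BackboneConfig, TrainConfig, train
from .explain import pixelwise_auc, upsample_heatmap
from .io import child_seed
from .phantom import PhantomConfig, generate_cohort
from .screen_eval import (fixed_sensitivity_point, grouped_kfold, roc_auc,
                          wilcoxon_compare)

DEMO_BACKBONE = dict(channels=(8, 16, 32, 32), strides=(1, 2, 1, 2))


def demo_backbone(seed: int = 0) -> BackboneConfig:
    """Light backbone for CPU-scale experiments (stride 4, receptive field 13)."""
    return BackboneConfig(seed=seed, **DEMO_BACKBONE)


def demo_train_config(seed: int = 0, epochs: int = 10, lr: float = 1e-2) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=32, lr=lr, momentum=0.9,
                       weight_decay=1e-4, cosine_decay=True, seed=seed)


def _cohort_arrays(config: PhantomConfig):
    """Generate a cohort in memory; canonical-orientation arrays by image_id."""
    manifest, images = generate_cohort(config)
    data = {img.image_id: img for img in images}
    contra = {}
    for img in images:
        other = "right" if img.laterality == "left" else "left"
        contra[img.image_id] = f"{img.exam_id}_{other}"
    return manifest, data, contra


def _stack(ids, data, contra_map=None):
    x = np.stack([data[i].canonical_pixels() for i in ids])
    y = np.array([data[i].label for i in ids], dtype=float)
    xc = None
    if contra_map is not None:
        xc = np.stack([data[contra_map[i]].canonical_pixels() for i in ids])
    return x, y, xc


def run_balanced_phantom_experiment(seed: int, n_patients: int = 200,
                                    image_size: int = 64, epochs: int = 30,
                                    lr: float = 0.05,
                                    objective: str = "fcdd") -> dict:
    """Train one detector on a 20%-prevalence phantom cohort (one grouped
    fold held out) and measure test AUC plus mean pixelwise AUC of the
    upsampled heat maps on malignant test images."""
    cfg = PhantomConfig(image_height=image_size, image_width=image_size,
                        n_patients=n_patients, prevalence=0.20,
                        seed=child_seed(seed, "phantom", "balanced"))
    manifest, data, contra = _cohort_arrays(cfg)
    split = grouped_kfold(manifest, k=5, seed=child_seed(seed, "cv", "balanced"),
                          task="balanced")[0]
    needs_contra = objective == "fcdd-sym"
    xtr, ytr, xtr_c = _stack(split.train_ids, data, contra if needs_contra else None)
    xte, yte, xte_c = _stack(split.test_ids, data, contra if needs_contra else None)

    det = train(objective, xtr, ytr,
                backbone_config=demo_backbone(child_seed(seed, "init", objective)),
                train_config=demo_train_config(child_seed(seed, "train", objective),
                                               epochs=epochs, lr=lr),
                contralateral=xtr_c)
    scores = det.score(xte, contralateral=xte_c)
    auc = roc_auc(scores, yte)

    r, s = det.config.receptive_field, det.config.total_stride
    pix_aucs = []
    for i, iid in enumerate(split.test_ids):
        img = data[iid]
        if img.label != 1:
            continue
        low = det.anomaly_map(img.canonical_pixels(),
                              contralateral=data[contra[iid]].canonical_pixels()
                              if needs_contra else None)
        full = upsample_heatmap(low, r, s, out_shape=img.pixels.shape, source=objective)
        pix_aucs.append(pixelwise_auc(full, img.canonical_mask()))
    pix_aucs = [a for a in pix_aucs if np.isfinite(a)]
    score_table = pd.DataFrame({
        "image_id": split.test_ids,
        "score": scores,
        "label": yte.astype(int),
        "bpe": [data[i].bpe for i in split.test_ids],
        "lesion_type": [data[i].lesion_type for i in split.test_ids],
        "stage_proxy": [data[i].stage_proxy for i in split.test_ids],
        "fold": split.fold, "seed": 0, "model": objective, "task": "balanced",
    })
    return {
        "objective": objective,
        "auc": float(auc),
        "pixelwise_auc_mean": float(np.mean(pix_aucs)),
        "n_test": len(split.test_ids),
        "n_malignant_test": len(pix_aucs),
        "final_train_loss": det.loss_log[-1],
        "scores": score_table,
    }


def run_imbalanced_comparison(seed: int, n_train_patients: int = 100,
                              n_test_patients: int = 700, image_size: int = 48,
                              epochs: int = 12, n_seeds: int = 8,
                              models: tuple = ("fcdd", "bce")) -> dict:
    """Screening-prevalence comparison of detectors at 97% sensitivity.

    A training cohort (balanced composition, known cancers included — the
    supplementation that helps the imbalanced task) and a disjoint test
    cohort are generated; test images from known-cancer exams are excluded,
    leaving ~1.85% prevalence. Each model is trained with ``n_seeds``
    initializations and specificity at 97% sensitivity is compared pairwise
    per seed with the Wilcoxon signed-rank test.
    """
    train_cfg = PhantomConfig(image_height=image_size, image_width=image_size,
                              n_patients=n_train_patients, prevalence=0.20,
                              seed=child_seed(seed, "phantom", "imb-train"))
    test_cfg = PhantomConfig(image_height=image_size, image_width=image_size,
                             n_patients=n_test_patients, prevalence=0.20,
                             seed=child_seed(seed, "phantom", "imb-test"))
    tr_manifest, tr_data, _ = _cohort_arrays(train_cfg)
    te_manifest, te_data, _ = _cohort_arrays(test_cfg)

    tr_ids = (tr_manifest["exam_id"] + "_" + tr_manifest["laterality"]).tolist()
    keep = ~te_manifest["known_cancer"].astype(bool)
    te_ids = (te_manifest.loc[keep, "exam_id"] + "_" +
              te_manifest.loc[keep, "laterality"]).tolist()
    xtr, ytr, _ = _stack(tr_ids, tr_data)
    xte, yte, _ = _stack(te_ids, te_data)

    spec97 = {m: [] for m in models}
    aucs = {m: [] for m in models}
    for s_idx in range(n_seeds):
        for m in models:
            det = train(m, xtr, ytr,
                        backbone_config=demo_backbone(child_seed(seed, "init", m, s_idx)),
                        train_config=demo_train_config(
                            child_seed(seed, "train", m, s_idx), epochs=epochs))
            scores = det.score(xte)
            spec97[m].append(fixed_sensitivity_point(scores, yte, 0.97).specificity)
            aucs[m].append(roc_auc(scores, yte))

    out = {
        "test_prevalence": float(np.mean(yte)),
        "n_test": len(yte),
        "n_test_positive": int(yte.sum()),
        "n_seeds": n_seeds,
        "spec_at_97sens": {m: [float(v) for v in spec97[m]] for m in models},
        "auc": {m: [float(v) for v in aucs[m]] for m in models},
    }
    if len(models) >= 2:
        a, b = models[0], models[1]
        out["spec97_mean"] = {m: float(np.mean(spec97[m])) for m in models}
        if n_seeds >= 5:
            out["wilcoxon_p_spec97"] = wilcoxon_compare(spec97[a], spec97[b])
    return out


def random_classifier_baselines(seed: int, class_counts: dict[str, tuple[int, int]],
                                n_reps: int = 200) -> dict:
    """Mean AUPR and AUC of uniform-random scores at fixed class counts.

    The expectation of average precision under random scoring equals the
    positive-class prevalence (up to small-sample bias), and the AUC
    expectation is 0.5; this verifies both by simulation.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    rng = np.random.default_rng(child_seed(seed, "baselines"))
    out = {}
    for name, (n_pos, n_total) in class_counts.items():
        y = np.zeros(n_total, dtype=int)
        y[:n_pos] = 1
        auprs = np.empty(n_reps)
        aucs = np.empty(n_reps)
        for rep in range(n_reps):
            s = rng.random(n_total)
            auprs[rep] = average_precision_score(y, s)
            aucs[rep] = roc_auc_score(y, s)
        out[name] = {"prevalence": n_pos / n_total,
                     "mean_aupr": float(auprs.mean()),
                     "mean_auc": float(aucs.mean()),
                     "n_reps": n_reps}
    return out


PRINTED_CLASS_COUNTS = {
    "development_task1": (3399, 17029),
    "development_task2": (221, 11934),
    "internal_test_task1": (81, 342),
    "internal_test_task2": (31, 246),
}
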