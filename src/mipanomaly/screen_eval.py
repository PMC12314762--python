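"""Screening evaluation protocol: grouped CV, metrics, operating points.

Implements the evaluation a screening study needs when the unit of analysis
is the unilateral breast but patients contribute several exams: patient-
grouped k-fold cross-validation repeated over training seeds, threshold-free
metrics (ROC AUC; AUPR as average precision, whose random baseline equals
the positive-class prevalence), three operating points (Youden-optimal, and
minimum-threshold points achieving 95% / 97% sensitivity), paired Wilcoxon
signed-rank comparisons over (fold, seed) cells, percentile bootstrap CIs,
and stratified breakdowns (BPE, lesion type, stage proxy).

Two task constructions are supported: "balanced" uses every image;
"imbalanced" removes known-cancer images from test folds (they remain
available for training supplementation), approximating true screening
prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

TASKS = ("balanced", "imbalanced")


# ---------------------------------------------------------------------------
# fold construction


@dataclass
class FoldSplit:
    fold: int
    seed: int
    task: str
    train_ids: list[str]
    test_ids: list[str]


def _image_ids(manifest: pd.DataFrame) -> pd.Series:
    return manifest["exam_id"].astype(str) + "_" + manifest["laterality"].astype(str)


def grouped_kfold(manifest: pd.DataFrame, k: int, seed: int,
                  task: str = "balanced") -> list[FoldSplit]:
    """Patient-grouped k-fold splits.

    Patients are shuffled (seeded) and partitioned into k near-equal groups;
    an image is tested in exactly one fold and trained in the others, so
    train/test patient sets are always disjoint. For the imbalanced task,
    known-cancer images are dropped from every test fold but kept in the
    training folds.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    patients = manifest["patient_id"].astype(str).unique()
    if k > len(patients):
        raise ValueError(f"k={k} exceeds number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    groups = np.array_split(patients[order], k)

    ids = _image_ids(manifest)
    known = manifest["known_cancer"].astype(bool).to_numpy()
    pid = manifest["patient_id"].astype(str).to_numpy()
    splits = []
    for f, test_patients in enumerate(groups):
        in_test = np.isin(pid, test_patients)
        test_mask = in_test & ~known if task == "imbalanced" else in_test
        splits.append(FoldSplit(
            fold=f, seed=seed, task=task,
            train_ids=ids[~in_test].tolist(),
            test_ids=ids[test_mask].tolist()))
    return splits


# ---------------------------------------------------------------------------
# threshold-free metrics


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC AUC with tie correction."""
    y = _check_two_class(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve, average-precision convention."""
    y = _check_two_class(labels)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def prevalence_percent(n_positive: int, n_total: int, sig: int = 3) -> float:
    """Prevalence as a percentage rounded to ``sig`` significant figures,
    matching how screening-cohort tables print it (e.g. 221/11934 -> 1.85)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    pct = 100.0 * n_positive / n_total
    if pct == 0.0:
        return 0.0
    return float(round(pct, sig - 1 - int(math.floor(math.log10(abs(pct))))))


# ---------------------------------------------------------------------------
# operating points


@dataclass
class OperatingPoint:
    criterion: str
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    tp: int
    fp: int
    tn: int
    fn: int


def _point_at(scores: np.ndarray, y: np.ndarray, thr: float, criterion: str) -> OperatingPoint:
    pred = scores >= thr
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return OperatingPoint(criterion, float(thr), sens, spec, ppv, tp, fp, tn, fn)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    # one threshold per distinct score (predict positive at >= t), plus one
    # above the maximum for the all-negative rule
    return np.concatenate([uniq, [uniq[-1] + 1.0]])


def youden_point(scores, labels) -> OperatingPoint:
    """Operating point maximizing J = sensitivity + specificity - 1.

    All distinct-score thresholds are swept; ties in J are broken toward
    higher specificity (the screening-friendly choice), so a degenerate
    constant score yields the all-negative rule (sens 0, spec 1).
    """
    s = np.asarray(scores, dtype=float)
    y = _check_two_class(labels)
    best = None
    for thr in _candidate_thresholds(s):
        pt = _point_at(s, y, thr, "youden")
        j = pt.sensitivity + pt.specificity - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12
                                                   and pt.specificity > best[1].specificity):
            best = (j, pt)
    return best[1]


def fixed_sensitivity_point(scores, labels, target: float = 0.95) -> OperatingPoint:
    """Largest threshold whose empirical sensitivity meets the target.

    The constraint is sensitivity >= target (not nearest), as in
    "specificity at 95%/97% sensitivity" reporting; a threshold below all
    scores always satisfies it, so the point always exists.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError("target sensitivity must be in (0, 1]")
    s = np.asarray(scores, dtype=float)
    y = _check_two_class(labels)
    for thr in _candidate_thresholds(s)[::-1]:
        pt = _point_at(s, y, thr, f"sens{int(round(target * 100))}")
        if pt.sensitivity >= target - 1e-12:
            return pt
    raise AssertionError("unreachable: minimum threshold has sensitivity 1")


# ---------------------------------------------------------------------------
# paired tests and bootstrap


def wilcoxon_compare(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired metric values.

    Zero differences are dropped (Wilcoxon convention); if every pair is
    tied, p = 1.0 by definition here. Exact distribution for n <= 25
    (tie-free), normal approximation with tie correction otherwise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "approx" if (d.size > 25 or has_ties) else "exact"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         correction=False, method=method)
    return float(res.pvalue)


def bootstrap_ci(scores, labels, metric_fn, n_boot: int = 1000, seed: int = 0,
                 unit: str = "breast", groups=None,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for a score-based metric.

    ``unit="breast"`` resamples images; ``unit="patient"`` resamples whole
    patients (``groups`` gives each image's patient). Single-class resamples
    are redrawn; if more than half of the draws fail, the metric is judged
    unstable and an error is raised.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_two_class(labels)
    if unit not in ("breast", "patient"):
        raise ValueError("unit must be 'breast' or 'patient'")
    if unit == "patient":
        if groups is None:
            raise ValueError("patient-level bootstrap needs groups")
        groups = np.asarray(groups)
        uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    vals, failures = [], 0
    while len(vals) < n_boot:
        if failures > n_boot * 0.5 + 10:
            raise RuntimeError("metric undefined on >50% of bootstrap resamples")
        if unit == "breast":
            idx = rng.integers(0, len(s), len(s))
        else:
            chosen = uniq[rng.integers(0, len(uniq), len(uniq))]
            idx = np.concatenate([np.flatnonzero(groups == g) for g in chosen])
        yb = y[idx]
        if yb.min() == yb.max():
            failures += 1
            continue
        vals.append(metric_fn(s[idx], yb))
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# run-level summaries (MetricsReport)


def evaluate_scores(scores, labels) -> dict:
    """All per-run detection metrics for one (model, task, fold, seed) cell."""
    out = {"auc": roc_auc(scores, labels), "aupr": aupr(scores, labels),
           "n": int(len(labels)), "prevalence": float(np.mean(labels))}
    yp = youden_point(scores, labels)
    out.update(youden_threshold=yp.threshold, youden_sensitivity=yp.sensitivity,
               youden_specificity=yp.specificity, youden_ppv=yp.ppv)
    for target in (0.95, 0.97):
        pt = fixed_sensitivity_point(scores, labels, target)
        key = f"spec_at_{int(target * 100)}sens"
        out[key] = pt.specificity
        out[f"ppv_at_{int(target * 100)}sens"] = pt.ppv
    return out


SCORE_COLUMNS = ["image_id", "score", "label", "fold", "seed", "model", "task"]

_METRIC_KEYS = ["auc", "aupr", "youden_ppv", "youden_specificity",
                "youden_sensitivity", "spec_at_95sens", "spec_at_97sens"]


def summarize_runs(score_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(model, task, fold, seed) metric table from a long score table."""
    missing = [c for c in SCORE_COLUMNS if c not in score_table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    rows = []
    for (model, task, fold, seed), g in score_table.groupby(
            ["model", "task", "fold", "seed"], sort=True):
        m = evaluate_scores(g["score"].to_numpy(), g["label"].to_numpy())
        rows.append({"model": model, "task": task, "fold": fold, "seed": seed, **m})
    return pd.DataFrame(rows)


def aggregate_metrics(run_metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD over the fold x seed cells, with random baselines attached
    (AUC 0.5; AUPR = test prevalence)."""
    rows = []
    for (model, task), g in run_metrics.groupby(["model", "task"], sort=True):
        row = {"model": model, "task": task, "n_cells": len(g),
               "baseline_auc": 0.5, "baseline_aupr": float(g["prevalence"].mean())}
        for key in _METRIC_KEYS:
            row[f"{key}_mean"] = float(g[key].mean())
            row[f"{key}_sd"] = float(g[key].std(ddof=1)) if len(g) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(run_metrics: pd.DataFrame, metric: str, model_a: str, model_b: str,
                   task: str) -> float:
    """Paired Wilcoxon p between two models on matched (fold, seed) cells."""
    sub = run_metrics[run_metrics["task"] == task]
    a = sub[sub["model"] == model_a].set_index(["fold", "seed"])[metric]
    b = sub[sub["model"] == model_b].set_index(["fold", "seed"])[metric]
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1, join="inner")
    return wilcoxon_compare(joined["a"].to_numpy(), joined["b"].to_numpy())


def stratified_report(score_table: pd.DataFrame, manifest: pd.DataFrame,
                      strata_keys: list[str], min_n: int = 10) -> pd.DataFrame:
    """Per-stratum AUC/AUPR with counts; small strata flagged, never dropped.

    Strata with a single outcome class report NaN metrics and are flagged.
    """
    for key in strata_keys:
        if key not in manifest.columns:
            raise KeyError(f"unknown stratum key {key!r}")
    man = manifest.copy()
    man["image_id"] = _image_ids(man)
    merged = score_table.merge(man[["image_id"] + strata_keys], on="image_id", how="left")
    rows = []
    for key in strata_keys:
        for val, g in merged.groupby(key, sort=True):
            y = g["label"].to_numpy()
            degenerate = y.min() == y.max() if len(y) else True
            rows.append({
                "stratum_key": key, "stratum": val, "n": len(g),
                "n_positive": int(y.sum()),
                "auc": roc_auc(g["score"], y) if not degenerate else float("nan"),
                "aupr": aupr(g["score"], y) if not degenerate else float("nan"),
                "flagged": bool(len(g) < min_n or degenerate),
            })
    return pd.DataFrame(rows)


def report_markdown(aggregate: pd.DataFrame) -> str:
    """Render the aggregate table as a Markdown report (means +/- SDs)."""
    lines = ["| Task | Model | AUC | AUPR | PPV (Youden) | Spec (Youden) | "
             "Sens (Youden) | Spec@95%Sens | Spec@97%Sens |",
             "|---|---|---|---|---|---|---|---|---|"]
    for _, r in aggregate.iterrows():
        cells = [r["task"], r["model"]]
        for key in _METRIC_KEYS:
            cells.append(f"{r[f'{key}_mean']:.2f} ± {r[f'{key}_sd']:.2f}")
        lines.append("| " + " | ".join(str(c) for c in cells) + " |")
    lines.append("")
    lines.append(f"Random-guess baselines: AUC 0.50; AUPR = prevalence "
                 f"({', '.join(f'{r.baseline_aupr:.3g} ({r.model}/{r.task})' for r in aggregate.itertuples())}).")
    return "\n".join(lines)
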