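"""Model validation: ROC/AUC with convex hull and DeLong 95% CI, the DeLong
paired-AUC test, and stratified k-fold cross-validation with optional prior
hyperparameter tuning.

The AUC is the Mann-Whitney probability that a random case outranks a random
control, ties counted one half.  Its sampling variance (for the CI and the
paired test) comes from DeLong's structural components — the per-observation
placement values V10/V01 — giving the usual asymptotic normal treatment of a
single AUC and of the difference of two AUCs computed on the same records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .model import DAGStructure, MixedDataset
from .scoring import PriorHyper

DEFAULT_ALPHA_GRID = (0.5, 1.0, 2.0, 5.0, 10.0)
DEFAULT_NU_GRID = (0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass
class ROCAnalysis:
    points: np.ndarray  # (m, 2) columns (FPR, TPR), from (0,0) to (1,1)
    auc: float
    convex_hull_auc: float
    ci95: tuple[float, float]
    se: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    return (labels == classes.max()).astype(int)


def _placement_values(scores: np.ndarray, labels01: np.ndarray):
    """DeLong structural components V10 (cases) and V01 (controls)."""
    x = scores[labels01 == 1]
    y = scores[labels01 == 0]
    m, n = len(x), len(y)
    tz = rankdata(np.concatenate([x, y]))
    tx = rankdata(x)
    ty = rankdata(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def _upper_hull_auc(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Upper concave envelope of ROC points and its area."""
    pts = points[np.lexsort((points[:, 1], points[:, 0]))]
    hull: list[np.ndarray] = []
    for p in pts:
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0])
            if cross >= 0:  # a lies on/below chord o-p: not on the upper hull
                hull.pop()
            else:
                break
        hull.append(p)
    hull_arr = np.array(hull)
    area = float(np.trapezoid(hull_arr[:, 1], hull_arr[:, 0]))
    return hull_arr, area


def roc_auc(scores, labels) -> ROCAnalysis:
    """ROC analysis of continuous scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels01 = _check_binary(np.asarray(labels))
    if len(scores) != len(labels01):
        raise ValueError("scores and labels must have equal length")
    auc, v10, v01 = _placement_values(scores, labels01)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    fpr, tpr, _ = roc_curve(labels01, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    _, hull_auc = _upper_hull_auc(points)
    return ROCAnalysis(points, float(auc), hull_auc, (lo, hi), se)


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong test for the difference of two correlated AUCs
    computed on the same records.  Identical score vectors give p = 1 by
    convention; zero variance with unequal AUCs gives the limiting p = 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels01 = _check_binary(np.asarray(labels))
    if not (len(a) == len(b) == len(labels01)):
        raise ValueError("paired scores and labels must have equal length")
    auc_a, v10_a, v01_a = _placement_values(a, labels01)
    auc_b, v10_b, v01_b = _placement_values(b, labels01)
    if np.array_equal(a, b):
        return DeLongResult(float(auc_a), float(auc_b), 0.0, 1.0)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ (s10 / m + s01 / n) @ contrast)
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
        return DeLongResult(float(auc_a), float(auc_b), np.inf if diff else 0.0, p)
    z = diff / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(float(auc_a), float(auc_b), float(z), p)


@dataclass
class CVResult:
    fold_aucs: list[float]
    pooled_auc: float
    mean_fold_auc: float
    prior: PriorHyper
    fold_assignment: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    tuning_table: list[tuple[PriorHyper, float]] = field(default_factory=list)


def _positive_scores(net, test: MixedDataset, phenotype: str) -> np.ndarray:
    """Posterior probability of the phenotype's last-declared state."""
    from .inference import predict_dataset

    result = predict_dataset(net, test, target=phenotype)
    return result.probabilities[:, -1]


def _run_cv(
    data: MixedDataset,
    config,
    folds: int,
    seed: int,
    structure: DAGStructure | None,
) -> tuple[list[float], np.ndarray, np.ndarray, np.ndarray]:
    from .inference import fit_parameters
    from .search import learn_structure

    phenotype = config.phenotype or data.phenotype
    y = data.codes(phenotype)
    counts = np.bincount(y)
    if (counts[counts > 0] < folds).any():
        raise ValueError(f"stratified {folds}-fold split infeasible: class counts {counts}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_assignment = np.empty(data.n, dtype=int)
    scores = np.empty(data.n)
    labels = (y == y.max()).astype(int)
    fold_aucs = []
    for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(data.n), y)):
        fold_assignment[test_idx] = f
        train = data.take(train_idx)
        test = data.take(test_idx)
        struct = structure if structure is not None else learn_structure(train, config)
        net = fit_parameters(struct, train, config.prior)
        s = _positive_scores(net, test, phenotype)
        scores[test_idx] = s
        if len(np.unique(labels[test_idx])) == 2:
            fold_aucs.append(roc_auc(s, labels[test_idx]).auc)
    return fold_aucs, fold_assignment, scores, labels


def cross_validate(
    data: MixedDataset,
    config,
    folds: int = 5,
    seed: int = 0,
    tune: bool = False,
    structure: DAGStructure | None = None,
    alpha_grid=DEFAULT_ALPHA_GRID,
    nu_grid=DEFAULT_NU_GRID,
) -> CVResult:
    """Seeded stratified k-fold CV; learns structure and parameters on the
    training folds only (or refits parameters of a fixed ``structure``).

    With ``tune=True``, grid-searches (alpha, nu) by pooled CV AUC; ties go to
    the smaller alpha, then the smaller nu.
    """
    from dataclasses import replace

    tuning_table: list[tuple[PriorHyper, float]] = []
    if tune:
        best = None
        for alpha in sorted(alpha_grid):
            for nu in sorted(nu_grid):
                prior = replace(config.prior, alpha=alpha, nu=nu)
                cfg = replace(config, prior=prior)
                fold_aucs, _, scores, labels = _run_cv(data, cfg, folds, seed, structure)
                pooled = roc_auc(scores, labels).auc
                tuning_table.append((prior, pooled))
                if best is None or pooled > best[1]:
                    best = (cfg, pooled)
        config = best[0]
    fold_aucs, fold_assignment, scores, labels = _run_cv(data, config, folds, seed, structure)
    pooled = roc_auc(scores, labels).auc
    return CVResult(
        fold_aucs=fold_aucs,
        pooled_auc=float(pooled),
        mean_fold_auc=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        prior=config.prior,
        fold_assignment=fold_assignment,
        scores=scores,
        labels=labels,
        tuning_table=tuning_table,
    )
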