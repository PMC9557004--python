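"""Statistical comparison and multivariate classification of HFO features.

Mood's median test compares feature distributions between groups via the
2x2 table of counts above vs at-or-below the pooled grand median (Pearson
chi-square, 1 df, no continuity correction); 25 tests (5 features x 5
contrasts) share a Bonferroni-corrected significance level of 0.05/25 =
0.002. Multivariate separability is quantified by Random-Forest classifiers
under nested cross-validation (stratified 5-fold outer and inner loops,
grid-searched hyperparameters, SMOTE balancing applied to training folds
only) reporting AUC and mean-decrease-in-Gini feature importances; a
leave-one-patient-out variant checks robustness to patient effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.ensemble import IsolationForest, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from hfopipe.features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

N_CONTRASTS = 5
BONFERRONI_ALPHA = 0.05 / (len(FEATURE_COLUMNS) * N_CONTRASTS)

#: default hyperparameter grid for the nested-CV search; the axes are the
#: forest size, tree depth, feature subsampling and bootstrap fraction.
DEFAULT_PARAM_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [3, None],
    "max_features": ["sqrt", None],
    "max_samples": [0.8],
}


@dataclass(frozen=True)
class MedianTestResult:
    feature: str
    grouping: str
    chi2: float
    p: float
    significant: bool
    median_x: float
    iqr_x: float
    median_y: float
    iqr_y: float
    n_x: int
    n_y: int
    degenerate: bool = False


def remove_outliers(
    table: pd.DataFrame,
    contamination: float = 0.05,
    min_group: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Drop Isolation-Forest outliers within each (patient, class) group.

    Groups smaller than ``min_group`` pass through untouched. The removal
    fraction per group is bounded by ``contamination``.
    """
    keep_masks = []
    for (pid, cls), grp in table.groupby(["patient_id", "class"], sort=False):
        if len(grp) < min_group:
            logger.info("outlier removal: group (%s, %s) of %d passed through", pid, cls, len(grp))
            keep_masks.append(pd.Series(True, index=grp.index))
            continue
        forest = IsolationForest(contamination=contamination, random_state=seed)
        flags = forest.fit_predict(grp[list(FEATURE_COLUMNS)].values)
        keep_masks.append(pd.Series(flags == 1, index=grp.index))
    keep = pd.concat(keep_masks).reindex(table.index)
    removed = int((~keep).sum())
    if removed:
        logger.info("outlier removal: dropped %d of %d events", removed, len(table))
    return table.loc[keep]


def zscore_features(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Standardize each feature with mean/SD over the whole table.

    Returns the standardized table and the scaler record, which can be
    re-applied to held-out data via ``apply_scaler``.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 events")
    scaler = {}
    out = table.copy()
    for col in FEATURE_COLUMNS:
        mu = float(table[col].mean())
        sd = float(table[col].std(ddof=0))
        if sd == 0:
            raise ValueError(f"feature {col!r} has zero variance")
        out[col] = (table[col] - mu) / sd
        scaler[col] = (mu, sd)
    return out, scaler


def apply_scaler(table: pd.DataFrame, scaler: dict) -> pd.DataFrame:
    out = table.copy()
    for col, (mu, sd) in scaler.items():
        out[col] = (table[col] - mu) / sd
    return out


def moods_median_test(x, y) -> tuple[float, float, dict]:
    """Mood's median test: chi-square for the 2x2 above/at-or-below table.

    Ties with the grand median count in the "at or below" cell; the Pearson
    statistic n(ad - bc)^2 / (r1 r2 c1 c2) is referred to chi-square with
    one degree of freedom, no continuity correction. All pooled values
    identical is a degenerate case: chi2 = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    gm = float(np.median(pooled))
    a = int(np.sum(x > gm))  # x above
    b = int(np.sum(y > gm))  # y above
    c = x.size - a
    d = y.size - b
    n = x.size + y.size
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    extras = {
        "table": ((a, b), (c, d)),
        "grand_median": gm,
        "median_x": float(np.median(x)),
        "median_y": float(np.median(y)),
        "iqr_x": float(np.subtract(*np.percentile(x, [75, 25]))),
        "iqr_y": float(np.subtract(*np.percentile(y, [75, 25]))),
        "degenerate": False,
    }
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        extras["degenerate"] = True
        return 0.0, 1.0, extras
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2.sf(stat, df=1)), extras


def smote_oversample(
    X: np.ndarray, y: np.ndarray, seed: int | None = None, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Balance two classes by synthetic minority over-sampling.

    New minority points are drawn on the segment between a random minority
    sample and one of its k nearest minority neighbours, the classical
    interpolation scheme. Returns the augmented (X, y); already-balanced
    input passes through unchanged.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE supports exactly two classes")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X, y
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise ValueError("minority class too small for SMOTE")
    k_eff = min(k, len(Xm) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xm), size=n_needed)
    nb = idx[base, rng.integers(1, k_eff + 1, size=n_needed)]
    lam = rng.uniform(0, 1, size=(n_needed, 1))
    X_new = Xm[base] + lam * (Xm[nb] - Xm[base])
    return np.vstack([X, X_new]), np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])


def _grid_combos(param_grid: dict) -> list[dict]:
    keys = list(param_grid)
    return [dict(zip(keys, vals)) for vals in product(*(param_grid[k] for k in keys))]


def _fit_rf(X, y, params: dict, seed: int) -> RandomForestClassifier:
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    clf.fit(X, y)
    return clf


def _inner_grid_search(X, y, param_grid, n_inner, seed) -> dict:
    """Pick the grid point with the best mean inner-fold AUC (SMOTE on train only)."""
    combos = _grid_combos(param_grid)
    if len(combos) == 1:
        return combos[0]
    inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
    scores = np.zeros(len(combos))
    for tr, va in inner.split(X, y):
        Xb, yb = smote_oversample(X[tr], y[tr], seed=seed)
        for ci, params in enumerate(combos):
            clf = _fit_rf(Xb, yb, params, seed)
            prob = clf.predict_proba(X[va])[:, 1]
            scores[ci] += roc_auc_score(y[va], prob)
    return combos[int(np.argmax(scores))]


def nested_cv_rf(
    table: pd.DataFrame,
    label_column: str,
    seed: int,
    param_grid: dict | None = None,
    n_outer: int = 5,
    n_inner: int = 5,
    contrast: str = "",
) -> dict:
    """Nested cross-validated Random Forest: AUC and Gini importances.

    Outer stratified K-fold held out for evaluation; within each outer
    training set an inner stratified K-fold grid search selects the forest
    hyperparameters by AUC; SMOTE balances training folds only, never the
    evaluation folds. Reports mean/SD AUC (percent) over outer test folds
    and Gini importances averaged over outer models (normalized to sum 1).
    """
    param_grid = param_grid or DEFAULT_PARAM_GRID
    X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    labels = table[label_column].to_numpy()
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes in {label_column!r}, got {list(classes)}")
    y = (labels == classes[1]).astype(int)
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    aucs, importances = [], []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        fold_seed = seed + 1000 * (fold + 1)
        best = _inner_grid_search(X[tr], y[tr], param_grid, n_inner, fold_seed)
        Xb, yb = smote_oversample(X[tr], y[tr], seed=fold_seed)
        clf = _fit_rf(Xb, yb, best, fold_seed)
        aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1]))
        importances.append(clf.feature_importances_)
    imp = np.mean(importances, axis=0)
    imp = imp / imp.sum()
    return {
        "contrast": contrast,
        "auc_mean": float(np.mean(aucs) * 100),
        "auc_sd": float(np.std(aucs, ddof=0) * 100),
        "fold_aucs": [float(a * 100) for a in aucs],
        "importances": dict(zip(FEATURE_COLUMNS, (float(v) for v in imp))),
        "cv_scheme": f"nested-{n_outer}x{n_inner}",
        "positive_class": str(classes[1]),
        "seed": seed,
    }


def leave_one_patient_out_cv(
    table: pd.DataFrame,
    label_column: str,
    seed: int,
    param_grid: dict | None = None,
    n_inner: int = 5,
    contrast: str = "",
) -> dict:
    """Leave-one-patient-out variant: outer folds are patients.

    A held-out patient with a single class has no defined AUC; such folds
    are excluded with a logged count. Requires at least 3 patients carrying
    both classes.
    """
    param_grid = param_grid or DEFAULT_PARAM_GRID
    X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    labels = table[label_column].to_numpy()
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y = (labels == classes[1]).astype(int)
    pids = table["patient_id"].to_numpy()
    both = [p for p in pd.unique(pids) if len(np.unique(y[pids == p])) == 2]
    if len(both) < 3:
        raise ValueError("leave-one-patient-out needs >= 3 patients with both classes")
    aucs, importances, skipped = [], [], 0
    for fold, pid in enumerate(pd.unique(pids)):
        te = pids == pid
        tr = ~te
        if len(np.unique(y[te])) < 2:
            skipped += 1
            continue
        fold_seed = seed + 1000 * (fold + 1)
        best = _inner_grid_search(X[tr], y[tr], param_grid, n_inner, fold_seed)
        Xb, yb = smote_oversample(X[tr], y[tr], seed=fold_seed)
        clf = _fit_rf(Xb, yb, best, fold_seed)
        aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1]))
        importances.append(clf.feature_importances_)
    if skipped:
        logger.info("leave-one-patient-out: %d single-class patients excluded", skipped)
    imp = np.mean(importances, axis=0)
    imp = imp / imp.sum()
    return {
        "contrast": contrast,
        "auc_mean": float(np.mean(aucs) * 100),
        "auc_sd": float(np.std(aucs, ddof=0) * 100),
        "fold_aucs": [float(a * 100) for a in aucs],
        "importances": dict(zip(FEATURE_COLUMNS, (float(v) for v in imp))),
        "cv_scheme": "leave-one-patient-out",
        "n_folds_scored": len(aucs),
        "n_folds_skipped": skipped,
        "positive_class": str(classes[1]),
        "seed": seed,
    }


#: the five contrasts: (name, row filter, grouping column)
CONTRASTS = (
    ("class1-vs-class2-all", None, "class"),
    ("class1-vs-class2-mtl", ("region", "MTL"), "class"),
    ("class1-vs-class2-neocortex", ("region", "Neocortex"), "class"),
    ("mtl-vs-neocortex-class1", ("class", "Class-1"), "region"),
    ("mtl-vs-neocortex-class2", ("class", "Class-2"), "region"),
)


def run_contrasts(
    table: pd.DataFrame,
    seed: int = 0,
    classify: bool = False,
    param_grid: dict | None = None,
) -> tuple[list[MedianTestResult], list[dict]]:
    """All 25 Mood's tests (and optionally 5 classifiers) over the contrasts.

    Significance uses the Bonferroni level 0.05/25 = 0.002 jointly. A
    contrast whose stratum is empty on either side is skipped with a
    warning; its tests are not emitted.
    """
    tests: list[MedianTestResult] = []
    reports: list[dict] = []
    for k, (name, filt, group_col) in enumerate(CONTRASTS):
        sub = table if filt is None else table[table[filt[0]] == filt[1]]
        groups = sorted(sub[group_col].unique()) if len(sub) else []
        if len(groups) != 2:
            logger.warning("contrast %s skipped: stratum empty or single-group", name)
            continue
        gx = sub[sub[group_col] == groups[0]]
        gy = sub[sub[group_col] == groups[1]]
        for feat in FEATURE_COLUMNS:
            stat, p, extras = moods_median_test(gx[feat], gy[feat])
            tests.append(
                MedianTestResult(
                    feature=feat,
                    grouping=name,
                    chi2=stat,
                    p=p,
                    significant=bool(p < BONFERRONI_ALPHA) and not extras["degenerate"],
                    median_x=extras["median_x"],
                    iqr_x=extras["iqr_x"],
                    median_y=extras["median_y"],
                    iqr_y=extras["iqr_y"],
                    n_x=len(gx),
                    n_y=len(gy),
                    degenerate=extras["degenerate"],
                )
            )
        if classify:
            reports.append(
                nested_cv_rf(sub, group_col, seed=seed + k, param_grid=param_grid, contrast=name)
            )
    return tests, reports
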