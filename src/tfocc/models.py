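"""Occupancy modeling: normalization, classification, regression, importance.

The quantitative target is the ChIP-seq tag count of each site.  Two tasks
are supported: discriminating strong from weak sites (top and bottom
quantiles of the target; auROC metric) and regressing the tag count
directly (Pearson correlation between measured and predicted counts).
Models are SVMs with radial or polynomial kernels and random forests,
evaluated under leave-one-group-out cross-validation with randomized,
seeded group assignment, plus an optional stratified holdout.

Feature importance is model-agnostic permutation importance: the drop in
the task metric when one feature column is shuffled, averaged over
permutations and normalized to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC, SVR

from .pwm import SiteList

DEFAULT_C_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)

METHODS = ("svm-radial", "svm-poly", "rf")


@dataclass
class FeatureTable:
    """Sites x features with a reserved ``target`` column.

    ``frame`` is indexed by site id; every column except ``target`` is a
    feature.  After :func:`normalize`, ``means``/``stds`` hold the
    centering and scaling parameters for reuse on held-out data.
    """

    frame: pd.DataFrame
    normalized: bool = False
    means: pd.Series | None = None
    stds: pd.Series | None = None
    cell: str = ""
    factor: str = ""

    def __post_init__(self):
        if "target" not in self.frame.columns:
            raise ValueError("feature table requires a 'target' column")

    @property
    def feature_names(self) -> list:
        return [c for c in self.frame.columns if c != "target"]

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_names]

    @property
    def target(self) -> pd.Series:
        return self.frame["target"]

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path):
        self.frame.rename_axis("id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, **kw) -> "FeatureTable":
        frame = pd.read_csv(path, sep="\t", index_col="id")
        return cls(frame, **kw)


@dataclass
class ModelReport:
    """Fitted-model metadata and performance summary."""

    task: str                    # classify | regress
    method: str
    metric_name: str             # auROC | PCC
    cv_metric: float
    per_fold: list
    holdout_metric: float | None
    hyperparameters: dict
    seed: int
    fold_assignment: np.ndarray
    feature_names: list
    means: pd.Series | None
    stds: pd.Series | None
    model: object = field(repr=False, default=None)
    importance: pd.Series | None = None
    resubstitution_metric: float | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task, "method": self.method,
            "metric": self.metric_name, "cv_metric": self.cv_metric,
            "per_fold": list(map(float, self.per_fold)),
            "holdout_metric": self.holdout_metric,
            "hyperparameters": {k: (v if not isinstance(v, np.generic)
                                    else v.item())
                                for k, v in self.hyperparameters.items()},
            "seed": self.seed,
            "features": list(self.feature_names),
            "importance": (None if self.importance is None
                           else self.importance.to_dict()),
        }


def normalize(table: FeatureTable) -> FeatureTable:
    """Z-score every feature column; drop zero-variance features.

    Centering and scaling parameters are stored on the returned table so
    that held-out data can be transformed identically.  Idempotent up to
    numerical tolerance.
    """
    if len(table) < 2:
        raise ValueError("normalization requires at least 2 rows")
    features = table.features
    means = features.mean()
    stds = features.std(ddof=1)
    keep = stds > 0
    dropped = list(features.columns[~keep])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
    scaled = (features.loc[:, keep] - means[keep]) / stds[keep]
    frame = scaled.copy()
    frame["target"] = table.target
    # compose with any previous normalization so parameters always map
    # raw-scale data onto the current representation
    if table.normalized and table.means is not None:
        prev_m, prev_s = table.means[keep.index[keep]], table.stds[keep.index[keep]]
        total_s = prev_s * stds[keep]
        total_m = prev_m + means[keep] * prev_s
        means, stds = total_m, total_s
    else:
        means, stds = means[keep], stds[keep]
    return FeatureTable(frame, normalized=True, means=means, stds=stds,
                        cell=table.cell, factor=table.factor)


def apply_normalization(features: pd.DataFrame, means: pd.Series,
                        stds: pd.Series) -> pd.DataFrame:
    missing = [f for f in means.index if f not in features.columns]
    if missing:
        raise ValueError(f"missing model features: {missing}")
    return (features[means.index] - means) / stds


def label_strong_weak(table: FeatureTable, fraction: float = 0.2):
    """Label the top ``fraction`` of sites by target strong, bottom weak.

    Returns ``(labels, subset)`` where labels is a 0/1 series (1 = strong)
    over the retained sites; the middle of the distribution is discarded.
    Ties at the quantile boundary are broken by stable site order.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(table)
    k = int(np.floor(fraction * n))
    if k < 1:
        raise ValueError("too few sites for the requested fraction")
    order = table.target.to_numpy().argsort(kind="stable")
    weak_idx = table.frame.index[order[:k]]
    strong_idx = table.frame.index[order[-k:]]
    subset_index = table.frame.index[
        table.frame.index.isin(weak_idx) | table.frame.index.isin(strong_idx)]
    labels = pd.Series(0, index=subset_index, dtype=int)
    labels.loc[strong_idx] = 1
    subset = FeatureTable(table.frame.loc[subset_index].copy(),
                          normalized=table.normalized, means=table.means,
                          stds=table.stds, cell=table.cell,
                          factor=table.factor)
    return labels, subset


def _make_groups(n: int, cv_groups: int, rng: np.random.Generator):
    groups = np.arange(n) % cv_groups   # sizes differ by at most one
    rng.shuffle(groups)
    return groups


def median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator,
                           max_points: int = 500) -> float:
    """RBF kernel width: gamma = 1 / (2 sigma^2), sigma the median pairwise
    distance of a seeded subsample."""
    if len(X) > max_points:
        X = X[rng.choice(len(X), max_points, replace=False)]
    from scipy.spatial.distance import pdist
    dists = pdist(X)
    dists = dists[dists > 0]
    sigma = np.median(dists) if len(dists) else 1.0
    return float(1.0 / (2.0 * sigma ** 2))


def _build_estimator(task: str, method: str, c: float, gamma: float,
                     seed: int):
    if method == "svm-radial":
        if task == "classify":
            return SVC(kernel="rbf", C=c, gamma=gamma)
        return SVR(kernel="rbf", C=c, gamma=gamma)
    if method == "svm-poly":
        if task == "classify":
            return SVC(kernel="poly", degree=3, C=c, gamma="scale")
        return SVR(kernel="poly", degree=3, C=c, gamma="scale")
    if method == "rf":
        if task == "classify":
            return RandomForestClassifier(n_estimators=300,
                                          random_state=seed)
        return RandomForestRegressor(n_estimators=300, random_state=seed)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _score(task: str, model, X, y) -> float:
    if task == "classify":
        if hasattr(model, "decision_function"):
            pred = model.decision_function(X)
        else:
            pred = model.predict_proba(X)[:, 1]
        return float(roc_auc_score(y, pred))
    pred = model.predict(X)
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(pearsonr(y, pred)[0])


def _grouped_cv(task, method, X, y, groups, c, gamma, seed):
    """Leave-one-group-out CV; returns per-fold metrics (classification)
    or pooled predictions (regression)."""
    fold_metrics = []
    pooled = np.full(len(y), np.nan)
    for g in np.unique(groups):
        test = groups == g
        train = ~test
        if task == "classify" and len(np.unique(y[train])) < 2:
            raise _SingleClassFold()
        model = _build_estimator(task, method, c, gamma, seed)
        model.fit(X[train], y[train])
        if task == "classify":
            if len(np.unique(y[test])) < 2:
                raise _SingleClassFold()
            fold_metrics.append(_score(task, model, X[test], y[test]))
        else:
            pooled[test] = model.predict(X[test])
    return fold_metrics, pooled


class _SingleClassFold(Exception):
    pass


def _cv_with_refold(task, method, X, y, cv_groups, c, gamma, seed,
                    max_tries: int = 10):
    """Grouped CV, re-drawing group assignment if a fold is single-class."""
    for attempt in range(max_tries):
        rng = np.random.default_rng(seed + attempt)
        groups = _make_groups(len(y), cv_groups, rng)
        try:
            folds, pooled = _grouped_cv(task, method, X, y, groups, c,
                                        gamma, seed)
            if attempt:
                warnings.warn(f"refolded {attempt} time(s) to balance classes")
            return folds, pooled, groups
        except _SingleClassFold:
            continue
    raise ValueError("could not build folds with both classes present")


def train_classifier(table: FeatureTable, labels: pd.Series,
                     method: str = "svm-radial", cv_groups: int = 10,
                     holdout: float = 0.1, c_grid=DEFAULT_C_GRID,
                     seed: int = 0) -> ModelReport:
    """Strong-vs-weak classifier with grouped CV model selection.

    The data is split stratified into a model-building part and a
    ``holdout`` fraction for final testing.  The SVM cost parameter is
    chosen by leave-one-group-out CV auROC on the model-building part,
    with the RBF width fixed beforehand by the median heuristic.  Reports
    both the CV auROC (best hyperparameters) and the holdout auROC.
    """
    if not table.normalized:
        table = normalize(table)
    X_all = table.features.loc[labels.index].to_numpy()
    y_all = labels.to_numpy()
    if len(np.unique(y_all)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    if holdout > 0:
        X, X_hold, y, y_hold = train_test_split(
            X_all, y_all, test_size=holdout, stratify=y_all,
            random_state=seed)
    else:
        X, y = X_all, y_all
        X_hold = y_hold = None
    gamma = (median_heuristic_gamma(X, rng)
             if method == "svm-radial" else 0.0)
    if method != "rf":
        best = None
        for c in c_grid:
            folds, _, groups = _cv_with_refold("classify", method, X, y,
                                               cv_groups, c, gamma, seed)
            mean_auc = float(np.mean(folds))
            if best is None or mean_auc > best[0]:
                best = (mean_auc, c, folds, groups)
        cv_metric, c_best, per_fold, groups = best
    else:
        folds, _, groups = _cv_with_refold("classify", method, X, y,
                                           cv_groups, 1.0, gamma, seed)
        cv_metric, c_best, per_fold = float(np.mean(folds)), 1.0, folds
    final = _build_estimator("classify", method, c_best, gamma, seed)
    final.fit(X, y)
    holdout_metric = (_score("classify", final, X_hold, y_hold)
                      if X_hold is not None else None)
    return ModelReport(
        task="classify", method=method, metric_name="auROC",
        cv_metric=cv_metric, per_fold=per_fold,
        holdout_metric=holdout_metric,
        hyperparameters={"C": c_best, "gamma": gamma, "holdout": holdout},
        seed=seed, fold_assignment=groups,
        feature_names=list(table.feature_names),
        means=table.means, stds=table.stds, model=final,
        resubstitution_metric=_score("classify", final, X_all, y_all))


def train_regressor(table: FeatureTable, method: str = "svm-radial",
                    cv_groups: int = 10, c: float = 1.0,
                    seed: int = 0) -> ModelReport:
    """SVM (or RF) regression of tag counts with grouped-CV PCC.

    All sites are used (no strong/weak subsetting).  The reported metric
    is the Pearson correlation between measured targets and the pooled
    out-of-fold predictions.
    """
    if not table.normalized:
        table = normalize(table)
    X = table.features.to_numpy()
    y = table.target.to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("target variance must be positive")
    rng = np.random.default_rng(seed)
    gamma = (median_heuristic_gamma(X, rng)
             if method == "svm-radial" else 0.0)
    groups = _make_groups(len(y), cv_groups, np.random.default_rng(seed))
    folds, pooled = _grouped_cv("regress", method, X, y, groups, c, gamma,
                                seed)
    cv_metric = float(pearsonr(y, pooled)[0])
    per_fold = [float(pearsonr(y[groups == g], pooled[groups == g])[0])
                for g in np.unique(groups)
                if np.std(y[groups == g]) > 0
                and np.std(pooled[groups == g]) > 0]
    final = _build_estimator("regress", method, c, gamma, seed)
    final.fit(X, y)
    return ModelReport(
        task="regress", method=method, metric_name="PCC",
        cv_metric=cv_metric, per_fold=per_fold, holdout_metric=None,
        hyperparameters={"C": c, "gamma": gamma}, seed=seed,
        fold_assignment=groups, feature_names=list(table.feature_names),
        means=table.means, stds=table.stds, model=final,
        resubstitution_metric=_score("regress", final, X, y))


def cross_predict(report: ModelReport, other: FeatureTable) -> float:
    """Metric of the fitted model on another (raw-scale) feature table.

    The other table is transformed with the *training* table's centering
    and scaling parameters; a feature-name mismatch raises with the list
    of missing features.  Returns the PCC (regression) or auROC-style
    score is not defined here — cross-dataset prediction follows the
    regression design.
    """
    if report.model is None:
        raise ValueError("report carries no fitted model")
    features = other.features
    if other.normalized:
        X = features[report.feature_names].to_numpy()
    else:
        X = apply_normalization(features, report.means,
                                report.stds).to_numpy()
    y = other.target.to_numpy(dtype=float)
    return _score(report.task, report.model, X, y)


def feature_importance(report: ModelReport, table: FeatureTable,
                       labels_or_target=None, n_permutations: int = 20,
                       seed: int = 0) -> pd.Series:
    """Permutation importance of every model feature.

    The metric drop when one feature column is shuffled, averaged over
    ``n_permutations`` draws, clipped at zero and normalized to sum to 1.
    """
    if not table.normalized:
        table = normalize(table)
    if labels_or_target is None:
        y = table.target.to_numpy(dtype=float)
        X_frame = table.features
    elif isinstance(labels_or_target, pd.Series):
        y = labels_or_target.to_numpy()
        X_frame = table.features.loc[labels_or_target.index]
    else:
        y = np.asarray(labels_or_target)
        X_frame = table.features
    X = X_frame[report.feature_names].to_numpy()
    rng = np.random.default_rng(seed)
    base = _score(report.task, report.model, X, y)
    drops = np.zeros(len(report.feature_names))
    for j in range(X.shape[1]):
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[j] += base - _score(report.task, report.model, Xp, y)
    drops /= n_permutations
    drops = np.clip(drops, 0.0, None)
    total = drops.sum()
    if total == 0:
        drops = np.full_like(drops, 1.0 / len(drops))
    else:
        drops = drops / total
    return pd.Series(drops, index=report.feature_names, name="importance")


def recursive_feature_elimination(table: FeatureTable, labels: pd.Series,
                                  method: str = "svm-radial",
                                  cv_groups: int = 10, c: float = 1.0,
                                  n_permutations: int = 10,
                                  seed: int = 0):
    """Backward feature elimination, one feature per step.

    At each step the current feature set is evaluated by grouped-CV auROC
    and the feature with the lowest permutation importance is removed.
    Returns ``(elimination_order, curve)`` where the curve maps feature-set
    size to CV auROC; its entry at the full set equals
    :func:`train_classifier` run without holdout at the same seed and cost.
    """
    if not table.normalized:
        table = normalize(table)
    remaining = list(table.feature_names)
    if len(remaining) < 2:
        raise ValueError("RFE requires at least two features")
    y = labels.to_numpy()
    order = []
    sizes, scores = [], []
    rng = np.random.default_rng(seed)
    while remaining:
        X = table.features.loc[labels.index, remaining].to_numpy()
        gamma = (median_heuristic_gamma(
            X, np.random.default_rng(seed)) if method == "svm-radial" else 0.0)
        folds, _, groups = _cv_with_refold("classify", method, X, y,
                                           cv_groups, c, gamma, seed)
        sizes.append(len(remaining))
        scores.append(float(np.mean(folds)))
        if len(remaining) == 1:
            order.append(remaining.pop())
            break
        model = _build_estimator("classify", method, c, gamma, seed)
        model.fit(X, y)
        base = _score("classify", model, X, y)
        drops = np.zeros(len(remaining))
        for j in range(len(remaining)):
            for _ in range(n_permutations):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops[j] += base - _score("classify", model, Xp, y)
        worst = int(np.argmin(drops))
        order.append(remaining.pop(worst))
    curve = pd.DataFrame({"n_features": sizes, "cv_auroc": scores})
    return order, curve


@dataclass
class VennSummary:
    """Venn partition of 2-3 site lists matched by center distance."""

    region_counts: dict          # frozenset of list names -> count
    list_names: list

    @property
    def union_total(self) -> int:
        return sum(self.region_counts.values())

    @property
    def common_count(self) -> int:
        return self.region_counts.get(frozenset(self.list_names), 0)

    @property
    def percent_common(self) -> float:
        return round(100.0 * self.common_count / self.union_total, 1)

    @classmethod
    def from_counts(cls, common: int, union: int,
                    names=("a", "b", "c")) -> "VennSummary":
        """Summary from printed common/union totals (remaining sites pooled
        into a single exclusive region for arithmetic purposes)."""
        names = list(names)
        counts = {frozenset(names): common,
                  frozenset(names[:1]): union - common}
        return cls(counts, names)


def venn_overlap_summary(lists: dict, match_distance: int = 100) -> VennSummary:
    """Overlap structure of 2-3 site lists.

    Sites from different lists whose centers lie within ``match_distance``
    of each other (transitively) form one matched entity; each entity is
    assigned to the Venn region of the set of lists it contains.  Counts
    are entities, the union total their sum.
    """
    names = list(lists)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn summary requires 2 or 3 lists")
    rows = []
    for name, sites in lists.items():
        if len(sites) == 0:
            raise ValueError(f"site list {name!r} is empty")
        for site in sites:
            rows.append((site.chrom, site.center, name))
    frame = pd.DataFrame(rows, columns=["chrom", "center", "list"])
    region_counts: dict = {}
    for _, sub in frame.groupby("chrom"):
        sub = sub.sort_values("center")
        centers = sub["center"].to_numpy()
        members = sub["list"].to_numpy()
        breaks = np.nonzero(np.diff(centers) > match_distance)[0] + 1
        for cluster in np.split(np.arange(len(sub)), breaks):
            key = frozenset(members[cluster])
            region_counts[key] = region_counts.get(key, 0) + 1
    return VennSummary(region_counts, names)
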