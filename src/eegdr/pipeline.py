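"""Depression-recognition classification pipeline.

From a subjects x features matrix with binary labels the pipeline runs,
*inside every training fold only*:

    SMOTE oversampling -> z-score normalisation -> feature selection
    -> classifier fit

and evaluates on the untouched test fold, pooling Accuracy, Recall and
Precision over repeated stratified 5-fold cross-validation (10 repeats by
default).  The positive class for recall/precision is the depressed /
A-MDD group (label 1).

Four selection routes are provided: ``all`` (no selection), ``l1``
(non-zero coefficients of an L1-penalised linear classifier), ``tree``
(impurity importances of a seeded random forest above a threshold rule),
and ``fdr`` (per-feature Welch tests with Benjamini-Hochberg correction).

SMOTE is implemented here in its canonical form: each synthetic minority
row is a uniform interpolation between a minority sample and one of its k
nearest minority-class neighbours (Euclidean), generated until the classes
balance; original rows are never modified.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from statsmodels.stats.multitest import multipletests

from ._errors import ParameterError, SchemaError, ValidationError
from .features import FEATURE_NAMES

__all__ = [
    "FeatureMatrix", "SelectionResult", "NormalizerParams", "CVReport",
    "assemble_matrix", "smote_oversample", "fit_normalizer", "apply_normalizer",
    "select_l1", "select_tree", "select_fdr", "select_features",
    "cross_validate", "fit_pipeline", "FittedPipeline", "compare_selection",
    "SELECTION_METHODS",
]

SELECTION_METHODS = ("all", "l1", "tree", "fdr")
POSITIVE_LABEL = 1


@dataclass
class FeatureMatrix:
    """Subjects (or epochs) x named features with binary labels (1 = depressed)."""
    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValidationError("X and y lengths differ")
        if self.X.columns.duplicated().any():
            raise ValidationError("duplicate feature names")
        if self.X.isna().any().any():
            raise ValidationError("missing values in feature matrix")
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) != 2:
            raise ValidationError(f"need exactly 2 classes, got {list(classes)}")
        if counts.min() < 2:
            raise ValidationError("need >= 2 rows per class")

    @property
    def features(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class SelectionResult:
    method: str
    selected: list[str]
    scores: pd.Series


@dataclass
class NormalizerParams:
    mean: pd.Series
    sd: pd.Series
    dropped: list[str]


@dataclass
class CVReport:
    """Repeated stratified CV metrics plus a per-fold audit trail."""
    folds: int
    repeats: int
    seed: int
    selection_method: str
    pooled: dict[str, float]
    per_repeat: pd.DataFrame
    fold_details: list[dict]
    confusion: dict[str, int]

    def to_json(self, path=None) -> str:
        payload = {
            "folds": self.folds, "repeats": self.repeats, "seed": self.seed,
            "selection_method": self.selection_method, "pooled": self.pooled,
            "confusion": self.confusion,
            "per_repeat": self.per_repeat.to_dict(orient="records"),
            "selected_features_per_fold": [d["selected"] for d in self.fold_details],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# assembly

def assemble_matrix(feature_table: pd.DataFrame, labels: dict,
                    aggregate: str = "mean") -> FeatureMatrix:
    """Build the wide subjects x (channel x feature) matrix from a tidy table.

    ``feature_table`` has columns subject_id, channel, epoch, feature, value
    (as produced by :func:`eegdr.features.feature_table`).  ``aggregate`` is
    ``"mean"`` (average each channel x feature over epochs, one row per
    subject) or ``"epoch"`` (one row per subject x epoch).  Columns are
    ordered channel-major, feature-minor.
    """
    need = {"subject_id", "channel", "feature", "value"}
    if not need.issubset(feature_table.columns):
        raise SchemaError(f"feature table lacks columns {sorted(need - set(feature_table.columns))}")
    subjects = sorted(feature_table["subject_id"].unique())
    missing = [s for s in subjects if s not in labels]
    if missing:
        raise SchemaError(f"no label for subject(s): {missing}")
    per_subject = feature_table.groupby("subject_id")[["channel", "feature"]].apply(
        lambda g: frozenset(zip(g["channel"], g["feature"])))
    if per_subject.nunique() != 1:
        ref = per_subject.iloc[0]
        diffs = {s: sorted(map(str, ref ^ fs))[:5] for s, fs in per_subject.items() if fs != ref}
        raise SchemaError(f"feature sets differ between subjects: {diffs}")
    channels = sorted(feature_table["channel"].unique())
    feat_order = [f for f in FEATURE_NAMES if f in set(feature_table["feature"])]
    feat_order += [f for f in sorted(feature_table["feature"].unique()) if f not in feat_order]
    if aggregate == "mean":
        wide = (feature_table.groupby(["subject_id", "channel", "feature"])["value"]
                .mean().unstack(["channel", "feature"]))
    elif aggregate == "epoch":
        wide = (feature_table.set_index(["subject_id", "epoch", "channel", "feature"])["value"]
                .unstack(["channel", "feature"]))
    else:
        raise ParameterError(f"unknown aggregate mode {aggregate!r}")
    cols = [(c, f) for c in channels for f in feat_order]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols)).sort_index()
    wide.columns = [f"{c}:{f}" for c, f in wide.columns]
    if aggregate == "epoch":
        y = np.array([labels[s] for s, _ in wide.index])
        wide.index = [f"{s}#e{e}" for s, e in wide.index]
    else:
        y = np.array([labels[s] for s in wide.index])
    return FeatureMatrix(X=wide, y=y)


# ---------------------------------------------------------------------------
# SMOTE

def smote_oversample(m: FeatureMatrix, k_neighbors: int = 5,
                     seed: int = 0) -> FeatureMatrix:
    """Balance the classes by canonical SMOTE interpolation.

    Synthetic rows are ``x_i + u * (x_j - x_i)`` with u ~ Uniform(0, 1) and
    x_j one of x_i's k nearest minority neighbours; originals are preserved
    unchanged and synthetic rows get ``smote_<n>`` identifiers.
    """
    classes, counts = np.unique(m.y, return_counts=True)
    if counts[0] == counts[1]:
        return FeatureMatrix(X=m.X.copy(), y=m.y.copy())
    minority = classes[np.argmin(counts)]
    n_new = int(abs(counts[0] - counts[1]))
    Xmin = m.X.to_numpy(float)[m.y == minority]
    if len(Xmin) < k_neighbors + 1:
        raise ParameterError(
            f"minority class has {len(Xmin)} rows; needs k_neighbors + 1 = "
            f"{k_neighbors + 1} (reduce k_neighbors)")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)          # column 0 is the point itself
    rows = []
    for t in range(n_new):
        i = int(rng.integers(0, len(Xmin)))
        j = int(idx[i, 1 + rng.integers(0, k_neighbors)])
        u = rng.uniform()
        rows.append(Xmin[i] + u * (Xmin[j] - Xmin[i]))
    synth = pd.DataFrame(rows, columns=m.X.columns,
                         index=[f"smote_{t}" for t in range(n_new)])
    X = pd.concat([m.X, synth])
    y = np.concatenate([m.y, np.full(n_new, minority)])
    return FeatureMatrix(X=X, y=y)


# ---------------------------------------------------------------------------
# normalisation (leakage contract: fit on training rows only)

def fit_normalizer(train: FeatureMatrix | pd.DataFrame) -> NormalizerParams:
    """Per-feature mean/SD from training rows; constant features are dropped
    with a warning."""
    X = train.X if isinstance(train, FeatureMatrix) else train
    mean = X.mean()
    sd = X.std(ddof=1)
    dropped = list(sd.index[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"dropping constant feature(s): {dropped}")
    keep = [c for c in X.columns if c not in set(dropped)]
    return NormalizerParams(mean=mean[keep], sd=sd[keep], dropped=dropped)


def apply_normalizer(params: NormalizerParams, X: pd.DataFrame) -> pd.DataFrame:
    """z-score with previously fitted parameters (test rows never refit)."""
    missing = [c for c in params.mean.index if c not in X.columns]
    if missing:
        raise SchemaError(f"matrix lacks feature(s) seen at fit time: {missing[:5]}")
    Z = X[list(params.mean.index)]
    return (Z - params.mean) / params.sd


# ---------------------------------------------------------------------------
# selection routes

def select_l1(m: FeatureMatrix, penalty_strength: float = 1.0,
              seed: int = 0) -> SelectionResult:
    """Features with non-zero coefficients in an L1-penalised linear classifier."""
    if penalty_strength <= 0:
        raise ParameterError("penalty_strength must be > 0")
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                             C=1.0 / penalty_strength, random_state=seed,
                             max_iter=2000)
    clf.fit(m.X.to_numpy(float), m.y)
    coefs = pd.Series(np.abs(clf.coef_[0]), index=m.X.columns)
    selected = [c for c in m.X.columns if coefs[c] > 0]
    if not selected:
        warnings.warn("L1 selection is empty (penalty too strong)")
    return SelectionResult(method="l1", selected=selected, scores=coefs)


def select_tree(m: FeatureMatrix, importance_threshold="mean",
                seed: int = 0, n_estimators: int = 200) -> SelectionResult:
    """Features whose impurity importance exceeds the threshold rule
    (``"mean"``, ``"median"`` or an absolute float); ties keep canonical
    column order."""
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(m.X.to_numpy(float), m.y)
    imp = pd.Series(forest.feature_importances_, index=m.X.columns)
    if importance_threshold == "mean":
        thr = imp.mean()
    elif importance_threshold == "median":
        thr = imp.median()
    elif isinstance(importance_threshold, (int, float)):
        thr = float(importance_threshold)
    else:
        raise ParameterError(f"unknown importance threshold {importance_threshold!r}")
    selected = [c for c in m.X.columns if imp[c] > thr]
    return SelectionResult(method="tree", selected=selected, scores=imp)


def select_fdr(m: FeatureMatrix, alpha_level: float = 0.05) -> SelectionResult:
    """Per-feature two-sample Welch test with Benjamini-Hochberg correction;
    keeps features with adjusted p below ``alpha_level``.  Features with zero
    variance in both classes are skipped with a note."""
    classes = np.unique(m.y)
    A = m.X.to_numpy(float)[m.y == classes[0]]
    B = m.X.to_numpy(float)[m.y == classes[1]]
    var_ok = (A.var(axis=0) > 0) | (B.var(axis=0) > 0)
    if not var_ok.all():
        warnings.warn(f"skipping {int((~var_ok).sum())} zero-variance feature(s)")
    pvals = np.full(m.X.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(A[:, var_ok], B[:, var_ok], equal_var=False)
    pvals[var_ok] = p
    adj = np.full_like(pvals, np.nan)
    adj[var_ok] = multipletests(pvals[var_ok], method="fdr_bh")[1]
    scores = pd.Series(adj, index=m.X.columns)
    selected = [c for c, q in scores.items() if np.isfinite(q) and q < alpha_level]
    return SelectionResult(method="fdr", selected=selected, scores=scores)


def select_features(m: FeatureMatrix, method: str, seed: int = 0,
                    **kwargs) -> SelectionResult:
    """Dispatch to one of the four selection routes."""
    if method == "all":
        return SelectionResult(method="all", selected=list(m.X.columns),
                               scores=pd.Series(1.0, index=m.X.columns))
    if method == "l1":
        return select_l1(m, seed=seed, **kwargs)
    if method == "tree":
        return select_tree(m, seed=seed, **kwargs)
    if method == "fdr":
        return select_fdr(m, **kwargs)
    raise ParameterError(f"unknown selection method {method!r}; use one of {SELECTION_METHODS}")


# ---------------------------------------------------------------------------
# classifiers

def _make_classifier(config, seed: int):
    config = config or {}
    if isinstance(config, str):
        config = {"kind": config}
    kind = config.get("kind", "logistic")
    if kind == "logistic":
        return LogisticRegression(C=config.get("C", 1.0), max_iter=2000)
    if kind == "tree":
        return RandomForestClassifier(n_estimators=config.get("n_estimators", 200),
                                      random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=config.get("n_neighbors", 5))
    raise ParameterError(f"unknown classifier kind {kind!r}")


# ---------------------------------------------------------------------------
# cross-validation

def _fit_fold(train: FeatureMatrix, selection_method: str, classifier_config,
              seed: int, k_neighbors: int, selection_kwargs: dict):
    balanced = smote_oversample(train, k_neighbors=min(
        k_neighbors, int(np.bincount(train.y.astype(int)).min()) - 1) or 1, seed=seed)
    params = fit_normalizer(balanced)
    Z = apply_normalizer(params, balanced.X)
    sel = select_features(FeatureMatrix(X=Z, y=balanced.y), selection_method,
                          seed=seed, **selection_kwargs)
    feats = sel.selected if sel.selected else list(Z.columns)
    clf = _make_classifier(classifier_config, seed)
    clf.fit(Z[feats].to_numpy(float), balanced.y)
    return params, sel, feats, clf


def cross_validate(m: FeatureMatrix, selection_method: str = "all",
                   classifier_config=None, folds: int = 5, repeats: int = 10,
                   seed: int = 0, k_neighbors: int = 5,
                   selection_kwargs: dict | None = None) -> CVReport:
    """Repeated stratified k-fold evaluation of the full in-fold pipeline.

    Oversampling, normalisation and selection are re-estimated inside every
    training fold; test rows only ever pass through ``apply_normalizer`` and
    the fitted classifier.  Metrics use label 1 (depressed) as positive.
    """
    counts = np.bincount(m.y.astype(int))
    if counts.min() < folds:
        raise ValidationError(f"need >= {folds} samples per class for {folds}-fold CV")
    selection_kwargs = selection_kwargs or {}
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                   random_state=seed)
    X, y = m.X, m.y
    tp = tn = fp = fn = 0
    per_repeat_rows = []
    rep_conf = np.zeros(4, dtype=int)  # tp, tn, fp, fn within current repeat
    fold_details = []
    for fold_i, (tr, te) in enumerate(rskf.split(X, y)):
        train = FeatureMatrix(X=X.iloc[tr], y=y[tr])
        params, sel, feats, clf = _fit_fold(train, selection_method,
                                            classifier_config, seed + fold_i,
                                            k_neighbors, selection_kwargs)
        Zte = apply_normalizer(params, X.iloc[te])
        pred = clf.predict(Zte[feats].to_numpy(float))
        yt = y[te]
        f_tp = int(np.sum((pred == POSITIVE_LABEL) & (yt == POSITIVE_LABEL)))
        f_tn = int(np.sum((pred != POSITIVE_LABEL) & (yt != POSITIVE_LABEL)))
        f_fp = int(np.sum((pred == POSITIVE_LABEL) & (yt != POSITIVE_LABEL)))
        f_fn = int(np.sum((pred != POSITIVE_LABEL) & (yt == POSITIVE_LABEL)))
        tp, tn, fp, fn = tp + f_tp, tn + f_tn, fp + f_fp, fn + f_fn
        rep_conf += (f_tp, f_tn, f_fp, f_fn)
        fold_details.append({
            "fold": fold_i, "test_index": te.tolist(), "selected": feats,
            "normalizer_mean": params.mean.to_numpy().copy(),
            "normalizer_sd": params.sd.to_numpy().copy(),
        })
        if (fold_i + 1) % folds == 0:
            r_tp, r_tn, r_fp, r_fn = map(int, rep_conf)
            per_repeat_rows.append({
                "repeat": fold_i // folds,
                "accuracy": (r_tp + r_tn) / rep_conf.sum(),
                "recall": r_tp / (r_tp + r_fn) if r_tp + r_fn else np.nan,
                "precision": r_tp / (r_tp + r_fp) if r_tp + r_fp else np.nan,
            })
            rep_conf[:] = 0
    pooled = {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }
    return CVReport(folds=folds, repeats=repeats, seed=seed,
                    selection_method=selection_method, pooled=pooled,
                    per_repeat=pd.DataFrame(per_repeat_rows),
                    fold_details=fold_details,
                    confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn})


# ---------------------------------------------------------------------------
# final fit / prediction

@dataclass
class FittedPipeline:
    normalizer: NormalizerParams
    selection: SelectionResult
    features: list[str]
    classifier: object
    classes_: np.ndarray

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Label and calibrated positive-class probability per row."""
        if not isinstance(X, pd.DataFrame):
            raise SchemaError("predict expects a feature DataFrame")
        Z = apply_normalizer(self.normalizer, X)
        prob = self.classifier.predict_proba(Z[self.features].to_numpy(float))
        pos_col = int(np.flatnonzero(self.classes_ == POSITIVE_LABEL)[0])
        label = self.classes_[prob.argmax(axis=1)]
        return pd.DataFrame({"label": label, "probability": prob[:, pos_col]},
                            index=X.index)


def fit_pipeline(m: FeatureMatrix, selection_method: str = "all",
                 classifier_config=None, seed: int = 0, k_neighbors: int = 5,
                 selection_kwargs: dict | None = None) -> FittedPipeline:
    """Fit oversample -> normalize -> select -> classify on the full matrix."""
    params, sel, feats, clf = _fit_fold(m, selection_method, classifier_config,
                                        seed, k_neighbors, selection_kwargs or {})
    return FittedPipeline(normalizer=params, selection=sel, features=feats,
                          classifier=clf, classes_=clf.classes_)


def compare_selection(m: FeatureMatrix, methods=SELECTION_METHODS,
                      classifier_config=None, folds: int = 5, repeats: int = 10,
                      seed: int = 0, **kwargs) -> pd.DataFrame:
    """One-command selection-route comparison: methods x metrics table
    (pooled and mean-over-repeats values)."""
    rows = []
    for method in methods:
        rep = cross_validate(m, selection_method=method,
                             classifier_config=classifier_config, folds=folds,
                             repeats=repeats, seed=seed, **kwargs)
        rows.append({
            "method": method,
            **{f"pooled_{k}": v for k, v in rep.pooled.items()},
            **{f"repeat_mean_{k}": rep.per_repeat[k].mean()
               for k in ("accuracy", "recall", "precision")},
            "mean_n_selected": float(np.mean([len(d["selected"])
                                              for d in rep.fold_details])),
        })
    return pd.DataFrame(rows)
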