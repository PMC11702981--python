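"""Linear maximum-margin classification of p53 functional status.

A linear-kernel SVM is trained on the seven CES features of adjacent normal
tissue (NT, coded 0) versus TP53-truncated tumors (TM, coded 1). Applied to
wild-type (WT) and missense (MM) tumors, a positive decision value labels a
sample pRF (predicted reduced function) and a negative one pN (predicted
normal). A ten-repeat stratified 75/25 hold-out scheme — with gene-set
re-selection and CES refitting inside every training partition — estimates
generalization, and an agglomerative-clustering fallback covers cohorts too
small to train on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .ces import CES_COLUMNS, CESModel
from .cohort import ExpressionCohort
from .feature_selection import differential_expression, select_gene_sets

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class TrainedClassifier:
    """Linear decision rule over the seven CES features.

    The decision value of a sample x is ``w . (x - mu) / scale + b``; under
    the 0 = NT / 1 = TM coding, positive values mean reduced p53 function.
    """

    weights: list[float]
    bias: float
    C: float
    feature_means: list[float]
    feature_scales: list[float]
    feature_names: list[str] = field(default_factory=lambda: list(CES_COLUMNS))
    label_coding: dict = field(default_factory=lambda: {"0": "NT/normal", "1": "TM/reduced"})
    seed: int = 0
    train_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.feature_names):
            raise ValueError("one weight per feature required")
        if any(s <= 0 for s in self.feature_scales):
            raise ValueError("feature scales must be positive")

    def decision_function(self, features: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        x = features[self.feature_names].to_numpy(dtype=float)
        z = (x - np.asarray(self.feature_means)) / np.asarray(self.feature_scales)
        return pd.Series(z @ np.asarray(self.weights) + self.bias, index=features.index)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TrainedClassifier":
        with open(path) as fh:
            return cls(**json.load(fh))


def train(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    C_grid=DEFAULT_C_GRID,
    seed: int = 0,
    kernel: str = "linear",
    class_weight=None,
) -> TrainedClassifier:
    """Fit the linear SVM with internal cross-validated grid search over C.

    Features are standardized with training-set statistics; the
    regularization constant is chosen by stratified k-fold accuracy
    (k = min(5, smallest class size)). Deterministic given the seed.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires both classes (0 = NT, 1 = TM)")
    if len(y) < 4:
        raise ValueError("training requires at least 4 samples")
    missing = [c for c in CES_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature columns missing: {missing}")
    x = features[list(CES_COLUMNS)].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    z = (x - mu) / scale

    n_splits = int(min(5, counts.min()))
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        search = GridSearchCV(SVC(kernel=kernel, class_weight=class_weight), {"C": list(C_grid)}, cv=cv)
        search.fit(z, y)
        svm, best_c = search.best_estimator_, float(search.best_params_["C"])
    else:
        warnings.warn("too few samples per class for cross-validation; using the smallest C")
        best_c = float(sorted(C_grid)[0])
        svm = SVC(kernel=kernel, C=best_c, class_weight=class_weight).fit(z, y)
    if kernel != "linear":
        raise ValueError("only the linear kernel yields an explicit weight vector")
    return TrainedClassifier(
        weights=[float(w) for w in svm.coef_[0]],
        bias=float(svm.intercept_[0]),
        C=best_c,
        feature_means=[float(v) for v in mu],
        feature_scales=[float(v) for v in scale],
        seed=seed,
        train_samples=[str(s) for s in features.index],
    )


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Recall, precision, accuracy and F1 from a confusion matrix.

    Zero-denominator ratios are reported as NaN with a warning rather than
    silently coerced to 0.
    """
    if c.total == 0:
        raise ValueError("no evaluated samples")

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    accuracy = (c.tp + c.tn) / c.total
    if recall and precision and not (np.isnan(recall) or np.isnan(precision)):
        f1 = 2.0 / (1.0 / recall + 1.0 / precision)
    else:
        warnings.warn("F1 undefined (zero recall or precision); reporting NaN")
        f1 = float("nan")
    return {"recall": recall, "precision": precision, "accuracy": accuracy, "f1": f1}


def roc_auc(scores, labels) -> float:
    """AUROC as the probability a random positive outscores a random negative.

    Computed from the rank-sum (Mann-Whitney) statistic; ties count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    from scipy.stats import rankdata

    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ValidationReport:
    """Per-repeat hold-out metrics plus their means and selected gene sets."""

    per_repeat: pd.DataFrame
    gene_sets: list[dict]

    @property
    def means(self) -> dict[str, float]:
        cols = ["recall", "precision", "accuracy", "f1", "auroc"]
        return {c: float(self.per_repeat[c].mean()) for c in cols}


def holdout_validate(
    counts: ExpressionCohort,
    log2fpkm: ExpressionCohort,
    candidates: pd.DataFrame,
    split: float = 0.75,
    repeats: int = 10,
    seed: int = 0,
    C_grid=DEFAULT_C_GRID,
    adj_p_max: float = 0.05,
    min_abs_fc: float = 2.0,
    fallback_top_n: int = 10,
    labels: pd.Series | None = None,
) -> ValidationReport:
    """Repeated stratified hold-out validation of the full NT-vs-TM pipeline.

    Each repeat splits the NT and TM samples 75/25, then derives everything
    — differential expression, DR/UR gene sets, CES parameters, feature
    standardization, and the SVM — from the training partition alone, and
    scores the held-out partition. ``labels`` overrides the sample-sheet
    groups (used by permutation-null experiments).
    """
    nt = counts.group_samples("NT")
    tm = counts.group_samples("TM")
    samples = nt + tm
    if labels is None:
        y_all = pd.Series([0] * len(nt) + [1] * len(tm), index=samples)
    else:
        y_all = labels.loc[samples].astype(int)
    if y_all.value_counts().min() < 4:
        raise ValueError("need at least 4 samples per class to split with both classes on both sides")

    rows = []
    gene_sets: list[dict] = []
    cand_genes = list(candidates["gene"])
    for rep in range(repeats):
        tr, te = train_test_split(
            samples, train_size=split, random_state=seed * 1000 + rep, stratify=y_all
        )
        y_tr, y_te = y_all.loc[tr], y_all.loc[te]
        de = differential_expression(
            counts,
            [s for s in tr if y_tr[s] == 0],
            [s for s in tr if y_tr[s] == 1],
            genes=cand_genes,
        )
        pair = select_gene_sets(
            de, adj_p_max=adj_p_max, min_abs_fc=min_abs_fc, fallback_top_n=fallback_top_n
        )
        gene_sets.append({"repeat": rep, "dr": list(pair.dr), "ur": list(pair.ur)})

        ces_model = CESModel().fit(
            log2fpkm.matrix[tr],
            pair,
            [s for s in tr if y_tr[s] == 0],
            [s for s in tr if y_tr[s] == 1],
        )
        model = train(ces_model.transform(log2fpkm.matrix[tr]), y_tr, C_grid=C_grid, seed=seed + rep)
        scores = model.decision_function(ces_model.transform(log2fpkm.matrix[te]))
        pred = (scores > 0).astype(int)
        cc = ConfusionCounts(
            tp=int(((pred == 1) & (y_te == 1)).sum()),
            fp=int(((pred == 1) & (y_te == 0)).sum()),
            tn=int(((pred == 0) & (y_te == 0)).sum()),
            fn=int(((pred == 0) & (y_te == 1)).sum()),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = compute_metrics(cc)
        metrics["auroc"] = roc_auc(scores.to_numpy(), y_te.to_numpy())
        rows.append({"repeat": rep, **{k: getattr(cc, k) for k in ("tp", "fp", "tn", "fn")}, **metrics})
    return ValidationReport(pd.DataFrame(rows).set_index("repeat"), gene_sets)


def predict(model: TrainedClassifier, features: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Label WT/MM samples pRF (decision value > 0) or pN.

    Returns a table with the original group, the signed decision value and
    the predicted label; an empty feature table yields an empty result.
    """
    if features.empty:
        return pd.DataFrame(columns=["group", "decision_value", "predicted"])
    scores = model.decision_function(features)
    out = pd.DataFrame(
        {
            "group": groups.loc[features.index] if groups is not None else pd.NA,
            "decision_value": scores,
            "predicted": np.where(scores > 0, "pRF", "pN"),
        },
        index=features.index,
    )
    return out


def cluster_predict(features: pd.DataFrame, nt_ref: list[str], tm_ref: list[str]) -> pd.DataFrame:
    """Unsupervised fallback: two-cluster Ward clustering on standardized CES.

    The cluster whose centroid lies nearer the NT reference centroid is
    labelled pN, the other pRF. Both reference id lists must be non-empty
    and present in the feature table.
    """
    nt_ref, tm_ref = list(nt_ref), list(tm_ref)
    if not nt_ref or not tm_ref:
        raise ValueError("both NT and TM reference sample ids are required")
    for sid in nt_ref + tm_ref:
        if sid not in features.index:
            raise ValueError(f"reference sample {sid!r} not in the feature table")
    if len(features) < 4:
        raise ValueError("clustering needs at least 4 samples")
    x = features[list(CES_COLUMNS)].to_numpy(dtype=float)
    scale = x.std(axis=0, ddof=0)
    if (scale == 0).all():
        raise ValueError("degenerate input: all samples identical")
    scale[scale == 0] = 1.0
    z = (x - x.mean(axis=0)) / scale
    assign = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(z)
    zf = pd.DataFrame(z, index=features.index)
    cent = {c: zf[assign == c].mean(axis=0).to_numpy() for c in (0, 1)}
    nt_cent = zf.loc[nt_ref].mean(axis=0).to_numpy()
    tm_cent = zf.loc[tm_ref].mean(axis=0).to_numpy()
    # relative affinity of each cluster centroid for the NT anchor
    pull = {c: np.linalg.norm(cent[c] - nt_cent) - np.linalg.norm(cent[c] - tm_cent) for c in (0, 1)}
    pn_cluster = min(pull, key=pull.get)
    labels = np.where(assign == pn_cluster, "pN", "pRF")
    return pd.DataFrame({"cluster": assign, "predicted": labels}, index=features.index)
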