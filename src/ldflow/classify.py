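"""Two-class linear discriminant classification and ROC/AUC evaluation.

The feature triples (AbC, DBP, <v>31) are small-cohort inputs; a linear
discriminant with pooled within-class covariance and equal priors is the
matching classifier.  Classifiers are carried around as an explicit affine
score ``Y = intercept + sum_j w_j x_j`` whose decision boundary is
``Y = 0``, so the reference discriminant functions from the clinical study
that introduced the AbC statistic can be stored alongside freshly fitted
ones.  AUC is the tie-aware Mann-Whitney statistic: the probability that a
random positive scores above a random negative, ties credited one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve

from .errors import LabelError, MissingFeatureError, SingularCovarianceError
from .protocol import FeatureVector

__all__ = [
    "LinearClassifier",
    "RocResult",
    "reference_classifier",
    "REFERENCE_CLASSIFIERS",
    "discriminant_score",
    "fit_lda",
    "roc_auc",
    "compare_feature_sets",
    "DEFAULT_FEATURE_SETS",
]


@dataclass(frozen=True)
class LinearClassifier:
    """Affine discriminant score with a named, ordered coefficient map.

    ``provenance`` is ``"fitted"`` for models estimated from data and
    ``"published"`` for the stored reference discriminants.
    """

    intercept: float
    coefficients: dict[str, float]
    positive_label: str | None = None
    provenance: str = "fitted"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise MissingFeatureError("classifier has non-finite parameters")

    @property
    def feature_order(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


# Reference discriminant functions of the thermal-test feature space, in the
# (abc, dbp) mapping; the boundary Y = 0 separates the named pairs.
#   patients-vs-older:  Y = -5.0622  + 0.84 * x1 + 0.0177 * x2
#   younger-vs-older:   Y = -4.28022 + 0.86 * x1 + 0.0076 * x2
_REFERENCE_PARAMS = {
    "patients-vs-older": (-5.0622, (0.84, 0.0177), "older-volunteers"),
    "younger-vs-older": (-4.28022, (0.86, 0.0076), "older-volunteers"),
}


def reference_classifier(
    name: str, feature_order: tuple[str, str] = ("abc", "dbp")
) -> LinearClassifier:
    """A stored reference discriminant by name.

    ``"patients-vs-older"`` separates diabetic patients from older healthy
    volunteers; ``"younger-vs-older"`` separates the two healthy age
    groups.  The source reports the two coefficients without units, so the
    mapping of (AbC, DBP) onto the coefficient order is configurable via
    `feature_order`; the default assigns the larger coefficient to AbC
    (DBP spans a larger numeric range).
    """
    try:
        intercept, coefs, positive = _REFERENCE_PARAMS[name]
    except KeyError:
        raise KeyError(
            f"unknown reference classifier {name!r}; choose from {sorted(_REFERENCE_PARAMS)}"
        ) from None
    if len(feature_order) != 2:
        raise MissingFeatureError("reference classifiers take exactly two features")
    return LinearClassifier(
        intercept=intercept,
        coefficients=dict(zip(feature_order, coefs)),
        positive_label=positive,
        provenance="published",
        meta={"name": name, "feature_order_mapping": "configurable"},
    )


REFERENCE_CLASSIFIERS = tuple(_REFERENCE_PARAMS)


def _feature_values(
    clf: LinearClassifier, features: FeatureVector | Mapping[str, float] | Sequence[float]
) -> np.ndarray:
    if isinstance(features, FeatureVector):
        features = features.as_dict()
    if isinstance(features, Mapping):
        vals = []
        for name in clf.feature_order:
            if name not in features:
                raise MissingFeatureError(f"feature {name!r} missing from input")
            vals.append(features[name])
    else:
        vals = list(features)
        if len(vals) != len(clf.feature_order):
            raise MissingFeatureError(
                f"expected {len(clf.feature_order)} features "
                f"{clf.feature_order}, got {len(vals)}"
            )
    arr = np.asarray(vals, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise MissingFeatureError("features must be finite")
    return arr


def discriminant_score(
    clf: LinearClassifier,
    features: FeatureVector | Mapping[str, float] | Sequence[float],
) -> float:
    """Affine score ``intercept + sum(w * x)`` in the classifier's feature order."""
    x = _feature_values(clf, features)
    w = np.array(list(clf.coefficients.values()))
    return float(clf.intercept + w @ x)


def _two_classes(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise LabelError(f"need exactly two classes, got {list(classes)}")
    return y, classes


def fit_lda(
    features: pd.DataFrame | Sequence[FeatureVector],
    labels: Sequence | None = None,
    feature_names: Sequence[str] | None = None,
    ridge: bool = False,
    positive_label: str | None = None,
) -> LinearClassifier:
    """Two-class LDA with pooled covariance and equal priors.

    `features` is either a DataFrame of feature columns or a sequence of
    :class:`~ldflow.protocol.FeatureVector` (then `labels` defaults to their
    ``group`` fields).  The fitted hyperplane is returned as an affine score
    with boundary 0; scores are positive towards `positive_label` (default:
    the lexicographically larger class).  A singular pooled covariance
    raises :class:`~ldflow.errors.SingularCovarianceError` unless
    ``ridge=True`` enables Ledoit-Wolf shrinkage.
    """
    if isinstance(features, pd.DataFrame):
        names = list(feature_names) if feature_names else list(features.columns)
        X = features[names].to_numpy(dtype=float)
    else:
        fvs = list(features)
        names = list(feature_names) if feature_names else ["abc", "dbp", "dv31"]
        X = np.array([[fv.as_dict()[n] for n in names] for fv in fvs])
        if labels is None:
            labels = [fv.group for fv in fvs]
    if labels is None:
        raise LabelError("labels are required")
    y, classes = _two_classes(labels)
    counts = [np.sum(y == c) for c in classes]
    if min(counts) < 2:
        raise LabelError(f"need at least 2 samples per class, got {counts}")
    if positive_label is not None:
        if positive_label not in classes:
            raise LabelError(f"positive_label {positive_label!r} not among {list(classes)}")
        order = [c for c in classes if c != positive_label] + [positive_label]
    else:
        order = list(classes)
    y01 = (y == order[1]).astype(int)

    # pooled within-class covariance; singularity check before delegating
    centred = np.vstack([X[y01 == g] - X[y01 == g].mean(axis=0) for g in (0, 1)])
    pooled = centred.T @ centred / max(len(X) - 2, 1)
    rank = np.linalg.matrix_rank(pooled, tol=1e-10 * max(1.0, np.abs(pooled).max()))
    shrinkage = None
    if rank < X.shape[1]:
        if not ridge:
            raise SingularCovarianceError(
                "pooled within-class covariance is singular; pass ridge=True"
            )
        shrinkage = "auto"

    lda = LinearDiscriminantAnalysis(
        solver="lsqr", priors=[0.5, 0.5], shrinkage=shrinkage
    )
    lda.fit(X, y01)
    return LinearClassifier(
        intercept=float(lda.intercept_[0]),
        coefficients=dict(zip(names, lda.coef_[0].astype(float))),
        positive_label=str(order[1]),
        provenance="fitted",
        meta={"classes": [str(c) for c in order], "n": len(X), "ridge": shrinkage is not None},
    )


@dataclass(frozen=True)
class RocResult:
    """ROC points and area under the curve."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence) -> RocResult:
    """ROC curve and tie-aware AUC of a score against two-class labels.

    AUC is the Mann-Whitney U statistic normalised by ``n_pos * n_neg``
    (rank-based, ties credited 0.5); the positive class is the
    lexicographically larger label.
    """
    s = np.asarray(scores, dtype=float)
    y, classes = _two_classes(labels)
    pos = y == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(s)
    u = float(ranks[pos].sum() - n_pos * (n_pos + 1) / 2)
    auc = u / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(pos.astype(int), s)
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


#: Feature subsets evaluated by default, single features first, then the
#: pairwise and full combinations.
DEFAULT_FEATURE_SETS: tuple[tuple[str, ...], ...] = (
    ("dbp",),
    ("abc",),
    ("dv31",),
    ("dbp", "abc"),
    ("dbp", "dv31"),
    ("dbp", "abc", "dv31"),
)


def compare_feature_sets(
    table: pd.DataFrame,
    feature_sets: Sequence[Sequence[str]] = DEFAULT_FEATURE_SETS,
    label_col: str = "group",
    positive_label: str | None = None,
    ridge: bool = False,
) -> pd.DataFrame:
    """In-sample LDA AUC for each feature subset of a cohort table.

    For every subset an LDA is fitted on those columns and the AUC of its
    in-sample scores is reported (no resampling; appropriate for the small
    cohorts this method targets, and flagged as in-sample in the output).
    """
    y = table[label_col]
    rows = []
    for subset in feature_sets:
        subset = tuple(subset)
        if not subset:
            raise MissingFeatureError("empty feature subset")
        clf = fit_lda(
            table[list(subset)], y, ridge=ridge, positive_label=positive_label
        )
        s = [discriminant_score(clf, dict(zip(subset, row))) for row in
             table[list(subset)].to_numpy(dtype=float)]
        rows.append(
            {
                "features": "+".join(subset),
                "n_features": len(subset),
                "auc": roc_auc(s, y).auc,
                "evaluation": "in-sample",
            }
        )
    return pd.DataFrame(rows)
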