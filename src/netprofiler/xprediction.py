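"""Edge-knockout explainable prediction (Xprediction).

Which molecular interactions drive a phenotype prediction?  The procedure
classifies samples as drug *sensitive* (sensitivity below the 5th
percentile) or *resistant* (above the 95th percentile), trains a classifier
on the per-sample regulatory-effect features (one feature per network edge),
and measures each edge's importance as the significance of the accuracy
drop when that edge's feature column is removed:

1. compute the k-fold cross-validated accuracy of the full model, repeated
   N times on freshly randomized fold splits -> N baseline accuracies;
2. for each edge (l, j), remove its column and recompute N knockout
   accuracies on fresh fold splits;
3. compare the two accuracy samples by a pooled two-sample t-test; the edge
   importance is the (two-sided) p value, with p < alpha flagging crucial
   edges.

Classifiers: an RBF-kernel SVM, a random forest, or a two-hidden-layer
feed-forward network (ReLU hidden layers, sigmoid output).  Repeat-level CV
accuracies are not independent samples, so the t-test is heuristic; its
type-I error can be mildly inflated.

Cost: one baseline plus one model family per candidate edge — (q*p)+1
cross-validated model fits in the worst case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from numpy.typing import ArrayLike, NDArray
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .effects import RegulatoryEffectSet
from .exceptions import (
    DegenerateLabelingError,
    InvalidParameterError,
)

__all__ = [
    "LabeledEffects",
    "PredictorSpec",
    "AccuracyRecord",
    "label_by_percentile",
    "cv_accuracy",
    "knockout_accuracy",
    "pooled_t_test",
    "xprediction",
    "EdgeKnockoutImportance",
]


@dataclass
class LabeledEffects:
    """Edge features and binary labels for the labeled (extreme) samples."""

    features: NDArray[np.float64]  # (n_labeled, E)
    labels: NDArray[np.intp]  # 1 = sensitive, 0 = resistant
    edge_index: list[tuple[str, str]]  # (target, regulator) per column
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != len(self.labels):
            raise InvalidParameterError("features and labels disagree in length")
        if self.features.shape[1] != len(self.edge_index):
            raise InvalidParameterError("edge index does not match feature count")
        if self.features.shape[1] < 1:
            raise InvalidParameterError("at least one edge feature is required")
        classes = np.unique(self.labels)
        if not np.array_equal(classes, [0, 1]):
            raise DegenerateLabelingError(
                "both sensitive and resistant classes must be present"
            )


@dataclass
class PredictorSpec:
    """Classifier family, hyperparameters and CV design.

    ``n_repeats`` is the number N of repeated k-fold CV rounds whose
    accuracies form the baseline sample; knockouts use the same N with
    fresh fold seeds.
    """

    model: str = "feedforward_nn"
    hyperparameters: Mapping | None = None
    cv_folds: int = 10
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("kernel_svm", "random_forest", "feedforward_nn"):
            raise InvalidParameterError(f"unknown model {self.model!r}")
        if self.cv_folds < 2:
            raise InvalidParameterError("cv_folds must be >= 2")
        if self.n_repeats < 2:
            raise InvalidParameterError("n_repeats must be >= 2")


@dataclass
class AccuracyRecord:
    """Repeat-level CV accuracies of one model configuration."""

    accuracies: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise InvalidParameterError("accuracies must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.accuracies)

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.n > 1 else 0.0


def label_by_percentile(
    sensitivity: ArrayLike,
    low_p: float = 5.0,
    high_p: float = 95.0,
) -> tuple[NDArray[np.intp], NDArray[np.intp], NDArray[np.intp]]:
    """Binary sensitive/resistant labels from strict percentile cutoffs.

    Sensitive: sensitivity < ``low_p``-th percentile (label 1); resistant:
    sensitivity > ``high_p``-th percentile (label 0); everything else is
    excluded.  Percentiles use linear interpolation; the strict inequalities
    mean boundary samples are excluded.  Returns
    ``(labels, labeled_indices, excluded_indices)``.
    """
    if not low_p < high_p:
        raise InvalidParameterError("low_p must be smaller than high_p")
    s = np.asarray(sensitivity, dtype=float)
    if s.ndim != 1:
        raise InvalidParameterError("sensitivity must be a vector")
    lo, hi = np.percentile(s, [low_p, high_p], method="linear")
    sensitive = s < lo
    resistant = s > hi
    if sensitive.sum() < 2 or resistant.sum() < 2:
        raise DegenerateLabelingError(
            f"need >= 2 samples per class, got {int(sensitive.sum())} "
            f"sensitive and {int(resistant.sum())} resistant"
        )
    labeled = np.nonzero(sensitive | resistant)[0]
    labels = sensitive[labeled].astype(int)
    excluded = np.nonzero(~(sensitive | resistant))[0]
    return labels, labeled, excluded


def _build_model(spec: PredictorSpec, seed: int):
    hp = dict(spec.hyperparameters or {})
    if spec.model == "kernel_svm":
        clf = SVC(kernel="rbf", **hp)
    elif spec.model == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            random_state=seed,
            n_jobs=1,
            **hp,
        )
    else:  # two-hidden-layer feed-forward net, ReLU hidden, sigmoid output
        clf = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64, 32)),
            activation="relu",
            early_stopping=hp.pop("early_stopping", True),
            max_iter=hp.pop("max_iter", 300),
            random_state=seed,
            **hp,
        )
    # features are effect values on wildly different scales; standardize
    # inside each training fold
    return make_pipeline(StandardScaler(), clf)


def _stream_seed(seed: int, stream: int, repeat: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(stream, repeat))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _cv_accuracies(
    X: NDArray, y: NDArray, spec: PredictorSpec, stream: int, n_repeats: int
) -> NDArray[np.float64]:
    from sklearn.model_selection import StratifiedKFold

    counts = np.bincount(y, minlength=2)
    if counts.min() < spec.cv_folds:
        raise InvalidParameterError(
            f"each class needs >= cv_folds={spec.cv_folds} members, "
            f"got {counts.tolist()}"
        )
    accs = np.empty(n_repeats)
    for rep in range(n_repeats):
        rs = _stream_seed(spec.seed, stream, rep)
        skf = StratifiedKFold(
            n_splits=spec.cv_folds, shuffle=True, random_state=rs
        )
        fold_accs = []
        for fold_i, (train, test) in enumerate(skf.split(X, y)):
            model = _build_model(spec, seed=(rs + fold_i) % (2**31 - 1))
            model.fit(X[train], y[train])
            fold_accs.append(float(np.mean(model.predict(X[test]) == y[test])))
        accs[rep] = float(np.mean(fold_accs))
    return accs


def cv_accuracy(data: LabeledEffects, spec: PredictorSpec) -> AccuracyRecord:
    """Baseline repeated k-fold CV accuracy of the full-feature model.

    Folds are stratified; each of the N repeats uses a fresh seeded fold
    split, and the per-repeat accuracy is the mean over the k validation
    folds.  Identical spec (including seed) gives identical accuracies.
    """
    return AccuracyRecord(
        _cv_accuracies(data.features, data.labels, spec, stream=0,
                       n_repeats=spec.n_repeats)
    )


def knockout_accuracy(
    data: LabeledEffects,
    spec: PredictorSpec,
    edge: tuple[str, str],
    n_repeats: int | None = None,
) -> AccuracyRecord:
    """CV accuracy after removing one edge's feature column entirely.

    The column is removed (not zeroed) so the knocked-out model has one
    fewer input; fold splits use fresh seeds distinct from the baseline's.
    """
    edge = (str(edge[0]), str(edge[1]))
    try:
        pos = data.edge_index.index(edge)
    except ValueError:
        raise InvalidParameterError(f"unknown edge {edge!r}") from None
    if data.features.shape[1] == 1:
        raise InvalidParameterError(
            "cannot knock out the only feature column"
        )
    X = np.delete(data.features, pos, axis=1)
    return AccuracyRecord(
        _cv_accuracies(X, data.labels, spec, stream=1 + pos,
                       n_repeats=n_repeats or spec.n_repeats)
    )


def pooled_t_test(
    full: AccuracyRecord,
    knockout: AccuracyRecord,
    as_printed: bool = False,
) -> tuple[float, float]:
    """Pooled two-sample t-test between baseline and knockout accuracies.

    T = (mean_full - mean_knockout) / (s_p sqrt(1/N + 1/N')), with s_p the
    textbook pooled standard deviation
    sqrt(((N-1)s^2 + (N'-1)s'^2) / (N+N'-2)); ``as_printed=True`` instead
    uses the unsquared, unrooted variant (s(N-1) + s'(N'-1))/(N+N'-2) for
    comparison with software following that convention.  Returns the
    two-sided (T, p) from the t distribution with N+N'-2 degrees of freedom.
    """
    N, Np = full.n, knockout.n
    if N < 2 or Np < 2:
        raise InvalidParameterError("both records need at least 2 repeats")
    df = N + Np - 2
    if as_printed:
        sp = (full.sd * (N - 1) + knockout.sd * (Np - 1)) / df
    else:
        sp = math.sqrt(
            ((N - 1) * full.sd**2 + (Np - 1) * knockout.sd**2) / df
        )
    diff = full.mean - knockout.mean
    if sp == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    T = diff / (sp * math.sqrt(1.0 / N + 1.0 / Np))
    p = 2.0 * float(stats.t.sf(abs(T), df))
    return T, min(p, 1.0)


def _labeled_effects(
    effects: RegulatoryEffectSet,
    sensitivity: ArrayLike,
    low_p: float,
    high_p: float,
) -> LabeledEffects:
    s = np.asarray(sensitivity, dtype=float)
    if len(s) != len(effects.sample_ids):
        raise InvalidParameterError(
            "sensitivity length must match the number of samples"
        )
    features, edge_index = effects.feature_matrix()
    labels, labeled, excluded = label_by_percentile(s, low_p, high_p)
    return LabeledEffects(
        features[labeled],
        labels,
        edge_index,
        [effects.sample_ids[i] for i in excluded],
    )


def xprediction(
    effects: RegulatoryEffectSet | LabeledEffects,
    sensitivity: ArrayLike | None = None,
    spec: PredictorSpec | None = None,
    alpha: float = 0.05,
    edge_subset: Sequence[tuple[str, str]] | None = None,
    low_p: float = 5.0,
    high_p: float = 95.0,
    adjust: str | None = None,
    threads: int = 1,
    baseline: AccuracyRecord | None = None,
) -> pd.DataFrame:
    """Rank edges by the significance of their knockout accuracy drop.

    The baseline accuracy record is computed exactly once and shared by all
    knockouts.  The returned table (one row per tested edge, sorted by p
    ascending) has columns target, regulator, T, p, mean_drop and
    significant (raw p < alpha); ``adjust="bh"`` adds a
    Benjamini-Hochberg-adjusted column ``p_adj`` and bases the flag on it.
    Results are independent of ``threads``.
    """
    spec = spec or PredictorSpec()
    if isinstance(effects, LabeledEffects):
        data = effects
    else:
        if sensitivity is None:
            raise InvalidParameterError(
                "sensitivity is required with a RegulatoryEffectSet input"
            )
        data = _labeled_effects(effects, sensitivity, low_p, high_p)

    edges = list(data.edge_index)
    if edge_subset is not None:
        wanted = [(str(t), str(r)) for t, r in edge_subset]
        missing = [e for e in wanted if e not in set(edges)]
        if missing:
            raise InvalidParameterError(f"unknown edges in subset: {missing}")
        edges = wanted
    if not edges:
        raise InvalidParameterError("no candidate edges to test")

    if baseline is None:
        baseline = cv_accuracy(data, spec)

    def test_edge(edge):
        rec = knockout_accuracy(data, spec, edge)
        T, p = pooled_t_test(baseline, rec)
        return edge[0], edge[1], T, p, baseline.mean - rec.mean

    rows = Parallel(n_jobs=threads, prefer="threads")(
        delayed(test_edge)(e) for e in edges
    )
    table = pd.DataFrame(
        rows, columns=["target", "regulator", "T", "p", "mean_drop"]
    )
    if adjust is not None:
        if adjust != "bh":
            raise InvalidParameterError(f"unknown adjustment {adjust!r}")
        table["p_adj"] = stats.false_discovery_control(table["p"], method="bh")
        table["significant"] = table["p_adj"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    table = table.sort_values(
        ["p", "target", "regulator"], kind="stable"
    ).reset_index(drop=True)
    return table


class EdgeKnockoutImportance(BaseEstimator):
    """Edge-importance estimator (scikit-learn style wrapper of xprediction).

    After ``fit`` the attributes ``results_`` (the importance table),
    ``baseline_`` (the full-model :class:`AccuracyRecord`) and
    ``excluded_samples_`` are available.
    """

    def __init__(self, model: str = "feedforward_nn",
                 hyperparameters: Mapping | None = None, cv_folds: int = 10,
                 n_repeats: int = 20, alpha: float = 0.05,
                 low_percentile: float = 5.0, high_percentile: float = 95.0,
                 adjust: str | None = None, seed: int = 0, threads: int = 1):
        self.model = model
        self.hyperparameters = hyperparameters
        self.cv_folds = cv_folds
        self.n_repeats = n_repeats
        self.alpha = alpha
        self.low_percentile = low_percentile
        self.high_percentile = high_percentile
        self.adjust = adjust
        self.seed = seed
        self.threads = threads

    def _spec(self) -> PredictorSpec:
        return PredictorSpec(
            model=self.model, hyperparameters=self.hyperparameters,
            cv_folds=self.cv_folds, n_repeats=self.n_repeats, seed=self.seed,
        )

    def fit(self, X: RegulatoryEffectSet | LabeledEffects, y: ArrayLike | None = None,
            *, edge_subset=None):
        """X: effect set (with y = per-sample sensitivity) or LabeledEffects."""
        spec = self._spec()
        if isinstance(X, LabeledEffects):
            data = X
        else:
            data = _labeled_effects(
                X, y, self.low_percentile, self.high_percentile
            )
        self.baseline_ = cv_accuracy(data, spec)
        self.results_ = xprediction(
            data, spec=spec, alpha=self.alpha, edge_subset=edge_subset,
            adjust=self.adjust, threads=self.threads, baseline=self.baseline_,
        )
        self.excluded_samples_ = list(data.excluded_samples)
        return self
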