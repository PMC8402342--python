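"""Multi-class classifiers and the 4-band likelihood-ratio clinical metric block.

A trained classifier emits a per-sample probability triplet
(P(bacterial), P(viral), P(noninfected)).  For each diagnostic class the
one-vs-rest score axis is cut into four interpretation bands by thresholds
``t1 < t2 < t3``:

- band 1 ``[0, t1)`` — rule-out: the class is called absent;
- bands 2-3 — intermediate;
- band 4 ``[t3, 1]`` — rule-in: the class is called present.

Clinical utility is summarized per class as:

- ``auroc`` — one-vs-rest area under the ROC curve (rank / Mann-Whitney form);
- ``lr_minus = P(band1 | positive) / P(band1 | negative)`` — how strongly a
  band-1 score argues against the diagnosis (0 is a perfect rule-out);
- ``band1_sensitivity`` — sensitivity of the *not-band-1* call, i.e.
  100 * P(bands 2-4 | positive);
- ``lr_plus = P(band4 | positive) / P(band4 | negative)`` — how strongly a
  band-4 score argues for the diagnosis (infinite when no negative reaches
  band 4);
- ``band4_specificity`` — specificity of the *not-band-4* call, i.e.
  100 * P(bands 1-3 | negative);
- ``fraction1`` / ``fraction4`` — percentage of *all* samples falling in the
  extreme bands (how often the test returns an actionable call).

The band fractions obey an exact prevalence-weighted identity on any finite
dataset: with prevalence pi of the positive class,

    fraction_b / 100 = pi * P(band b | pos) + (1 - pi) * P(band b | neg)

so e.g. ``fraction4 = (1 - spec4/100) * (pi * LR+ + 1 - pi) * 100``.  This
identity is exposed as :func:`band_fraction_from_likelihood_ratio` and used
as a consistency oracle in the tests.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted


@contextmanager
def _quiet_fit():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """One-vs-rest AUROC as the normalized Mann-Whitney U statistic.

    ``auroc = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg)``
    with midranks for ties, equal to the probability that a random positive
    outscores a random negative (ties counted half).

    Parameters
    ----------
    scores : array-like of float
    labels : array-like of bool/int, truthy = positive

    Raises
    ------
    ValueError if either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both positive and negative labels are required")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mauroc(proba: pd.DataFrame | np.ndarray, y, classes: Sequence | None = None) -> float:
    """Mean one-vs-rest AUROC over the diagnostic classes (unweighted)."""
    if isinstance(proba, pd.DataFrame):
        classes = list(proba.columns) if classes is None else list(classes)
        proba = proba.to_numpy()
    elif classes is None:
        raise ValueError("classes are required with an array of probabilities")
    y = np.asarray(y)
    return float(
        np.mean([auroc(proba[:, i], y == cls) for i, cls in enumerate(classes)])
    )


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class MLPEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Seeded ensemble of multi-layer perceptrons averaged on probabilities.

    Members share architecture and hyperparameters and differ only in the
    weight-initialization / shuffling seed, derived deterministically from
    ``seed``.  The ensemble probability triplet is the mean of member
    ``predict_proba`` outputs, renormalized to sum to one.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int, default (32,)
    ensemble_size : int, default 5
    alpha : float, default 1e-3
        L2 weight decay.
    learning_rate_init : float, default 1e-3
    max_iter : int, default 300
    seed : int, default 0
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple = (32,),
        ensemble_size: int = 5,
        alpha: float = 1e-3,
        learning_rate_init: float = 1e-3,
        max_iter: int = 300,
        seed: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.ensemble_size = ensemble_size
        self.alpha = alpha
        self.learning_rate_init = learning_rate_init
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain at least two classes")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        rng = np.random.default_rng(self.seed)
        subseeds = rng.integers(0, 2**31 - 1, size=self.ensemble_size)
        self.members_ = []
        for s in subseeds:
            member = MLPClassifier(
                hidden_layer_sizes=self.hidden_layer_sizes,
                alpha=self.alpha,
                learning_rate_init=self.learning_rate_init,
                max_iter=self.max_iter,
                random_state=int(s),
            )
            with _quiet_fit():
                member.fit(np.asarray(X, dtype=float), y)
            self.members_.append(member)
        self.classes_ = self.members_[0].classes_
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        proba = np.mean([m.predict_proba(X) for m in self.members_], axis=0)
        return proba / proba.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class SVMRbfClassifier(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM baseline emitting probability triplets.

    Kept behind the same interface as the MLP ensemble so an original-panel
    SVM baseline and a new-panel neural-network model can be compared on
    identical metric code.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale", seed: int = 0):
        self.C = C
        self.gamma = gamma
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain at least two classes")
        self.model_ = SVC(
            C=self.C, gamma=self.gamma, probability=True, random_state=self.seed
        )
        self.model_.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_classifier(X, y, spec: "ClassifierSpec"):
    """Train the configured classifier family on a locked panel."""
    return spec.build().fit(X, y)


@dataclass
class ClassifierSpec:
    """Configuration of the final classifier."""

    family: str = "mlp_ensemble"  # or "svm_rbf"
    ensemble_size: int = 5
    hyperparameters: dict | None = None
    seed: int = 0

    def build(self):
        params = dict(self.hyperparameters or {})
        if self.family == "mlp_ensemble":
            return MLPEnsembleClassifier(
                ensemble_size=self.ensemble_size, seed=self.seed, **params
            )
        if self.family == "svm_rbf":
            return SVMRbfClassifier(seed=self.seed, **params)
        raise ValueError(f"unknown classifier family {self.family!r}")


# ---------------------------------------------------------------------------
# Bands
# ---------------------------------------------------------------------------

@dataclass
class BandConfig:
    """Score thresholds t1 < t2 < t3 cutting [0, 1] into bands 1-4.

    Bands are half-open: [0,t1), [t1,t2), [t2,t3), [t3,1].
    """

    t1: float
    t2: float
    t3: float

    def __post_init__(self):
        if not (self.t1 < self.t2 < self.t3):
            raise ValueError(
                f"thresholds must satisfy t1 < t2 < t3, got "
                f"({self.t1}, {self.t2}, {self.t3})"
            )

    def bands(self, scores) -> np.ndarray:
        """Band index (1-4) for each score."""
        scores = np.asarray(scores, dtype=float)
        return np.digitize(scores, [self.t1, self.t2, self.t3]) + 1


@dataclass
class BandMetrics:
    """The per-class clinical metric block (percentages on the 0-100 scale)."""

    auroc: float
    lr_minus: float
    fraction1: float
    band1_sensitivity: float
    lr_plus: float
    fraction4: float
    band4_specificity: float

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "lr_minus": self.lr_minus,
            "fraction1": self.fraction1,
            "band1_sensitivity": self.band1_sensitivity,
            "lr_plus": self.lr_plus,
            "fraction4": self.fraction4,
            "band4_specificity": self.band4_specificity,
        }


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent observed scores, plus outer sentinels."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    lo = uniq[0] - max(1e-9, abs(uniq[0]) * 1e-9)
    hi = uniq[-1] + max(1e-9, abs(uniq[-1]) * 1e-9)
    return np.concatenate([[lo], mids, [hi]])


def fit_band_thresholds(
    scores,
    labels,
    band1_sensitivity_target: float = 98.0,
    band4_specificity_target: float = 92.0,
) -> BandConfig:
    """Fit band thresholds on training scores to hit sensitivity/specificity targets.

    ``t1`` is the largest candidate threshold whose not-band-1 call keeps
    sensitivity >= ``band1_sensitivity_target`` (percent); ``t3`` is the
    smallest whose not-band-4 call keeps specificity >=
    ``band4_specificity_target``; ``t2`` is their midpoint.  Candidates are
    midpoints between adjacent observed scores, so the fitted thresholds
    never sit exactly on a data point.  When the two extremes cross (which
    happens exactly when the score separates the classes well) both
    thresholds are pulled to the middle of the crossed interval — any
    smaller t1 / larger t3 still satisfies its target by monotonicity.

    Raises
    ------
    ValueError when no rule-out/rule-in split satisfying both targets
    exists on these scores; lower one of the targets.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels).astype(bool)
    if pos.all() or (~pos).all():
        raise ValueError("both positive and negative labels are required")
    cands = _candidate_thresholds(scores)
    pos_scores, neg_scores = scores[pos], scores[~pos]

    # sensitivity of the call "score >= t" among positives, decreasing in t
    sens = 100.0 * (pos_scores[None, :] >= cands[:, None]).mean(axis=1)
    ok1 = np.nonzero(sens >= band1_sensitivity_target)[0]
    t1 = cands[ok1[-1]]  # largest t keeping the sensitivity target
    # specificity of the call "score < t" among negatives, increasing in t
    spec = 100.0 * (neg_scores[None, :] < cands[:, None]).mean(axis=1)
    ok3 = np.nonzero(spec >= band4_specificity_target)[0]
    t3 = cands[ok3[0]]  # smallest t keeping the specificity target

    if t1 >= t3:
        # the extremes cross exactly when positives and negatives are well
        # separated: any t <= t1 keeps the sensitivity target and any
        # t >= t3 keeps the specificity target, so place the intermediate
        # zone in the middle of the crossed interval
        mid = (t1 + t3) / 2.0
        below = cands[(cands <= mid) & (cands >= t3)]
        above = cands[(cands >= mid) & (cands <= t1)]
        new_t1 = below[-1] if len(below) else cands[cands < t3][-1] if (cands < t3).any() else None
        new_t3 = above[0] if len(above) else None
        if new_t1 is not None and new_t3 is not None and new_t1 == new_t3:
            higher = cands[(cands > new_t1) & (cands <= t1)]
            lower = cands[cands < new_t1]
            if len(higher):
                new_t3 = higher[0]
            elif len(lower):
                new_t1 = lower[-1]
            else:
                new_t3 = None
        if new_t1 is None or new_t3 is None or new_t1 >= new_t3:
            raise ValueError(
                "band targets cannot be separated into a rule-out and a "
                "rule-in region on these scores; lower the sensitivity or "
                "specificity target"
            )
        t1, t3 = new_t1, new_t3
    return BandConfig(t1=float(t1), t2=float((t1 + t3) / 2.0), t3=float(t3))


def compute_band_metrics(scores, labels, cfg: BandConfig) -> BandMetrics:
    """Compute the clinical metric block for one class on one dataset.

    Parameters
    ----------
    scores : one-vs-rest probabilities for the class of interest.
    labels : truthy = sample belongs to the class.
    cfg : fitted :class:`BandConfig` (frozen thresholds).
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels).astype(bool)
    if pos.all() or (~pos).all():
        raise ValueError("both positive and negative labels are required")
    bands = cfg.bands(scores)
    n = len(scores)
    n_pos, n_neg = int(pos.sum()), n - int(pos.sum())

    p1_pos = float((bands[pos] == 1).mean())
    p1_neg = float((bands[~pos] == 1).mean())
    p4_pos = float((bands[pos] == 4).mean())
    p4_neg = float((bands[~pos] == 4).mean())

    lr_minus = 0.0 if p1_pos == 0 else (np.inf if p1_neg == 0 else p1_pos / p1_neg)
    lr_plus = 0.0 if p4_pos == 0 else (np.inf if p4_neg == 0 else p4_pos / p4_neg)

    return BandMetrics(
        auroc=auroc(scores, pos),
        lr_minus=float(lr_minus),
        fraction1=100.0 * float((bands == 1).mean()),
        band1_sensitivity=100.0 * (1.0 - p1_pos),
        lr_plus=float(lr_plus),
        fraction4=100.0 * float((bands == 4).mean()),
        band4_specificity=100.0 * (1.0 - p4_neg),
    )


def band_fraction_from_likelihood_ratio(
    prevalence: float, lr: float, band_rate_negative: float
) -> float:
    """Overall band occupancy (%) implied by a likelihood ratio.

    For a band with rate ``band_rate_negative = P(band | negative)`` and
    likelihood ratio ``lr = P(band | positive) / P(band | negative)``, the
    fraction of all samples in the band at positive-class prevalence ``pi``
    is ``100 * band_rate_negative * (pi * lr + 1 - pi)`` — the
    prevalence-weighted mixture identity.  For the rule-in band,
    ``band_rate_negative = 1 - specificity/100``.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if lr < 0 or band_rate_negative < 0:
        raise ValueError("lr and band_rate_negative must be >= 0")
    return 100.0 * band_rate_negative * (prevalence * lr + 1.0 - prevalence)


# ---------------------------------------------------------------------------
# Panel evaluation (the full metric table)
# ---------------------------------------------------------------------------

def _oof_scores(model, X: pd.DataFrame, y: np.ndarray, n_splits: int, seed: int):
    """Out-of-fold probability triplets on the training set (stratified CV)."""
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    proba = np.zeros((len(y), len(np.unique(y))))
    classes = np.unique(y)
    for tr, te in skf.split(X, y):
        with _quiet_fit():
            m = clone(model).fit(X.iloc[tr], y[tr])
        p = m.predict_proba(X.iloc[te])
        cols = {c: i for i, c in enumerate(m.classes_)}
        proba[te] = p[:, [cols[c] for c in classes]]
    return pd.DataFrame(proba, index=X.index, columns=classes)


def evaluate_panel(
    panel: Sequence[str],
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    spec: ClassifierSpec | None = None,
    band1_sensitivity_target: float = 98.0,
    band4_specificity_target: float = 92.0,
    eval_classes: Sequence[str] = ("bacterial", "viral"),
    cv_folds: int = 5,
) -> dict:
    """Train a classifier on a locked panel and compute the full metric table.

    Training metrics are computed on out-of-fold cross-validation scores
    (thresholds are fitted on those same training scores); validation metrics
    reuse the frozen thresholds with a model refit on the full training set.

    Returns a dict with keys ``metrics`` (DataFrame: metric x
    (dataset, class)), ``thresholds`` (class -> BandConfig), ``scores``
    (dataset -> triplet DataFrame) and ``model`` (the refit classifier).
    """
    spec = spec or ClassifierSpec()
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    Xtr, Xv = X_train[list(panel)], X_val[list(panel)]

    oof = _oof_scores(spec.build(), Xtr, y_train, cv_folds, spec.seed)
    model = spec.build().fit(Xtr, y_train)
    val_proba = model.predict_proba(Xv)
    cols = {c: i for i, c in enumerate(model.classes_)}
    val = pd.DataFrame(
        val_proba[:, [cols[c] for c in oof.columns]],
        index=Xv.index,
        columns=oof.columns,
    )

    thresholds, blocks = {}, {}
    for cls in eval_classes:
        cfg = fit_band_thresholds(
            oof[cls], y_train == cls,
            band1_sensitivity_target, band4_specificity_target,
        )
        thresholds[cls] = cfg
        blocks[("train", cls)] = compute_band_metrics(oof[cls], y_train == cls, cfg)
        blocks[("validation", cls)] = compute_band_metrics(val[cls], y_val == cls, cfg)

    metrics = pd.DataFrame(
        {key: bm.as_dict() for key, bm in blocks.items()}
    )
    metrics.columns = pd.MultiIndex.from_tuples(metrics.columns, names=["dataset", "class"])
    return {
        "metrics": metrics,
        "thresholds": thresholds,
        "scores": {"train_oof": oof, "validation": val},
        "model": model,
    }
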