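"""Two-phase greedy forward feature selection over a candidate marker pool.

Each forward step tries every remaining candidate on top of the current
panel: a model (logistic regression in Phase I, multi-layer perceptron in
Phase II) is tuned by seeded hyperparameter search under stratified,
cohort-grouped cross-validation on the training compendium, refit on the
full training set, and scored on a held-out validation compendium.  The
chosen candidate maximizes validation mAUROC among those whose training CV
mAUROC is within ``trainval_tradeoff_epsilon`` of the best — a deterministic
formalization of picking the best train/validation trade-off from the
per-step scatter of (train CV AUC, validation AUC) pairs.  Ties break
lexicographically on marker name.  Phase I grows the panel to
``phase1_size`` with a logistic model and random search; Phase II continues
to ``target_size`` with an MLP and Bayesian (sequential model-based) search.

The full audit trail — every candidate's AUC pair at every step, the chosen
marker and the winning hyperparameters — is returned as a tidy trace
DataFrame from which a per-step scatter plot can be regenerated.
"""

from __future__ import annotations

import json
import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.pipeline import Pipeline

from hostpanel import optim
from hostpanel.classify_eval import mauroc

@contextmanager
def _quiet_fit():
    """Silence convergence chatter: selection scores partially converged fits."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


DEFAULT_LOGISTIC_SPACE = {"C": ("log", 1e-2, 1e2)}
DEFAULT_MLP_SPACE = {
    "hidden": ("int", 8, 64),
    "depth": ("int", 1, 2),
    "learning_rate_init": ("log", 1e-4, 1e-2),
    "alpha": ("log", 1e-5, 1e-1),
}


@dataclass
class ModelSpec:
    """Model family plus hyperparameter-search configuration for one phase."""

    family: str = "logistic"  # "logistic" or "mlp"
    hyperparameter_space: Mapping[str, tuple] | None = None
    search_strategy: str = "random"  # "random" or "bayes"
    search_budget: int = 20
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.search_budget < 1:
            raise ValueError("search_budget must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.family not in ("logistic", "mlp"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.hyperparameter_space is None:
            self.hyperparameter_space = (
                dict(DEFAULT_LOGISTIC_SPACE)
                if self.family == "logistic"
                else dict(DEFAULT_MLP_SPACE)
            )

    def build(self, params: Mapping[str, object] | None = None) -> BaseEstimator:
        """Instantiate the model with the given hyperparameters (standardized inputs)."""
        params = dict(params or {})
        if self.family == "logistic":
            core = LogisticRegression(
                C=float(params.get("C", 1.0)), max_iter=2000, random_state=self.seed
            )
        else:
            width = int(params.get("hidden", 32))
            depth = int(params.get("depth", 1))
            core = MLPClassifier(
                hidden_layer_sizes=(width,) * depth,
                learning_rate_init=float(params.get("learning_rate_init", 1e-3)),
                alpha=float(params.get("alpha", 1e-3)),
                max_iter=300,
                random_state=self.seed,
            )
        return Pipeline([("scale", StandardScaler()), ("model", core)])


@dataclass
class SelectionConfig:
    """Sizes and the train/validation trade-off rule of the two-phase selection."""

    phase1_size: int = 19
    target_size: int = 29
    trainval_tradeoff_epsilon: float = 0.01

    def validate(self) -> None:
        if not (0 <= self.phase1_size < self.target_size):
            raise ValueError("need 0 <= phase1_size < target_size")
        if self.trainval_tradeoff_epsilon < 0:
            raise ValueError("trainval_tradeoff_epsilon must be >= 0")


def _cv_splitter(spec: ModelSpec, groups):
    if groups is not None:
        return StratifiedGroupKFold(n_splits=spec.cv_folds)
    return StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)


def cross_validated_auc(
    X: pd.DataFrame,
    y,
    spec: ModelSpec,
    groups=None,
    params: Mapping[str, object] | None = None,
) -> float:
    """Cross-validated mAUROC of the spec'd model with fixed hyperparameters.

    Folds are stratified by class; when cohort ``groups`` are given, whole
    cohorts stay within one fold (generalization across cohorts is the
    quantity of interest in a multi-cohort design).  Each fold's mAUROC is
    the unweighted mean of the one-vs-rest AUROCs; folds are averaged.

    Raises :class:`ValueError` when a class is missing from a training fold.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    model = spec.build(params)
    scores = []
    for tr, te in _cv_splitter(spec, groups).split(X, y, groups):
        if len(np.unique(y[tr])) < len(classes) or len(np.unique(y[te])) < len(classes):
            raise ValueError(
                "every class must be present in every fold; "
                "use fewer folds or larger cohorts"
            )
        with _quiet_fit():
            m = clone(model).fit(X.iloc[tr], y[tr])
        proba = m.predict_proba(X.iloc[te])
        order = {c: i for i, c in enumerate(m.classes_)}
        proba = proba[:, [order[c] for c in classes]]
        scores.append(mauroc(proba, y[te], classes))
    return float(np.mean(scores))


def search_hyperparameters(
    X: pd.DataFrame, y, spec: ModelSpec, groups=None
) -> tuple[dict, float]:
    """Tune the spec's hyperparameters by seeded search; returns (params, cv_auc)."""
    best_params, best_auc, _ = optim.maximize(
        lambda p: cross_validated_auc(X, y, spec, groups, p),
        spec.hyperparameter_space,
        budget=spec.search_budget,
        seed=spec.seed,
        strategy="bayes" if spec.search_strategy == "bayes" else "random",
    )
    return best_params, best_auc


def _validation_auc(
    X_train, y_train, X_val, y_val, spec: ModelSpec, params
) -> float:
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    classes = np.unique(y_train)
    with _quiet_fit():
        m = spec.build(params).fit(X_train, y_train)
    proba = m.predict_proba(X_val)
    order = {c: i for i, c in enumerate(m.classes_)}
    return mauroc(proba[:, [order[c] for c in classes]], y_val, classes)


def forward_select_step(
    current_set: Sequence[str],
    candidates: Sequence[str],
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    spec: ModelSpec,
    groups=None,
    epsilon: float = 0.01,
) -> tuple[pd.DataFrame, str]:
    """Evaluate every candidate addition and choose one marker.

    Returns ``(records, chosen)`` where ``records`` has one row per candidate
    with columns ``candidate``, ``train_cv_auc``, ``val_auc``, ``params``
    (JSON) and ``chosen``.  The chosen candidate maximizes ``val_auc`` among
    candidates with ``train_cv_auc >= max(train_cv_auc) - epsilon``; exact
    ties break on lexicographic marker name.
    """
    current_set = list(current_set)
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("candidate set is empty")
    overlap = set(candidates) & set(current_set)
    if overlap:
        raise ValueError(f"candidates overlap current set: {sorted(overlap)}")

    rows = []
    for cand in candidates:
        feats = current_set + [cand]
        params, cv_auc = search_hyperparameters(
            X_train[feats], y_train, spec, groups
        )
        val_auc = _validation_auc(
            X_train[feats], y_train, X_val[feats], y_val, spec, params
        )
        rows.append(
            {
                "candidate": cand,
                "train_cv_auc": cv_auc,
                "val_auc": val_auc,
                "params": json.dumps(params, sort_keys=True),
            }
        )
    records = pd.DataFrame(rows)
    best_train = records["train_cv_auc"].max()
    eligible = records[records["train_cv_auc"] >= best_train - epsilon]
    # max val_auc; exact ties -> lexicographically first candidate
    top = eligible[eligible["val_auc"] == eligible["val_auc"].max()]
    chosen = sorted(top["candidate"])[0]
    records["chosen"] = records["candidate"] == chosen
    return records, str(chosen)


def run_two_phase_selection(
    pool: Sequence[str],
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    phase1_spec: ModelSpec | None = None,
    phase2_spec: ModelSpec | None = None,
    cfg: SelectionConfig | None = None,
    groups=None,
) -> tuple[list[str], pd.DataFrame]:
    """Run Phase I (logistic, random search) then Phase II (MLP, Bayesian search).

    Returns the final panel (ordered by selection step) and the full trace
    with columns ``step``, ``phase``, ``candidate``, ``train_cv_auc``,
    ``val_auc``, ``params``, ``chosen``.
    """
    cfg = cfg or SelectionConfig()
    cfg.validate()
    phase1_spec = phase1_spec or ModelSpec(family="logistic", search_strategy="random")
    phase2_spec = phase2_spec or ModelSpec(family="mlp", search_strategy="bayes")
    pool = list(dict.fromkeys(pool))
    if len(pool) < cfg.target_size:
        raise ValueError(
            f"pool has {len(pool)} markers, fewer than target_size={cfg.target_size}"
        )

    panel: list[str] = []
    traces = []
    for step in range(cfg.target_size):
        phase = 1 if step < cfg.phase1_size else 2
        spec = phase1_spec if phase == 1 else phase2_spec
        candidates = [m for m in pool if m not in panel]
        records, chosen = forward_select_step(
            panel, candidates, X_train, y_train, X_val, y_val,
            spec, groups, cfg.trainval_tradeoff_epsilon,
        )
        records.insert(0, "phase", phase)
        records.insert(0, "step", step + 1)
        traces.append(records)
        panel.append(chosen)
    return panel, pd.concat(traces, ignore_index=True)


def plot_selection_trace(trace: pd.DataFrame, path) -> None:
    """Scatter of (train CV mAUROC, validation mAUROC) per step.

    One colour per selection step, chosen markers circled — the standard way
    to visualize the train/validation trade-off the step rule formalizes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    steps = sorted(trace["step"].unique())
    cmap = plt.get_cmap("viridis", len(steps))
    for i, step in enumerate(steps):
        sub = trace[trace["step"] == step]
        ax.scatter(
            sub["train_cv_auc"], sub["val_auc"], s=14, color=cmap(i),
            label=f"step {step}", alpha=0.7,
        )
        won = sub[sub["chosen"]]
        ax.scatter(
            won["train_cv_auc"], won["val_auc"], s=80, facecolors="none",
            edgecolors="red", linewidths=1.2,
        )
    ax.set_xlabel("training cross-validation mAUROC")
    ax.set_ylabel("validation mAUROC")
    if len(steps) <= 10:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


class ForwardPanelSelector(BaseEstimator):
    """Sklearn-style wrapper around the two-phase forward selection.

    ``fit(X, y, X_val=..., y_val=..., groups=..., pool=...)`` runs the
    selection over ``pool`` (default: all columns of ``X``); ``transform``
    restricts a matrix to the selected panel.

    Attributes
    ----------
    panel_ : list of selected marker ids in selection order.
    trace_ : tidy DataFrame of every candidate evaluation at every step.
    """

    def __init__(
        self,
        phase1_spec: ModelSpec | None = None,
        phase2_spec: ModelSpec | None = None,
        config: SelectionConfig | None = None,
    ):
        self.phase1_spec = phase1_spec
        self.phase2_spec = phase2_spec
        self.config = config

    def fit(self, X: pd.DataFrame, y, X_val=None, y_val=None, groups=None, pool=None):
        if X_val is None or y_val is None:
            raise ValueError("a held-out validation set (X_val, y_val) is required")
        pool = list(pool) if pool is not None else list(X.columns)
        self.panel_, self.trace_ = run_two_phase_selection(
            pool, X, y, X_val, y_val,
            self.phase1_spec, self.phase2_spec, self.config, groups,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.panel_]

    def get_support(self, X_columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(X_columns) if X_columns is not None else None
        if cols is None:
            raise ValueError("pass the column list to compute a support mask")
        return np.asarray([c in set(self.panel_) for c in cols])
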