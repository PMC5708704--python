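"""Two-group soft-voting ensemble for PD/control classification.

The 27 features are split into their Hold (9) and Latency (18) groups and
each group gets its own preprocessing chain — mean imputation of missing
values, 0-1 min-max scaling, then a one-component linear discriminant
projection — followed by the same roster of eight base classifiers (SVM,
multilayer perceptron, logistic regression, random forest, Nu-SVC, decision
tree, k-nearest neighbours, quadratic discriminant analysis), all with
library-default parameters apart from pinned seeds and iteration caps.

Each base model emits a predicted probability of PD.  The sixteen
probabilities are combined into a single decision probability by a weighted
mean-probabilities rule: the Hold probabilities enter as they are, while each
Latency probability is pulled away from 0.5 by the group weight ``Wt``
(default 1.2, reflecting the Latency group's higher standalone accuracy),

    P_PD = ( sum_i P(MH_i) + sum_i (0.5 + Wt * (P(ML_i) - 0.5)) ) / (2n)

with ``n`` models per group.  With ``Wt > 1`` the raw value can leave [0, 1]
(up to 1.05 / down to -0.05 at ``Wt = 1.2``); it is clamped afterwards and
the clamping is recorded.  A subject is labelled PD when ``P_PD >= 0.5``
(threshold inclusive).

All preprocessing state is learned from training data only; at prediction
time missing features are filled with the stored *training* means, never with
test-set statistics.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC, NuSVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, HOLD_FEATURES, LATENCY_FEATURES

__all__ = [
    "MODEL_ROSTER",
    "EnsembleConfig",
    "PreprocessState",
    "EnsembleModel",
    "PredictionResult",
    "CombinedProbability",
    "make_base_models",
    "fit_preprocess",
    "fit_ensemble",
    "combine_probabilities",
    "predict",
    "predictions_to_frame",
    "save_model",
    "load_model",
]

#: The eight base classifier types, identical in both feature groups.
MODEL_ROSTER = ("SVM", "MLP", "LRM", "RFC", "NSVC", "DTC", "KNN", "QDA")

#: Non-default constructor arguments, pinned so results are stable across
#: library versions.  Everything not listed here is a library default.
PINNED_PARAMS = {
    "SVM": {"probability": True},
    "MLP": {"max_iter": 2000},
    "LRM": {"max_iter": 1000},
    "NSVC": {"probability": True},
}


@contextmanager
def _quiet_svc_probability():
    """Silence the scikit-learn 1.9 deprecation of ``probability=True``.

    Platt-scaled SVC probabilities are part of the documented model roster;
    the deprecation is cosmetic until the parameter is removed.
    """
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*`probability` parameter was deprecated.*",
            category=FutureWarning,
        )
        yield


def make_base_models(seed: int) -> dict:
    """Instantiate the eight-classifier roster with a common seed."""
    return {
        "SVM": SVC(random_state=seed, **PINNED_PARAMS["SVM"]),
        "MLP": MLPClassifier(random_state=seed, **PINNED_PARAMS["MLP"]),
        "LRM": LogisticRegression(**PINNED_PARAMS["LRM"]),
        "RFC": RandomForestClassifier(random_state=seed),
        "NSVC": NuSVC(random_state=seed, **PINNED_PARAMS["NSVC"]),
        "DTC": DecisionTreeClassifier(random_state=seed),
        "KNN": KNeighborsClassifier(),
        "QDA": QuadraticDiscriminantAnalysis(),
    }


@dataclass(frozen=True)
class EnsembleConfig:
    """Tunables of the meta-classifier.

    ``weight`` is the Latency-group weighting factor ``Wt``; ``threshold`` is
    the PD decision cut on the combined probability (inclusive).
    """

    weight: float = 1.2
    threshold: float = 0.5
    seed: int = 0
    roster: Sequence[str] = MODEL_ROSTER

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    @property
    def n_models(self) -> int:
        return len(self.roster)


@dataclass
class PreprocessState:
    """Fitted per-group preprocessing: impute -> scale to [0,1] -> 1-D LDA."""

    hold_pipeline: Pipeline
    latency_pipeline: Pipeline
    hold_features: tuple = HOLD_FEATURES
    latency_features: tuple = LATENCY_FEATURES

    def transform(self, X: pd.DataFrame) -> tuple:
        H = self.hold_pipeline.transform(X.loc[:, list(self.hold_features)].to_numpy(float))
        L = self.latency_pipeline.transform(
            X.loc[:, list(self.latency_features)].to_numpy(float)
        )
        return H, L


def _group_pipeline() -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="mean", keep_empty_features=True)),
            ("scale", MinMaxScaler()),
            ("lda", LinearDiscriminantAnalysis(n_components=1)),
        ]
    )


def _check_feature_frame(X: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_NAMES if c not in X.columns]
    if missing:
        raise ValueError(f"feature frame is missing columns {missing}")


def fit_preprocess(X: pd.DataFrame, y: Sequence[int]) -> PreprocessState:
    """Fit imputation means, 0-1 scaling bounds and per-group LDA projections.

    Constant (zero-width) feature columns scale to 0 and are reported with a
    warning.  Deterministic: refitting on identical input reproduces the
    state exactly.
    """
    _check_feature_frame(X)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit preprocessing")
    for name in FEATURE_NAMES:
        col = X[name].to_numpy(float)
        finite = col[np.isfinite(col)]
        if finite.size and np.nanmin(finite) == np.nanmax(finite):
            warnings.warn(
                f"feature {name!r} is constant in the training data; "
                f"it scales to 0 and carries no signal",
                stacklevel=2,
            )
    state = PreprocessState(_group_pipeline(), _group_pipeline())
    state.hold_pipeline.fit(X.loc[:, list(HOLD_FEATURES)].to_numpy(float), y)
    state.latency_pipeline.fit(X.loc[:, list(LATENCY_FEATURES)].to_numpy(float), y)
    return state


@dataclass
class EnsembleModel:
    """Fitted preprocessing plus the 8+8 base classifiers and the combiner."""

    preprocess: PreprocessState
    hold_models: dict
    latency_models: dict
    config: EnsembleConfig
    feature_names: tuple = FEATURE_NAMES

    @property
    def n_models(self) -> int:
        return len(self.hold_models)


def fit_ensemble(
    X: pd.DataFrame,
    y: Sequence[int],
    config: Optional[EnsembleConfig] = None,
) -> EnsembleModel:
    """Fit the full two-group ensemble on labelled training features."""
    config = config or EnsembleConfig()
    _check_feature_frame(X)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels are all identical; need both classes")
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise ValueError(f"class {cls} has fewer than 2 training subjects")

    state = fit_preprocess(X, y)
    H, L = state.transform(X)
    hold_models = make_base_models(config.seed)
    latency_models = make_base_models(config.seed)
    hold_models = {k: hold_models[k] for k in config.roster}
    latency_models = {k: latency_models[k] for k in config.roster}
    with _quiet_svc_probability():
        for m in hold_models.values():
            m.fit(H, y)
        for m in latency_models.values():
            m.fit(L, y)
    return EnsembleModel(
        preprocess=state,
        hold_models=hold_models,
        latency_models=latency_models,
        config=config,
    )


@dataclass(frozen=True)
class CombinedProbability:
    raw: float
    value: float  # clamped to [0, 1]

    @property
    def clamped(self) -> bool:
        return self.raw != self.value


def combine_probabilities(
    hold_probs: Sequence[float],
    latency_probs: Sequence[float],
    weight: float = 1.2,
) -> CombinedProbability:
    """Weighted mean-probabilities combination of the two model groups.

    Implements the combiner literally as stated above: Hold probabilities are
    averaged as-is, Latency probabilities are expanded about 0.5 by ``Wt``
    first, and the grand sum is divided by twice the per-group model count.
    The raw value is retained alongside the [0, 1]-clamped one.
    """
    h = np.asarray(hold_probs, dtype=float)
    l = np.asarray(latency_probs, dtype=float)
    if h.size != l.size or h.size == 0:
        raise ValueError("hold and latency probability lists must have equal, nonzero length")
    for arr, name in ((h, "hold"), (l, "latency")):
        if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} probabilities must lie in [0, 1]")
    if weight <= 0:
        raise ValueError("weight must be positive")
    n = h.size
    raw = float((h.sum() + (0.5 + weight * (l - 0.5)).sum()) / (2 * n))
    return CombinedProbability(raw=raw, value=min(1.0, max(0.0, raw)))


@dataclass(frozen=True)
class PredictionResult:
    """Per-subject ensemble output: 16 base probabilities and the decision."""

    subject_id: str
    hold_probs: Mapping[str, float]
    latency_probs: Mapping[str, float]
    hold_mean: float
    latency_mean: float
    p_pd_raw: float
    p_pd: float
    label: bool
    all_missing: bool = False


def _positive_proba(model, Z: np.ndarray) -> np.ndarray:
    idx = int(np.flatnonzero(model.classes_ == 1)[0])
    return model.predict_proba(Z)[:, idx]


def predict(model: EnsembleModel, X: pd.DataFrame) -> list:
    """Score feature rows with a fitted ensemble.

    Missing feature values are imputed with the stored training means.  Rows
    with every feature missing are scored from pure imputation means and
    flagged.  Deterministic given the fitted model.
    """
    _check_feature_frame(X)
    H, L = model.preprocess.transform(X)
    hold = {name: _positive_proba(m, H) for name, m in model.hold_models.items()}
    lat = {name: _positive_proba(m, L) for name, m in model.latency_models.items()}
    all_missing = X.loc[:, list(FEATURE_NAMES)].isna().all(axis=1).to_numpy()

    results = []
    for i, sid in enumerate(X.index):
        hp = {name: float(hold[name][i]) for name in model.hold_models}
        lp = {name: float(lat[name][i]) for name in model.latency_models}
        combined = combine_probabilities(
            list(hp.values()), list(lp.values()), weight=model.config.weight
        )
        results.append(
            PredictionResult(
                subject_id=str(sid),
                hold_probs=hp,
                latency_probs=lp,
                hold_mean=float(np.mean(list(hp.values()))),
                latency_mean=float(np.mean(list(lp.values()))),
                p_pd_raw=combined.raw,
                p_pd=combined.value,
                label=combined.value >= model.config.threshold,
                all_missing=bool(all_missing[i]),
            )
        )
    return results


def predictions_to_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {f"p_hold_{k}": v for k, v in r.hold_probs.items()}
        row.update({f"p_latency_{k}": v for k, v in r.latency_probs.items()})
        row.update(
            hold_mean=r.hold_mean,
            latency_mean=r.latency_mean,
            p_pd_raw=r.p_pd_raw,
            p_pd=r.p_pd,
            label=int(r.label),
        )
        rows.append(pd.Series(row, name=r.subject_id))
    df = pd.DataFrame(rows)
    df.index.name = "subject_id"
    return df


def save_model(model: EnsembleModel, path) -> None:
    """Persist a fitted ensemble with a manifest of its configuration."""
    bundle = {
        "model": model,
        "manifest": {
            "feature_names": list(model.feature_names),
            "roster": list(model.config.roster),
            "weight": model.config.weight,
            "threshold": model.config.threshold,
            "seed": model.config.seed,
        },
    }
    joblib.dump(bundle, path)


def load_model(path) -> EnsembleModel:
    bundle = joblib.load(path)
    model = bundle["model"]
    if list(model.feature_names) != list(FEATURE_NAMES):
        raise ValueError("model bundle feature names do not match this package version")
    return model
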