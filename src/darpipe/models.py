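"""The candidate model zoo: 10 pipeline candidates across 3 frameworks.

Four gradient-boosted-tree candidates (XGBoost), five linear
stochastic-gradient-descent candidates and one multi-layer perceptron, each
paired with its own preprocessing chain (one-hot thresholds 30/5/6/7/7/7/9,
PCA on candidates 2/5/7, scale-and-centre everywhere).  Each candidate is
tuned with a Bayesian search maximising macro-F1 on the validation
partition; the best candidate overall is selected by support-weighted F1.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import f1_score
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .optimize import BayesianSearch, Dimension
from .preprocess import FittedTransformer, TransformSpec, fit_transform
from .simulate import CLASSES

GBT_SPACE = {
    "max_depth": Dimension("max_depth", "int", 2, 10),
    "learning_rate": Dimension("learning_rate", "float", 1e-3, 0.5, log=True),
    "n_estimators": Dimension("n_estimators", "int", 50, 1000),
    "subsample": Dimension("subsample", "float", 0.5, 1.0),
    "colsample_bytree": Dimension("colsample_bytree", "float", 0.5, 1.0),
    "reg_alpha": Dimension("reg_alpha", "float", 1e-5, 10.0, log=True),
    "reg_lambda": Dimension("reg_lambda", "float", 1e-5, 10.0, log=True),
}
LINEAR_SPACE = {
    "alpha": Dimension("alpha", "float", 1e-6, 1.0, log=True),
    "l1_ratio": Dimension("l1_ratio", "float", 0.0, 1.0),
    "eta0": Dimension("eta0", "float", 1e-4, 0.1, log=True),
}
MLP_SPACE = {
    "n_layers": Dimension("n_layers", "int", 1, 3),
    "layer_size": Dimension("layer_size", "int", 16, 256),
    "alpha": Dimension("alpha", "float", 1e-5, 1e-1, log=True),
    "learning_rate_init": Dimension("learning_rate_init", "float", 1e-4, 1e-2, log=True),
}


@dataclasses.dataclass
class CandidateSpec:
    """One row of the candidate zoo."""

    candidate_id: int
    framework: str  # "gbt" | "linear_sgd" | "mlp"
    transform: TransformSpec
    search_space: Mapping[str, Dimension]


def _chain(*steps) -> TransformSpec:
    return TransformSpec(tuple(steps))


def make_candidates() -> list[CandidateSpec]:
    """The 10 candidate pipelines (framework + transform chain)."""
    imp = ("impute", {})
    sc = ("scale_center", {})
    pca = ("pca", {"variance_kept": 0.95})

    def oh(t):
        return ("threshold_one_hot", {"threshold": t})

    rows = [
        (1, "gbt", _chain(imp, oh(30), sc), GBT_SPACE),
        (2, "linear_sgd", _chain(imp, ("quantile_uniform", {}), sc, pca), LINEAR_SPACE),
        (3, "linear_sgd", _chain(imp, sc), LINEAR_SPACE),
        (4, "gbt", _chain(imp, oh(5), sc), GBT_SPACE),
        (5, "linear_sgd", _chain(imp, oh(6), sc, pca), LINEAR_SPACE),
        (6, "linear_sgd", _chain(imp, oh(7), sc), LINEAR_SPACE),
        (7, "linear_sgd", _chain(imp, oh(7), sc, pca), LINEAR_SPACE),
        (8, "gbt", _chain(imp, oh(7), sc), GBT_SPACE),
        (9, "gbt", _chain(imp, oh(9), sc), GBT_SPACE),
        (10, "mlp", _chain(imp, sc), MLP_SPACE),
    ]
    return [CandidateSpec(cid, fw, tf, space) for cid, fw, tf, space in rows]


def build_estimator(framework: str, params: Mapping, seed: int):
    if framework == "gbt":
        return XGBClassifier(
            tree_method="hist", n_jobs=1, random_state=seed,
            verbosity=0, **params)
    if framework == "linear_sgd":
        return SGDClassifier(
            loss="log_loss", penalty="elasticnet", learning_rate="adaptive",
            max_iter=300, tol=1e-4, random_state=seed, **params)
    if framework == "mlp":
        p = dict(params)
        hidden = tuple([int(p.pop("layer_size"))] * int(p.pop("n_layers")))
        return MLPClassifier(hidden_layer_sizes=hidden, max_iter=400,
                             early_stopping=False, random_state=seed, **p)
    raise ValueError(f"unknown framework {framework!r}")


@dataclasses.dataclass
class TunedModel:
    """A tuned candidate: transformer, classifier and tuning history."""

    candidate_id: int
    framework: str
    best_params: dict
    transformer: FittedTransformer
    classifier: object
    classes_: list[str]
    validation_macro_f1: float
    history: pd.DataFrame  # trial, params (json), macro_f1

    def save(self, directory) -> None:
        """Serialise transformer/metadata (JSON) and tuning history (CSV).

        The classifier itself is refit on load via :func:`load_tuned`, using
        the stored best hyperparameters — keeping the on-disk format plain
        text.
        """
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.transformer.to_json(d / "transformer.json")
        meta = {
            "candidate_id": self.candidate_id,
            "framework": self.framework,
            "best_params": self.best_params,
            "classes": self.classes_,
            "validation_macro_f1": self.validation_macro_f1,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        self.history.to_csv(d / "tuning_history.csv", index=False)


def _encode_labels(labels: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    unknown = set(labels) - set(lut)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    return np.asarray([lut[l] for l in labels])


def tune(
    candidate: CandidateSpec,
    train: pd.DataFrame,
    val: pd.DataFrame,
    n_evals: int = 200,
    seed: int = 0,
    feature_cols: Sequence[str] | None = None,
    classes: Sequence[str] = CLASSES,
) -> TunedModel:
    """Tune one candidate with a Bayesian search on validation macro-F1.

    The preprocessing chain is fitted on the training partition only; every
    trial trains on the transformed training rows and is scored by macro-F1
    on the transformed validation rows.  The returned model carries the
    best trial's classifier (refit deterministically) and the full history.
    """
    if n_evals < 1:
        raise ValueError("n_evals must be >= 1")
    transformer = fit_transform(candidate.transform, train, feature_cols)
    Xtr = transformer.apply(train).to_numpy(dtype=float)
    Xva = transformer.apply(val).to_numpy(dtype=float)
    present = [c for c in classes if c in set(train["label"])]
    ytr = _encode_labels(train["label"], present)
    # a validation label absent from training can never be predicted; it
    # scores as an error rather than failing the run
    lut = {c: i for i, c in enumerate(present)}
    yva = np.asarray([lut.get(l, -1) for l in val["label"]])
    labels = list(range(len(present)))
    search = BayesianSearch(candidate.search_space, n_evals, seed=seed)
    rows = []
    best = (-np.inf, None, None)
    for trial in range(n_evals):
        params = search.ask()
        clf = build_estimator(candidate.framework, params, seed)
        clf.fit(Xtr, ytr)
        score = f1_score(yva, clf.predict(Xva), average="macro",
                         labels=labels, zero_division=0)
        search.tell(score)
        rows.append({"trial": trial, "params": json.dumps(params),
                     "macro_f1": score})
        if score > best[0]:
            best = (score, params, clf)
    history = pd.DataFrame(rows)
    return TunedModel(
        candidate_id=candidate.candidate_id, framework=candidate.framework,
        best_params=best[1], transformer=transformer, classifier=best[2],
        classes_=list(present), validation_macro_f1=float(best[0]),
        history=history)


def fit_with_params(candidate: CandidateSpec, params: Mapping,
                    train: pd.DataFrame, seed: int = 0,
                    feature_cols: Sequence[str] | None = None,
                    classes: Sequence[str] = CLASSES) -> TunedModel:
    """Fit a candidate with fixed hyperparameters (no search)."""
    transformer = fit_transform(candidate.transform, train, feature_cols)
    Xtr = transformer.apply(train).to_numpy(dtype=float)
    present = [c for c in classes if c in set(train["label"])]
    ytr = _encode_labels(train["label"], present)
    clf = build_estimator(candidate.framework, dict(params), seed)
    clf.fit(Xtr, ytr)
    return TunedModel(candidate.candidate_id, candidate.framework, dict(params),
                      transformer, clf, list(present), float("nan"),
                      pd.DataFrame(columns=["trial", "params", "macro_f1"]))


def predict(model: TunedModel, table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict class labels (and per-class probabilities) for raw feature rows."""
    X = model.transformer.apply(table).to_numpy(dtype=float)
    proba = model.classifier.predict_proba(X)
    labels = np.asarray(model.classes_)[np.argmax(proba, axis=1)]
    return labels, pd.DataFrame(proba, columns=model.classes_, index=table.index)


def load_tuned(directory, train: pd.DataFrame,
               feature_cols: Sequence[str] | None = None) -> TunedModel:
    """Rehydrate a saved model: restore transformer, refit classifier on the
    stored best hyperparameters against the supplied training table."""
    d = pathlib.Path(directory)
    meta = json.loads((d / "model.json").read_text())
    transformer = FittedTransformer.from_json(d / "transformer.json")
    Xtr = transformer.apply(train).to_numpy(dtype=float)
    ytr = _encode_labels(train["label"], meta["classes"])
    clf = build_estimator(meta["framework"], meta["best_params"], seed=0)
    clf.fit(Xtr, ytr)
    history = pd.read_csv(d / "tuning_history.csv") if (d / "tuning_history.csv").exists() \
        else pd.DataFrame(columns=["trial", "params", "macro_f1"])
    return TunedModel(meta["candidate_id"], meta["framework"], meta["best_params"],
                      transformer, clf, meta["classes"],
                      meta["validation_macro_f1"], history)
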