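"""Dataset assembly: train/validation/test splitting and leakage-safe
preprocessing.

The split is 64/16/20 by default.  Every preprocessing statistic (imputation
medians, scaling means/sds, one-hot categories, quantile maps, PCA rotations)
is fitted on the training partition only and then applied unchanged to
validation and test rows, so no information flows from held-out data into the
transforms.  Fitted transformers serialise to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_FRACTIONS = (0.64, 0.16, 0.20)


@dataclasses.dataclass
class SplitIndices:
    """Disjoint, exhaustive row-index sets for train/validation/test."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int
    mode: str

    def to_csv(self, path) -> None:
        rows = [(int(i), part) for part, idx in
                (("train", self.train), ("validation", self.validation),
                 ("test", self.test)) for i in idx]
        pd.DataFrame(rows, columns=["index", "partition"]).to_csv(path, index=False)


def _target_sizes(n: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_test = n - n_train - n_val
    return n_train, n_val, n_test


def split(
    table: pd.DataFrame,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    mode: str = "record",
    stratify_by: str | None = "label",
    group_by: str = "animal_id",
) -> SplitIndices:
    """Split a feature table into train/validation/test partitions.

    ``mode='record'`` assigns rows independently (stratified by class when a
    label column is present, which stabilises rare-class evaluation);
    ``mode='grouped'`` keeps all rows of one animal in a single partition,
    guarding against within-animal leakage.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    n = len(table)
    rng = np.random.default_rng(seed)
    if mode == "grouped":
        groups = table[group_by].to_numpy()
        uniq = pd.unique(groups)
        if len(uniq) < 3:
            raise ValueError("grouped split needs at least 3 animals")
        order = rng.permutation(len(uniq))
        shuffled = uniq[order]
        # allocate whole animals greedily to partitions until targets are met
        n_train, n_val, _ = _target_sizes(n, fractions)
        sizes = pd.Series(groups).value_counts()
        parts: dict[str, list] = {"train": [], "validation": [], "test": []}
        filled = {"train": 0, "validation": 0}
        for g in shuffled:
            if filled["train"] + sizes[g] / 2 <= n_train:
                parts["train"].append(g)
                filled["train"] += sizes[g]
            elif filled["validation"] + sizes[g] / 2 <= n_val:
                parts["validation"].append(g)
                filled["validation"] += sizes[g]
            else:
                parts["test"].append(g)
        idx = {p: np.flatnonzero(np.isin(groups, parts[p])) for p in parts}
        return SplitIndices(idx["train"], idx["validation"], idx["test"], seed, mode)
    if mode != "record":
        raise ValueError("mode must be 'record' or 'grouped'")

    n_train, n_val, n_test = _target_sizes(n, fractions)
    if stratify_by and stratify_by in table.columns:
        # proportional allocation per class, largest-remainder rounding,
        # then a global adjustment pass so totals match exactly
        labels = table[stratify_by].to_numpy()
        assigned = np.empty(n, dtype=object)
        for cls in pd.unique(labels):
            rows = np.flatnonzero(labels == cls)
            rows = rng.permutation(rows)
            k_tr = int(round(fractions[0] * len(rows)))
            k_va = int(round(fractions[1] * len(rows)))
            k_tr = min(k_tr, len(rows))
            k_va = min(k_va, len(rows) - k_tr)
            assigned[rows[:k_tr]] = "train"
            assigned[rows[k_tr:k_tr + k_va]] = "validation"
            assigned[rows[k_tr + k_va:]] = "test"
        want = {"train": n_train, "validation": n_val, "test": n_test}
        while True:
            counts = {p: int((assigned == p).sum()) for p in want}
            over = [p for p in want if counts[p] > want[p]]
            under = [p for p in want if counts[p] < want[p]]
            if not over:
                break
            cand = np.flatnonzero(assigned == over[0])
            assigned[rng.choice(cand)] = under[0]
        train = np.flatnonzero(assigned == "train")
        val = np.flatnonzero(assigned == "validation")
        test = np.flatnonzero(assigned == "test")
    else:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        val = np.sort(perm[n_train:n_train + n_val])
        test = np.sort(perm[n_train + n_val:])
    return SplitIndices(np.sort(train), np.sort(val), np.sort(test), seed, mode)


# ---------------------------------------------------------------------------
# Transform steps
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TransformSpec:
    """Ordered preprocessing steps for one candidate pipeline.

    Steps are drawn from ``impute``, ``scale_center``, ``quantile_uniform``,
    ``threshold_one_hot`` (with its distinct-value threshold) and ``pca``
    (with the variance fraction kept).
    """

    steps: tuple[tuple[str, dict], ...]

    def __post_init__(self) -> None:
        for name, kw in self.steps:
            if name == "threshold_one_hot" and kw.get("threshold", 2) < 2:
                raise ValueError("one-hot threshold must be >= 2")
            if name == "pca" and not 0 < kw.get("variance_kept", 0.95) <= 1:
                raise ValueError("variance_kept must be in (0, 1]")


class _Step:
    name = "base"

    def fit(self, X: pd.DataFrame) -> "_Step":
        raise NotImplementedError

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        raise NotImplementedError

    def state(self) -> dict:
        raise NotImplementedError

    @classmethod
    def from_state(cls, state: dict) -> "_Step":
        obj = cls.__new__(cls)
        obj.__dict__.update(state)
        return obj


class Impute(_Step):
    """Fill missing values with the training median per feature."""

    name = "impute"

    def __init__(self):
        self.medians_: dict[str, float] = {}

    def fit(self, X):
        med = X.median(numeric_only=True)
        self.medians_ = {c: (0.0 if np.isnan(m) else float(m))
                         for c, m in med.items()}
        return self

    def transform(self, X):
        return X.fillna(pd.Series(self.medians_))

    def state(self):
        return {"medians_": self.medians_}


class ScaleCenter(_Step):
    """Centre to training mean and scale to unit training sd.

    Zero-variance features are centred but passed through unscaled.  Binary
    indicator columns produced by one-hot encoding (all values in {0, 1})
    are left untouched — the sparsity-aware convention.
    """

    name = "scale_center"

    def __init__(self):
        self.means_: dict[str, float] = {}
        self.sds_: dict[str, float] = {}

    @staticmethod
    def _is_indicator(col: pd.Series) -> bool:
        v = col.dropna().unique()
        return len(v) <= 2 and set(np.asarray(v, dtype=float)) <= {0.0, 1.0}

    def fit(self, X):
        self.means_, self.sds_ = {}, {}
        for c in X.columns:
            if self._is_indicator(X[c]):
                continue
            self.means_[c] = float(X[c].mean())
            sd = float(X[c].std(ddof=0))
            self.sds_[c] = sd if sd > 0 else 1.0
        return self

    def transform(self, X):
        out = X.copy()
        for c, m in self.means_.items():
            if c in out.columns:
                out[c] = (out[c] - m) / self.sds_[c]
        return out

    def state(self):
        return {"means_": self.means_, "sds_": self.sds_}


class QuantileUniform(_Step):
    """Map each feature through its training empirical CDF to [0, 1].

    Robust to extreme values: the transformed feature is the training-set
    quantile rank, linearly interpolated between training order statistics.
    """

    name = "quantile_uniform"

    def __init__(self):
        self.quantiles_: dict[str, list[float]] = {}

    def fit(self, X):
        self.quantiles_ = {
            c: np.sort(X[c].dropna().to_numpy(dtype=float)).tolist()
            for c in X.columns
        }
        return self

    def transform(self, X):
        out = X.copy()
        for c, q in self.quantiles_.items():
            if c not in out.columns or not q:
                continue
            q = np.asarray(q, dtype=float)
            ranks = np.linspace(0.0, 1.0, len(q))
            out[c] = np.interp(out[c].to_numpy(dtype=float), q, ranks)
        return out

    def state(self):
        return {"quantiles_": self.quantiles_}


class ThresholdOneHot(_Step):
    """Expand sparse-valued features into indicator columns.

    Any feature with at most ``threshold`` distinct training values becomes
    one indicator column per training value; values unseen in training map to
    all-zero indicators.  Dense features pass through unchanged.
    """

    name = "threshold_one_hot"

    def __init__(self, threshold: int = 30):
        self.threshold = threshold
        self.categories_: dict[str, list[float]] = {}

    def fit(self, X):
        self.categories_ = {}
        for c in X.columns:
            vals = np.unique(X[c].dropna().to_numpy(dtype=float))
            if 0 < len(vals) <= self.threshold:
                self.categories_[c] = [float(v) for v in vals]
        return self

    def transform(self, X):
        out = {}
        for c in X.columns:
            if c in self.categories_:
                col = X[c].to_numpy(dtype=float)
                for v in self.categories_[c]:
                    out[f"{c}={v:g}"] = np.isclose(col, v, atol=1e-9).astype(float)
            else:
                out[c] = X[c].to_numpy(dtype=float)
        return pd.DataFrame(out, index=X.index)

    def state(self):
        return {"threshold": self.threshold, "categories_": self.categories_}


class PCA(_Step):
    """Rotate features onto training principal components.

    Keeps the smallest number of components whose training variance share
    reaches ``variance_kept``.
    """

    name = "pca"

    def __init__(self, variance_kept: float = 0.95):
        self.variance_kept = variance_kept
        self.columns_: list[str] = []
        self.means_: list[float] = []
        self.components_: list[list[float]] = []

    def fit(self, X):
        self.columns_ = list(X.columns)
        A = X.to_numpy(dtype=float)
        mu = A.mean(axis=0)
        self.means_ = mu.tolist()
        _, s, vt = np.linalg.svd(A - mu, full_matrices=False)
        var = s ** 2
        share = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
        k = int(np.searchsorted(share, self.variance_kept - 1e-12) + 1)
        self.components_ = vt[:k].tolist()
        return self

    def transform(self, X):
        A = X[self.columns_].to_numpy(dtype=float) - np.asarray(self.means_)
        Z = A @ np.asarray(self.components_).T
        return pd.DataFrame(Z, index=X.index,
                            columns=[f"pc{i + 1}" for i in range(Z.shape[1])])

    def state(self):
        return {"variance_kept": self.variance_kept, "columns_": self.columns_,
                "means_": self.means_, "components_": self.components_}


_STEP_CLASSES = {cls.name: cls for cls in
                 (Impute, ScaleCenter, QuantileUniform, ThresholdOneHot, PCA)}


class FittedTransformer:
    """An ordered chain of fitted preprocessing steps."""

    def __init__(self, spec: TransformSpec, steps: list[_Step], columns: list[str]):
        self.spec = spec
        self.steps = steps
        self.columns = columns  # raw feature columns seen at fit time

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks fitted feature column(s): {missing}")
        out = X[self.columns].astype(float)
        for step in self.steps:
            out = step.transform(out)
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "columns": self.columns,
            "spec": [[name, kw] for name, kw in self.spec.steps],
            "steps": [{"name": s.name, "state": s.state()} for s in self.steps],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "FittedTransformer":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        spec = TransformSpec(tuple((n, kw) for n, kw in payload["spec"]))
        steps = [_STEP_CLASSES[s["name"]].from_state(s["state"])
                 for s in payload["steps"]]
        return cls(spec, steps, payload["columns"])


def fit_transform(spec: TransformSpec, train_table: pd.DataFrame,
                  feature_cols: Sequence[str] | None = None) -> FittedTransformer:
    """Fit a transform chain on training rows only."""
    if feature_cols is None:
        feature_cols = [c for c in train_table.columns
                        if c not in ("animal_id", "date", "label")]
    X = train_table[list(feature_cols)].astype(float)
    steps: list[_Step] = []
    for name, kw in spec.steps:
        step = _STEP_CLASSES[name](**kw)
        step.fit(X)
        X = step.transform(X)
        steps.append(step)
    return FittedTransformer(spec, steps, list(feature_cols))
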