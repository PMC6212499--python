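"""Bagged regularized logistic-regression ensemble for PU training.

Training data is positive-vs-unlabeled: the unlabeled class is treated
as label 0 during member fits (the standard non-traditional PU
classifier), and the class-prior machinery in :mod:`arginylome.pu`
later corrects the resulting scores. Each ensemble member is fitted on
a bootstrap resample of the positives plus an equal-size uniform
subsample of the unlabeled pool, z-scored per bag; bag membership is
recorded so out-of-bag scores can be computed. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .peptides import PeptideSet


@dataclass
class TrainingSet:
    """Feature matrix with PU labels and optional provenance/peptides.

    ``y`` is 1 for labeled positives and 0 for unlabeled instances.
    """

    X: np.ndarray
    y: np.ndarray
    sources: Optional[List[str]] = None
    peptides: Optional[PeptideSet] = None
    feature_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y differ in length")
        if np.isnan(self.X).any():
            raise ValueError("missing values in feature matrix")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be 0 (unlabeled) or 1 (positive)")
        if (self.y == 1).sum() < 1 or (self.y == 0).sum() < 1:
            raise ValueError("need at least one positive and one unlabeled instance")
        if self.sources is not None and len(self.sources) != len(self.y):
            raise ValueError("sources length mismatch")
        if self.peptides is not None and len(self.peptides) != len(self.y):
            raise ValueError("peptides length mismatch")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: Sequence[int]) -> "TrainingSet":
        idx = np.asarray(idx)
        return TrainingSet(
            self.X[idx],
            self.y[idx],
            [self.sources[i] for i in idx] if self.sources is not None else None,
            PeptideSet([self.peptides[i] for i in idx], allow_duplicates=True)
            if self.peptides is not None
            else None,
            self.feature_names,
        )


@dataclass
class EnsembleMember:
    weights: np.ndarray  # p coefficients
    intercept: float
    mean: np.ndarray  # per-feature standardization mean (on the bag)
    scale: np.ndarray  # per-feature standardization sd (0 -> 1)
    bag: np.ndarray  # training-row indices used (with bootstrap multiplicity)


@dataclass
class LREModel:
    """Bagged L2 logistic regression with recorded bags."""

    members: List[EnsembleMember]
    n_members: int
    l2_strength: float
    seed: int
    feature_names: Optional[List[str]] = None

    @property
    def n_features(self) -> int:
        return self.members[0].weights.shape[0]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def train_ensemble(
    data: TrainingSet,
    n_members: int = 100,
    l2_strength: float = 1.0,
    seed: int = 0,
) -> LREModel:
    """Fit the bagged PU logistic ensemble.

    Each member: bootstrap of the positives (size n_pos, with
    replacement) plus a uniform subsample of the unlabeled pool of the
    same size (without replacement when the pool allows), standardized
    on the bag, fitted with L2-regularized logistic regression
    (tolerance 1e-6, max 1000 iterations). A degenerate single-class bag
    is resampled up to 100 times.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if l2_strength <= 0:
        raise ValueError("l2_strength must be positive")
    pos_idx = np.flatnonzero(data.y == 1)
    unl_idx = np.flatnonzero(data.y == 0)
    n_pos = pos_idx.size

    member_seeds = np.random.SeedSequence(seed).spawn(n_members)
    members: List[EnsembleMember] = []
    for ss in member_seeds:
        rng = np.random.default_rng(ss)
        for _ in range(100):
            boot_pos = rng.choice(pos_idx, size=n_pos, replace=True)
            replace = unl_idx.size < n_pos
            sub_unl = rng.choice(unl_idx, size=n_pos, replace=replace)
            bag = np.concatenate([boot_pos, sub_unl])
            yb = data.y[bag]
            if yb.min() != yb.max():
                break
        else:  # pragma: no cover - unreachable with balanced construction
            raise RuntimeError("could not draw a two-class bag in 100 retries")
        Xb = data.X[bag]
        mean = Xb.mean(axis=0)
        scale = Xb.std(axis=0)
        scale[scale == 0] = 1.0
        Zb = (Xb - mean) / scale
        clf = LogisticRegression(
            C=1.0 / l2_strength,  # L2 penalty (sklearn default)
            tol=1e-6,
            max_iter=1000,
            solver="lbfgs",
        )
        clf.fit(Zb, yb)
        members.append(
            EnsembleMember(
                weights=clf.coef_.ravel().copy(),
                intercept=float(clf.intercept_[0]),
                mean=mean,
                scale=scale,
                bag=bag,
            )
        )
    return LREModel(members, n_members, l2_strength, seed, data.feature_names)


def predict_scores(model: LREModel, X: np.ndarray) -> np.ndarray:
    """Mean over members of logistic(wᵀx); order-preserving, in (0, 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.n_features})"
        )
    acc = np.zeros(X.shape[0])
    for m in model.members:
        z = (X - m.mean) / m.scale
        acc += _sigmoid(z @ m.weights + m.intercept)
    return acc / len(model.members)


def oob_scores(model: LREModel, data: TrainingSet) -> np.ndarray:
    """Out-of-bag score per training instance; NaN where no member omits it."""
    if data.n_features != model.n_features:
        raise ValueError("feature count mismatch between model and data")
    n = len(data)
    total = np.zeros(n)
    count = np.zeros(n)
    for m in model.members:
        in_bag = np.zeros(n, dtype=bool)
        in_bag[m.bag] = True
        out = ~in_bag
        if not out.any():
            continue
        z = (data.X[out] - m.mean) / m.scale
        total[out] += _sigmoid(z @ m.weights + m.intercept)
        count[out] += 1
    with np.errstate(invalid="ignore"):
        scores = total / count
    scores[count == 0] = np.nan
    return scores


def model_to_json(model: LREModel) -> str:
    """Serialize for bit-exact reload."""
    payload = {
        "n_members": model.n_members,
        "l2_strength": model.l2_strength,
        "seed": model.seed,
        "feature_names": model.feature_names,
        "members": [
            {
                "weights": m.weights.tolist(),
                "intercept": m.intercept,
                "mean": m.mean.tolist(),
                "scale": m.scale.tolist(),
                "bag": m.bag.tolist(),
            }
            for m in model.members
        ],
    }
    return json.dumps(payload)


def model_from_json(text: str) -> LREModel:
    payload = json.loads(text)
    members = [
        EnsembleMember(
            weights=np.array(m["weights"]),
            intercept=float(m["intercept"]),
            mean=np.array(m["mean"]),
            scale=np.array(m["scale"]),
            bag=np.array(m["bag"], dtype=int),
        )
        for m in payload["members"]
    ]
    return LREModel(
        members,
        payload["n_members"],
        payload["l2_strength"],
        payload["seed"],
        payload.get("feature_names"),
    )
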