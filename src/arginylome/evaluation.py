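"""Predictor evaluation: AUC, cross-validation, transfer, feature
association, and the in-silico baseline protocols.

The baselines re-run the training protocol under randomized conditions
to quantify how much apparent performance survives when parts of the
real signal are destroyed:

* ``random_labels`` — keep the literature-analogue positives, permute
  the assay outcomes of the array subset.
* ``random_design`` — additionally replace the designed array peptides
  with uniformly drawn background peptides.
* ``random_initial`` — re-run the whole campaign from a random initial
  training set, design a follow-up array by score binning, assign
  random outcomes, and evaluate the final model.

Their mean cross-validated AUCs order as
random_design <= random_labels <= full-model CV AUC: permuted labels on
a *designed* array still place genuine signal peptides in the positive
class by chance, while a random design contributes pure noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .ensemble import LREModel, TrainingSet, predict_scores, train_ensemble
from .motif import fit_motif, residue_frequencies, score_motif_many
from .peptides import Label, PeptideSet


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann–Whitney rank form (ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc requires at least one positive and one negative")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# model specifications: fit on a TrainingSet, score a TrainingSet


class LRESpec:
    """Logistic-regression-ensemble model specification for CV/transfer.

    ``fit`` returns a scorer ``f(X, peptides=None) -> scores``.
    """

    def __init__(self, n_members: int = 100, l2_strength: float = 1.0):
        self.n_members = n_members
        self.l2_strength = l2_strength

    def fit(self, data: TrainingSet, seed: int) -> Callable[..., np.ndarray]:
        model = train_ensemble(data, self.n_members, self.l2_strength, seed)
        return lambda X, peptides=None: predict_scores(model, X)


class MotifSpec:
    """PSSM motif model specification; requires peptides on the data."""

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, data: TrainingSet, seed: int) -> Callable[..., np.ndarray]:
        if data.peptides is None:
            raise ValueError("MotifSpec requires peptides on the TrainingSet")
        pos = PeptideSet(
            [data.peptides[i] for i in np.flatnonzero(data.y == 1)], allow_duplicates=True
        )
        unl = PeptideSet(
            [data.peptides[i] for i in np.flatnonzero(data.y == 0)], allow_duplicates=True
        )
        background = residue_frequencies(unl) if len(unl) else None
        model = fit_motif(pos, background, self.pseudocount)
        return lambda X, peptides=None: score_motif_many(model, peptides)


ModelSpec = Union[LRESpec, MotifSpec]


def resolve_model_spec(spec) -> ModelSpec:
    if isinstance(spec, str):
        if spec == "lre":
            return LRESpec()
        if spec == "motif":
            return MotifSpec()
        raise ValueError(f"unknown model spec {spec!r}")
    return spec


# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    fold_assignment: np.ndarray
    fold_aucs: List[float]
    mean_auc: float
    sd_auc: float
    pooled_auc: float
    k: int
    seed: int


def stratified_kfold_cv(
    data: TrainingSet, k: int = 10, seed: int = 0, model_spec: ModelSpec = "lre"
) -> CVResult:
    """Stratified k-fold cross-validation; deterministic folds given seed.

    The model is refit on the training folds only; both the mean of
    per-fold AUCs (the headline number) and the pooled AUC over all
    held-out scores are reported.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if (data.y == 1).sum() < k or (data.y == 0).sum() < k:
        raise ValueError("need at least k positives and k unlabeled instances")
    spec = resolve_model_spec(model_spec)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.empty(len(data), dtype=int)
    pooled_scores = np.empty(len(data))
    fold_aucs: List[float] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(data.X, data.y)):
        fold_assignment[test_idx] = fold
        y_test = data.y[test_idx]
        if y_test.min() == y_test.max():
            raise ValueError(f"fold {fold} holds a single class")
        test = data.subset(test_idx)
        scorer = spec.fit(data.subset(train_idx), seed=seed * 1000 + fold)
        scores = scorer(test.X, test.peptides)
        pooled_scores[test_idx] = scores
        fold_aucs.append(auc(scores, y_test))
    return CVResult(
        fold_assignment,
        fold_aucs,
        float(np.mean(fold_aucs)),
        float(np.std(fold_aucs)),
        auc(pooled_scores, data.y),
        k,
        seed,
    )


@dataclass
class TransferResult:
    auc: float
    sequence_overlap: bool


def transfer_auc(
    train: TrainingSet, test: TrainingSet, model_spec: ModelSpec = "lre", seed: int = 0
) -> TransferResult:
    """Fit once on ``train`` and report AUC on ``test``.

    Provenance tags must be disjoint between the two sets; shared
    sequences are flagged (not fatal) in the result.
    """
    if train.sources is not None and test.sources is not None:
        shared = set(train.sources) & set(test.sources)
        if shared:
            raise ValueError(f"train and test share provenance tags: {sorted(shared)}")
    overlap = False
    if train.peptides is not None and test.peptides is not None:
        overlap = bool(
            set(train.peptides.sequences()) & set(test.peptides.sequences())
        )
        if overlap:
            warnings.warn("train and test share peptide sequences", stacklevel=2)
    spec = resolve_model_spec(model_spec)
    scorer = spec.fit(train, seed=seed)
    return TransferResult(auc(scorer(test.X, test.peptides), test.y), overlap)


# ---------------------------------------------------------------------------


@dataclass
class FeatureAssociation:
    feature: str
    tau: float
    p: float
    significant: bool


def kendall_association(
    X: np.ndarray,
    labels: np.ndarray,
    correction: str = "bonferroni",
    alpha: float = 0.05,
    feature_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Kendall tau-b of each feature against the binary label.

    p-values use the normal approximation; the significance flag applies
    the chosen multiple-testing correction (``bonferroni`` or ``none``)
    at level ``alpha``. Constant features get tau = 0 and p = 1.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("labels are constant")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{i}" for i in range(X.shape[1])]
    )
    taus = np.empty(X.shape[1])
    ps = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            taus[j], ps[j] = 0.0, 1.0
            continue
        tau, p = stats.kendalltau(col, labels, method="asymptotic")
        taus[j], ps[j] = tau, p
    if correction == "bonferroni":
        flags = multipletests(ps, alpha=alpha, method="bonferroni")[0]
    else:
        flags = ps < alpha
    return pd.DataFrame(
        {"feature": names, "tau": taus, "p": ps, "significant": flags}
    )


# ---------------------------------------------------------------------------
# simulation baselines


BASELINE_PROTOCOLS = ("random_labels", "random_design", "random_initial")


@dataclass
class BaselineResult:
    protocol: str
    n_runs: int
    mean_auc: float
    sd_auc: float
    run_aucs: List[float]


def _permute_subset_labels(
    y: np.ndarray, subset: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = y.copy()
    out[subset] = rng.permutation(y[subset])
    return out


def simulate_baseline(
    protocol: str,
    base: TrainingSet,
    n_runs: int,
    seed: int = 0,
    model_spec: ModelSpec = "lre",
    k: int = 5,
    array_prefix: str = "array",
) -> BaselineResult:
    """Mean ± sd of cross-validated AUC under a randomized protocol.

    ``base`` must carry source tags; rows whose source starts with
    ``array_prefix`` form the array subset that the protocols randomize.
    """
    if protocol not in BASELINE_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {BASELINE_PROTOCOLS}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if base.sources is None:
        raise ValueError("baseline simulation requires source tags on the data")
    from . import synthetic  # deferred to keep module import light

    spec = resolve_model_spec(model_spec)
    array_rows = np.array([s.startswith(array_prefix) for s in base.sources])
    if protocol in ("random_labels", "random_design") and not array_rows.any():
        raise ValueError("no array-subset rows found in base data")

    run_aucs: List[float] = []
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    for run, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        run_seed = int(ss.generate_state(1)[0] % 2**31)
        if protocol == "random_labels":
            y = _permute_subset_labels(base.y, np.flatnonzero(array_rows), rng)
            data = TrainingSet(base.X, y, base.sources, base.peptides, base.feature_names)
        elif protocol == "random_design":
            n_array = int(array_rows.sum())
            repl = synthetic.generate_background_peptides(n_array, seed=run_seed)
            _, X_repl = synthetic.featurize(repl)
            X = base.X.copy()
            X[array_rows] = X_repl
            y = _permute_subset_labels(base.y, np.flatnonzero(array_rows), rng)
            peptides = None
            if base.peptides is not None:
                merged = list(base.peptides)
                for row, pep in zip(np.flatnonzero(array_rows), repl):
                    merged[row] = pep
                peptides = PeptideSet(merged, allow_duplicates=True)
            data = TrainingSet(X, y, base.sources, peptides, base.feature_names)
        else:  # random_initial
            data = _random_initial_campaign(base, spec, rng, run_seed)
        result = stratified_kfold_cv(data, k=k, seed=run_seed % 100000, model_spec=spec)
        run_aucs.append(result.mean_auc)
    return BaselineResult(
        protocol,
        n_runs,
        float(np.mean(run_aucs)),
        float(np.std(run_aucs)),
        run_aucs,
    )


def _random_initial_campaign(
    base: TrainingSet, spec: ModelSpec, rng: np.random.Generator, run_seed: int
) -> TrainingSet:
    """Full-protocol rerun: random initial set with random outcomes, a
    model trained on it, a follow-up array designed by score tertiles
    from that model, and random outcomes on the follow-up array."""
    from . import synthetic
    from .design import select_by_score_bins
    from .features import featurize

    n_initial = len(base) // 2
    n_per_bin = max((len(base) - n_initial) // 3, 2)
    init_peps = synthetic.generate_background_peptides(n_initial, seed=run_seed)
    _, X_init = featurize(init_peps)
    y_init = (rng.random(n_initial) < 0.5).astype(int)
    if y_init.sum() in (0, n_initial):  # force two classes
        y_init[0] = 1 - y_init[0]
    init_data = TrainingSet(X_init, y_init, ["literature"] * n_initial, init_peps)
    scorer = spec.fit(init_data, seed=run_seed)

    pool_peps = synthetic.generate_background_peptides(
        9 * n_per_bin + 3, seed=run_seed + 1
    )
    _, X_pool = featurize(pool_peps)
    pool_scores = scorer(X_pool, pool_peps)
    selection = select_by_score_bins(
        pool_peps, pool_scores, n_per_bin=n_per_bin, seed=run_seed + 2
    )
    sel_idx = selection.indices
    y_sel = (rng.random(sel_idx.size) < 0.5).astype(int)
    X = np.vstack([X_init, X_pool[sel_idx]])
    y = np.concatenate([y_init, y_sel])
    peptides = PeptideSet(
        list(init_peps) + [pool_peps[i] for i in sel_idx], allow_duplicates=True
    )
    sources = ["literature"] * n_initial + ["array3"] * sel_idx.size
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        flip = np.argsort(y)[:2] if y.sum() >= len(y) - 1 else np.argsort(-y)[:2]
        y[flip] = 1 - y[flip]
    return TrainingSet(X, y, sources, peptides)
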