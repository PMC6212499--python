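"""Synthetic peptide sets, score mixtures, and proteomes with known truth.

The peptide generator emulates the statistical structure of an
N-terminal arginylation study: 12-mer windows anchored at a D/E site,
with positives enriched for His/Cys at offsets +1 and +2, Tyr at +3 and
+4, Met at +7, and a mildly positive net charge (K/R favored and D/E
disfavored at non-signal offsets). Unlabeled peptides are background
12-mers over the same D/E-anchored window, contaminated with a known
fraction ``alpha_true`` of signal-carrying peptides; a fraction
``beta_true`` of the labeled positives is replaced by background
(mislabeling). Every draw is deterministic given the seed, and the
ground truth for each instance is returned alongside the peptides so
recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .ensemble import TrainingSet
from .features import FeatureConfig, featurize
from .peptides import AMINO_ACIDS, Label, Peptide, PeptideSet, ProteinRecord, Source

_AA = list(AMINO_ACIDS)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _uniform_background() -> np.ndarray:
    return np.full(len(_AA), 1.0 / len(_AA))


@dataclass(frozen=True)
class SignalParams:
    """Planted positive-class signal.

    ``p_hc1``/``p_hc2`` are the probabilities of planting H-or-C at
    offsets +1/+2, ``p_y3``/``p_y4`` of Tyr at +3/+4 and ``p_m7`` of Met
    at +7. ``charge_bias`` multiplies the K/R draw probability (and
    divides the D/E probability) at non-signal offsets of positives,
    shifting their net charge mildly positive. ``p_first_d`` is the
    probability that the anchored first residue is D rather than E.
    """

    p_hc1: float = 0.6
    p_hc2: float = 0.6
    p_y3: float = 0.4
    p_y4: float = 0.4
    p_m7: float = 0.5
    charge_bias: float = 2.0
    p_first_d: float = 0.5
    background: Tuple[float, ...] = tuple(_uniform_background())

    def __post_init__(self) -> None:
        for name in ("p_hc1", "p_hc2", "p_y3", "p_y4", "p_m7", "p_first_d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        bg = np.asarray(self.background)
        if bg.size != len(_AA) or not np.isclose(bg.sum(), 1.0) or np.any(bg < 0):
            raise ValueError("background must be 20 non-negative frequencies summing to 1")

    @property
    def positive_offset_background(self) -> np.ndarray:
        """Charge-shifted residue distribution for positive non-signal offsets."""
        probs = np.asarray(self.background, dtype=float).copy()
        for aa in "KR":
            probs[_AA_INDEX[aa]] *= self.charge_bias
        for aa in "DE":
            probs[_AA_INDEX[aa]] /= self.charge_bias
        return probs / probs.sum()

    #: (offset, candidate residues, plant probability) of the planted cells
    @property
    def signal_cells(self) -> List[Tuple[int, str, float]]:
        return [
            (1, "HC", self.p_hc1),
            (2, "HC", self.p_hc2),
            (3, "Y", self.p_y3),
            (4, "Y", self.p_y4),
            (7, "M", self.p_m7),
        ]


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside generated data."""

    is_true_positive: np.ndarray  # per instance, in generation order
    alpha_true: float
    beta_true: float


def _draw_sequence(rng: np.random.Generator, probs: np.ndarray, length: int) -> str:
    idx = rng.choice(len(_AA), size=length, p=probs)
    return "".join(_AA[i] for i in idx)


def _positive_window(rng: np.random.Generator, params: SignalParams, length: int = 12) -> str:
    first = "D" if rng.random() < params.p_first_d else "E"
    probs = params.positive_offset_background
    tail = list(_draw_sequence(rng, probs, length - 1))
    for offset, residues, p in params.signal_cells:
        if offset <= length - 1 and rng.random() < p:
            tail[offset - 1] = residues[rng.integers(len(residues))]
    return first + "".join(tail)


def _background_window(rng: np.random.Generator, params: SignalParams, length: int = 12) -> str:
    first = "D" if rng.random() < params.p_first_d else "E"
    probs = np.asarray(params.background, dtype=float)
    return first + _draw_sequence(rng, probs, length - 1)


def generate_dataset(
    n_pos: int,
    n_unl: int,
    alpha_true: float = 0.0,
    beta_true: float = 0.0,
    params: SignalParams = SignalParams(),
    seed: int = 0,
    window_length: int = 12,
    source: Source = Source.SYNTHETIC,
) -> Tuple[PeptideSet, SyntheticTruth]:
    """Generate a PU peptide dataset with planted signal and known truth.

    Returns the peptides (positives first, then unlabeled) and the
    per-instance truth: labeled positives carry signal except for a
    ``beta_true`` fraction replaced by background; unlabeled peptides
    are background except for an ``alpha_true`` fraction replaced by
    signal peptides.
    """
    for name, v in (("alpha_true", alpha_true), ("beta_true", beta_true)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if n_pos < 1 or n_unl < 1:
        raise ValueError("n_pos and n_unl must be >= 1")
    rng = np.random.default_rng(seed)
    peptides: List[Peptide] = []
    truth = np.zeros(n_pos + n_unl, dtype=bool)
    for i in range(n_pos):
        mislabeled = rng.random() < beta_true
        seq = (
            _background_window(rng, params, window_length)
            if mislabeled
            else _positive_window(rng, params, window_length)
        )
        truth[i] = not mislabeled
        peptides.append(Peptide(seq, Label.POSITIVE, source))
    for j in range(n_unl):
        hidden_positive = rng.random() < alpha_true
        seq = (
            _positive_window(rng, params, window_length)
            if hidden_positive
            else _background_window(rng, params, window_length)
        )
        truth[n_pos + j] = hidden_positive
        peptides.append(Peptide(seq, Label.UNLABELED, source))
    return (
        PeptideSet(peptides, metadata=f"synthetic seed={seed}", allow_duplicates=True),
        SyntheticTruth(truth, alpha_true, beta_true),
    )


def generate_background_peptides(
    n: int,
    params: SignalParams = SignalParams(),
    seed: int = 0,
    window_length: int = 12,
    label: Label = Label.UNLABELED,
    source: Source = Source.SYNTHETIC,
) -> PeptideSet:
    """Uniformly drawn D/E-anchored background 12-mers (no planted signal)."""
    rng = np.random.default_rng(seed)
    peps = [
        Peptide(_background_window(rng, params, window_length), label, source)
        for _ in range(n)
    ]
    return PeptideSet(peps, allow_duplicates=True)


def generate_score_mixture(
    n_pos: int,
    n_unl: int,
    alpha_true: float,
    separation: float = 2.0,
    beta_true: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Generate labeled-positive and unlabeled score samples in [0, 1].

    Latent positive and negative score logits are unit-variance normals
    with means ``±separation/2``, squashed by the logistic map. The
    unlabeled sample mixes the components at ``alpha_true``; a
    ``beta_true`` fraction of the "positive" sample is drawn from the
    negative component (mislabeling).
    """
    if not 0.0 <= alpha_true <= 1.0 or not 0.0 <= beta_true <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    mu = separation / 2.0
    pos_is_tp = rng.random(n_pos) >= beta_true
    pos_logits = np.where(pos_is_tp, rng.normal(mu, 1.0, n_pos), rng.normal(-mu, 1.0, n_pos))
    unl_is_tp = rng.random(n_unl) < alpha_true
    unl_logits = np.where(unl_is_tp, rng.normal(mu, 1.0, n_unl), rng.normal(-mu, 1.0, n_unl))
    squash = lambda z: 1.0 / (1.0 + np.exp(-z))
    truth = SyntheticTruth(np.concatenate([pos_is_tp, unl_is_tp]), alpha_true, beta_true)
    return squash(pos_logits), squash(unl_logits), truth


def to_training_set(
    peptides: PeptideSet, config: FeatureConfig = FeatureConfig()
) -> TrainingSet:
    """Featurize a labeled peptide set into a :class:`TrainingSet`."""
    names, X = featurize(peptides, config)
    y = np.array([1 if p.label is Label.POSITIVE else 0 for p in peptides])
    return TrainingSet(X, y, [p.source.value for p in peptides], peptides, names)


def generate_campaign(
    n_lit_pos: int = 40,
    n_lit_unl: int = 600,
    n_array_per_bin: int = 40,
    pool_signal_rate: float = 0.5,
    pool_factor: int = 4,
    design_members: int = 10,
    params: SignalParams = SignalParams(),
    seed: int = 0,
    config: FeatureConfig = FeatureConfig(),
) -> TrainingSet:
    """A literature + designed-array training set emulating the full
    model-guided campaign.

    A small literature set (genuine signal positives against a large
    unlabeled background) trains an initial ensemble; the ensemble
    scores a candidate pool carrying signal peptides at
    ``pool_signal_rate``, and equal numbers of low-, medium- and
    high-scoring peptides are selected for the array. Array labels are
    the selected peptides' true signal status (the assay outcome).
    Sources are tagged ``literature`` and ``array2`` so the baseline
    simulations can randomize the array subset while keeping the
    literature positives intact.
    """
    from .design import select_by_score_bins
    from .ensemble import train_ensemble, predict_scores

    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    lit, _ = generate_dataset(
        n_lit_pos, n_lit_unl, params=params, seed=seeds[0], source=Source.LITERATURE
    )
    lit_data = to_training_set(lit, config)
    initial = train_ensemble(lit_data, n_members=design_members, seed=seeds[1])

    n_pool = pool_factor * 3 * n_array_per_bin
    pool, pool_truth = generate_dataset(
        n_pos=max(int(round(n_pool * pool_signal_rate)), 1),
        n_unl=n_pool - max(int(round(n_pool * pool_signal_rate)), 1),
        params=params,
        seed=seeds[2],
        source=Source.ARRAY2,
    )
    _, X_pool = featurize(pool, config)
    pool_scores = predict_scores(initial, X_pool)
    selection = select_by_score_bins(pool, pool_scores, n_array_per_bin, seed=seeds[2])

    array_peps = []
    array_truth = []
    for i in selection.indices:
        is_signal = bool(pool_truth.is_true_positive[i])
        p = pool[int(i)]
        array_peps.append(
            Peptide(
                p.sequence,
                Label.POSITIVE if is_signal else Label.UNLABELED,
                Source.ARRAY2,
            )
        )
        array_truth.append(is_signal)
    if not any(array_truth) or all(array_truth):
        raise ValueError("designed array subset is single-class; enlarge the pool")
    combined = PeptideSet(list(lit) + array_peps, allow_duplicates=True)
    return to_training_set(combined, config)


def generate_proteome(
    n_proteins: int,
    signal_fraction: float = 0.03,
    params: SignalParams = SignalParams(),
    min_length: int = 30,
    max_length: int = 120,
    seed: int = 0,
) -> Tuple[List[ProteinRecord], np.ndarray]:
    """Synthetic proteome where every protein starts with Met + a D/E window.

    A ``signal_fraction`` of proteins carries a positive-signal
    N-terminal window (arginylation-favorable after Met cleavage); the
    rest carry background windows. Returns the records and the boolean
    truth vector.
    """
    if not 0.0 <= signal_fraction <= 1.0:
        raise ValueError("signal_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bg = np.asarray(params.background, dtype=float)
    records: List[ProteinRecord] = []
    truth = np.zeros(n_proteins, dtype=bool)
    for i in range(n_proteins):
        is_signal = rng.random() < signal_fraction
        window = (
            _positive_window(rng, params) if is_signal else _background_window(rng, params)
        )
        tail_len = int(rng.integers(min_length, max_length + 1)) - len(window) - 1
        tail = _draw_sequence(rng, bg, max(tail_len, 0))
        # keep the tail free of D/E so the N-terminal window is each
        # protein's only conservative-mode candidate site
        tail = tail.replace("D", "S").replace("E", "T")
        records.append(ProteinRecord(f"prot{i:05d}", "M" + window + tail))
        truth[i] = is_signal
    return records, truth
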