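"""Consensus-motif predictor and per-position enrichment statistics.

The motif predictor is a position-specific scoring matrix over offsets
+1..+11 relative to the target site (position 1, the constrained D/E,
is excluded). Log-odds are computed against a background residue
distribution with a pseudocount, and the summed raw score is calibrated
to (0, 1) with a logistic map fitted on the training-score distribution,
so motif scores live on the same scale as ensemble scores.

The two-sample logo compares per-(offset, residue) frequencies between
a positive and a background peptide set with Fisher's exact test,
uncorrected by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .peptides import AMINO_ACIDS, PAD, Peptide, PeptideError, PeptideSet

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def residue_frequencies(peptides: PeptideSet, pseudocount: float = 1.0) -> np.ndarray:
    """Overall residue frequencies of a peptide set (pads ignored).

    A small pseudocount keeps every frequency positive so log-odds stay
    finite. Used to build the background distribution, by default from
    the unlabeled set.
    """
    counts = np.full(len(AMINO_ACIDS), float(pseudocount))
    for p in peptides:
        for ch in p.unpadded:
            counts[_AA_INDEX[ch]] += 1.0
    return counts / counts.sum()


@dataclass
class MotifModel:
    """PSSM log-odds with background and score calibration."""

    log_odds: np.ndarray  # (window_length - 1, 20); row o-1 is offset +o
    background: np.ndarray  # 20 frequencies summing to 1
    pseudocount: float
    calibration: tuple  # (mean, sd) of raw training scores

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not math.isclose(self.background.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @property
    def window_length(self) -> int:
        return self.log_odds.shape[0] + 1

    def consensus(self, first_residue: str = "D") -> str:
        """Per-offset argmax sequence (the consensus motif)."""
        tail = "".join(AMINO_ACIDS[j] for j in self.log_odds.argmax(axis=1))
        return first_residue + tail


def raw_motif_score(model: MotifModel, peptide: Union[Peptide, str]) -> float:
    """Sum of log-odds over offsets +1..+(L−1); pads contribute zero."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    L = model.window_length
    if len(seq) > L:
        raise PeptideError(f"peptide length {len(seq)} exceeds model window {L}")
    seq = seq + PAD * (L - len(seq))
    total = 0.0
    for o in range(1, L):
        ch = seq[o]
        if ch != PAD:
            total += model.log_odds[o - 1, _AA_INDEX[ch]]
    return total


def fit_motif(
    positives: PeptideSet,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 1.0,
) -> MotifModel:
    """Fit a PSSM on the positive set.

    log_odds[o][a] = log((count(o,a) + pc·bg[a]) / ((N_o + pc)·bg[a]))
    where N_o is the number of non-pad residues observed at offset +o.
    Calibration (mean, sd) is fitted on the raw scores of the training
    positives; a degenerate sd of 0 falls back to 1.
    """
    if len(positives) == 0:
        raise PeptideError("cannot fit a motif on an empty positive set")
    lengths = {len(p) for p in positives}
    if len(lengths) != 1:
        raise PeptideError(f"positives must share one window length, got {sorted(lengths)}")
    L = lengths.pop()
    if background is None:
        background = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValueError("background frequencies must be strictly positive")

    counts = np.zeros((L - 1, len(AMINO_ACIDS)))
    n_obs = np.zeros(L - 1)
    for p in positives:
        for o in range(1, L):
            ch = p.sequence[o]
            if ch != PAD:
                counts[o - 1, _AA_INDEX[ch]] += 1.0
                n_obs[o - 1] += 1.0

    with np.errstate(divide="ignore"):
        numer = counts + pseudocount * background[None, :]
        denom = (n_obs[:, None] + pseudocount) * background[None, :]
        log_odds = np.log(numer / denom)
    log_odds[np.isneginf(log_odds)] = -30.0  # zero count, zero pseudocount

    model = MotifModel(log_odds, background, pseudocount, (0.0, 1.0))
    raws = np.array([raw_motif_score(model, p) for p in positives])
    sd = float(raws.std())
    model.calibration = (float(raws.mean()), sd if sd > 0 else 1.0)
    return model


def score_motif(model: MotifModel, peptide: Union[Peptide, str]) -> float:
    """Calibrated motif score in (0, 1), monotone in the raw PSSM score."""
    mean, sd = model.calibration
    raw = raw_motif_score(model, peptide)
    return float(1.0 / (1.0 + math.exp(-(raw - mean) / sd)))


def score_motif_many(model: MotifModel, peptides) -> np.ndarray:
    return np.array([score_motif(model, p) for p in peptides])


def two_sample_logo(
    positives: PeptideSet, negatives: PeptideSet, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-(offset, residue) enrichment of positives over a background set.

    For each offset +1..+(L−1) and residue, a Fisher exact test compares
    the residue's occurrence in the two sets; the p-value is the exact
    tail in the direction of the observed frequency difference,
    uncorrected for multiple testing by default (``significant`` flags
    p < alpha). Returns a table with columns offset, residue, freq_pos,
    freq_neg, diff, p, direction, significant.
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise PeptideError("two_sample_logo requires non-empty sets")
    L = len(positives[0])
    if any(len(p) != L for p in positives) or any(len(p) != L for p in negatives):
        raise PeptideError("all peptides must share one window length")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")

    def offset_counts(ps: PeptideSet) -> tuple:
        cnt = np.zeros((L - 1, len(AMINO_ACIDS)), dtype=int)
        tot = np.zeros(L - 1, dtype=int)
        for p in ps:
            for o in range(1, L):
                ch = p.sequence[o]
                if ch != PAD:
                    cnt[o - 1, _AA_INDEX[ch]] += 1
                    tot[o - 1] += 1
        return cnt, tot

    cpos, npos = offset_counts(positives)
    cneg, nneg = offset_counts(negatives)

    rows = []
    for o in range(1, L):
        for j, aa in enumerate(AMINO_ACIDS):
            a, b = int(cpos[o - 1, j]), int(npos[o - 1] - cpos[o - 1, j])
            c, d = int(cneg[o - 1, j]), int(nneg[o - 1] - cneg[o - 1, j])
            fp = a / npos[o - 1] if npos[o - 1] else 0.0
            fn = c / nneg[o - 1] if nneg[o - 1] else 0.0
            diff = fp - fn
            direction = "enriched" if diff >= 0 else "depleted"
            alternative = "greater" if diff >= 0 else "less"
            if diff == 0.0:
                p = 1.0
            else:
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            rows.append(
                {
                    "offset": o,
                    "residue": aa,
                    "freq_pos": fp,
                    "freq_neg": fn,
                    "diff": diff,
                    "p": float(p),
                    "direction": direction,
                    "significant": bool(p < alpha and diff != 0.0),
                }
            )
    return pd.DataFrame(rows)
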