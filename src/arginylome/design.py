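"""Peptide-array design utilities.

Score-guided selection picks equal numbers of low-, medium- and
high-scoring peptides (tertile bins) from a scored pool for
experimental validation. The single-site design keeps only peptides
whose sole acidic residue (D or E) sits at position 1, so an observed
arginylation signal can be localized unambiguously. Shuffle pairs hold
the first residue fixed and permute the rest, producing a partner with
identical composition but scrambled positional context — the control
that separates composition-driven from position-driven recognition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np

from .peptides import ACIDIC, Label, Peptide, PeptideError, PeptideSet


@dataclass
class BinSelection:
    """Result of score-binned selection: peptides, pool indices, bin tags."""

    peptides: PeptideSet
    indices: np.ndarray
    bins: List[str]  # "low" | "medium" | "high", aligned with peptides

    def __len__(self) -> int:
        return len(self.peptides)


def select_by_score_bins(
    pool: Union[PeptideSet, Sequence[Peptide]],
    scores: np.ndarray,
    n_per_bin: int,
    seed: int = 0,
) -> BinSelection:
    """Sample ``n_per_bin`` peptides from each score tertile of the pool.

    The pool is rank-split at score tertiles into low/medium/high bins
    and a uniform sample without replacement is drawn from each;
    deterministic given the seed. Identical tertile boundary scores
    (degenerate tertiles) are an error, as is a bin smaller than
    ``n_per_bin``.
    """
    peptides = list(pool)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(peptides):
        raise ValueError("scores and pool differ in length")
    if len(peptides) < 3 * n_per_bin:
        raise ValueError(
            f"pool of {len(peptides)} cannot supply 3 bins of {n_per_bin}"
        )
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    if q1 == q2:
        raise PeptideError("degenerate score tertiles: boundary scores coincide")
    order = np.argsort(scores, kind="stable")
    third = len(peptides) // 3
    bins = {
        "low": order[:third],
        "medium": order[third : 2 * third],
        "high": order[2 * third :],
    }
    rng = np.random.default_rng(seed)
    chosen: List[Peptide] = []
    chosen_idx: List[int] = []
    chosen_bin: List[str] = []
    for name in ("low", "medium", "high"):
        members = bins[name]
        if members.size < n_per_bin:
            raise PeptideError(f"bin {name!r} holds only {members.size} peptides")
        pick = rng.choice(members, size=n_per_bin, replace=False)
        for i in sorted(pick):
            chosen.append(peptides[i])
            chosen_idx.append(int(i))
            chosen_bin.append(name)
    return BinSelection(
        PeptideSet(chosen, allow_duplicates=True),
        np.array(chosen_idx, dtype=int),
        chosen_bin,
    )


def _single_acidic_at_start(p: Peptide) -> bool:
    seq = p.unpadded
    return seq[0] in ACIDIC and not any(ch in ACIDIC for ch in seq[1:])


def design_single_site_set(pool: Union[PeptideSet, Sequence[Peptide]], n: int = 222) -> PeptideSet:
    """Select ``n`` peptides whose only D-or-E occurrence is position 1.

    Keeps pool order; raises with the qualifying count if fewer than
    ``n`` peptides pass the filter.
    """
    qualifying = [p for p in pool if _single_acidic_at_start(p)]
    if len(qualifying) < n:
        raise PeptideError(
            f"only {len(qualifying)} peptides have their single D/E at position 1 "
            f"(need {n})"
        )
    return PeptideSet(qualifying[:n], allow_duplicates=True)


def make_shuffled_pair(
    peptide: Peptide, seed: int = 0, min_hamming: int = 9, max_attempts: int = 1000
) -> Peptide:
    """Shuffled partner: position 1 fixed, positions 2+ permuted.

    The permutation must differ from the original in at least
    ``min_hamming`` of the shuffled positions ("highly dissimilar");
    sub-seeded retries make the draw deterministic. Raises when the
    constraint is unsatisfiable (e.g. a homopolymer tail).
    """
    seq = peptide.sequence
    if seq[0] not in ACIDIC:
        raise PeptideError("shuffle design requires D or E at position 1")
    tail = list(seq[1:])
    if min_hamming > len(tail):
        raise ValueError("min_hamming exceeds the number of shuffled positions")
    for attempt_seed in np.random.SeedSequence(seed).spawn(max_attempts):
        rng = np.random.default_rng(attempt_seed)
        perm = list(rng.permutation(tail))
        hamming = sum(a != b for a, b in zip(tail, perm))
        if hamming >= min_hamming:
            return Peptide(seq[0] + "".join(perm), peptide.label, peptide.source)
    raise PeptideError(
        f"no permutation of {seq!r} reaches Hamming distance {min_hamming} "
        f"in {max_attempts} attempts"
    )


def make_shuffled_pairs(
    peptides: Union[PeptideSet, Sequence[Peptide]],
    seed: int = 0,
    min_hamming: int = 9,
) -> List[tuple]:
    """Original/shuffled pairs for a batch; one pair per input peptide."""
    items = list(peptides)
    pairs = []
    seeds = np.random.SeedSequence(seed).spawn(len(items))
    for p, ss in zip(items, seeds):
        sub = int(ss.generate_state(1)[0] % 2**31)
        pairs.append((p, make_shuffled_pair(p, seed=sub, min_hamming=min_hamming)))
    return pairs
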