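"""Proteome scanning and the conservation-intersection filter.

Every D/E residue in a protein defines a candidate arginylation site;
its 12-residue window (starting at the site, right pad-extended at the
C-terminus) is scored by a trained predictor under the assumption that
the site is N-terminally exposed. Two scan modes are supported:
``all_DE`` scores every D/E in the proteome, while ``nterm_conservative``
keeps only D/E at protein positions 1 or 2 — the position-2 case being
an MD/ME start whose initiator methionine is cleaved in vivo. Scores
are converted to posterior probabilities with the estimated class
prior, and the mean posterior is the proteome fraction estimate.

The conservation filter intersects predictions with precomputed
alignment metrics: transcripts need a branch length score above the
threshold, complete conservation of the arginylatable residue, a
positive PhyloCSF score, and a consensus-motif score at or above the
cutoff; one transcript per gene is retained (highest consensus score,
ties broken lexicographically by id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .ensemble import LREModel, predict_scores
from .features import FeatureConfig, extract_features
from .motif import MotifModel, score_motif
from .peptides import ACIDIC, PAD, Peptide, PeptideError, ProteinRecord
from .pu import PriorEstimate, posterior_transform

SCAN_MODES = ("all_DE", "nterm_conservative")


@dataclass(frozen=True)
class SiteWindow:
    """One candidate site: protein, 1-based position, residue, 12-mer window."""

    protein_id: str
    position: int
    residue: str
    window: str

    def __post_init__(self) -> None:
        if self.window[0] != self.residue:
            raise ValueError("window must start at the site residue")


@dataclass
class ScanResult:
    table: pd.DataFrame  # protein, position, residue, window, score, posterior
    fraction: float
    mode: str
    n_sites: int


def extract_site_windows(
    protein: ProteinRecord, mode: str = "all_DE", window_length: int = 12
) -> List[SiteWindow]:
    """Candidate D/E site windows of one protein.

    ``all_DE`` takes every D/E; ``nterm_conservative`` only positions 1
    and 2 (MD/ME starts). Windows truncated by the C-terminus are
    pad-extended; windows containing masked residues (X) are skipped.
    """
    if mode not in SCAN_MODES:
        raise ValueError(f"unknown scan mode {mode!r}; choose from {SCAN_MODES}")
    seq = protein.sequence
    if mode == "all_DE":
        positions = [i for i, ch in enumerate(seq) if ch in ACIDIC]
    else:
        positions = [i for i in (0, 1) if i < len(seq) and seq[i] in ACIDIC]
    windows = []
    for i in positions:
        win = seq[i : i + window_length]
        if "X" in win:
            continue
        win = win + PAD * (window_length - len(win))
        windows.append(SiteWindow(protein.id, i + 1, seq[i], win))
    return windows


def _score_windows(
    windows: Sequence[SiteWindow],
    model: Union[LREModel, MotifModel],
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    peptides = [Peptide(w.window) for w in windows]
    if isinstance(model, LREModel):
        X = np.vstack([extract_features(p, config).values for p in peptides])
        return predict_scores(model, X)
    return np.array([score_motif(model, p) for p in peptides])


def scan_proteome(
    proteins: Sequence[ProteinRecord],
    model: Union[LREModel, MotifModel],
    prior: PriorEstimate,
    mode: str = "nterm_conservative",
    config: FeatureConfig = FeatureConfig(),
) -> ScanResult:
    """Score all candidate windows and estimate the arginylated fraction.

    Windows are extracted per protein, featurized and scored by the
    given predictor; scores become posteriors via the class prior and
    its score densities, and the fraction estimate is the mean
    posterior. Order of proteins does not affect the estimate.
    """
    if prior.densities is None:
        raise ValueError("prior must carry score densities (from estimate_alpha)")
    windows: List[SiteWindow] = []
    for rec in proteins:
        windows.extend(extract_site_windows(rec, mode))
    if not windows:
        raise PeptideError("no candidate D/E windows found in the proteome")
    scores = _score_windows(windows, model, config)
    posteriors = posterior_transform(scores, prior.alpha, prior.densities)
    table = pd.DataFrame(
        {
            "protein": [w.protein_id for w in windows],
            "position": [w.position for w in windows],
            "residue": [w.residue for w in windows],
            "window": [w.window for w in windows],
            "score": scores,
            "posterior": posteriors,
        }
    )
    return ScanResult(table, float(posteriors.mean()), mode, len(windows))


CONSERVATION_COLUMNS = (
    "id",
    "branch_length",
    "phylocsf",
    "residue_conserved",
    "consensus_score",
)


def conservation_filter(
    candidates: pd.DataFrame,
    branch_min: float = 0.4,
    score_min: float = 0.0,
    gene_column: str = "id",
) -> pd.DataFrame:
    """Intersect candidates with conservation evidence.

    Keeps rows with branch_length > ``branch_min``, residue_conserved
    true, phylocsf > 0 and consensus_score >= ``score_min``; retains one
    row per gene id (highest consensus score, ties by lexicographic id).
    """
    missing = [c for c in CONSERVATION_COLUMNS if c not in candidates.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    kept = candidates[
        (candidates["branch_length"] > branch_min)
        & candidates["residue_conserved"].astype(bool)
        & (candidates["phylocsf"] > 0)
        & (candidates["consensus_score"] >= score_min)
    ].copy()
    if kept.empty:
        return kept
    kept = kept.sort_values(
        ["consensus_score", gene_column], ascending=[False, True], kind="stable"
    )
    kept = kept.drop_duplicates(subset=gene_column, keep="first")
    return kept.sort_index()
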