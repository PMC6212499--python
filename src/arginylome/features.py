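"""Peptide featurization.

Each peptide window is turned into a fixed, named feature vector. Under
the default configuration (12-mer windows) the vector has exactly 294
entries, organised in blocks:

* 220 positional indicators — one per (offset, residue) for offsets
  +1..+11 relative to the target site. Position 1 (the site itself) is
  excluded: canonical positives are constrained to D/E there, so it
  carries no discriminative signal.
* 20 global composition frequencies over the whole window.
* 20 proximal composition frequencies over offsets +1..+5.
* 20 distal composition frequencies over offsets +6..+11.
* 14 physicochemical scalars (charge, hydropathy, residue-class
  fractions; see :func:`physchem_scalars`).

Pads (``-``) contribute nothing: indicators at padded offsets are zero
and compositions are computed over non-pad residues only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple, Union

import numpy as np

from .peptides import AMINO_ACIDS, PAD, Peptide, PeptideError, PeptideSet

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPATHY_SCALES = {"kyte_doolittle": KYTE_DOOLITTLE}

AROMATIC = frozenset("FWY")
ALIPHATIC = frozenset("AVLI")
POLAR = frozenset("NQSTYCH")  # uncharged polar side chains
SMALL = frozenset("ACDGNPSTV")  # Taylor's "small" class

SCALAR_NAMES = (
    "net_charge",
    "total_charge",
    "count_KR",
    "count_DE",
    "net_charge_sign",
    "mean_hydropathy",
    "min_hydropathy",
    "max_hydropathy",
    "aromatic_frac",
    "aliphatic_frac",
    "polar_frac",
    "small_frac",
    "HCY_freq",
    "charge_density",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature roster toggles. Defaults give exactly 294 features."""

    window_length: int = 12
    positional: bool = True
    global_composition: bool = True
    proximal_composition: bool = True
    distal_composition: bool = True
    scalars: bool = True
    hydropathy_scale: str = "kyte_doolittle"
    #: last proximal offset; proximal = +1..+5, distal = +6..window end
    proximal_end: int = 5

    def feature_names(self) -> List[str]:
        names: List[str] = []
        if self.positional:
            for o in range(1, self.window_length):
                for aa in AMINO_ACIDS:
                    names.append(f"pos+{o}_{aa}")
        if self.global_composition:
            names.extend(f"comp_global_{aa}" for aa in AMINO_ACIDS)
        if self.proximal_composition:
            names.extend(f"comp_proximal_{aa}" for aa in AMINO_ACIDS)
        if self.distal_composition:
            names.extend(f"comp_distal_{aa}" for aa in AMINO_ACIDS)
        if self.scalars:
            names.extend(SCALAR_NAMES)
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names())


@dataclass
class FeatureVector:
    names: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("feature names and values differ in length")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))

    def __len__(self) -> int:
        return len(self.names)


def physchem_scalars(sequence: str, hydropathy_scale: str = "kyte_doolittle") -> Dict[str, float]:
    """Physicochemical scalars of a (pad-stripped) residue string.

    Charge convention: K and R count +1, D and E count −1; H is not
    counted as charged. ``net_charge = #K+#R − (#D+#E)``;
    ``total_charge = #K+#R+#D+#E``. Hydropathy statistics use the
    configured scale (default Kyte–Doolittle).
    """
    seq = sequence.rstrip(PAD)
    if not seq:
        raise PeptideError("cannot compute scalars of an all-pad sequence")
    if PAD in seq:
        raise PeptideError("internal pad symbol in scalar input")
    scale = HYDROPATHY_SCALES[hydropathy_scale]
    n = len(seq)
    kr = sum(seq.count(a) for a in "KR")
    de = sum(seq.count(a) for a in "DE")
    net = kr - de
    total = kr + de
    hyd = [scale[ch] for ch in seq]
    return {
        "net_charge": float(net),
        "total_charge": float(total),
        "count_KR": float(kr),
        "count_DE": float(de),
        "net_charge_sign": float(np.sign(net)),
        "mean_hydropathy": float(np.mean(hyd)),
        "min_hydropathy": float(np.min(hyd)),
        "max_hydropathy": float(np.max(hyd)),
        "aromatic_frac": sum(ch in AROMATIC for ch in seq) / n,
        "aliphatic_frac": sum(ch in ALIPHATIC for ch in seq) / n,
        "polar_frac": sum(ch in POLAR for ch in seq) / n,
        "small_frac": sum(ch in SMALL for ch in seq) / n,
        "HCY_freq": sum(ch in "HCY" for ch in seq) / n,
        "charge_density": total / n,
    }


def _composition(residues: str) -> np.ndarray:
    """Residue frequencies over non-pad residues; zeros if region is all pad."""
    body = [ch for ch in residues if ch != PAD]
    out = np.zeros(len(AMINO_ACIDS))
    if not body:
        return out
    for ch in body:
        out[AMINO_ACIDS.index(ch)] += 1.0
    return out / len(body)


def extract_features(
    peptide: Union[Peptide, str], config: FeatureConfig = FeatureConfig()
) -> FeatureVector:
    """Featurize one peptide window.

    Peptides shorter than ``window_length`` are right pad-extended;
    longer ones are rejected. Deterministic, with stable names.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    seq = peptide.sequence
    L = config.window_length
    if len(seq) > L:
        raise PeptideError(f"peptide longer ({len(seq)}) than window length {L}")
    seq = seq + PAD * (L - len(seq))

    values: List[float] = []
    if config.positional:
        for o in range(1, L):
            ch = seq[o]
            row = [0.0] * len(AMINO_ACIDS)
            if ch != PAD:
                row[AMINO_ACIDS.index(ch)] = 1.0
            values.extend(row)
    if config.global_composition:
        values.extend(_composition(seq))
    if config.proximal_composition:
        values.extend(_composition(seq[1 : config.proximal_end + 1]))
    if config.distal_composition:
        values.extend(_composition(seq[config.proximal_end + 1 : L]))
    if config.scalars:
        sc = physchem_scalars(seq, config.hydropathy_scale)
        values.extend(sc[name] for name in SCALAR_NAMES)
    return FeatureVector(config.feature_names(), np.asarray(values))


def featurize(
    peptides: PeptideSet, config: FeatureConfig = FeatureConfig()
) -> Tuple[List[str], np.ndarray]:
    """Featurize a peptide set into a (names, n × p matrix) pair."""
    names = config.feature_names()
    X = np.empty((len(peptides), len(names)))
    for i, p in enumerate(peptides):
        X[i] = extract_features(p, config).values
    return names, X
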