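"""Domain types and I/O for peptide tables and protein FASTA.

Peptides are fixed-length sequence windows anchored at a putative
arginylation site (canonically an N-terminally exposed Asp or Glu).
Windows truncated by a protein C-terminus are right-padded with ``-``.
Coordinates are 1-based throughout; a 12-mer window anchored at a site
covers positions [site, site+11].
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, List, Optional, Union

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"
ACIDIC = frozenset("DE")

_AA_SET = frozenset(AMINO_ACIDS)


class Label(str, Enum):
    POSITIVE = "positive"
    UNLABELED = "unlabeled"
    ASSAY_NEGATIVE = "assay_negative"


class Source(str, Enum):
    LITERATURE = "literature"
    ARRAY1 = "array1"
    ARRAY2 = "array2"
    ARRAY3 = "array3"
    PROTEOME = "proteome"
    SYNTHETIC = "synthetic"


class PeptideError(ValueError):
    """Raised for malformed or invalid peptide data."""


@dataclass(frozen=True)
class Peptide:
    """A site-anchored peptide window.

    Parameters
    ----------
    sequence : str
        Residues over the 20 one-letter codes, optionally right-padded
        with ``-`` (pads only at the right end).
    label : Label
        ``positive`` (observed arginylated), ``unlabeled`` (unknown) or
        ``assay_negative``.
    source : Source
        Provenance tag (literature set, one of the arrays, proteome scan,
        or synthetic).
    site_offset : int
        1-based position of the putative target residue within the
        window (default 1, the canonical N-terminal site).
    """

    sequence: str
    label: Label = Label.UNLABELED
    source: Source = Source.SYNTHETIC
    site_offset: int = 1

    def __post_init__(self) -> None:
        seq = self.sequence
        if len(seq) < 2:
            raise PeptideError(f"peptide too short (length {len(seq)}): {seq!r}")
        body = seq.rstrip(PAD)
        if PAD in body:
            raise PeptideError(f"pad symbols only allowed at the right end: {seq!r}")
        for ch in body:
            if ch not in _AA_SET:
                raise PeptideError(f"illegal residue {ch!r} in {seq!r}")
        if not body:
            raise PeptideError(f"all-pad peptide: {seq!r}")
        if not 1 <= self.site_offset <= len(seq):
            raise PeptideError(f"site_offset {self.site_offset} outside window")
        if self.label is Label.POSITIVE and self.site_offset == 1 and seq[0] not in ACIDIC:
            raise PeptideError(
                f"canonical positive must have D or E at position 1: {seq!r}"
            )

    @property
    def unpadded(self) -> str:
        return self.sequence.rstrip(PAD)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideSet:
    """Ordered collection of peptides with provenance metadata."""

    peptides: List[Peptide] = field(default_factory=list)
    metadata: str = ""
    allow_duplicates: bool = True

    def __post_init__(self) -> None:
        if not self.allow_duplicates:
            seen = set()
            for p in self.peptides:
                key = (p.sequence, p.label)
                if key in seen:
                    raise PeptideError(
                        f"duplicate (sequence, label) pair: {key[0]!r}/{key[1].value}"
                    )
                seen.add(key)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i):
        return self.peptides[i]

    def filter(self, **kwargs) -> "PeptideSet":
        """Subset by field equality, e.g. ``ps.filter(label=Label.POSITIVE)``."""
        keep = [
            p
            for p in self.peptides
            if all(getattr(p, k) == v for k, v in kwargs.items())
        ]
        return PeptideSet(keep, metadata=self.metadata, allow_duplicates=True)

    def sequences(self) -> List[str]:
        return [p.sequence for p in self.peptides]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier (carrier for proteome scans)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise PeptideError("protein record with empty id")
        if not self.sequence:
            raise PeptideError(f"protein {self.id!r} has empty sequence")
        for ch in self.sequence:
            if ch not in _AA_SET and ch != "X":
                raise PeptideError(f"illegal residue {ch!r} in protein {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


PEPTIDE_TSV_HEADER = "sequence\tlabel\tsource"


def parse_peptide_table(text: str) -> PeptideSet:
    """Parse a peptide TSV with header ``sequence<TAB>label<TAB>source``.

    Row order is preserved; each row is validated on construction.
    Raises :class:`PeptideError` naming the offending line.
    """
    lines = text.splitlines()
    if not lines or lines[0].rstrip("\r\n") != PEPTIDE_TSV_HEADER:
        raise PeptideError(
            f"expected header {PEPTIDE_TSV_HEADER!r}, got {(lines[0] if lines else '')!r}"
        )
    peptides: List[Peptide] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\r\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise PeptideError(f"line {lineno}: expected 3 tab-separated fields")
        seq, label, source = parts
        try:
            peptides.append(Peptide(seq, Label(label), Source(source)))
        except ValueError as exc:
            raise PeptideError(f"line {lineno}: {exc}") from exc
    return PeptideSet(peptides, allow_duplicates=True)


def write_peptide_table(peptides: Union[PeptideSet, Iterable[Peptide]]) -> str:
    rows = [PEPTIDE_TSV_HEADER]
    for p in peptides:
        rows.append(f"{p.sequence}\t{p.label.value}\t{p.source.value}")
    return "\n".join(rows) + "\n"


def read_fasta(stream: Union[str, io.TextIOBase], on_unknown: str = "error") -> List[ProteinRecord]:
    """Read protein records from FASTA text or a text stream.

    Ids are the first whitespace-delimited token after ``>``; sequences are
    uppercased with line breaks removed. Duplicate ids are rejected.
    ``on_unknown`` controls residues outside the 20-letter alphabet:
    ``"error"`` rejects them, ``"mask"`` maps them to ``X``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text_start = stream.read(1)
    stream.seek(0)
    if text_start and not text_start.startswith(">") and text_start.strip():
        raise PeptideError("sequence data before any FASTA header")
    if on_unknown not in ("error", "mask"):
        raise ValueError(f"on_unknown must be 'error' or 'mask', got {on_unknown!r}")

    records: List[ProteinRecord] = []
    seen_ids = set()
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in seen_ids:
            raise PeptideError(f"duplicate FASTA id {rec.id!r}")
        seen_ids.add(rec.id)
        seq = str(rec.seq).upper()
        if on_unknown == "mask":
            seq = "".join(ch if ch in _AA_SET else "X" for ch in seq)
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], width: int = 60) -> str:
    chunks = []
    for rec in records:
        chunks.append(f">{rec.id}")
        for i in range(0, len(rec.sequence), width):
            chunks.append(rec.sequence[i : i + width])
    return "\n".join(chunks) + "\n"


def count_by(peptides: PeptideSet) -> dict:
    """Counts per label and per source, for validation summaries."""
    by_label: dict = {}
    by_source: dict = {}
    for p in peptides:
        by_label[p.label.value] = by_label.get(p.label.value, 0) + 1
        by_source[p.source.value] = by_source.get(p.source.value, 0) + 1
    return {"label": by_label, "source": by_source, "total": len(peptides)}
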