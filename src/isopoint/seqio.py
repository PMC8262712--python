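"""Sequence input/output: FASTA and plain-text parsing, composition, mass, CSV.

Sequences are one-letter amino-acid code over the 20 standard residues plus
``X`` for unknown. Ambiguity codes (B, Z) and non-standard residues (U, O)
are rejected rather than silently remapped, because downstream encodings
reserve exactly one unknown symbol.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import IO, Iterable, Mapping, Sequence

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_AA = "X"
ALPHABET = STANDARD_AA + UNKNOWN_AA

#: Side chains bearing an ionizable group (plus both chain termini).
IONIZABLE_RESIDUES = "CDEHKRY"

# Average residue masses in Da (monomer minus water), 2D-PAGE convention.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.01524
_MEAN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)


class SequenceError(ValueError):
    """Raised for malformed or empty sequence input."""


@dataclass(frozen=True)
class PolypeptideSequence:
    """A validated polypeptide chain in one-letter code.

    Parameters
    ----------
    id : str
        Identifier (FASTA header up to first whitespace, or synthesized).
    residues : str
        Upper-case residues over the 21-letter alphabet (20 standard + X).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for ch in self.residues:
            if ch not in ALPHABET:
                raise SequenceError(
                    f"sequence {self.id!r} contains illegal character {ch!r}; "
                    f"allowed: 20 standard amino acids and X"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class IonizableComposition:
    """Counts of ionizable side chains plus the two free chain termini."""

    C: int = 0
    D: int = 0
    E: int = 0
    H: int = 0
    K: int = 0
    R: int = 0
    Y: int = 0
    has_n_terminus: bool = True
    has_c_terminus: bool = True

    def side_chain_count(self, residue: str) -> int:
        return int(getattr(self, residue))

    @property
    def n_ionizable_side_chains(self) -> int:
        return self.C + self.D + self.E + self.H + self.K + self.R + self.Y


def _clean_body(raw: str, seq_id: str) -> str:
    body = "".join(raw.split()).upper()
    if body.endswith("*"):
        warnings.warn(f"stripping terminal stop character '*' from {seq_id!r}")
        body = body.rstrip("*")
    return body


def read_sequences(source: IO[str] | str, format: str = "fasta") -> list[PolypeptideSequence]:
    """Parse sequences from a text stream or string.

    Parameters
    ----------
    source : file-like or str
        Text input. ``fasta`` format: multi-record, free line width, id from
        the header up to the first whitespace. ``plain`` format: one sequence
        per line, ids synthesized as ``seq1``, ``seq2``, ...
    format : {"fasta", "plain"}

    Returns
    -------
    list of PolypeptideSequence, in input order.

    Raises
    ------
    SequenceError
        On empty input or illegal characters (error names the offending
        sequence and character).
    """
    if isinstance(source, str):
        source = StringIO(source)
    text = source.read()
    if format == "fasta":
        seqs = _read_fasta(text)
    elif format == "plain":
        seqs = _read_plain(text)
    else:
        raise ValueError(f"unknown format {format!r}; use 'fasta' or 'plain'")
    if not seqs:
        raise SequenceError("empty input: no sequences found")
    return seqs


def _read_fasta(text: str) -> list[PolypeptideSequence]:
    seqs: list[PolypeptideSequence] = []
    header: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                seqs.append(PolypeptideSequence(header, _clean_body("".join(chunks), header)))
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise SequenceError("FASTA record with empty identifier")
            chunks = []
        else:
            if header is None:
                raise SequenceError("FASTA input must start with a '>' header line")
            chunks.append(line)
    if header is not None:
        seqs.append(PolypeptideSequence(header, _clean_body("".join(chunks), header)))
    return seqs


def _read_plain(text: str) -> list[PolypeptideSequence]:
    seqs = []
    for i, line in enumerate(ln for ln in text.splitlines() if ln.strip()):
        seq_id = f"seq{i + 1}"
        seqs.append(PolypeptideSequence(seq_id, _clean_body(line, seq_id)))
    return seqs


def ionizable_composition(seq: PolypeptideSequence) -> IonizableComposition:
    """Count the ionizable side chains (C, D, E, H, K, R, Y) of a sequence.

    Both termini are always flagged free: the model treats every input as an
    intact polypeptide with an alpha-amino and alpha-carboxyl group.
    """
    r = seq.residues
    return IonizableComposition(
        C=r.count("C"), D=r.count("D"), E=r.count("E"), H=r.count("H"),
        K=r.count("K"), R=r.count("R"), Y=r.count("Y"),
    )


def molecular_weight(seq: PolypeptideSequence) -> float:
    """Average molecular weight in Da (sum of residue masses plus one water).

    ``X`` contributes the mean of the 20 standard residue masses.
    """
    total = WATER_MASS
    for ch in seq.residues:
        total += AVERAGE_RESIDUE_MASS.get(ch, _MEAN_RESIDUE_MASS)
    return total


def write_predictions_csv(
    records: Sequence[Mapping[str, object]],
    destination: IO[str] | str,
    columns: Iterable[str] | None = None,
) -> None:
    """Write prediction rows as RFC-4180-style CSV with a header.

    All rows must share a column schema; ``columns`` fixes the column order
    (default: order of keys in the first record). Zero records still produce
    a header-only file when ``columns`` is given, else an empty file with a
    bare header is impossible and a ValueError is raised.
    """
    if columns is None:
        if not records:
            raise ValueError("cannot infer columns from zero records; pass `columns`")
        columns = list(records[0].keys())
    columns = list(columns)
    for rec in records:
        if set(rec.keys()) != set(columns):
            raise ValueError(f"record columns {sorted(rec)} != schema {sorted(columns)}")

    def _write(fh: IO[str]) -> None:
        writer = csv.DictWriter(fh, fieldnames=columns, lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow({k: _fmt(v) for k, v in rec.items()})

    if isinstance(destination, str):
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            _write(fh)
    else:
        _write(destination)


def _fmt(value: object) -> object:
    if isinstance(value, float):
        return f"{value:.4f}"
    return value
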