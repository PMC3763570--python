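"""Sequences, PSI-BLAST PSSMs, and standardized per-residue profiles.

A PSSM row holds 20 signed integer log-odds scores ``E(i->j)`` describing how
readily position i tolerates substitution by amino acid j.  Softmax
standardization,

    A(i->j) = exp(E(i->j)) / sum_j' exp(E(i->j')),

turns each row into a probability distribution over the 20 amino acids.  When
no PSSM is available a sequence degrades to a one-hot profile (``A(i->R_i)=1``),
so every downstream computation sees the same row-stochastic L x 20 matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
from Bio import SeqIO

from .properties import DEGENERATE_RESIDUES, RESIDUE_ORDER, _RESIDUE_INDEX

logger = logging.getLogger(__name__)

_VALID_RESIDUES = set(RESIDUE_ORDER) | set(DEGENERATE_RESIDUES)


class SequenceError(ValueError):
    """Raised for malformed FASTA input or illegal residues."""


class PSSMFormatError(ValueError):
    """Raised for files that do not follow the psiblast ASCII PSSM dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence ``P = R_1 R_2 ... R_L``."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise SequenceError(f"record {self.identifier!r}: empty sequence")
        bad = sorted(set(seq) - _VALID_RESIDUES)
        if bad:
            raise SequenceError(
                f"record {self.identifier!r}: illegal characters {bad} "
                f"(allowed: 20 standard residues plus {sorted(DEGENERATE_RESIDUES)})"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSSMMatrix:
    """Integer log-odds scores from a PSI-BLAST ASCII PSSM.

    ``E`` is L x 20 in the canonical column order; ``residue_column`` is the
    query sequence as read from the file.
    """

    identifier: str
    E: np.ndarray = field(repr=False)
    residue_column: str = ""

    def __post_init__(self) -> None:
        E = np.asarray(self.E)
        if E.ndim != 2 or E.shape[1] != 20:
            raise PSSMFormatError(
                f"{self.identifier}: PSSM must be L x 20, got {E.shape}"
            )
        if not np.all(np.isfinite(E)):
            raise PSSMFormatError(f"{self.identifier}: non-finite PSSM entries")
        object.__setattr__(self, "E", E.astype(np.int64))


@dataclass(frozen=True)
class StandardizedProfile:
    """Row-stochastic L x 20 profile ``A``; origin is 'pssm' or 'one_hot'."""

    identifier: str
    A: np.ndarray = field(repr=False)
    origin: str = "pssm"

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[1] != 20:
            raise ValueError(f"{self.identifier}: profile must be L x 20")
        if np.any(A < -1e-12) or np.any(A > 1 + 1e-12):
            raise ValueError(f"{self.identifier}: profile entries outside [0, 1]")
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError(f"{self.identifier}: profile rows must sum to 1")
        if self.origin not in ("pssm", "one_hot"):
            raise ValueError(f"unknown profile origin {self.origin!r}")
        object.__setattr__(self, "A", A)

    @property
    def length(self) -> int:
        return self.A.shape[0]


def read_fasta(source) -> list[ProteinRecord]:
    """Read protein records from a FASTA file or stream.

    Identifiers are the first whitespace-delimited token of each header;
    sequences are upper-cased.  Empty input, duplicate identifiers and
    illegal residue characters raise :class:`SequenceError` naming the
    offending record.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate identifier {rec.id!r} in FASTA input")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    if not records:
        raise SequenceError("no FASTA records found in input")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records as plain FASTA, 60 columns per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def parse_ascii_pssm(
    source, expected_sequence: str | None = None, identifier: str = ""
) -> PSSMMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The dialect: two header lines, then one row per query residue carrying a
    1-based position index, the residue letter, 20 integer log-odds columns,
    20 weighted-percentage columns and two trailing per-position statistics;
    footer lines follow a blank line.  Only the first (signed log-odds) block
    is retained.

    Parameters
    ----------
    source : path or readable text stream
    expected_sequence : str, optional
        When given, the file's residue column must match it exactly.

    Raises
    ------
    PSSMFormatError
        On truncated rows, non-integer score fields, or a residue-column
        mismatch; messages carry 1-based line numbers.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = identifier or "<stream>"
    else:
        text = Path(source).read_text(encoding="utf-8")
        name = identifier or Path(source).stem
    lines = text.splitlines()

    rows: list[list[int]] = []
    residues: list[str] = []
    in_body = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not in_body:
            fields = stripped.split()
            # the column-header line lists the 20 residues (twice)
            if len(fields) >= 20 and fields[:20] == list(RESIDUE_ORDER):
                in_body = True
            continue
        if not stripped:
            break  # blank line ends the matrix body; footer follows
        fields = stripped.split()
        if len(fields) < 22:
            raise PSSMFormatError(
                f"{name}: line {lineno}: truncated PSSM row "
                f"({len(fields)} fields, need position, residue and 20 scores)"
            )
        pos_s, aa = fields[0], fields[1]
        if not pos_s.isdigit() or len(aa) != 1 or not aa.isalpha():
            raise PSSMFormatError(
                f"{name}: line {lineno}: expected '<pos> <residue>' row start, "
                f"got {pos_s!r} {aa!r}"
            )
        try:
            scores = [int(x) for x in fields[2:22]]
        except ValueError as exc:
            raise PSSMFormatError(
                f"{name}: line {lineno}: non-integer log-odds score ({exc})"
            ) from exc
        rows.append(scores)
        residues.append(aa.upper())

    if not rows:
        raise PSSMFormatError(f"{name}: no PSSM rows found (not ascii-pssm dialect?)")

    residue_column = "".join(residues)
    if expected_sequence is not None:
        expected = expected_sequence.upper()
        if residue_column != expected:
            if len(residue_column) != len(expected):
                raise PSSMFormatError(
                    f"{name}: PSSM has {len(residue_column)} rows but the "
                    f"sequence has {len(expected)} residues"
                )
            i = next(
                i for i, (a, b) in enumerate(zip(residue_column, expected)) if a != b
            )
            raise PSSMFormatError(
                f"{name}: residue mismatch at position {i + 1}: PSSM has "
                f"{residue_column[i]!r}, sequence has {expected[i]!r}"
            )
    return PSSMMatrix(name, np.array(rows, dtype=np.int64), residue_column)


def write_ascii_pssm(pssm: PSSMMatrix, path) -> None:
    """Write a PSSM in the psiblast ASCII dialect (round-trips losslessly).

    The weighted-percentage block is filled with the softmax of each row
    rounded to integer percentages, and the two per-position statistics with
    zeros; :func:`parse_ascii_pssm` ignores both.
    """
    A = standardize_pssm(pssm).A
    header = "".join(f"{aa:>4}" for aa in RESIDUE_ORDER)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write("          " + header + " " + header + "\n")
        for i, row in enumerate(pssm.E):
            aa = pssm.residue_column[i] if pssm.residue_column else "X"
            scores = "".join(f"{int(v):>4d}" for v in row)
            pcts = "".join(f"{int(round(100 * p)):>4d}" for p in A[i])
            fh.write(f"{i + 1:>5d} {aa} {scores} {pcts}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3190\n")


def standardize_pssm(pssm: PSSMMatrix) -> StandardizedProfile:
    """Softmax each PSSM row into a probability distribution.

    Computed with per-row maximum subtraction so that arbitrarily large
    integer scores stay finite; where the naive formula does not overflow the
    results agree to machine precision.
    """
    E = pssm.E.astype(float)
    shifted = E - E.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    A = expd / expd.sum(axis=1, keepdims=True)
    return StandardizedProfile(pssm.identifier, A, origin="pssm")


def one_hot_profile(record: ProteinRecord) -> StandardizedProfile:
    """One-hot profile for a plain sequence (the no-PSSM degradation rule).

    Standard residues get a unit row at their own column; degenerate codes
    (X, B, Z, U, O, J) get a uniform row (all 0.05), the zero-information
    choice that keeps sequence and profile lengths consistent.
    """
    A = np.zeros((record.length, 20))
    for i, aa in enumerate(record.sequence):
        j = _RESIDUE_INDEX.get(aa)
        if j is None:
            A[i, :] = 0.05
        else:
            A[i, j] = 1.0
    return StandardizedProfile(record.identifier, A, origin="one_hot")


def load_profile(
    record: ProteinRecord, pssm_dir: str | Path | None
) -> StandardizedProfile:
    """Profile for one record: its ``<identifier>.pssm`` file if present
    under ``pssm_dir``, else the one-hot fallback."""
    if pssm_dir is not None:
        path = Path(pssm_dir) / f"{record.identifier}.pssm"
        if path.exists():
            pssm = parse_ascii_pssm(
                path, expected_sequence=record.sequence, identifier=record.identifier
            )
            return standardize_pssm(pssm)
    return one_hot_profile(record)


def load_profiles(
    records: list[ProteinRecord], pssm_dir: str | Path | None
) -> list[StandardizedProfile]:
    """Profiles for all records, logging the one-hot fallback count."""
    profiles = [load_profile(rec, pssm_dir) for rec in records]
    n_fallback = sum(1 for p in profiles if p.origin == "one_hot")
    if n_fallback:
        logger.info(
            "one-hot fallback used for %d/%d sequences (no PSSM file)",
            n_fallback,
            len(records),
        )
    return profiles


def psiblast_command(
    fasta_path: str, db: str = "swissprot", out_pssm: str = "query.pssm"
) -> str:
    """Convenience helper: the psiblast invocation that produces the expected
    PSSM dialect (three iterations, e-value threshold 0.001).  The package
    never runs this itself."""
    return (
        f"psiblast -query {fasta_path} -db {db} -num_iterations 3 "
        f"-evalue 0.001 -out_ascii_pssm {out_pssm}"
    )
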