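"""Amino-acid physicochemical property scales and their z-normalization.

A property scale assigns one real number ``H(r, j)`` to each of the 20
standard amino acids.  Before a scale enters any descriptor computation it is
z-normalized over the 20 amino acids,

    h(r, j) = (H(r, j) - m(r)) / s(r),

where ``m(r)`` is the mean and ``s(r)`` the population standard deviation
(divide by 20) of the raw values.  Every normalized scale therefore has mean
0 and unit population spread, which makes properties with different physical
units commensurable.

All arrays in this package index amino acids in the PSI-BLAST PSSM column
order ``A R N D C Q E G H I L K M F P S T W Y V``; scales published in other
orders are remapped on load.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from ._aaindex import AAINDEX_SCALES, DEFAULT_ACCESSIONS

#: Canonical residue order: the PSI-BLAST PSSM column order.
RESIDUE_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Degenerate residue codes tolerated in input sequences.
DEGENERATE_RESIDUES: frozenset[str] = frozenset("XBZUOJ")

_RESIDUE_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}


class PropertyError(ValueError):
    """Raised for malformed or degenerate property scales."""


@dataclass(frozen=True)
class PropertyScale:
    """One physicochemical property: 20 raw values in canonical residue order.

    Parameters
    ----------
    accession : str
        AAindex identifier (or any non-empty label for user scales).
    description : str
        Free-text description of the property.
    values : numpy.ndarray
        Shape (20,), raw values ``H(r, j)`` ordered as :data:`RESIDUE_ORDER`.
    """

    accession: str
    description: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.accession:
            raise PropertyError("property accession must be non-empty")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (20,):
            raise PropertyError(
                f"{self.accession}: expected 20 values, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise PropertyError(f"{self.accession}: non-finite property values")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_mapping(
        cls, accession: str, description: str, mapping: dict[str, float]
    ) -> "PropertyScale":
        """Build a scale from a residue->value mapping (any key order)."""
        missing = set(RESIDUE_ORDER) - set(mapping)
        if missing:
            raise PropertyError(
                f"{accession}: missing values for residues {sorted(missing)}"
            )
        vals = np.array([float(mapping[aa]) for aa in RESIDUE_ORDER])
        return cls(accession, description, vals)


@dataclass(frozen=True)
class NormalizedPropertyTable:
    """R z-normalized property scales, stacked as an (R, 20) matrix ``h``.

    Attributes
    ----------
    h : numpy.ndarray
        Shape (R, 20); row r holds the normalized property ``h(r, .)`` in
        canonical residue order, with mean 0 and population sd 1.
    source_accessions : tuple of str
        Accessions in input order.
    """

    h: np.ndarray = field(repr=False)
    source_accessions: tuple[str, ...]
    descriptions: tuple[str, ...] = ()

    @property
    def R(self) -> int:
        """Number of property scales."""
        return self.h.shape[0]


def load_default_properties() -> list[PropertyScale]:
    """Return the nine bundled AAindex property scales, in canonical order.

    The accessions are BULH740101, EISD840101, HOPT810101, RADA880108,
    ZIMJ680104, MCMT640101, BHAR880101, CHOC750101 and COSI940101; the values
    are embedded package data sourced from the AAindex database.

    Raises
    ------
    PropertyError
        If the bundled data is missing or corrupt.
    """
    scales = []
    for acc in DEFAULT_ACCESSIONS:
        entry = AAINDEX_SCALES.get(acc)
        if entry is None:
            raise PropertyError(f"bundled property data missing accession {acc}")
        scales.append(
            PropertyScale.from_mapping(acc, str(entry["description"]), entry["values"])
        )
    return scales


def normalize_properties(scales: list[PropertyScale]) -> NormalizedPropertyTable:
    """Z-normalize property scales over the 20 amino acids.

    Each scale is centered by its mean and divided by its population standard
    deviation.  Scale order is preserved.

    Raises
    ------
    PropertyError
        If a scale has zero spread (all 20 values identical); the error names
        the offending accession.
    """
    if not scales:
        raise PropertyError("no property scales given")
    rows = []
    for scale in scales:
        m = scale.values.mean()
        s = scale.values.std()  # population sd: ddof=0
        if s <= 1e-12 * max(1.0, abs(m)) or not np.isfinite(s):
            raise PropertyError(
                f"{scale.accession}: constant property scale (zero spread), "
                "cannot normalize"
            )
        rows.append((scale.values - m) / s)
    return NormalizedPropertyTable(
        h=np.vstack(rows),
        source_accessions=tuple(s.accession for s in scales),
        descriptions=tuple(s.description for s in scales),
    )


def default_property_table() -> NormalizedPropertyTable:
    """Normalized table of the nine bundled scales (convenience)."""
    return normalize_properties(load_default_properties())


def read_property_table(source) -> list[PropertyScale]:
    """Read user-supplied property scales from a tab-separated file.

    Layout: a header row ``accession<TAB>A<TAB>R<TAB>...<TAB>V`` naming the 20
    residues in canonical order, then one row per scale: accession followed by
    20 numeric values.  The header is validated against the canonical order.

    Parameters
    ----------
    source : path or readable text stream
    """
    if hasattr(source, "read"):
        stream = source
    else:
        stream = io.StringIO(open(source, encoding="utf-8").read())
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if not lines:
        raise PropertyError("empty property table")
    header = lines[0].split("\t")
    expected = ["accession", *RESIDUE_ORDER]
    if header != expected:
        raise PropertyError(
            "property table header must be 'accession' followed by the 20 "
            f"residues in canonical order {RESIDUE_ORDER}; got {header!r}"
        )
    scales = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 21:
            raise PropertyError(
                f"line {lineno}: expected accession + 20 values, got "
                f"{len(fields)} fields"
            )
        acc = fields[0]
        if acc in seen:
            raise PropertyError(f"line {lineno}: duplicate accession {acc}")
        seen.add(acc)
        try:
            vals = np.array([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise PropertyError(f"line {lineno}: non-numeric value ({exc})") from exc
        scales.append(PropertyScale(acc, "user-supplied", vals))
    return scales
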