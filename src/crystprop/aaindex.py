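"""AAIndex1 flat-file parsing and serialisation.

AAIndex1 catalogues constant per-residue characteristics (hydrophobicity,
volume, secondary-structure propensities, ...). Each record is keyed by a
10-character accession (``H`` line), described by a ``D`` line, and carries
20 numeric values in the ``I`` block, laid out as two rows of ten in the
database's native order::

    I    A/L  R/K  N/M  D/F  C/P  Q/S  E/T  G/W  H/Y  I/V

Values are re-ordered to the package-wide alphabetical one-letter order at
parse time. ``NA`` fields are recorded in ``na_mask``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .sequences import AMINO_ACIDS

#: Residue order of the two numeric rows in an AAIndex1 ``I`` block.
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"


class AAIndexParseError(ValueError):
    """Raised for structurally invalid AAIndex1 records."""


@dataclass(frozen=True)
class CharacteristicTable:
    """One AAIndex1 entry: a constant amino-acid characteristic."""

    accession: str
    title: str
    values: dict[str, float]
    na_mask: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.accession:
            raise AAIndexParseError("accession must be non-empty")
        if set(self.values) != set(AMINO_ACIDS):
            raise AAIndexParseError(
                f"{self.accession}: values must cover exactly the 20 residues"
            )

    @property
    def vector(self) -> np.ndarray:
        """Values in alphabetical residue order; masked residues are NaN."""
        return np.array(
            [math.nan if aa in self.na_mask else self.values[aa]
             for aa in AMINO_ACIDS]
        )


def _parse_entry(lines: list[str], source: str) -> CharacteristicTable | None:
    accession = ""
    title_parts: list[str] = []
    value_rows: list[str] = []
    key = ""
    in_i = False
    for line in lines:
        if line[:1].isalpha() and (len(line) == 1 or line[1:2] == " "):
            key = line[0]
            rest = line[2:].strip()
            in_i = key == "I"
            if key == "H":
                accession = rest.split()[0] if rest else ""
            elif key == "D":
                title_parts.append(rest)
            continue
        if in_i and line.startswith(" "):
            value_rows.append(line)
        elif key == "D" and line.startswith(" "):
            title_parts.append(line.strip())
    if not accession:
        raise AAIndexParseError(f"{source}: entry without an H (accession) line")
    if not value_rows:
        warnings.warn(f"{source}: entry {accession} has no I block; skipped",
                      stacklevel=3)
        return None
    fields = " ".join(value_rows).split()
    if len(fields) != 20:
        raise AAIndexParseError(
            f"{source}: entry {accession} has {len(fields)} numeric fields, "
            "expected 20"
        )
    values: dict[str, float] = {}
    na: set[str] = set()
    for aa, raw in zip(AAINDEX_ORDER, fields):
        if raw.upper() == "NA":
            na.add(aa)
            values[aa] = math.nan
        else:
            try:
                values[aa] = float(raw)
            except ValueError as exc:
                raise AAIndexParseError(
                    f"{source}: entry {accession}: bad value {raw!r}"
                ) from exc
    return CharacteristicTable(accession, " ".join(title_parts), values,
                               frozenset(na))


def parse_aaindex1(path) -> list[CharacteristicTable]:
    """Parse an AAIndex1 flat file into :class:`CharacteristicTable` s.

    Entries lacking an ``I`` block are skipped with a warning; entries with
    other structural defects raise :class:`AAIndexParseError` naming the
    accession.
    """
    text = Path(path).read_text()
    return parse_aaindex1_text(text, source=str(path))


def parse_aaindex1_text(text: str, source: str = "<string>") -> list[CharacteristicTable]:
    """Parse AAIndex1-format text (entries delimited by ``//``)."""
    tables: list[CharacteristicTable] = []
    entry: list[str] = []
    for line in text.splitlines():
        if line.strip() == "//":
            if any(ln.strip() for ln in entry):
                table = _parse_entry(entry, source)
                if table is not None:
                    tables.append(table)
            entry = []
        else:
            entry.append(line)
    if any(ln.strip() for ln in entry):
        table = _parse_entry(entry, source)
        if table is not None:
            tables.append(table)
    return tables


def format_aaindex1(tables: Iterable[CharacteristicTable]) -> str:
    """Serialise tables back to AAIndex1 flat-file text (parse round-trip)."""
    chunks = []
    for t in tables:
        def fmt(aa: str) -> str:
            return "NA" if aa in t.na_mask else f"{t.values[aa]:.3f}"

        row1 = " ".join(f"{fmt(aa):>8}" for aa in AAINDEX_ORDER[:10])
        row2 = " ".join(f"{fmt(aa):>8}" for aa in AAINDEX_ORDER[10:])
        chunks.append(
            f"H {t.accession}\n"
            f"D {t.title}\n"
            "I    A/L     R/K     N/M     D/F     C/P     "
            "Q/S     E/T     G/W     H/Y     I/V\n"
            f"  {row1}\n"
            f"  {row2}\n"
            "//"
        )
    return "\n".join(chunks) + ("\n" if chunks else "")


def write_aaindex1(tables: Iterable[CharacteristicTable], path) -> None:
    Path(path).write_text(format_aaindex1(tables))


def usable_tables(
    tables: Iterable[CharacteristicTable], present_residues: set[str]
) -> tuple[list[CharacteristicTable], list[str]]:
    """Filter out tables with an NA value for any residue present in a dataset.

    Returns (kept tables, excluded accessions). This reproduces the kind of
    completeness filter needed to run a per-characteristic screen over a
    database that contains partially-populated entries.
    """
    kept, dropped = [], []
    for t in tables:
        if t.na_mask & present_residues:
            dropped.append(t.accession)
        else:
            kept.append(t)
    return kept, dropped
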