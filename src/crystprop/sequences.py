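"""Protein sequence records, FASTA/label I/O, and residue-alphabet validation.

All positions quoted to users are 1-based (the first residue of a protein is
position 1). The 20-letter amino-acid alphabet is fixed in alphabetical
one-letter order (``ACDEFGHIKLMNPQRSTVWY``); every 20-vector in the package
follows this order.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical residue order used for every 20-dimensional vector in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

#: Characters treated as nonstandard: ambiguity codes, rare residues, stops, gaps.
NONSTANDARD = frozenset("XBZUJO*-. ")


class SequenceError(ValueError):
    """Raised for malformed sequences, records, or label tables."""


def sanitize_sequence(raw: str, policy: str = "drop") -> str:
    """Validate or clean a raw amino-acid sequence.

    Parameters
    ----------
    raw:
        Input sequence; case-insensitive.
    policy:
        ``"strict"`` raises on any character outside the 20-letter alphabet,
        naming the 1-based position of the first offender. ``"drop"`` removes
        nonstandard characters (X, B, Z, U, J, O, ``*``, gaps) with a warning
        reporting the removal count.

    Returns
    -------
    str
        Upper-cased sequence over the 20-letter alphabet.
    """
    if policy not in ("strict", "drop"):
        raise ValueError(f"unknown sanitize policy {policy!r}")
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.upper()
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in _AA_SET]
    if not bad:
        return seq
    if policy == "strict":
        pos, char = bad[0]
        raise SequenceError(
            f"nonstandard residue {char!r} at position {pos} (strict policy)"
        )
    warnings.warn(
        f"dropped {len(bad)} nonstandard residue(s): "
        + ", ".join(f"{c}@{p}" for p, c in bad[:5])
        + ("..." if len(bad) > 5 else ""),
        stacklevel=2,
    )
    cleaned = "".join(c for c in seq if c in _AA_SET)
    if not cleaned:
        raise SequenceError("sequence empty after dropping nonstandard residues")
    return cleaned


@dataclass
class ProteinRecord:
    """A validated protein sequence.

    Attributes
    ----------
    id:
        Sequence identifier (FASTA header token).
    sequence:
        Upper-case sequence over the 20 standard amino acids.
    """

    id: str
    sequence: str
    counts: Mapping[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: nonstandard residues {sorted(bad)} "
                "(sanitize first)"
            )
        c = Counter(self.sequence)
        self.counts = {aa: c.get(aa, 0) for aa in AMINO_ACIDS}

    @property
    def length(self) -> int:
        """Number of residues L."""
        return len(self.sequence)

    def positions(self, aa: str) -> list[int]:
        """1-based positions of residue type ``aa`` in the sequence."""
        return [i + 1 for i, c in enumerate(self.sequence) if c == aa]


def read_fasta(path, policy: str = "drop") -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file into validated :class:`ProteinRecord` s.

    Sequences are upper-cased; nonstandard residues are handled per
    :func:`sanitize_sequence` ``policy``. An empty file yields an empty list.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise SequenceError(f"{path}: FASTA entry with empty header")
        raw = str(entry.seq)
        if not raw:
            raise SequenceError(f"{path}: record {entry.id!r} has an empty sequence")
        try:
            clean = sanitize_sequence(raw, policy=policy)
        except SequenceError as exc:
            raise SequenceError(f"record {entry.id!r}: {exc}") from exc
        if entry.id in seen:
            raise SequenceError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=clean))
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records to FASTA (round-trips with :func:`read_fasta`)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


@dataclass
class LabeledDataset:
    """Protein records joined with binary crystallization labels.

    ``labels[id] == 1`` means the protein crystallized.
    """

    records: list[ProteinRecord]
    labels: dict[str, int]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.id not in self.labels:
                raise SequenceError(f"record {r.id!r} has no label")
        for rid, lab in self.labels.items():
            if lab not in (0, 1):
                raise SequenceError(f"label for {rid!r} is {lab!r}, not binary")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def y(self):
        """Labels aligned with ``records`` order, as a list of ints."""
        return [self.labels[r.id] for r in self.records]

    @property
    def prevalence(self) -> float:
        """Fraction of positive (crystallized) labels."""
        return sum(self.y) / len(self.records)

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        recs = [self.records[i] for i in indices]
        return LabeledDataset(recs, {r.id: self.labels[r.id] for r in recs})


def _looks_numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_labels(path, records: list[ProteinRecord]) -> LabeledDataset:
    """Join a two-column (id, 0/1) label table with parsed records.

    The delimiter (comma or tab) is auto-detected; an optional header row is
    recognised by a non-numeric second field. Ids present only on one side are
    reported with a warning; records without a label are excluded from the
    returned dataset.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SequenceError(f"{path}: empty label table")
    delim = "\t" if "\t" in lines[0] else ","
    rows = list(csv.reader(lines, delimiter=delim))
    if len(rows[0]) >= 2 and not _looks_numeric(rows[0][1]):
        rows = rows[1:]  # header
    labels: dict[str, int] = {}
    for i, row in enumerate(rows, start=1):
        if len(row) < 2:
            raise SequenceError(f"{path}: line {i} has fewer than 2 columns")
        rid, raw = row[0].strip(), row[1].strip()
        if raw not in ("0", "1"):
            raise SequenceError(f"{path}: non-binary label {raw!r} for id {rid!r}")
        if rid in labels:
            raise SequenceError(f"{path}: duplicate id {rid!r}")
        labels[rid] = int(raw)

    record_ids = {r.id for r in records}
    unlabeled = sorted(record_ids - labels.keys())
    orphan = sorted(labels.keys() - record_ids)
    if unlabeled:
        warnings.warn(f"{len(unlabeled)} record(s) without labels dropped: "
                      f"{unlabeled[:5]}", stacklevel=2)
    if orphan:
        warnings.warn(f"{len(orphan)} label(s) without records ignored: "
                      f"{orphan[:5]}", stacklevel=2)
    kept = [r for r in records if r.id in labels]
    if not kept:
        raise SequenceError(f"{path}: no label matches any record id")
    return LabeledDataset(kept, {r.id: labels[r.id] for r in kept})


def write_labels(dataset: LabeledDataset, path) -> None:
    """Write the dataset's labels as a two-column CSV with header."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "label"])
        for r in dataset.records:
            w.writerow([r.id, dataset.labels[r.id]])
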