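"""Protein -> 20-vector encoders, as scikit-learn transformers.

Every classifier in the package consumes a fixed-length 20-vector per
protein (one coordinate per amino-acid type, alphabetical order). Two
families of encodings are provided:

* constant (benchmark): an AAIndex characteristic, either weighted by the
  protein's residue counts (x_a = value_a * count_a, the default) or raw
  (x_a = value_a, identical for every protein — kept to demonstrate the
  inflexibility of unweighted constant characteristics);
* dynamic: the per-type distribution probabilities or the future
  composition, which respond to residue positions and composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .aaindex import CharacteristicTable
from .dynamic import MutationMatrix, build_mutation_matrix, distribution_vector, future_composition
from .sequences import AMINO_ACIDS, ProteinRecord


@dataclass(frozen=True)
class EncodedProtein:
    """A protein rendered as the 20 predictors x1..x20 (alphabetical order)."""

    id: str
    x: np.ndarray
    y: int | None = None
    source: str = ""


class AAIndexEncoder(TransformerMixin, BaseEstimator):
    """Encode proteins with one constant AAIndex characteristic.

    Parameters
    ----------
    table:
        The :class:`~crystprop.aaindex.CharacteristicTable` to encode with.
    mode:
        ``"weighted"`` (default): x_a = value_a * count_a.
        ``"raw"``: x_a = value_a, constant across proteins.
    impute:
        Value substituted for masked (NA) residues; ``None`` raises if a
        masked residue occurs in a protein.
    """

    def __init__(self, table: CharacteristicTable, mode: str = "weighted",
                 impute: float | None = None):
        self.table = table
        self.mode = mode
        self.impute = impute

    def fit(self, X, y=None):
        if self.mode not in ("weighted", "raw"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        self.source_ = f"aaindex:{self.table.accession}:{self.mode}"
        return self

    def transform(self, X: list[ProteinRecord]) -> np.ndarray:
        if not hasattr(self, "source_"):
            self.fit(X)
        values = np.empty(20)
        for i, aa in enumerate(AMINO_ACIDS):
            if aa in self.table.na_mask:
                if self.impute is None:
                    present = any(r.counts[aa] for r in X)
                    if present:
                        raise ValueError(
                            f"{self.table.accession}: residue {aa} is NA but "
                            "occurs in the data (set impute to proceed)"
                        )
                    values[i] = 0.0
                else:
                    values[i] = self.impute
            else:
                values[i] = self.table.values[aa]
        if self.mode == "raw":
            return np.tile(values, (len(X), 1))
        counts = np.array([[r.counts[aa] for aa in AMINO_ACIDS] for r in X],
                          dtype=float)
        return counts * values


class DynamicEncoder(TransformerMixin, BaseEstimator):
    """Encode proteins with one dynamic characteristic.

    Parameters
    ----------
    kind:
        ``"distribution"`` for per-type distribution probabilities (values in
        [0, 1]) or ``"future"`` for the future composition in percent.
    matrix:
        Mutation matrix for ``kind="future"``; defaults to the standard
        genetic code derivation with stops excluded and synonymous mutations
        included.
    """

    def __init__(self, kind: str = "distribution",
                 matrix: MutationMatrix | None = None):
        self.kind = kind
        self.matrix = matrix

    def fit(self, X, y=None):
        if self.kind not in ("distribution", "future"):
            raise ValueError(f"unknown dynamic encoding {self.kind!r}")
        self.matrix_ = (self.matrix if self.matrix is not None
                        else build_mutation_matrix())
        self.source_ = f"dynamic:{self.kind}"
        return self

    def transform(self, X: list[ProteinRecord]) -> np.ndarray:
        if not hasattr(self, "source_"):
            self.fit(X)
        if self.kind == "distribution":
            return np.array([distribution_vector(r) for r in X])
        return np.array([future_composition(r, self.matrix_) for r in X])


def encode_constant(record: ProteinRecord, table: CharacteristicTable,
                    mode: str = "weighted") -> EncodedProtein:
    """Encode a single protein with a constant characteristic."""
    enc = AAIndexEncoder(table, mode=mode).fit([record])
    return EncodedProtein(record.id, enc.transform([record])[0],
                          source=enc.source_)


def encode_dynamic(record: ProteinRecord, which: str = "distribution",
                   matrix: MutationMatrix | None = None) -> EncodedProtein:
    """Encode a single protein with a dynamic characteristic."""
    enc = DynamicEncoder(kind=which, matrix=matrix).fit([record])
    return EncodedProtein(record.id, enc.transform([record])[0],
                          source=enc.source_)
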