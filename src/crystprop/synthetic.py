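"""Synthetic sequence datasets with planted or noise labels.

The generator emulates the shape of a structural-genomics screening set:
by default 301 proteins of 50-1000 residues with crystallization prevalence
85/301, sequences drawn i.i.d. from a residue composition, and labels drawn
either as pure noise or from a logistic model with known coefficients on a
chosen per-protein 20-vector encoding (the "planted" fixture every
estimator in the package can be validated against). Everything is fully
determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from .aaindex import CharacteristicTable, format_aaindex1
from .encoding import AAIndexEncoder, DynamicEncoder
from .sequences import AMINO_ACIDS, LabeledDataset, ProteinRecord

#: Residue counts of a real 122-residue plant protein, used (scaled to
#: arbitrary length) as a realistic non-uniform composition preset.
TABLE1_COUNTS: Mapping[str, int] = {
    "A": 6, "R": 1, "N": 3, "D": 10, "C": 1, "E": 9, "Q": 2, "G": 7,
    "H": 4, "I": 9, "L": 6, "K": 17, "M": 3, "F": 10, "P": 4, "S": 8,
    "T": 8, "W": 1, "Y": 2, "V": 11,
}


def composition_preset(name: str = "uniform") -> np.ndarray:
    """Named residue-frequency presets on the 20-simplex (alphabetical order)."""
    if name == "uniform":
        return np.full(20, 1 / 20)
    if name == "table1":
        c = np.array([TABLE1_COUNTS[aa] for aa in AMINO_ACIDS], dtype=float)
        return c / c.sum()
    raise ValueError(f"unknown composition preset {name!r}")


@dataclass(frozen=True)
class PlantedLogistic:
    """Labels drawn from Bernoulli(sigmoid(b0 + b . x)) on a known encoding.

    The intercept b0 is tuned by bisection so the mean simulated probability
    matches ``prevalence``.
    """

    coef: np.ndarray
    encoding: str = "distribution"  # distribution | future | aaindex
    table: CharacteristicTable | None = None
    prevalence: float = 85 / 301

    def encoder(self):
        if self.encoding in ("distribution", "future"):
            return DynamicEncoder(kind=self.encoding)
        if self.encoding == "aaindex":
            if self.table is None:
                raise ValueError("aaindex planted encoding needs a table")
            return AAIndexEncoder(self.table)
        raise ValueError(f"unknown planted encoding {self.encoding!r}")


@dataclass(frozen=True)
class NoiseLabels:
    """Labels independent of sequence: Bernoulli(prevalence)."""

    prevalence: float = 85 / 301


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset (deterministic given seed)."""

    n_proteins: int = 301
    length_range: tuple[int, int] = (50, 1000)
    composition: np.ndarray = field(
        default_factory=lambda: composition_preset("uniform"))
    label_model: PlantedLogistic | NoiseLabels = field(
        default_factory=NoiseLabels)
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (20,) or (comp < 0).any() or \
                abs(comp.sum() - 1) > 1e-9:
            raise ValueError("composition must be a 20-simplex vector")
        self.composition = comp
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        prev = self.label_model.prevalence
        if not 0 < prev < 1:
            raise ValueError("prevalence must lie strictly in (0, 1)")


def _tune_intercept(linear: np.ndarray, target: float) -> float:
    """Bisect b0 so that mean(sigmoid(b0 + linear)) == target."""
    lo, hi = -50.0, 50.0
    f = lambda b0: float(np.mean(expit(b0 + linear))) - target  # noqa: E731
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("prevalence target unreachable by intercept tuning")
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw the dataset described by ``spec``.

    Sequences are i.i.d. draws from ``spec.composition`` with lengths uniform
    over ``spec.length_range``. Planted labels: the proteins are encoded with
    the label model's encoder, the intercept is tuned to the target
    prevalence, and labels are Bernoulli draws from the resulting logistic
    probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_proteins)
    width = len(str(spec.n_proteins))
    records = [
        ProteinRecord(
            id=f"syn{i + 1:0{width}d}",
            sequence="".join(rng.choice(letters, size=L, p=spec.composition)),
        )
        for i, L in enumerate(lengths)
    ]
    lm = spec.label_model
    if isinstance(lm, NoiseLabels):
        y = rng.binomial(1, lm.prevalence, size=spec.n_proteins)
    else:
        coef = np.asarray(lm.coef, dtype=float)
        if coef.shape != (20,):
            raise ValueError("planted coefficients must be a 20-vector")
        enc = lm.encoder().fit(records)
        X = enc.transform(records)
        linear = X @ coef
        b0 = _tune_intercept(linear, lm.prevalence)
        y = rng.binomial(1, expit(b0 + linear))
    labels = {r.id: int(v) for r, v in zip(records, y)}
    return LabeledDataset(records, labels)


def planted_intercept(spec: SyntheticSpec) -> float:
    """The tuned intercept b0 for a planted-logistic spec (for audits)."""
    lm = spec.label_model
    if not isinstance(lm, PlantedLogistic):
        raise ValueError("intercept is only defined for planted labels")
    dataset = generate_dataset(spec)
    enc = lm.encoder().fit(dataset.records)
    X = enc.transform(dataset.records)
    return _tune_intercept(X @ np.asarray(lm.coef, dtype=float),
                           lm.prevalence)


def toy_aaindex(n_entries: int, seed: int = 0,
                include_na: bool = False) -> str:
    """Generate syntactically valid AAIndex1 text with pseudo-random values.

    Round-trips through the parser; with ``include_na`` a few entries carry
    NA-masked residues, exercising the downstream completeness filter.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(n_entries):
        values = {aa: round(float(v), 3)
                  for aa, v in zip(AMINO_ACIDS, rng.normal(0, 2, 20))}
        na: frozenset[str] = frozenset()
        if include_na and i % 7 == 3:
            masked = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
            na = frozenset(str(a) for a in masked)
            for aa in na:
                values[aa] = float("nan")
        tables.append(CharacteristicTable(
            accession=f"SYNT{i + 1:06d}",
            title=f"synthetic characteristic {i + 1}",
            values=values, na_mask=na,
        ))
    return format_aaindex1(tables)
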