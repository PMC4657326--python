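"""The three dynamic amino-acid characteristics.

Unlike the constant per-residue indices catalogued in AAIndex, these
quantities depend on the particular protein a residue sits in:

* **Distribution probability** — treat the r residues of one type as
  distinguishable balls dropped uniformly into n = r equal contiguous
  partitions of the sequence; the characteristic is the probability of the
  observed occupancy pattern,

      r!/(q0! q1! ... qn!) * r!/(r1! r2! ... rn!) * n**(-r)

  where r_i is the number of residues landing in partition i and q_j the
  number of partitions holding exactly j residues.

* **Future composition** — the residue composition expected after one round
  of single-nucleotide codon mutation, obtained by multiplying the current
  composition by a 20x20 amino-acid transition matrix derived from the
  standard genetic code.

* **Pair predictability** — each adjacent residue pair type is classified
  predictable when its observed count matches the count expected from
  composition alone; the per-protein summary is the percentage of the L-1
  adjacent pairs that are predictable.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .sequences import AMINO_ACIDS, ProteinRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# distribution probability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancyPattern:
    """Occupancy of r distinguishable balls in n = r partitions.

    ``occ[i]`` is the number of residues of the type that fall in partition i
    (partitions ordered along the sequence); ``q[j]`` is the number of
    partitions holding exactly j residues.
    """

    occ: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.occ:
            raise ValueError("occupancy vector must be non-empty (r >= 1)")
        if any(o < 0 for o in self.occ):
            raise ValueError("occupancy entries must be >= 0")
        if sum(self.occ) != len(self.occ):
            raise ValueError(
                f"occupancy {self.occ} invalid: sum must equal the number of "
                "partitions (n = r convention)"
            )

    @property
    def r(self) -> int:
        """Number of balls (residues of the type)."""
        return sum(self.occ)

    @property
    def n(self) -> int:
        """Number of partitions (equal to r)."""
        return len(self.occ)

    @property
    def q(self) -> tuple[int, ...]:
        """Multiplicities: q[j] = number of partitions holding exactly j balls."""
        c = Counter(self.occ)
        return tuple(c.get(j, 0) for j in range(self.n + 1))


def partition_boundaries(length: int, r: int) -> list[tuple[int, int]]:
    """Cut positions 1..length into r contiguous partitions differing by <=1.

    The first ``length mod r`` partitions are one residue longer. Returns
    1-based inclusive (start, end) intervals.
    """
    if r < 1 or length < r:
        raise ValueError(f"cannot cut length {length} into {r} partitions")
    base, extra = divmod(length, r)
    bounds = []
    start = 1
    for i in range(r):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size - 1))
        start += size
    return bounds


def partition_occupancy(positions: Sequence[int], length: int) -> OccupancyPattern:
    """Occupancy pattern of one residue type given its 1-based positions.

    The sequence is cut into n = r contiguous near-equal partitions (see
    :func:`partition_boundaries`); ``occ[i]`` counts how many of the type's
    positions fall in partition i.
    """
    r = len(positions)
    if r == 0:
        raise ValueError("r = 0: absent residue type has no occupancy pattern")
    pos = sorted(positions)
    if pos[0] < 1 or pos[-1] > length:
        raise ValueError(f"positions must lie in [1, {length}]")
    if len(set(pos)) != r:
        raise ValueError("positions must be distinct")
    bounds = partition_boundaries(length, r)
    occ = [sum(1 for p in pos if lo <= p <= hi) for lo, hi in bounds]
    return OccupancyPattern(tuple(occ))


def _distribution_probability_fraction(pattern: OccupancyPattern) -> Fraction:
    r, n = pattern.r, pattern.n
    num = math.factorial(r) * math.factorial(r)
    den_q = math.prod(math.factorial(qj) for qj in pattern.q)
    den_r = math.prod(math.factorial(ri) for ri in pattern.occ)
    return Fraction(num, den_q * den_r * n**r)


def distribution_probability(pattern: OccupancyPattern) -> float:
    """Probability of the observed occupancy pattern.

    Computed as ``r!/(prod q_j!) * r!/(prod r_i!) * n**(-r)`` with exact
    integer factorials before a single final division, so large residue
    counts neither overflow nor lose leading digits.
    """
    return float(_distribution_probability_fraction(pattern))


def distribution_probability_bruteforce(pattern: OccupancyPattern) -> float:
    """Independent enumeration oracle for :func:`distribution_probability`.

    Enumerates all n**r assignments of r distinguishable balls to n holes and
    returns the fraction whose sorted occupancy equals the sorted observed
    occupancy. Refuses r > 8.
    """
    r, n = pattern.r, pattern.n
    if r > 8:
        raise ValueError("brute-force enumeration limited to r <= 8")
    target = tuple(sorted(pattern.occ))
    hits = 0
    for assignment in itertools.product(range(n), repeat=r):
        occ = [0] * n
        for hole in assignment:
            occ[hole] += 1
        if tuple(sorted(occ)) == target:
            hits += 1
    return hits / n**r


def distribution_vector(record: ProteinRecord) -> np.ndarray:
    """Per-type distribution probabilities as a 20-vector.

    Types ordered alphabetically by one-letter code; an absent type maps to
    0.0 (the convention used for zero-count table entries).
    """
    out = np.zeros(20)
    for i, aa in enumerate(AMINO_ACIDS):
        if record.counts[aa] == 0:
            continue
        pattern = partition_occupancy(record.positions(aa), record.length)
        out[i] = distribution_probability(pattern)
    return out


# ---------------------------------------------------------------------------
# future composition
# ---------------------------------------------------------------------------

_RNA_TABLE = CodonTable.unambiguous_rna_by_id[1]  # standard genetic code
_RNA_BASES = "ACGU"


def _codons_by_aa() -> dict[str, list[str]]:
    by_aa: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
    for codon, aa in _RNA_TABLE.forward_table.items():
        if aa in by_aa:
            by_aa[aa].append(codon)
    return by_aa


def _translate(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    if codon in _RNA_TABLE.stop_codons:
        return "*"
    return _RNA_TABLE.forward_table[codon]


@dataclass(frozen=True)
class MutationMatrix:
    """20x20 amino-acid transition probabilities under single-nucleotide
    codon mutation, rows/columns in alphabetical one-letter order."""

    probs: np.ndarray
    options: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (20, 20):
            raise ValueError("mutation matrix must be 20x20")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", p)

    def prob(self, a: str, b: str) -> float:
        """P(a -> b)."""
        return float(self.probs[_AA_INDEX[a], _AA_INDEX[b]])


def build_mutation_matrix(
    stop_handling: str = "exclude",
    synonymous: str = "include",
) -> MutationMatrix:
    """Derive the transition matrix from the standard genetic code.

    For each amino acid, every codon is expanded into its 9 single-nucleotide
    mutants (codons weighted uniformly) and the translated targets tallied.

    ``stop_handling="exclude"`` drops mutation events whose target is a stop
    codon before normalising; ``"renormalize"`` tallies over all events and
    rescales each row to sum to 1 afterwards. Under uniform codon weighting
    the two coincide. ``synonymous="exclude"`` additionally drops a -> a
    events.
    """
    if stop_handling not in ("exclude", "renormalize"):
        raise ValueError(f"unknown stop_handling {stop_handling!r}")
    if synonymous not in ("include", "exclude"):
        raise ValueError(f"unknown synonymous option {synonymous!r}")

    probs = np.zeros((20, 20))
    for a, codons in _codons_by_aa().items():
        tally: Counter[str] = Counter()
        total = 0
        for codon in codons:
            for pos in range(3):
                for base in _RNA_BASES:
                    if base == codon[pos]:
                        continue
                    mutant = codon[:pos] + base + codon[pos + 1:]
                    target = _translate(mutant)
                    if target == "*":
                        if stop_handling == "exclude":
                            continue
                        total += 1  # renormalize: keep in denominator for now
                        continue
                    if synonymous == "exclude" and target == a:
                        continue
                    tally[target] += 1
                    total += 1
        row = np.zeros(20)
        for b, count in tally.items():
            row[_AA_INDEX[b]] = count / total
        if stop_handling == "renormalize" and row.sum() > 0:
            row /= row.sum()
        probs[_AA_INDEX[a]] = row
    return MutationMatrix(
        probs, {"stop_handling": stop_handling, "synonymous": synonymous}
    )


def future_composition(
    record: ProteinRecord, matrix: MutationMatrix | None = None
) -> np.ndarray:
    """Composition (in percent) expected after one codon-mutation round.

    future_b = 100 * sum_a (counts[a]/L) * P(a -> b). With a row-stochastic
    matrix the 20 percentages sum to 100.
    """
    if matrix is None:
        matrix = build_mutation_matrix()
    current = np.array(
        [record.counts[aa] / record.length for aa in AMINO_ACIDS]
    )
    return 100.0 * current @ matrix.probs


# ---------------------------------------------------------------------------
# pair predictability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairReport:
    """Predictability verdict for one ordered residue pair type."""

    pair: tuple[str, str]
    actual: int
    expected: float
    predicted: int
    predictable: bool


def _expected_pair_fraction(
    counts: Mapping[str, int], length: int, x: str, y: str
) -> Fraction:
    if length < 2:
        raise ValueError("pair expectations need L >= 2")
    rx, ry = counts.get(x, 0), counts.get(y, 0)
    if x == y:
        return Fraction(rx * (rx - 1), length) if rx >= 1 else Fraction(0)
    return Fraction(rx * ry, length)


def expected_pair_count(
    counts: Mapping[str, int], length: int, x: str, y: str
) -> float:
    """Expected number of adjacent occurrences of the ordered pair (x, y).

    Under independent sampling without replacement the expectation over the
    L - 1 adjacent positions is r_x * r_y / L for x != y and
    r_x * (r_x - 1) / L for x == y.
    """
    return float(_expected_pair_fraction(counts, length, x, y))


def _round_half_up(value: Fraction) -> int:
    return math.floor(value + Fraction(1, 2))


def pair_predictability(
    record: ProteinRecord, rule: str = "strict"
) -> tuple[list[PairReport], float, float]:
    """Classify all 400 ordered pair types and summarise the protein.

    The predicted count is the expected count rounded half-up to an integer.
    Under the default ``strict`` rule a pair type's occurrences are all
    predictable iff its actual count equals its predicted count; under the
    ``min`` rule, min(actual, predicted) occurrences are predictable.

    Returns the 400 :class:`PairReport` s plus the predictable and
    unpredictable portions as percentages of the L - 1 adjacent pairs
    (summing to 100).
    """
    if rule not in ("strict", "min"):
        raise ValueError(f"unknown predictability rule {rule!r}")
    L = record.length
    if L < 2:
        raise ValueError("pair predictability needs L >= 2")
    actual = Counter(zip(record.sequence, record.sequence[1:]))
    reports: list[PairReport] = []
    predictable_pairs = 0
    for x in AMINO_ACIDS:
        for y in AMINO_ACIDS:
            a = actual.get((x, y), 0)
            exp = _expected_pair_fraction(record.counts, L, x, y)
            pred = _round_half_up(exp)
            if rule == "strict":
                ok = a == pred
                predictable_pairs += a if ok else 0
            else:
                ok = a <= pred
                predictable_pairs += min(a, pred)
            reports.append(
                PairReport((x, y), a, float(exp), pred, ok)
            )
    total = L - 1
    p = 100.0 * predictable_pairs / total
    return reports, p, 100.0 - p
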