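"""Constrained 4-position stimulus sequences and their redundancy score.

A training sequence is a string of 48 spatial positions (labels 1-4) in
which no position repeats consecutively and every position occurs exactly
12 times.  Its *regularity* G measures first-order redundancy: G = 1 means
every observed transition is deterministic, G near 0 means successors are
close to maximally uncertain given the no-repeat constraint.

G is defined from the maximum-likelihood first-order (bigram) transition
table: for each symbol ``s`` with at least one observed successor, ``H(s)``
is the base-2 entropy of the successor distribution in row ``s``; rows with
no observed successor contribute 0.  Then

    G = 1 - mean_s H(s) / log2(4)

with the mean taken over all four symbols with equal weight 1/4.  Because a
no-repeat sequence has at most 3 possible successors per symbol,
G >= 1 - log2(3)/2 ~= 0.2075 for any valid training sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd

ALPHABET = (1, 2, 3, 4)
TRAINING_LENGTH = 48
RECALL_LENGTH = 24

#: Constraint-imposed floor on G for a valid no-repeat training sequence.
G_FLOOR = 1.0 - math.log2(3) / 2.0

Role = Literal["training", "recall"]


@dataclass(frozen=True)
class SymbolSequence:
    """An ordered sequence of position labels 1-4.

    ``role`` is ``"training"`` (48 items, no consecutive repeats, balanced
    counts) or ``"recall"`` (24 items, labels 1-4, otherwise unconstrained).
    Construction does not validate the role invariants; use
    :func:`validate_sequence`.
    """

    items: tuple[int, ...]
    role: Role = "training"

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(int(i) for i in self.items))

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_string(cls, text: str, role: Role = "training") -> "SymbolSequence":
        """Parse a dash- (or comma-) separated label string like ``1-2-3-4``."""
        sep = "-" if "-" in text else ","
        return cls(tuple(int(tok) for tok in text.strip().split(sep)), role=role)

    def to_string(self) -> str:
        return "-".join(str(i) for i in self.items)


@dataclass
class ValidationReport:
    """Outcome of checking a sequence against its role's invariants."""

    passed: bool
    violations: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TransitionTable:
    """4x4 matrix of observed successor counts, rows indexed by symbol 1-4."""

    counts: np.ndarray  # shape (4, 4), counts[s-1, t-1] = #(s -> t)

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class RegularityScore:
    """Redundancy G in [0, 1]; ``rounded`` is the 2-decimal display value."""

    G: float

    @property
    def rounded(self) -> float:
        return round_half_up(self.G, 2)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.685 -> 0.69), as printed tables do."""
    scale = 10**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def validate_sequence(seq: SymbolSequence, role: Role | None = None) -> ValidationReport:
    """Check a sequence against its role's structural invariants.

    Training: length 48, labels in {1,2,3,4}, no two consecutive items equal,
    each label exactly 12 times.  Recall: length 24, labels in {1,2,3,4}.
    Every violation is reported with the offending index or label.
    """
    role = role or seq.role
    violations: list[str] = []
    items = seq.items
    if len(items) == 0:
        raise ValueError("empty sequence is not a valid input")
    for i, v in enumerate(items):
        if v not in ALPHABET:
            violations.append(f"label out of alphabet at index {i}: {v}")
    expected_len = TRAINING_LENGTH if role == "training" else RECALL_LENGTH
    if len(items) != expected_len:
        violations.append(f"length {len(items)} != {expected_len} for role {role}")
    if role == "training":
        for i in range(1, len(items)):
            if items[i] == items[i - 1]:
                violations.append(f"consecutive repeat at index {i}")
        for label in ALPHABET:
            n = items.count(label)
            if len(items) == TRAINING_LENGTH and n != TRAINING_LENGTH // 4:
                violations.append(f"label {label} occurs {n} times, expected 12")
    return ValidationReport(passed=not violations, violations=violations)


def transition_counts(seq: SymbolSequence) -> TransitionTable:
    """First-order successor counts; total cells sum to ``len(seq) - 1``."""
    items = seq.items
    if any(v not in ALPHABET for v in items):
        raise ValueError("labels must be in {1,2,3,4}")
    if len(items) < 2:
        raise ValueError("sequence too short for transitions (need length >= 2)")
    counts = np.zeros((4, 4), dtype=np.int64)
    arr = np.asarray(items)
    np.add.at(counts, (arr[:-1] - 1, arr[1:] - 1), 1)
    return TransitionTable(counts=counts)


def redundancy_G(seq: SymbolSequence) -> RegularityScore:
    """Redundancy G = 1 - mean per-symbol successor entropy / 2 bits.

    Rows with no observed successor contribute zero entropy.  Full precision
    is carried; use ``.rounded`` for 2-decimal display.
    """
    table = transition_counts(seq)
    mean_H = _mean_row_entropy(table.counts)
    return RegularityScore(G=1.0 - mean_H / 2.0)


def _mean_row_entropy(counts: np.ndarray) -> float:
    entropies = []
    for row in counts:
        total = row.sum()
        if total == 0:
            entropies.append(0.0)
            continue
        p = row[row > 0] / total
        entropies.append(float(-(p * np.log2(p)).sum()))
    return float(np.mean(entropies))


def random_training_sequence(rng: np.random.Generator, length: int = TRAINING_LENGTH) -> SymbolSequence:
    """Uniform-ish random valid training sequence (no repeats, balanced).

    Sequential sampling with restart on dead ends; a dead end can only occur
    near the tail, so restarts are rare.
    """
    per = length // 4
    while True:
        remaining = {s: per for s in ALPHABET}
        items: list[int] = []
        ok = True
        for _ in range(length):
            choices = [s for s in ALPHABET if remaining[s] > 0 and (not items or s != items[-1])]
            if not choices:
                ok = False
                break
            weights = np.array([remaining[s] for s in choices], dtype=float)
            s = int(rng.choice(choices, p=weights / weights.sum()))
            items.append(s)
            remaining[s] -= 1
        if ok:
            return SymbolSequence(tuple(items), role="training")


class SearchFailure(RuntimeError):
    """Raised when sequence synthesis cannot reach the target G."""

    def __init__(self, target: float, best_G: float, best: SymbolSequence | None = None):
        super().__init__(
            f"could not reach target G={target:.4f}; best found G={best_G:.4f}"
        )
        self.target = target
        self.best_G = best_G
        self.best = best


def generate_sequence(
    target_G: float,
    length: int = TRAINING_LENGTH,
    seed: int | np.random.Generator = 0,
    tol: float = 0.02,
    max_iter: int = 20_000,
) -> SymbolSequence:
    """Synthesize a valid training sequence with redundancy near ``target_G``.

    Seeded stochastic local search: start from a random valid sequence and
    propose constraint-preserving position swaps, accepting moves that reduce
    |G - target| (with a small annealed chance of uphill moves to escape
    local minima).  ``target_G = 1`` short-circuits to a repeated 4-cycle.

    Raises :class:`SearchFailure` if no sequence within ``tol`` is found.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if target_G < G_FLOOR - 1e-9 or target_G > 1.0 + 1e-9:
        raise SearchFailure(target_G, best_G=G_FLOOR)
    if target_G >= 1.0 - tol / 2:
        perm = list(rng.permutation(list(ALPHABET)))
        return SymbolSequence(tuple(perm * (length // 4)), role="training")

    seq = list(random_training_sequence(rng, length).items)
    arr = np.array(seq)

    def g_of(a: np.ndarray) -> float:
        counts = np.zeros((4, 4), dtype=np.int64)
        np.add.at(counts, (a[:-1] - 1, a[1:] - 1), 1)
        return 1.0 - _mean_row_entropy(counts) / 2.0

    def swap_ok(a: np.ndarray, i: int, j: int) -> bool:
        b = a.copy()
        b[i], b[j] = b[j], b[i]
        for k in (i, j):
            if k > 0 and b[k] == b[k - 1]:
                return False
            if k < len(b) - 1 and b[k] == b[k + 1]:
                return False
        return True

    cur_err = abs(g_of(arr) - target_G)
    best_arr, best_err = arr.copy(), cur_err
    temp = 0.05
    for it in range(max_iter):
        if best_err <= tol:
            break
        i, j = rng.integers(0, length, size=2)
        if i == j or arr[i] == arr[j] or not swap_ok(arr, int(i), int(j)):
            continue
        cand = arr.copy()
        cand[i], cand[j] = cand[j], cand[i]
        err = abs(g_of(cand) - target_G)
        if err < cur_err or rng.random() < math.exp(-(err - cur_err) / max(temp, 1e-6)):
            arr, cur_err = cand, err
            if err < best_err:
                best_arr, best_err = arr.copy(), err
        temp *= 0.999
    if best_err > tol:
        raise SearchFailure(target_G, best_G=g_of(best_arr), best=SymbolSequence(tuple(best_arr)))
    result = SymbolSequence(tuple(int(v) for v in best_arr), role="training")
    assert validate_sequence(result).passed
    return result


def load_stimulus_table() -> pd.DataFrame:
    """Load the 11 shipped stimulus sequences with their printed G values.

    Columns: ``id``, ``participant_n``, ``sequence`` (dash-separated string),
    ``printed_G`` (period decimal; the source table's European "1,0" is
    normalized), plus computed ``G`` and a ``printed_matches`` flag marking
    rows whose printed value disagrees with the computed one at 2 decimals.
    """
    with resources.files("wagertrack.data").joinpath("table1_sequences.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"printed_G": str})
    df["printed_G"] = df["printed_G"].str.replace(",", ".", regex=False).astype(float)
    df["G"] = [
        redundancy_G(SymbolSequence.from_string(s)).rounded for s in df["sequence"]
    ]
    df["printed_matches"] = np.isclose(df["G"], df["printed_G"], atol=5e-3)
    return df


def stimulus_sequences() -> list[SymbolSequence]:
    """The 11 shipped training sequences as :class:`SymbolSequence` objects."""
    df = load_stimulus_table()
    return [SymbolSequence.from_string(s) for s in df["sequence"]]
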