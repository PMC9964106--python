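"""Secondary structure by base-pair maximization (Nussinov DP).

The structural descriptors downstream need only the maximum number of
nested base pairs and a stability proxy, so the built-in folder is the
exact Nussinov dynamic program with Watson-Crick plus G:T(U) wobble
pairing and a minimum hairpin loop.  The energy estimate is a per-pair
sum (GC -3, AU -2, GU -1), which preserves the sign and monotonicity of
a free energy without a nearest-neighbor thermodynamic engine; an
external folding backend returning (dot-bracket, MFE) can be plugged in
where kcal/mol fidelity matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit

from .records import ALPHABET, SequenceRecord, SequenceError, normalize_sequence

DEFAULT_MIN_LOOP = 3
DEFAULT_PAIR_ENERGIES = {"GC": -3.0, "AU": -2.0, "GU": -1.0}

# letter codes: A=0, C=1, G=2, T=3 (lexicographic)
_CODE = {c: i for i, c in enumerate(ALPHABET)}
# canonical pairs incl. wobble, symmetric
_PAIRABLE = np.zeros((4, 4), dtype=np.bool_)
for a, b in [("A", "T"), ("G", "C"), ("G", "T")]:
    _PAIRABLE[_CODE[a], _CODE[b]] = True
    _PAIRABLE[_CODE[b], _CODE[a]] = True


class FoldError(ValueError):
    pass


@dataclass(frozen=True)
class FoldResult:
    """One nested secondary structure of a sequence."""

    dotbracket: str
    n_pairs: int
    mfe: float

    def pairs(self) -> list[tuple[int, int]]:
        return parse_dotbracket(self.dotbracket)


def encode_letters(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise SequenceError(f"non-alphabet character {exc.args[0]!r}") from exc


@njit(cache=True)
def _nussinov_table(codes, pairable, min_loop):  # pragma: no cover - numba
    n = codes.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pairable[codes[i], codes[k]]:
                    left = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = M[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            M[i, j] = best
    return M


@njit(cache=True)
def _traceback(M, codes, pairable, min_loop):  # pragma: no cover - numba
    """Deterministic traceback: pairing i with the smallest admissible k wins
    over leaving i unpaired only when it is strictly required to reach M[i,j]."""
    n = codes.shape[0]
    pair_of = np.full(n, -1, dtype=np.int32)
    stack = np.empty((n + 1, 2), dtype=np.int32)
    top = 0
    if n > 0:
        stack[top, 0] = 0
        stack[top, 1] = n - 1
        top += 1
    while top > 0:
        top -= 1
        i, j = stack[top, 0], stack[top, 1]
        if j - i <= min_loop:
            continue
        # prefer pairing i: smallest k first
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if pairable[codes[i], codes[k]]:
                left = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = M[k + 1, j] if k + 1 <= j else 0
                if 1 + left + right == M[i, j]:
                    pair_of[i] = k
                    pair_of[k] = i
                    if k - 1 > i + 1:
                        stack[top, 0] = i + 1
                        stack[top, 1] = k - 1
                        top += 1
                    if k + 1 < j:
                        stack[top, 0] = k + 1
                        stack[top, 1] = j
                        top += 1
                    paired = True
                    break
        if not paired:
            stack[top, 0] = i + 1
            stack[top, 1] = j
            top += 1
    return pair_of


def nussinov_max_pairs(seq: SequenceRecord | str, min_loop: int = DEFAULT_MIN_LOOP) -> FoldResult:
    """Maximum nested base pairing with a deterministic traceback.

    ``n_pairs`` is exact (the DP optimum over all nested structures with
    hairpin loops of at least ``min_loop`` unpaired bases); ``mfe`` is the
    per-pair-sum estimate of :func:`mfe_estimate` for the returned structure.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else normalize_sequence(seq)
    if len(s) == 0:
        raise FoldError("empty sequence")
    codes = encode_letters(s)
    n = len(s)
    if n <= min_loop + 1:
        return FoldResult("." * n, 0, 0.0)
    M = _nussinov_table(codes, _PAIRABLE, min_loop)
    pair_of = _traceback(M, codes, _PAIRABLE, min_loop)
    db = np.full(n, ".", dtype="U1")
    for i in range(n):
        j = pair_of[i]
        if j > i:
            db[i] = "("
            db[j] = ")"
    fold = FoldResult("".join(db), int(M[0, n - 1]), 0.0)
    object.__setattr__(fold, "mfe", mfe_estimate(fold, s))
    return fold


def mfe_estimate(
    fold: FoldResult,
    seq: SequenceRecord | str,
    pair_energies: dict[str, float] = DEFAULT_PAIR_ENERGIES,
) -> float:
    """Sum of per-pair energies over the pairs of ``fold`` (0 if unpaired)."""
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if len(s) != len(fold.dotbracket):
        raise FoldError("fold/sequence length mismatch")
    canon = {frozenset("GC"): "GC", frozenset("AT"): "AU", frozenset("GT"): "GU"}
    total = 0.0
    for i, j in parse_dotbracket(fold.dotbracket):
        key = canon.get(frozenset((s[i], s[j])))
        if key is None:
            raise FoldError(f"non-canonical pair {s[i]}:{s[j]} at ({i},{j})")
        total += pair_energies[key]
    return total


def parse_dotbracket(db: str) -> list[tuple[int, int]]:
    """Stack-match a dot-bracket string into 0-based index pairs."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FoldError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise FoldError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise FoldError(f"unmatched '(' at position {stack[-1]}")
    return sorted(pairs)


# Optional external backend: a callable seq -> (dotbracket, mfe), e.g. an
# adapter around an RNA-folding tool.  Output is validated against the
# FoldResult invariants via parse_dotbracket.
FoldBackend = Callable[[str], tuple[str, float]]


def fold_with_backend(seq: SequenceRecord | str, backend: FoldBackend) -> FoldResult:
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    db, mfe = backend(s)
    if len(db) != len(s):
        raise FoldError("backend dot-bracket length mismatch")
    pairs = parse_dotbracket(db)
    if mfe > 0:
        raise FoldError("backend MFE must be <= 0")
    return FoldResult(db, len(pairs), float(mfe))
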