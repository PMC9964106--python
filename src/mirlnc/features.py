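"""Per-sequence and per-pair feature vectors.

Each sequence is described by 407 values: k-mer composition (1/2/3-mer:
4+16+64), gapped compositions (64 + 256), and three secondary-structure
descriptors — DM = MFE/L (length-normalized stability), E1 =
n_pairs/(L/2) (base-pairing rate) and E2 = (n_G+n_C)/L (G+C fraction).
A pair vector concatenates the miRNA and lncRNA blocks (814 values).

Gapped compositions count windows of ``n_specified + n_gaps`` positions,
aggregated over every placement of the gap positions within the window;
the defaults (3 specified, 1 gap) and (4 specified, 2 gaps) give the
64- and 256-dimensional blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .folding import FoldResult, nussinov_max_pairs
from .records import ALPHABET, SequenceRecord, normalize_sequence

N_FEATURES_PER_SEQ = 4 + 16 + 64 + 64 + 256 + 3  # = 407
N_FEATURES_PER_PAIR = 2 * N_FEATURES_PER_SEQ  # = 814


class FeatureError(ValueError):
    pass


def _as_seq(seq: SequenceRecord | str) -> str:
    return seq.seq if isinstance(seq, SequenceRecord) else normalize_sequence(seq)


def _codes(s: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(ALPHABET):
        lut[ord(c)] = i
    arr = lut[np.frombuffer(s.encode(), dtype=np.uint8)]
    return arr


def kmer_labels(k: int) -> list[str]:
    return ["".join(t) for t in product(ALPHABET, repeat=k)]


def kmer_counts(seq: SequenceRecord | str, k: int, normalize: bool = True) -> np.ndarray:
    """Counts (or frequencies) of all 4^k k-mers, lexicographic order A<C<G<T."""
    if k < 1:
        raise FeatureError("k must be >= 1")
    s = _as_seq(seq)
    out = np.zeros(4 ** k)
    n_windows = len(s) - k + 1
    if n_windows <= 0:
        return out
    codes = _codes(s)
    idx = np.zeros(n_windows, dtype=np.int64)
    for off in range(k):
        idx = idx * 4 + codes[off: off + n_windows]
    np.add.at(out, idx, 1.0)
    if normalize:
        out /= n_windows
    return out


def gapped_counts(
    seq: SequenceRecord | str,
    n_specified: int,
    n_gaps: int,
    normalize: bool = True,
) -> np.ndarray:
    """Gapped composition: 4^n_specified counts, summed over gap placements.

    A window of length ``n_specified + n_gaps`` contributes to the tuple
    formed by its letters at the specified positions, for every way of
    choosing which ``n_gaps`` window positions are wildcards.  With
    ``n_gaps=0`` this is exactly :func:`kmer_counts`.
    """
    if n_specified < 1 or n_gaps < 0:
        raise FeatureError("need n_specified >= 1 and n_gaps >= 0")
    s = _as_seq(seq)
    w = n_specified + n_gaps
    out = np.zeros(4 ** n_specified)
    n_windows = len(s) - w + 1
    if n_windows <= 0:
        return out
    codes = _codes(s)
    n_placements = 0
    for gap_pos in combinations(range(w), n_gaps):
        spec_pos = [p for p in range(w) if p not in gap_pos]
        idx = np.zeros(n_windows, dtype=np.int64)
        for off in spec_pos:
            idx = idx * 4 + codes[off: off + n_windows]
        np.add.at(out, idx, 1.0)
        n_placements += 1
    if normalize:
        out /= n_windows * n_placements
    return out


def structure_features(seq: SequenceRecord | str, fold: FoldResult) -> tuple[float, float, float]:
    """(DM, E1, E2): MFE/L, n_pairs/(L/2), (n_G+n_C)/L."""
    s = _as_seq(seq)
    L = len(s)
    if L == 0:
        raise FeatureError("empty sequence")
    if len(fold.dotbracket) != L:
        raise FeatureError("fold/sequence length mismatch")
    dm = fold.mfe / L
    e1 = fold.n_pairs / (L / 2.0)
    e2 = (s.count("G") + s.count("C")) / L
    return dm, e1, e2


def feature_names(prefix: str = "") -> list[str]:
    names: list[str] = []
    names += [f"{prefix}k1_{m}" for m in kmer_labels(1)]
    names += [f"{prefix}k2_{m}" for m in kmer_labels(2)]
    names += [f"{prefix}k3_{m}" for m in kmer_labels(3)]
    names += [f"{prefix}gap1_{m}" for m in kmer_labels(3)]
    names += [f"{prefix}gap2_{m}" for m in kmer_labels(4)]
    names += [f"{prefix}DM", f"{prefix}E1", f"{prefix}E2"]
    return names


@dataclass(frozen=True)
class FeatureVector:
    """The 407-value per-sequence descriptor with stable feature names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.values)


def featurize(seq: SequenceRecord | str, fold_backend=None, normalize: bool = True) -> FeatureVector:
    """Full per-sequence vector: k-mer, gapped and structural blocks.

    ``fold_backend`` may be a callable ``seq_str -> FoldResult``; the default
    is the built-in Nussinov folder.
    """
    s = _as_seq(seq)
    fold = fold_backend(s) if fold_backend is not None else nussinov_max_pairs(s)
    dm, e1, e2 = structure_features(s, fold)
    vec = np.concatenate([
        kmer_counts(s, 1, normalize),
        kmer_counts(s, 2, normalize),
        kmer_counts(s, 3, normalize),
        gapped_counts(s, 3, 1, normalize),
        gapped_counts(s, 4, 2, normalize),
        [dm, e1, e2],
    ])
    return FeatureVector(vec, tuple(feature_names()))


def featurize_pair(
    mirna: SequenceRecord | str,
    lncrna: SequenceRecord | str,
    fold_backend=None,
    normalize: bool = True,
) -> FeatureVector:
    """[miRNA block || lncRNA block], 814 values, names prefixed by role."""
    fm = featurize(mirna, fold_backend, normalize)
    fl = featurize(lncrna, fold_backend, normalize)
    names = tuple(feature_names("mirna_")) + tuple(feature_names("lncrna_"))
    return FeatureVector(np.concatenate([fm.values, fl.values]), names)


def feature_matrix(
    pairs,
    sequences: dict[str, SequenceRecord],
    fold_backend=None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pair-feature matrix for a list of InteractionPair.

    Per-sequence vectors are cached by id, so each distinct sequence is
    folded once.  Returns (X, y, names).
    """
    cache: dict[str, np.ndarray] = {}

    def vec(sid: str) -> np.ndarray:
        if sid not in cache:
            cache[sid] = featurize(sequences[sid], fold_backend).values
        return cache[sid]

    X = np.empty((len(pairs), N_FEATURES_PER_PAIR))
    y = np.empty(len(pairs), dtype=np.int64)
    for i, p in enumerate(pairs):
        X[i, :N_FEATURES_PER_SEQ] = vec(p.mirna_id)
        X[i, N_FEATURES_PER_SEQ:] = vec(p.lncrna_id)
        y[i] = p.label
    names = feature_names("mirna_") + feature_names("lncrna_")
    return X, y, names
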