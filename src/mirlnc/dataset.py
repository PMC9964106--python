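"""Training-set construction: similarity filtering, negative pairing,
SMOTE balancing, length filtering, and integer encoding.

Redundancy control follows the usual protocol for interaction datasets:
candidate non-interacting lncRNAs whose best global-alignment identity
against the interacting group exceeds 80% are dropped, negatives are
random (miRNA, retained lncRNA) pairs, and the minority class can be
topped up by SMOTE interpolation in feature space.  Sequences are
integer-encoded (A=1, T=2, C=3, G=4, pad 0, separator 5) as
[miRNA | sep | lncRNA | pad] rows for the neural model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
from Bio import Align
from sklearn.neighbors import NearestNeighbors

from .records import InteractionPair, SequenceRecord, normalize_sequence

TOKEN_PAD = 0
TOKEN_SEP = 5
TOKEN_OF = {"A": 1, "T": 2, "C": 3, "G": 4}
LETTER_OF = {v: k for k, v in TOKEN_OF.items()}

DEFAULT_MAX_LEN = 4000
DEFAULT_SIMILARITY_THRESHOLD = 0.80


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment and its identity fraction."""

    score: float
    aligned_a: str
    aligned_b: str
    identity: float


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def needleman_wunsch(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentResult:
    """Optimal global alignment under linear gap costs.

    Identity is matched columns over alignment length, computed on the
    first (deterministic) optimal traceback.
    """
    sa = a.seq if isinstance(a, SequenceRecord) else normalize_sequence(a)
    sb = b.seq if isinstance(b, SequenceRecord) else normalize_sequence(b)
    if not sa or not sb:
        raise AlignmentError("empty sequence")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return AlignmentResult(float(aln.score), ga, gb, matches / len(ga))


def similarity_filter(
    candidates: list[SequenceRecord],
    references: list[SequenceRecord],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    **nw_kwargs,
) -> list[SequenceRecord]:
    """Keep candidates whose max identity to any reference is <= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if not candidates or not references:
        raise ValueError("candidate and reference sets must be nonempty")
    kept = []
    for cand in candidates:
        best = max(needleman_wunsch(cand, ref, **nw_kwargs).identity for ref in references)
        if best <= threshold:
            kept.append(cand)
    return kept


def build_negatives(
    noninteracting: list[SequenceRecord],
    mirnas: list[SequenceRecord],
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[InteractionPair]:
    """n distinct random (miRNA, non-interacting lncRNA) pairs, label 0."""
    grid = len(noninteracting) * len(mirnas)
    if n > grid:
        raise ValueError(f"requested {n} negatives from a grid of {grid}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(grid, size=n, replace=False)
    out = []
    for flat in chosen:
        mi, li = divmod(int(flat), len(noninteracting))
        out.append(InteractionPair(mirnas[mi].id, noninteracting[li].id, 0, provenance="random"))
    return out


def smote(
    vectors: np.ndarray,
    k_neighbors: int = 5,
    n_new: int = 0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Synthetic minority oversampling: x + u * (x_nn - x), u ~ U[0,1].

    ``x`` is a uniformly sampled class member and ``x_nn`` one of its
    ``k_neighbors`` nearest same-class neighbours (Euclidean).
    """
    vectors = np.asarray(vectors, dtype=float)
    n, d = vectors.shape
    if k_neighbors < 1 or n <= k_neighbors:
        raise ValueError("need class size > k_neighbors >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(vectors)
    _, idx = nn.kneighbors(vectors)  # column 0 is the point itself
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    u = rng.random(size=(n_new, 1))
    x = vectors[base]
    x_nn = vectors[idx[base, pick + 1]]
    return x + u * (x_nn - x)


def length_filter(records: list[SequenceRecord], max_len: int = DEFAULT_MAX_LEN) -> list[SequenceRecord]:
    """Drop sequences strictly longer than max_len, preserving order."""
    return [r for r in records if len(r.seq) <= max_len]


@dataclass(frozen=True)
class EncodedPairBatch:
    """Integer-encoded pair rows [miRNA | sep | lncRNA | pad] with labels."""

    tokens: np.ndarray  # (n_pairs, max_len) int8/int64
    lengths: np.ndarray  # used length per row (incl. separator)
    labels: np.ndarray  # {0,1}
    max_len: int

    def __len__(self) -> int:
        return self.tokens.shape[0]


def encode_sequence(s: str) -> list[int]:
    s = normalize_sequence(s)
    return [TOKEN_OF[c] for c in s]


def encode_pairs(
    pairs: list[InteractionPair],
    sequences: dict[str, SequenceRecord],
    max_len: int | None = None,
    truncate: bool = False,
) -> EncodedPairBatch:
    """Encode labelled pairs into one padded token matrix.

    ``max_len=None`` sizes the matrix to the longest combined row.
    Without ``truncate``, a row longer than ``max_len`` is an error.
    """
    rows = []
    for p in pairs:
        m = encode_sequence(sequences[p.mirna_id].seq)
        l = encode_sequence(sequences[p.lncrna_id].seq)
        rows.append(m + [TOKEN_SEP] + l)
    need = max(len(r) for r in rows)
    if max_len is None:
        max_len = need
    elif need > max_len:
        if not truncate:
            raise ValueError(f"combined length {need} exceeds max_len {max_len}")
        rows = [r[:max_len] for r in rows]
    tokens = np.zeros((len(rows), max_len), dtype=np.int64)
    lengths = np.empty(len(rows), dtype=np.int64)
    for i, r in enumerate(rows):
        tokens[i, : len(r)] = r
        lengths[i] = len(r)
    labels = np.array([p.label for p in pairs], dtype=np.int64)
    return EncodedPairBatch(tokens, lengths, labels, max_len)


def decode_row(row: np.ndarray) -> tuple[str, str]:
    """Inverse of the row layout: (miRNA, lncRNA) strings."""
    toks = [int(t) for t in row if t != TOKEN_PAD]
    sep = toks.index(TOKEN_SEP)
    mir = "".join(LETTER_OF[t] for t in toks[:sep])
    lnc = "".join(LETTER_OF[t] for t in toks[sep + 1:])
    return mir, lnc


def save_batch(batch: EncodedPairBatch, path: str | Path) -> None:
    """Persist as NPZ with a JSON sidecar recording the token map."""
    path = Path(path)
    np.savez(path, tokens=batch.tokens, lengths=batch.lengths, labels=batch.labels)
    sidecar = {"max_len": batch.max_len, "token_map": {"pad": TOKEN_PAD, "sep": TOKEN_SEP, **TOKEN_OF}}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_batch(path: str | Path) -> EncodedPairBatch:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return EncodedPairBatch(data["tokens"], data["lengths"], data["labels"], sidecar["max_len"])
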