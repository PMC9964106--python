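"""Sequence records and plain-text I/O.

All sequences are held over the canonical DNA alphabet {A, C, G, T}; ``U``
is mapped to ``T`` on ingest so that miRNA (RNA) and lncRNA inputs share one
alphabet throughout the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

ROLE_MIRNA = "miRNA"
ROLE_LNCRNA = "lncRNA"


class SequenceError(ValueError):
    """Raised for malformed or out-of-alphabet sequence input."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U->T; reject characters outside {A,C,G,T,U}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(ALPHABET)
    if bad:
        raise SequenceError(f"non-alphabet characters {sorted(bad)} in sequence")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA/DNA sequence with its role in the interaction pair."""

    id: str
    seq: str
    role: str  # ROLE_MIRNA or ROLE_LNCRNA

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_sequence(self.seq))
        if self.role not in (ROLE_MIRNA, ROLE_LNCRNA):
            raise SequenceError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class InteractionPair:
    """A labelled (miRNA, lncRNA) pair; label 1 = interacting."""

    mirna_id: str
    lncrna_id: str
    label: int
    provenance: str = ""
    site_pos: int | None = None


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with ``>id role=...`` headers."""
    bio = [
        SeqRecord(Seq(r.seq), id=r.id, description=f"role={r.role}")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_fasta(path: str | Path, default_role: str = ROLE_LNCRNA) -> list[SequenceRecord]:
    """Read FASTA written by :func:`write_fasta` (or any FASTA, with a default role)."""
    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        role = default_role
        for tok in rec.description.split():
            if tok.startswith("role="):
                role = tok[len("role="):]
        try:
            out.append(SequenceRecord(rec.id, str(rec.seq), role))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    return out


PAIRS_HEADER = ["mirna_id", "lncrna_id", "label", "provenance"]


def write_pairs_tsv(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAIRS_HEADER) + "\n")
        for p in pairs:
            fh.write(f"{p.mirna_id}\t{p.lncrna_id}\t{p.label}\t{p.provenance}\n")


def read_pairs_tsv(path: str | Path) -> list[InteractionPair]:
    pairs: list[InteractionPair] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PAIRS_HEADER:
            raise ValueError(f"unexpected pairs TSV header {header}")
        for line in fh:
            m, l, lab, prov = line.rstrip("\n").split("\t")
            pairs.append(InteractionPair(m, l, int(lab), prov))
    return pairs


def write_manifest(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
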