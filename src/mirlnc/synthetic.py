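"""Synthetic miRNA/lncRNA sequences with a planted complementarity signal.

Positive (interacting) pairs are simulated by splicing a noisy reverse
complement of the miRNA into the lncRNA, mimicking a miRNA target site;
negative pairs draw lncRNAs that carry no planted site.  The generator
stands in for a real miRNA-target predictor: it produces a learnable,
fully reproducible signal, not plant-genome sequence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .records import (
    ALPHABET,
    ROLE_LNCRNA,
    ROLE_MIRNA,
    InteractionPair,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_manifest,
    write_pairs_tsv,
)


class ConfigError(ValueError):
    pass


class CapacityError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic interaction dataset.

    Defaults mirror the shape of real plant data: ~21-nt miRNAs against
    200-4000 nt lncRNAs at a miRNA:lncRNA ratio of roughly 1:62 (the ratio
    of the public wheat resources, scaled down ~15x), with one planted
    target site per positive pair and 10% per-position mutation noise on
    the site.
    """

    n_mirna: int = 20
    n_lncrna: int = 1230
    mirna_len_range: tuple[int, int] = (20, 24)
    lncrna_len_range: tuple[int, int] = (200, 4000)
    site_mutation_rate: float = 0.1
    gc_bias: float = 0.5
    n_positive: int = 1000
    n_negative: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_lncrna", "n_positive", "n_negative"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("mirna_len_range", "lncrna_len_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must be an ordered positive interval")
        for name in ("site_mutation_rate", "gc_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")


def _random_seq(rng: np.random.Generator, length: int, gc_bias: float) -> str:
    # letters drawn as G/C with prob gc_bias, A/T otherwise; uniform within each pair
    p_each_gc = gc_bias / 2.0
    p_each_at = (1.0 - gc_bias) / 2.0
    probs = [p_each_at, p_each_gc, p_each_gc, p_each_at]  # A, C, G, T
    idx = rng.choice(4, size=length, p=probs)
    return "".join(ALPHABET[i] for i in idx)


def generate_sequences(config: SynthConfig) -> list[SequenceRecord]:
    """Draw n_mirna miRNA-like and n_lncrna lncRNA-like background sequences."""
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    lo, hi = config.mirna_len_range
    for i in range(config.n_mirna):
        L = int(rng.integers(lo, hi + 1))
        records.append(SequenceRecord(f"mir{i:04d}", _random_seq(rng, L, config.gc_bias), ROLE_MIRNA))
    lo, hi = config.lncrna_len_range
    for i in range(config.n_lncrna):
        L = int(rng.integers(lo, hi + 1))
        records.append(SequenceRecord(f"lnc{i:05d}", _random_seq(rng, L, config.gc_bias), ROLE_LNCRNA))
    return records


def plant_positive_pair(
    mirna: SequenceRecord,
    lncrna: SequenceRecord,
    mutation_rate: float,
    rng: np.random.Generator,
) -> tuple[SequenceRecord, InteractionPair, int]:
    """Splice a noisy reverse complement of the miRNA into the lncRNA.

    Each planted position is independently mutated with ``mutation_rate``;
    a mutation always substitutes a *different* letter, so rate 1 yields a
    site with no position matching the reverse complement.
    """
    m = len(mirna.seq)
    L = len(lncrna.seq)
    if L < m:
        raise ValueError(f"lncRNA {lncrna.id} shorter than miRNA {mirna.id}")
    site = reverse_complement(mirna.seq)
    mutated = []
    for ch in site:
        if rng.random() < mutation_rate:
            others = [c for c in ALPHABET if c != ch]
            ch = others[int(rng.integers(3))]
        mutated.append(ch)
    pos = int(rng.integers(0, L - m + 1))
    new_seq = lncrna.seq[:pos] + "".join(mutated) + lncrna.seq[pos + m:]
    modified = SequenceRecord(lncrna.id, new_seq, ROLE_LNCRNA)
    pair = InteractionPair(mirna.id, lncrna.id, 1, provenance="planted", site_pos=pos)
    return modified, pair, pos


def make_dataset(
    config: SynthConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[SequenceRecord], list[InteractionPair], dict]:
    """Build the full labelled dataset under one seed.

    Positive pairs each get their own lncRNA with one planted site; negative
    pairs are drawn without replacement from the (miRNA x unplanted-lncRNA)
    grid.  Requires ``n_positive <= n_lncrna`` donor lncRNAs for planting
    plus a nonempty unplanted pool for negatives.
    """
    if config.n_positive > config.n_mirna * config.n_lncrna:
        raise CapacityError("n_positive exceeds miRNA x lncRNA capacity")
    if config.n_positive > config.n_lncrna:
        raise CapacityError("n_positive exceeds lncRNA pool (one planted site per lncRNA)")
    n_unplanted = config.n_lncrna - config.n_positive
    if config.n_negative > config.n_mirna * n_unplanted:
        raise CapacityError("n_negative exceeds miRNA x unplanted-lncRNA capacity")

    records = generate_sequences(config)
    mirnas = [r for r in records if r.role == ROLE_MIRNA]
    lncrnas = [r for r in records if r.role == ROLE_LNCRNA]

    ss = np.random.SeedSequence(config.seed)
    rng_plant, rng_pair = (np.random.default_rng(s) for s in ss.spawn(2))

    # plant sites into the first n_positive lncRNAs (generation order is seeded)
    planted: dict[str, SequenceRecord] = {}
    pairs: list[InteractionPair] = []
    for i in range(config.n_positive):
        mir = mirnas[int(rng_plant.integers(len(mirnas)))]
        lnc = lncrnas[i]
        mod, pair, _ = plant_positive_pair(mir, lnc, config.site_mutation_rate, rng_plant)
        planted[lnc.id] = mod
        pairs.append(pair)

    unplanted = lncrnas[config.n_positive:]
    grid = len(mirnas) * len(unplanted)
    chosen = rng_pair.choice(grid, size=config.n_negative, replace=False)
    for flat in chosen:
        mi, li = divmod(int(flat), len(unplanted))
        pairs.append(InteractionPair(mirnas[mi].id, unplanted[li].id, 0, provenance="random"))

    order = rng_pair.permutation(len(pairs))
    pairs = [pairs[i] for i in order]

    out_records = mirnas + [planted.get(r.id, r) for r in lncrnas]
    manifest = {"config": {**asdict(config),
                           "mirna_len_range": list(config.mirna_len_range),
                           "lncrna_len_range": list(config.lncrna_len_range)},
                "n_records": len(out_records), "n_pairs": len(pairs)}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(out_records, out_dir / "sequences.fasta")
        write_pairs_tsv(pairs, out_dir / "pairs.tsv")
        write_manifest(manifest, out_dir / "manifest.json")
    return out_records, pairs, manifest
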