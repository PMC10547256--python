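"""TE consensus and matched background sequence libraries with planted sites.

A chosen motif consensus is planted at a random position and strand in a
configurable fraction of the TE sequences and never occurs in the background
library, whose length multiset matches the TE library exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

__all__ = ["TeLibraryConfig", "SeqRecordLite", "simulate_te_libraries"]

_BASES = np.array(list("ACGT"))
_TE_CLASSES = ("LTR", "LINE", "SINE", "DNA")


@dataclass(frozen=True)
class SeqRecordLite:
    seq_id: str
    seq: str
    te_class: str | None = None


@dataclass
class TeLibraryConfig:
    seed: int = 0
    n_te: int = 100
    length_range: tuple[int, int] = (300, 800)
    plant_fraction: float = 0.3
    motif: str = "GACGGTAAGCGT"


@dataclass
class PlantedSites:
    sites: list = field(default_factory=list)  # (seq_id, position, strand)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _contains(seq: str, motif: str) -> bool:
    rc = str(Seq(motif).reverse_complement())
    return motif in seq or rc in seq


def simulate_te_libraries(config: TeLibraryConfig):
    """Return (te_lib, bg_lib, truth) with planted motif sites in te_lib only."""
    if not (0.0 <= config.plant_fraction <= 1.0):
        raise ValueError("plant_fraction must be in [0,1]")
    lo, hi = config.length_range
    if len(config.motif) > lo:
        raise ValueError("motif longer than the shortest sequence")
    rng = np.random.default_rng(config.seed)
    lengths = rng.integers(lo, hi + 1, size=config.n_te)
    n_plant = int(round(config.plant_fraction * config.n_te))
    plant_idx = set(rng.choice(config.n_te, size=n_plant, replace=False).tolist())
    truth = PlantedSites()
    te_lib: list[SeqRecordLite] = []
    for i, L in enumerate(lengths):
        L = int(L)
        # draw until motif absent by chance, then plant deterministically
        seq = _random_seq(rng, L)
        while _contains(seq, config.motif):
            seq = _random_seq(rng, L)
        if i in plant_idx:
            pos = int(rng.integers(0, L - len(config.motif) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = (
                config.motif
                if strand == "+"
                else str(Seq(config.motif).reverse_complement())
            )
            seq = seq[:pos] + planted + seq[pos + len(planted) :]
            truth.sites.append((f"te{i}", pos, strand))
        te_lib.append(
            SeqRecordLite(f"te{i}", seq, _TE_CLASSES[i % len(_TE_CLASSES)])
        )
    bg_lib: list[SeqRecordLite] = []
    for i, L in enumerate(lengths):
        seq = _random_seq(rng, int(L))
        while _contains(seq, config.motif):
            seq = _random_seq(rng, int(L))
        bg_lib.append(SeqRecordLite(f"bg{i}", seq))
    return te_lib, bg_lib, truth
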