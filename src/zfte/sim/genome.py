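"""Genomes with planted tandem-C2H2 and retroelement ORFs.

Background sequence is i.i.d. uniform nucleotide with extra stop codons
sprinkled on both strands so that long stop-free background stretches are
rare.  Planted ORFs are ATG..stop constructs flanked by in-frame stops, so
the census recovers them at exactly their planted coordinates.  ZNF ORFs
encode k tandem C2H2 repeats with 5-10 residue inter-finger spacers and
controllable recognition-helix contact residues; retroelement ORFs carry the
RT (YxDD) or RNase-H catalytic-core motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = ["GenomeSimConfig", "PlantedOrf", "simulate_genome"]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# residues safe to use as filler inside finger x-regions and spacers
# (no C/H, so the C2H2 pattern anchors only where planted)
_FILLER = "ADEFGIKLMNPQRSTVWY".replace("D", "")  # also avoid D: keeps RT/RNaseH cores unique
# residues with sharp recognition-code entries, per helix contact position
_CONTACT_CHOICES = {
    -1: "RQETNKSV",
    2: "DESTRNKQ",
    3: "NDASTVEK",
    6: "RQETKSDN",
}

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()


@dataclass(frozen=True)
class PlantedOrf:
    orf_id: str
    contig_id: str
    start: int  # forward-strand 0-based half-open span of ATG..last codon
    end: int
    strand: str
    kind: str  # ZNF | RT | RNaseH
    n_domains: int
    finger_quads: tuple[tuple[str, str, str, str], ...] = ()
    protein: str = ""


@dataclass
class GenomeSimConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 60_000
    znf_finger_counts: tuple[int, ...] = (6, 5, 7)
    znf_quads: tuple | None = None  # optional per-ORF tuple of per-finger quads
    rt_orf_count: int = 2
    rnaseh_orf_count: int = 1
    stop_rate: float = 0.02  # per-bp rate of sprinkled stop codons, each strand
    minus_strand_fraction: float = 0.5


@dataclass
class PlantedTruth:
    orfs: list[PlantedOrf] = field(default_factory=list)

    def by_id(self, orf_id: str) -> PlantedOrf:
        for o in self.orfs:
            if o.orf_id == orf_id:
                return o
        raise KeyError(orf_id)


def _random_dna(rng: np.random.Generator, n: int, stop_rate: float) -> str:
    seq = rng.choice(_BASES, size=n)
    if stop_rate > 0 and n >= 3:
        n_stops = rng.binomial(n, stop_rate)
        for pos in rng.integers(0, n - 2, size=n_stops):
            stop = _STOPS[rng.integers(0, 3)]
            if rng.random() < 0.5:
                stop = str(Seq(stop).reverse_complement())
            seq[pos : pos + 3] = list(stop)
    return "".join(seq)


def _encode(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(0, len(_CODONS_BY_AA[aa]))] for aa in protein
    )


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_FILLER), size=n))


def make_finger(rng: np.random.Generator, quad: Sequence[str]) -> str:
    """One C2H2 repeat C-x2-C-x12-H-x3-H with the given (-1,+2,+3,+6) quad.

    The recognition helix occupies the last seven residues of the 12-mer
    between the second Cys and the first His; positions -1/+2/+3/+6 sit at
    12-mer indices 5/7/8/11.
    """
    x12 = list(_filler(rng, 12))
    x12[5], x12[7], x12[8], x12[11] = quad
    return "C" + _filler(rng, 2) + "C" + "".join(x12) + "H" + _filler(rng, 3) + "H"


def znf_protein(
    rng: np.random.Generator, quads: Sequence[Sequence[str]]
) -> str:
    parts = ["M", _filler(rng, int(rng.integers(24, 40)))]
    for i, quad in enumerate(quads):
        if i > 0:
            parts.append(_filler(rng, int(rng.integers(5, 11))))
        parts.append(make_finger(rng, quad))
    parts.append(_filler(rng, int(rng.integers(10, 20))))
    return "".join(parts)


def _retro_protein(rng: np.random.Generator, kind: str, min_aa: int = 130) -> str:
    core = "YVDDLL" if kind == "RT" else "LDTGASTQA"
    pre = _filler(rng, int(rng.integers(40, 70)))
    post_len = max(5, min_aa - 1 - len(pre) - len(core))
    return "M" + pre + core + _filler(rng, post_len + int(rng.integers(0, 30)))


def _random_quads(rng: np.random.Generator, k: int):
    return tuple(
        tuple(
            str(rng.choice(list(_CONTACT_CHOICES[pos]))) for pos in (-1, 2, 3, 6)
        )
        for _ in range(k)
    )


def simulate_genome(config: GenomeSimConfig):
    """Return (contigs: dict id->sequence, truth: PlantedTruth)."""
    rng = np.random.default_rng(config.seed)
    # assemble the planting plan
    plan = []
    quads_by_orf = list(config.znf_quads) if config.znf_quads else None
    for i, k in enumerate(config.znf_finger_counts):
        quads = (
            tuple(tuple(q) for q in quads_by_orf[i])
            if quads_by_orf
            else _random_quads(rng, k)
        )
        plan.append(("ZNF", znf_protein(rng, quads), quads))
    for _ in range(config.rt_orf_count):
        plan.append(("RT", _retro_protein(rng, "RT"), ()))
    for _ in range(config.rnaseh_orf_count):
        plan.append(("RNaseH", _retro_protein(rng, "RNaseH"), ()))

    contigs: dict[str, str] = {}
    truth = PlantedTruth()
    per_contig: list[list] = [[] for _ in range(config.n_contigs)]
    for i, item in enumerate(plan):
        per_contig[i % config.n_contigs].append((i, item))

    for c in range(config.n_contigs):
        cid = f"contig{c}"
        pieces: list[str] = []
        pos = 0
        for i, (kind, protein, quads) in per_contig[c]:
            spacer = _random_dna(rng, int(rng.integers(300, 900)), config.stop_rate)
            assert protein[0] == "M"  # cds therefore begins ATG
            cds = _encode(rng, protein)
            construct = "TAA" + cds + "TAA"  # stop | ATG..codons | stop
            minus = rng.random() < config.minus_strand_fraction
            placed = (
                str(Seq(construct).reverse_complement()) if minus else construct
            )
            start = pos + len(spacer) + 3  # forward coord of the ORF span
            end = start + len(cds)
            pieces.append(spacer)
            pieces.append(placed)
            n_domains = len(quads) if kind == "ZNF" else 1
            truth.orfs.append(
                PlantedOrf(
                    orf_id=f"orf{i}",
                    contig_id=cid,
                    start=start,
                    end=end,
                    strand="-" if minus else "+",
                    kind=kind,
                    n_domains=n_domains,
                    finger_quads=quads,
                    protein=protein,
                )
            )
            pos += len(spacer) + len(placed)
        tail = config.contig_length - pos
        if tail < 0:
            raise ValueError(
                f"contig {cid}: planted ORFs need {pos} bp > {config.contig_length}"
            )
        pieces.append(_random_dna(rng, tail, config.stop_rate))
        contigs[cid] = "".join(pieces)
        assert len(contigs[cid]) == config.contig_length
    return contigs, truth
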