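"""Assembly-wide census of tandem-C2H2 and retroelement ORFs.

The census walks genome assemblies in six reading frames, extracts ATG-to-stop
open reading frames within size bounds, scans the translations for C2H2
zinc-finger domains (or retroelement / user-supplied control patterns), and
aggregates per-assembly counts after an assembly-quality (scaffold N50)
filter.  Domain detection is deterministic regular-expression scoring over
canonical motif spacings rather than profile-HMM search; the corresponding
Pfam accessions are recorded as metadata on each pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .stats import ConstantInputError, spearman_rho

__all__ = [
    "OrfRecord",
    "DomainHit",
    "DomainCensusRow",
    "DOMAIN_PATTERNS",
    "MIN_ORF_NT",
    "MAX_ORF_NT",
    "scaffold_n50",
    "extract_orfs",
    "scan_domains",
    "count_tandem_znf_orfs",
    "build_census",
]

# ORF length bounds in nucleotides (stop codon excluded)
MIN_ORF_NT = 375
MAX_ORF_NT = 10_000

# Minimum tandem-array size for a ZNF ORF to enter the census
MIN_ZNF_DOMAINS = 5

# Hits closer than this many residues are grouped into one array
ARRAY_MERGE_RESIDUES = 100


@dataclass(frozen=True)
class DomainPattern:
    kind: str
    regex: str
    pfam: tuple[str, ...]

    @property
    def compiled(self) -> re.Pattern:
        return re.compile(self.regex)


# Deterministic stand-ins for the profile-HMM domain models.  The C2H2
# pattern covers the canonical Cys2-His2 spacing; the retroelement patterns
# are short catalytic-core motifs (RT polymerase YxDD box; RNase-H DEDD-like
# core) specific enough that chance hits in random protein are negligible.
DOMAIN_PATTERNS: dict[str, DomainPattern] = {
    "C2H2": DomainPattern("C2H2", r"C.{2,4}C.{12}H.{3,5}H", ("PF00096",)),
    "RT": DomainPattern(
        "RT", r"[FY][AVLI]DD[LIVMA][LIVMA]", ("PF00078", "PF07727", "PF13456")
    ),
    "RNaseH": DomainPattern(
        "RNaseH", r"[LIVM]D[ST]G[AS][ST].{2}[AG]", ("PF00075", "PF17917", "PF17919")
    ),
}

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    assembly_id: str
    contig_id: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str  # '+' or '-'
    frame: int  # 0-2
    aa_seq: str

    def __post_init__(self) -> None:
        length = self.end - self.start
        if not (MIN_ORF_NT <= length <= MAX_ORF_NT):
            raise ValueError(f"ORF length {length} outside [{MIN_ORF_NT},{MAX_ORF_NT}]")
        if length != 3 * len(self.aa_seq):
            raise ValueError("aa_seq length inconsistent with coordinates")


@dataclass(frozen=True)
class DomainHit:
    orf: OrfRecord
    kind: str
    aa_start: int  # 0-based half-open residue coordinates
    aa_end: int
    score: float


@dataclass
class DomainCensusRow:
    assembly_id: str
    species: str
    family: str
    phylum: str
    scaffold_n50: int
    znf_orf_count: int
    retro_orf_count: int
    control_orf_count: int = 0
    znf_arrays: list = field(default_factory=list)


def scaffold_n50(contig_lengths_or_seqs: Iterable) -> int:
    """Smallest length L such that contigs >= L cover half the assembly."""
    lengths = sorted(
        (len(c) if not isinstance(c, (int, np.integer)) else int(c))
        for c in contig_lengths_or_seqs
    )
    if not lengths:
        raise ValueError("empty assembly")
    total = sum(lengths)
    acc = 0
    for L in reversed(lengths):
        acc += L
        if 2 * acc >= total:
            return L
    return lengths[0]


def _translate(codons: Sequence[str]) -> str:
    aa = []
    for codon in codons:
        if "N" in codon:
            aa.append("X")
        else:
            aa.append(str(Seq(codon).translate()))
    return "".join(aa)


def _orfs_one_strand(seq: str, strand: str, contig_len: int):
    """Yield (fwd_start, fwd_end, frame, aa) for ATG..stop ORFs on one strand.

    ``seq`` is already the strand-oriented sequence; coordinates are mapped
    back to the forward strand.
    """
    n = len(seq)
    for frame in range(3):
        i = frame
        codons = [seq[j : j + 3] for j in range(frame, n - 2, 3)]
        # split into stop-delimited stretches; within each stretch the ORF
        # starts at the first ATG (maximal per stop-free stretch)
        stretch_start = 0  # codon index where current stretch begins
        k = 0
        n_codons = len(codons)
        while k <= n_codons:
            at_stop = k == n_codons or codons[k] in _STOPS
            if at_stop:
                # locate first ATG in [stretch_start, k)
                for m in range(stretch_start, k):
                    if codons[m] == "ATG":
                        nt_len = 3 * (k - m)
                        if MIN_ORF_NT <= nt_len <= MAX_ORF_NT:
                            s = frame + 3 * m
                            e = frame + 3 * k
                            aa = _translate(codons[m:k])
                            if strand == "+":
                                yield s, e, frame, aa
                            else:
                                yield contig_len - e, contig_len - s, frame, aa
                        break
                stretch_start = k + 1
            k += 1


def extract_orfs(contig_seq: str, contig_id: str = "contig", assembly_id: str = "asm") -> list[OrfRecord]:
    """All six-frame ATG-to-stop ORFs within the nucleotide size bounds.

    Codons containing N translate to X and never act as start or stop.
    Coordinates are 0-based half-open on the forward strand; the stop codon
    is excluded from the ORF span.
    """
    seq = contig_seq.upper()
    if not set(seq) <= set("ACGTN"):
        raise ValueError("sequence must be over A/C/G/T/N")
    out: list[OrfRecord] = []
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for start, end, frame, aa in _orfs_one_strand(s, strand, len(seq)):
            out.append(
                OrfRecord(
                    assembly_id=assembly_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    frame=frame,
                    aa_seq=aa,
                )
            )
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def scan_domains(
    orf: OrfRecord, pattern_kind: str, control_pattern: str | None = None
) -> list[DomainHit]:
    """Scan an ORF's protein sequence for one domain kind.

    Overlapping candidate matches are resolved leftmost-longest (the regex
    engine's greedy leftmost match, then continuing after its end); hits come
    back in coordinate order.  ``pattern_kind='control'`` scans the
    user-supplied ``control_pattern`` (the olfactory-receptor control re-uses
    this path).
    """
    if pattern_kind == "control":
        if not control_pattern:
            raise ValueError("control scan requires a pattern")
        pat = re.compile(control_pattern)
    elif pattern_kind in DOMAIN_PATTERNS:
        pat = DOMAIN_PATTERNS[pattern_kind].compiled
    else:
        raise ValueError(f"unknown pattern kind: {pattern_kind!r}")
    hits = []
    pos = 0
    aa = orf.aa_seq
    while True:
        m = pat.search(aa, pos)
        if m is None:
            break
        hits.append(
            DomainHit(
                orf=orf,
                kind=pattern_kind,
                aa_start=m.start(),
                aa_end=m.end(),
                score=float(m.end() - m.start()),
            )
        )
        pos = m.end()
    return hits


def count_tandem_znf_orfs(
    hits_by_orf: Mapping[OrfRecord, Sequence[DomainHit]],
    min_domains: int = MIN_ZNF_DOMAINS,
) -> tuple[int, dict]:
    """Count ORFs whose tandem C2H2 hit total reaches ``min_domains``.

    Hits separated by < 100 residues are grouped into one array for
    reporting; grouping never reduces the per-ORF domain count, which is the
    raw number of hits.
    """
    count = 0
    descriptors: dict = {}
    for orf, hits in hits_by_orf.items():
        hits = sorted(hits, key=lambda h: h.aa_start)
        arrays: list[list[DomainHit]] = []
        for h in hits:
            if arrays and h.aa_start - arrays[-1][-1].aa_end < ARRAY_MERGE_RESIDUES:
                arrays[-1].append(h)
            else:
                arrays.append([h])
        n_domains = len(hits)
        qualifies = n_domains >= min_domains
        descriptors[orf] = {
            "n_domains": n_domains,
            "n_arrays": len(arrays),
            "arrays": [(a[0].aa_start, a[-1].aa_end, len(a)) for a in arrays],
            "qualifies": qualifies,
        }
        if qualifies:
            count += 1
    return count, descriptors


def census_one_assembly(
    assembly_id: str,
    contigs: Mapping[str, str],
    control_pattern: str | None = None,
) -> dict:
    """Raw per-assembly counts (no N50 filter applied here)."""
    orfs: list[OrfRecord] = []
    for cid, seq in contigs.items():
        orfs.extend(extract_orfs(seq, contig_id=cid, assembly_id=assembly_id))
    znf_hits = {o: h for o in orfs if (h := scan_domains(o, "C2H2"))}
    znf_count, descriptors = count_tandem_znf_orfs(znf_hits)
    # retroelement proxy: >= 1 RT or RNase-H hit, no per-ORF hit minimum
    retro_count = sum(
        1
        for o in orfs
        if scan_domains(o, "RT") or scan_domains(o, "RNaseH")
    )
    control_count = 0
    if control_pattern:
        control_count = sum(
            1 for o in orfs if scan_domains(o, "control", control_pattern)
        )
    return {
        "n50": scaffold_n50(contigs.values()),
        "znf_orf_count": znf_count,
        "retro_orf_count": retro_count,
        "control_orf_count": control_count,
        "znf_arrays": descriptors,
        "n_orfs": len(orfs),
    }


def build_census(
    assemblies: Mapping[str, Mapping[str, str]],
    taxon_table: Mapping[str, Mapping[str, str]],
    n50_min: int = 50_000,
    control_pattern: str | None = None,
) -> tuple[list[DomainCensusRow], float | None]:
    """Census rows for assemblies passing the scaffold-N50 filter.

    Returns the rows plus a QC Spearman rho between ZNF ORF count and
    scaffold N50 across retained assemblies (None when fewer than three rows
    or when either variable is constant).
    """
    missing = [a for a in assemblies if a not in taxon_table]
    if missing:
        raise ValueError(f"assemblies missing taxon labels: {sorted(missing)}")
    rows: list[DomainCensusRow] = []
    for asm_id, contigs in assemblies.items():
        res = census_one_assembly(asm_id, contigs, control_pattern=control_pattern)
        if res["n50"] < n50_min:
            continue
        labels = taxon_table[asm_id]
        rows.append(
            DomainCensusRow(
                assembly_id=asm_id,
                species=labels["species"],
                family=labels["family"],
                phylum=labels["phylum"],
                scaffold_n50=res["n50"],
                znf_orf_count=res["znf_orf_count"],
                retro_orf_count=res["retro_orf_count"],
                control_orf_count=res["control_orf_count"],
                znf_arrays=list(res["znf_arrays"].values()),
            )
        )
    qc_rho: float | None = None
    if len(rows) >= 3:
        try:
            qc_rho = spearman_rho(
                [r.znf_orf_count for r in rows], [r.scaffold_n50 for r in rows]
            ).statistic
        except ConstantInputError:
            qc_rho = None
    return rows, qc_rho
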