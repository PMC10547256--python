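"""Positive-selection and variability analysis of tandem-ZNF paralogs.

Pairwise global protein alignments feed a distance matrix and
neighbor-joining gene tree; clades of recent in-paralogs are selected by
species purity, size and length spread; protein-guided codon alignments are
analysed with Nei–Gojobori (1986) counting, site-wise dN/dS profiles, a
Fisher test for enrichment of positive selection at DNA-contacting finger
residues, and per-position sequence entropy over the canonical C2H2 domain.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .stats import ContingencyTable2x2, fisher_exact, shannon_entropy

__all__ = [
    "DistanceMatrix",
    "NG86Result",
    "SiteOmega",
    "EntropyPosition",
    "needleman_wunsch",
    "protein_distance",
    "pairwise_distance_matrix",
    "neighbor_joining",
    "select_clades",
    "codon_align_from_protein",
    "ng86_pairwise",
    "site_omega_profile",
    "contact_enrichment",
    "contact_site_indices",
    "entropy_profile",
]

_AA_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_FINGER_RE = re.compile(r"C(.{2,4})C(.{12})H(.{3,5})H")


# ---------------------------------------------------------------------------
# Needleman-Wunsch with affine gaps (EMBOSS-needle-like defaults)


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def _sub_score(mat, a: str, b: str) -> float:
    try:
        return float(mat[a, b])
    except (KeyError, IndexError):
        # wildcard row for nonstandard residues
        try:
            return float(mat["*", "*"])
        except (KeyError, IndexError):
            return -4.0


def needleman_wunsch(
    a: str,
    b: str,
    substitution: object | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[tuple[str, str], float]:
    """Global alignment with affine gap penalty open + extend*length.

    Deterministic traceback preference: diagonal, then up (gap in ``b``),
    then left (gap in ``a``).  Returns ((aligned_a, aligned_b), score).
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    mat = substitution if substitution is not None else _blosum62()
    n, m = len(a), len(b)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a; vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b; horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * i
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * j
    for i in range(1, n + 1):
        si = a[i - 1]
        for j in range(1, m + 1):
            s = _sub_score(mat, si, b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend
            )
    score = max(M[n, m], X[n, m], Y[n, m])
    # traceback, preferring diagonal then up then left
    out_a, out_b = [], []
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])), key=lambda t: t[1]
    )[0]
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = M[i, j] - _sub_score(mat, a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            for cand, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(val - prev) < 1e-9:
                    state = cand
                    break
        elif state == "X" or (state == "M" and j == 0):
            out_a.append(a[i - 1])
            out_b.append("-")
            if i > 1 and abs(X[i, j] - (X[i - 1, j] - gap_extend)) < 1e-9 and not (
                abs(X[i, j] - (M[i - 1, j] - gap_open - gap_extend)) < 1e-9
            ):
                state = "X"
            else:
                state = "M" if abs(X[i, j] - (M[i - 1, j] - gap_open - gap_extend)) < 1e-9 else "X"
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            if abs(Y[i, j] - (M[i, j - 1] - gap_open - gap_extend)) < 1e-9:
                state = "M"
            else:
                state = "Y"
            j -= 1
    return ("".join(reversed(out_a)), "".join(reversed(out_b))), float(score)


def protein_distance(alignment: tuple[str, str]) -> float:
    """1 - fractional identity over columns that are not gap-gap."""
    aa, bb = alignment
    if len(aa) != len(bb):
        raise ValueError("aligned sequences must be equal length")
    cols = ident = 0
    for x, y in zip(aa, bb):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x == y:
            ident += 1
    if cols == 0:
        raise ValueError("no aligned columns")
    return 1.0 - ident / cols


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.matrix, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.matrix = d


def pairwise_distance_matrix(
    proteins: Mapping[str, str], gap_open: float = 10.0, gap_extend: float = 0.5
) -> DistanceMatrix:
    labels = sorted(proteins)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        aln, _ = needleman_wunsch(
            proteins[labels[i]], proteins[labels[j]], gap_open=gap_open,
            gap_extend=gap_extend,
        )
        d[i, j] = d[j, i] = protein_distance(aln)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou-Nei), deterministic


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei NJ with deterministic tie-breaking.

    Ties in the Q criterion break by lexicographically smallest label pair;
    negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch.  The returned dendropy tree has a trifurcating root
    (unrooted topology).
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    d = dm.matrix.copy()
    # node -> newick fragment
    frags = {lab: lab for lab in labels}
    active = list(labels)

    def join(i_lab: str, j_lab: str, bi: float, bj: float) -> str:
        # clamp negatives, compensating the sibling
        if bi < 0:
            bj += -bi
            bi = 0.0
        if bj < 0:
            bi += -bj
            bj = 0.0
        return f"({frags[i_lab]}:{bi:.12f},{frags[j_lab]}:{bj:.12f})"

    idx = {lab: k for k, lab in enumerate(labels)}
    D = {
        (a, b): d[idx[a], idx[b]] for a in labels for b in labels
    }

    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (n - 2) * D[(a, b)] - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        via = 0.5 * D[(a, b)] + (r[a] - r[b]) / (2 * (n - 2))
        vib = D[(a, b)] - via
        new = f"_n{counter}"
        counter += 1
        frags[new] = join(a, b, via, vib)
        for c in active:
            if c in (a, b):
                continue
            dist = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
            D[(new, c)] = D[(c, new)] = dist
        D[(new, new)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]
    a, b, c = sorted(active, key=lambda lab: (lab.startswith("_n"), lab))
    ba = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
    bb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
    bc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
    parts = []
    for lab, bl in ((a, ba), (b, bb), (c, bc)):
        parts.append(f"{frags[lab]}:{max(bl, 0.0):.12f}")
    newick = "(" + ",".join(parts) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


def select_clades(
    tree: dendropy.Tree,
    species_of: Mapping[str, str],
    lengths: Mapping[str, int],
    target_species: str,
    min_size: int = 10,
    max_len_spread: int = 30,
) -> list[list[str]]:
    """Maximal single-species clades passing size and length-spread rules."""
    pure: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pure[node] = species_of[node.taxon.label] == target_species
        else:
            pure[node] = all(pure[c] for c in node.child_nodes())
    out: list[list[str]] = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if pure[node] and (parent is None or not pure[parent]):
            tips = sorted(l.taxon.label for l in node.leaf_iter())
            if len(tips) < min_size:
                continue
            ls = [lengths[t] for t in tips]
            if max(ls) - min(ls) > max_len_spread:
                continue
            out.append(tips)
    return out


# ---------------------------------------------------------------------------
# Codon alignment and NG86


def codon_align_from_protein(
    cds: Mapping[str, str], protein_alignment: Mapping[str, str]
) -> dict[str, str]:
    """Back-thread codons through a protein alignment; drop gap columns."""
    aligned: dict[str, list[str]] = {}
    width = None
    for name, aln in protein_alignment.items():
        seq = cds[name].upper()
        plain = aln.replace("-", "")
        if len(seq) != 3 * len(plain):
            raise ValueError(f"{name}: CDS length is not 3x protein length")
        prot = str(Seq(seq).translate())
        if prot != plain:
            for k, (x, y) in enumerate(zip(prot, plain)):
                if x != y:
                    raise ValueError(
                        f"{name}: translation mismatch at residue {k}: {x} != {y}"
                    )
            raise ValueError(f"{name}: translation mismatch")
        cods = [seq[3 * k : 3 * k + 3] for k in range(len(plain))]
        row, ci = [], 0
        for ch in aln:
            if ch == "-":
                row.append("---")
            else:
                row.append(cods[ci])
                ci += 1
        aligned[name] = row
        if width is None:
            width = len(row)
        elif width != len(row):
            raise ValueError("aligned proteins have unequal widths")
    keep = [
        j
        for j in range(width)
        if all(aligned[n][j] != "---" for n in aligned)
    ]
    return {n: "".join(aligned[n][j] for j in keep) for n in aligned}


def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Per position, changes producing stop codons are excluded from the
    counted changes; the synonymous fraction is taken over the remaining
    valid changes.
    """
    aa = _AA_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            valid += 1
            if _AA_TABLE[mut] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=4096)
def _pair_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) pathway-averaged over stop-free shortest paths c1 -> c2."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _AA_TABLE[cur] == _AA_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        # no stop-free path (does not occur for the standard code at <= 3
        # steps between sense codons, but guard anyway): count via amino
        # acid identity of the endpoints
        return (len(diff), 0.0) if _AA_TABLE[c1] == _AA_TABLE[c2] else (0.0, float(len(diff)))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass(frozen=True)
class NG86Result:
    dN: float
    dS: float
    omega: float  # nan when undefined
    Nd: float
    Sd: float
    N: float
    S: float
    saturated: bool = False


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise _Saturation
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


class _Saturation(Exception):
    pass


def _split_codons(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    cods = [seq[k : k + 3] for k in range(0, len(seq), 3)]
    bad = [c for c in cods if c in _STOPS or c not in _AA_TABLE]
    if bad:
        raise ValueError(f"invalid/stop codons present: {bad[:3]}")
    return cods


def ng86_pairwise(codon_a: str, codon_b: str) -> NG86Result:
    """Nei–Gojobori (1986) dN/dS between two gap-free codon sequences."""
    ca, cb = _split_codons(codon_a), _split_codons(codon_b)
    if len(ca) != len(cb):
        raise ValueError("sequences must be equal length")
    S = N = Sd = Nd = 0.0
    for x, y in zip(ca, cb):
        sx, nx = _codon_site_fractions(x)
        sy, ny = _codon_site_fractions(y)
        S += 0.5 * (sx + sy)
        N += 0.5 * (nx + ny)
        sd, nd = _pair_counts(x, y)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    try:
        dS = _jc_correct(pS)
        dN = _jc_correct(pN)
    except _Saturation:
        return NG86Result(math.nan, math.nan, math.nan, Nd, Sd, N, S, saturated=True)
    omega = dN / dS if dS > 0 else math.nan
    return NG86Result(dN, dS, omega, Nd, Sd, N, S)


# ---------------------------------------------------------------------------
# site-wise omega profile and contact enrichment


@dataclass
class SiteOmega:
    site: int
    Nd: float
    Sd: float
    N: float
    S: float
    omega: float  # nan when undefined (no differences at all)
    is_contact: bool = False


def contact_site_indices(protein: str) -> set[int]:
    """Residue indices of the -1/+2/+3/+6 contact positions of each finger."""
    out: set[int] = set()
    for m in _FINGER_RE.finditer(protein):
        x12_start = m.start() + 1 + len(m.group(1)) + 1
        for off in (5, 7, 8, 11):
            out.add(x12_start + off)
    return out


def site_omega_profile(
    alignment: Mapping[str, str], contact_sites: set[int] | None = None
) -> list[SiteOmega]:
    """Per-codon-site NG86 counts summed over all sequence pairs.

    omega at a site is (Nd/N)/(Sd/S); when the site's Sd is zero the dS
    denominator falls back to the alignment-wide mean Sd/S so that sites
    with nonsynonymous change but no synonymous change still get a (large)
    finite omega.  Sites with no differences at all have omega = nan.
    """
    names = sorted(alignment)
    if len(names) < 3:
        raise ValueError("need at least 3 sequences")
    rows = {n: _split_codons(alignment[n]) for n in names}
    n_sites = len(rows[names[0]])
    if any(len(rows[n]) != n_sites for n in names):
        raise ValueError("unequal alignment lengths")
    profile: list[SiteOmega] = []
    for j in range(n_sites):
        S = N = Sd = Nd = 0.0
        for a, b in itertools.combinations(names, 2):
            x, y = rows[a][j], rows[b][j]
            sx, nx = _codon_site_fractions(x)
            sy, ny = _codon_site_fractions(y)
            S += 0.5 * (sx + sy)
            N += 0.5 * (nx + ny)
            sd, nd = _pair_counts(x, y)
            Sd += sd
            Nd += nd
        profile.append(
            SiteOmega(
                site=j,
                Nd=Nd,
                Sd=Sd,
                N=N,
                S=S,
                omega=math.nan,
                is_contact=bool(contact_sites and j in contact_sites),
            )
        )
    _ds_vals = [p.Sd / p.S for p in profile if p.S > 0]
    mean_ds = float(np.mean(_ds_vals)) if _ds_vals else 0.0
    for p in profile:
        if p.Nd == 0 and p.Sd == 0:
            continue  # no information: omega stays nan (neutral flag)
        dn = p.Nd / p.N if p.N > 0 else 0.0
        ds = p.Sd / p.S if p.Sd > 0 and p.S > 0 else mean_ds
        p.omega = dn / ds if ds > 0 else math.inf
    return profile


def contact_enrichment(profile: Sequence[SiteOmega]) -> tuple[float, float]:
    """Fisher one-sided test: contact sites enriched for omega > 1."""
    defined = [p for p in profile if not math.isnan(p.omega)]
    if not defined:
        raise ValueError("no sites with defined omega")
    a = sum(1 for p in defined if p.is_contact and p.omega > 1)
    b = sum(1 for p in defined if p.is_contact and p.omega <= 1)
    c = sum(1 for p in defined if not p.is_contact and p.omega > 1)
    d = sum(1 for p in defined if not p.is_contact and p.omega <= 1)
    res = fisher_exact(ContingencyTable2x2(a, b, c, d), sided="greater")
    return res.statistic, res.p


# ---------------------------------------------------------------------------
# canonical-domain entropy profile


@dataclass(frozen=True)
class EntropyPosition:
    position: str  # canonical coordinate label
    entropy: float  # bits
    coverage: int


# canonical C2H2 coordinate system: C1, up to 4 spacer, C2, 12 helix/linker,
# H1, up to 5 spacer, H2; spacer residues left-aligned, padded to max span
_CANON = (
    ["C1"]
    + [f"s1.{i}" for i in range(4)]
    + ["C2"]
    + [f"x.{i}" for i in range(12)]
    + ["H1"]
    + [f"s2.{i}" for i in range(5)]
    + ["H2"]
)


def entropy_profile(domains: Sequence[str]) -> list[EntropyPosition]:
    """Shannon entropy (bits) per canonical C2H2 position over domains.

    Each domain must match the canonical pattern so the four anchors are
    unambiguous; anchor-ambiguous sequences are skipped.
    """
    columns: dict[str, list[str]] = {k: [] for k in _CANON}
    for dom in domains:
        m = _FINGER_RE.fullmatch(dom)
        if m is None:
            continue  # anchor-ambiguous domain, skipped
        s1, x12, s2 = m.group(1), m.group(2), m.group(3)
        columns["C1"].append("C")
        for i in range(4):
            if i < len(s1):
                columns[f"s1.{i}"].append(s1[i])
        columns["C2"].append("C")
        for i in range(12):
            columns[f"x.{i}"].append(x12[i])
        columns["H1"].append("H")
        for i in range(5):
            if i < len(s2):
                columns[f"s2.{i}"].append(s2[i])
        columns["H2"].append("H")
    out = []
    for key in _CANON:
        col = columns[key]
        if not col:
            out.append(EntropyPosition(key, math.nan, 0))
            continue
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        out.append(EntropyPosition(key, shannon_entropy(counts), len(col)))
    return out
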