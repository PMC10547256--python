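"""ZNF binding-motif prediction, exact-p scanning, and enrichment tests.

A fixed recognition-code table (package data) maps the four DNA-contacting
helix residues of each C2H2 finger to base preferences; fingers contribute
3-bp blocks concatenated 3'→5' (the C-terminal finger binds the 5'-most
triplet).  Motif occurrences are scored by log-odds against a background
model, with exact p-values from a dynamic-programming convolution of the
discretized per-column score distributions, BH q-values per motif–library
pair, and binomial enrichment tests against matched-background and
shuffled-motif nulls.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .stats import ContingencyTable2x2, binomial_tail_ge, bh_adjust, fisher_exact

__all__ = [
    "PositionWeightMatrix",
    "MotifMatch",
    "EnrichmentResult",
    "finger_quadruplets",
    "predict_pwm",
    "shuffle_pwm",
    "pwm_exact_pvalue",
    "scan_library",
    "matched_fraction",
    "sample_matched_background",
    "enrichment_test",
    "motif_similarity",
    "cross_species_comparison",
    "write_meme",
]

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
CONTACT_POSITIONS = (-1, 2, 3, 6)

_FINGER_RE = re.compile(r"C(.{2,4})C(.{12})H(.{3,5})H")


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position base probabilities, columns indexed A,C,G,T."""

    probs: np.ndarray  # (width, 4)
    motif_id: str = "pwm"
    source_orf: str = ""
    finger_count: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("columns must sum to 1")
        if (p <= 0).any():
            raise ValueError("zero entries not allowed (apply a pseudocount)")
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = _as_background(background)
        return np.log2(self.probs / bg)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            probs=self.probs[::-1, ::-1].copy(),
            motif_id=self.motif_id + "_rc",
            source_orf=self.source_orf,
            finger_count=self.finger_count,
        )


@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    seq_id: str
    position: int
    strand: str
    score: float
    p: float
    q: float


@dataclass(frozen=True)
class EnrichmentResult:
    motif_set_id: str
    library_id: str
    x: int
    n: int
    p0: float
    p_binomial: float
    comparison: str  # background | shuffled
    degenerate_baseline: bool = False


def _as_background(background: np.ndarray | Sequence[float] | None) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 frequencies summing to 1")
    return bg


@lru_cache(maxsize=1)
def recognition_code() -> dict:
    """(helix position, residue) -> base-preference 4-vector, from package data."""
    table: dict[tuple[int, str], np.ndarray] = {}
    text = (
        importlib.resources.files("zfte.data")
        .joinpath("recognition_code.tsv")
        .read_text()
    )
    for line in text.splitlines()[1:]:
        pos, res, a, c, g, t = line.split("\t")
        table[(int(pos), res)] = np.array([float(a), float(c), float(g), float(t)])
    return table


def finger_quadruplets(aa_seq: str) -> list[tuple[str, str, str, str]]:
    """Extract (-1, +2, +3, +6) helix residues of each C2H2 finger.

    The recognition helix occupies the last seven residues of the 12-mer
    between the second Cys and the first His.
    """
    quads = []
    for m in _FINGER_RE.finditer(aa_seq):
        x12 = m.group(2)
        quads.append((x12[5], x12[7], x12[8], x12[11]))
    return quads


def predict_pwm(
    quads: Sequence[Sequence[str]],
    motif_id: str = "pwm",
    source_orf: str = "",
) -> PositionWeightMatrix:
    """Recognition-code PWM from per-finger contact-residue quadruplets.

    Each finger yields a 3-bp block: 5' base from position +6, middle base
    from +3, 3' base from the elementwise product of -1 and +2 preferences.
    Blocks are concatenated in reverse finger order, so the C-terminal
    finger binds the 5'-most triplet.  Residues absent from the table fall
    back to the uniform 0.25 column.
    """
    if len(quads) < 1:
        raise ValueError("need at least one finger")
    code = recognition_code()
    uniform = np.full(4, 0.25)

    def lookup(pos: int, res: str) -> np.ndarray:
        if not (res.isalpha() and res.isupper() and res in "ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(f"nonstandard residue {res!r}")
        return code.get((pos, res), uniform)

    blocks = []
    for quad in quads:
        m1, p2, p3, p6 = (lookup(p, r) for p, r in zip(CONTACT_POSITIONS, quad))
        three_prime = m1 * p2
        three_prime = three_prime / three_prime.sum()
        blocks.append(np.vstack([p6, p3, three_prime]))
    mat = np.vstack(blocks[::-1])
    return PositionWeightMatrix(
        probs=mat, motif_id=motif_id, source_orf=source_orf, finger_count=len(quads)
    )


def shuffle_pwm(pwm: PositionWeightMatrix, seed: int = 0) -> PositionWeightMatrix:
    """Columns permuted uniformly at random; at least one column must move."""
    if pwm.width < 2:
        raise ValueError("cannot shuffle a width-1 motif")
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(pwm.width)
        if (perm != np.arange(pwm.width)).any():
            break
    return PositionWeightMatrix(
        probs=pwm.probs[perm],
        motif_id=pwm.motif_id + "_shuf",
        source_orf=pwm.source_orf,
        finger_count=pwm.finger_count,
    )


# ---------------------------------------------------------------------------
# exact p-values by DP convolution


def _discretized_distribution(
    pwm: PositionWeightMatrix,
    background: np.ndarray | None = None,
    granularity_steps: int = 1000,
):
    """Integer-binned distribution of log-odds scores of random bg words.

    The granularity step is 1/1000 of the motif's score range (configurable);
    columns are rounded at step/width so the summed rounding error stays
    within half a step.  Returns (bin_values, probabilities, col_step,
    int_cols) where int_cols are the per-column integer scores used both
    here and by the scanner, guaranteeing consistent p-value lookup.
    """
    bg = _as_background(background)
    lo = pwm.log_odds(bg)
    span = float(lo.max(axis=1).sum() - lo.min(axis=1).sum())
    step = span / granularity_steps if span > 0 else 1.0
    col_step = step / pwm.width
    cols = np.rint(lo / col_step).astype(np.int64)
    offset = int(cols.min(axis=1).sum())
    width_bins = int((cols.max(axis=1) - cols.min(axis=1)).sum()) + 1
    dist = np.zeros(width_bins)
    dist[0] = 1.0
    for w in range(pwm.width):
        col = cols[w] - cols[w].min()
        new = np.zeros(dist.size)
        for b in range(4):
            if bg[b] > 0:
                new[col[b] :] += (
                    bg[b] * dist[: dist.size - col[b]] if col[b] else bg[b] * dist
                )
        dist = new
    bins = offset + np.arange(width_bins)
    return bins, dist, col_step, cols


def pwm_exact_pvalue(
    pwm: PositionWeightMatrix,
    threshold: float,
    background: np.ndarray | None = None,
    granularity_steps: int = 1000,
) -> float:
    """P(log-odds score of a random background word >= threshold).

    Guaranteed within one granularity step of the exact tail: every word
    whose true score reaches the threshold is counted, and only words within
    one step below it can additionally slip in.
    """
    bins, dist, col_step, _ = _discretized_distribution(
        pwm, background, granularity_steps
    )
    # lower the integer threshold by the worst-case rounding drift (w/2
    # column steps) so no truly-passing word is excluded
    t_bin = math.ceil(threshold / col_step - pwm.width / 2.0 - 1e-9)
    return float(dist[bins >= t_bin].sum())


def _encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        out[arr == ord(b)] = i
    return out


def _window_int_scores(cols: np.ndarray, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer window scores (sum of per-column integer scores) and validity."""
    w = cols.shape[0]
    n = enc.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(w):
        window = enc[i : i + n]
        ok = window >= 0
        valid &= ok
        scores += np.where(ok, cols[i, np.clip(window, 0, 3)], 0)
    return scores, valid  # windows containing non-ACGT are invalid


def scan_library(
    pwm: PositionWeightMatrix,
    library: Iterable,
    alpha: float = 0.05,
    background: np.ndarray | None = None,
    granularity_steps: int = 1000,
) -> tuple[list[MotifMatch], set[str]]:
    """Scan both strands of every library sequence with exact p-values.

    Positions score the motif's log-odds; per-position p-values come from
    the DP score distribution; BH q-values are computed over all positions
    scanned for this motif–library pair.  A sequence is *matched* iff it has
    at least one position with q < alpha.  Sequences shorter than the motif
    are skipped.
    """
    bg = _as_background(background)
    bins, dist, col_step, cols = _discretized_distribution(pwm, bg, granularity_steps)
    sf = np.cumsum(dist[::-1])[::-1]  # survival over bins
    cols_rc = cols[::-1, ::-1]

    ids: list[str] = []
    positions: list[np.ndarray] = []
    strands: list[str] = []
    int_scores: list[np.ndarray] = []
    for rec in library:
        seq_id, seq = rec.seq_id, rec.seq
        if len(seq) < pwm.width:
            continue
        enc = _encode_seq(seq)
        for strand, mat in (("+", cols), ("-", cols_rc)):
            s, valid = _window_int_scores(mat, enc)
            pos = np.nonzero(valid)[0]
            if pos.size:
                ids.extend([seq_id] * pos.size)
                strands.extend([strand] * pos.size)
                positions.append(pos)
                int_scores.append(s[pos])
    if not int_scores:
        return [], set()
    all_pos = np.concatenate(positions)
    all_scores = np.concatenate(int_scores)
    idx = np.searchsorted(bins, all_scores, side="left")
    pvals = np.where(idx < sf.size, sf[np.clip(idx, 0, sf.size - 1)], 0.0)
    pvals = np.clip(pvals, 0.0, 1.0)
    qvals = bh_adjust(pvals)
    keep = np.nonzero(qvals < alpha)[0]
    matches = [
        MotifMatch(
            pwm.motif_id,
            ids[i],
            int(all_pos[i]),
            strands[i],
            float(all_scores[i] * col_step),
            float(pvals[i]),
            float(qvals[i]),
        )
        for i in keep
    ]
    matched_ids = {m.seq_id for m in matches}
    return matches, matched_ids


def matched_fraction(
    pwms: Sequence[PositionWeightMatrix],
    library: Sequence,
    alpha: float = 0.05,
    background: np.ndarray | None = None,
) -> tuple[int, int, dict[str, set[str]]]:
    """Sequences matched by >= 1 motif of a motif set (counted once per set)."""
    per_motif: dict[str, set[str]] = {}
    matched: set[str] = set()
    for pwm in pwms:
        _, ids = scan_library(pwm, library, alpha=alpha, background=background)
        per_motif[pwm.motif_id] = ids
        matched |= ids
    return len(matched), len(list(library)), per_motif


def sample_matched_background(
    genome: Mapping[str, str],
    repeat_mask: Mapping[str, Sequence[tuple[int, int]]],
    te_lib: Sequence,
    seed: int = 0,
    max_tries: int = 10_000,
):
    """Length-matched non-repetitive background intervals, without overlap.

    For each TE sequence one interval of identical length is drawn uniformly
    from the unmasked portion of the genome; sampled intervals may not
    overlap each other or the mask.
    """
    from .sim.telib import SeqRecordLite

    rng = np.random.default_rng(seed)
    contigs = sorted(genome)
    masked = {
        c: sorted(tuple(iv) for iv in repeat_mask.get(c, [])) for c in contigs
    }
    unmasked_total = sum(
        len(genome[c]) - sum(e - s for s, e in masked[c]) for c in contigs
    )
    need = sum(len(r.seq) for r in te_lib)
    if unmasked_total < need:
        raise ValueError(
            f"insufficient unmasked sequence: need {need} bp, have {unmasked_total}"
        )
    taken: dict[str, list[tuple[int, int]]] = {c: list(masked[c]) for c in contigs}

    def overlaps(c: str, s: int, e: int) -> bool:
        return any(s < e2 and s2 < e for s2, e2 in taken[c])

    out = []
    # longest first so large intervals are not squeezed out
    order = sorted(range(len(te_lib)), key=lambda i: -len(te_lib[i].seq))
    intervals: dict[int, tuple[str, int, int]] = {}
    for i in order:
        L = len(te_lib[i].seq)
        for _ in range(max_tries):
            c = contigs[int(rng.integers(0, len(contigs)))]
            if len(genome[c]) < L:
                continue
            s = int(rng.integers(0, len(genome[c]) - L + 1))
            if not overlaps(c, s, s + L):
                taken[c].append((s, s + L))
                intervals[i] = (c, s, s + L)
                break
        else:
            raise ValueError(f"could not place a {L} bp background interval")
    for i in range(len(te_lib)):
        c, s, e = intervals[i]
        out.append(SeqRecordLite(f"bg{i}", genome[c][s:e]))
    return out


def enrichment_test(
    x: int, n: int, p0: float, motif_set_id: str = "", library_id: str = "",
    comparison: str = "background",
) -> EnrichmentResult:
    """One-tailed binomial test for >= x matched sequences out of n at p0."""
    degenerate = p0 == 0.0 and x > 0
    p = 0.0 if degenerate else binomial_tail_ge(x, n, p0)
    return EnrichmentResult(
        motif_set_id=motif_set_id,
        library_id=library_id,
        x=x,
        n=n,
        p0=p0,
        p_binomial=p,
        comparison=comparison,
        degenerate_baseline=degenerate,
    )


def motif_similarity(
    pwm_a: PositionWeightMatrix,
    pwm_b: PositionWeightMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    min_overlap: int = 4,
) -> tuple[int, str, float]:
    """Best ungapped alignment of two motifs plus a permutation p-value.

    All offsets and both orientations of ``pwm_b`` are scored by the mean
    per-column Pearson correlation over the overlap; the null permutes
    ``pwm_b``'s columns.
    """
    if pwm_a.width < min_overlap or pwm_b.width < min_overlap:
        raise ValueError(f"both motifs must be at least {min_overlap} wide")

    def best(a: np.ndarray, b: np.ndarray):
        score, arg = -np.inf, (0, "+")
        for orient, bb in (("+", b), ("-", b[::-1, ::-1])):
            for off in range(-(bb.shape[0] - min_overlap), a.shape[0] - min_overlap + 1):
                sa = a[max(0, off) : min(a.shape[0], off + bb.shape[0])]
                sb = bb[max(0, -off) : max(0, -off) + sa.shape[0]]
                if sa.shape[0] < min_overlap:
                    continue
                cors = []
                for i in range(sa.shape[0]):
                    u, v = sa[i] - sa[i].mean(), sb[i] - sb[i].mean()
                    denom = np.sqrt((u @ u) * (v @ v))
                    cors.append(0.0 if denom == 0 else float(u @ v) / denom)
                s = float(np.mean(cors))
                if s > score:
                    score, arg = s, (off, orient)
        return score, arg

    obs, (offset, orient) = best(pwm_a.probs, pwm_b.probs)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pwm_b.width)
        s, _ = best(pwm_a.probs, pwm_b.probs[perm])
        if s >= obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return offset, orient, p


def cross_species_comparison(
    native_pairs: Mapping[str, set[str]],
    foreign_pairs: Mapping[str, set[str]],
    n_te: int,
):
    """Fisher test of native vs foreign motif–TE pair significance.

    The counting unit is the motif–TE pair: for each motif the set of TE
    sequences it matches.  One-sided alternative: native motifs hit more.
    """
    if not native_pairs or not foreign_pairs:
        raise ValueError("both motif sets must be nonempty")
    a = sum(len(v) for v in native_pairs.values())
    b = len(native_pairs) * n_te - a
    c = sum(len(v) for v in foreign_pairs.values())
    d = len(foreign_pairs) * n_te - c
    res = fisher_exact(ContingencyTable2x2(a, b, c, d), sided="greater")
    return res.statistic, res.p, res.flagged


def write_meme(pwms: Sequence[PositionWeightMatrix], path) -> None:
    """MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
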