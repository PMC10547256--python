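"""Developmental expression and knockdown-derepression statistics.

Custom effective lengths (median union-exon length for genes, summed
insertion length for TE families), TPM normalisation, expression-wave
classification against the zygotic-genome-activation stages, TE peak-timing
clustering, a minimal negative-binomial Wald test for knockdown vs control,
and the derepression summary statistics (Fisher, Wilcoxon young-vs-old,
per-category binomial, morpholino target counting, gene-age comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .stats import (
    ContingencyTable2x2,
    bh_adjust,
    binomial_tail_ge,
    fisher_exact,
    wilcoxon_rank_sum,
)

__all__ = [
    "effective_length",
    "union_exon_length",
    "compute_tpm",
    "classify_waves",
    "cluster_te_peaks",
    "nb_differential_expression",
    "call_de",
    "knockdown_summary",
    "mo_target_count",
    "gene_age_compare",
    "te_age_class",
]

FDR_THRESHOLD = 0.05
MIN_ABS_LFC = 0.32
MIN_TPM_EXPRESSED = 0.5
YOUNG_DIVERGENCE = 0.01  # substitutions per site; median insertion age below


# ---------------------------------------------------------------------------
# effective lengths and TPM


def union_exon_length(exons: Sequence[tuple[int, int]]) -> int:
    """Total length of the union of half-open exon intervals."""
    if not exons:
        raise ValueError("empty exon set")
    ivs = sorted(exons)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


def effective_length(feature: Mapping) -> float:
    """Effective length of a gene or TE family.

    Genes: median over transcripts of the union-of-exon length (even count:
    mean of the middle two).  TE families: sum of all insertion lengths.
    """
    if feature["kind"] == "gene":
        txs = feature["transcripts"]
        if not txs:
            raise ValueError("gene without transcripts")
        lengths = sorted(union_exon_length(t) for t in txs)
        n = len(lengths)
        mid = n // 2
        return float(lengths[mid]) if n % 2 else 0.5 * (lengths[mid - 1] + lengths[mid])
    if feature["kind"] == "te_family":
        ins = feature["insertions"]
        if not ins:
            raise ValueError("TE family without insertions")
        return float(sum(length for length, _div in ins))
    raise ValueError(f"unknown feature kind {feature['kind']!r}")


def compute_tpm(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Transcripts per million: rate_i = count_i/length_i, scaled to 1e6."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)  # all-zero column, flagged by caller
    return 1e6 * rates / total


# ---------------------------------------------------------------------------
# wave classification and peak-timing clustering


def classify_waves(
    tpm: pd.DataFrame,
    stages: Sequence[str],
    zga_minor_stage: str,
    zga_major_stage: str,
    min_tpm: float = MIN_TPM_EXPRESSED,
) -> pd.Series:
    """maternal / early / late / unexpressed labels from TPM trajectories.

    Unexpressed if the trajectory never reaches ``min_tpm``; maternal if
    expressed at the first (egg) stage; else early when the peak precedes
    the major ZGA wave, late otherwise.
    """
    for st in (zga_minor_stage, zga_major_stage):
        if st not in stages:
            raise ValueError(f"stage {st!r} missing from stage order")
    mat = tpm[list(stages)].to_numpy(dtype=float)
    major_idx = list(stages).index(zga_major_stage)
    labels = []
    for row in mat:
        if row.max() < min_tpm:
            labels.append("unexpressed")
        elif row[0] >= min_tpm:
            labels.append("maternal")
        elif int(row.argmax()) < major_idx:
            labels.append("early")
        else:
            labels.append("late")
    return pd.Series(labels, index=tpm.index, name="wave")


def cluster_te_peaks(
    tpm: pd.DataFrame, stages: Sequence[str], split_stage: str
) -> pd.Series:
    """before/after labels from average-linkage clustering of trajectories.

    Trajectories are z-scored and clustered (average linkage, Euclidean,
    cut at k=2); each cluster is labelled by whether its mean peak stage
    falls before the split stage.  Constant trajectories are assigned
    directly by argmax with a flag value suffix.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    if len(tpm) < 2:
        raise ValueError("need at least 2 TE families")
    split_idx = list(stages).index(split_stage)
    mat = tpm[list(stages)].to_numpy(dtype=float)
    sd = mat.std(axis=1)
    variable = sd > 0
    z = np.zeros_like(mat)
    z[variable] = (mat[variable] - mat[variable].mean(axis=1, keepdims=True)) / sd[
        variable
    ][:, None]
    labels = np.empty(len(tpm), dtype=object)
    if variable.sum() >= 2:
        Z = linkage(z[variable], method="average")
        cl = fcluster(Z, t=2, criterion="maxclust")
        peaks = mat[variable].argmax(axis=1)
        for c in np.unique(cl):
            mean_peak = peaks[cl == c].mean()
            lab = "before" if mean_peak < split_idx else "after"
            idxs = np.nonzero(variable)[0][cl == c]
            labels[idxs] = lab
    elif variable.sum() == 1:
        i = int(np.nonzero(variable)[0][0])
        labels[i] = "before" if mat[i].argmax() < split_idx else "after"
    for i in np.nonzero(~variable)[0]:
        labels[i] = "before" if mat[i].argmax() < split_idx else "after"
    return pd.Series(labels, index=tpm.index, name="peak_timing")


# ---------------------------------------------------------------------------
# negative-binomial differential expression


def _median_of_ratios(counts: pd.DataFrame) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(counts.to_numpy(dtype=float))
        ref = logs.mean(axis=1)  # log geometric mean
    usable = np.isfinite(ref)
    if not usable.any():
        return np.ones(counts.shape[1])
    factors = np.exp(np.median(logs[usable] - ref[usable, None], axis=0))
    return factors


def nb_differential_expression(
    treatment: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Minimal NB Wald test of treatment vs control counts.

    Library sizes are normalised by median-of-ratios across all samples;
    per-feature dispersions are moment estimates shrunk toward a
    mean–dispersion trend (alpha(mu) = a0 + a1/mu fit across features); the
    Wald statistic on the log2 fold change is referred to a standard normal;
    q-values are BH across features.
    Features with all-zero counts in both arms are excluded and reported in
    the ``excluded`` attribute.
    """
    if treatment.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need >= 2 replicates per arm")
    if not treatment.index.equals(control.index):
        raise ValueError("treatment/control features differ")
    both = pd.concat([treatment, control], axis=1)
    nonzero = both.sum(axis=1) > 0
    excluded = both.index[~nonzero].tolist()
    both = both.loc[nonzero]
    sf = _median_of_ratios(both)
    norm = both.to_numpy(dtype=float) / sf
    n1 = treatment.shape[1]
    t_arm, c_arm = norm[:, :n1], norm[:, n1:]

    mu_t = t_arm.mean(axis=1)
    mu_c = c_arm.mean(axis=1)
    # moment dispersion per feature from both arms pooled around arm means
    resid = np.concatenate(
        [t_arm - mu_t[:, None], c_arm - c_arm.mean(axis=1)[:, None]], axis=1
    )
    df_resid = t_arm.shape[1] + c_arm.shape[1] - 2
    var_pooled = (resid**2).sum(axis=1) / max(df_resid, 1)
    mu_pooled = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (var_pooled - mu_pooled) / mu_pooled**2
    alpha_raw = np.clip(alpha_raw, 1e-8, 10.0)
    # mean-dispersion trend alpha(mu) = a0 + a1/mu, fit by least squares on
    # informative features, then 50/50 shrinkage in log space
    ok = mu_pooled > 0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu_pooled[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_raw[ok], rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = np.clip(a0 + a1 / np.maximum(mu_pooled, 1e-8), 1e-8, 10.0)
    alpha = np.exp(0.5 * np.log(alpha_raw) + 0.5 * np.log(trend))

    pseud = 0.5
    lfc = np.log2((mu_t + pseud) / (mu_c + pseud))
    # delta-method variance of log2 mean ratio under NB(mu, alpha)
    var_t = (mu_t + alpha * mu_t**2) / t_arm.shape[1]
    var_c = (mu_c + alpha * mu_c**2) / c_arm.shape[1]
    ln2sq = math.log(2.0) ** 2
    se = np.sqrt(
        var_t / np.maximum(mu_t + pseud, pseud) ** 2 / ln2sq
        + var_c / np.maximum(mu_c + pseud, pseud) ** 2 / ln2sq
    )
    se = np.maximum(se, 1e-8)
    wald = lfc / se
    pvals = np.array(
        [math.erfc(abs(w) / math.sqrt(2.0)) for w in wald]
    )  # two-sided normal
    pvals = np.clip(pvals, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "base_mean": mu_pooled,
            "lfc": lfc,
            "se": se,
            "p": pvals,
            "q": bh_adjust(pvals),
        },
        index=both.index,
    )
    out.attrs["excluded"] = excluded
    return out


def call_de(
    results: pd.DataFrame,
    fdr: float = FDR_THRESHOLD,
    min_abs_lfc: float = MIN_ABS_LFC,
) -> pd.Series:
    """up / down / ns calls at the FDR and |log2FC| thresholds."""
    calls = np.where(
        (results["q"] < fdr) & (results["lfc"] >= min_abs_lfc),
        "up",
        np.where(
            (results["q"] < fdr) & (results["lfc"] <= -min_abs_lfc), "down", "ns"
        ),
    )
    return pd.Series(calls, index=results.index, name="de_call")


# ---------------------------------------------------------------------------
# knockdown summary statistics


def te_age_class(insertions: Sequence[tuple[int, float]]) -> str:
    """young iff the median per-insertion divergence is < 0.01 subs/site."""
    divs = sorted(d for _l, d in insertions)
    if not divs:
        raise ValueError("TE family without insertions")
    med = float(np.median(divs))
    return "young" if med < YOUNG_DIVERGENCE else "old"


def _fisher_row(a: int, b: int, c: int, d: int, sided: str = "greater"):
    if a + b + c + d == 0:
        return math.nan, math.nan, True
    res = fisher_exact(ContingencyTable2x2(a, b, c, d), sided=sided)
    return res.statistic, res.p, res.flagged


def knockdown_summary(
    results: pd.DataFrame,
    calls: pd.Series,
    annotation: Mapping,
    peak_timing: pd.Series | None = None,
) -> pd.DataFrame:
    """Derepression summary mirroring the knockdown figure panels.

    Rows (statistic, value, p, n, stratum): Fisher tests of up/down by
    feature kind (TE vs gene) overall and per TE class; one-sided Wilcoxon
    of log2 fold changes young vs old (overall and per class); per-category
    binomial tests of at-least-x up-regulated among DE features; Wilcoxon of
    lfc by expression peak before vs after the collection stage.  Empty
    strata yield NA rows rather than disappearing.
    """
    kind = pd.Series(
        {f: annotation["kind"][f] for f in results.index}, name="kind"
    )
    te_feats = [f for f in results.index if kind[f] == "te_family"]
    gene_feats = [f for f in results.index if kind[f] == "gene"]
    age = {
        f: te_age_class(annotation["insertions"][f]) for f in te_feats
    }
    te_class = {f: annotation["te_class"][f] for f in te_feats}
    rows = []

    def add(stat, value, p, n, stratum, flagged=False):
        rows.append(
            {
                "statistic": stat,
                "value": value,
                "p": p,
                "n": n,
                "stratum": stratum,
                "flagged": flagged,
            }
        )

    # (i) Fisher: kind x up/down among DE features
    te_up = sum(1 for f in te_feats if calls[f] == "up")
    te_dn = sum(1 for f in te_feats if calls[f] == "down")
    g_up = sum(1 for f in gene_feats if calls[f] == "up")
    g_dn = sum(1 for f in gene_feats if calls[f] == "down")
    if te_up + te_dn + g_up + g_dn == 0:
        add("fisher_te_vs_gene_or", math.nan, math.nan, 0, "all", True)
    else:
        orr, p, fl = _fisher_row(te_up, te_dn, g_up, g_dn)
        add("fisher_te_vs_gene_or", orr, p, te_up + te_dn + g_up + g_dn, "all", fl)

    # (ii) same per TE class (class TEs vs genes baseline)
    for cls in ("LTR", "LINE", "SINE", "DNA"):
        cf = [f for f in te_feats if te_class[f] == cls]
        cu = sum(1 for f in cf if calls[f] == "up")
        cd = sum(1 for f in cf if calls[f] == "down")
        if cu + cd + g_up + g_dn == 0:
            add("fisher_te_vs_gene_or", math.nan, math.nan, 0, cls, True)
        else:
            orr, p, fl = _fisher_row(cu, cd, g_up, g_dn)
            add("fisher_te_vs_gene_or", orr, p, cu + cd + g_up + g_dn, cls, fl)

    # (iii) Wilcoxon one-sided: lfc of young > old TE families
    young_lfc = [results.loc[f, "lfc"] for f in te_feats if age[f] == "young"]
    old_lfc = [results.loc[f, "lfc"] for f in te_feats if age[f] == "old"]
    if young_lfc and old_lfc:
        res = wilcoxon_rank_sum(young_lfc, old_lfc, sided="greater")
        add(
            "wilcoxon_young_gt_old_p",
            res.p,
            res.p,
            len(young_lfc) + len(old_lfc),
            "all",
            res.flagged,
        )
    else:
        add("wilcoxon_young_gt_old_p", math.nan, math.nan, 0, "all", True)
    for cls in ("LTR", "LINE", "SINE", "DNA"):
        yl = [results.loc[f, "lfc"] for f in te_feats if age[f] == "young" and te_class[f] == cls]
        ol = [results.loc[f, "lfc"] for f in te_feats if age[f] == "old" and te_class[f] == cls]
        if yl and ol:
            res = wilcoxon_rank_sum(yl, ol, sided="greater")
            add("wilcoxon_young_gt_old_p", res.p, res.p, len(yl) + len(ol), cls, res.flagged)
        else:
            add("wilcoxon_young_gt_old_p", math.nan, math.nan, 0, cls, True)

    # (iv) binomial: at least x up-regulated among DE, null 50%
    for name, feats in (
        ("te_family", te_feats),
        ("gene", gene_feats),
        ("te_young", [f for f in te_feats if age[f] == "young"]),
        ("te_old", [f for f in te_feats if age[f] == "old"]),
    ):
        de = [f for f in feats if calls[f] in ("up", "down")]
        x_up = sum(1 for f in de if calls[f] == "up")
        if de:
            add(
                "binomial_up_p",
                binomial_tail_ge(x_up, len(de), 0.5),
                binomial_tail_ge(x_up, len(de), 0.5),
                len(de),
                name,
            )
        else:
            add("binomial_up_p", math.nan, math.nan, 0, name, True)

    # (v) peak timing: lfc before vs after the collection stage
    if peak_timing is not None:
        before = [
            results.loc[f, "lfc"]
            for f in te_feats
            if f in peak_timing.index and peak_timing[f] == "before"
        ]
        after = [
            results.loc[f, "lfc"]
            for f in te_feats
            if f in peak_timing.index and peak_timing[f] == "after"
        ]
        if before and after:
            res = wilcoxon_rank_sum(before, after, sided="greater")
            add(
                "wilcoxon_before_gt_after_p",
                res.p,
                res.p,
                len(before) + len(after),
                "all",
                res.flagged,
            )
        else:
            add("wilcoxon_before_gt_after_p", math.nan, math.nan, 0, "all", True)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# morpholino targets and gene-age comparison


def mo_target_count(
    windows: Mapping[str, str], mo_seq: str
) -> tuple[int, dict[str, bool]]:
    """Count transcripts whose start window contains the MO's complement.

    A transcript is targeted iff the reverse complement of the morpholino
    occurs exactly (zero mismatches) in its sense-strand window around the
    annotated start codon.  Windows shorter than the MO are skipped with a
    None flag.
    """
    rc = str(Seq(mo_seq.upper()).reverse_complement())
    flags: dict[str, bool] = {}
    count = 0
    for tid in sorted(windows):
        win = windows[tid].upper()
        if len(win) < len(rc):
            flags[tid] = None  # window too short to assess
            continue
        hit = rc in win
        flags[tid] = hit
        count += hit
    return count, flags


def gene_age_compare(
    tree, wave_labels: Mapping[str, str]
) -> tuple[dict[str, float], float]:
    """Terminal-branch-length gene ages; one-sided Wilcoxon maternal older.

    Maternal genes are compared against all other expressed (zygotic) genes.
    """
    ages: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        ages[leaf.taxon.label] = float(leaf.edge.length or 0.0)
    missing = [g for g in wave_labels if g not in ages]
    if missing:
        raise ValueError(f"genes missing from tree: {sorted(missing)[:5]}")
    maternal = [ages[g] for g, w in wave_labels.items() if w == "maternal"]
    zygotic = [
        ages[g] for g, w in wave_labels.items() if w in ("early", "late")
    ]
    if not maternal or not zygotic:
        return ages, math.nan
    res = wilcoxon_rank_sum(maternal, zygotic, sided="greater")
    return ages, res.p
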