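"""Synthetic developmental expression and knockdown experiments.

Features are genes plus TE families.  Each feature follows a stage
trajectory template (maternal / early-peak / late-peak / flat) scaled to a
target expression level; counts are negative-binomial.  The knockdown arm
plants per-feature log2 fold changes that differ between young and old TE
families, and the generator also emits transcript exon structures, TE
insertion tables (length + divergence), and translation-start windows for
morpholino target counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = ["ExpressionSimConfig", "simulate_expression_experiment", "STAGES"]

STAGES = (
    "egg",
    "cleavage",
    "zga_minor",
    "zga_major",
    "shield",
    "gastrula",
    "somite",
    "24h",
)

_TE_CLASSES = ("LTR", "LINE", "SINE", "DNA")

# trajectory templates over the 8 stages (relative expression)
_TEMPLATES = {
    "maternal": np.array([1.0, 0.9, 0.6, 0.35, 0.2, 0.12, 0.08, 0.05]),
    "early": np.array([0.0, 0.02, 1.0, 0.12, 0.05, 0.02, 0.01, 0.01]),
    "late": np.array([0.0, 0.0, 0.02, 0.06, 0.25, 0.7, 1.0, 0.95]),
    "flat": np.array([0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3]),
}


@dataclass
class ExpressionSimConfig:
    seed: int = 0
    n_genes: int = 200
    n_te: int = 80
    n_reps: int = 3
    dispersion: float = 0.1
    young_te_lfc: float = 1.5
    old_te_lfc: float = 0.3
    gene_lfc: float = 0.0
    # the knockdown also perturbs many genes directly, in both directions
    # (the experiment this emulates saw ~1000 DE genes); a fraction of genes
    # get a strong symmetric effect so kind-by-direction tables are populated
    de_gene_fraction: float = 0.15
    de_gene_lfc: float = 1.2
    lfc_sd: float = 0.15
    young_fraction: float = 0.5
    mo_seq: str = "CTCTCCTCTTTAATAAACGCCATCT"
    mo_target_fraction: float = 0.4
    mean_log10_tpm: float = 1.2
    sd_log10_tpm: float = 0.6
    unexpressed_fraction: float = 0.1


@dataclass
class ExpressionTruth:
    template: dict = field(default_factory=dict)  # feature -> template name
    lfc: dict = field(default_factory=dict)  # feature -> planted log2 fc
    age_class: dict = field(default_factory=dict)  # TE feature -> young|old
    mo_targets: set = field(default_factory=set)
    expected_stage_mu: "pd.DataFrame | None" = None  # planted mean trajectories


def _nb_draws(rng, mu, dispersion, size=None):
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size if size is not None else mu.shape)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def simulate_expression_experiment(config: ExpressionSimConfig):
    """Return (stage_counts, kd_counts, annotation, truth).

    ``stage_counts``: DataFrame features x stages (one library per stage).
    ``kd_counts``: DataFrame features x replicate columns trt1.. / ctl1.. .
    ``annotation``: dict with per-feature kind, transcript exon structures,
    TE insertion tables, classes, and MO start windows.
    """
    if config.n_reps < 2:
        raise ValueError("need >= 2 replicates per arm")
    rng = np.random.default_rng(config.seed)
    features = [f"gene{i}" for i in range(config.n_genes)] + [
        f"te{i}" for i in range(config.n_te)
    ]
    truth = ExpressionTruth()
    annotation: dict = {"kind": {}, "transcripts": {}, "insertions": {}, "te_class": {},
                        "mo_window": {}}
    template_names = list(_TEMPLATES)
    base_level = 10 ** rng.normal(
        config.mean_log10_tpm, config.sd_log10_tpm, size=len(features)
    )

    n_young = int(round(config.young_fraction * config.n_te))
    te_ages = ["young"] * n_young + ["old"] * (config.n_te - n_young)

    stage_mu = np.zeros((len(features), len(STAGES)))
    planted_lfc = np.zeros(len(features))
    for idx, feat in enumerate(features):
        is_te = feat.startswith("te")
        annotation["kind"][feat] = "te_family" if is_te else "gene"
        if not is_te and rng.random() < config.unexpressed_fraction:
            tmpl = "unexpressed"
            traj = np.zeros(len(STAGES))
        else:
            tmpl = template_names[int(rng.integers(0, len(template_names)))]
            traj = _TEMPLATES[tmpl]
        truth.template[feat] = tmpl
        stage_mu[idx] = traj * base_level[idx] * 10  # counts scale
        if is_te:
            te_i = int(feat[2:])
            age = te_ages[te_i]
            truth.age_class[feat] = age
            annotation["te_class"][feat] = _TE_CLASSES[te_i % len(_TE_CLASSES)]
            center = config.young_te_lfc if age == "young" else config.old_te_lfc
            planted_lfc[idx] = rng.normal(center, config.lfc_sd)
            # insertion table: young families have low per-insertion divergence
            n_ins = int(rng.integers(4, 25))
            if age == "young":
                div = rng.uniform(0.000, 0.008, size=n_ins)
            else:
                div = rng.uniform(0.015, 0.25, size=n_ins)
            lens = rng.integers(200, 4000, size=n_ins)
            annotation["insertions"][feat] = list(
                zip(lens.tolist(), np.round(div, 5).tolist())
            )
        else:
            if rng.random() < config.de_gene_fraction:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                planted_lfc[idx] = rng.normal(
                    sign * config.de_gene_lfc, config.lfc_sd
                )
            else:
                planted_lfc[idx] = rng.normal(config.gene_lfc, config.lfc_sd / 3)
            # transcript structures: 1-3 transcripts of 2-6 exons
            txs = []
            for _ in range(int(rng.integers(1, 4))):
                n_ex = int(rng.integers(2, 7))
                start = 0
                exons = []
                for _ in range(n_ex):
                    start += int(rng.integers(50, 500))
                    length = int(rng.integers(80, 400))
                    exons.append((start, start + length))
                    start += length
                txs.append(exons)
            annotation["transcripts"][feat] = txs
            # -30..+25 window around the annotated start codon
            win = list(_random_dna(rng, 55))
            win[30:33] = list("ATG")
            if rng.random() < config.mo_target_fraction:
                rc = str(Seq(config.mo_seq).reverse_complement())
                # place the complement so it overlaps the start codon
                pos = 33 - len(rc) + int(rng.integers(3, 10))
                pos = max(0, min(pos, 55 - len(rc)))
                win[pos : pos + len(rc)] = list(rc)
                truth.mo_targets.add(feat)
            annotation["mo_window"][feat] = "".join(win)
        truth.lfc[feat] = float(planted_lfc[idx])

    # stage series: single library per stage
    truth.expected_stage_mu = pd.DataFrame(
        stage_mu, index=features, columns=list(STAGES)
    )
    stage_counts = pd.DataFrame(
        _nb_draws(rng, stage_mu, config.dispersion),
        index=features,
        columns=list(STAGES),
    )

    # knockdown at shield stage: control mu from the shield column
    shield_mu = np.maximum(stage_mu[:, STAGES.index("shield")], 0.0) + 1.0
    cols = {}
    for r in range(config.n_reps):
        cols[f"ctl{r + 1}"] = _nb_draws(rng, shield_mu, config.dispersion)
    trt_mu = shield_mu * 2.0**planted_lfc
    for r in range(config.n_reps):
        cols[f"trt{r + 1}"] = _nb_draws(rng, trt_mu, config.dispersion)
    kd_counts = pd.DataFrame(cols, index=features)
    return stage_counts, kd_counts, annotation, truth
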