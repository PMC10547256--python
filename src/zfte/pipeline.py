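"""End-to-end synthetic study orchestration.

One flat configuration drives every stage: generate synthetic inputs,
census the genomes, correlate copy numbers on the tree, run the motif
enrichment, the selection analysis, and the expression/knockdown
statistics.  Each stage writes plain-text outputs plus a manifest (input
hashes, parameters, seed, package version) and is deterministic for a fixed
configuration.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .census import build_census, census_one_assembly, extract_orfs
from .expression import (
    call_de,
    classify_waves,
    cluster_te_peaks,
    compute_tpm,
    effective_length,
    knockdown_summary,
    mo_target_count,
    nb_differential_expression,
)
from .motifs import (
    enrichment_test,
    finger_quadruplets,
    matched_fraction,
    predict_pwm,
    shuffle_pwm,
    write_meme,
)
from .phylo import correlate_traits
from .selection import (
    contact_enrichment,
    contact_site_indices,
    entropy_profile,
    site_omega_profile,
)
from .sim import (
    ExpressionSimConfig,
    GenomeSimConfig,
    TeLibraryConfig,
    simulate_codon_alignment,
    simulate_expression_experiment,
    simulate_genome,
    simulate_te_libraries,
    simulate_trait_tree,
)
from .sim.expression import STAGES
from .sim.genome import _random_quads, znf_protein

STAGE_NAMES = ("generate", "census", "correlate", "enrich", "select", "express")

# every tunable the stages consume, with the study's default thresholds
DEFAULT_CONFIG: dict = {
    "seed": 0,
    # generate
    "n_assemblies": 3,
    "contig_length": 50_000,
    "n_contigs": 2,
    "znf_finger_counts": [6, 5, 7],
    "n_taxa": 60,
    "trait_rho": 0.8,
    "brownian_sigma2": 1.0,
    "n_te_seqs": 60,
    "te_length_range": [300, 600],
    "motif_plant_fraction": 0.3,
    "selection_taxa": 10,
    "selection_fingers": 8,
    "omega_positive": 5.0,
    "omega_purifying": 0.2,
    "kappa": 2.0,
    "branch_scale": 0.3,
    "n_genes": 150,
    "n_te_families": 60,
    "n_replicates": 3,
    # thresholds (the study's values)
    "n50_min": 50_000,
    "min_znf_domains": 5,
    "min_orf_nt": 375,
    "max_orf_nt": 10_000,
    "scan_alpha": 0.05,
    "fdr": 0.05,
    "min_abs_lfc": 0.32,
    "min_tpm": 0.5,
    "young_divergence": 0.01,
    "mo_seq": "CTCTCCTCTTTAATAAACGCCATCT",
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    unknown = set(overrides) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(overrides)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, cfg: dict, inputs: list[Path],
                    outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg["seed"],
        "parameters": {k: v for k, v in sorted(cfg.items())},
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _write_fasta(path: Path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _read_fasta(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                out[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        out[name] = "".join(chunks)
    return out


# ---------------------------------------------------------------------------
# stages


def stage_generate(cfg: dict, outdir: Path) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    outputs: list[Path] = []

    # genomes + taxon table
    taxa_rows = []
    for a in range(int(cfg["n_assemblies"])):
        gcfg = GenomeSimConfig(
            seed=seed * 1000 + a,
            n_contigs=int(cfg["n_contigs"]),
            contig_length=int(cfg["contig_length"]),
            znf_finger_counts=tuple(cfg["znf_finger_counts"]),
        )
        contigs, truth = simulate_genome(gcfg)
        p = outdir / f"assembly{a}.fa"
        _write_fasta(p, sorted(contigs.items()))
        outputs.append(p)
        taxa_rows.append(
            {
                "assembly_id": f"assembly{a}",
                "species": f"species{a}",
                "family": f"family{a}",
                "phylum": "phylum0",
            }
        )
        tp = outdir / f"assembly{a}.truth.tsv"
        pd.DataFrame(
            [
                {
                    "orf_id": o.orf_id,
                    "contig_id": o.contig_id,
                    "start": o.start,
                    "end": o.end,
                    "strand": o.strand,
                    "kind": o.kind,
                    "n_domains": o.n_domains,
                }
                for o in truth.orfs
            ]
        ).to_csv(tp, sep="\t", index=False)
        outputs.append(tp)
    p = outdir / "taxa.tsv"
    pd.DataFrame(taxa_rows).to_csv(p, sep="\t", index=False)
    outputs.append(p)

    # trait tree
    tree, traits = simulate_trait_tree(
        int(cfg["n_taxa"]), float(cfg["trait_rho"]), float(cfg["brownian_sigma2"]),
        seed=seed + 1,
    )
    p = outdir / "trait_tree.nwk"
    p.write_text(tree.as_string(schema="newick"))
    outputs.append(p)
    p = outdir / "traits.tsv"
    pd.DataFrame(
        [
            {"species": s, "log_znf": x, "log_retro": y}
            for s, (x, y) in sorted(traits.items())
        ]
    ).to_csv(p, sep="\t", index=False)
    outputs.append(p)

    # TE + background libraries with a motif predictable from a ZNF
    rng = np.random.default_rng(seed + 2)
    quads = _random_quads(rng, 4)
    pwm = predict_pwm(quads, motif_id="planted")
    tcfg = TeLibraryConfig(
        seed=seed + 3,
        n_te=int(cfg["n_te_seqs"]),
        length_range=tuple(cfg["te_length_range"]),
        plant_fraction=float(cfg["motif_plant_fraction"]),
        motif=pwm.consensus(),
    )
    te, bg, te_truth = simulate_te_libraries(tcfg)
    _write_fasta(outdir / "te_lib.fa", [(r.seq_id, r.seq) for r in te])
    _write_fasta(outdir / "bg_lib.fa", [(r.seq_id, r.seq) for r in bg])
    outputs += [outdir / "te_lib.fa", outdir / "bg_lib.fa"]
    p = outdir / "planted_quads.json"
    p.write_text(json.dumps({"quads": [list(q) for q in quads]}))
    outputs.append(p)

    # codon alignment with positive selection at contact sites
    rng = np.random.default_rng(seed + 4)
    prot = znf_protein(rng, _random_quads(rng, int(cfg["selection_fingers"])))
    contact = contact_site_indices(prot)
    omegas = [
        float(cfg["omega_positive"]) if i in contact else float(cfg["omega_purifying"])
        for i in range(len(prot))
    ]
    sel_tree, _ = simulate_trait_tree(int(cfg["selection_taxa"]), 0.0, seed=seed + 5)
    for e in sel_tree.preorder_edge_iter():
        if e.length:
            e.length *= float(cfg["branch_scale"])
    aln, _ = simulate_codon_alignment(sel_tree, omegas, float(cfg["kappa"]), seed=seed + 6)
    _write_fasta(outdir / "codon_alignment.fa", sorted(aln.items()))
    outputs.append(outdir / "codon_alignment.fa")
    p = outdir / "selection_meta.json"
    p.write_text(
        json.dumps({"protein": prot, "contact_sites": sorted(contact)})
    )
    outputs.append(p)

    # expression experiment
    ecfg = ExpressionSimConfig(
        seed=seed + 7,
        n_genes=int(cfg["n_genes"]),
        n_te=int(cfg["n_te_families"]),
        n_reps=int(cfg["n_replicates"]),
        mo_seq=str(cfg["mo_seq"]),
    )
    stage_counts, kd_counts, ann, truth = simulate_expression_experiment(ecfg)
    stage_counts.to_csv(outdir / "stage_counts.tsv", sep="\t")
    kd_counts.to_csv(outdir / "kd_counts.tsv", sep="\t")
    outputs += [outdir / "stage_counts.tsv", outdir / "kd_counts.tsv"]
    ann_ser = {
        "kind": ann["kind"],
        "te_class": ann["te_class"],
        "mo_window": ann["mo_window"],
        "transcripts": {
            g: [[list(e) for e in tx] for tx in txs]
            for g, txs in ann["transcripts"].items()
        },
        "insertions": {t: [list(i) for i in ins] for t, ins in ann["insertions"].items()},
    }
    p = outdir / "annotation.json"
    p.write_text(json.dumps(ann_ser, sort_keys=True))
    outputs.append(p)
    _write_manifest(outdir, "generate", cfg, [], outputs)
    return outputs


def stage_census(cfg: dict, outdir: Path) -> list[Path]:
    taxa = pd.read_csv(outdir / "taxa.tsv", sep="\t")
    assemblies = {
        row.assembly_id: _read_fasta(outdir / f"{row.assembly_id}.fa")
        for row in taxa.itertuples()
    }
    taxon_table = {
        row.assembly_id: {
            "species": row.species,
            "family": row.family,
            "phylum": row.phylum,
        }
        for row in taxa.itertuples()
    }
    rows, qc_rho = build_census(assemblies, taxon_table, n50_min=int(cfg["n50_min"]))
    columns = [
        "assembly_id",
        "species",
        "family",
        "phylum",
        "scaffold_n50",
        "znf_orf_count",
        "retro_orf_count",
        "control_orf_count",
    ]
    df = pd.DataFrame(
        [
            {
                "assembly_id": r.assembly_id,
                "species": r.species,
                "family": r.family,
                "phylum": r.phylum,
                "scaffold_n50": r.scaffold_n50,
                "znf_orf_count": r.znf_orf_count,
                "retro_orf_count": r.retro_orf_count,
                "control_orf_count": r.control_orf_count,
            }
            for r in rows
        ],
        columns=columns,
    )
    p = outdir / "census.tsv"
    df.to_csv(p, sep="\t", index=False)
    (outdir / "census_qc.json").write_text(
        json.dumps({"qc_spearman_znf_vs_n50": qc_rho})
    )
    inputs = [outdir / "taxa.tsv"] + [
        outdir / f"{a}.fa" for a in sorted(assemblies)
    ]
    _write_manifest(outdir, "census", cfg, inputs, [p, outdir / "census_qc.json"])
    return [p]


def stage_correlate(cfg: dict, outdir: Path) -> list[Path]:
    import dendropy

    tree = dendropy.Tree.get(path=str(outdir / "trait_tree.nwk"), schema="newick")
    tr = pd.read_csv(outdir / "traits.tsv", sep="\t")
    x = dict(zip(tr.species, tr.log_znf))
    y = dict(zip(tr.species, tr.log_retro))
    rows = []
    raw, n_raw = correlate_traits(x, y, method="raw", log_transform=False)
    rows.append({"method": "raw", "rho": raw.statistic, "p": raw.p, "n": n_raw})
    pic, n_pic = correlate_traits(x, y, tree, method="pic", log_transform=False)
    rows.append({"method": "pic", "rho": pic.statistic, "p": pic.p, "n": n_pic})
    pic_s, _ = correlate_traits(
        x, y, tree, method="pic", positivize=False, log_transform=False
    )
    rows.append({"method": "pic_signed", "rho": pic_s.statistic, "p": pic_s.p, "n": n_pic})
    p = outdir / "correlations.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    _write_manifest(
        outdir, "correlate", cfg, [outdir / "trait_tree.nwk", outdir / "traits.tsv"], [p]
    )
    return [p]


def stage_enrich(cfg: dict, outdir: Path) -> list[Path]:
    from .sim.telib import SeqRecordLite

    te = [
        SeqRecordLite(k, v) for k, v in sorted(_read_fasta(outdir / "te_lib.fa").items())
    ]
    bg = [
        SeqRecordLite(k, v) for k, v in sorted(_read_fasta(outdir / "bg_lib.fa").items())
    ]
    quads = [
        tuple(q)
        for q in json.loads((outdir / "planted_quads.json").read_text())["quads"]
    ]
    pwm = predict_pwm(quads, motif_id="znf0")
    alpha = float(cfg["scan_alpha"])
    x_te, n_te, _ = matched_fraction([pwm], te, alpha=alpha)
    x_bg, n_bg, _ = matched_fraction([pwm], bg, alpha=alpha)
    p0_bg = max(x_bg / n_bg, 1.0 / (2 * n_bg))
    res_bg = enrichment_test(x_te, n_te, p0_bg, "znf0", "te_lib", "background")
    shuf = shuffle_pwm(pwm, seed=int(cfg["seed"]) + 8)
    x_sh, n_sh, _ = matched_fraction([shuf], te, alpha=alpha)
    p0_sh = max(x_sh / n_sh, 1.0 / (2 * n_sh))
    res_sh = enrichment_test(x_te, n_te, p0_sh, "znf0", "te_lib", "shuffled")
    rows = [
        {
            "motif_set": r.motif_set_id,
            "library": r.library_id,
            "x": r.x,
            "n": r.n,
            "p0": r.p0,
            "p_binomial": r.p_binomial,
            "comparison": r.comparison,
        }
        for r in (res_bg, res_sh)
    ]
    p = outdir / "enrichment.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    write_meme([pwm, shuf], outdir / "motifs.meme")
    inputs = [outdir / "te_lib.fa", outdir / "bg_lib.fa", outdir / "planted_quads.json"]
    _write_manifest(outdir, "enrich", cfg, inputs, [p, outdir / "motifs.meme"])
    return [p]


def stage_select(cfg: dict, outdir: Path) -> list[Path]:
    aln = _read_fasta(outdir / "codon_alignment.fa")
    meta = json.loads((outdir / "selection_meta.json").read_text())
    contact = set(meta["contact_sites"])
    profile = site_omega_profile(aln, contact_sites=contact)
    orr, pval = contact_enrichment(profile)
    df = pd.DataFrame(
        [
            {
                "site": s.site,
                "Nd": s.Nd,
                "Sd": s.Sd,
                "N": s.N,
                "S": s.S,
                "omega": s.omega,
                "is_contact": s.is_contact,
            }
            for s in profile
        ]
    )
    p1 = outdir / "site_omega.tsv"
    df.to_csv(p1, sep="\t", index=False)
    # entropy over the planted protein's fingers across taxa
    from Bio.Seq import Seq as _Seq

    doms = []
    for name in sorted(aln):
        prot = str(_Seq(aln[name]).translate())
        import re as _re

        for m in _re.finditer(r"C.{2,4}C.{12}H.{3,5}H", prot):
            doms.append(m.group(0))
    ent = entropy_profile(doms)
    p2 = outdir / "entropy_profile.tsv"
    pd.DataFrame(
        [
            {"position": e.position, "entropy": e.entropy, "coverage": e.coverage}
            for e in ent
        ]
    ).to_csv(p2, sep="\t", index=False)
    p3 = outdir / "selection_tests.json"
    p3.write_text(
        json.dumps({"contact_or": orr, "contact_p": pval}, sort_keys=True)
    )
    _write_manifest(
        outdir,
        "select",
        cfg,
        [outdir / "codon_alignment.fa", outdir / "selection_meta.json"],
        [p1, p2, p3],
    )
    return [p1, p2, p3]


def stage_express(cfg: dict, outdir: Path) -> list[Path]:
    stage_counts = pd.read_csv(outdir / "stage_counts.tsv", sep="\t", index_col=0)
    kd = pd.read_csv(outdir / "kd_counts.tsv", sep="\t", index_col=0)
    ann = json.loads((outdir / "annotation.json").read_text())
    ann["insertions"] = {
        k: [tuple(i) for i in v] for k, v in ann["insertions"].items()
    }
    lens = {}
    for f in stage_counts.index:
        if ann["kind"][f] == "gene":
            lens[f] = effective_length(
                {
                    "kind": "gene",
                    "transcripts": [
                        [tuple(e) for e in tx] for tx in ann["transcripts"][f]
                    ],
                }
            )
        else:
            lens[f] = effective_length(
                {"kind": "te_family", "insertions": ann["insertions"][f]}
            )
    L = np.array([lens[f] for f in stage_counts.index])
    tpm = pd.DataFrame(
        {s: compute_tpm(stage_counts[s].to_numpy(), L) for s in STAGES},
        index=stage_counts.index,
    )
    waves = classify_waves(
        tpm, STAGES, "zga_minor", "zga_major", min_tpm=float(cfg["min_tpm"])
    )
    te_feats = [f for f in stage_counts.index if ann["kind"][f] == "te_family"]
    peaks = cluster_te_peaks(tpm.loc[te_feats], STAGES, "shield")
    n_rep = int(cfg["n_replicates"])
    trt = kd[[f"trt{i+1}" for i in range(n_rep)]]
    ctl = kd[[f"ctl{i+1}" for i in range(n_rep)]]
    de = nb_differential_expression(trt, ctl)
    calls = call_de(de, fdr=float(cfg["fdr"]), min_abs_lfc=float(cfg["min_abs_lfc"]))
    summary = knockdown_summary(de, calls, ann, peak_timing=peaks)
    mo_n, _flags = mo_target_count(ann["mo_window"], str(cfg["mo_seq"]))
    outputs = []
    for name, obj in (
        ("tpm.tsv", tpm),
        ("waves.tsv", waves.to_frame()),
        ("peak_timing.tsv", peaks.to_frame()),
        ("de_results.tsv", de.join(calls)),
        ("kd_summary.tsv", summary),
    ):
        p = outdir / name
        obj.to_csv(p, sep="\t")
        outputs.append(p)
    p = outdir / "express_stats.json"
    n_expressed = int((tpm.max(axis=1) >= float(cfg["min_tpm"])).sum())
    p.write_text(
        json.dumps(
            {"mo_target_count": mo_n, "n_expressed": n_expressed},
            sort_keys=True,
        )
    )
    outputs.append(p)
    inputs = [outdir / "stage_counts.tsv", outdir / "kd_counts.tsv", outdir / "annotation.json"]
    _write_manifest(outdir, "express", cfg, inputs, outputs)
    return outputs


_STAGE_FUNCS = {
    "generate": stage_generate,
    "census": stage_census,
    "correlate": stage_correlate,
    "enrich": stage_enrich,
    "select": stage_select,
    "express": stage_express,
}


def run_stage(cfg: dict, stage: str, outdir: str | Path) -> list[Path]:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGE_NAMES}")
    return _STAGE_FUNCS[stage](cfg, Path(outdir))


def run_all(cfg: dict, outdir: str | Path) -> dict:
    """Run every stage in order and write one combined report."""
    outdir = Path(outdir)
    for stage in STAGE_NAMES:
        run_stage(cfg, stage, outdir)
    report: dict = {"seed": cfg["seed"], "package_version": __version__}
    census = pd.read_csv(outdir / "census.tsv", sep="\t")
    report["census"] = census.to_dict(orient="records")
    report["correlations"] = pd.read_csv(
        outdir / "correlations.tsv", sep="\t"
    ).to_dict(orient="records")
    report["enrichment"] = pd.read_csv(outdir / "enrichment.tsv", sep="\t").to_dict(
        orient="records"
    )
    report["selection"] = json.loads((outdir / "selection_tests.json").read_text())
    summary = pd.read_csv(outdir / "kd_summary.tsv", sep="\t", index_col=0)
    report["knockdown"] = summary.replace({np.nan: None}).to_dict(orient="records")
    report["expression"] = json.loads((outdir / "express_stats.json").read_text())
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
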