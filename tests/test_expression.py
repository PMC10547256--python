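"""Effective lengths, TPM, waves, NB differential expression, knockdown stats."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from zfte.expression import (
    call_de,
    classify_waves,
    cluster_te_peaks,
    compute_tpm,
    effective_length,
    gene_age_compare,
    knockdown_summary,
    mo_target_count,
    nb_differential_expression,
    te_age_class,
    union_exon_length,
)
from zfte.sim import ExpressionSimConfig, simulate_expression_experiment
from zfte.sim.expression import STAGES

MO = "CTCTCCTCTTTAATAAACGCCATCT"


def _tpm_table(stage_counts, ann):
    lens = {}
    for f in stage_counts.index:
        if ann["kind"][f] == "gene":
            lens[f] = effective_length(
                {"kind": "gene", "transcripts": ann["transcripts"][f]}
            )
        else:
            lens[f] = effective_length(
                {"kind": "te_family", "insertions": ann["insertions"][f]}
            )
    L = np.array([lens[f] for f in stage_counts.index])
    return pd.DataFrame(
        {s: compute_tpm(stage_counts[s].to_numpy(), L) for s in STAGES},
        index=stage_counts.index,
    )


class TestEffectiveLength:
    def test_union_overlapping_exons(self):
        assert union_exon_length([(0, 100), (50, 150)]) == 150

    def test_gene_median_rule(self):
        gene = {
            "kind": "gene",
            "transcripts": [[(0, 300)], [(0, 500)], [(0, 700)]],
        }
        assert effective_length(gene) == 500
        gene["transcripts"].append([(0, 900)])
        assert effective_length(gene) == 600.0  # even count: mean of middle two

    def test_te_sum_rule(self):
        te = {"kind": "te_family", "insertions": [(1000, 0.1), (2500, 0.02)]}
        assert effective_length(te) == 3500

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            effective_length({"kind": "gene", "transcripts": []})


class TestTpm:
    def test_direct_formula(self):
        tpm = compute_tpm([10, 10], [1000, 500])
        assert tpm == pytest.approx([1e6 / 3, 2e6 / 3])

    def test_single_feature_and_normalisation(self):
        assert compute_tpm([7], [123])[0] == pytest.approx(1e6)
        rng = np.random.default_rng(0)
        tpm = compute_tpm(rng.integers(0, 100, 50), rng.integers(100, 999, 50))
        assert tpm.sum() == pytest.approx(1e6)

    def test_all_zero_column(self):
        assert (compute_tpm([0, 0], [100, 100]) == 0).all()


class TestWaves:
    def test_rule_on_noiseless_trajectories_exact(self):
        for seed in range(3):
            cfg = ExpressionSimConfig(seed=seed)
            stage, _, ann, truth = simulate_expression_experiment(cfg)
            mu = truth.expected_stage_mu
            lens = np.ones(len(mu))
            tpm = pd.DataFrame(
                {s: compute_tpm(mu[s].to_numpy(), lens) for s in STAGES},
                index=mu.index,
            )
            waves = classify_waves(tpm, STAGES, "zga_minor", "zga_major")
            for f in mu.index:
                t = truth.template[f]
                if t in ("early", "late") and tpm.loc[f].max() >= 0.5:
                    assert waves[f] == t, (f, t)

    def test_noisy_counts_agreement_rate(self):
        tot = agree = 0
        for seed in range(3):
            cfg = ExpressionSimConfig(seed=seed)
            stage, _, ann, truth = simulate_expression_experiment(cfg)
            tpm = _tpm_table(stage, ann)
            waves = classify_waves(tpm, STAGES, "zga_minor", "zga_major")
            for f in stage.index:
                t = truth.template[f]
                if t in ("early", "late") and tpm.loc[f].max() >= 2.0:
                    tot += 1
                    agree += waves[f] == t
        assert agree / tot >= 0.95

    def test_all_zero_unexpressed_and_maternal(self):
        tpm = pd.DataFrame(
            [[0.0] * 8, [5.0, 4, 3, 2, 1, 1, 1, 1]],
            index=["dead", "mat"],
            columns=list(STAGES),
        )
        waves = classify_waves(tpm, STAGES, "zga_minor", "zga_major")
        assert waves["dead"] == "unexpressed" and waves["mat"] == "maternal"

    def test_missing_stage_rejected(self):
        tpm = pd.DataFrame([[1.0] * 8], columns=list(STAGES))
        with pytest.raises(ValueError):
            classify_waves(tpm, STAGES, "zga_minor", "nosuch")


class TestPeakClustering:
    def test_separated_templates_recovered(self):
        cfg = ExpressionSimConfig(seed=4)
        stage, _, ann, truth = simulate_expression_experiment(cfg)
        tpm = _tpm_table(stage, ann)
        te = [f for f in stage.index if f.startswith("te")]
        labels = cluster_te_peaks(tpm.loc[te], STAGES, "shield")
        shield_idx = list(STAGES).index("shield")
        for f in te:
            t = truth.template[f]
            mu = truth.expected_stage_mu.loc[f]
            if t in ("early", "maternal") and mu.max() >= 20:
                assert labels[f] == "before", f
            if t == "late" and mu.max() >= 20:
                assert labels[f] == "after", f

    def test_feature_order_invariance(self):
        cfg = ExpressionSimConfig(seed=5)
        stage, _, ann, _ = simulate_expression_experiment(cfg)
        tpm = _tpm_table(stage, ann)
        te = [f for f in stage.index if f.startswith("te")]
        l1 = cluster_te_peaks(tpm.loc[te], STAGES, "shield")
        l2 = cluster_te_peaks(tpm.loc[te[::-1]], STAGES, "shield")
        assert all(l1[f] == l2[f] for f in te)

    def test_constant_trajectories_flag_path(self):
        tpm = pd.DataFrame(
            [[1.0] * 8, [1.0] * 8], index=["a", "b"], columns=list(STAGES)
        )
        labels = cluster_te_peaks(tpm, STAGES, "shield")
        assert set(labels) <= {"before", "after"}


class TestDifferentialExpression:
    def _arms(self, kd, n=3):
        return kd[[f"trt{i+1}" for i in range(n)]], kd[[f"ctl{i+1}" for i in range(n)]]

    def test_identical_arms_mostly_ns(self):
        cfg = ExpressionSimConfig(seed=0, n_genes=800, n_te=200, young_te_lfc=0,
                                  old_te_lfc=0, de_gene_fraction=0, lfc_sd=0)
        _, kd, _, _ = simulate_expression_experiment(cfg)
        res = nb_differential_expression(*self._arms(kd))
        assert (call_de(res) != "ns").mean() <= 0.05

    def test_planted_effect_power(self):
        detected = total = 0
        for seed in range(3):
            cfg = ExpressionSimConfig(seed=seed, young_te_lfc=2.0, old_te_lfc=2.0,
                                      lfc_sd=0.0, de_gene_fraction=0.0)
            _, kd, ann, truth = simulate_expression_experiment(cfg)
            res = nb_differential_expression(*self._arms(kd))
            calls = call_de(res)
            for f in res.index:
                if f.startswith("te") and res.loc[f, "base_mean"] >= 50:
                    total += 1
                    detected += calls[f] == "up"
        assert detected / total >= 0.9

    def test_library_size_invariance(self):
        cfg = ExpressionSimConfig(seed=2)
        _, kd, _, _ = simulate_expression_experiment(cfg)
        trt, ctl = self._arms(kd)
        res1 = nb_differential_expression(trt, ctl)
        trt2 = trt.copy()
        trt2["trt1"] = trt2["trt1"] * 2  # doubled sequencing depth
        res2 = nb_differential_expression(trt2, ctl)
        common = res1.index.intersection(res2.index)
        big = res1.loc[common, "base_mean"] >= 20
        diffs = (res1.loc[common, "lfc"] - res2.loc[common, "lfc"])[big].abs()
        assert diffs.median() < 0.05

    def test_all_zero_features_excluded(self):
        trt = pd.DataFrame({"trt1": [0, 5], "trt2": [0, 7]}, index=["z", "g"])
        ctl = pd.DataFrame({"ctl1": [0, 6], "ctl2": [0, 4]}, index=["z", "g"])
        res = nb_differential_expression(trt, ctl)
        assert res.attrs["excluded"] == ["z"] and list(res.index) == ["g"]

    def test_call_thresholds(self):
        res = pd.DataFrame(
            {"lfc": [0.30, 0.5, 3.0, -0.5], "q": [0.01, 0.01, 0.2, 0.001]},
            index=list("abcd"),
        )
        calls = call_de(res)
        assert list(calls) == ["ns", "up", "ns", "down"]


class TestKnockdownSummary:
    def test_planted_experiment_recovered(self):
        cfg = ExpressionSimConfig(seed=0)
        _, kd, ann, _ = simulate_expression_experiment(cfg)
        trt = kd[["trt1", "trt2", "trt3"]]
        ctl = kd[["ctl1", "ctl2", "ctl3"]]
        res = nb_differential_expression(trt, ctl)
        summ = knockdown_summary(res, call_de(res), ann)
        fish = summ[(summ.statistic == "fisher_te_vs_gene_or") & (summ.stratum == "all")].iloc[0]
        wil = summ[(summ.statistic == "wilcoxon_young_gt_old_p") & (summ.stratum == "all")].iloc[0]
        assert fish.value > 1 and fish.p < 0.05
        assert wil.p < 0.05

    def test_binomial_hand_value(self):
        from zfte.stats import binomial_tail_ge

        assert binomial_tail_ge(5, 5, 0.5) == pytest.approx(0.03125)

    def test_all_ns_gives_na_rows(self):
        cfg = ExpressionSimConfig(seed=1, n_genes=30, n_te=10, young_te_lfc=0,
                                  old_te_lfc=0, de_gene_fraction=0, lfc_sd=0)
        _, kd, ann, _ = simulate_expression_experiment(cfg)
        res = nb_differential_expression(kd[["trt1", "trt2", "trt3"]],
                                         kd[["ctl1", "ctl2", "ctl3"]])
        calls = pd.Series("ns", index=res.index)
        summ = knockdown_summary(res, calls, ann)
        fish = summ[(summ.statistic == "fisher_te_vs_gene_or") & (summ.stratum == "all")].iloc[0]
        assert fish.flagged or math.isnan(fish.value)
        # strata present even when empty
        assert set(summ.stratum) >= {"all", "LTR", "LINE", "SINE", "DNA"}

    def test_age_class_median_rule(self):
        assert te_age_class([(100, 0.001), (100, 0.005), (100, 0.3)]) == "young"
        assert te_age_class([(100, 0.01)]) == "old"  # tie goes to old


class TestMoTargets:
    def test_printed_sequence_reverse_complement(self):
        window = "GG" + "AGATGGCGTTTATTAAAGAGGAGAG" + "CCCCCCCCCCCCCCCCCCCCCCCCCCCC"
        count, flags = mo_target_count({"tx1": window}, MO)
        assert count == 1 and flags["tx1"]

    def test_single_mismatch_not_targeted(self):
        rc = "AGATGGCGTTTATTAAAGAGGAGAG"
        bad = rc[:10] + "C" + rc[11:]
        assert bad != rc
        window = "GG" + bad + "C" * 28
        count, _ = mo_target_count({"tx1": window}, MO)
        assert count == 0

    def test_case_and_order_invariance(self):
        cfg = ExpressionSimConfig(seed=3)
        _, _, ann, truth = simulate_expression_experiment(cfg)
        wins = ann["mo_window"]
        c1, f1 = mo_target_count(wins, MO)
        c2, f2 = mo_target_count(
            {k: v.lower() for k, v in reversed(list(wins.items()))}, MO.lower()
        )
        assert c1 == c2 == len(truth.mo_targets)
        assert f1 == f2

    def test_short_window_flagged_none(self):
        count, flags = mo_target_count({"tx1": "ACGT"}, MO)
        assert count == 0 and flags["tx1"] is None

    def test_empty_set(self):
        assert mo_target_count({}, MO) == (0, {})


class TestGeneAge:
    def test_planted_older_maternal_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 30
            labels = {}
            parts = []
            for i in range(n):
                maternal = i < 10
                bl = rng.uniform(2.0, 4.0) if maternal else rng.uniform(0.1, 0.9)
                labels[f"g{i}"] = "maternal" if maternal else "late"
                parts.append(f"g{i}:{bl:.4f}")
            tree = dendropy.Tree.get(
                data="(" + ",".join(parts) + ");", schema="newick"
            )
            ages, p = gene_age_compare(tree, labels)
            hits += p < 0.05
        assert hits >= 9

    def test_single_maternal_gene_defined(self):
        tree = dendropy.Tree.get(data="(g0:5.0,g1:1.0,g2:1.0);", schema="newick")
        ages, p = gene_age_compare(
            tree, {"g0": "maternal", "g1": "late", "g2": "early"}
        )
        assert 0 <= p <= 1

    def test_missing_gene_rejected(self):
        tree = dendropy.Tree.get(data="(g0:1,g1:1,g2:1);", schema="newick")
        with pytest.raises(ValueError):
            gene_age_compare(tree, {"nope": "maternal"})
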