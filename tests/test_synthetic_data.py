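"""Synthetic-data generator: determinism, null fidelity and planted-effect
recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mzarch.annotation_io import write_gff3
from mzarch.gene_classes import ALL_MATERNAL_MEMBERS
from mzarch.ks_stats import StatConfig, ks_one_sided, percentile_sweep
from mzarch.ortholog_rank import (
    compare_maternal_vs_all,
    percentile_ranks,
    rank_fold_changes,
)
from mzarch.region_metrics import compute_region_table, metric_values
from mzarch.synthetic_data import (
    ClassEffect,
    SimConfig,
    simulate_expression,
    simulate_genome,
    simulate_orthologs,
    simulate_phylo_profiles,
    simulate_rnai,
)


def maternal_ids(labels):
    return set(
        labels.loc[
            labels["origin_class"].isin(ALL_MATERNAL_MEMBERS), "gene_id"
        ]
    )


class TestDeterminism:
    def test_genome_is_byte_identical_across_runs(self, tmp_path):
        config = SimConfig(seed=61, n_genes=120, operon_fraction=0.1)
        paths = []
        for run in (1, 2):
            ann, operons, labels = simulate_genome(config)
            path = tmp_path / f"run{run}.gff3"
            write_gff3(ann, str(path))
            paths.append(path)
            if run == 2:
                expr = simulate_expression(labels, config)
                prof, _ = simulate_phylo_profiles(labels, config)
                expr2 = simulate_expression(labels, config)
                prof2, _ = simulate_phylo_profiles(labels, config)
                pd.testing.assert_frame_equal(expr, expr2)
                pd.testing.assert_frame_equal(prof, prof2)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self):
        a, _, _ = simulate_genome(SimConfig(seed=1, n_genes=40))
        b, _, _ = simulate_genome(SimConfig(seed=2, n_genes=40))
        assert a != b


class TestConfigValidation:
    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(frac_core=0.8, frac_metazoan=0.5)
        with pytest.raises(ValueError):
            SimConfig(origin_fracs={"strict_maternal": 0.5})

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=1)


class TestExpression:
    def test_strict_zygotic_pre_mzt_below_presence(self):
        config = SimConfig(seed=62, n_genes=300, expression_noise_sd=0.0)
        _, _, labels = simulate_genome(config)
        expr = simulate_expression(labels, config)
        zyg = labels.loc[
            labels["origin_class"] == "strict_zygotic", "gene_id"
        ]
        pre = expr.loc[zyg, [f"t{i}" for i in range(config.n_timepoints_pre)]]
        assert (pre.to_numpy() < config.presence_call).all()

    def test_maternal_decay_at_least_threefold(self):
        config = SimConfig(seed=63, n_genes=300, expression_noise_sd=0.2)
        _, _, labels = simulate_genome(config)
        expr = simulate_expression(labels, config)
        strict = labels.loc[
            labels["origin_class"] == "strict_maternal", "gene_id"
        ]
        fold = expr.loc[strict, "t0"] / expr.loc[strict, "t2"]
        assert (fold >= 3.0).mean() > 0.99


class TestNullFidelity:
    def test_no_planted_effects_means_no_maternal_signal(self):
        """With empty class_effects, the rejection rate of the plain
        maternal-vs-others test stays at its nominal level."""
        rejections = 0
        n_reps = 120
        for rep in range(n_reps):
            config = SimConfig(seed=10_000 + rep, n_genes=150)
            ann, _, labels = simulate_genome(config)
            table = compute_region_table(ann)
            mat = maternal_ids(labels)
            a = metric_values(table, "utr3", mat)
            b = metric_values(
                table, "utr3", set(table["gene_id"]) - mat
            )
            if ks_one_sided(a, b).p < 0.05:
                rejections += 1
        assert rejections / n_reps <= 0.07

    def test_null_class_igr5_distributions_indistinguishable(self):
        config = SimConfig(seed=64, n_genes=800)
        ann, _, labels = simulate_genome(config)
        table = compute_region_table(ann)
        mat = maternal_ids(labels)
        a = metric_values(table, "igr5", mat)
        b = metric_values(table, "igr5", set(table["gene_id"]) - mat)
        assert ks_one_sided(a, b).p > 0.001


class TestPlantedEffects:
    def test_utr3_truncation_detected_by_sweep(self):
        """A maternal 3' UTR redraw above the 20th percentile is flagged by
        the percentile sweep with its minimum p at a low percentile."""
        effects = {
            cls: ClassEffect(utr3_left_truncation_percentile=20.0)
            for cls in ("strict_maternal", "mostly_maternal",
                        "maternal_zygotic")
        }
        config = SimConfig(seed=65, n_genes=2000, class_effects=effects)
        ann, _, labels = simulate_genome(config)
        table = compute_region_table(ann)
        mat = maternal_ids(labels)
        a = metric_values(table, "utr3", mat)
        b = metric_values(table, "utr3", set(table["gene_id"]) - mat)
        res = percentile_sweep(a, b)
        assert res.p_min < 1e-6
        assert res.q_at_p_min <= 30
        assert res.q_top_significant == 100.0

    def test_zygotic_igr5_scale_detected(self):
        effects = {"strict_zygotic": ClassEffect(igr5_scale=2.5)}
        config = SimConfig(seed=66, n_genes=1500, class_effects=effects)
        ann, _, labels = simulate_genome(config)
        table = compute_region_table(ann)
        zyg = set(
            labels.loc[
                labels["origin_class"] == "strict_zygotic", "gene_id"
            ]
        )
        a = metric_values(table, "igr5", zyg)
        b = metric_values(table, "igr5", set(table["gene_id"]) - zyg)
        assert ks_one_sided(a, b).p < 1e-4


class TestOperons:
    def test_operon_fraction_and_positions(self):
        config = SimConfig(seed=67, n_genes=400, operon_fraction=0.2)
        ann, operons, _ = simulate_genome(config)
        assert 0.05 < len(operons) / len(ann) < 0.4
        for _, group in operons.groupby("operon_id"):
            assert sorted(group["position"]) == list(
                range(1, len(group) + 1)
            )
            for gid in group["gene_id"]:
                assert ann[gid].strand == "+"


class TestOrthologs:
    def test_zero_noise_rank_preserving_gives_exact_zeros(self):
        config = SimConfig(seed=68, n_genes=300)
        ann, _, labels = simulate_genome(config)
        table = compute_region_table(ann)
        igr5 = table.set_index("gene_id")["igr5"]
        sim = simulate_orthologs(igr5, maternal_ids(labels), config)
        for sp in sim.pairs:
            fcs = rank_fold_changes(
                sim.pairs[sp],
                percentile_ranks(igr5),
                percentile_ranks(sim.lengths[sp]),
            )
            assert np.all(fcs["log2_fc"].to_numpy() == 0.0)

    def test_planted_shift_pattern(self):
        """The shifted pair is significant, the unshifted pair is null."""
        config = SimConfig(
            seed=69,
            n_genes=600,
            ortholog_rank_noise=0.06,
            ortholog_maternal_shift=0.3,
            ortholog_shifted_species="b",
        )
        ann, _, labels = simulate_genome(config)
        igr5 = compute_region_table(ann).set_index("gene_id")["igr5"]
        sim = simulate_orthologs(igr5, maternal_ids(labels), config)
        results = {}
        for sp in ("b", "c"):
            fcs = rank_fold_changes(
                sim.pairs[sp],
                percentile_ranks(igr5),
                percentile_ranks(sim.lengths[sp]),
            )
            results[sp] = compare_maternal_vs_all(
                fcs, sim.maternal_both[sp] & set(fcs["gene_a"])
            )
        assert results["b"].p < 0.01
        assert results["c"].p > 0.01

    def test_zero_overlap_errors_cleanly_downstream(self):
        config = SimConfig(seed=70, n_genes=100, maternal_overlap=0.0)
        ann, _, labels = simulate_genome(config)
        igr5 = compute_region_table(ann).set_index("gene_id")["igr5"]
        sim = simulate_orthologs(igr5, maternal_ids(labels), config)
        fcs = rank_fold_changes(
            sim.pairs["b"],
            percentile_ranks(igr5),
            percentile_ranks(sim.lengths["b"]),
        )
        assert sim.maternal_both["b"] == set()
        with pytest.raises(ValueError, match="empty"):
            compare_maternal_vs_all(fcs, sim.maternal_both["b"])


class TestRnai:
    def test_null_effect_independent_of_igr5(self):
        config = SimConfig(seed=71, n_genes=800, rnai_effect=0.0)
        ann, _, labels = simulate_genome(config)
        table = compute_region_table(ann)
        calls = simulate_rnai(labels, table, config)
        merged = table.set_index("gene_id").join(calls.rename("phen"))
        merged = merged[merged["phen"].notna()]
        a = merged.loc[merged["phen"] == "observed", "igr5"].dropna()
        b = merged.loc[merged["phen"] == "none", "igr5"].dropna()
        assert ks_one_sided(a, b).p > 0.001

    def test_positive_effect_links_phenotype_to_long_igr5(self):
        config = SimConfig(seed=72, n_genes=800, rnai_effect=3.0)
        ann, _, labels = simulate_genome(config)
        table = compute_region_table(ann)
        calls = simulate_rnai(labels, table, config)
        merged = table.set_index("gene_id").join(calls.rename("phen"))
        merged = merged[merged["phen"].notna()]
        a = merged.loc[merged["phen"] == "observed", "igr5"].dropna()
        b = merged.loc[merged["phen"] == "none", "igr5"].dropna()
        assert a.median() > b.median()
        assert ks_one_sided(a, b).p < 1e-3
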