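"""Region-length metrics: worked examples, brute-force oracle agreement,
and distribution-level robustness properties."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mzarch.models import GeneModel, GenomeAnnotation, TranscriptModel
from mzarch.region_metrics import (
    compute_region_table,
    first_intron_lengths,
    five_prime_igr,
    three_prime_igr,
    utr_lengths,
)
from mzarch.synthetic_data import SimConfig, simulate_genome

from tests._brute import check_genome_against_oracle


def simple_gene(gene_id, chrom, strand, exons, cds_start, cds_end):
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, transcripts=(tx,)
    )


class TestFivePrimeIgr:
    def test_upstream_coding_gap_of_100(self):
        # gene B (+) CDS starts at 300; gene A's coding ends at 200
        a = simple_gene("A", "c", "+", [(100, 200)], 100, 200)
        b = simple_gene("B", "c", "+", [(300, 500)], 300, 500)
        ann = GenomeAnnotation([a, b])
        assert five_prime_igr(b, ann) == 100

    def test_overlapping_cds_gives_zero(self):
        a = simple_gene("A", "c", "+", [(100, 320)], 100, 320)
        b = simple_gene("B", "c", "+", [(300, 500)], 300, 500)
        ann = GenomeAnnotation([a, b])
        assert five_prime_igr(b, ann) == 0

    def test_abutting_cds_gives_zero(self):
        a = simple_gene("A", "c", "+", [(100, 300)], 100, 300)
        b = simple_gene("B", "c", "+", [(300, 500)], 300, 500)
        ann = GenomeAnnotation([a, b])
        assert five_prime_igr(b, ann) == 0

    def test_only_gene_on_chromosome_censored(self):
        a = simple_gene("A", "c", "+", [(100, 200)], 100, 200)
        b = simple_gene("B", "c2", "+", [(0, 50)], 0, 50)
        ann = GenomeAnnotation([a, b])
        assert five_prime_igr(a, ann) is None

    def test_neighbor_on_opposite_strand_counts(self):
        a = simple_gene("A", "c", "-", [(100, 200)], 100, 200)
        b = simple_gene("B", "c", "+", [(300, 500)], 300, 500)
        ann = GenomeAnnotation([a, b])
        assert five_prime_igr(b, ann) == 100

    def test_gene_absent_from_annotation_errors(self):
        a = simple_gene("A", "c", "+", [(100, 200)], 100, 200)
        b = simple_gene("B", "c", "+", [(300, 500)], 300, 500)
        ann = GenomeAnnotation([a])
        with pytest.raises(KeyError):
            five_prime_igr(b, ann)


class TestThreePrimeIgr:
    def test_tandem_gap_symmetry(self):
        # igr3 of the upstream gene equals igr5 of the downstream gene
        a = simple_gene("A", "c", "+", [(100, 200)], 100, 200)
        b = simple_gene("B", "c", "+", [(300, 500)], 300, 500)
        ann = GenomeAnnotation([a, b])
        assert three_prime_igr(a, ann) == 100 == five_prime_igr(b, ann)

    def test_minus_strand_measures_leftward(self):
        a = simple_gene("A", "c", "+", [(100, 200)], 100, 200)
        b = simple_gene("B", "c", "-", [(300, 500)], 300, 500)
        ann = GenomeAnnotation([a, b])
        assert three_prime_igr(b, ann) == 100
        assert five_prime_igr(b, ann) is None  # nothing 3'-ward of 500

    def test_chromosome_end_censored(self):
        a = simple_gene("A", "c", "+", [(100, 200)], 100, 200)
        b = simple_gene("B", "c", "+", [(300, 500)], 300, 500)
        ann = GenomeAnnotation([a, b])
        assert three_prime_igr(b, ann) is None


class TestFirstIntron:
    def test_intronless_gene(self):
        g = simple_gene("A", "c", "+", [(0, 300)], 0, 300)
        assert first_intron_lengths(g) == (0, 0)

    def test_max_over_isoforms(self):
        tx1 = TranscriptModel(
            "t1", "+", ((0, 100), (180, 300)), 50, 280
        )  # first intron 80
        tx2 = TranscriptModel(
            "t2", "+", ((0, 100), (220, 340)), 50, 320
        )  # first intron 120
        g = GeneModel("A", "c", "+", (tx1, tx2))
        assert first_intron_lengths(g)[0] == 120

    def test_intron_in_utr5_is_not_first_intron(self):
        # (+) intron before the translation start does not count
        tx = TranscriptModel(
            "t1", "+", ((0, 50), (100, 200), (260, 400)), 150, 380
        )
        g = GeneModel("A", "c", "+", (tx,))
        assert first_intron_lengths(g)[0] == 60

    def test_nested_coding_interval_splits_noncoding_run(self):
        host = simple_gene(
            "H", "c", "+", [(0, 100), (220, 400)], 50, 380
        )  # first intron [100, 220), length 120
        nested = simple_gene("N", "c", "+", [(150, 180)], 150, 180)
        ann = GenomeAnnotation([host, nested])
        intron1, noncoding = first_intron_lengths(host, ann)
        assert intron1 == 120
        assert noncoding == 50  # larger flanking run [100,150)


class TestUtrLengths:
    def test_short_utr3_discarded(self):
        # 3' UTR of 4 bp is treated as an annotation artifact
        g = simple_gene("A", "c", "+", [(0, 104)], 0, 100)
        utr3, _, _ = utr_lengths(g)
        assert utr3 is None

    def test_short_utr5_discarded(self):
        g = simple_gene("A", "c", "+", [(0, 110)], 2, 100)
        _, utr5, _ = utr_lengths(g)
        assert utr5 is None

    def test_thresholds_are_inclusive(self):
        g = simple_gene("A", "c", "+", [(0, 108)], 3, 103)
        utr3, utr5, _ = utr_lengths(g)
        assert (utr3, utr5) == (5, 3)

    def test_multiexon_utr3_excluded_from_max(self):
        def iso(tid, utr3_exons):
            exons = ((0, 100),) + utr3_exons
            return TranscriptModel(tid, "+", exons, 0, 90)

        t150 = TranscriptModel("a", "+", ((0, 250),), 0, 100)  # utr3 150
        t300 = TranscriptModel("b", "+", ((0, 400),), 0, 100)  # utr3 300
        t500 = TranscriptModel(  # 2-exon utr3 of 500
            "c", "+", ((0, 150), (200, 650)), 0, 100
        )
        g = GeneModel("A", "c", "+", (t150, t300, t500))
        utr3, _, multi = utr_lengths(g, allow_multiexon_utr3=False)
        assert utr3 == 300 and multi
        utr3_all, _, _ = utr_lengths(g, allow_multiexon_utr3=True)
        assert utr3_all == 500

    def test_all_isoforms_multiexon_gives_absent(self):
        t = TranscriptModel("a", "+", ((0, 150), (200, 650)), 0, 100)
        g = GeneModel("A", "c", "+", (t,))
        utr3, _, multi = utr_lengths(g)
        assert utr3 is None and multi


class TestRegionTable:
    def operon_annotation(self):
        genes = [
            simple_gene(f"g{i}", "c", "+",
                        [(i * 1000, i * 1000 + 300)],
                        i * 1000, i * 1000 + 300)
            for i in range(1, 4)
        ]
        operons = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "operon_id": ["op1"] * 3,
                "position": [1, 2, 3],
            }
        )
        return GenomeAnnotation(genes), operons

    def test_only_first_operon_gene_in_igr5_set(self):
        ann, operons = self.operon_annotation()
        table = compute_region_table(ann, operons=operons)
        flags = table.set_index("gene_id")["included_in_igr5_set"]
        assert flags["g1"] and not flags["g2"] and not flags["g3"]

    def test_unknown_operon_gene_errors(self):
        ann, operons = self.operon_annotation()
        operons.loc[0, "gene_id"] = "missing"
        with pytest.raises(KeyError, match="missing"):
            compute_region_table(ann, operons=operons)

    def test_worm_mode_drops_utr_sum_column(self, small_genome):
        annotation, operons, _ = small_genome
        table = compute_region_table(
            annotation, species_flags={"trans_spliced": True}
        )
        assert "utr5_plus_utr3" not in table.columns
        assert "utr3" in table.columns

    def test_combined_variants_are_component_sums(self, small_genome):
        annotation, _, _ = small_genome
        t = compute_region_table(annotation)
        ok = t["igr5"].notna() & t["igr3"].notna()
        assert np.allclose(
            t.loc[ok, "igr5_plus_intron1_plus_igr3"],
            t.loc[ok, "igr5"] + t.loc[ok, "intron1_max"] + t.loc[ok, "igr3"],
        )

    def test_utr_filter_monotonicity(self, small_genome):
        """Lowering the UTR thresholds never decreases the number of genes
        with a present UTR."""
        annotation, _, _ = small_genome
        strict = compute_region_table(annotation, utr3_min=5, utr5_min=3)
        loose = compute_region_table(annotation, utr3_min=1, utr5_min=1)
        assert loose["utr3"].notna().sum() >= strict["utr3"].notna().sum()
        assert loose["utr5"].notna().sum() >= strict["utr5"].notna().sum()


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_per_base_brute_force(self, seed):
        """Every igr5/igr3/intron/UTR value on a random small genome equals
        an independent per-base computation from the coding mask."""
        rng = np.random.default_rng(seed)
        config = SimConfig(
            seed=seed,
            n_genes=int(rng.integers(40, 120)),
            n_chromosomes=2,
            operon_fraction=0.1,
            nested_gene_prob=0.1,
            utr3_multiexon_prob=0.15,
            alt_transcript_prob=0.3,
        )
        annotation, _, _ = simulate_genome(config)
        table = compute_region_table(annotation)
        mismatches = check_genome_against_oracle(annotation, table)
        assert mismatches == []


class TestRobustnessCorrelation:
    def test_combined_variants_track_igr5(self):
        """The alternative transcriptional-region estimates are strongly
        positively correlated with plain 5' IGR length across genes."""
        annotation, _, _ = simulate_genome(SimConfig(seed=5, n_genes=300))
        t = compute_region_table(annotation)
        base = t["igr5"]
        for variant in (
            "igr5_plus_intron1",
            "igr5_plus_igr3",
            "igr5_plus_intron1_plus_igr3",
        ):
            ok = base.notna() & t[variant].notna()
            rho, p = spearmanr(base[ok], t[variant][ok])
            assert rho > 0 and p < 0.01
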