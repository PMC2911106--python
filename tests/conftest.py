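"""Shared fixtures: hand-written annotation fixtures and a small simulated
genome reused across test modules."""

from __future__ import annotations

import pytest

from mzarch.annotation_io import parse_annotation
from mzarch.synthetic_data import SimConfig, simulate_genome

# Two genes on chr1: geneA (+) with a UTR-only first exon region and a
# 2-exon CDS; geneB (-) single exon. Coordinates 1-based inclusive (GFF3).
TWO_GENE_GFF3 = """##gff-version 3
chr1\ttest\tgene\t101\t400\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=tA1;Parent=geneA
chr1\ttest\texon\t101\t200\t.\t+\t.\tParent=tA1
chr1\ttest\texon\t301\t400\t.\t+\t.\tParent=tA1
chr1\ttest\tCDS\t151\t200\t.\t+\t0\tParent=tA1
chr1\ttest\tCDS\t301\t380\t.\t+\t0\tParent=tA1
chr1\ttest\tgene\t601\t900\t.\t-\t.\tID=geneB
chr1\ttest\tmRNA\t601\t900\t.\t-\t.\tID=tB1;Parent=geneB
chr1\ttest\texon\t601\t900\t.\t-\t.\tParent=tB1
chr1\ttest\tCDS\t651\t850\t.\t-\t0\tParent=tB1
"""

TWO_GENE_GTF = """chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "geneA"; transcript_id "tA1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "geneA"; transcript_id "tA1";
chr1\ttest\tCDS\t151\t200\t.\t+\t0\tgene_id "geneA"; transcript_id "tA1";
chr1\ttest\tCDS\t301\t380\t.\t+\t0\tgene_id "geneA"; transcript_id "tA1";
chr1\ttest\texon\t601\t900\t.\t-\t.\tgene_id "geneB"; transcript_id "tB1";
chr1\ttest\tCDS\t651\t850\t.\t-\t0\tgene_id "geneB"; transcript_id "tB1";
"""

# One gene with two isoforms sharing the CDS start but ending in different
# 3' UTRs.
TWO_ISOFORM_GFF3 = """##gff-version 3
chr2\ttest\tgene\t1001\t2000\t.\t+\t.\tID=geneC
chr2\ttest\tmRNA\t1001\t1700\t.\t+\t.\tID=tC1;Parent=geneC
chr2\ttest\texon\t1001\t1700\t.\t+\t.\tParent=tC1
chr2\ttest\tCDS\t1101\t1500\t.\t+\t0\tParent=tC1
chr2\ttest\tmRNA\t1001\t2000\t.\t+\t.\tID=tC2;Parent=geneC
chr2\ttest\texon\t1001\t2000\t.\t+\t.\tParent=tC2
chr2\ttest\tCDS\t1101\t1500\t.\t+\t0\tParent=tC2
"""


@pytest.fixture()
def two_gene_gff3(tmp_path):
    path = tmp_path / "two_gene.gff3"
    path.write_text(TWO_GENE_GFF3)
    return str(path)


@pytest.fixture()
def two_gene_gtf(tmp_path):
    path = tmp_path / "two_gene.gtf"
    path.write_text(TWO_GENE_GTF)
    return str(path)


@pytest.fixture()
def two_gene_annotation(two_gene_gff3):
    return parse_annotation(two_gene_gff3)


@pytest.fixture(scope="session")
def small_genome():
    """An 80-gene simulated genome with operons and occasional nested
    genes, shared read-only across tests."""
    config = SimConfig(
        seed=11, n_genes=80, operon_fraction=0.12, nested_gene_prob=0.08
    )
    annotation, operons, labels = simulate_genome(config)
    return annotation, operons, labels
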