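# mzarch

Comparative analysis of **maternal vs. zygotic gene regulatory
architecture** from genome annotation.

Early embryos carry mRNA from two origins: transcripts deposited by the
mother in the oocyte (maternal) and transcripts made by the embryo itself
after fertilization (zygotic). Maternal transcripts can only be regulated
post-transcriptionally — their control information lives in the 3' UTR —
while zygotic genes can also use transcriptional control encoded in the
DNA upstream of the gene. Using region *length* as a proxy for regulatory
content, the architecture of a gene can therefore be read off its
annotation alone:

* **L(5' IGR)** — the distance from a gene's 5'-most coding nucleotide to
  the nearest coding nucleotide of a different gene in the 5' direction,
  on either strand: a proxy for transcriptional regulatory complexity;
* **L(3' UTR)** — the longest single-exon 3' UTR across isoforms: a proxy
  for post-transcriptional regulatory complexity;
* robustness variants (5' IGR + first intron, sum of IGRs, 5'+3' UTR).

`mzarch` is for genomicists and evolutionary developmental biologists who
want to run this comparison design — on their own annotations and
expression data, or on the package's fully synthetic six-species study
with planted, recoverable effects.

## What it computes

1. **Region metrics** (`mzarch.region_metrics`) — per-gene 5'/3' IGR,
   first-intron measures, UTR lengths and combined variants, by pure
   coordinate arithmetic on GFF3/GTF input (0-based half-open internally),
   with the standard filters: 3' UTRs < 5 bp and 5' UTRs < 3 bp treated as
   annotation artifacts; multi-exon 3' UTRs excluded from the per-gene
   maximum; in operon-containing (nematode-style) genomes only the 5'-most
   operon member enters 5' IGR analyses.
2. **Gene classes** (`mzarch.gene_classes`) — origin-of-synthesis classes
   (strict-maternal, mostly-maternal, maternal-zygotic, mostly-zygotic,
   strict-zygotic) from decoupled maternal/zygotic components (fold change
   ≥ 3, P ≤ 0.001, minority fraction < 33%), from expression time courses
   spanning the maternal-to-zygotic transition, or from single-stage
   abundance rank thresholds; conservation classes by phylogenetic
   profiling (core = present in ≥ 1 unicellular organism; metazoan =
   present in ≥ 2 animals, absent from unicellular organisms and plants).
3. **The percentile-sweep KS test** (`mzarch.ks_stats`) — a one-sided
   two-sample Kolmogorov–Smirnov statistic D+ = sup_x [F_ref(x) − F(x)]
   with p = exp(−2 D+² · n_a n_b / (n_a + n_b)), applied iteratively to
   bottom-percentile truncations of both samples (15th percentile, then in
   5% steps up to 100%). A gene class *depleted of short lengths* lights
   up at low percentiles. An exact permutation p-value (exhaustive for
   small samples) handles the heavy ties of integer length data.
4. **Ortholog rank fold changes** (`mzarch.ortholog_rank`) — within-genome
   percentile ranks of 5' IGR length and log2 rank ratios across 1:1
   ortholog pairs; one-sided KS of maternal pairs vs. all pairs.
5. **Summaries** (`mzarch.summaries`) — maternal-to-genome 5' IGR ratios
   (median, 75th percentile, 5% trimmed mean) across species ordered by
   maternal nutritional contribution, and the RNAi phenotype vs.
   no-phenotype comparison.
6. **Synthetic data** (`mzarch.synthetic_data`, `mzarch.study`) — simulated
   genomes emitted as real GFF3 (log-normal gaps/UTRs/introns, operons,
   alternative isoforms, nested genes), expression time courses,
   phylogenetic profiles, ortholog tables and RNAi tables, all
   deterministic per seed, with configurable planted class effects.

## Worked example

Simulate a genome in which the maternal classes' 3' UTR lengths are
redrawn above the 20th percentile of their distribution (no short maternal
3' UTRs), then ask the sweep whether maternal 3' UTRs are depleted of
short values relative to all other genes:

```python
from mzarch import SimConfig, simulate_genome, compute_region_table, percentile_sweep
from mzarch.synthetic_data import ClassEffect
from mzarch.region_metrics import metric_values
from mzarch.gene_classes import ALL_MATERNAL_MEMBERS

effects = {c: ClassEffect(utr3_left_truncation_percentile=20.0)
           for c in ("strict_maternal", "mostly_maternal", "maternal_zygotic")}
config = SimConfig(seed=4, n_genes=1500, class_effects=effects)
annotation, operons, labels = simulate_genome(config)
table = compute_region_table(annotation)

maternal = set(labels.loc[labels["origin_class"].isin(ALL_MATERNAL_MEMBERS), "gene_id"])
a = metric_values(table, "utr3", maternal)
b = metric_values(table, "utr3", set(table["gene_id"]) - maternal)
res = percentile_sweep(a, b)
print(f"p_min={res.p_min:.3g} at q={res.q_at_p_min:g}; "
      f"top significant q={res.q_top_significant:g}")
```

prints

```
p_min=2.52e-22 at q=15; top significant q=100
```

i.e. the maternal 3' UTR distribution differs most strongly within the
shortest 15% of lengths (D = 0.69 over 82 maternal vs. 141 reference
genes there) — the planted depletion of short 3' UTRs — and the
difference remains significant with no truncation at all (q = 100).

The same analysis end-to-end from a shell:

```bash
mzarch simulate --out study/ --seed 1          # six synthetic species
mzarch run-all --config study/study.yaml --out results/
```

`results/` then contains per-species metric, class and sweep tables, the
ortholog fold-change analysis, the cross-species ratio summary, the RNAi
comparison and a manifest with input digests; rerunning produces
byte-identical files.

## Layout

```
src/mzarch/
  models.py          gene/transcript containers, coding-interval index
  annotation_io.py   GFF3/GTF reading (gffutils), GFF3/TSV writing
  region_metrics.py  IGR / intron / UTR length metrics and filters
  gene_classes.py    origin and conservation classifiers
  ks_stats.py        one-sided KS test and percentile sweep
  ortholog_rank.py   percentile ranks and rank fold changes
  summaries.py       ratio summaries, RNAi comparison
  synthetic_data.py  genome/expression/profile/ortholog/RNAi simulators
  study.py           the packaged six-species synthetic study
  pipeline.py        orchestration (run_species / run_full)
  cli.py             `mzarch` command-line interface
```

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
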