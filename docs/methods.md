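# Methods

This note documents the definitions, conventions and design choices behind
`mzarch`, in the order the pipeline applies them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and gene models

All internal coordinates are 0-based half-open; GFF3/GTF input (1-based
inclusive) is converted at the parsing boundary. A "coding nucleotide" of
a gene is any base covered by any isoform's CDS (the union over
alternative transcripts). Genes with no CDS annotation are excluded from
the coding index and from all analyses: every metric in the package is
anchored on coding positions, and the comparison design concerns
protein-coding genes. Transcripts whose CDS boundaries fall outside their
exons are rejected rather than repaired — silently "fixing" inconsistent
annotation would make results depend on the repair heuristic.

## Region-length metrics

**5' IGR.** The number of bases strictly between a gene's 5'-most coding
base (in gene orientation) and the nearest coding base of a *different*
gene in the gene's 5' direction, on either strand. Overlapping or abutting
coding sequence gives 0; the value is a length of non-coding sequence and
is never negative. The search is directional: the separate 3' IGR
definition mirrors it in the 3' direction, measured from the 3'-most
coding base across isoforms. Genes with no coding neighbor in the required
direction (chromosome ends) are *censored* and excluded from that
metric's distributions rather than assigned a distance to the contig
edge, which would be an assembly artifact, not biology.

**First introns.** Per transcript, the first intron is the intron nearest
3' of the translation start (an intron inside the 5' UTR does not count).
Two per-gene measures: the largest first-intron length across isoforms,
and the largest continuous run inside that intron covered by no gene's
coding sequence (nested genes shorten it). Intronless genes score (0, 0).

**UTRs.** Per-gene UTR length is the maximum of per-transcript total UTR
lengths. 3' UTRs spanning more than one exon (a signature of
nonsense-mediated-decay targets and of unreliable annotation) are excluded
from the maximum by default; a flag records their presence and a switch
re-admits them. After the maximum, 3' UTRs < 5 bp and 5' UTRs < 3 bp are
reported absent: stub UTRs of a few bases are annotation placeholders, and
because they are numerous they would otherwise dominate location measures.
An optional per-species gene allow-list restricts which genes may report a
3' UTR at all (for genomes where only a subset of models has trustworthy
UTR annotation).

**Combined variants.** igr5+intron1, igr5+igr3 and igr5+intron1+igr3 as
alternative transcriptional-region estimates; utr5+utr3 as the total
post-transcriptional estimate. The UTR sum is omitted in trans-spliced
(worm-mode) genomes, where outron splicing replaces the annotated 5' UTR
and the sum is not meaningful. For operon-transcribed genes only the
5'-most member keeps `included_in_igr5_set = True`: internal members sit
a few dozen bases behind their predecessor and have no individual
promoter region; they are retained in the table but excluded from 5' IGR
distributions. A possible alternative 3' IGR convention — measuring from
the 3' UTR end instead of the last coding base — would shorten igr3 by
the UTR length; the coding-anchored convention is used throughout because
it needs no UTR annotation quality assumptions.

## Origin and conservation classification

Three classifiers cover the three shapes of source data:

* **Decoupled components** (per-gene maternal and zygotic abundance plus a
  time course): maternal presence above the detection threshold puts a
  gene in the all-maternal superset; a significant decrease (fold change
  ≥ 3; additionally p ≤ 0.001 when replicate-level p-values are supplied)
  with zero zygotic component → strict-maternal; with a minority (< 33%)
  zygotic fraction → mostly-maternal; no significant change →
  maternal-zygotic; genes expressed only after the transition are
  strict-zygotic (no maternal part) or mostly-zygotic (< 33% maternal).
  Without replicate data the p criterion cannot be evaluated per gene and
  the fold-change rule alone decides "decreasing".
* **Time courses**: present before the transition and reduced ≥ 3-fold at
  *every* post-transition point → strict-maternal; absent before, present
  after → strict-zygotic; present and stable → maternal-zygotic. The
  maternal-zygotic class is deliberately loose — it is whatever the
  stability test leaves, and includes slowly decaying maternal genes.
* **Rank thresholds** (single-stage snapshots such as a laid egg or a
  gastrulation-stage embryo): the top fraction (default 50% for the
  egg-maternal call, 25% for the gastrulation-zygotic call) of expressed
  genes by abundance rank, with all cutoff ties included. The sets are
  nested and monotone in the fraction.

Precomputed label tables are accepted verbatim everywhere — published
datasets often ship their own calls.

**Conservation**: core = detected in ≥ 1 unicellular organism of the
panel (the prokaryote counts as unicellular for this purpose); metazoan =
detected in ≥ 2 animals, absent from unicellular organisms and from
plants; everything else "other". The panel must contain ≥ 1 unicellular,
≥ 1 plant and ≥ 2 animal taxa. The default synthetic panel has 26 taxa
(4 unicellular incl. one prokaryote, 2 plants, 20 animals).

## The one-sided KS percentile sweep

The statistic is D+ = sup_x [F_b(x) − F_a(x)] over the observed support,
where b is the reference sample; large D+ means a is shifted right of b
(fewer short values). The asymptotic p is the classical one-sided bound
exp(−2 D+² n_a n_b/(n_a+n_b)), clipped to (0, 1]. Length data are
integers with heavy ties; the empirical-CDF sup over observed points
handles ties exactly, and the asymptotic p (slightly conservative under
discreteness) can be replaced by a permutation p: exhaustive enumeration
of label splits when their number fits the permutation budget (so small
samples are exact), Monte Carlo with a +1 correction otherwise.

The sweep truncates both samples to their bottom-q tails for q = 15, 20,
…, 95, 100 and reruns the test on the truncations, skipping q where a
truncation is empty; the q = 100 entry is exactly the untruncated test.
Reported: every per-q (D, p, n_a, n_b), the minimum p with the (lowest)
percentile attaining it, and the top-most percentile with p < α
(α = 0.05). Percentiles use linear interpolation between order statistics
(any consistent convention works; one had to be fixed for
reproducibility). Per-percentile p-values are reported raw — the sweep is
read percentile by percentile, not as a family — with a Bonferroni column
emitted alongside for the reader.

**Truncation anchor.** Whose percentile defines the cutoff is genuinely
open; three options are implemented (`subset_anchor`): each sample's own
percentile (`each`, default), the reference sample's (`reference`), or
the pooled sample's (`pooled`). `each` is the default because it directly
expresses the question "does the bottom-q of this class look like the
bottom-q of the reference?": for a class depleted of short values the
bottom-q supports separate and D+ → 1 at low q, so the minimum p lands at
the lowest informative percentile. Under a reference-anchored cutoff a
depleted class's truncation is nearly empty at low q and the most
significant percentile drifts to wherever the sample-size/effect-size
product peaks (around q ≈ 33 for a 20%-depleted class, by maximizing
(F−0.2)/(F(1.8F−0.2))), which answers a different question.

## Ortholog rank analysis

Within each genome, genes are ranked by 5' IGR length ascending (short =
low rank), average ranks for ties, normalized by the number of usable
genes, so ranks lie in (0, 1] and are invariant to any monotone transform
of lengths. The rank direction is a convention; it fixes the sign of fold
changes (positive log2 fc = relatively longer in the anchor species) and
does not affect any symmetry or recovery property. For 1:1 ortholog pairs
the log2 ratio of ranks is the fold change in percentile ranking; pairs
with a censored member are dropped (with a count logged), duplicated
genes violate the 1:1 premise and raise. The 1:1:1 restriction across
three species is enforced by intersecting the two pairwise tables on the
anchor species. The maternal subset for the maternal-vs-all KS comparison
is pairs maternal in *both* species.

## Ratio summaries and the RNAi comparison

The maternal-to-genome ratio divides a location measure of maternal
metazoan genes' 5' IGR lengths by the same measure over all metazoan
genes (maternal genes included in the denominator — it is a genome-wide
reference, and restricting to metazoan genes removes the functional-class
confound). Three measures: median, 75th percentile, and a 5% trimmed
mean. "5% trimmed" is ambiguous between 5% per tail and 5% total; the
default trims 5% from each tail, with 2.5%-per-tail available as an
option. Nutrition class (low/medium/high maternal nutritional
contribution) is input metadata, not computed. The RNAi comparison runs
the percentile sweep on 5' IGR and 3' UTR separately between maternal
genes with and without an observed phenotype.

## The synthetic-data generator

The generator emulates, at the coordinate level, the statistical structure
the analysis assumes — it emits real GFF3 so the parser and interval
engine are exercised, not just the statistics. Gene structure: log-normal
intergenic gaps (default median 2 kb, σ = 0.9 on the log scale), CDS
(median 1.2 kb), per-conservation-class UTR and intron lengths (3' UTR
medians 180/420/300 bp for core/metazoan/other; 5' UTR about half that;
introns 300–500 bp), 70% of genes with a first intron, 20% with a second
isoform differing in 3' UTR, 10% with a multi-exon 3' UTR isoform, 5%
with a 1–4 bp stub UTR (the annotation-artifact regime the filters
exist for), and occasional nested intronic genes. Strands are random;
operon members (configurable fraction, worm mode) are consecutive '+'
genes at 50–150 bp spacing. Planted effects are class-conditional:
`igr5_scale` multiplies every gap faced by a class's 5' end (a
conservation-class multiplier exists likewise), and
`utr3_left_truncation_percentile` redraws a class's 3' UTRs conditional on
exceeding that percentile of the class distribution. Expression time
courses follow the class profiles (maternal decaying 8-fold across the
transition, zygotic rising from below the presence threshold of 50
abundance units, maternal-zygotic flat) under multiplicative log-normal
noise (default 0.2 log2 units). Phylogenetic profiles are drawn consistent
with the planted conservation class by construction. Ortholog tables pair
the anchor species' genes with partner genes so that partner ranks equal
anchor ranks plus Gaussian noise, optionally shifting maternal-in-both
pairs of one partner; with zero noise and no shift, partner lengths are an
exact monotone transform of anchor lengths, so every fold change is
exactly 0. All generators are deterministic given the seed, with
independent substreams per data type.

What the generator does **not** emulate: sequence content, splice-site
biology, expression platform effects, annotation errors beyond stub UTRs,
correlated gene order across species (synteny), or realistic phylogenetic
covariance among taxa. Passing recovery tests therefore shows the
*pipeline* recovers planted effects of realistic size and shape — it does
not validate the biological conclusions on real genomes.

## The packaged six-species study

`mzarch.study.write_study` emits a complete study (six species × 1000
genes on 3 chromosomes by default) spanning low/medium/high maternal
nutrition with maternal 5' gap scales 0.06, 0.16, 0.35, 0.75, 1.5 and
3.0; these spacings were chosen, together with a reduced gap dispersion
(σ = 0.45) and a ~30% maternal gene fraction, so that the planted
ratio ordering exceeds the sampling noise of the median/p75/trimmed-mean
ratios at this genome size (the maternal-to-genome ratio saturates when
maternal genes dominate the genome-wide pool, since they sit in the
denominator too). All species carry the 20th-percentile maternal 3' UTR
truncation and a core-vs-metazoan gap contrast (0.6 vs 1.4); oviparous
species get 2-fold enlarged strict-zygotic gaps, the mouse-like species
0.6-fold. The worm-like species is trans-spliced with ~10% operon genes
and an RNAi table whose phenotype odds rise with 5' IGR rank. Origin
labels reach the pipeline by all three routes: time courses (worm, fly,
fish, mouse), an egg-abundance top-50% rank call (chicken-like, whose
maternal classes were set to half the genome so the call aligns), and a
label table (human-like). Ortholog tables anchor on the human-like
species with rank noise 0.06 and a 0.3 rank-unit maternal shift planted
in the chicken-like pair only.

## Problem sizes used by the test and acceptance suites

Unit and property tests run on genomes of 40–400 genes; oracle agreement
is checked on 50 random genomes of ≤ 200 genes against a per-base
brute-force implementation; KS null calibration uses 2000 replicates at
n = 500 per sample; sweep recovery 200 replicates at n = 500; ortholog
pattern recovery 100 replicates at 500 genes; the end-to-end study runs
at the packaged 1000 genes per species, twice, for the byte-identity
check. The acceptance script uses the same designs at moderately reduced
replicate counts and prints each quantity with the size it was computed
at.

## Known limitations

* The asymptotic one-sided p-value is a bound; at α = 0.05 and large ties
  it can be mildly conservative or anti-conservative at the third decimal.
  The permutation option is the defensible exact fallback.
* Censoring at chromosome ends discards genes rather than modelling them;
  on highly fragmented assemblies this loses a biased subset (long-IGR
  genes are more likely censored).
* The decoupled classifier's p-value criterion is inert without
  replicate-level variance input.
* `maternal_zygotic` is a residual class by construction; downstream
  analyses that need a sharp maternal set should use strict-maternal.
* GTF input relies on gene/transcript inference from attributes; files
  with inconsistent `gene_id`/`transcript_id` usage should be converted
  to GFF3 first.
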