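"""Synthetic genomes, expression time courses, phylogenetic profiles,
ortholog tables and RNAi tables with planted, recoverable effects.

Gene structure is simulated at the coordinate level and emitted as real
GFF3, so the annotation parser and the interval engine are exercised
end-to-end rather than fed bare length vectors. Lengths (intergenic gaps,
UTRs, introns, CDS) are log-normal: positive, heavy right tails, the
standard first-order description of genomic length data. Every gene first
receives a conservation class and an origin-of-synthesis class; its
structure is then drawn from class-conditional distributions with the
configured class effects applied:

* ``igr5_scale`` multiplies the intergenic gap facing a gene's 5' end
  (e.g. < 1 for maternal classes in an egg-laying species, > 1 for
  strictly zygotic patterning-like genes);
* ``utr3_left_truncation_percentile`` redraws a class's 3' UTR lengths
  conditional on exceeding that percentile of the class distribution,
  planting the "no short 3' UTRs" signature.

All generators are deterministic given the config seed; sub-streams are
derived per data type so the genome, expression, profile, ortholog and
RNAi draws are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .gene_classes import ALL_MATERNAL_MEMBERS
from .models import GeneModel, GenomeAnnotation, TranscriptModel


@dataclass(frozen=True)
class LengthDist:
    """Log-normal length distribution; ``mu``/``sigma`` on the natural-log
    scale (exp(mu) is the median length in bp)."""

    mu: float
    sigma: float

    def sample(self, rng, n=None, min_quantile: float = 0.0):
        u = rng.uniform(min_quantile, 1.0, size=n)
        return np.exp(self.mu + self.sigma * norm.ppf(u))

    def sample_int(self, rng, minimum: int = 1, min_quantile: float = 0.0):
        return max(minimum, int(round(self.sample(rng, None, min_quantile))))


@dataclass(frozen=True)
class ClassEffect:
    igr5_scale: float = 1.0
    utr3_left_truncation_percentile: Optional[float] = None


def default_taxon_panel() -> dict[str, str]:
    """26-taxon panel: 4 unicellular organisms (one of them a prokaryote),
    2 plants, 20 animals."""
    panel = {f"unicellular_{i}": "unicellular" for i in range(1, 5)}
    panel.update({f"plant_{i}": "plant" for i in range(1, 3)})
    panel.update({f"animal_{i}": "animal" for i in range(1, 21)})
    return panel


def _default_origin_fracs() -> dict[str, float]:
    return {
        "strict_maternal": 0.20,
        "mostly_maternal": 0.05,
        "maternal_zygotic": 0.15,
        "mostly_zygotic": 0.05,
        "strict_zygotic": 0.10,
        "unclassified": 0.45,
    }


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 500
    n_chromosomes: int = 2
    # structural length distributions (bp)
    spacing: LengthDist = LengthDist(math.log(2000.0), 0.9)
    cds: LengthDist = LengthDist(math.log(1200.0), 0.5)
    utr3_by_class: dict = field(
        default_factory=lambda: {
            "core": LengthDist(math.log(180.0), 0.6),
            "metazoan": LengthDist(math.log(420.0), 0.6),
            "other": LengthDist(math.log(300.0), 0.6),
        }
    )
    utr5_by_class: dict = field(
        default_factory=lambda: {
            "core": LengthDist(math.log(90.0), 0.6),
            "metazoan": LengthDist(math.log(180.0), 0.6),
            "other": LengthDist(math.log(130.0), 0.6),
        }
    )
    intron_by_class: dict = field(
        default_factory=lambda: {
            "core": LengthDist(math.log(300.0), 0.8),
            "metazoan": LengthDist(math.log(500.0), 0.8),
            "other": LengthDist(math.log(400.0), 0.8),
        }
    )
    intron_prob: float = 0.7
    alt_transcript_prob: float = 0.2
    utr3_multiexon_prob: float = 0.1
    utr_artifact_prob: float = 0.05
    nested_gene_prob: float = 0.03
    # class composition
    frac_core: float = 0.35
    frac_metazoan: float = 0.45
    origin_fracs: dict = field(default_factory=_default_origin_fracs)
    class_effects: dict = field(default_factory=dict)
    # conservation-class multiplier on 5'-facing gaps (e.g. core < 1,
    # metazoan > 1); empty dict = conservation-neutral spacing
    igr5_scale_by_cons: dict = field(default_factory=dict)
    operon_fraction: float = 0.0
    # expression time course
    n_timepoints_pre: int = 1
    n_timepoints_post: int = 2
    maternal_level: float = 400.0
    zygotic_level: float = 400.0
    decay_fold: float = 8.0
    expression_noise_sd: float = 0.2  # log2 units
    presence_call: float = 50.0
    # phylogenetic profile panel
    taxa: dict = field(default_factory=default_taxon_panel)
    # orthologs
    ortholog_fraction: float = 1.0
    ortholog_rank_noise: float = 0.0
    ortholog_maternal_shift: float = 0.0
    ortholog_shifted_species: str = ""
    ortholog_scale: float = 2.0
    maternal_overlap: float = 0.9
    # RNAi
    rnai_base_rate: float = 0.8
    rnai_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.frac_core + self.frac_metazoan > 1.0 + 1e-9:
            raise ValueError("conservation fractions must sum to <= 1")
        if abs(sum(self.origin_fracs.values()) - 1.0) > 1e-9:
            raise ValueError("origin_fracs must sum to 1")
        if self.n_genes < 2 or self.n_chromosomes < 1:
            raise ValueError("need >= 2 genes on >= 1 chromosome")
        for d in (self.spacing, self.cds):
            if d.sigma <= 0:
                raise ValueError("length distribution sigma must be > 0")

    def effect(self, origin_class: str) -> ClassEffect:
        return self.class_effects.get(origin_class, ClassEffect())


def _build_isoforms(
    rng, config: SimConfig, cons: str, origin: str, strand: str, start: int
) -> tuple[list[TranscriptModel], int, str]:
    """Assemble 1-2 isoforms of one gene at genomic ``start``; returns
    (transcripts, span_end, gene_id placeholder)."""
    effect = config.effect(origin)
    u5 = config.utr5_by_class[cons].sample_int(rng, minimum=1)
    trunc_q = effect.utr3_left_truncation_percentile
    utr3_dist = config.utr3_by_class[cons]

    def draw_utr3() -> int:
        if rng.random() < config.utr_artifact_prob:
            return int(rng.integers(1, 5))
        if trunc_q is not None:
            return utr3_dist.sample_int(
                rng, minimum=1, min_quantile=trunc_q / 100.0
            )
        return utr3_dist.sample_int(rng, minimum=1)

    cds_len = config.cds.sample_int(rng, minimum=60)
    has_intron = rng.random() < config.intron_prob
    intron_len = (
        config.intron_by_class[cons].sample_int(rng, minimum=40)
        if has_intron
        else 0
    )
    c1 = max(3, int(cds_len * 0.4))
    c2 = max(3, cds_len - c1)

    def elements(u3_parts: list[int], utr_intron: int) -> list:
        els = [("utr5", u5), ("cds", c1)]
        if has_intron:
            els.append(("intron", intron_len))
        els.append(("cds", c2))
        els.append(("utr3", u3_parts[0]))
        if len(u3_parts) > 1:
            els.append(("intron", utr_intron))
            els.append(("utr3", u3_parts[1]))
        return els

    iso_specs = [([draw_utr3()], 0)]
    if rng.random() < config.alt_transcript_prob:
        iso_specs.append(([draw_utr3()], 0))
    if rng.random() < config.utr3_multiexon_prob:
        u3 = max(4, draw_utr3())
        a = max(2, int(u3 * 0.6))
        iso_specs.append(([a, max(2, u3 - a)], int(rng.integers(60, 140))))

    # align isoforms on the shared CDS anchor
    def left_block(spec) -> int:
        u3_parts, utr_intron = spec
        if strand == "+":
            return u5
        return sum(u3_parts) + (utr_intron if len(u3_parts) > 1 else 0)

    max_left = max(left_block(s) for s in iso_specs)
    transcripts = []
    span_end = start
    for i, spec in enumerate(iso_specs):
        els = elements(*spec)
        if strand == "-":
            els = els[::-1]
        pos = start + (max_left - left_block(spec))
        segs = []
        for kind, ln in els:
            segs.append((kind, pos, pos + ln))
            pos += ln
        span_end = max(span_end, pos)
        exons: list[list[int]] = []
        for kind, s, e in segs:
            if kind == "intron":
                exons.append(None)  # type: ignore[arg-type]
                continue
            if exons and exons[-1] is not None:
                exons[-1][1] = e
            else:
                if exons and exons[-1] is None:
                    exons.pop()
                exons.append([s, e])
        exon_ivs = tuple(
            (s, e) for s, e in (x for x in exons if x is not None)
        )
        cds_s = min(s for kind, s, e in segs if kind == "cds")
        cds_e = max(e for kind, s, e in segs if kind == "cds")
        transcripts.append(
            TranscriptModel(
                transcript_id=f"@T{i}",
                strand=strand,
                exons=exon_ivs,
                cds_start=cds_s,
                cds_end=cds_e,
            )
        )
    return transcripts, span_end, ""


def _retag(transcripts, gene_id: str):
    return tuple(
        TranscriptModel(
            transcript_id=f"{gene_id}.t{i}",
            strand=tx.strand,
            exons=tx.exons,
            cds_start=tx.cds_start,
            cds_end=tx.cds_end,
        )
        for i, tx in enumerate(transcripts, start=1)
    )


def simulate_genome(
    config: SimConfig,
) -> tuple[GenomeAnnotation, pd.DataFrame, pd.DataFrame]:
    """Generate an annotated genome; returns (annotation, operon table,
    truth labels).

    Genes are laid down sequentially per chromosome with log-normal gaps.
    The gap 5'-adjacent to a gene is multiplied by its origin class's
    ``igr5_scale``; internal operon members follow their predecessor at a
    short fixed-scale gap and all operon members share the '+' strand.
    Truth labels carry the planted origin and conservation class per gene.
    """
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_genes
    cons_classes = rng.choice(
        ["core", "metazoan", "other"],
        size=n,
        p=[
            config.frac_core,
            config.frac_metazoan,
            1.0 - config.frac_core - config.frac_metazoan,
        ],
    )
    origin_names = sorted(config.origin_fracs)
    origins = rng.choice(
        origin_names, size=n, p=[config.origin_fracs[k] for k in origin_names]
    )

    per_chrom = int(math.ceil(n / config.n_chromosomes))
    genes: list[GeneModel] = []
    operon_rows: list[dict] = []
    label_rows: list[dict] = []
    nested_counter = 0

    idx = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        block = list(range(idx, min(idx + per_chrom, n)))
        idx += len(block)
        if not block:
            continue

        # operon membership over the consecutive gene sequence
        operon_of: dict[int, tuple[str, int]] = {}
        j = 0
        op_counter = 0
        while j < len(block):
            if (
                config.operon_fraction > 0
                and j + 1 < len(block)
                and rng.random() < config.operon_fraction / 2.5
            ):
                size = int(rng.integers(2, 4))
                size = min(size, len(block) - j)
                op_counter += 1
                op_id = f"{chrom}_op{op_counter}"
                for k in range(size):
                    operon_of[block[j + k]] = (op_id, k + 1)
                j += size
            else:
                j += 1

        strands = [
            "+" if gi in operon_of else ("+", "-")[int(rng.integers(2))]
            for gi in block
        ]

        pos = 0
        prev_gi: Optional[int] = None
        for bi, gi in enumerate(block):
            strand = strands[bi]
            in_operon = operon_of.get(gi)
            if in_operon is not None and in_operon[1] > 1:
                gap = int(rng.integers(50, 150))
            else:
                # the gap is scaled by every adjacent gene whose 5' end
                # faces it (origin effect x conservation effect)
                def facing_scale(idx: int) -> float:
                    return config.effect(origins[idx]).igr5_scale * (
                        config.igr5_scale_by_cons.get(
                            cons_classes[idx], 1.0
                        )
                    )

                scale = 1.0
                if strand == "+":
                    scale *= facing_scale(gi)
                if prev_gi is not None and strands[bi - 1] == "-":
                    scale *= facing_scale(prev_gi)
                gap = max(1, int(round(config.spacing.sample(rng) * scale)))
            start = pos + gap
            transcripts, span_end, _ = _build_isoforms(
                rng, config, cons_classes[gi], origins[gi], strand, start
            )
            gene_id = f"g{gi + 1:05d}"
            gene = GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                transcripts=_retag(transcripts, gene_id),
            )
            genes.append(gene)
            label_rows.append(
                {
                    "gene_id": gene_id,
                    "origin_class": origins[gi],
                    "conservation_class": cons_classes[gi],
                    "chrom": chrom,
                }
            )
            if in_operon is not None:
                operon_rows.append(
                    {
                        "gene_id": gene_id,
                        "operon_id": in_operon[0],
                        "position": in_operon[1],
                    }
                )
            # occasionally nest a small intronless gene inside the first
            # intron, exercising overlap and non-coding-run logic
            intron = max(
                (
                    tx.first_intron
                    for tx in gene.transcripts
                    if tx.first_intron is not None
                ),
                key=lambda iv: iv[1] - iv[0],
                default=None,
            )
            if (
                intron is not None
                and rng.random() < config.nested_gene_prob
            ):
                ilen = intron[1] - intron[0]
                inner_span = 40 + 150 + 30
                if ilen >= inner_span + 40:
                    nested_counter += 1
                    nid = f"g{gi + 1:05d}n{nested_counter}"
                    ns = intron[0] + (ilen - inner_span) // 2
                    nstrand = ("+", "-")[int(rng.integers(2))]
                    u5n, cdsn, u3n = (
                        (40, 150, 30) if nstrand == "+" else (30, 150, 40)
                    )
                    ntx = TranscriptModel(
                        transcript_id=f"{nid}.t1",
                        strand=nstrand,
                        exons=((ns, ns + inner_span),),
                        cds_start=ns + u5n,
                        cds_end=ns + u5n + cdsn,
                    )
                    genes.append(
                        GeneModel(
                            gene_id=nid,
                            chrom=chrom,
                            strand=nstrand,
                            transcripts=(ntx,),
                        )
                    )
                    label_rows.append(
                        {
                            "gene_id": nid,
                            "origin_class": "unclassified",
                            "conservation_class": "other",
                            "chrom": chrom,
                        }
                    )
            pos = span_end
            prev_gi = gi

    annotation = GenomeAnnotation(genes)
    operons = pd.DataFrame(
        operon_rows, columns=["gene_id", "operon_id", "position"]
    )
    labels = pd.DataFrame(label_rows)
    return annotation, operons, labels


PROFILE_CLASS = {
    "strict_maternal": "strict_maternal",
    "mostly_maternal": "strict_maternal",
    "maternal_zygotic": "maternal_zygotic",
    "mostly_zygotic": "strict_zygotic",
    "strict_zygotic": "strict_zygotic",
    "zygotic": "strict_zygotic",
    "all_maternal": "maternal_zygotic",
    "unclassified": "unclassified",
}


def simulate_expression(
    labels: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Expression time course (gene x time point) implied by the truth
    labels: maternal profiles decay >= decay_fold across the MZT, zygotic
    profiles rise from below the presence threshold, maternal-zygotic
    profiles stay flat; multiplicative log-normal noise on every entry.
    The first ``n_timepoints_pre`` columns are pre-MZT."""
    rng = np.random.default_rng([config.seed, 202])
    n_pre, n_post = config.n_timepoints_pre, config.n_timepoints_post
    cols = [f"t{i}" for i in range(n_pre + n_post)]
    floor = config.presence_call * 0.02
    rows = []
    for origin in labels["origin_class"]:
        prof = PROFILE_CLASS.get(origin, "unclassified")
        if prof == "strict_maternal":
            pre = max(
                config.maternal_level * 2 ** rng.normal(0.0, 0.3),
                config.presence_call * 4,
            )
            vals = [pre] * n_pre + [pre / config.decay_fold] * n_post
        elif prof == "maternal_zygotic":
            lvl = max(
                config.maternal_level * 2 ** rng.normal(0.0, 0.3),
                config.presence_call * 4,
            )
            vals = [lvl] * (n_pre + n_post)
        elif prof == "strict_zygotic":
            post = max(
                config.zygotic_level * 2 ** rng.normal(0.0, 0.3),
                config.presence_call * 4,
            )
            vals = [floor] * n_pre + [post] * n_post
        else:
            vals = [floor] * (n_pre + n_post)
        rows.append(vals)
    values = np.asarray(rows, dtype=float)
    if config.expression_noise_sd > 0:
        values = values * 2 ** rng.normal(
            0.0, config.expression_noise_sd, size=values.shape
        )
    return pd.DataFrame(
        np.round(values, 4), index=labels["gene_id"].to_numpy(), columns=cols
    ).rename_axis("gene_id")


def simulate_phylo_profiles(
    labels: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Presence/absence profiles consistent with the truth conservation
    classes (core: present in >= 1 unicellular taxon; metazoan: >= 2
    animals, no unicellular, no plants; other: patterns satisfying
    neither)."""
    rng = np.random.default_rng([config.seed, 303])
    taxa = list(config.taxa)
    kinds = config.taxa
    uni = [t for t in taxa if kinds[t] == "unicellular"]
    plants = [t for t in taxa if kinds[t] == "plant"]
    animals = [t for t in taxa if kinds[t] == "animal"]
    rows = []
    for cons in labels["conservation_class"]:
        present: set[str] = set()
        if cons == "core":
            k = int(rng.integers(1, len(uni) + 1))
            present |= set(rng.choice(uni, size=k, replace=False))
            mask = rng.random(len(animals)) < 0.85
            present |= {a for a, m in zip(animals, mask) if m}
            mask = rng.random(len(plants)) < 0.7
            present |= {p for p, m in zip(plants, mask) if m}
        elif cons == "metazoan":
            k = 2 + int(rng.binomial(len(animals) - 2, 0.55))
            present |= set(rng.choice(animals, size=k, replace=False))
        else:
            mode = rng.random()
            if mode < 0.4:  # lineage-restricted: a single animal
                present.add(str(rng.choice(animals)))
            elif mode < 0.7:  # plant-shared, fails the metazoan rule
                present.add(str(rng.choice(plants)))
                k = int(rng.integers(0, 4))
                if k:
                    present |= set(
                        rng.choice(animals, size=k, replace=False)
                    )
            # else: absent everywhere
        rows.append([1 if t in present else 0 for t in taxa])
    profiles = pd.DataFrame(
        rows, index=labels["gene_id"].to_numpy(), columns=taxa
    ).rename_axis("gene_id")
    return profiles, dict(kinds)


@dataclass
class OrthologSim:
    """Ortholog tables over an anchor species 'a' and partner species."""

    pairs: dict[str, pd.DataFrame]  # species -> (gene_a, gene_b)
    maternal_both: dict[str, set]  # species -> gene_a ids maternal in both
    lengths: dict[str, pd.Series]  # species -> igr5 by species gene id


def simulate_orthologs(
    igr5_anchor: pd.Series,
    maternal_anchor: set[str],
    config: SimConfig,
    partner_lengths: Optional[dict[str, pd.Series]] = None,
) -> OrthologSim:
    """Construct 1:1 ortholog tables between the anchor species and each
    partner species such that partner 5' IGR percentile ranks equal the
    anchor ranks perturbed by Gaussian noise (sd ``ortholog_rank_noise``),
    with the maternal-in-both pairs of ``ortholog_shifted_species``
    additionally shifted down by ``ortholog_maternal_shift`` rank units
    (their anchor rank then exceeds their partner rank).

    ``partner_lengths`` maps species name to its real igr5 table; the
    pairing is then an assignment of those real genes. Without it a
    partner length pool is synthesized; in the exactly-rank-preserving
    case (zero noise, no shift) partner lengths are a monotone transform
    of the anchor lengths, so every fold change is exactly zero.

    The returned maternal-in-both sets are generated by conserving the
    anchor's maternal status with probability ``maternal_overlap``.
    """
    rng = np.random.default_rng([config.seed, 404])
    usable = igr5_anchor.dropna().astype(float)
    k = int(round(config.ortholog_fraction * len(usable)))
    if k < 2:
        raise ValueError("ortholog core needs >= 2 genes")
    chosen_idx = np.sort(
        rng.choice(len(usable), size=k, replace=False)
    )
    anchor = usable.iloc[chosen_idx]
    partner_lengths = partner_lengths or {}
    species_names = sorted(partner_lengths) or ["b", "c"]

    pairs: dict[str, pd.DataFrame] = {}
    maternal_both: dict[str, set] = {}
    lengths: dict[str, pd.Series] = {}
    for sp in species_names:
        mat_both = {
            g
            for g in anchor.index
            if g in maternal_anchor
            and rng.random() < config.maternal_overlap
        }
        shift = (
            config.ortholog_maternal_shift
            if sp == config.ortholog_shifted_species
            else 0.0
        )
        noise = config.ortholog_rank_noise
        pool = partner_lengths.get(sp)
        if pool is None and noise == 0.0 and shift == 0.0:
            sp_ids = [f"{g}@{sp}" for g in anchor.index]
            sp_lengths = pd.Series(
                anchor.to_numpy() * config.ortholog_scale, index=sp_ids
            )
            partner_gene = sp_ids
        else:
            r = rankdata(anchor.to_numpy(), method="average") / k
            target = r + rng.normal(0.0, max(noise, 1e-9), size=k)
            if shift:
                is_mat = np.array(
                    [g in mat_both for g in anchor.index], dtype=bool
                )
                target = target - shift * is_mat
            order = np.argsort(target, kind="stable")
            if pool is None:
                sp_ids = [f"{g}@{sp}" for g in anchor.index]
                draws = np.sort(config.spacing.sample(rng, k))
                vals = np.empty(k)
                vals[order] = draws
                sp_lengths = pd.Series(vals, index=sp_ids)
                partner_gene = sp_ids
            else:
                pool_usable = pool.dropna().astype(float).sort_values(
                    kind="stable"
                )
                if len(pool_usable) < k:
                    raise ValueError(
                        f"partner species {sp} has fewer usable genes "
                        f"({len(pool_usable)}) than the ortholog core ({k})"
                    )
                take = np.sort(
                    rng.choice(len(pool_usable), size=k, replace=False)
                )
                pool_sorted = pool_usable.iloc[take]
                partner_arr = np.empty(k, dtype=object)
                partner_arr[order] = pool_sorted.index.to_numpy()
                partner_gene = list(partner_arr)
                sp_lengths = pool
        pairs[sp] = pd.DataFrame(
            {"gene_a": list(anchor.index), "gene_b": partner_gene}
        )
        maternal_both[sp] = mat_both
        lengths[sp] = sp_lengths
    return OrthologSim(
        pairs=pairs, maternal_both=maternal_both, lengths=lengths
    )


def simulate_rnai(
    labels: pd.DataFrame, region_table: pd.DataFrame, config: SimConfig
) -> pd.Series:
    """Phenotype calls ('observed'/'none') for maternal genes.

    With ``rnai_effect = 0`` the call is independent of gene architecture
    (null); positive values make the phenotype probability increase with
    the gene's 5' IGR percentile rank, planting the longer-IGR-for-
    functional-genes association."""
    rng = np.random.default_rng([config.seed, 505])
    maternal = labels.loc[
        labels["origin_class"].isin(ALL_MATERNAL_MEMBERS), "gene_id"
    ]
    rows = region_table[
        region_table["gene_id"].isin(set(maternal))
        & region_table["included_in_igr5_set"]
        & region_table["igr5"].notna()
    ]
    if rows.empty:
        raise ValueError("no maternal genes with usable igr5")
    ranks = rankdata(rows["igr5"].to_numpy(), method="average") / len(rows)
    logit0 = math.log(config.rnai_base_rate / (1 - config.rnai_base_rate))
    p = 1.0 / (1.0 + np.exp(-(logit0 + config.rnai_effect * 2 * (ranks - 0.5))))
    calls = np.where(rng.random(len(rows)) < p, "observed", "none")
    return pd.Series(
        calls, index=rows["gene_id"].to_numpy(), name="phenotype"
    ).rename_axis("gene_id")
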