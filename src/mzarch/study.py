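"""The packaged six-species synthetic study.

Emulates the comparison design of a cross-animal survey of maternal vs.
zygotic regulatory architecture: six species spanning low, medium and high
maternal nutritional contribution, with planted class effects —

* every maternal class's 3' UTRs are redrawn above the 20th percentile of
  the class distribution (the "no short maternal 3' UTRs" signature, all
  species);
* maternal-class 5' gaps are scaled by a species-specific factor that
  increases with maternal nutritional contribution (oviparous species
  below 1, viviparous species above 1), so the maternal-to-genome 5' IGR
  ratio is monotone in nutrition class;
* strictly zygotic genes get enlarged 5' gaps in the oviparous species and
  reduced ones in the mouse-like species;
* the worm-like species is trans-spliced and transcribes ~10% of its genes
  in operons; it also carries an RNAi phenotype table whose phenotype
  probability increases with 5' IGR rank;
* 1:1:1 ortholog tables anchor on the human-like species, with the
  maternal-in-both pairs of the chicken-like partner shifted down in rank
  (the systematic relative-size change), and no shift for the mouse-like
  partner.

Origin labels reach the pipeline through all three supported routes:
expression time courses (worm, fly, fish, mouse), a single-stage egg
abundance table classified by top-rank fraction (chicken), and a
precomputed label table (human).
"""

from __future__ import annotations

import math
import os
from dataclasses import replace

import numpy as np
import pandas as pd
import yaml

from .annotation_io import write_gff3, write_table
from .gene_classes import ALL_MATERNAL_MEMBERS
from .region_metrics import compute_region_table
from .synthetic_data import (
    ClassEffect,
    SimConfig,
    simulate_expression,
    simulate_genome,
    simulate_orthologs,
    simulate_phylo_profiles,
    simulate_rnai,
)

MATERNAL_CLASSES = ("strict_maternal", "mostly_maternal", "maternal_zygotic")

# (name, nutrition, maternal igr5 scale, zygotic igr5 scale); the maternal
# scale spread is wide enough that the median/p75/trimmed-mean ratios stay
# ordered after sampling noise at the packaged genome size
SPECIES_PLAN = [
    ("worm_like", "low", 0.06, 2.0),
    ("fly_like", "low", 0.16, 2.0),
    ("fish_like", "medium", 0.35, 2.0),
    ("chicken_like", "medium", 0.75, 1.0),
    ("mouse_like", "high", 1.50, 0.6),
    ("human_like", "high", 3.00, 1.0),
]

UTR3_TRUNCATION_PERCENTILE = 20.0
# core genes sit in compact neighborhoods, metazoan genes in expanded ones
CONS_IGR5_SCALE = {"core": 0.6, "metazoan": 1.4, "other": 1.0}


def species_sim_config(
    name: str,
    seed: int,
    n_genes: int = 1000,
    maternal_scale: float = 1.0,
    zygotic_scale: float = 1.0,
) -> SimConfig:
    effects = {
        cls: ClassEffect(
            igr5_scale=maternal_scale,
            utr3_left_truncation_percentile=UTR3_TRUNCATION_PERCENTILE,
        )
        for cls in MATERNAL_CLASSES
    }
    effects["strict_zygotic"] = ClassEffect(igr5_scale=zygotic_scale)
    kwargs = dict(
        seed=seed,
        n_genes=n_genes,
        n_chromosomes=3,
        class_effects=effects,
        igr5_scale_by_cons=dict(CONS_IGR5_SCALE),
        spacing=replace(SimConfig().spacing, sigma=0.45),
        frac_core=0.30,
        frac_metazoan=0.50,
        # maternal classes total ~30% of genes so the genome-wide pool
        # keeps a stable, mostly unimodal length distribution
        origin_fracs={
            "strict_maternal": 0.18,
            "mostly_maternal": 0.04,
            "maternal_zygotic": 0.08,
            "mostly_zygotic": 0.05,
            "strict_zygotic": 0.10,
            "unclassified": 0.55,
        },
    )
    if name == "worm_like":
        kwargs["operon_fraction"] = 0.10
        kwargs["rnai_effect"] = 3.0
        kwargs["rnai_base_rate"] = 0.75
    if name == "chicken_like":
        # maternal classes sum to 0.5 so the top-50% egg-rank call aligns
        kwargs["origin_fracs"] = {
            "strict_maternal": 0.30,
            "mostly_maternal": 0.05,
            "maternal_zygotic": 0.15,
            "mostly_zygotic": 0.0,
            "strict_zygotic": 0.0,
            "unclassified": 0.50,
        }
    return SimConfig(**kwargs)


def _egg_abundance(labels: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Single-stage oocyte abundance: maternal genes high, others low,
    with little overlap so the top-rank call recovers the maternal set."""
    rng = np.random.default_rng([seed, 606])
    maternal = labels["origin_class"].isin(MATERNAL_CLASSES).to_numpy()
    level = np.where(maternal, 800.0, 40.0)
    values = level * 2 ** rng.normal(0.0, 0.4, size=len(labels))
    return pd.DataFrame(
        {"gene_id": labels["gene_id"], "abundance": np.round(values, 4)}
    )


def write_study(outdir: str, seed: int = 1, n_genes: int = 1000) -> str:
    """Write the full six-species synthetic study under ``outdir`` and
    return the path of the study config YAML."""
    os.makedirs(outdir, exist_ok=True)
    taxon_kinds_path = os.path.join(outdir, "taxon_kinds.tsv")
    panel = SimConfig().taxa
    pd.DataFrame(
        {"taxon": list(panel), "kind": [panel[t] for t in panel]}
    ).to_csv(taxon_kinds_path, sep="\t", index=False)

    species_entries = []
    igr5_tables: dict[str, pd.Series] = {}
    labels_by_species: dict[str, pd.DataFrame] = {}
    for si, (name, nutrition, m_scale, z_scale) in enumerate(SPECIES_PLAN):
        sp_seed = seed * 1000 + si
        config = species_sim_config(
            name, sp_seed, n_genes, m_scale, z_scale
        )
        annotation, operons, labels = simulate_genome(config)
        sp_dir = os.path.join(outdir, name)
        os.makedirs(sp_dir, exist_ok=True)
        gff = os.path.join(sp_dir, "genome.gff3")
        write_gff3(annotation, gff)
        write_table(labels, os.path.join(sp_dir, "truth_labels.tsv"))
        profiles, kinds = simulate_phylo_profiles(labels, config)
        profiles.reset_index().to_csv(
            os.path.join(sp_dir, "profiles.tsv"), sep="\t", index=False
        )
        entry: dict = {
            "name": name,
            "annotation": os.path.join(name, "genome.gff3"),
            "profiles": os.path.join(name, "profiles.tsv"),
            "taxon_kinds": "taxon_kinds.tsv",
            "nutrition": nutrition,
        }
        metrics = compute_region_table(
            annotation,
            operons=operons if len(operons) else None,
            species_flags=(
                {"trans_spliced": True} if name == "worm_like" else None
            ),
        )
        igr5_tables[name] = metrics[metrics["included_in_igr5_set"]].set_index(
            "gene_id"
        )["igr5"]
        labels_by_species[name] = labels
        if name == "worm_like":
            write_table(operons, os.path.join(sp_dir, "operons.tsv"))
            entry["operons"] = os.path.join(name, "operons.tsv")
            entry["flags"] = {"trans_spliced": True}
            rnai = simulate_rnai(labels, metrics, config)
            rnai.reset_index().to_csv(
                os.path.join(sp_dir, "rnai.tsv"), sep="\t", index=False
            )
            entry["rnai"] = os.path.join(name, "rnai.tsv")
        if name == "chicken_like":
            egg = _egg_abundance(labels, sp_seed)
            egg.to_csv(
                os.path.join(sp_dir, "egg_abundance.tsv"),
                sep="\t",
                index=False,
            )
            entry["abundance"] = os.path.join(name, "egg_abundance.tsv")
            entry["top_fraction"] = 0.5
            entry["maternal_ratio_class"] = "all_maternal"
        elif name == "human_like":
            label_out = labels[["gene_id", "origin_class"]].copy()
            # pre-MZT snapshot only: collapse maternal classes to the
            # all_maternal call a single-stage dataset supports
            label_out.loc[
                label_out["origin_class"].isin(MATERNAL_CLASSES),
                "origin_class",
            ] = "all_maternal"
            label_out.loc[
                ~label_out["origin_class"].isin(
                    ["all_maternal"]
                ),
                "origin_class",
            ] = "unclassified"
            write_table(label_out, os.path.join(sp_dir, "labels.tsv"))
            entry["labels"] = os.path.join(name, "labels.tsv")
            entry["maternal_ratio_class"] = "all_maternal"
        else:
            expr = simulate_expression(labels, config)
            expr.reset_index().to_csv(
                os.path.join(sp_dir, "expression.tsv"), sep="\t", index=False
            )
            entry["expression"] = os.path.join(name, "expression.tsv")
            entry["mzt_index"] = config.n_timepoints_pre
        species_entries.append(entry)

    # 1:1:1 orthologs anchored on the human-like species, chicken pair
    # carrying the planted maternal rank shift
    ortho_dir = os.path.join(outdir, "orthologs")
    os.makedirs(ortho_dir, exist_ok=True)
    anchor = "human_like"
    anchor_labels = labels_by_species[anchor]
    maternal_anchor = set(
        anchor_labels.loc[
            anchor_labels["origin_class"].isin(MATERNAL_CLASSES), "gene_id"
        ]
    )
    ocfg = replace(
        species_sim_config(anchor, seed * 1000 + 99),
        ortholog_fraction=0.8,
        ortholog_rank_noise=0.06,
        ortholog_maternal_shift=0.30,
        ortholog_shifted_species="chicken_like",
        maternal_overlap=0.9,
    )
    sim = simulate_orthologs(
        igr5_tables[anchor],
        maternal_anchor,
        ocfg,
        partner_lengths={
            "chicken_like": igr5_tables["chicken_like"],
            "mouse_like": igr5_tables["mouse_like"],
        },
    )
    pair_entries = []
    for sp in ("chicken_like", "mouse_like"):
        table_path = os.path.join(ortho_dir, f"{anchor}__{sp}.tsv")
        write_table(sim.pairs[sp], table_path)
        mat_path = os.path.join(ortho_dir, f"maternal_{anchor}__{sp}.tsv")
        pd.DataFrame({"gene_a": sorted(sim.maternal_both[sp])}).to_csv(
            mat_path, sep="\t", index=False
        )
        pair_entries.append(
            {
                "species": sp,
                "table": os.path.join(
                    "orthologs", f"{anchor}__{sp}.tsv"
                ),
                "maternal_pairs": os.path.join(
                    "orthologs", f"maternal_{anchor}__{sp}.tsv"
                ),
            }
        )

    config = {
        "seed": seed,
        "stat": {
            "alpha": 0.05,
            "q_start": 15,
            "q_step": 5,
            "subset_anchor": "each",
        },
        "species": species_entries,
        "ortholog": {"anchor": anchor, "pairs": pair_entries},
    }
    config_path = os.path.join(outdir, "study.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
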