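"""End-to-end orchestration: per-species metrics -> gene classes ->
percentile sweeps -> ortholog rank analysis -> cross-species summaries.

A study is described by a single YAML config (paths relative to the config
file). Each species entry supplies an annotation, optionally an operon
table, one source of origin labels (a label TSV, an expression time course
with an MZT index, or a single-stage abundance table with a top-rank
fraction), a phylogenetic profile, flags and a nutrition class. Outputs
are TSV tables plus a JSON manifest; reruns with the same config produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation_io import (
    attach_operons,
    parse_annotation,
    read_operon_table,
    write_table,
)
from .gene_classes import (
    ALL_MATERNAL_MEMBERS,
    ClassifierConfig,
    classify_conservation_table,
    classify_origin_rank,
    classify_timecourse_table,
    read_label_table,
    read_profile_table,
)
from .ks_stats import StatConfig, percentile_sweep, sweep_table
from .ortholog_rank import (
    compare_maternal_vs_all,
    intersect_one_to_one,
    percentile_ranks,
    rank_fold_changes,
)
from .region_metrics import compute_region_table, metric_values
from .summaries import ratio_table, rnai_phenotype_compare

logger = logging.getLogger(__name__)

# (class_a, reference pool, metric) per conservation stratum; the UTR
# comparison uses the all-other-genes pool, the IGR comparisons the
# all-genes genome-wide pool
DEFAULT_COMPARISONS = [
    {"class_a": "all_maternal", "reference": "others", "metric": "utr3"},
    {"class_a": "strict_maternal", "reference": "all", "metric": "igr5"},
    {"class_a": "strict_zygotic", "reference": "all", "metric": "igr5"},
]


@dataclass
class SpeciesResult:
    name: str
    metrics: pd.DataFrame
    classes: pd.DataFrame
    sweeps: pd.DataFrame
    skipped_comparisons: list = field(default_factory=list)


def load_config(path: str) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))
    _resolve_paths(config, base)
    _validate_paths(config)
    return config


_PATH_KEYS = {
    "annotation",
    "operons",
    "labels",
    "expression",
    "abundance",
    "profiles",
    "taxon_kinds",
    "rnai",
    "table",
    "maternal_pairs",
}


def _resolve_paths(node, base: str) -> None:
    if isinstance(node, dict):
        for key, value in node.items():
            if key in _PATH_KEYS and isinstance(value, str):
                node[key] = os.path.join(base, value)
            else:
                _resolve_paths(value, base)
    elif isinstance(node, list):
        for item in node:
            _resolve_paths(item, base)


def _validate_paths(node) -> None:
    if isinstance(node, dict):
        for key, value in node.items():
            if key in _PATH_KEYS and isinstance(value, str):
                if not os.path.exists(value):
                    raise FileNotFoundError(
                        f"config references missing file: {value}"
                    )
            else:
                _validate_paths(value)
    elif isinstance(node, list):
        for item in node:
            _validate_paths(item)


def _origin_labels(entry: dict, classifier: ClassifierConfig) -> pd.Series:
    """Resolve the species' origin labels from whichever source the entry
    provides: labels | expression (+ mzt_index) | abundance
    (+ top_fraction)."""
    if "labels" in entry:
        return read_label_table(entry["labels"])
    if "expression" in entry:
        expr = pd.read_csv(entry["expression"], sep="\t", index_col="gene_id")
        return classify_timecourse_table(
            expr, int(entry.get("mzt_index", 1)), classifier
        )
    if "abundance" in entry:
        ab = pd.read_csv(
            entry["abundance"], sep="\t", index_col="gene_id"
        ).iloc[:, 0]
        top = classify_origin_rank(
            ab,
            float(entry.get("top_fraction", 0.5)),
            target_class="all_maternal",
            presence_call=float(entry.get("presence_call", 0.0)),
        )
        out = pd.Series("unclassified", index=ab.index, dtype=object)
        out[out.index.isin(top)] = "all_maternal"
        out.name = "origin_class"
        return out
    raise ValueError(
        f"species {entry.get('name')}: need one of labels / expression / "
        f"abundance"
    )


def _class_gene_ids(
    selector: str, origin: pd.Series, conservation: pd.Series, stratum: str
) -> set[str]:
    if selector == "all_maternal":
        ids = set(origin.index[origin.isin(ALL_MATERNAL_MEMBERS)])
    elif selector in ("core", "metazoan", "other"):
        ids = set(conservation.index[conservation == selector])
    else:
        ids = set(origin.index[origin == selector])
    if stratum:
        ids &= set(conservation.index[conservation == stratum])
    return ids


def run_species(
    entry: dict,
    stat: Optional[StatConfig] = None,
    classifier: Optional[ClassifierConfig] = None,
    comparisons: Optional[list[dict]] = None,
) -> SpeciesResult:
    """Metrics, classes and comparison sweeps for one species entry."""
    stat = stat or StatConfig()
    classifier = classifier or ClassifierConfig()
    name = entry["name"]
    flags = entry.get("flags") or {}

    annotation = parse_annotation(
        entry["annotation"], entry.get("dialect", "gff3")
    )
    operons = None
    if entry.get("operons"):
        operons = read_operon_table(entry["operons"])
        attach_operons(annotation, operons)
    metrics = compute_region_table(
        annotation, operons=operons, species_flags=flags
    )
    origin = _origin_labels(entry, classifier)
    profiles, kinds = read_profile_table(
        entry["profiles"], entry["taxon_kinds"]
    )
    conservation = classify_conservation_table(profiles, kinds)

    classes = pd.DataFrame(
        {
            "gene_id": metrics["gene_id"],
            "origin_class": metrics["gene_id"]
            .map(origin)
            .fillna("unclassified"),
            "conservation_class": metrics["gene_id"]
            .map(conservation)
            .fillna("other"),
        }
    )
    origin_s = classes.set_index("gene_id")["origin_class"]
    cons_s = classes.set_index("gene_id")["conservation_class"]

    sweep_frames = []
    skipped = []
    plan = []
    for comp in comparisons if comparisons is not None else DEFAULT_COMPARISONS:
        for stratum in ("core", "metazoan"):
            plan.append({**comp, "stratum": stratum})
    plan.append(
        {
            "class_a": "metazoan",
            "class_b": "core",
            "reference": "class",
            "metric": "igr5",
            "stratum": "",
        }
    )
    for comp in plan:
        metric = comp["metric"]
        stratum = comp.get("stratum", "")
        ids_a = _class_gene_ids(
            comp["class_a"], origin_s, cons_s, stratum
        )
        if comp["reference"] == "class":
            ids_b = _class_gene_ids(
                comp["class_b"], origin_s, cons_s, stratum
            )
            label_b = comp["class_b"]
        elif comp["reference"] == "others":
            stratum_ids = (
                set(cons_s.index[cons_s == stratum])
                if stratum
                else set(origin_s.index)
            )
            ids_b = stratum_ids - ids_a
            label_b = "others"
        else:  # genome-wide pool, class_a genes included
            ids_b = (
                set(cons_s.index[cons_s == stratum])
                if stratum
                else set(origin_s.index)
            )
            label_b = "genome"
        a = metric_values(metrics, metric, ids_a)
        b = metric_values(metrics, metric, ids_b)
        tag = (
            f"{comp['class_a']}_vs_{label_b}/{metric}"
            + (f"/{stratum}" if stratum else "")
        )
        if a.size == 0 or b.size == 0:
            logger.warning(
                "%s: comparison %s skipped (empty class)", name, tag
            )
            skipped.append(tag)
            continue
        result = percentile_sweep(a, b, stat)
        frame = sweep_table(result, comparison=tag)
        frame.insert(0, "species", name)
        sweep_frames.append(frame)
    sweeps = (
        pd.concat(sweep_frames, ignore_index=True)
        if sweep_frames
        else pd.DataFrame()
    )
    return SpeciesResult(
        name=name,
        metrics=metrics,
        classes=classes,
        sweeps=sweeps,
        skipped_comparisons=skipped,
    )


def _species_igr5(result: SpeciesResult) -> pd.Series:
    df = result.metrics
    usable = df[df["included_in_igr5_set"]]
    return usable.set_index("gene_id")["igr5"]


def run_ortholog_analysis(
    ortho_config: dict,
    species_results: dict[str, SpeciesResult],
    stat: StatConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank fold-change analysis for each configured ortholog pair,
    restricted to the 1:1:1 core across all pairs; returns (fold-change
    table, per-pair KS summary)."""
    anchor = ortho_config["anchor"]
    ranks_anchor = percentile_ranks(
        _species_igr5(species_results[anchor])
    )
    pair_entries = ortho_config["pairs"]
    tables = []
    for pe in pair_entries:
        t = pd.read_csv(pe["table"], sep="\t", dtype=str)
        tables.append(t)
    if len(tables) == 2:
        tables = list(intersect_one_to_one(tables[0], tables[1]))
    fc_frames = []
    summary_rows = []
    for pe, pairs in zip(pair_entries, tables):
        sp = pe["species"]
        ranks_b = percentile_ranks(_species_igr5(species_results[sp]))
        fcs = rank_fold_changes(pairs, ranks_anchor, ranks_b)
        maternal_ids = set(
            pd.read_csv(pe["maternal_pairs"], sep="\t", dtype=str)["gene_a"]
        ) & set(fcs["gene_a"])
        ks = compare_maternal_vs_all(fcs, maternal_ids, stat)
        fcs = fcs.assign(
            pair=f"{anchor}-{sp}",
            maternal_flag=fcs["gene_a"].isin(maternal_ids),
        )
        fc_frames.append(fcs)
        summary_rows.append(
            {
                "pair": f"{anchor}-{sp}",
                "n_pairs": len(fcs),
                "n_maternal": len(maternal_ids),
                "median_log2_fc_maternal": float(
                    fcs.loc[fcs["maternal_flag"], "log2_fc"].median()
                ),
                "median_log2_fc_all": float(fcs["log2_fc"].median()),
                "d": ks.d,
                "p": ks.p,
            }
        )
    return (
        pd.concat(fc_frames, ignore_index=True),
        pd.DataFrame(summary_rows),
    )


def run_full(config: dict, output_dir: str) -> dict:
    """Run the whole study; returns a manifest dict (also written as
    manifest.json). Individual species failures are recorded and the rest
    proceed; raises only if every species fails."""
    os.makedirs(output_dir, exist_ok=True)
    stat = StatConfig(**(config.get("stat") or {}))
    classifier = ClassifierConfig(**(config.get("classifier") or {}))
    species_results: dict[str, SpeciesResult] = {}
    failures: dict[str, str] = {}
    for entry in config["species"]:
        name = entry["name"]
        try:
            res = run_species(
                entry, stat, classifier, config.get("comparisons")
            )
        except Exception as exc:  # noqa: BLE001 - recorded per species
            logger.error("species %s failed: %s", name, exc)
            failures[name] = str(exc)
            continue
        species_results[name] = res
        sp_dir = os.path.join(output_dir, name)
        os.makedirs(sp_dir, exist_ok=True)
        write_table(res.metrics, os.path.join(sp_dir, "metrics.tsv"))
        write_table(res.classes, os.path.join(sp_dir, "classes.tsv"))
        write_table(res.sweeps, os.path.join(sp_dir, "sweeps.tsv"))
    if not species_results:
        raise RuntimeError(f"all species failed: {failures}")

    if species_results:
        combined = pd.concat(
            [r.sweeps for r in species_results.values()], ignore_index=True
        )
        write_table(combined, os.path.join(output_dir, "all_sweeps.tsv"))

    if config.get("ortholog"):
        try:
            fcs, summary = run_ortholog_analysis(
                config["ortholog"], species_results, stat
            )
            write_table(
                fcs, os.path.join(output_dir, "ortholog_fold_changes.tsv")
            )
            write_table(
                summary, os.path.join(output_dir, "ortholog_summary.tsv")
            )
        except Exception as exc:  # noqa: BLE001
            logger.error("ortholog analysis failed: %s", exc)
            failures["ortholog"] = str(exc)

    panel = []
    for entry in config["species"]:
        name = entry["name"]
        if name not in species_results:
            continue
        res = species_results[name]
        cls = res.classes.set_index("gene_id")
        ratio_class = entry.get("maternal_ratio_class", "strict_maternal")
        maternal_ids = set(
            cls.index[
                (cls["origin_class"] == ratio_class)
                & (cls["conservation_class"] == "metazoan")
            ]
        )
        if not maternal_ids and ratio_class != "all_maternal":
            maternal_ids = set(
                cls.index[
                    cls["origin_class"].isin(ALL_MATERNAL_MEMBERS)
                    & (cls["conservation_class"] == "metazoan")
                ]
            )
        genome_ids = set(cls.index[cls["conservation_class"] == "metazoan"])
        m = metric_values(res.metrics, "igr5", maternal_ids)
        g = metric_values(res.metrics, "igr5", genome_ids)
        if m.size and g.size:
            panel.append(
                {
                    "species": name,
                    "nutrition_class": entry.get("nutrition", ""),
                    "maternal_lengths": m,
                    "genome_lengths": g,
                }
            )
    if panel:
        write_table(
            ratio_table(panel), os.path.join(output_dir, "ratio_summary.tsv")
        )

    for entry in config["species"]:
        if entry.get("rnai") and entry["name"] in species_results:
            res = species_results[entry["name"]]
            phen = pd.read_csv(
                entry["rnai"], sep="\t", index_col="gene_id"
            )["phenotype"]
            cls = res.classes.set_index("gene_id")
            maternal_ids = set(
                cls.index[cls["origin_class"].isin(ALL_MATERNAL_MEMBERS)]
            )
            maternal_metrics = res.metrics[
                res.metrics["gene_id"].isin(maternal_ids)
            ]
            try:
                sweeps = rnai_phenotype_compare(maternal_metrics, phen, stat)
            except ValueError as exc:
                logger.error(
                    "rnai comparison failed for %s: %s", entry["name"], exc
                )
                failures[f"rnai:{entry['name']}"] = str(exc)
                continue
            frames = [
                sweep_table(res_, comparison=f"rnai_{metric}")
                for metric, res_ in sweeps.items()
            ]
            out = pd.concat(frames, ignore_index=True)
            out.insert(0, "species", entry["name"])
            write_table(
                out,
                os.path.join(
                    output_dir, f"rnai_compare_{entry['name']}.tsv"
                ),
            )

    manifest = {
        "mzarch_version": __version__,
        "seed": config.get("seed"),
        "stat": {
            "alpha": stat.alpha,
            "q_start": stat.q_start,
            "q_step": stat.q_step,
            "subset_anchor": stat.subset_anchor,
        },
        "inputs": _input_digests(config),
        "species_run": sorted(species_results),
        "failures": failures,
        "skipped_comparisons": {
            name: res.skipped_comparisons
            for name, res in sorted(species_results.items())
            if res.skipped_comparisons
        },
    }
    with open(os.path.join(output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _input_digests(node, out: Optional[dict] = None) -> dict:
    if out is None:
        out = {}
    if isinstance(node, dict):
        for key, value in node.items():
            if key in _PATH_KEYS and isinstance(value, str):
                with open(value, "rb") as fh:
                    digest = hashlib.sha256(fh.read()).hexdigest()
                parent = os.path.basename(os.path.dirname(value))
                out[os.path.join(parent, os.path.basename(value))] = digest
            else:
                _input_digests(value, out)
    elif isinstance(node, list):
        for item in node:
            _input_digests(item, out)
    return dict(sorted(out.items()))
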