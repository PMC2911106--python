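"""Cross-class and cross-species summary statistics.

Maternal-to-genome 5' IGR ratio: the ratio of a location measure (median,
75th percentile, or 5% trimmed mean) of maternal metazoan genes' 5' IGR
lengths to the same measure over all metazoan genes. Ratios below 1 mean
maternal genes carry less transcriptional regulatory sequence than the
genome at large. Comparing this ratio across species ordered by maternal
nutritional contribution (low / medium / high) probes whether maternal
transcriptional specificity tracks reproductive strategy.

RNAi comparison: percentile sweeps of 5' IGR and 3' UTR lengths between
maternal genes with an observed RNAi phenotype and those without, testing
whether presumed non-functional maternal genes have simpler regulatory
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .ks_stats import StatConfig, SweepResult, percentile_sweep
from .region_metrics import metric_values

MEASURES = ("median", "p75", "trimmed_mean_5")


@dataclass(frozen=True)
class RatioSummary:
    species: str
    nutrition_class: str
    measure: str
    maternal_value: float
    genome_value: float
    ratio: float


def _location(values: np.ndarray, measure: str, trim_per_tail: float) -> float:
    if measure == "median":
        return float(np.median(values))
    if measure == "p75":
        return float(np.percentile(values, 75))
    if measure == "trimmed_mean_5":
        return float(trim_mean(values, trim_per_tail))
    raise ValueError(f"unknown measure {measure!r}")


def maternal_genome_ratio(
    maternal_lengths,
    genome_lengths,
    measure: str = "median",
    *,
    species: str = "",
    nutrition_class: str = "",
    trim_per_tail: float = 0.05,
) -> RatioSummary:
    """Ratio of a location measure of maternal vs. genome-wide lengths.

    The 5% trimmed mean removes ``trim_per_tail`` of observations from each
    tail before averaging (default 5% per tail; pass 0.025 for the
    2.5%-per-tail / 5%-total convention).
    """
    m = np.asarray(maternal_lengths, dtype=float)
    g = np.asarray(genome_lengths, dtype=float)
    m = m[np.isfinite(m)]
    g = g[np.isfinite(g)]
    if m.size == 0 or g.size == 0:
        raise ValueError("both length samples must be non-empty")
    mv = _location(m, measure, trim_per_tail)
    gv = _location(g, measure, trim_per_tail)
    if gv == 0:
        raise ValueError("genome-wide location measure is zero")
    return RatioSummary(
        species=species,
        nutrition_class=nutrition_class,
        measure=measure,
        maternal_value=mv,
        genome_value=gv,
        ratio=mv / gv,
    )


def ratio_table(
    panel: list[dict], trim_per_tail: float = 0.05
) -> pd.DataFrame:
    """Species x measure ratio table.

    Each panel entry: {species, nutrition_class, maternal_lengths,
    genome_lengths}. Rows are ordered by nutrition class (low, medium,
    high), keeping the panel's own order within a class.
    """
    order = {"low": 0, "medium": 1, "high": 2}
    rows = []
    for entry in sorted(
        panel, key=lambda e: order.get(e["nutrition_class"], 9)
    ):
        for measure in MEASURES:
            rs = maternal_genome_ratio(
                entry["maternal_lengths"],
                entry["genome_lengths"],
                measure,
                species=entry["species"],
                nutrition_class=entry["nutrition_class"],
                trim_per_tail=trim_per_tail,
            )
            rows.append(
                {
                    "species": rs.species,
                    "nutrition_class": rs.nutrition_class,
                    "measure": rs.measure,
                    "maternal_value": rs.maternal_value,
                    "genome_value": rs.genome_value,
                    "ratio": rs.ratio,
                }
            )
    return pd.DataFrame(rows)


def rnai_phenotype_compare(
    maternal_metrics: pd.DataFrame,
    phenotype_table: pd.Series,
    config: Optional[StatConfig] = None,
) -> dict[str, SweepResult]:
    """Percentile sweeps (with-phenotype vs. no-phenotype) for igr5 and
    utr3 among maternal genes.

    ``phenotype_table`` maps gene_id -> {'observed', 'none'}; maternal
    genes without an entry are excluded. Direction: with-phenotype shifted
    right of no-phenotype.
    """
    config = config or StatConfig()
    values = set(phenotype_table.unique())
    if not values <= {"observed", "none"}:
        raise ValueError(
            f"phenotype values must be 'observed'/'none', got {values}"
        )
    covered = maternal_metrics[
        maternal_metrics["gene_id"].isin(phenotype_table.index)
    ]
    calls = phenotype_table.loc[covered["gene_id"]]
    with_ids = set(calls.index[calls == "observed"])
    without_ids = set(calls.index[calls == "none"])
    if not with_ids or not without_ids:
        raise ValueError("both phenotype groups must be non-empty")
    out = {}
    for metric in ("igr5", "utr3"):
        a = metric_values(covered, metric, with_ids)
        b = metric_values(covered, metric, without_ids)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty group for metric {metric}")
        out[metric] = percentile_sweep(a, b, config)
    return out
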