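"""Origin-of-synthesis and conservation gene classification.

Origin classes
--------------
``strict_maternal`` / ``strict_zygotic``: transcripts derived solely from
the maternal or the zygotic genome. ``mostly_maternal`` /
``mostly_zygotic``: profile like the strict counterpart but with a minority
(< 33% by default) contribution from the other origin. ``maternal_zygotic``:
maternally present transcripts whose abundance does not change
significantly over the time course (stable or replenished zygotically).
The ``all_maternal`` superset is every gene detected before the
maternal-to-zygotic transition (MZT).

Three classifiers cover the three kinds of source data this analysis
consumes: decoupled maternal/zygotic abundance components (chromosome-
ablation style data), plain expression time courses spanning the MZT, and
single-stage abundance rank thresholds (egg / gastrulation snapshots).
Precomputed label tables can always be supplied instead.

Conservation classes
--------------------
From a phylogenetic presence/absence profile: ``core`` = detected in at
least one unicellular organism (the prokaryote counts as unicellular here);
``metazoan`` = detected in two or more animals, absent from unicellular
organisms and from plants; everything else ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

ORIGIN_CLASSES = (
    "strict_maternal",
    "mostly_maternal",
    "maternal_zygotic",
    "mostly_zygotic",
    "strict_zygotic",
    "zygotic",
    "all_maternal",
    "unclassified",
)

# fine-grained classes whose transcripts are detectable before the MZT
ALL_MATERNAL_MEMBERS = frozenset(
    {"strict_maternal", "mostly_maternal", "maternal_zygotic", "all_maternal"}
)

CONSERVATION_CLASSES = ("core", "metazoan", "other")

TAXON_KINDS = ("unicellular", "plant", "animal")


@dataclass(frozen=True)
class ClassifierConfig:
    fold_change_min: float = 3.0
    p_max: float = 0.001
    zygotic_fraction_max: float = 0.33
    maternal_rank_top: float = 0.50
    zygotic_rank_top: float = 0.25
    presence_call: float = 50.0

    def __post_init__(self) -> None:
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must exceed 1")
        for name in ("p_max", "zygotic_fraction_max", "maternal_rank_top",
                     "zygotic_rank_top"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class PhyloProfile:
    """Presence/absence of one gene across a taxon panel."""

    gene_id: str
    presence: Mapping[str, bool]
    taxon_kind: Mapping[str, str]

    def __post_init__(self) -> None:
        kinds = list(self.taxon_kind.values())
        for taxon in self.presence:
            if taxon not in self.taxon_kind:
                raise ValueError(f"taxon {taxon} has no kind")
        if kinds.count("unicellular") < 1 or kinds.count("plant") < 1:
            raise ValueError("panel needs >=1 unicellular and >=1 plant taxon")
        if kinds.count("animal") < 2:
            raise ValueError("panel needs >=2 animal taxa")


def classify_conservation(profile: PhyloProfile) -> str:
    present_kinds = [
        profile.taxon_kind[t] for t, p in profile.presence.items() if p
    ]
    if present_kinds.count("unicellular") >= 1:
        return "core"
    if (
        present_kinds.count("animal") >= 2
        and present_kinds.count("plant") == 0
    ):
        return "metazoan"
    return "other"


def classify_conservation_table(
    profiles: pd.DataFrame, taxon_kind: Mapping[str, str]
) -> pd.Series:
    """Vectorized conservation call for a gene x taxon 0/1 matrix."""
    kinds = pd.Series({t: taxon_kind[t] for t in profiles.columns})
    uni = profiles.loc[:, kinds == "unicellular"].sum(axis=1)
    plant = profiles.loc[:, kinds == "plant"].sum(axis=1)
    animal = profiles.loc[:, kinds == "animal"].sum(axis=1)
    out = pd.Series("other", index=profiles.index, dtype=object)
    out[(animal >= 2) & (plant == 0)] = "metazoan"
    out[uni >= 1] = "core"
    out.name = "conservation_class"
    return out


def classify_origin_decoupled(
    maternal_component: float,
    zygotic_component: float,
    timecourse: Sequence[float],
    config: Optional[ClassifierConfig] = None,
    p_value: Optional[float] = None,
) -> str:
    """Classify from decoupled maternal/zygotic abundance components plus
    the gene's abundance time course.

    'Decreasing significantly' means fold change >= ``fold_change_min``
    between the first and last time points, and, when a per-gene ``p_value``
    from replicate data is supplied, p <= ``p_max`` as well.
    """
    config = config or ClassifierConfig()
    if maternal_component < 0 or zygotic_component < 0:
        raise ValueError("abundance components must be non-negative")
    tc = np.asarray(timecourse, dtype=float)
    total = maternal_component + zygotic_component
    zyg_frac = 0.0 if total == 0 else zygotic_component / total
    mat_frac = 0.0 if total == 0 else maternal_component / total

    decreasing = False
    if tc.size >= 2 and tc[-1] > 0:
        decreasing = tc[0] / tc[-1] >= config.fold_change_min
    elif tc.size >= 2 and tc[0] > 0:
        decreasing = True  # decays to zero
    if p_value is not None and p_value > config.p_max:
        decreasing = False

    if maternal_component >= config.presence_call:
        # member of the all_maternal superset
        if decreasing and zygotic_component == 0:
            return "strict_maternal"
        if decreasing and 0 < zyg_frac < config.zygotic_fraction_max:
            return "mostly_maternal"
        if not decreasing:
            return "maternal_zygotic"
        return "unclassified"
    if zygotic_component >= config.presence_call:
        if maternal_component == 0:
            return "strict_zygotic"
        if 0 < mat_frac < config.zygotic_fraction_max:
            return "mostly_zygotic"
        return "unclassified"
    return "unclassified"


def classify_origin_timecourse(
    timecourse: Sequence[float],
    mzt_index: int,
    config: Optional[ClassifierConfig] = None,
) -> str:
    """Classify from an expression time course spanning the MZT.

    ``mzt_index`` is the first post-MZT time point. Present before the MZT
    and reduced by >= ``fold_change_min`` at every post-MZT point ->
    strict_maternal; absent before and present at every point after ->
    strict_zygotic; present before and not reduced -> maternal_zygotic.
    """
    config = config or ClassifierConfig()
    tc = np.asarray(timecourse, dtype=float)
    if not 0 < mzt_index < tc.size:
        raise ValueError(
            f"mzt_index {mzt_index} needs >=1 time point on each side"
        )
    pre, post = tc[:mzt_index], tc[mzt_index:]
    pre_level = float(np.max(pre))
    pre_present = pre_level >= config.presence_call
    post_present = bool(np.all(post >= config.presence_call))
    if pre_present:
        reduced = np.all(
            pre_level >= config.fold_change_min * np.maximum(post, 1e-300)
        )
        return "strict_maternal" if reduced else "maternal_zygotic"
    if post_present:
        return "strict_zygotic"
    return "unclassified"


def classify_origin_rank(
    abundances: pd.Series,
    top_fraction: float,
    target_class: str = "all_maternal",
    presence_call: float = 0.0,
) -> set[str]:
    """Single-stage rank-threshold classifier.

    Returns the genes whose abundance rank (descending) falls within the
    top ``top_fraction`` of genes called expressed; ties at the cutoff are
    all included, so the set may exceed the nominal count.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if target_class not in ("all_maternal", "zygotic"):
        raise ValueError(f"unknown target_class {target_class!r}")
    expressed = abundances[abundances >= presence_call].astype(float)
    if expressed.empty:
        raise ValueError("no genes called expressed")
    k = int(round(top_fraction * len(expressed)))
    k = max(k, 1)
    cutoff = expressed.sort_values(ascending=False).iloc[k - 1]
    return set(expressed.index[expressed >= cutoff])


def classify_timecourse_table(
    expression: pd.DataFrame,
    mzt_index: int,
    config: Optional[ClassifierConfig] = None,
) -> pd.Series:
    """Apply the time-course classifier to a gene x time-point table."""
    config = config or ClassifierConfig()
    values = expression.to_numpy(dtype=float)
    out = [
        classify_origin_timecourse(row, mzt_index, config) for row in values
    ]
    return pd.Series(out, index=expression.index, name="origin_class")


def read_label_table(path: str) -> pd.Series:
    """Label TSV (gene_id, origin_class) -> Series indexed by gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "origin_class" not in df.columns:
        raise ValueError(
            f"label table {path} must have columns gene_id, origin_class"
        )
    bad = set(df["origin_class"]) - set(ORIGIN_CLASSES)
    if bad:
        raise ValueError(f"unknown origin classes in {path}: {sorted(bad)}")
    return df.set_index("gene_id")["origin_class"]


def read_profile_table(
    profile_path: str, taxon_kind_path: str
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Profile TSV (gene_id x taxon 0/1) plus taxon-kind TSV
    (taxon, kind)."""
    profiles = pd.read_csv(profile_path, sep="\t", index_col="gene_id")
    kinds_df = pd.read_csv(taxon_kind_path, sep="\t", dtype=str)
    kinds = dict(zip(kinds_df["taxon"], kinds_df["kind"]))
    unknown = set(kinds.values()) - set(TAXON_KINDS)
    if unknown:
        raise ValueError(f"unknown taxon kinds: {sorted(unknown)}")
    return profiles, kinds
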