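"""Percentile-rank normalization of 5' IGR lengths and fold change of rank
across 1:1 ortholog pairs.

Ranking within each genome removes absolute genome-size differences:
rank(g) = (average rank of g's 5' IGR length among all usable genes) / n,
ascending (short IGR = low rank), ties averaged, so ranks lie in (0, 1].
For a 1:1 ortholog pair the log2 ratio of the two within-genome ranks is
the fold change in percentile ranking; 0 means the gene's 5' IGR occupies
the same relative position in both genomes.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ks_stats import KsResult, StatConfig, ks_one_sided

logger = logging.getLogger(__name__)


def percentile_ranks(lengths: pd.Series) -> pd.Series:
    """Ascending average-rank percentiles in (0, 1]; censored (NaN) genes
    are excluded. Any strictly monotone transform of the lengths yields an
    identical rank table."""
    usable = lengths.dropna().astype(float)
    if len(usable) < 2:
        raise ValueError("need at least 2 genes with usable lengths")
    ranks = rankdata(usable.to_numpy(), method="average") / len(usable)
    out = pd.Series(ranks, index=usable.index, name="percentile_rank")
    return out


def rank_fold_changes(
    pairs: pd.DataFrame, ranks_a: pd.Series, ranks_b: pd.Series
) -> pd.DataFrame:
    """log2 rank ratio per 1:1 ortholog pair.

    ``pairs`` has columns gene_a, gene_b. Pairs with a censored member
    (absent from either rank table) are dropped with a count logged;
    duplicated genes violate the 1:1 premise and raise.
    """
    for col in ("gene_a", "gene_b"):
        if col not in pairs.columns:
            raise ValueError("pairs table must have columns gene_a, gene_b")
        if pairs[col].duplicated().any():
            dup = pairs[col][pairs[col].duplicated()].iloc[0]
            raise ValueError(
                f"gene {dup} appears in more than one pair ({col}); "
                f"table is not 1:1"
            )
    ra = pairs["gene_a"].map(ranks_a)
    rb = pairs["gene_b"].map(ranks_b)
    keep = ra.notna() & rb.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "rank_fold_changes: dropped %d/%d pairs with a censored member",
            n_dropped,
            len(pairs),
        )
    out = pairs.loc[keep, ["gene_a", "gene_b"]].copy()
    out["log2_fc"] = np.log2(ra[keep].to_numpy() / rb[keep].to_numpy())
    return out.reset_index(drop=True)


def compare_maternal_vs_all(
    fcs_all: pd.DataFrame,
    maternal_pair_ids: set[str],
    config: Optional[StatConfig] = None,
) -> KsResult:
    """One-sided KS of the maternal pairs' log2 fold changes against the
    full pair set, direction 'maternal shifted right'.

    ``maternal_pair_ids`` identifies pairs by their gene_a member (unique
    under the 1:1 premise): pairs whose gene is maternal in both species.
    """
    if not maternal_pair_ids:
        raise ValueError("maternal pair set is empty")
    unknown = maternal_pair_ids - set(fcs_all["gene_a"])
    if unknown:
        raise ValueError(
            f"maternal pair ids not in fold-change table: "
            f"{sorted(unknown)[:5]}"
        )
    maternal = fcs_all.loc[
        fcs_all["gene_a"].isin(maternal_pair_ids), "log2_fc"
    ]
    return ks_one_sided(
        maternal.to_numpy(), fcs_all["log2_fc"].to_numpy(), config
    )


def fold_change_deciles(fcs: pd.DataFrame) -> pd.DataFrame:
    """Empirical-CDF summary of log2 fold changes tabulated at deciles."""
    qs = np.arange(0.1, 1.0, 0.1)
    vals = np.quantile(fcs["log2_fc"].to_numpy(), qs)
    return pd.DataFrame({"decile": np.round(qs, 1), "log2_fc": vals})


def intersect_one_to_one(
    pairs_ab: pd.DataFrame, pairs_ac: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two pairwise 1:1 tables to the 1:1:1 core by intersecting
    on the anchor species (gene_a)."""
    common = set(pairs_ab["gene_a"]) & set(pairs_ac["gene_a"])
    return (
        pairs_ab[pairs_ab["gene_a"].isin(common)].reset_index(drop=True),
        pairs_ac[pairs_ac["gene_a"].isin(common)].reset_index(drop=True),
    )
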