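"""Regulatory-region length metrics.

Per gene, from coordinate arithmetic on the annotation alone:

* 5' IGR: bases strictly between the gene's 5'-most coding nucleotide and
  the nearest coding nucleotide of a *different* gene lying in the gene's
  5' direction, on either strand. 0 when another gene's coding sequence
  abuts or overlaps; censored when no coding neighbor exists in that
  direction on the chromosome.
* 3' IGR: the mirror image in the 3' direction, measured from the 3'-most
  coding base across isoforms.
* First-intron measures: the largest first intron across isoforms, and the
  largest continuous non-coding run inside that intron (non-coding with
  respect to every gene's coding intervals, so nested genes shorten it).
* UTR lengths: per-gene maximum of per-transcript total UTR length; 3' UTRs
  spanning more than one exon are excluded from the maximum by default;
  post-maximum values under the artifact thresholds (3' UTR < 5 bp,
  5' UTR < 3 bp) are reported absent.
* Combined variants: igr5+intron1, igr5+igr3, igr5+intron1+igr3 as
  alternative transcriptional-region estimates, utr5+utr3 as the total
  post-transcriptional estimate (omitted for trans-spliced species, where
  5' UTRs are replaced by spliced leaders and the sum is not meaningful).

Genes inside an operon keep their raw igr5 value but are flagged
``included_in_igr5_set = False`` unless they are the 5'-most (position 1)
member, since internal operon genes have no individual promoter region.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd

from .models import GeneModel, GenomeAnnotation

logger = logging.getLogger(__name__)

CENSORED = float("nan")

COMBINED_VARIANTS = (
    "igr5_plus_intron1",
    "igr5_plus_igr3",
    "igr5_plus_intron1_plus_igr3",
    "utr5_plus_utr3",
)


def five_prime_igr(
    gene: GeneModel, annotation: GenomeAnnotation
) -> Optional[int]:
    """5' IGR length in bp, or None when censored (no coding neighbor in
    the 5' direction)."""
    if gene.gene_id not in annotation:
        raise KeyError(f"gene {gene.gene_id} not in annotation")
    index = annotation.coding_index(gene.chrom)
    if gene.strand == "+":
        p = gene.cds_union[0][0]
        e = index.max_end_leq(p, exclude=gene.gene_id)
        return None if e is None else max(0, p - e)
    q = gene.cds_union[-1][1]
    s = index.min_start_geq(q, exclude=gene.gene_id)
    return None if s is None else max(0, s - q)


def three_prime_igr(
    gene: GeneModel, annotation: GenomeAnnotation
) -> Optional[int]:
    """3' IGR length in bp, or None when censored."""
    if gene.gene_id not in annotation:
        raise KeyError(f"gene {gene.gene_id} not in annotation")
    index = annotation.coding_index(gene.chrom)
    if gene.strand == "+":
        q = gene.cds_union[-1][1]
        s = index.min_start_geq(q, exclude=gene.gene_id)
        return None if s is None else max(0, s - q)
    p = gene.cds_union[0][0]
    e = index.max_end_leq(p, exclude=gene.gene_id)
    return None if e is None else max(0, p - e)


def first_intron_lengths(
    gene: GeneModel, annotation: Optional[GenomeAnnotation] = None
) -> tuple[int, int]:
    """(intron1_max, intron1_noncoding) in bp; (0, 0) for intronless genes.

    ``intron1_max`` is the largest first-intron length across isoforms.
    ``intron1_noncoding`` is the largest run of bases within that maximal
    first intron covered by no gene's coding interval; without an
    annotation context it equals the intron length.
    """
    best: Optional[tuple[int, int]] = None
    for tx in gene.transcripts:
        iv = tx.first_intron
        if iv is None:
            continue
        if best is None or iv[1] - iv[0] > best[1] - best[0]:
            best = iv
    if best is None:
        return (0, 0)
    length = best[1] - best[0]
    if annotation is None:
        return (length, length)
    return (length, _max_noncoding_run(best, gene.chrom, annotation))


def _max_noncoding_run(
    interval: tuple[int, int], chrom: str, annotation: GenomeAnnotation
) -> int:
    s0, e0 = interval
    coding = [
        (max(s, s0), min(e, e0))
        for s, e, _ in annotation.coding_intervals(chrom)
        if e > s0 and s < e0
    ]
    coding.sort()
    best, cursor = 0, s0
    for s, e in coding:
        best = max(best, s - cursor)
        cursor = max(cursor, e)
    return max(best, e0 - cursor)


def utr_lengths(
    gene: GeneModel,
    allow_multiexon_utr3: bool = False,
    utr3_min: int = 5,
    utr5_min: int = 3,
) -> tuple[Optional[int], Optional[int], bool]:
    """(utr3, utr5, utr3_multiexon) for one gene.

    Per-gene UTR length is the maximum of per-transcript total UTR length.
    Transcripts whose 3' UTR spans more than one exon are excluded from the
    3' UTR maximum unless ``allow_multiexon_utr3``. Post-maximum values
    under the artifact thresholds are reported as None (absent);
    ``utr3_multiexon`` is True when any isoform's 3' UTR is multi-exon.
    """
    utr3_candidates: list[int] = []
    utr5_candidates: list[int] = []
    multiexon = False
    for tx in gene.transcripts:
        segs3 = tx.utr3_segments
        if len(segs3) > 1:
            multiexon = True
        if segs3 and (allow_multiexon_utr3 or len(segs3) == 1):
            utr3_candidates.append(sum(e - s for s, e in segs3))
        segs5 = tx.utr5_segments
        if segs5:
            utr5_candidates.append(sum(e - s for s, e in segs5))
    utr3 = max(utr3_candidates, default=None)
    utr5 = max(utr5_candidates, default=None)
    if utr3 is not None and utr3 < utr3_min:
        utr3 = None
    if utr5 is not None and utr5 < utr5_min:
        utr5 = None
    return utr3, utr5, multiexon


def compute_region_table(
    annotation: GenomeAnnotation,
    operons: Optional[pd.DataFrame] = None,
    species_flags: Optional[dict] = None,
    *,
    allow_multiexon_utr3: bool = False,
    utr3_min: int = 5,
    utr5_min: int = 3,
    utr3_allowlist: Optional[set[str]] = None,
) -> pd.DataFrame:
    """One row of region-length metrics per coding gene.

    ``operons``: optional table (gene_id, operon_id, position); only the
    position-1 member of each operon keeps ``included_in_igr5_set=True``.
    ``species_flags``: e.g. ``{"trans_spliced": True}`` drops the
    utr5_plus_utr3 combined column (worm mode). ``utr3_allowlist``
    restricts which genes may report a 3' UTR (generalization of
    annotation-confidence filters such as a RefSeq-backed gene list).
    """
    flags = species_flags or {}
    operon_info: dict[str, tuple[str, int]] = {}
    if operons is not None:
        for row in operons.itertuples(index=False):
            if row.gene_id not in annotation:
                raise KeyError(
                    f"operon table references unknown gene {row.gene_id}"
                )
            operon_info[row.gene_id] = (row.operon_id, int(row.position))

    records = []
    genes = sorted(
        annotation.genes.values(), key=lambda g: (g.chrom, g.span, g.gene_id)
    )
    for gene in genes:
        igr5 = five_prime_igr(gene, annotation)
        igr3 = three_prime_igr(gene, annotation)
        intron1_max, intron1_noncoding = first_intron_lengths(
            gene, annotation
        )
        utr3, utr5, multiexon = utr_lengths(
            gene,
            allow_multiexon_utr3=allow_multiexon_utr3,
            utr3_min=utr3_min,
            utr5_min=utr5_min,
        )
        if utr3_allowlist is not None and gene.gene_id not in utr3_allowlist:
            utr3 = None
        reasons = []
        if igr5 is None:
            reasons.append("igr5:no_coding_neighbor_5prime")
        if igr3 is None:
            reasons.append("igr3:no_coding_neighbor_3prime")

        op = operon_info.get(gene.gene_id)
        included = op is None or op[1] == 1

        rec = {
            "gene_id": gene.gene_id,
            "chrom": gene.chrom,
            "strand": gene.strand,
            "igr5": CENSORED if igr5 is None else float(igr5),
            "igr3": CENSORED if igr3 is None else float(igr3),
            "intron1_max": float(intron1_max),
            "intron1_noncoding": float(intron1_noncoding),
            "utr5": CENSORED if utr5 is None else float(utr5),
            "utr3": CENSORED if utr3 is None else float(utr3),
            "utr3_multiexon": bool(multiexon),
            "igr5_plus_intron1": (
                CENSORED if igr5 is None else float(igr5 + intron1_max)
            ),
            "igr5_plus_igr3": (
                CENSORED
                if igr5 is None or igr3 is None
                else float(igr5 + igr3)
            ),
            "igr5_plus_intron1_plus_igr3": (
                CENSORED
                if igr5 is None or igr3 is None
                else float(igr5 + intron1_max + igr3)
            ),
            "utr5_plus_utr3": (
                CENSORED
                if utr5 is None or utr3 is None
                else float(utr5 + utr3)
            ),
            "included_in_igr5_set": included,
            "operon_id": op[0] if op else "",
            "censored_reason": ";".join(reasons),
        }
        records.append(rec)

    df = pd.DataFrame.from_records(records)
    logger.info(
        "region table: %d genes; igr5 censored %d, igr3 censored %d; "
        "operon-excluded from igr5 set %d; utr3 present %d "
        "(multi-exon flagged %d), utr5 present %d",
        len(df),
        int(df["igr5"].isna().sum()),
        int(df["igr3"].isna().sum()),
        int((~df["included_in_igr5_set"]).sum()),
        int(df["utr3"].notna().sum()),
        int(df["utr3_multiexon"].sum()),
        int(df["utr5"].notna().sum()),
    )
    if flags.get("trans_spliced"):
        df = df.drop(columns=["utr5_plus_utr3"])
    return df


def metric_values(
    table: pd.DataFrame, metric: str, gene_ids: Optional[set[str]] = None
) -> np.ndarray:
    """Finite values of one metric column, applying that metric's inclusion
    rules (operon rule for igr5-containing metrics), optionally restricted
    to a gene set."""
    df = table
    if gene_ids is not None:
        df = df[df["gene_id"].isin(gene_ids)]
    if metric.startswith("igr5"):
        df = df[df["included_in_igr5_set"]]
    values = df[metric].to_numpy(dtype=float)
    return values[np.isfinite(values)]
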