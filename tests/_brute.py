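"""Per-base brute-force oracle for the region-length metrics.

Independent of the interval-index implementation: every question is
answered by materializing per-base coding masks for a whole chromosome and
scanning them, so agreement with the production code validates the interval
arithmetic end to end.
"""

from __future__ import annotations

from typing import Optional

import numpy as np


def merged_cds(gene) -> list[list[int]]:
    ivs = []
    for tx in gene.transcripts:
        for s, e in tx.exons:
            s2, e2 = max(s, tx.cds_start), min(e, tx.cds_end)
            if e2 > s2:
                ivs.append([s2, e2])
    ivs.sort()
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def chrom_coding_count(annotation, chrom: str) -> np.ndarray:
    """Per-base count of genes whose coding sequence covers the base."""
    genes = [g for g in annotation if g.chrom == chrom]
    length = max(g.span[1] for g in genes) + 2
    count = np.zeros(length, dtype=np.int32)
    for g in genes:
        for s, e in merged_cds(g):
            count[s:e] += 1
    return count


def other_coding_mask(count: np.ndarray, gene) -> np.ndarray:
    m = count.copy()
    for s, e in merged_cds(gene):
        m[s:e] -= 1
    return m > 0


def brute_igr5(gene, mask: np.ndarray) -> Optional[int]:
    cds = merged_cds(gene)
    if gene.strand == "+":
        p = cds[0][0]
        hits = np.nonzero(mask[: p + 1])[0]
        if hits.size == 0:
            return None
        return max(0, p - int(hits[-1]) - 1)
    p = cds[-1][1] - 1
    hits = np.nonzero(mask[p:])[0]
    if hits.size == 0:
        return None
    return max(0, int(hits[0]) - 1)


def brute_igr3(gene, mask: np.ndarray) -> Optional[int]:
    cds = merged_cds(gene)
    if gene.strand == "+":
        p = cds[-1][1] - 1
        hits = np.nonzero(mask[p:])[0]
        if hits.size == 0:
            return None
        return max(0, int(hits[0]) - 1)
    p = cds[0][0]
    hits = np.nonzero(mask[: p + 1])[0]
    if hits.size == 0:
        return None
    return max(0, p - int(hits[-1]) - 1)


def _tx_first_intron(tx) -> Optional[tuple[int, int]]:
    introns = [
        (e0, s1) for (_, e0), (s1, _) in zip(tx.exons, tx.exons[1:])
    ]
    if tx.strand == "+":
        cands = [iv for iv in introns if iv[0] >= tx.cds_start]
        return min(cands, default=None)
    cands = [iv for iv in introns if iv[1] < tx.cds_end]
    if not cands:
        return None
    return max(cands, key=lambda iv: iv[1])


def brute_first_intron(gene, count: np.ndarray) -> tuple[int, int]:
    best = None
    for tx in gene.transcripts:
        iv = _tx_first_intron(tx)
        if iv is None:
            continue
        if best is None or iv[1] - iv[0] > best[1] - best[0]:
            best = iv
    if best is None:
        return (0, 0)
    s, e = best
    noncoding = count[s:e] == 0
    # longest run of True
    best_run = run = 0
    for flag in noncoding:
        run = run + 1 if flag else 0
        best_run = max(best_run, run)
    return (e - s, best_run)


def _tx_utr_lengths(tx) -> tuple[int, int, int, int]:
    """(utr5_len, utr5_nseg, utr3_len, utr3_nseg) for one transcript."""
    left = []
    right = []
    for s, e in tx.exons:
        if min(e, tx.cds_start) > s:
            left.append((s, min(e, tx.cds_start)))
        if e > max(s, tx.cds_end):
            right.append((max(s, tx.cds_end), e))
    u5, u3 = (left, right) if tx.strand == "+" else (right, left)
    return (
        sum(e - s for s, e in u5),
        len(u5),
        sum(e - s for s, e in u3),
        len(u3),
    )


def brute_utr(
    gene,
    allow_multiexon_utr3: bool = False,
    utr3_min: int = 5,
    utr5_min: int = 3,
) -> tuple[Optional[int], Optional[int], bool]:
    utr3s, utr5s = [], []
    multiexon = False
    for tx in gene.transcripts:
        u5, _, u3, n3 = _tx_utr_lengths(tx)
        if n3 > 1:
            multiexon = True
        if u3 > 0 and (allow_multiexon_utr3 or n3 == 1):
            utr3s.append(u3)
        if u5 > 0:
            utr5s.append(u5)
    utr3 = max(utr3s) if utr3s else None
    utr5 = max(utr5s) if utr5s else None
    if utr3 is not None and utr3 < utr3_min:
        utr3 = None
    if utr5 is not None and utr5 < utr5_min:
        utr5 = None
    return utr3, utr5, multiexon


def check_genome_against_oracle(annotation, table) -> list[str]:
    """Compare every metric row against the brute-force values; returns a
    list of mismatch descriptions (empty = full agreement)."""
    import math

    mismatches = []
    counts = {
        chrom: chrom_coding_count(annotation, chrom)
        for chrom in annotation.chroms
    }

    def eq(x, y) -> bool:
        if y is None:
            return isinstance(x, float) and math.isnan(x)
        return x == y

    for row in table.itertuples(index=False):
        gene = annotation[row.gene_id]
        count = counts[gene.chrom]
        mask = other_coding_mask(count, gene)
        expected = {
            "igr5": brute_igr5(gene, mask),
            "igr3": brute_igr3(gene, mask),
        }
        i1, i1nc = brute_first_intron(gene, count)
        expected["intron1_max"] = i1
        expected["intron1_noncoding"] = i1nc
        u3, u5, multi = brute_utr(gene)
        expected["utr3"] = u3
        expected["utr5"] = u5
        expected["utr3_multiexon"] = multi
        for key, want in expected.items():
            got = getattr(row, key)
            if not eq(got, want):
                mismatches.append(
                    f"{row.gene_id}.{key}: got {got!r}, oracle {want!r}"
                )
    return mismatches
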