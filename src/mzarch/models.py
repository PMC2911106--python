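"""Gene-model containers.

All coordinates are 0-based half-open genomic intervals. GFF3/GTF input
(1-based inclusive) is converted at the parsing boundary, so every distance
below is plain end-minus-start arithmetic with no off-by-one cases.

Only protein-coding structure is modelled: a transcript is its exon chain
plus the genomic span of its CDS; UTR segments are derived from the two.
Genes entirely lacking CDS annotation are excluded upstream (recorded as
skipped by the parser) because every metric in this package is anchored on
coding nucleotides.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Optional

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input."""


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Union of intervals as a sorted tuple of maximal disjoint intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: exon chain plus CDS genomic span.

    ``cds_start``/``cds_end`` bound the translated region in genomic
    coordinates (half-open, strand-independent). UTR segments are the exon
    pieces outside that span; which side is 5' vs 3' depends on strand.
    """

    transcript_id: str
    strand: str
    exons: tuple[Interval, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        object.__setattr__(self, "exons", exons)
        for (s, e) in exons:
            if e <= s:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty exon [{s}, {e})"
                )
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        if not self.cds_start < self.cds_end:
            raise AnnotationError(
                f"transcript {self.transcript_id}: empty CDS span"
            )
        if not (
            self._in_exon(self.cds_start) and self._in_exon(self.cds_end - 1)
        ):
            raise AnnotationError(
                f"transcript {self.transcript_id}: CDS outside exons"
            )

    def _in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    @cached_property
    def cds_segments(self) -> tuple[Interval, ...]:
        """Exon pieces overlapping the CDS span: the coding intervals."""
        segs = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if e2 > s2:
                segs.append((s2, e2))
        return tuple(segs)

    @cached_property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    def _utr_segments(self, left: bool) -> tuple[Interval, ...]:
        segs = []
        for s, e in self.exons:
            if left:
                s2, e2 = s, min(e, self.cds_start)
            else:
                s2, e2 = max(s, self.cds_end), e
            if e2 > s2:
                segs.append((s2, e2))
        return tuple(segs)

    @cached_property
    def utr5_segments(self) -> tuple[Interval, ...]:
        return self._utr_segments(left=self.strand == "+")

    @cached_property
    def utr3_segments(self) -> tuple[Interval, ...]:
        return self._utr_segments(left=self.strand == "-")

    @cached_property
    def first_intron(self) -> Optional[Interval]:
        """The intron closest downstream (in transcript orientation) of the
        translation start, or None when no intron lies 3' of it."""
        if self.strand == "+":
            cands = [iv for iv in self.introns if iv[0] >= self.cds_start]
            return min(cands, default=None)
        cands = [iv for iv in self.introns if iv[1] < self.cds_end]
        return max(cands, key=lambda iv: iv[1], default=None)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]
    operon_id: Optional[str] = None
    operon_position: Optional[int] = None

    def __post_init__(self) -> None:
        # canonical isoform order so equality is representation-independent
        self.transcripts = tuple(
            sorted(
                self.transcripts,
                key=lambda t: (t.exons[0][0], t.exons[-1][1], t.transcript_id),
            )
        )
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")
        for tx in self.transcripts:
            if tx.strand != self.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: transcript {tx.transcript_id} "
                    f"strand mismatch"
                )
        if (self.operon_id is None) != (self.operon_position is None):
            raise AnnotationError(
                f"gene {self.gene_id}: operon_id and operon_position must be "
                f"set together"
            )

    @cached_property
    def cds_union(self) -> tuple[Interval, ...]:
        """Union over isoforms of coding intervals (merged, sorted).

        A 'coding nucleotide' of this gene is any base covered by any
        isoform's CDS.
        """
        return merge_intervals(
            seg for tx in self.transcripts for seg in tx.cds_segments
        )

    @property
    def span(self) -> Interval:
        s = min(tx.exons[0][0] for tx in self.transcripts)
        e = max(tx.exons[-1][1] for tx in self.transcripts)
        return (s, e)

    @property
    def five_prime_coding_pos(self) -> int:
        """Genomic position of the 5'-most coding base (gene orientation)."""
        if self.strand == "+":
            return self.cds_union[0][0]
        return self.cds_union[-1][1] - 1

    @property
    def three_prime_coding_pos(self) -> int:
        if self.strand == "+":
            return self.cds_union[-1][1] - 1
        return self.cds_union[0][0]


class _Top2:
    """Prefix/suffix accumulator of the two best values with distinct owners.

    Lets a query ask for the best value among intervals NOT owned by one
    given gene: if the best entry is owned by the excluded gene, the
    second-best (which by construction has a different owner) answers.
    """

    __slots__ = ("b_v", "b_o", "s_v", "s_o", "better")

    def __init__(self, better):
        self.b_v = None
        self.b_o = None
        self.s_v = None
        self.s_o = None
        self.better = better

    def add(self, v, o) -> None:
        better = self.better
        if self.b_v is None or o == self.b_o:
            if self.b_v is None or better(v, self.b_v):
                self.b_v = v
            self.b_o = o
        elif better(v, self.b_v):
            self.s_v, self.s_o = self.b_v, self.b_o
            self.b_v, self.b_o = v, o
        elif o == self.s_o:
            if better(v, self.s_v):
                self.s_v = v
        elif self.s_v is None or better(v, self.s_v):
            self.s_v, self.s_o = v, o

    def query(self, exclude):
        if self.b_o is not None and self.b_o != exclude:
            return self.b_v
        return self.s_v

    def snapshot(self) -> tuple:
        return (self.b_v, self.b_o, self.s_v, self.s_o)


class _ChromCodingIndex:
    """Sorted coding-interval index for one chromosome.

    Supports the two neighbor queries the IGR metrics need, each excluding
    the querying gene's own intervals:

    * max end over intervals with start <= pos  (nearest coding base at or
      left of ``pos``; the interval's last base is ``end - 1``)
    * min start over intervals with end >= pos  (nearest coding base at or
      right of ``pos - 1``)
    """

    def __init__(self, triples: list[tuple[int, int, str]]):
        by_start = sorted(triples)
        self._starts = [t[0] for t in by_start]
        acc = _Top2(lambda a, b: a > b)
        self._prefix_max_end: list[tuple] = []
        for s, e, g in by_start:
            acc.add(e, g)
            self._prefix_max_end.append(acc.snapshot())

        by_end = sorted(triples, key=lambda t: (t[1], t[0], t[2]))
        self._ends = [t[1] for t in by_end]
        acc = _Top2(lambda a, b: a < b)
        suffix: list[tuple] = []
        for s, e, g in reversed(by_end):
            acc.add(s, g)
            suffix.append(acc.snapshot())
        self._suffix_min_start = suffix[::-1]

    @staticmethod
    def _resolve(snapshot: tuple, exclude: str):
        b_v, b_o, s_v, _ = snapshot
        if b_o is not None and b_o != exclude:
            return b_v
        return s_v

    def max_end_leq(self, pos: int, exclude: str) -> Optional[int]:
        i = bisect_right(self._starts, pos)
        if i == 0:
            return None
        return self._resolve(self._prefix_max_end[i - 1], exclude)

    def min_start_geq(self, pos: int, exclude: str) -> Optional[int]:
        i = bisect_left(self._ends, pos)
        if i == len(self._ends):
            return None
        return self._resolve(self._suffix_min_start[i], exclude)


class GenomeAnnotation:
    """A collection of coding genes plus a per-chromosome coding index."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        skipped: Optional[dict[str, str]] = None,
    ):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.skipped: dict[str, str] = dict(skipped or {})
        self._indexes: dict[str, _ChromCodingIndex] = {}
        self._intervals: dict[str, list[tuple[int, int, str]]] = {}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id} not in annotation") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self.genes == other.genes

    @property
    def chroms(self) -> list[str]:
        return sorted({g.chrom for g in self})

    def coding_intervals(self, chrom: str) -> list[tuple[int, int, str]]:
        """Coordinate-sorted (start, end, gene_id) coding intervals of every
        gene on ``chrom``, both strands merged into one list.

        Each gene contributes the merged union of its isoforms' coding
        segments; intervals of different genes may overlap each other.
        """
        if chrom not in {g.chrom for g in self}:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if chrom not in self._intervals:
            triples = [
                (s, e, g.gene_id)
                for g in self
                if g.chrom == chrom
                for s, e in g.cds_union
            ]
            triples.sort()
            self._intervals[chrom] = triples
        return list(self._intervals[chrom])

    def coding_index(self, chrom: str) -> _ChromCodingIndex:
        if chrom not in self._indexes:
            self._indexes[chrom] = _ChromCodingIndex(
                self.coding_intervals(chrom)
            )
        return self._indexes[chrom]
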