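"""Read GFF3/GTF annotation into :class:`~mzarch.models.GenomeAnnotation`
and write gene models and per-gene tables back out as text.

Parsing is delegated to :mod:`gffutils` (in-memory sqlite feature db); this
module only validates structure, converts 1-based inclusive coordinates to
the internal 0-based half-open convention, and assembles the dataclasses.
"""

from __future__ import annotations

import os
from typing import Optional

import gffutils
import pandas as pd

from .models import (
    AnnotationError,
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
)

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _prevalidate(path: str) -> None:
    """Cheap structural scan so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: expected 9 tab-"
                    f"separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: non-integer "
                    f"coordinates"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: bad coordinate range "
                    f"{start}..{end}"
                )


def parse_annotation(path: str, dialect: str = "gff3") -> GenomeAnnotation:
    """Parse a GFF3 or GTF file into a :class:`GenomeAnnotation`.

    Every gene with at least one CDS-bearing transcript is represented;
    genes without any CDS are recorded in ``annotation.skipped`` with a
    reason. Input coordinates (1-based inclusive) are converted to 0-based
    half-open.
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"dialect must be 'gff3' or 'gtf', got {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _prevalidate(path)

    infer = dialect == "gtf"
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=not infer,
        disable_infer_transcripts=not infer,
    )

    gene_ids = {f.id for f in db.features_of_type("gene")}
    for ttype in _TRANSCRIPT_TYPES:
        for tx in db.features_of_type(ttype):
            parents = [p.id for p in db.parents(tx, featuretype="gene")]
            if not parents:
                raise AnnotationError(
                    f"transcript {tx.id} has no parent gene"
                )

    genes: list[GeneModel] = []
    skipped: dict[str, str] = {}
    for gf in db.features_of_type("gene"):
        transcripts = []
        for ttype in _TRANSCRIPT_TYPES:
            for tx in db.children(gf, featuretype=ttype, order_by="start"):
                exons = [
                    (ex.start - 1, ex.end)
                    for ex in db.children(
                        tx, featuretype="exon", order_by="start"
                    )
                ]
                cds = [
                    (c.start - 1, c.end)
                    for c in db.children(
                        tx, featuretype="CDS", order_by="start"
                    )
                ]
                if not cds:
                    continue
                if not exons:
                    # CDS-only annotation: treat CDS segments as exons.
                    exons = cds
                transcripts.append(
                    TranscriptModel(
                        transcript_id=tx.id,
                        strand=gf.strand,
                        exons=tuple(exons),
                        cds_start=min(s for s, _ in cds),
                        cds_end=max(e for _, e in cds),
                    )
                )
        if not transcripts:
            skipped[gf.id] = "no CDS-bearing transcript"
            continue
        genes.append(
            GeneModel(
                gene_id=gf.id,
                chrom=gf.seqid,
                strand=gf.strand,
                transcripts=tuple(transcripts),
            )
        )
    if not gene_ids and not genes:
        raise AnnotationError(f"{path}: no gene features found")
    return GenomeAnnotation(genes, skipped=skipped)


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Write the annotation as GFF3 (deterministic feature order).

    Re-parsing the output reconstructs an equal :class:`GenomeAnnotation`
    (operon membership is carried in a separate table, not in the GFF3).
    """
    genes = sorted(
        annotation.genes.values(), key=lambda g: (g.chrom, g.span, g.gene_id)
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            fh.write(
                _line(g.chrom, "gene", gs, ge, g.strand, f"ID={g.gene_id}")
            )
            for tx in g.transcripts:
                ts, te = tx.exons[0][0], tx.exons[-1][1]
                fh.write(
                    _line(
                        g.chrom,
                        "mRNA",
                        ts,
                        te,
                        g.strand,
                        f"ID={tx.transcript_id};Parent={g.gene_id}",
                    )
                )
                for s, e in tx.exons:
                    fh.write(
                        _line(
                            g.chrom,
                            "exon",
                            s,
                            e,
                            g.strand,
                            f"Parent={tx.transcript_id}",
                        )
                    )
                for s, e in tx.cds_segments:
                    fh.write(
                        _line(
                            g.chrom,
                            "CDS",
                            s,
                            e,
                            g.strand,
                            f"Parent={tx.transcript_id}",
                        )
                    )
                for kind, segs in (
                    ("five_prime_UTR", tx.utr5_segments),
                    ("three_prime_UTR", tx.utr3_segments),
                ):
                    for s, e in segs:
                        fh.write(
                            _line(
                                g.chrom,
                                kind,
                                s,
                                e,
                                g.strand,
                                f"Parent={tx.transcript_id}",
                            )
                        )


def _line(chrom, ftype, start0, end0, strand, attrs) -> str:
    # internal 0-based half-open -> GFF3 1-based inclusive
    return (
        f"{chrom}\tmzarch\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t"
        f".\t{attrs}\n"
    )


def read_operon_table(path: str) -> pd.DataFrame:
    """3-column TSV: gene_id, operon_id, position (1 = 5'-most gene)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "operon_id": str})
    required = {"gene_id", "operon_id", "position"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"operon table {path} must have columns {sorted(required)}"
        )
    df["position"] = df["position"].astype(int)
    return df


def attach_operons(
    annotation: GenomeAnnotation, operons: pd.DataFrame
) -> None:
    """Set operon membership on the gene models in place."""
    for row in operons.itertuples(index=False):
        if row.gene_id not in annotation:
            raise AnnotationError(
                f"operon table references unknown gene {row.gene_id}"
            )
        gene = annotation[row.gene_id]
        gene.operon_id = row.operon_id
        gene.operon_position = int(row.position)


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a per-gene table as TSV with a header row; missing values as
    NA. Output is deterministic for a given frame."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
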