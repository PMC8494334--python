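"""Readers/writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open (BED convention) everywhere in memory;
GFF3 is emitted and read 1-based inclusive per its standard.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from telocus.ids import parse_te_id

if TYPE_CHECKING:  # pragma: no cover
    from telocus.synth import Gene, TEAnnotation

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_te_bed",
    "read_te_bed",
    "write_gene_gff3",
    "read_gene_gff3",
    "write_fastq",
]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_te_bed(tes: Iterable["TEAnnotation"], path: str | Path) -> None:
    """BED6; the name field is the pipe-delimited TE identifier."""
    with open(path, "w") as fh:
        for te in tes:
            fh.write(
                f"{te.chrom}\t{te.start}\t{te.end}\t{te.te_id}\t{te.score}\t{te.strand}\n"
            )


def read_te_bed(path: str | Path) -> list["TEAnnotation"]:
    from telocus.synth import TEAnnotation

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            tid = parse_te_id(name)
            out.append(
                TEAnnotation(
                    te_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    subfamily=tid.subfamily,
                    family=tid.family,
                    te_class=tid.te_class,
                    consensus_id="",
                    divergence_pct=tid.score / 10.0,
                    score=int(score),
                )
            )
    return out


def write_gene_gff3(genes: Iterable["Gene"], path: str | Path) -> None:
    """gene/mRNA/exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\ttelocus\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\ttelocus\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\ttelocus\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )


def read_gene_gff3(path: str | Path) -> list["Gene"]:
    from telocus.synth import Gene

    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    mrna_parent: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = fields["ID"]
                meta[gid] = (chrom, strand)
                exons.setdefault(gid, [])
            elif ftype == "mRNA":
                mrna_parent[fields["ID"]] = fields["Parent"]
            elif ftype == "exon":
                gid = mrna_parent.get(fields["Parent"], fields["Parent"])
                exons.setdefault(gid, []).append((int(start) - 1, int(end)))
    genes = []
    for gid in sorted(exons):
        chrom, strand = meta.get(gid, ("", "+"))
        ex = sorted(exons[gid])
        genes.append(
            Gene(
                gene_id=gid,
                chrom=chrom,
                start=ex[0][0],
                end=ex[-1][1],
                strand=strand,
                exons=ex,
            )
        )
    return genes


def write_fastq(
    read_pairs: Iterable, path1: str | Path, path2: str | Path, quality_char: str = "I"
) -> None:
    """Paired FASTQ, Phred+33, fixed quality."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rp in read_pairs:
            q1 = quality_char * len(rp.mate1)
            q2 = quality_char * len(rp.mate2)
            f1.write(f"@{rp.read_id}/1\n{rp.mate1}\n+\n{q1}\n")
            f2.write(f"@{rp.read_id}/2\n{rp.mate2}\n+\n{q2}\n")
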