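"""Readers and writers for the plain-text formats used by the pipeline.

FASTA goes through Bio.SeqIO; GFF3/BED/TSV are simple tabular text written
and read here.  Coordinates are converted between the package's 0-based
half-open convention and the 1-based inclusive convention of GFF3.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rep_families import GeneFeature
from .rep_scanner import RepCandidate
from .synthetic_data import PlantedTruth, TruthRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genes_gff3",
    "write_genes_gff3",
    "write_rep_bed",
    "read_rep_bed",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_labels_tsv",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_genes_gff3(path, attribute_filter: dict[str, str] | None = None) -> list[GeneFeature]:
    """Gene features from GFF3; ``attribute_filter`` keeps only records
    whose attributes carry the given key=value pairs (e.g.
    ``{"product": "tnpA"}``)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("gene", "CDS"):
                continue
            attributes = _parse_attributes(attrs)
            if attribute_filter and any(
                attributes.get(k) != v for k, v in attribute_filter.items()
            ):
                continue
            genes.append(
                GeneFeature(
                    contig_id=contig,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    gene_id=attributes.get("ID", f"gene{len(genes)}"),
                    product_label=attributes.get("product", ""),
                )
            )
    return genes


def write_genes_gff3(genes: list[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product_label:
                attrs += f";product={g.product_label}"
            fh.write(
                f"{g.contig_id}\treptronkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


_BED_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "kind", "foot", "offset", "stem1", "loop", "bulge", "stem2", "double_foot",
]


def write_rep_bed(candidates: list[RepCandidate], path) -> None:
    """BED6+ with geometry columns; score = paired length."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        c.contig_id, c.start, c.end, c.rep_id or ".", c.paired_len,
                        c.strand, c.hairpin_kind, c.foot_seq, c.foot_offset,
                        c.stem1_len, c.loop_len,
                        "." if c.bulge_len is None else c.bulge_len,
                        "." if c.stem2_len is None else c.stem2_len,
                        int(c.double_foot),
                    ]
                )
                + "\n"
            )


def read_rep_bed(path, sequences: dict[str, str] | None = None) -> list[RepCandidate]:
    """Read candidates back from BED6+; if genome ``sequences`` are given,
    each candidate's sequence is recovered in strand orientation."""
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        seq = ""
        if sequences and row.chrom in sequences:
            seq = sequences[row.chrom][row.start : row.end]
            if row.strand == "-":
                from .dna import revcomp

                seq = revcomp(seq)
        out.append(
            RepCandidate(
                contig_id=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                foot_seq=row.foot,
                foot_offset=int(row.offset),
                hairpin_kind=row.kind,
                stem1_len=int(row.stem1),
                loop_len=int(row.loop),
                bulge_len=None if row.bulge == "." else int(row.bulge),
                stem2_len=None if row.stem2 == "." else int(row.stem2),
                double_foot=bool(int(row.double_foot)),
                sequence=seq,
                hairpin_start=int(row.start),
                hairpin_end=int(row.end),
                rep_id=row.name,
            )
        )
    return out


def write_truth_tsv(truth: PlantedTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tkind\tparams\n")
        for r in truth.records:
            params = ";".join(f"{k}={v}" for k, v in r.params.items())
            fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.kind}\t{params}\n")


def read_truth_tsv(path) -> PlantedTruth:
    truth = PlantedTruth()
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for row in df.itertuples(index=False):
        params = {}
        if row.params:
            for item in str(row.params).split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    params[k] = v
        truth.records.append(
            TruthRecord(
                kind=row.kind, contig_id=row.contig, start=int(row.start),
                end=int(row.end), strand=row.strand, params=params,
            )
        )
    return truth


def write_labels_tsv(labels, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tclass\tsubclass\tprovenance\n")
        for lab in labels:
            fh.write(
                f"{lab.protein_id}\t{lab.class_id or '.'}\t"
                f"{lab.subclass_id or '.'}\t{lab.provenance}\n"
            )
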