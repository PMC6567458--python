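"""Standard-format input/output shared by all pipeline stages.

Dialects: FASTA and FASTQ (Phred+33) through Biopython; gene annotations as
BED12 with thickStart carrying the TSS; variants as a minimal 8-column VCF
(CHROM POS ID REF ALT QUAL FILTER INFO); per-sample cytosine reports,
sample sheets, differential results and expression matrices as TSV; the
dendrogram as a Newick string.  Text formats are 1-based where the field
convention is 1-based (VCF POS, cytosine-report pos); everything in memory
stays 0-based half-open.  Malformed records are rejected with the line
number in the message.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bscall import CytosineCall, CytosineCallSet
from .diffmeth import DiffMethRecord
from .simgen import (
    GeneAnnotation,
    GeneRecord,
    Genome,
    Read,
    ReadSet,
    Variant,
    VariantSet,
)

__all__ = [
    "write_fasta", "read_fasta",
    "write_fastq", "read_fastq",
    "write_bed12", "read_bed12",
    "write_vcf", "read_vcf",
    "write_cytosine_report", "read_cytosine_report",
    "write_sample_sheet", "read_sample_sheet",
    "write_diff_results", "read_diff_results",
    "write_expression", "read_expression",
    "write_newick",
]


class FormatError(ValueError):
    """Malformed record in a text format; message carries the line number."""


# --- FASTA ----------------------------------------------------------------


def write_fasta(genome: Genome, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="spikein" if name in genome.spikein_names else "")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> Genome:
    contigs: dict[str, str] = {}
    spike: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs[rec.id] = str(rec.seq).upper()
        if "spikein" in rec.description.split():
            spike.add(rec.id)
    if not contigs:
        raise FormatError(f"{path}: no FASTA records")
    return Genome(contigs=contigs, spikein_names=spike)


# --- FASTQ ----------------------------------------------------------------


def write_fastq(reads: ReadSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | os.PathLike) -> ReadSet:
    reads = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4:
        raise FormatError(f"{path}: truncated FASTQ (line {len(lines)})")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise FormatError(f"{path} line {i + 1}: expected '@' header")
        if not plus.startswith("+"):
            raise FormatError(f"{path} line {i + 3}: expected '+' separator")
        if len(seq) != len(qual):
            raise FormatError(f"{path} line {i + 2}: sequence/quality length mismatch")
        reads.append(Read(read_id=header[1:].split()[0], sequence=seq, quality=qual))
    return ReadSet(reads)


# --- BED12 ----------------------------------------------------------------


def write_bed12(annotation: GeneAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in annotation:
            start, end = g.span
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.contig, str(start), str(end), g.gene_id, "0", g.strand,
                        str(g.tss), str(g.tss + 1), "0", str(len(g.exons)), sizes, starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | os.PathLike) -> GeneAnnotation:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path} line {ln}: BED12 needs 12 fields, got {len(f)}")
            try:
                start = int(f[1])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as e:
                raise FormatError(f"{path} line {ln}: {e}") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path} line {ln}: block count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            strand = f[5]
            tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
            try:
                records.append(
                    GeneRecord(gene_id=f[3], contig=f[0], strand=strand, tss=tss, exons=exons)
                )
            except ValueError as e:
                raise FormatError(f"{path} line {ln}: {e}") from None
    return GeneAnnotation(records)


# --- minimal VCF ----------------------------------------------------------

_VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def write_vcf(variants: VariantSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in variants:
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tAF={v.freq:.4g}\n"
            )


def read_vcf(path: str | os.PathLike, genome: Genome | None = None) -> VariantSet:
    variants = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise FormatError(f"{path} line {ln}: VCF needs 8 fields, got {len(f)}")
            try:
                pos = int(f[1]) - 1
            except ValueError:
                raise FormatError(f"{path} line {ln}: bad POS {f[1]!r}") from None
            if pos < 0:
                raise FormatError(f"{path} line {ln}: POS must be >= 1")
            if genome is not None and (f[0] not in genome or pos >= len(genome[f[0]])):
                raise FormatError(f"{path} line {ln}: POS outside contig {f[0]}")
            freq = 0.5
            for kv in f[7].split(";"):
                if kv.startswith("AF="):
                    freq = float(kv[3:])
            try:
                variants.append(Variant(contig=f[0], pos=pos, ref=f[3], alt=f[4], freq=freq))
            except ValueError as e:
                raise FormatError(f"{path} line {ln}: {e}") from None
    return VariantSet(variants, genome)


# --- cytosine report ------------------------------------------------------

_CYTO_COLS = ["contig", "pos", "strand", "context", "count_methylated", "count_unmethylated"]


def write_cytosine_report(callset: CytosineCallSet, path: str | os.PathLike) -> None:
    """Bismark-coverage-style dialect: 1-based position, per-strand rows."""
    df = callset.to_dataframe()
    df["pos"] = df["pos"] + 1
    df.to_csv(path, sep="\t", index=False)


def read_cytosine_report(path: str | os.PathLike, sample: str = "sample") -> CytosineCallSet:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CYTO_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    cs = CytosineCallSet(sample=sample)
    for row in df.itertuples(index=False):
        pos = int(row.pos) - 1
        cs.calls[(row.contig, pos, row.strand)] = CytosineCall(
            contig=row.contig, pos=pos, strand=row.strand, context=row.context,
            count_methylated=int(row.count_methylated),
            count_unmethylated=int(row.count_unmethylated),
        )
    return cs


# --- sample sheet, results, expression ------------------------------------


def write_sample_sheet(groups: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame({"sample": list(groups), "group": list(groups.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(df.columns):
        raise FormatError(f"{path}: sample sheet needs 'sample' and 'group' columns")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def write_diff_results(records: list[DiffMethRecord], path: str | os.PathLike) -> None:
    rows = [
        (r.site[0], r.site[1] + 1, r.site[2], r.p_value, r.q_value, r.meth_diff,
         r.hyper_group, r.significant)
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["contig", "pos", "strand", "p_value", "q_value", "meth_diff",
                 "hyper_group", "significant"],
    ).to_csv(path, sep="\t", index=False)


def read_diff_results(path: str | os.PathLike) -> list[DiffMethRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DiffMethRecord(
            site=(row.contig, int(row.pos) - 1, row.strand),
            p_value=float(row.p_value), q_value=float(row.q_value),
            meth_diff=float(row.meth_diff), hyper_group=row.hyper_group,
            significant=bool(row.significant),
        )
        for row in df.itertuples(index=False)
    ]


def write_expression(values: pd.DataFrame, path: str | os.PathLike) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_newick(newick: str, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(newick + "\n")
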