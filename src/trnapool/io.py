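"""Readers and writers for the on-disk formats the pipeline touches.

Coordinates follow the BED convention (0-based, half-open) everywhere on
disk.  All writes are atomic (temp file + rename) so an interrupted run
never leaves a truncated table behind.  Missing values are errors, never
imputed.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quant import CountMatrix, TRNAGeneRecord, parse_trna_gene_name


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_annotation(records: Iterable[TRNAGeneRecord], bed_path: str | Path,
                     tsv_path: str | Path | None = None) -> None:
    """Write the catalogue as 6-column BED plus an optional TSV side table."""
    bed_lines, tsv_rows = [], []
    for i, r in enumerate(records):
        start = r.start if r.start is not None else 1000 * (i + 1)
        end = r.end if r.end is not None else start + 72
        strand = r.strand or "+"
        bed_lines.append(
            f"{r.chrom or 'chr1'}\t{start}\t{end}\t{r.name}\t"
            f"{1 if r.is_high_confidence else 0}\t{strand}"
        )
        tsv_rows.append((r.name, r.isotype, r.anticodon, r.transcript_group,
                         r.copy, f"{r.isotype}-{r.anticodon}-{r.transcript_group}",
                         int(r.is_trx), int(r.is_high_confidence)))
    atomic_write_text(bed_path, "\n".join(bed_lines) + "\n")
    if tsv_path is not None:
        header = ("gene\tisotype\tanticodon\tgroup\tcopy\t"
                  "identical_group_id\tis_trx\tis_high_confidence")
        body = "\n".join("\t".join(map(str, row)) for row in tsv_rows)
        atomic_write_text(tsv_path, header + "\n" + body + "\n")


def read_annotation(path: str | Path) -> list[TRNAGeneRecord]:
    """Read a tRNA catalogue from BED (6 columns) or the TSV side table.

    BED score column carries the confidence flag (1 = high-confidence).
    Malformed coordinates (start >= end) are reported with their line
    number.
    """
    path = Path(path)
    first = path.read_text().splitlines()
    if not first:
        return []
    if first[0].startswith("gene\t"):
        df = pd.read_csv(path, sep="\t")
        out = []
        for _, row in df.iterrows():
            out.append(TRNAGeneRecord(
                name=row["gene"], isotype=row["isotype"],
                anticodon=str(row["anticodon"]),
                transcript_group=int(row["group"]), copy=int(row["copy"]),
                is_trx=bool(int(row["is_trx"])),
                is_high_confidence=bool(int(row["is_high_confidence"])),
            ))
        return out
    records = []
    for ln, line in enumerate(first, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{ln}: expected >=6 BED columns")
        chrom, start, end, name, score, strand = fields[:6]
        start, end = int(start), int(end)
        if start >= end:
            raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
        parsed = parse_trna_gene_name(name)
        records.append(TRNAGeneRecord(
            name=parsed.name, isotype=parsed.isotype,
            anticodon=parsed.anticodon,
            transcript_group=parsed.transcript_group, copy=parsed.copy,
            is_trx=parsed.is_trx,
            is_high_confidence=bool(int(float(score))),
            chrom=chrom, start=start, end=end, strand=strand,
        ))
    return records


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = index_name
    atomic_write_text(path, out.to_csv(sep="\t"))


def read_matrix(path: str | Path, non_negative: bool = True) -> pd.DataFrame:
    """TSV matrix: first column ids, header = sample ids.

    Duplicate ids, ragged rows, missing and negative values are errors
    naming the offending location.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValueError(f"{path}: missing value in column {col!r}")
    if non_negative and (df.values < 0).any():
        raise ValueError(f"{path}: negative value found")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    out = sheet.copy()
    out.index.name = "sample"
    atomic_write_text(path, out.to_csv(sep="\t"))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", index_col=0)
    required = {"cell_type", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return sheet


def read_count_matrix(
    counts_path: str | Path,
    sample_sheet_path: str | Path,
    annotation_path: str | Path | None = None,
) -> CountMatrix:
    counts = read_matrix(counts_path)
    sheet = read_sample_sheet(sample_sheet_path)
    missing = set(counts.columns) - set(sheet.index)
    if missing:
        raise ValueError(
            f"sample(s) absent from sample sheet: {sorted(missing)}")
    annotation = None
    if annotation_path is not None:
        annotation = {r.name: r for r in read_annotation(annotation_path)}
    return CountMatrix(counts.astype(int), sheet, annotation=annotation)


def write_fasta(cds_by_id: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=t, description="") for t, s in cds_by_id.items()]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            SeqIO.write(recs, fh, "fasta")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_json(obj, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")
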