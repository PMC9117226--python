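"""Readers and writers for the plain-text genomics formats used here.

All genomic coordinates are held 0-based, half-open in memory.  GTF input
(1-based, closed) is converted on read; BED, refFlat, narrowPeak and the
tabular formats are already 0-based half-open.  Minimal VCF positions
(1-based) are converted to 0-based points.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .errors import AnnotationParseError, ValidationError

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_transcripts(path, feature: str = "transcript") -> pd.DataFrame:
    """Read GTF rows of one feature type into a per-transcript table.

    Returns columns ``gene_id, chrom, start, end, strand, biotype`` with
    coordinates converted to 0-based half-open.  The biotype is taken from
    the ``gene_type`` or ``gene_biotype`` attribute when present.
    Malformed lines raise :class:`AnnotationParseError` with the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}",
                    lineno,
                )
            if fields[2] != feature:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationParseError(
                    f"non-integer coordinates {fields[3]!r}/{fields[4]!r}",
                    lineno,
                ) from None
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise AnnotationParseError("missing gene_id attribute", lineno)
            biotype = attrs.get("gene_type", attrs.get("gene_biotype", ""))
            rows.append((gene_id, fields[0], start1 - 1, end1, fields[6],
                         biotype))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
    )
    return df


def read_refflat(path) -> pd.DataFrame:
    """Read a refFlat-style gene table (0-based half-open txStart/txEnd)."""
    names = ["geneName", "name", "chrom", "strand", "txStart", "txEnd",
             "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=names, usecols=range(6))
    out = pd.DataFrame({
        "gene_id": df["geneName"],
        "chrom": df["chrom"],
        "start": df["txStart"].astype(np.int64),
        "end": df["txEnd"].astype(np.int64),
        "strand": df["strand"],
    })
    return out


def read_bed_genes(path) -> pd.DataFrame:
    """Read a BED6+ gene table; an optional 7th column is the biotype."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise AnnotationParseError(
            f"BED gene table needs >= 6 columns, got {df.shape[1]}")
    out = pd.DataFrame({
        "gene_id": df[3],
        "chrom": df[0],
        "start": df[1].astype(np.int64),
        "end": df[2].astype(np.int64),
        "strand": df[5],
    })
    if df.shape[1] >= 7:
        out["biotype"] = df[6]
    return out


def read_peaks(path, tissue: str | None = None,
               assay: str | None = None) -> pd.DataFrame:
    """Read BED3/BED6 or ENCODE narrowPeak peak calls.

    The narrowPeak summit column, when present, is ignored: the peak
    coordinate used downstream is always the interval midpoint.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValidationError("peak file needs >= 3 columns")
    out = pd.DataFrame({
        "chrom": df[0],
        "start": df[1].astype(np.int64),
        "end": df[2].astype(np.int64),
    })
    if tissue is not None:
        out["tissue"] = tissue
    if assay is not None:
        out["assay"] = assay
    return out


def read_snps(path) -> pd.DataFrame:
    """Read SNP positions from BED, a two-column chrom/pos TSV, or minimal VCF.

    Returns columns ``chrom, pos, id`` with 0-based positions.
    """
    path = str(path)
    if path.endswith(".vcf"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                snp_id = f[2] if len(f) > 2 and f[2] != "." else f"{f[0]}:{f[1]}"
                rows.append((f[0], int(f[1]) - 1, snp_id))
        return pd.DataFrame(rows, columns=["chrom", "pos", "id"])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 3 and pd.api.types.is_integer_dtype(df[2]):
        # BED: chrom start end [name]
        out = pd.DataFrame({"chrom": df[0], "pos": df[1].astype(np.int64)})
        out["id"] = df[3] if df.shape[1] >= 4 else [
            f"{c}:{p}" for c, p in zip(out["chrom"], out["pos"])]
        return out
    out = pd.DataFrame({"chrom": df[0], "pos": df[1].astype(np.int64)})
    out["id"] = [f"{c}:{p}" for c, p in zip(out["chrom"], out["pos"])]
    return out


def read_interactions(path) -> pd.DataFrame:
    """Read an enhancer-promoter interaction table.

    Expected tab-separated columns: enhancer ``chrom, start, end``, target
    ``gene_id``, target ``tss`` position (0-based).  A header line starting
    with ``chrom`` is tolerated.
    """
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene_id", "tss"])
    required = {"chrom", "start", "end", "gene_id", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"interaction table missing columns: {sorted(missing)}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["tss"] = df["tss"].astype(np.int64)
    return df


# ---------------------------------------------------------------- writers

def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g"):
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_gtf(genes: pd.DataFrame, path, source: str = "intergenic"):
    """Write one ``transcript`` feature line per collapsed gene span."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = (f'gene_id "{row.gene_id}"; '
                     f'gene_biotype "{row.biotype}";')
            fh.write("\t".join([
                str(row.chrom), source, "transcript",
                str(int(row.start) + 1), str(int(row.end)),
                ".", row.strand, ".", attrs,
            ]) + "\n")


def write_bed(df: pd.DataFrame, path, name_col: str | None = None,
              extra_cols: tuple = ()):
    """Write a BED3(+name) file from chrom/start/end columns."""
    cols = [df["chrom"], df["start"].astype(int), df["end"].astype(int)]
    if name_col is not None:
        cols.append(df[name_col])
    for c in extra_cols:
        cols.append(df[c])
    pd.concat(cols, axis=1).to_csv(path, sep="\t", index=False, header=False)


def write_expression_tsv(matrix: pd.DataFrame, path):
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
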