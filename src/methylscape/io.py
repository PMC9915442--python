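"""Readers and writers for every external format the pipeline touches.

Formats: FASTA genomes; per-cytosine reports (7-column TSV: chrom,
1-based position, strand, methylated count, unmethylated count, context,
trinucleotide — the Bismark cytosine-report dialect); GFF3/BED6 gene and
TE annotations; TSV expression matrices; BED6 small-RNA files whose name
field carries "sequence:count" for collapsed unique reads.

All coordinates are normalized to the package's internal 0-based
half-open convention at this boundary (cytosine reports and GFF3 are
1-based on disk).  Every reader transparently accepts gzip files.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeAssembly, classify_context_from_trinucleotide

REPORT_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]
FEATURE_COLUMNS = ["id", "chrom", "start", "end", "strand", "kind"]
SMRNA_COLUMNS = ["chrom", "start", "end", "sequence", "count", "strand", "length"]


class FormatError(ValueError):
    pass


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# -- FASTA --------------------------------------------------------------


def read_fasta(path, control_chrom: str | None = None) -> GenomeAssembly:
    with _open_text(path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise FormatError(f"no sequences in {path}")
    return GenomeAssembly(seqs, control_chrom=control_chrom)


def write_fasta(genome: GenomeAssembly, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# -- per-cytosine reports ----------------------------------------------


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a 7-column per-cytosine report into a site table.

    Positions are converted 1-based -> 0-based.  Zero-coverage records
    are retained (they are density denominators downstream).  The context
    label is cross-checked against the trinucleotide; on mismatch a
    warning is emitted and the trinucleotide wins.
    """
    try:
        df = pd.read_csv(
            _open_text(path),
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed cytosine report {path}: {exc}") from exc
    if df.empty:
        return df
    for col in ("pos", "n_meth", "n_unmeth"):
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 1 if len(bad) else "?"
            raise FormatError(f"{path}: non-integer {col!r} at line {line}")
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise FormatError(f"{path}: negative read counts")
    if not df["strand"].isin(["+", "-"]).all():
        line = int(df.index[~df["strand"].isin(["+", "-"])][0]) + 1
        raise FormatError(f"{path}: bad strand at line {line}")
    df["pos"] = df["pos"] - 1
    derived = df["trinucleotide"].map(classify_context_from_trinucleotide)
    mismatch = derived.notna() & (derived != df["context"])
    if mismatch.any():
        warnings.warn(
            f"{path}: {int(mismatch.sum())} context labels disagree with the "
            "trinucleotide; trinucleotide-derived context used",
            stacklevel=2,
        )
        df.loc[mismatch, "context"] = derived[mismatch]
    df["context"] = pd.Categorical(df["context"], categories=["CG", "CHG", "CHH"])
    return df


def write_cytosine_report(sites: pd.DataFrame, path) -> None:
    out = sites[REPORT_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# -- gene / TE features -------------------------------------------------


def read_features(path, kind: str | None = None) -> pd.DataFrame:
    """Read GFF3 (1-based inclusive) or BED6 (already half-open) features.

    Returns columns ``id, chrom, start, end, strand, kind`` with 0-based
    half-open intervals.  Format is chosen by extension.  ``kind``
    overrides the feature kind; when None, GFF3 uses its type column
    (BED6 requires an explicit kind).
    """
    suffixes = [s for s in Path(path).suffixes if s != ".gz"]
    ext = suffixes[-1].lower() if suffixes else ""
    if ext in (".gff", ".gff3"):
        df = pd.read_csv(
            _open_text(path), sep="\t", header=None, comment="#",
            names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
            dtype={"chrom": str},
        )
        ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
        if ids.isna().any():
            raise FormatError(f"{path}: GFF3 record without ID attribute")
        out = pd.DataFrame(
            {"id": ids, "chrom": df["chrom"], "start": df["start"] - 1, "end": df["end"],
             "strand": df["strand"], "kind": df["type"] if kind is None else kind}
        )
    elif ext == ".bed":
        if kind is None:
            raise FormatError("BED6 feature files need an explicit kind")
        df = pd.read_csv(
            _open_text(path), sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str},
        )
        out = pd.DataFrame(
            {"id": df["name"], "chrom": df["chrom"], "start": df["start"], "end": df["end"],
             "strand": df["strand"], "kind": kind}
        )
    else:
        raise FormatError(f"unknown feature file extension {ext!r} for {path}")
    validate_features(out)
    return out.reset_index(drop=True)


def validate_features(features: pd.DataFrame) -> None:
    if (features["start"] < 0).any() or (features["start"] >= features["end"]).any():
        raise FormatError("feature intervals must satisfy 0 <= start < end")
    if not features["strand"].isin(["+", "-"]).all():
        raise FormatError("feature strand must be + or -")
    dup = features.duplicated(subset=["id", "kind"])
    if dup.any():
        raise FormatError(f"duplicate feature ids within kind: {features.loc[dup, 'id'].tolist()[:5]}")


def write_features_gff3(features: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples():
            fh.write(
                f"{row.chrom}\tmethylscape\t{row.kind}\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.id}\n"
            )


# -- expression ----------------------------------------------------------


def read_expression_table(path) -> pd.DataFrame:
    """TSV with a header row naming samples and gene ids in the first column."""
    df = pd.read_csv(_open_text(path), sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return df


def write_expression_table(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


# -- small RNA -----------------------------------------------------------


def read_smrna_bed(path) -> pd.DataFrame:
    """BED6 of collapsed unique small-RNA reads; name field is 'sequence:count'."""
    df = pd.read_csv(
        _open_text(path), sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    if df.empty:
        return pd.DataFrame(columns=SMRNA_COLUMNS)
    parts = df["name"].str.rsplit(":", n=1, expand=True)
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["start"], "end": df["end"],
         "sequence": parts[0], "count": parts[1].astype(int), "strand": df["strand"]}
    )
    out["length"] = out["end"] - out["start"]
    if (out["length"] != out["sequence"].str.len()).any():
        raise FormatError(f"{path}: interval length disagrees with sequence length")
    if (out["count"] < 1).any():
        raise FormatError(f"{path}: collapsed read count must be >= 1")
    return out


def write_smrna_bed(reads: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {"chrom": reads["chrom"], "start": reads["start"], "end": reads["end"],
         "name": reads["sequence"].astype(str) + ":" + reads["count"].astype(str),
         "score": 0, "strand": reads["strand"]}
    )
    out.to_csv(path, sep="\t", header=False, index=False)
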