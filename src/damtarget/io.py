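"""Shared format readers and writers.

Conventions: BED and all internal coordinates are 0-based half-open;
GFF3 is 1-based inclusive and converted on ingest/egress.  TSV tables
are tab-separated with a header row.  All writers emit deterministic
byte streams for fixed inputs (no timestamps inside data files).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .countmodel import CountMatrix

__all__ = [
    "read_fasta", "write_fasta",
    "read_gff3", "write_gff3", "read_gene_tsv", "write_gene_tsv",
    "read_bed", "write_bed",
    "read_counts_tsv", "write_counts_tsv", "read_metadata_tsv", "write_metadata_tsv",
    "read_gmt", "write_gmt",
    "write_bedgraph", "write_tsv",
    "write_truth_json", "read_truth_json",
]

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "length"]


def read_fasta(path) -> dict[str, str]:
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path) -> pd.DataFrame:
    """Gene records of a GFF3 as a simplified gene table.

    Returns columns ``gene_id, chrom, tss, strand, length`` with the
    TSS converted to a 0-based position (GFF3 start/end are 1-based
    inclusive): TSS = start-1 on '+', end-1 on '-'.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            gene_id = None
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene record without ID attribute")
            tss = start_i - 1 if strand == "+" else end_i - 1
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "tss": tss,
                    "strand": strand,
                    "length": end_i - start_i + 1,
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write the simplified gene table as GFF3 gene records (1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            if g["strand"] == "+":
                start = int(g["tss"]) + 1
                end = int(g["tss"]) + int(g["length"])
            else:
                start = int(g["tss"]) - int(g["length"]) + 2
                end = int(g["tss"]) + 1
            fh.write(
                f"{g['chrom']}\tdamtarget\tgene\t{start}\t{end}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def read_gene_tsv(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ValueError(f"gene TSV {path} lacks columns: {sorted(missing)}")
    return genes[GENE_COLUMNS]


def write_gene_tsv(genes: pd.DataFrame, path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end (+ name if present)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                rec = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if len(parts) > 3:
                rec["name"] = parts[3]
            rows.append(rec)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"][: 4 if rows and "name" in rows[0] else 3])


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in intervals.columns else [])
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_counts_tsv(path, metadata_path=None, lengths: pd.Series | None = None) -> CountMatrix | pd.DataFrame:
    """Counts TSV (features in rows, samples in columns, first column = id).

    With ``metadata_path`` (TSV with columns ``sample, group``) a
    :class:`CountMatrix` is returned; otherwise the raw DataFrame.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.isna().any().any():
        raise ValueError(f"missing values in counts TSV {path}")
    if metadata_path is None:
        return counts
    meta = read_metadata_tsv(metadata_path)
    return CountMatrix(counts, meta, lengths)


def write_counts_tsv(cm: CountMatrix | pd.DataFrame, path) -> None:
    mat = cm.counts if isinstance(cm, CountMatrix) else cm
    mat.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata_tsv(path) -> pd.Series:
    meta = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(meta.columns):
        raise ValueError(f"metadata TSV {path} needs columns sample, group")
    return meta.set_index("sample")["group"]


def write_metadata_tsv(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs name, description, members")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_bedgraph(values: pd.Series, frag_table: pd.DataFrame, path) -> None:
    """Per-fragment signal as bedGraph (fragment order preserved)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph\n')
        for _, row in frag_table.iterrows():
            v = values.get(row["fragment_id"], 0.0)
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{v:.6g}\n")


def write_tsv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Float-stable TSV writer: 6 significant digits, deterministic."""
    df.to_csv(
        path, sep="\t", float_format="%.6g",
        index=index_label is not None, index_label=index_label,
    )


class _TruthEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        return super().default(o)


def write_truth_json(truth, path) -> None:
    payload = {
        "planted_markers": {k: sorted(v) for k, v in truth.planted_markers.items()},
        "planted_down": truth.planted_down,
        "planted_up": truth.planted_up,
        "planted_bound_fragments": truth.planted_bound_fragments,
        "planted_bound_genes": sorted(truth.planted_bound_genes),
        "planted_motif_hits": truth.planted_motif_hits,
    }
    Path(path).write_text(json.dumps(payload, indent=2, cls=_TruthEncoder, sort_keys=True))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
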