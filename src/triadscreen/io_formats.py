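"""Readers/writers for the pipeline's tables and sequences, plus region math.

All tabular formats are TSV with a header row of sample IDs; matrices put
transcripts (or SNPs) in rows.  Coordinates are 1-based and inclusive at
both ends everywhere in this package, so a fragment spanning 479-921 is
921 - 479 + 1 = 443 bases long.  Every writer states the convention in a
comment line where the format allows one.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "Region",
    "region_length",
    "extract_region",
    "read_matrix",
    "write_matrix",
    "align_samples",
    "read_gene_list",
    "write_gene_list",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "write_edge_list",
    "write_graphml",
]


@dataclass(frozen=True)
class Region:
    """1-based inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")


def region_length(region: Region) -> int:
    """Length of a 1-based inclusive interval: end - start + 1."""
    return region.end - region.start + 1


def extract_region(sequence: str | Seq, region: Region) -> str:
    """Subsequence covered by ``region`` (1-based inclusive coordinates)."""
    seq = str(sequence)
    if region.end > len(seq):
        raise ValueError(
            f"region {region.start}-{region.end} exceeds sequence length {len(seq)}"
        )
    return seq[region.start - 1 : region.end]


# ---------------------------------------------------------------------------
# tabular matrices


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix with row IDs in the first column.

    Raises on duplicate row/column identifiers and reports non-numeric
    cells with their row/column context.  Empty cells and ``NA`` become
    ``NaN`` and are handled pairwise-complete downstream.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row IDs in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column IDs in {path}: {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna() & (df[col].astype(str) != "NA")]
        if len(bad):
            raise ValueError(
                f"non-numeric cell in {path} at row {bad[0]!r}, column {col!r}: "
                f"{df.loc[bad[0], col]!r}"
            )
        df[col] = coerced
    return df


def write_matrix(matrix: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# coordinates/IDs: rows x columns TSV; missing values written as NA\n")
        matrix.to_csv(fh, sep="\t", na_rep="NA", float_format=float_format)


def align_samples(expr: pd.DataFrame, traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realign a samples x traits table to the expression sample order by ID."""
    shared = [s for s in expr.columns if s in traits.index]
    if not shared:
        raise ValueError("no shared sample IDs between expression and trait table")
    return expr[shared], traits.loc[shared]


# ---------------------------------------------------------------------------
# gene lists and FASTA


def read_gene_list(path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# minimal VCF subset
#
# The genotype tables here come from a transcript database, not a full
# variant-calling workflow, so only CHROM (transcript ID), POS (1-based),
# ID, REF, ALT and the GT field of each sample are honored.  Anything else
# is ignored with a logged warning.

_VCF_HEADER = [
    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
]

_GT_TO_DOSAGE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
                 "1/1": 2, "1|1": 2}


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse the minimal VCF subset.

    Returns ``(snps, calls)``: ``snps`` indexed by SNP ID with columns
    transcript/position/ref/alt, and ``calls`` as a SNP x sample matrix of
    alt-allele dosages (0/1/2, NaN for missing).
    """
    meta_rows, call_rows, samples = [], [], None
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            fields = line.split("\t")
            samples = fields[9:]
            continue
        fields = line.split("\t")
        chrom, pos, snp_id, ref, alt = fields[:5]
        fmt = fields[8] if len(fields) > 8 else "GT"
        keys = fmt.split(":")
        if keys != ["GT"]:
            log.warning("ignoring non-GT FORMAT fields %s at %s:%s", keys[1:], chrom, pos)
        gt_idx = keys.index("GT")
        dosages = []
        for cell in fields[9:]:
            gt = cell.split(":")[gt_idx]
            dosages.append(_GT_TO_DOSAGE.get(gt, np.nan))
        meta_rows.append((snp_id, chrom, int(pos), ref, alt))
        call_rows.append(dosages)
    snps = pd.DataFrame(
        meta_rows, columns=["snp_id", "transcript", "position", "ref", "alt"]
    ).set_index("snp_id")
    calls = pd.DataFrame(call_rows, index=snps.index, columns=samples, dtype=float)
    return snps, calls


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(snps: pd.DataFrame, calls: pd.DataFrame, path) -> None:
    """Write the minimal VCF subset (GT only; CHROM = transcript ID)."""
    lines = ["##fileformat=VCFv4.2",
             "##source=triadscreen (minimal subset: GT only; POS 1-based)"]
    lines.append("\t".join(_VCF_HEADER + list(calls.columns)))
    for snp_id, row in snps.iterrows():
        gts = []
        for d in calls.loc[snp_id]:
            gts.append("./." if (d != d) else _DOSAGE_TO_GT[int(d)])
        lines.append("\t".join([
            str(row["transcript"]), str(int(row["position"])), str(snp_id),
            str(row["ref"]), str(row["alt"]), ".", ".", ".", "GT", *gts,
        ]))
    Path(path).write_text("".join(f"{l}\n" for l in lines))


# ---------------------------------------------------------------------------
# networks and JSON


def write_edge_list(edges, path) -> None:
    """Edge list TSV: node_a, node_b, rho, p."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\trho\tp\n")
        for a, b, rho, p in edges:
            fh.write(f"{a}\t{b}\t{rho:.6g}\t{p:.6g}\n")


def write_graphml(graph, path) -> None:
    import networkx as nx

    nx.write_graphml(graph, str(path))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def normalize_gene_id(transcript_id: str) -> str:
    """Collapse a transcript ID to its gene by stripping a trailing '-NN'."""
    return re.sub(r"-\d+$", "", transcript_id)
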