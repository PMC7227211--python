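"""Readers and writers for the pipeline's on-disk formats.

Tabular artifacts are headered TSV read through pandas; feature tracks are
BED3+name (0-based, half-open); sequence windows are FASTA wrapped at 60
columns via Biopython; gene sets are standard GMT.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SNP_BASE_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "maf"]


def pvalue_column(trait: str) -> str:
    return f"p_{trait}"


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_snps(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"rsid": str, "chrom": str})
    missing = [c for c in SNP_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SNP columns {missing}")
    return df


def snp_traits(snps: pd.DataFrame) -> list[str]:
    """Trait names inferred from the p-value columns of a SNP table."""
    return [c[2:] for c in snps.columns if c.startswith("p_")]


def write_bed(df: pd.DataFrame, path: str | Path,
              cols: tuple[str, str, str, str] = ("chrom", "start", "end",
                                                 "name")) -> None:
    """Write BED3+name without header (chrom, start0, end0, name)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, list(cols)].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3(+name) into chrom/start/end(/name) with 0-based half-open
    coordinates preserved."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    names = ["chrom", "start", "end", "name"][: df.shape[1]]
    df = df.iloc[:, : len(names)]
    df.columns = names
    if "name" not in df.columns:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    return df


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Gene annotation stored as BED4 (name = gene_id); returns 1-based
    inclusive start/end as used throughout the pipeline."""
    bed = read_bed(path)
    return pd.DataFrame({
        "gene_id": bed["name"],
        "chrom": bed["chrom"],
        "start": bed["start"].astype(int) + 1,
        "end": bed["end"].astype(int),
    })


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"].astype(int) - 1,
        "end": genes["end"].astype(int),
        "name": genes["gene_id"],
    })
    write_bed(bed, path)


def write_windows_fasta(windows: pd.DataFrame, path: str | Path) -> None:
    """Write per-SNP sequence windows; header encodes rsid, chrom and
    1-based window start as ``rsid|chrom|start``."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(row.sequence),
                  id=f"{row.rsid}|{row.chrom}|{int(row.window_start)}",
                  description="")
        for row in windows.itertuples()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_windows_fasta(path: str | Path) -> pd.DataFrame:
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rsid, chrom, start = rec.id.split("|")
        rows.append((rsid, chrom, int(start), str(rec.seq)))
    return pd.DataFrame(rows, columns=["rsid", "chrom", "window_start",
                                       "sequence"])


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for set_id, members in sets.items():
            desc = (descriptions or {}).get(set_id, "na")
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_score_table(path: str | Path) -> pd.DataFrame:
    """External or internal score table: at least (rsid, score); percentile
    column preserved when present."""
    df = read_tsv(path, dtype={"rsid": str})
    if "rsid" not in df.columns or "score" not in df.columns:
        raise ValueError(f"{path}: score table needs rsid and score columns")
    return df


def require_files(paths: Iterable[str | Path]) -> None:
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"required input missing: {p}")
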