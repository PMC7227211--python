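"""Binary SNP x chromatin-feature overlap matrix.

A SNP at 1-based position ``p`` occupies the half-open interval
``[p-1, p)``; it overlaps a BED interval ``[start, end)`` iff
``start <= p-1 < end``. Queries run against per-chromosome merged interval
boundaries with binary search, so a track with m intervals answers n SNP
queries in O((n + m) log m).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class ChromosomeNameMismatch(ValueError):
    pass


def _merged_bounds(track: pd.DataFrame) -> dict[str, tuple[np.ndarray,
                                                            np.ndarray]]:
    """Per-chromosome merged, sorted (starts, ends) arrays."""
    out = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        iv = sub[["start", "end"]].to_numpy(dtype=np.int64)
        iv = iv[np.argsort(iv[:, 0], kind="stable")]
        starts, ends = [], []
        cur_s, cur_e = None, None
        for s, e in iv:
            if s >= e:
                raise ValueError(f"degenerate interval [{s}, {e}) on "
                                 f"{chrom}")
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
        if cur_s is not None:
            starts.append(cur_s)
            ends.append(cur_e)
        out[str(chrom)] = (np.asarray(starts, dtype=np.int64),
                           np.asarray(ends, dtype=np.int64))
    return out


def _covered(bounds, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
    hit = np.zeros(len(pos0), dtype=np.int8)
    for ch in np.unique(chrom):
        b = bounds.get(str(ch))
        if b is None:
            continue
        starts, ends = b
        sel = chrom == ch
        p = pos0[sel]
        i = np.searchsorted(starts, p, side="right") - 1
        ok = (i >= 0) & (p < ends[np.clip(i, 0, None)])
        hit[sel] = ok.astype(np.int8)
    return hit


def build_overlap_matrix(snps: pd.DataFrame,
                         tracks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Binary overlap matrix: index = rsid, columns = feature ids (in the
    given track order); cell 1 iff the SNP base falls in >= 1 interval.

    Raises :class:`ChromosomeNameMismatch` if a track names chromosomes
    absent from the SNP table (e.g. ``chr1`` vs ``1``).
    """
    snp_chroms = set(snps.chrom.astype(str).unique())
    offending = {}
    for fid, track in tracks.items():
        extra = set(track.chrom.astype(str).unique()) - snp_chroms
        if extra:
            offending[fid] = sorted(extra)
    if offending:
        raise ChromosomeNameMismatch(
            f"track chromosomes not present in SNP table: {offending}")

    chrom = snps.chrom.astype(str).to_numpy()
    pos0 = snps.pos.to_numpy(dtype=np.int64) - 1
    data = np.zeros((len(snps), len(tracks)), dtype=np.int8)
    for j, (fid, track) in enumerate(tracks.items()):
        if len(track):
            data[:, j] = _covered(_merged_bounds(track), chrom, pos0)
    return pd.DataFrame(data, index=pd.Index(snps.rsid, name="rsid"),
                        columns=list(tracks.keys()))


def overlap_fraction(matrix: pd.DataFrame,
                     snp_subset: list[str]) -> pd.Series:
    """Per-feature fraction of the subset's SNPs covered by the feature."""
    if len(snp_subset) == 0:
        raise ValueError("snp_subset is empty")
    unknown = [r for r in snp_subset if r not in matrix.index]
    if unknown:
        raise KeyError(f"rsids absent from overlap matrix: {unknown[:5]}")
    return matrix.loc[snp_subset].mean(axis=0)


def write_sparse(matrix: pd.DataFrame, path: str | Path,
                 columns_path: str | Path | None = None) -> None:
    """Serialize as (rsid, feature_id) rows for 1-cells plus a column
    manifest preserving feature order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows, cols = np.nonzero(matrix.to_numpy())
    pd.DataFrame({
        "rsid": matrix.index.to_numpy()[rows],
        "feature_id": np.asarray(matrix.columns)[cols],
    }).to_csv(path, sep="\t", index=False)
    manifest = Path(columns_path) if columns_path else \
        path.with_name("columns.txt")
    manifest.write_text("\n".join(map(str, matrix.columns)) + "\n")


def read_sparse(path: str | Path, rsids: list[str],
                columns_path: str | Path | None = None) -> pd.DataFrame:
    path = Path(path)
    manifest = Path(columns_path) if columns_path else \
        path.with_name("columns.txt")
    columns = manifest.read_text().split()
    cells = pd.read_csv(path, sep="\t", dtype=str)
    matrix = pd.DataFrame(0, index=pd.Index(rsids, name="rsid"),
                          columns=columns, dtype=np.int8)
    if len(cells):
        matrix.values[
            matrix.index.get_indexer(cells.rsid),
            matrix.columns.get_indexer(cells.feature_id)] = 1
    return matrix
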