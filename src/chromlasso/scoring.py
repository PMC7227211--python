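"""Genome-wide SNP scoring and percentile ranking.

A SNP's score is the sum of the scoring model's coefficients over the
features whose intervals it overlaps — no intercept, no background terms.
Percentiles use the strictly-smaller-count convention:
``100 * (# SNPs with strictly smaller score) / (# scored SNPs)``, so tied
SNPs share a percentile and an all-zero score distribution keeps
zero-score SNPs out of "top 5%" sets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import ScoringModel
from .overlap import build_overlap_matrix


def score_snps(snps: pd.DataFrame, scoring_model: ScoringModel,
               tracks: Mapping[str, pd.DataFrame] | None = None,
               overlap_matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Score every SNP as the coefficient-weighted sum of its overlaps.

    Supply either the raw ``tracks`` (intervals are intersected on the
    fly) or a precomputed ``overlap_matrix`` covering the model's features.
    """
    feats = scoring_model.feature_ids
    if overlap_matrix is None:
        if tracks is None:
            raise ValueError("need tracks or an overlap matrix")
        missing = [f for f in feats if f not in tracks]
        if missing:
            raise KeyError(f"model features without a track: {missing}")
        sub = {f: tracks[f] for f in feats}
        overlap_matrix = build_overlap_matrix(snps, sub)
    else:
        missing = [f for f in feats if f not in overlap_matrix.columns]
        if missing:
            raise KeyError(
                f"model features absent from overlap matrix: {missing}")

    if feats:
        beta = np.array([scoring_model.entries[f] for f in feats])
        mat = overlap_matrix.loc[snps.rsid, feats].to_numpy(dtype=float)
        scores = mat @ beta
    else:
        scores = np.zeros(len(snps))
    return pd.DataFrame({"rsid": snps.rsid.to_numpy(), "score": scores})


def percentile_rank(score_table: pd.DataFrame) -> pd.DataFrame:
    """Attach genome-wide percentiles (0–100, strictly-smaller count)."""
    if len(score_table) < 2:
        raise ValueError("need at least 2 scored SNPs to rank")
    s = score_table.score.to_numpy(dtype=float)
    order = np.sort(s)
    smaller = np.searchsorted(order, s, side="left")
    out = score_table.copy()
    out["percentile"] = 100.0 * smaller / len(s)
    return out


def top_fraction_threshold(top_fraction: float) -> float:
    """Percentile cutoff implementing a "top X%" rule."""
    return 100.0 * (1.0 - top_fraction)


def write_bedgraph(score_table: pd.DataFrame, snps: pd.DataFrame,
                   path: str | Path) -> None:
    """Optional browser-style export: chrom, pos-1, pos, score."""
    merged = score_table.merge(snps[["rsid", "chrom", "pos"]], on="rsid")
    df = pd.DataFrame({
        "chrom": merged.chrom,
        "start": merged.pos.astype(np.int64) - 1,
        "end": merged.pos.astype(np.int64),
        "score": merged.score,
    }).sort_values(["chrom", "start"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=False)
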