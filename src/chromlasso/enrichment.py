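"""Nearest-gene assignment and binomial gene-set enrichment with FDR.

Top-scoring SNPs (after excluding known trait loci) are assigned their
nearest gene; enrichment of those genes in each gene set is tested with a
binomial upper tail, p = P(X >= k) for X ~ Binomial(n, K/N), where n is
the number of selected genes, K the set's background members and N the
background size. Benjamini–Hochberg controls the FDR across sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def nearest_gene(snps: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene per SNP on its own chromosome (distance 0 inside a
    gene). Distance ties are broken toward the lower start coordinate and
    flagged. SNPs on chromosomes without genes come back unassigned."""
    if genes.empty:
        raise ValueError("gene table is empty")
    rows = []
    for chrom, sub in snps.groupby("chrom", sort=False):
        g = genes[genes.chrom == chrom].sort_values(
            ["start", "gene_id"]).reset_index(drop=True)
        if g.empty:
            log.warning("no gene on chromosome %s: %d SNPs unassigned",
                        chrom, len(sub))
            for r in sub.itertuples():
                rows.append((r.rsid, None, np.nan, False))
            continue
        starts = g.start.to_numpy(dtype=np.int64)
        ends = g.end.to_numpy(dtype=np.int64)
        for r in sub.itertuples():
            d = np.minimum(np.abs(r.pos - starts), np.abs(r.pos - ends))
            d[(r.pos >= starts) & (r.pos <= ends)] = 0
            best = d.min()
            winners = np.flatnonzero(d == best)
            rows.append((r.rsid, g.gene_id.iat[winners[0]], int(best),
                         len(winners) > 1))
    return pd.DataFrame(rows, columns=["rsid", "gene_id", "distance",
                                       "tie"])


def select_top_fraction(score_table: pd.DataFrame,
                        fraction: float = 0.01,
                        exclude: set[str] | None = None) -> list[str]:
    """Top-scoring rsids after exclusion-first recomputation.

    Known trait-associated loci are dropped *before* the cutoff is
    determined on the remaining table; the selection is the top
    ``ceil(fraction * n)`` scores, extended to every SNP tied with the
    boundary score, so the result never depends on input order.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    table = score_table
    if exclude:
        table = table[~table.rsid.isin(exclude)]
    if table.empty:
        raise ValueError("exclusion removed every scored SNP")
    s = table.score.to_numpy(dtype=float)
    m = max(1, int(np.ceil(fraction * len(s))))
    cutoff = np.sort(s)[::-1][m - 1]
    return table.loc[s >= cutoff, "rsid"].tolist()


def gene_set_enrichment(selected_genes: list[str],
                        gene_sets: dict[str, list[str]],
                        background_genes: list[str],
                        fdr_threshold: float | None = 0.05,
                        ) -> pd.DataFrame:
    """Binomial enrichment of the selected genes in each set, BH-adjusted.

    Returns one row per set (set_id, k, n, K, N, p, fdr, flagged), sorted
    by FDR; when ``fdr_threshold`` is given only sets below it are
    returned. Sets with no background members get p = 1 and a flag.
    """
    background = set(background_genes)
    selected = sorted(set(selected_genes) & background)
    outside = set(selected_genes) - background
    if outside:
        raise ValueError(
            f"selected genes outside the background: {sorted(outside)[:5]}")
    n = len(selected)
    N = len(background)
    if N == 0:
        raise ValueError("background gene list is empty")

    rows = []
    for set_id, members in gene_sets.items():
        mem = set(members) & background
        K = len(mem)
        k = len(mem & set(selected))
        if K == 0:
            p = 1.0
            flagged = True
        else:
            p = float(stats.binom.sf(k - 1, n, K / N)) if n else 1.0
            flagged = False
        rows.append((set_id, k, n, K, N, p, flagged))
    res = pd.DataFrame(rows, columns=["set_id", "k", "n", "K", "N", "p",
                                      "flagged"])
    res["fdr"] = _benjamini_hochberg(res.p.to_numpy())
    res = res.sort_values(["fdr", "p", "set_id"]).reset_index(drop=True)
    if fdr_threshold is not None:
        res = res[res.fdr < fdr_threshold].reset_index(drop=True)
    return res


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
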