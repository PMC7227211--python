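"""Model evaluation: ROC/AUC, score comparisons across methods, GWAS
p-value stratification, and region-set score summaries.

AUC is computed by the Mann–Whitney identity (probability that a random
positive outscores a random negative, counting ties as 1/2), which makes it
exactly invariant under strictly monotone transforms of the scores. Score
distribution comparisons use the Wilcoxon rank-sum test, appropriate for
the zero-inflated score distributions this pipeline produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class RocResult:
    method_name: str
    auc: float
    n_pos: int
    n_neg: int
    curve: pd.DataFrame | None = None   # columns fpr, tpr
    flagged: bool = False


@dataclass
class StratifiedScoreSummary:
    table: pd.DataFrame                 # bin, n, mean_score, median_score
    test_bins: tuple[str, str] | None = None
    ranksum_p: float = float("nan")
    warnings: list[str] = field(default_factory=list)


def roc_auc(scores, labels, method_name: str = "model",
            with_curve: bool = True) -> RocResult:
    """AUC via rank statistics; optional ROC curve swept over descending
    score thresholds. Requires both classes present; ties allowed."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")

    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    curve = None
    if with_curve:
        order = np.argsort(-scores, kind="stable")
        y = pos[order].astype(float)
        s = scores[order]
        tp = np.cumsum(y)
        fp = np.cumsum(1.0 - y)
        # collapse tied thresholds to their last index
        last_of_tie = np.r_[s[1:] != s[:-1], True]
        tpr = np.r_[0.0, tp[last_of_tie] / n_pos]
        fpr = np.r_[0.0, fp[last_of_tie] / n_neg]
        curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return RocResult(method_name=method_name, auc=float(auc),
                     n_pos=n_pos, n_neg=n_neg, curve=curve)


def compare_score_sets(score_tables: dict[str, pd.DataFrame],
                       positives: list[str],
                       negatives: list[str],
                       with_curve: bool = False) -> list[RocResult]:
    """Per-method ROC against shared positive/negative rsid sets.

    Items a method did not score are dropped for that method only and its
    effective n_pos/n_neg reported. A method covering zero positives (or
    zero negatives) is flagged with NaN AUC; other methods are unaffected.
    """
    results = []
    for name, table in score_tables.items():
        lut = dict(zip(table.rsid, table.score.astype(float)))
        pos = [lut[r] for r in positives if r in lut]
        neg = [lut[r] for r in negatives if r in lut]
        if not pos or not neg:
            log.warning("method %s scored %d positives / %d negatives; "
                        "flagged", name, len(pos), len(neg))
            results.append(RocResult(method_name=name, auc=float("nan"),
                                     n_pos=len(pos), n_neg=len(neg),
                                     flagged=True))
            continue
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        results.append(roc_auc(scores, labels, method_name=name,
                               with_curve=with_curve))
    return results


DEFAULT_BINS = (
    ("p>0.05", lambda p: p > 0.05),
    ("5e-8<p<=0.05", lambda p: (p > 5e-8) & (p <= 0.05)),
    ("p<=5e-8", lambda p: p <= 5e-8),
)


def pvalue_stratification(score_table: pd.DataFrame,
                          snps: pd.DataFrame,
                          trait: str,
                          bins=DEFAULT_BINS,
                          test_bins: tuple[int, int] = (0, 1),
                          ) -> StratifiedScoreSummary:
    """Mean scores by GWAS p-value bin, with a two-sided Wilcoxon rank-sum
    test between the designated pair of bins (by default: non-significant
    vs marginally significant, the genome-wide-significant bin excluded).

    Uses the exact null distribution when both groups are small, the
    normal approximation otherwise.
    """
    pcol = f"p_{trait}"
    if pcol not in snps.columns:
        raise KeyError(f"no p-value column for trait {trait!r}")
    merged = score_table.merge(snps[["rsid", pcol]], on="rsid", how="inner")
    p = merged[pcol].to_numpy(dtype=float)
    s = merged.score.to_numpy(dtype=float)

    rows, groups, warns = [], {}, []
    for label, pred in bins:
        mask = pred(p)
        vals = s[mask]
        groups[label] = vals
        rows.append((label, int(mask.sum()),
                     float(vals.mean()) if len(vals) else float("nan"),
                     float(np.median(vals)) if len(vals) else float("nan")))
    table = pd.DataFrame(rows, columns=["bin", "n", "mean_score",
                                        "median_score"])

    a_label, b_label = bins[test_bins[0]][0], bins[test_bins[1]][0]
    a, b = groups[a_label], groups[b_label]
    ranksum_p = float("nan")
    if len(a) == 0 or len(b) == 0:
        msg = f"empty bin among ({a_label!r}, {b_label!r}); test skipped"
        log.warning(msg)
        warns.append(msg)
    else:
        method = "exact" if max(len(a), len(b)) <= 30 else "asymptotic"
        ranksum_p = float(stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method).pvalue)
    return StratifiedScoreSummary(table=table, test_bins=(a_label, b_label),
                                  ranksum_p=ranksum_p, warnings=warns)


def region_score_summary(score_table: pd.DataFrame,
                         snps: pd.DataFrame,
                         region_sets: dict[str, pd.DataFrame],
                         comparisons: list[tuple[str, str]] | None = None,
                         ) -> tuple[pd.DataFrame, dict[tuple[str, str],
                                                       float]]:
    """Score summaries for SNPs falling in each region set (half-open
    overlap, same convention as the feature matrix), plus rank-sum p-values
    for requested set-vs-set comparisons. A SNP inside two sets counts in
    both. Sets overlapping zero SNPs are flagged and excluded from tests."""
    from .overlap import _covered, _merged_bounds

    if not region_sets:
        raise ValueError("no region sets supplied")
    merged = score_table.merge(snps[["rsid", "chrom", "pos"]], on="rsid")
    chrom = merged.chrom.astype(str).to_numpy()
    pos0 = merged.pos.to_numpy(dtype=np.int64) - 1
    s = merged.score.to_numpy(dtype=float)

    member_scores: dict[str, np.ndarray] = {}
    rows = []
    for name, regions in region_sets.items():
        inside = _covered(_merged_bounds(regions), chrom, pos0).astype(bool)
        vals = s[inside]
        member_scores[name] = vals
        if len(vals) == 0:
            log.warning("region set %s overlaps zero SNPs; excluded from "
                        "tests", name)
        rows.append((name, int(inside.sum()),
                     float(vals.mean()) if len(vals) else float("nan"),
                     float(np.median(vals)) if len(vals) else float("nan")))
    summary = pd.DataFrame(rows, columns=["region_set", "n", "mean_score",
                                          "median_score"])

    tests: dict[tuple[str, str], float] = {}
    if comparisons is None and len(region_sets) >= 2:
        names = list(region_sets)
        comparisons = [(names[0], names[1])]
    for a, b in comparisons or []:
        va, vb = member_scores.get(a), member_scores.get(b)
        if va is None or vb is None or len(va) == 0 or len(vb) == 0:
            tests[(a, b)] = float("nan")
            continue
        method = "exact" if max(len(va), len(vb)) <= 30 else "asymptotic"
        tests[(a, b)] = float(stats.mannwhitneyu(
            va, vb, alternative="two-sided", method=method).pvalue)
    return summary, tests
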