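"""Matched-control selection for trait-associated SNPs.

Controls are matched on three background covariates — distance to the
nearest gene, number of LD proxies at r² >= 0.8, and minor allele
frequency — with explicit calipers that widen stepwise (doubling) when a
case's eligible pool is too small. Case SNPs and their strong LD proxies
are excluded from every pool so labels cannot leak into the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DIST_INF = np.inf  # sentinel for "no gene on this chromosome"


@dataclass(frozen=True)
class Calipers:
    """Matching tolerances.

    maf: absolute difference in allele frequency.
    log_dist: absolute difference in log10(dist_to_gene + 1).
    proxies_abs / proxies_rel: |Δ n_proxies| allowed is
    ``max(proxies_abs, proxies_rel * case_n_proxies)``.
    """

    maf: float = 0.05
    log_dist: float = 0.25
    proxies_abs: float = 2.0
    proxies_rel: float = 0.25

    def widened(self, level: int) -> "Calipers":
        f = 2.0 ** level
        return Calipers(self.maf * f, self.log_dist * f,
                        self.proxies_abs * f, self.proxies_rel * f)


@dataclass
class MatchedSet:
    case_rsid: str
    control_rsids: list[str] = field(default_factory=list)
    relaxation_level: int = 0


def compute_matching_covariates(snps: pd.DataFrame,
                                genes: pd.DataFrame,
                                ld_pairs: pd.DataFrame,
                                proxy_r2_threshold: float = 0.8,
                                ) -> pd.DataFrame:
    """Per-SNP (dist_to_gene, n_proxies, maf) table.

    dist_to_gene is 0 inside a gene, else the minimal distance to a gene
    start or end on the same chromosome; SNPs on chromosomes without any
    gene get an infinite distance and a log warning. n_proxies counts
    distinct LD partners at r² >= ``proxy_r2_threshold``, scanning the pair
    table in both orientations.
    """
    if genes.empty:
        raise ValueError("gene table is empty")

    snps = snps.reset_index(drop=True)
    dist = np.full(len(snps), DIST_INF)
    for chrom, sub in snps.groupby("chrom", sort=False):
        g = genes[genes.chrom == chrom]
        if g.empty:
            log.warning("no gene on chromosome %s; distance set to inf "
                        "for %d SNPs", chrom, len(sub))
            continue
        starts = g.start.to_numpy(dtype=np.int64)
        ends = g.end.to_numpy(dtype=np.int64)
        pos = sub.pos.to_numpy(dtype=np.int64)
        inside = (pos[:, None] >= starts[None, :]) & \
                 (pos[:, None] <= ends[None, :])
        d = np.minimum(np.abs(pos[:, None] - starts[None, :]),
                       np.abs(pos[:, None] - ends[None, :]))
        d[inside] = 0
        dist[sub.index.to_numpy()] = d.min(axis=1)

    strong = ld_pairs[ld_pairs.r2 >= proxy_r2_threshold]
    partner_count = pd.concat([
        strong[["rsid_a", "rsid_b"]],
        strong[["rsid_b", "rsid_a"]].rename(
            columns={"rsid_b": "rsid_a", "rsid_a": "rsid_b"}),
    ]).drop_duplicates().groupby("rsid_a").size()

    return pd.DataFrame({
        "rsid": snps.rsid.to_numpy(),
        "dist_to_gene": dist,
        "n_proxies": snps.rsid.map(partner_count).fillna(0).astype(int)
                         .to_numpy(),
        "maf": snps.maf.to_numpy(),
    })


def _eligible_mask(case: pd.Series, pool: pd.DataFrame,
                   cal: Calipers) -> np.ndarray:
    """Boolean caliper filter of the pool against one case's covariates."""
    d_maf = np.abs(pool.maf.to_numpy() - case.maf)
    log_pool = np.log10(pool.dist_to_gene.to_numpy() + 1.0)
    log_case = np.log10(case.dist_to_gene + 1.0)
    d_dist = np.abs(log_pool - log_case)
    d_prox = np.abs(pool.n_proxies.to_numpy() - case.n_proxies)
    prox_tol = max(cal.proxies_abs, cal.proxies_rel * case.n_proxies)
    ok = (d_maf <= cal.maf) & (d_prox <= prox_tol)
    if np.isinf(case.dist_to_gene):
        ok &= np.isinf(pool.dist_to_gene.to_numpy())
    else:
        ok &= d_dist <= cal.log_dist
    return ok


def select_matched_controls(case_rsids: list[str],
                            covariates: pd.DataFrame,
                            ld_pairs: pd.DataFrame | None = None,
                            n_controls: int = 100,
                            maf_min: float = 0.10,
                            calipers: Calipers | None = None,
                            max_relaxations: int = 5,
                            proxy_r2_threshold: float = 0.8,
                            seed: int = 0,
                            ) -> tuple[list[MatchedSet], list[str]]:
    """Sample up to ``n_controls`` caliper-matched controls per case.

    The candidate pool excludes all case SNPs and (when an LD table is
    given) their r² >= 0.8 proxies, and is restricted to MAF > ``maf_min``.
    If a case's pool is smaller than ``n_controls`` the calipers double up
    to ``max_relaxations`` times; the realised relaxation level is recorded.
    Controls may repeat across cases but never within one case. Returns
    ``(matched_sets, unmatched_case_rsids)``.
    """
    if n_controls <= 0:
        raise ValueError("n_controls must be positive")
    calipers = calipers or Calipers()
    rng = np.random.default_rng(seed)

    cov = covariates.set_index("rsid", drop=False)
    missing = [r for r in case_rsids if r not in cov.index]
    if missing:
        raise KeyError(f"case rsids missing from covariate table: "
                       f"{missing[:5]}")

    excluded = set(case_rsids)
    if ld_pairs is not None and not ld_pairs.empty:
        strong = ld_pairs[ld_pairs.r2 >= proxy_r2_threshold]
        in_a = strong.rsid_a.isin(excluded)
        in_b = strong.rsid_b.isin(excluded)
        excluded |= set(strong.loc[in_a, "rsid_b"])
        excluded |= set(strong.loc[in_b, "rsid_a"])

    pool = cov[(~cov.rsid.isin(excluded)) & (cov.maf > maf_min)]
    pool = pool.reset_index(drop=True).sort_values("rsid") \
               .reset_index(drop=True)

    matched: list[MatchedSet] = []
    unmatched: list[str] = []
    for case_rsid in case_rsids:
        case = cov.loc[case_rsid]
        chosen = None
        for level in range(max_relaxations + 1):
            ok = _eligible_mask(case, pool, calipers.widened(level))
            n_ok = int(ok.sum())
            if n_ok >= min(n_controls, 1) and (n_ok >= n_controls
                                               or level == max_relaxations):
                idx = np.flatnonzero(ok)
                take = min(n_controls, n_ok)
                pick = rng.choice(idx, size=take, replace=False)
                chosen = MatchedSet(
                    case_rsid=case_rsid,
                    control_rsids=pool.rsid.to_numpy()[np.sort(pick)]
                                        .tolist(),
                    relaxation_level=level,
                )
                break
        if chosen is None:
            log.warning("case %s: no eligible controls after %d "
                        "relaxations", case_rsid, max_relaxations)
            unmatched.append(case_rsid)
        else:
            matched.append(chosen)
    return matched, unmatched


def matched_sets_to_frame(matched: list[MatchedSet]) -> pd.DataFrame:
    rows = [(m.case_rsid, c, m.relaxation_level)
            for m in matched for c in m.control_rsids]
    return pd.DataFrame(rows, columns=["case_rsid", "control_rsid",
                                       "relaxation_level"])
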