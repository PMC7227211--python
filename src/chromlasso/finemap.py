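"""Candidate-locus stratification: LD-block expansion, GATA motif scans,
and the four-way filter (LD block membership, dual top-percentile scores,
eQTL target genes, allele-level GATA site overlap).

A functional candidate must (i) sit in an LD block of a trait sentinel
(r² strictly above the block threshold), (ii) rank in the top fraction
genome-wide under the primary model, (iii) rank in the top fraction under
the secondary scheme, (iv) be an eQTL for at least one gene, and (v)
overlap a canonical or near-canonical GATA motif under at least one
allele. A within-block top-score flag is reported for interpretation but
is not a hard filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import top_fraction_threshold

log = logging.getLogger(__name__)

# canonical and near-canonical GATA binding motifs, as curated in
# hematopoietic regulatory genomics (hexamers; pentamers), all orientations
GATA_MOTIFS: tuple[str, ...] = (
    "AGATAA", "TTATCA", "AATAGA", "TTATCT",
    "GATAA", "AATAG", "CTATT", "TTATC",
)


@dataclass
class LdBlock:
    sentinel_rsid: str
    member_rsids: list[str]          # includes the sentinel
    r2_threshold: float


@dataclass(frozen=True)
class MotifHit:
    rsid: str
    motif: str
    offset: int                      # strandless offset within the window
    allele_status: str               # present_both | created_by_alt |
                                     # disrupted_by_alt


def expand_ld_blocks(sentinels: list[str],
                     ld_pairs: pd.DataFrame,
                     r2_threshold: float = 0.7,
                     known_rsids: set[str] | None = None) -> list[LdBlock]:
    """One block per sentinel: all partners with r² strictly above the
    threshold, looked up symmetrically; a sentinel with no partners yields
    a singleton block."""
    if known_rsids is not None:
        absent = [s for s in sentinels if s not in known_rsids]
        if absent:
            raise KeyError(f"sentinels absent from SNP table: {absent[:5]}")
    strong = ld_pairs[ld_pairs.r2 > r2_threshold]
    partners: dict[str, set[str]] = {}
    for a, b in zip(strong.rsid_a, strong.rsid_b):
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return [
        LdBlock(sentinel_rsid=s,
                member_rsids=[s] + sorted(partners.get(s, ())),
                r2_threshold=r2_threshold)
        for s in sentinels
    ]


def _overlapping_hits(seq: str, center: int) -> dict[str, int]:
    """Motif -> leftmost hit offset, for hits overlapping ``center``."""
    found: dict[str, int] = {}
    for m in GATA_MOTIFS:
        start = seq.find(m)
        while start != -1:
            if start <= center < start + len(m) and m not in found:
                found[m] = start
            start = seq.find(m, start + 1)
    return found


def scan_gata_motifs(window: str, snp_offset: int,
                     ref_allele: str, alt_allele: str,
                     rsid: str = "") -> list[MotifHit]:
    """Exact-match scan of the 8 GATA motifs against the reference-allele
    window and the alternate-substituted window; only hits overlapping the
    SNP base are reported, with their allele status."""
    window = window.upper()
    if not (0 <= snp_offset < len(window)):
        raise ValueError(f"snp_offset {snp_offset} outside window")
    if window[snp_offset] != ref_allele.upper():
        raise ValueError(
            f"{rsid or 'SNP'}: window base {window[snp_offset]!r} at offset "
            f"{snp_offset} does not match ref allele {ref_allele!r}; "
            "coordinates corrupt")
    alt_window = (window[:snp_offset] + alt_allele.upper()
                  + window[snp_offset + 1:])

    ref_hits = _overlapping_hits(window, snp_offset)
    alt_hits = _overlapping_hits(alt_window, snp_offset)

    hits = []
    for m in GATA_MOTIFS:
        in_ref, in_alt = m in ref_hits, m in alt_hits
        if not in_ref and not in_alt:
            continue
        if in_ref and in_alt:
            status = "present_both"
        elif in_ref:
            status = "disrupted_by_alt"
        else:
            status = "created_by_alt"
        hits.append(MotifHit(rsid=rsid, motif=m,
                             offset=ref_hits.get(m, alt_hits.get(m)),
                             allele_status=status))
    return hits


def scan_windows(windows: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    """Scan every sequence window; returns (rsid, motif, offset, status)
    rows for hits overlapping the SNP base."""
    alleles = snps.set_index("rsid")[["pos", "ref", "alt"]]
    rows = []
    for w in windows.itertuples():
        info = alleles.loc[w.rsid]
        offset = int(info.pos) - int(w.window_start)
        for h in scan_gata_motifs(w.sequence, offset, info.ref, info.alt,
                                  rsid=w.rsid):
            rows.append((h.rsid, h.motif, h.offset, h.allele_status))
    return pd.DataFrame(rows, columns=["rsid", "motif", "offset", "status"])


def passes_candidate_filter(in_block: bool,
                            pct_primary: float,
                            pct_secondary: float,
                            n_eqtl_genes: int,
                            has_gata_hit: bool,
                            top_fraction: float = 0.05) -> bool:
    """The candidate predicate: LD-block membership, both percentiles in
    the genome-wide top fraction, >= 1 eQTL target gene, and a GATA motif
    overlapping the SNP under at least one allele."""
    cut = top_fraction_threshold(top_fraction)
    return bool(in_block
                and pct_primary >= cut
                and pct_secondary >= cut
                and n_eqtl_genes > 0
                and has_gata_hit)


def load_published_candidates() -> pd.DataFrame:
    """Previously reported platelet-trait candidate loci (the published
    15-row fine-mapping table), shipped as package data: per-SNP primary
    and secondary scores with genome-wide percentiles, nearest gene, eQTL
    target genes, GATA-site overlap and LD-block membership."""
    from importlib import resources

    with resources.files("chromlasso.data").joinpath(
            "published_platelet_candidates.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"rsid": str, "chrom": str})


def stratify_candidates(blocks: list[LdBlock],
                        primary: pd.DataFrame,
                        secondary: pd.DataFrame,
                        eqtl: pd.DataFrame,
                        motif_hits: pd.DataFrame,
                        snps: pd.DataFrame,
                        genes: pd.DataFrame | None = None,
                        top_fraction: float = 0.05) -> pd.DataFrame:
    """Apply the candidate filter to all LD-block members.

    ``primary`` and ``secondary`` are score tables with percentiles; block
    members missing a secondary percentile are skipped with a warning
    (mirroring per-method score coverage gaps). Returns one row per
    passing SNP, sorted by (chrom, pos), with a ``block_top`` flag marking
    the highest-primary-score member of each block.
    """
    cut = top_fraction_threshold(top_fraction)
    p_lut = primary.set_index("rsid")
    s_lut = secondary.set_index("rsid")
    pos_lut = snps.set_index("rsid")[["chrom", "pos"]]
    eqtl_genes = eqtl.groupby("rsid").gene_id.apply(
        lambda g: sorted(set(g))).to_dict()
    motif_ok = set(motif_hits.rsid.unique()) if len(motif_hits) else set()
    motif_best = (motif_hits.groupby("rsid")
                  .apply(lambda d: ";".join(sorted(
                      f"{r.motif}:{r.status}" for r in d.itertuples())),
                      include_groups=False).to_dict()
                  if len(motif_hits) else {})

    nearest = {}
    if genes is not None and not genes.empty:
        from .enrichment import nearest_gene
        member_rsids = sorted({m for b in blocks for m in b.member_rsids})
        sub = snps[snps.rsid.isin(member_rsids)]
        assign = nearest_gene(sub, genes)
        nearest = dict(zip(assign.rsid, assign.gene_id))

    rows = []
    for block in blocks:
        block_scores = {m: float(p_lut.score.get(m, np.nan))
                        for m in block.member_rsids}
        finite = {m: v for m, v in block_scores.items() if np.isfinite(v)}
        block_top = max(finite, key=finite.get) if finite else None
        for m in block.member_rsids:
            if m not in p_lut.index:
                continue
            if m not in s_lut.index:
                log.warning("block member %s lacks a secondary score; "
                            "skipped", m)
                continue
            if p_lut.percentile[m] < cut or s_lut.percentile[m] < cut:
                continue
            eg = eqtl_genes.get(m, [])
            if not eg:
                continue
            if m not in motif_ok:
                continue
            loc = pos_lut.loc[m]
            rows.append({
                "rsid": m,
                "chrom": loc.chrom,
                "pos": int(loc.pos),
                "score_primary": float(p_lut.score[m]),
                "pct_primary": float(p_lut.percentile[m]),
                "score_secondary": float(s_lut.score[m]),
                "pct_secondary": float(s_lut.percentile[m]),
                "ld_sentinel": block.sentinel_rsid,
                "nearest_gene": nearest.get(m, ""),
                "eqtl_genes": ",".join(eg),
                "gata_status": motif_best.get(m, ""),
                "block_top": m == block_top,
            })
    out = pd.DataFrame(rows, columns=[
        "rsid", "chrom", "pos", "score_primary", "pct_primary",
        "score_secondary", "pct_secondary", "ld_sentinel", "nearest_gene",
        "eqtl_genes", "gata_status", "block_top"])
    if len(out):
        out = (out.drop_duplicates(subset="rsid")
               .sort_values(["chrom", "pos"]).reset_index(drop=True))
    return out


def dual_model_intersection(primary: pd.DataFrame,
                            second_trait: pd.DataFrame,
                            blocks_primary: list[LdBlock],
                            blocks_second: list[LdBlock],
                            eqtl: pd.DataFrame,
                            motif_hits: pd.DataFrame,
                            snps: pd.DataFrame,
                            genes: pd.DataFrame | None = None,
                            top_fraction: float = 0.05) -> pd.DataFrame:
    """Candidates in the top fraction of BOTH trait models, admissible via
    the union of the two traits' LD blocks; all other criteria as in
    :func:`stratify_candidates`."""
    return stratify_candidates(
        blocks_primary + blocks_second, primary, second_trait, eqtl,
        motif_hits, snps, genes=genes, top_fraction=top_fraction)
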