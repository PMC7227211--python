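"""Synthetic GWAS universe with planted regulatory signal.

Emulates, at desk scale, the ingredients of a trait-specific variant
prioritization study: a SNP table with per-trait GWAS p-values, a gene
annotation, an explicit LD pair table organised in blocks around sentinel
SNPs, chromatin feature tracks of which a planted subset is enriched at
trait-associated SNPs, eQTL assignments, per-SNP sequence windows with
allele-specific GATA motifs, enhancer-like region sets, and gene sets.

Every stream of randomness is derived from ``(config.seed, salt)`` with a
fixed per-function salt, so outputs are bit-identical for a fixed seed and
independent of the order in which generator functions are called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig

from .finemap import GATA_MOTIFS

GENOME_WIDE_P = 5e-8
BASES = np.array(list("ACGT"))

_SALTS = {
    "universe": 101,
    "tracks": 202,
    "eqtl": 303,
    "windows": 404,
    "regions": 505,
    "genesets": 606,
}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), _SALTS[stage]])


@dataclass
class Universe:
    """A generated cohort: public tables plus the planting truth.

    ``snps``/``genes``/``ld`` are the tables every downstream stage reads;
    ``roles`` records which SNPs are sentinels, proxies (with their r² to
    the block lead) or null background, per trait, and which are designated
    validated candidates.
    """

    snps: pd.DataFrame
    genes: pd.DataFrame
    ld: pd.DataFrame
    roles: pd.DataFrame
    config: SimulationConfig
    enriched_features: list[str] = field(default_factory=list)

    def sentinels(self, trait: str) -> list[str]:
        r = self.roles
        return r.loc[(r.role == "sentinel") & (r.trait == trait),
                     "rsid"].tolist()

    def case_block_members(self, trait: str) -> list[str]:
        r = self.roles
        return r.loc[r.trait == trait, "rsid"].tolist()

    @property
    def candidates(self) -> list[str]:
        return self.roles.loc[self.roles.is_candidate, "rsid"].tolist()


def generate_universe(config: SimulationConfig) -> Universe:
    """Build the SNP, gene and LD tables with designated case structure.

    SNPs are laid out in genome order and partitioned into consecutive LD
    blocks of ``ld_block_size + 1`` members (lead + proxies); ``n_case_snps``
    full blocks per trait become case blocks whose leads are genome-wide
    significant sentinels (p < 5e-8). Proxy p-values follow the lead on the
    −log10 scale, attenuated by r²; everything else is Uniform(0, 1).
    """
    config.validate()
    rng = _rng(config, "universe")
    c = config

    # --- positions -------------------------------------------------------
    per_chrom = np.full(c.n_chroms, c.n_snps // c.n_chroms)
    per_chrom[: c.n_snps % c.n_chroms] += 1
    chroms, positions = [], []
    for i, n in enumerate(per_chrom):
        pos = np.sort(rng.choice(
            np.arange(1, c.chrom_length + 1), size=n, replace=False))
        chroms.extend([f"chr{i + 1}"] * n)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    rsids = np.array([f"rs{i:07d}" for i in range(c.n_snps)])

    ref_idx = rng.integers(0, 4, c.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, c.n_snps)) % 4
    maf = rng.uniform(c.maf_floor, c.maf_ceiling, c.n_snps)

    snps = pd.DataFrame({
        "rsid": rsids,
        "chrom": chroms,
        "pos": pos_all.astype(np.int64),
        "ref": BASES[ref_idx],
        "alt": BASES[alt_idx],
        "maf": np.round(maf, 6),
    })

    # --- LD blocks -------------------------------------------------------
    block_size = c.ld_block_size + 1
    block_id = np.full(c.n_snps, -1, dtype=np.int64)
    offset, bid = 0, 0
    full_blocks = []
    for n in per_chrom:
        n_full = n // block_size
        for b in range(n_full):
            lo = offset + b * block_size
            block_id[lo: lo + block_size] = bid
            full_blocks.append(lo)
            bid += 1
        offset += int(n)
    n_blocks = len(full_blocks)
    needed = c.n_case_snps * len(c.traits)
    if needed > n_blocks:
        raise ConfigError(
            "n_case_snps: needs "
            f"{needed} full LD blocks but the universe only has {n_blocks}; "
            "increase n_snps or reduce ld_block_size")

    case_block_pick = rng.choice(n_blocks, size=needed, replace=False)
    trait_of_block = {}
    for t_i, trait in enumerate(c.traits):
        for b in case_block_pick[t_i * c.n_case_snps:
                                 (t_i + 1) * c.n_case_snps]:
            trait_of_block[int(b)] = trait

    ld_rows = []
    role = np.array(["null"] * c.n_snps, dtype=object)
    trait_col = np.array([""] * c.n_snps, dtype=object)
    r2_to_lead = np.full(c.n_snps, np.nan)
    lead_of = np.array([""] * c.n_snps, dtype=object)

    for b, lo in enumerate(full_blocks):
        lead = lo
        members = range(lo + 1, lo + block_size)
        case_trait = trait_of_block.get(b)
        if case_trait is not None:
            role[lead] = "sentinel"
            trait_col[lead] = case_trait
        for k, m in enumerate(members, start=1):
            r2 = float(np.clip(c.r2_decay ** k + rng.uniform(-0.05, 0.05),
                               0.01, 0.999))
            r2 = round(r2, 4)
            # store direction at random; LD is symmetric by contract
            a, bb = (rsids[lead], rsids[m]) if rng.random() < 0.5 else \
                    (rsids[m], rsids[lead])
            ld_rows.append((a, bb, r2))
            r2_to_lead[m] = r2
            lead_of[m] = rsids[lead]
            if case_trait is not None:
                role[m] = "proxy"
                trait_col[m] = case_trait
    ld = pd.DataFrame(ld_rows, columns=["rsid_a", "rsid_b", "r2"])

    # --- GWAS p-values ---------------------------------------------------
    for trait in c.traits:
        p = rng.uniform(0.0, 1.0, c.n_snps)
        is_sent = (role == "sentinel") & (trait_col == trait)
        neglog = rng.uniform(7.4, 12.0, int(is_sent.sum()))
        p[is_sent] = 10.0 ** (-neglog)
        # proxies follow their sentinel on the -log10 scale, scaled by r2
        sent_neglog = dict(zip(rsids[is_sent], neglog))
        is_prox = (role == "proxy") & (trait_col == trait)
        for i in np.flatnonzero(is_prox):
            p[i] = 10.0 ** (-(r2_to_lead[i] * sent_neglog[lead_of[i]]))
        snps[f"p_{trait}"] = p

    # --- candidates: high-r² proxies of the first trait ------------------
    prox_idx = np.flatnonzero((role == "proxy") &
                              (trait_col == c.traits[0]) &
                              (r2_to_lead > 0.75))
    n_cand = min(c.n_candidate_snps, len(prox_idx))
    cand_idx = rng.choice(prox_idx, size=n_cand, replace=False) \
        if n_cand else np.array([], dtype=int)
    is_candidate = np.zeros(c.n_snps, dtype=bool)
    is_candidate[cand_idx] = True

    roles = pd.DataFrame({
        "rsid": rsids,
        "role": role,
        "trait": trait_col,
        "block_lead": lead_of,
        "r2_to_lead": r2_to_lead,
        "is_candidate": is_candidate,
    })

    # --- genes -----------------------------------------------------------
    per_chrom_g = np.full(c.n_chroms, c.n_genes // c.n_chroms)
    per_chrom_g[: c.n_genes % c.n_chroms] += 1
    g_rows = []
    gi = 0
    for i, ng in enumerate(per_chrom_g):
        lengths = rng.integers(5_000, 50_000, ng)
        starts = np.sort(rng.integers(1, c.chrom_length - 50_000, ng))
        for s, L in zip(starts, lengths):
            g_rows.append((f"G{gi:05d}", f"chr{i + 1}", int(s), int(s + L),
                           f"GENE{gi}"))
            gi += 1
    genes = pd.DataFrame(g_rows,
                         columns=["gene_id", "chrom", "start", "end", "name"])

    return Universe(snps=snps, genes=genes, ld=ld, roles=roles, config=c)


def generate_feature_tracks(universe: Universe) -> dict[str, pd.DataFrame]:
    """Chromatin feature tracks as 0-based half-open interval tables.

    The first ``n_enriched_features`` tracks are planted: they cover case
    sentinels with probability ``p_overlap_case``, LD proxies of sentinels
    at the r²-interpolated rate, and everything else at ``p_overlap_null``.
    The remaining tracks cover all SNPs at the null rate.
    """
    c = universe.config
    rng = _rng(c, "tracks")
    snps, roles = universe.snps, universe.roles
    n = len(snps)

    is_sent = (roles.role == "sentinel").to_numpy()
    is_prox = (roles.role == "proxy").to_numpy()
    r2 = roles.r2_to_lead.to_numpy()

    p_vec_enriched = np.full(n, c.p_overlap_null)
    p_vec_enriched[is_sent] = c.p_overlap_case
    p_vec_enriched[is_prox] = (c.p_overlap_null +
                               r2[is_prox] * (c.p_overlap_case -
                                              c.p_overlap_null))
    p_vec_null = np.full(n, c.p_overlap_null)

    pos = snps.pos.to_numpy()
    chrom = snps.chrom.to_numpy()
    tracks: dict[str, pd.DataFrame] = {}
    enriched: list[str] = []
    for f in range(c.n_features):
        fid = f"F{f:04d}"
        p_vec = p_vec_enriched if f < c.n_enriched_features else p_vec_null
        if f < c.n_enriched_features:
            enriched.append(fid)
        covered = rng.random(n) < p_vec
        idx = np.flatnonzero(covered)
        left = rng.integers(0, 50, len(idx))
        right = rng.integers(1, 50, len(idx))
        start = np.maximum(pos[idx] - 1 - left, 0)
        end = np.minimum(pos[idx] + right, c.chrom_length)
        tracks[fid] = pd.DataFrame({
            "chrom": chrom[idx],
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "name": fid,
        })
    universe.enriched_features = enriched
    return tracks


def generate_eqtl_table(universe: Universe) -> pd.DataFrame:
    """(snp, gene, tissue, effect) rows for a random ``eqtl_fraction`` of
    SNPs; every designated candidate SNP gets at least one row, anchored on
    genes of its own chromosome (so multi-gene loci arise naturally)."""
    c = universe.config
    rng = _rng(c, "eqtl")
    snps, genes = universe.snps, universe.genes
    tissues = np.array(["whole_blood", "spleen", "liver", "lung"])

    n = len(snps)
    chosen = rng.random(n) < c.eqtl_fraction
    cand = snps.rsid.isin(universe.candidates).to_numpy()
    chosen |= cand

    genes_by_chrom = {ch: sub.gene_id.to_numpy()
                      for ch, sub in genes.groupby("chrom")}
    rows = []
    for i in np.flatnonzero(chosen):
        ch = snps.chrom.iat[i]
        pool = genes_by_chrom.get(ch, genes.gene_id.to_numpy())
        k = int(rng.integers(1, 4)) if cand[i] else int(rng.integers(1, 3))
        k = min(k, len(pool))
        for g in rng.choice(pool, size=k, replace=False):
            rows.append((snps.rsid.iat[i], g,
                         str(rng.choice(tissues)),
                         float(np.round(rng.normal(0, 0.5), 4))))
    return pd.DataFrame(rows, columns=["rsid", "gene_id", "tissue", "effect"])


def _scan_motif_positions(seq: str) -> list[tuple[int, str]]:
    hits = []
    for m in GATA_MOTIFS:
        start = seq.find(m)
        while start != -1:
            hits.append((start, m))
            start = seq.find(m, start + 1)
    return hits


def _hits_overlapping(seq: str, center: int) -> list[tuple[int, str]]:
    return [(s, m) for s, m in _scan_motif_positions(seq)
            if s <= center < s + len(m)]


def generate_sequence_windows(
        universe: Universe,
        n_background: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequence windows around candidate SNPs plus motif-free background.

    Returns ``(windows, truth)``. Each candidate window carries a GATA
    motif overlapping the SNP base under exactly one allele (mostly
    disrupted by the alternate allele; every third candidate gets a motif
    created by it instead). Background windows are rejection-sampled until
    neither allele's window contains any of the eight motifs.
    """
    c = universe.config
    if c.motif_window < 12:
        raise ConfigError("SimulationConfig.motif_window: must be >= 12")
    rng = _rng(c, "windows")
    snps = universe.snps.set_index("rsid")

    w = c.motif_window
    center = w // 2

    def random_window() -> np.ndarray:
        return rng.integers(0, 4, w)

    windows, truth = [], []

    def emit(rsid: str, seq: str, planted: str, status: str) -> None:
        row = snps.loc[rsid]
        start = max(1, int(row.pos) - center)
        windows.append((rsid, row.chrom, start, seq))
        truth.append((rsid, planted, status))

    for j, rsid in enumerate(universe.candidates):
        row = snps.loc[rsid]
        status = "created_by_alt" if j % 3 == 2 else "disrupted_by_alt"
        motif = GATA_MOTIFS[int(rng.integers(0, len(GATA_MOTIFS)))]
        L = len(motif)
        for _attempt in range(200):
            arr = random_window()
            s = int(rng.integers(center - L + 1, center + 1))
            jpos = center - s
            arr[s: s + L] = [BASES.tolist().index(b) for b in motif]
            present = "".join(BASES[arr])
            have = present[center]
            # the other allele replaces the motif base at the SNP
            others = [b for b in "ACGT" if b != have]
            absent_base = others[int(rng.integers(0, 3))]
            absent = present[:center] + absent_base + present[center + 1:]
            if (_hits_overlapping(present, center)
                    and not _hits_overlapping(absent, center)):
                break
        else:  # pragma: no cover - planting virtually always succeeds
            raise RuntimeError(f"could not plant motif for {rsid}")
        if status == "disrupted_by_alt":
            ref_seq, _alt_base = present, absent_base
            ref_base, alt_base = have, absent_base
        else:
            ref_seq = absent
            ref_base, alt_base = absent_base, have
        # record the generated alleles back onto the SNP table so the
        # scanner's ref-allele validation holds
        universe.snps.loc[universe.snps.rsid == rsid, "ref"] = ref_base
        universe.snps.loc[universe.snps.rsid == rsid, "alt"] = alt_base
        emit(rsid, ref_seq, motif, status)

    null_pool = universe.roles.loc[universe.roles.role == "null",
                                   "rsid"].to_numpy()
    n_bg = min(n_background, len(null_pool))
    for rsid in rng.choice(null_pool, size=n_bg, replace=False):
        row = snps.loc[rsid]
        for _attempt in range(500):
            arr = random_window()
            arr[center] = BASES.tolist().index(row.ref)
            seq = "".join(BASES[arr])
            alt_seq = seq[:center] + row.alt + seq[center + 1:]
            if not (_scan_motif_positions(seq)
                    or _scan_motif_positions(alt_seq)):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not build motif-free window for {rsid}")
        emit(rsid, seq, "", "absent")

    windows_df = pd.DataFrame(
        windows, columns=["rsid", "chrom", "window_start", "sequence"])
    truth_df = pd.DataFrame(truth, columns=["rsid", "motif", "status"])
    return windows_df, truth_df


def generate_region_sets(universe: Universe,
                         n_per_set: int = 300,
                         width: int = 200) -> dict[str, pd.DataFrame]:
    """Enhancer-like region sets: one dense in case-block SNPs (where the
    planted features concentrate), one around random null SNPs."""
    c = universe.config
    rng = _rng(c, "regions")
    roles, snps = universe.roles, universe.snps.set_index("rsid")

    def regions_around(rsids: np.ndarray) -> pd.DataFrame:
        sub = snps.loc[rsids]
        start = np.maximum(sub.pos.to_numpy() - 1 - width // 2, 0)
        return pd.DataFrame({
            "chrom": sub.chrom.to_numpy(),
            "start": start.astype(np.int64),
            "end": (start + width).astype(np.int64),
            "name": rsids,
        }).reset_index(drop=True)

    case_pool = roles.loc[roles.role.isin(["sentinel", "proxy"]),
                          "rsid"].to_numpy()
    null_pool = roles.loc[roles.role == "null", "rsid"].to_numpy()
    k1 = min(n_per_set, len(case_pool))
    k2 = min(n_per_set, len(null_pool))
    return {
        "hematopoietic_enhancer": regions_around(
            rng.choice(case_pool, size=k1, replace=False)),
        "control_region": regions_around(
            rng.choice(null_pool, size=k2, replace=False)),
    }


def generate_gene_sets(universe: Universe,
                       n_random_sets: int = 20) -> dict[str, list[str]]:
    """GMT-style gene sets: one built from genes nearest to case sentinels
    (the planted-signal loci) plus equally sized random sets."""
    from .enrichment import nearest_gene  # deferred: avoids import cycle

    c = universe.config
    rng = _rng(c, "genesets")
    sent = [s for t in c.traits for s in universe.sentinels(t)]
    assign = nearest_gene(
        universe.snps[universe.snps.rsid.isin(sent)], universe.genes)
    planted = sorted(assign.gene_id.dropna().unique().tolist())
    all_genes = universe.genes.gene_id.to_numpy()
    size = max(5, min(len(planted), 50))
    sets = {"planted_trait_geneset": planted[:50] if len(planted) > 50
            else planted}
    for i in range(n_random_sets):
        sets[f"random_set_{i:02d}"] = sorted(
            rng.choice(all_genes, size=size, replace=False).tolist())
    return sets


def write_cohort(universe: Universe, outdir) -> dict[str, str]:
    """Materialise every generator output under ``outdir`` in the formats
    the downstream readers expect; returns the path map."""
    from pathlib import Path

    from . import io_utils as io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    io.write_tsv(universe.snps, out / "snps.tsv")
    io.write_genes_bed(universe.genes, out / "genes.bed")
    io.write_tsv(universe.ld, out / "ld.tsv")
    io.write_tsv(universe.roles, out / "truth" / "roles.tsv")
    paths.update(snps=str(out / "snps.tsv"), genes=str(out / "genes.bed"),
                 ld=str(out / "ld.tsv"),
                 roles=str(out / "truth" / "roles.tsv"))

    tracks = generate_feature_tracks(universe)
    feat_dir = out / "features"
    for fid, df in tracks.items():
        io.write_bed(df, feat_dir / f"{fid}.bed")
    paths["features"] = str(feat_dir)
    io.write_tsv(pd.DataFrame({"feature_id": universe.enriched_features}),
                 out / "truth" / "enriched_features.tsv")

    eqtl = generate_eqtl_table(universe)
    io.write_tsv(eqtl, out / "eqtl.tsv")
    paths["eqtl"] = str(out / "eqtl.tsv")

    windows, truth = generate_sequence_windows(universe)
    # window generation may rewrite candidate alleles; re-emit the SNP table
    io.write_tsv(universe.snps, out / "snps.tsv")
    io.write_windows_fasta(windows, out / "windows.fa")
    io.write_tsv(truth, out / "truth" / "motifs.tsv")
    paths["windows"] = str(out / "windows.fa")

    for name, df in generate_region_sets(universe).items():
        io.write_bed(df, out / "regions" / f"{name}.bed")
    paths["regions"] = str(out / "regions")

    io.write_gmt(generate_gene_sets(universe), out / "sets.gmt")
    paths["gene_sets"] = str(out / "sets.gmt")
    return paths
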