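"""Generator tests: determinism, planted structure, file round-trips."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from scipy import stats

import chromlasso as cl
from chromlasso import io_utils as io
from chromlasso.config import ConfigError


def _cfg(**kw):
    base = dict(n_snps=2000, n_chroms=2, chrom_length=2_000_000,
                n_features=10, n_enriched_features=3, n_case_snps=30,
                n_genes=40, seed=42)
    base.update(kw)
    return cl.SimulationConfig(**base)


def test_fixed_seed_reproduces_identical_tables():
    u1 = cl.generate_universe(_cfg())
    u2 = cl.generate_universe(_cfg())
    pdt.assert_frame_equal(u1.snps, u2.snps)
    pdt.assert_frame_equal(u1.genes, u2.genes)
    pdt.assert_frame_equal(u1.ld, u2.ld)
    t1 = cl.generate_feature_tracks(u1)
    t2 = cl.generate_feature_tracks(u2)
    for fid in t1:
        pdt.assert_frame_equal(t1[fid], t2[fid])


def test_sentinel_count_and_proxy_pairs():
    cfg = _cfg(n_case_snps=50, ld_block_size=5)
    u = cl.generate_universe(cfg)
    sents = u.sentinels("plt")
    assert len(sents) == 50
    for s in sents:
        stored = ((u.ld.rsid_a == s) | (u.ld.rsid_b == s)).sum()
        assert stored == 5


def test_sentinels_reach_genome_wide_significance():
    u = cl.generate_universe(_cfg())
    sents = u.sentinels("plt")
    p = u.snps.set_index("rsid").loc[sents, "p_plt"]
    assert (p < 5e-8).all()


def test_proxy_pvalues_graded_by_r2():
    """Proxy -log10 p equals r² times the sentinel's -log10 p."""
    u = cl.generate_universe(_cfg())
    snp = u.snps.set_index("rsid")
    prox = u.roles[(u.roles.role == "proxy") & (u.roles.trait == "plt")]
    for row in prox.head(20).itertuples():
        expected = row.r2_to_lead * (-np.log10(snp.p_plt[row.block_lead]))
        assert -np.log10(snp.p_plt[row.rsid]) == pytest.approx(expected,
                                                               rel=1e-9)


def test_ld_r2_spans_both_thresholds():
    u = cl.generate_universe(_cfg(ld_block_size=5))
    assert (u.ld.r2 >= 0.8).any() and (u.ld.r2 < 0.8).any()
    assert (u.ld.r2 > 0.7).any() and (u.ld.r2 <= 0.7).any()


def test_invalid_config_names_field():
    with pytest.raises(ConfigError, match="maf_floor"):
        cl.SimulationConfig(maf_floor=0.001)
    with pytest.raises(ConfigError, match="n_enriched_features"):
        _cfg(n_features=5, n_enriched_features=6)
    with pytest.raises(ConfigError, match="motif_window"):
        _cfg(motif_window=8)


def test_enriched_track_case_coverage_within_binomial_bounds():
    """Empirical sentinel coverage of a planted track must fall in the
    exact two-sided 99% binomial interval around p_overlap_case."""
    cfg = cl.SimulationConfig(
        n_snps=8000, n_chroms=2, chrom_length=8_000_000, n_features=6,
        n_enriched_features=2, p_overlap_case=0.8, p_overlap_null=0.05,
        n_case_snps=500, n_genes=100, seed=9)
    u = cl.generate_universe(cfg)
    tracks = cl.generate_feature_tracks(u)
    sents = u.sentinels("plt")
    sub = u.snps[u.snps.rsid.isin(sents)]
    lo, hi = stats.binom.interval(0.99, len(sents), 0.8)
    for fid in u.enriched_features:
        mat = cl.build_overlap_matrix(sub, {fid: tracks[fid]})
        assert lo <= mat[fid].sum() <= hi


def test_planted_enrichment_odds_ratio_significant():
    """Case-vs-background overlap of an enriched track: one-sided exact
    test p < 0.01 for OR > 1."""
    u = cl.generate_universe(_cfg(n_case_snps=60))
    tracks = cl.generate_feature_tracks(u)
    fid = u.enriched_features[0]
    mat = cl.build_overlap_matrix(u.snps, {fid: tracks[fid]})
    is_case = u.snps.rsid.isin(u.sentinels("plt")).to_numpy()
    cov = mat[fid].to_numpy().astype(bool)
    table = [[int((cov & is_case).sum()), int((~cov & is_case).sum())],
             [int((cov & ~is_case).sum()), int((~cov & ~is_case).sum())]]
    _, p = stats.fisher_exact(table, alternative="greater")
    assert p < 0.01


def test_bed_round_trip(tmp_path, small_universe, small_tracks):
    fid, track = next(iter(small_tracks.items()))
    io.write_bed(track, tmp_path / "t.bed")
    back = io.read_bed(tmp_path / "t.bed")
    pdt.assert_frame_equal(
        back[["chrom", "start", "end"]].astype({"start": np.int64,
                                                "end": np.int64}),
        track[["chrom", "start", "end"]].reset_index(drop=True))


def test_eqtl_referential_integrity_and_candidates():
    u = cl.generate_universe(_cfg())
    eqtl = cl.generate_eqtl_table(u)
    assert set(eqtl.gene_id) <= set(u.genes.gene_id)
    assert set(u.candidates) <= set(eqtl.rsid)
    # multi-gene loci occur
    assert (eqtl.groupby("rsid").size() > 1).any()


def test_eqtl_fraction_zero_keeps_only_candidates():
    u = cl.generate_universe(_cfg(eqtl_fraction=0.0))
    eqtl = cl.generate_eqtl_table(u)
    assert set(eqtl.rsid) == set(u.candidates)


def test_window_truth_table_consistent_with_scanner():
    u = cl.generate_universe(_cfg())
    windows, truth = cl.generate_sequence_windows(u, n_background=20)
    snp = u.snps.set_index("rsid")
    for w in windows.itertuples():
        info = snp.loc[w.rsid]
        offset = int(info.pos) - int(w.window_start)
        hits = cl.scan_gata_motifs(w.sequence, offset, info.ref, info.alt,
                                   rsid=w.rsid)
        status = truth.set_index("rsid").status[w.rsid]
        if status == "absent":
            assert hits == []
        else:
            assert status in {h.allele_status for h in hits}


def test_windows_fasta_round_trip(tmp_path):
    u = cl.generate_universe(_cfg())
    windows, _ = cl.generate_sequence_windows(u, n_background=5)
    io.write_windows_fasta(windows, tmp_path / "w.fa")
    back = io.read_windows_fasta(tmp_path / "w.fa")
    pdt.assert_frame_equal(back, windows.reset_index(drop=True))


def test_region_sets_cover_planted_snps(small_universe):
    sets = cl.generate_region_sets(small_universe)
    assert set(sets) == {"hematopoietic_enhancer", "control_region"}
    case = set(small_universe.case_block_members("plt")) | \
        set(small_universe.case_block_members("rbc"))
    enh = sets["hematopoietic_enhancer"]
    assert set(enh.name) <= case


def test_gene_sets_written_as_gmt(tmp_path, small_universe):
    sets = cl.generate_gene_sets(small_universe, n_random_sets=3)
    io.write_gmt(sets, tmp_path / "s.gmt")
    back = io.read_gmt(tmp_path / "s.gmt")
    assert back == sets
    assert "planted_trait_geneset" in sets and len(
        sets["planted_trait_geneset"]) >= 5
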