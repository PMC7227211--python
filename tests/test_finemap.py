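"""LD-block expansion, GATA motif scanning, and candidate stratification."""

import numpy as np
import pandas as pd
import pytest

import chromlasso as cl
from chromlasso.finemap import GATA_MOTIFS


def _ld(*rows):
    return pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"])


class TestLdBlocks:
    def test_strict_threshold(self):
        blocks = cl.expand_ld_blocks(["s"], _ld(("s", "x", 0.9),
                                                ("s", "y", 0.5)),
                                     r2_threshold=0.7)
        assert blocks[0].member_rsids == ["s", "x"]

    def test_boundary_is_excluded(self):
        blocks = cl.expand_ld_blocks(["s"], _ld(("s", "x", 0.7)),
                                     r2_threshold=0.7)
        assert blocks[0].member_rsids == ["s"]

    def test_symmetric_lookup(self):
        blocks = cl.expand_ld_blocks(["s"], _ld(("x", "s", 0.9)))
        assert "x" in blocks[0].member_rsids

    def test_unknown_sentinel_errors(self):
        with pytest.raises(KeyError, match="ghost"):
            cl.expand_ld_blocks(["ghost"], _ld(("a", "b", 0.9)),
                                known_rsids={"a", "b"})

    def test_matches_brute_force_scan(self, rng):
        names = [f"r{i}" for i in range(40)]
        rows = [(names[int(rng.integers(40))], names[int(rng.integers(40))],
                 float(rng.random())) for _ in range(150)]
        ld = _ld(*rows)
        sentinels = names[:8]
        blocks = {b.sentinel_rsid: set(b.member_rsids)
                  for b in cl.expand_ld_blocks(sentinels, ld, 0.6)}
        for s in sentinels:
            expect = {s}
            for a, b, r2 in rows:
                if r2 > 0.6:
                    if a == s:
                        expect.add(b)
                    if b == s:
                        expect.add(a)
            assert blocks[s] == expect


class TestMotifScan:
    def test_disrupted_hexamer(self):
        # AGATAA spans offsets 2-7; the SNP sits on the G at offset 3
        hits = cl.scan_gata_motifs("CCAGATAACC", 3, "G", "T")
        by = {h.motif: h for h in hits}
        assert by["AGATAA"].allele_status == "disrupted_by_alt"
        # the embedded pentamer GATAA also overlaps and is disrupted
        assert by["GATAA"].allele_status == "disrupted_by_alt"

    def test_all_c_window_empty(self):
        assert cl.scan_gata_motifs("CCCCCCCCCC", 4, "C", "A") == []

    def test_motif_set_membership(self):
        assert "AGATAA" in GATA_MOTIFS
        assert "AGATAG" not in GATA_MOTIFS
        hits = cl.scan_gata_motifs("CCAGATAGCC", 3, "G", "T")
        assert "AGATAG" not in {h.motif for h in hits}

    def test_created_by_alt(self):
        # ref has no motif; alt A at offset 3 creates AGATAA
        hits = cl.scan_gata_motifs("CCAGCTAACC", 4, "C", "A")
        assert any(h.allele_status == "created_by_alt" for h in hits)

    def test_ref_mismatch_is_error(self):
        with pytest.raises(ValueError, match="corrupt"):
            cl.scan_gata_motifs("CCAGATAACC", 3, "T", "G")

    def test_hit_must_overlap_snp_base(self):
        # AGATAA present at offsets 2-7, SNP far away at offset 12
        hits = cl.scan_gata_motifs("CCAGATAACCCCGCC", 12, "G", "T")
        assert hits == []

    def test_scanner_matches_naive_substring_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(rng.choice(bases, 30))
            off = int(rng.integers(0, 30))
            ref = seq[off]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            alt_seq = seq[:off] + alt + seq[off + 1:]
            hits = {(h.motif, h.allele_status)
                    for h in cl.scan_gata_motifs(seq, off, ref, alt)}
            expect = set()
            for m in GATA_MOTIFS:
                in_ref = any(s <= off < s + len(m)
                             for s in range(len(seq) - len(m) + 1)
                             if seq[s:s + len(m)] == m)
                in_alt = any(s <= off < s + len(m)
                             for s in range(len(seq) - len(m) + 1)
                             if alt_seq[s:s + len(m)] == m)
                if in_ref and in_alt:
                    expect.add((m, "present_both"))
                elif in_ref:
                    expect.add((m, "disrupted_by_alt"))
                elif in_alt:
                    expect.add((m, "created_by_alt"))
            assert hits == expect


def _mini_inputs():
    snps = pd.DataFrame({
        "rsid": ["s", "x", "y", "z"],
        "chrom": "chr1", "pos": [100, 200, 300, 400],
        "ref": "A", "alt": "C", "maf": 0.2,
        "p_t": [1e-9, 1e-5, 0.5, 0.5],
    })
    primary = pd.DataFrame({"rsid": ["s", "x", "y", "z"],
                            "score": [5, 4, 0, 0],
                            "percentile": [98.0, 96.0, 0.0, 0.0]})
    secondary = pd.DataFrame({"rsid": ["s", "x", "y", "z"],
                              "score": [2, 3, 0, 0],
                              "percentile": [96.0, 97.0, 0.0, 0.0]})
    eqtl = pd.DataFrame({"rsid": ["x", "x"], "gene_id": ["TPM1", "LACTB"],
                         "tissue": "blood", "effect": [0.1, 0.2]})
    motifs = pd.DataFrame({"rsid": ["x"], "motif": ["AGATAA"],
                           "offset": [3], "status": ["disrupted_by_alt"]})
    blocks = cl.expand_ld_blocks(["s"], _ld(("s", "x", 0.9)))
    return snps, primary, secondary, eqtl, motifs, blocks


class TestStratification:
    def test_passing_record_retained_with_annotations(self):
        snps, primary, secondary, eqtl, motifs, blocks = _mini_inputs()
        out = cl.stratify_candidates(blocks, primary, secondary, eqtl,
                                     motifs, snps)
        assert list(out.rsid) == ["x"]
        row = out.iloc[0]
        assert row.eqtl_genes == "LACTB,TPM1"
        assert row.ld_sentinel == "s"
        assert "disrupted_by_alt" in row.gata_status

    def test_low_primary_percentile_excluded(self):
        snps, primary, secondary, eqtl, motifs, blocks = _mini_inputs()
        primary.loc[primary.rsid == "x", "percentile"] = 90.0
        out = cl.stratify_candidates(blocks, primary, secondary, eqtl,
                                     motifs, snps)
        assert out.empty

    def test_no_eqtl_excluded(self):
        snps, primary, secondary, eqtl, motifs, blocks = _mini_inputs()
        out = cl.stratify_candidates(blocks, primary, secondary,
                                     eqtl.iloc[0:0], motifs, snps)
        assert out.empty

    def test_no_motif_excluded(self):
        snps, primary, secondary, eqtl, motifs, blocks = _mini_inputs()
        out = cl.stratify_candidates(blocks, primary, secondary, eqtl,
                                     motifs.iloc[0:0], snps)
        assert out.empty

    def test_missing_secondary_score_skipped(self):
        snps, primary, secondary, eqtl, motifs, blocks = _mini_inputs()
        out = cl.stratify_candidates(blocks, primary,
                                     secondary[secondary.rsid != "x"],
                                     eqtl, motifs, snps)
        assert out.empty

    def test_larger_top_fraction_grows_candidate_set(self, small_universe,
                                                     small_scores):
        u = small_universe
        eqtl = cl.generate_eqtl_table(u)
        windows, _ = cl.generate_sequence_windows(u, n_background=5)
        motifs = cl.scan_windows(windows, u.snps)
        blocks = cl.expand_ld_blocks(u.sentinels("plt"), u.ld)
        prev: set = set()
        for frac in (0.01, 0.05, 0.20, 0.90):
            out = cl.stratify_candidates(blocks, small_scores,
                                         small_scores, eqtl, motifs,
                                         u.snps, top_fraction=frac)
            cur = set(out.rsid)
            assert prev <= cur
            prev = cur

    def test_every_emitted_row_reverifies_all_predicates(
            self, small_universe, small_scores):
        u = small_universe
        eqtl = cl.generate_eqtl_table(u)
        windows, _ = cl.generate_sequence_windows(u, n_background=5)
        motifs = cl.scan_windows(windows, u.snps)
        blocks = cl.expand_ld_blocks(u.sentinels("plt"), u.ld)
        out = cl.stratify_candidates(blocks, small_scores, small_scores,
                                     eqtl, motifs, u.snps,
                                     genes=u.genes, top_fraction=0.10)
        assert len(out) > 0
        members = {m for b in blocks for m in b.member_rsids}
        lut = small_scores.set_index("rsid")
        for row in out.itertuples():
            assert cl.passes_candidate_filter(
                row.rsid in members,
                lut.percentile[row.rsid],
                lut.percentile[row.rsid],
                len(row.eqtl_genes.split(",")),
                row.rsid in set(motifs.rsid),
                top_fraction=0.10)

    def test_dual_intersection_subset_of_single(self, small_universe,
                                                small_scores):
        u = small_universe
        eqtl = cl.generate_eqtl_table(u)
        windows, _ = cl.generate_sequence_windows(u, n_background=5)
        motifs = cl.scan_windows(windows, u.snps)
        blocks = cl.expand_ld_blocks(u.sentinels("plt"), u.ld)
        single = cl.stratify_candidates(blocks, small_scores, small_scores,
                                        eqtl, motifs, u.snps,
                                        top_fraction=0.10)
        dual = cl.dual_model_intersection(small_scores, small_scores,
                                          blocks, [], eqtl, motifs,
                                          u.snps, top_fraction=0.10)
        assert set(dual.rsid) == set(single.rsid)

    def test_top_five_percent_in_one_model_only_excluded(self):
        snps, primary, secondary, eqtl, motifs, blocks = _mini_inputs()
        secondary.loc[secondary.rsid == "x", "percentile"] = 50.0
        out = cl.dual_model_intersection(primary, secondary, blocks, [],
                                         eqtl, motifs, snps)
        assert out.empty
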