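"""End-to-end pipeline stages with manifests and fixed-seed reproducibility.

Each stage reads only files written by earlier stages (or the generator),
writes its outputs under the configured workdir, and records a manifest
(inputs, outputs, sha256 checksums, seed) so any artifact is traceable to
config + seed. Re-running a stage with unchanged inputs and seed
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_utils as io
from .config import PipelineConfig
from .enrichment import gene_set_enrichment, nearest_gene, \
    select_top_fraction
from .evaluation import pvalue_stratification, region_score_summary, roc_auc
from .finemap import dual_model_intersection, expand_ld_blocks, \
    scan_windows, stratify_candidates
from .matching import compute_matching_covariates, matched_sets_to_frame, \
    select_matched_controls
from .model import ScoringModel, assemble_design, extract_scoring_model, \
    fit_lasso_cv
from .overlap import build_overlap_matrix, read_sparse, write_sparse
from .scoring import percentile_rank, score_snps
from .synthetic import GENOME_WIDE_P, generate_universe, write_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "match", "overlap", "train", "score", "evaluate",
          "finemap", "enrich")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(cfg: PipelineConfig, stage: str,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs
                   if Path(p).is_file()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs
                    if Path(p).is_file()},
    }
    mdir = cfg.workdir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    (mdir / f"{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _cohort(cfg: PipelineConfig) -> Path:
    return cfg.workdir / "cohort"


def _load_snps(cfg: PipelineConfig) -> pd.DataFrame:
    io.require_files([_cohort(cfg) / "snps.tsv"])
    return io.read_snps(_cohort(cfg) / "snps.tsv")


def _load_tracks(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    feat_dir = _cohort(cfg) / "features"
    if not feat_dir.is_dir():
        raise FileNotFoundError(f"required input missing: {feat_dir}")
    return {p.stem: io.read_bed(p)
            for p in sorted(feat_dir.glob("*.bed"))}


def _case_rsids(snps: pd.DataFrame, trait: str) -> list[str]:
    return snps.loc[snps[f"p_{trait}"] < GENOME_WIDE_P, "rsid"].tolist()


def stage_simulate(cfg: PipelineConfig) -> None:
    sim = cfg.simulation
    if sim.seed != cfg.seed:
        sim = type(sim).from_dict({**sim.to_dict(), "seed": cfg.seed})
    universe = generate_universe(sim)
    paths = write_cohort(universe, _cohort(cfg))
    outputs = [Path(p) for p in paths.values() if Path(p).is_file()]
    outputs += sorted((_cohort(cfg) / "features").glob("*.bed"))
    _write_manifest(cfg, "simulate", [], outputs)


def stage_match(cfg: PipelineConfig) -> None:
    cohort = _cohort(cfg)
    io.require_files([cohort / "snps.tsv", cohort / "genes.bed",
                      cohort / "ld.tsv"])
    snps = _load_snps(cfg)
    genes = io.read_genes_bed(cohort / "genes.bed")
    ld = io.read_tsv(cohort / "ld.tsv", dtype={"rsid_a": str, "rsid_b": str})

    cov = compute_matching_covariates(snps, genes, ld,
                                      proxy_r2_threshold=cfg.proxy_r2)
    io.write_tsv(cov, cfg.workdir / "covariates.tsv")
    outputs = [cfg.workdir / "covariates.tsv"]
    for trait in io.snp_traits(snps):
        cases = _case_rsids(snps, trait)
        matched, unmatched = select_matched_controls(
            cases, cov, ld_pairs=ld, n_controls=cfg.n_controls,
            maf_min=cfg.maf_min, proxy_r2_threshold=cfg.proxy_r2,
            seed=cfg.seed)
        mpath = cfg.workdir / f"matched_{trait}.tsv"
        io.write_tsv(matched_sets_to_frame(matched), mpath)
        upath = cfg.workdir / f"unmatched_{trait}.tsv"
        io.write_tsv(pd.DataFrame({"case_rsid": unmatched}), upath)
        outputs += [mpath, upath]
    _write_manifest(cfg, "match",
                    [cohort / "snps.tsv", cohort / "genes.bed",
                     cohort / "ld.tsv"], outputs)


def stage_overlap(cfg: PipelineConfig) -> None:
    snps = _load_snps(cfg)
    tracks = _load_tracks(cfg)
    matrix = build_overlap_matrix(snps, tracks)
    write_sparse(matrix, cfg.workdir / "overlap.sparse.tsv",
                 cfg.workdir / "columns.txt")
    _write_manifest(cfg, "overlap", [_cohort(cfg) / "snps.tsv"],
                    [cfg.workdir / "overlap.sparse.tsv",
                     cfg.workdir / "columns.txt"])


def _load_overlap(cfg: PipelineConfig, snps: pd.DataFrame) -> pd.DataFrame:
    io.require_files([cfg.workdir / "overlap.sparse.tsv",
                      cfg.workdir / "columns.txt"])
    return read_sparse(cfg.workdir / "overlap.sparse.tsv",
                       snps.rsid.tolist(), cfg.workdir / "columns.txt")


def stage_train(cfg: PipelineConfig) -> None:
    from .matching import MatchedSet

    snps = _load_snps(cfg)
    matrix = _load_overlap(cfg, snps)
    io.require_files([cfg.workdir / "covariates.tsv"])
    cov = io.read_tsv(cfg.workdir / "covariates.tsv", dtype={"rsid": str})
    outputs = []
    for trait in io.snp_traits(snps):
        mpath = cfg.workdir / f"matched_{trait}.tsv"
        io.require_files([mpath])
        mdf = io.read_tsv(mpath, dtype={"case_rsid": str,
                                        "control_rsid": str})
        matched = [
            MatchedSet(case_rsid=case,
                       control_rsids=sub.control_rsid.tolist(),
                       relaxation_level=int(sub.relaxation_level.iat[0]))
            for case, sub in mdf.groupby("case_rsid", sort=False)
        ]
        design = assemble_design(matched, matrix, cov)
        t0 = time.monotonic()
        path = fit_lasso_cv(design, k_folds=cfg.folds, seed=cfg.seed)
        log.info("trait %s: CV path fit in %.1fs; lambda_se=%.4g "
                 "lambda_min=%.4g", trait, time.monotonic() - t0,
                 path.lambda_se, path.lambda_min)
        model = extract_scoring_model(path, "lambda_se", trait=trait,
                                      seed=cfg.seed)
        io.write_tsv(model.to_frame(), cfg.workdir / f"model_{trait}.tsv")
        path_df = pd.DataFrame({
            "lambda": path.lambdas, "cv_auc": path.cv_auc,
            "cv_se": path.cv_se, "n_nonzero": path.n_nonzero})
        io.write_tsv(path_df, cfg.workdir / f"path_{trait}.tsv")
        meta = {"trait": trait, "seed": cfg.seed,
                "lambda_min": path.lambda_min,
                "lambda_se": path.lambda_se,
                "n_features": len(model.entries),
                "background": model.background,
                "intercept": model.intercept}
        (cfg.workdir / f"fit_meta_{trait}.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n")
        outputs += [cfg.workdir / f"model_{trait}.tsv",
                    cfg.workdir / f"path_{trait}.tsv",
                    cfg.workdir / f"fit_meta_{trait}.json"]
    _write_manifest(cfg, "train",
                    [cfg.workdir / "overlap.sparse.tsv",
                     cfg.workdir / "covariates.tsv"], outputs)


def stage_score(cfg: PipelineConfig) -> None:
    snps = _load_snps(cfg)
    matrix = _load_overlap(cfg, snps)
    outputs = []
    for trait in io.snp_traits(snps):
        mpath = cfg.workdir / f"model_{trait}.tsv"
        io.require_files([mpath])
        model = ScoringModel.from_frame(io.read_tsv(mpath), trait=trait)
        table = score_snps(snps, model, overlap_matrix=matrix)
        table = percentile_rank(table)
        spath = cfg.workdir / f"scores_{trait}.tsv"
        io.write_tsv(table, spath)
        outputs.append(spath)
    _write_manifest(cfg, "score", [cfg.workdir / "overlap.sparse.tsv"],
                    outputs)


def stage_evaluate(cfg: PipelineConfig) -> None:
    snps = _load_snps(cfg)
    outputs = []
    roc_rows = []
    for trait in io.snp_traits(snps):
        spath = cfg.workdir / f"scores_{trait}.tsv"
        io.require_files([spath, cfg.workdir / f"matched_{trait}.tsv"])
        scores = io.read_score_table(spath)
        mdf = io.read_tsv(cfg.workdir / f"matched_{trait}.tsv",
                          dtype={"case_rsid": str, "control_rsid": str})
        cases = mdf.case_rsid.unique().tolist()
        controls = [c for c in mdf.control_rsid.unique()
                    if c not in set(cases)]
        lut = dict(zip(scores.rsid, scores.score))
        vals = np.array([lut[r] for r in cases + controls])
        labels = np.r_[np.ones(len(cases)), np.zeros(len(controls))]
        rr = roc_auc(vals, labels, method_name=f"model_{trait}")
        roc_rows.append((rr.method_name, rr.auc, rr.n_pos, rr.n_neg))
        cpath = cfg.workdir / f"curve_{trait}.tsv"
        io.write_tsv(rr.curve, cpath)
        outputs.append(cpath)

        strata = pvalue_stratification(scores, snps, trait)
        st = strata.table.copy()
        st["ranksum_p"] = strata.ranksum_p
        stpath = cfg.workdir / f"strata_{trait}.tsv"
        io.write_tsv(st, stpath)
        outputs.append(stpath)

        regions_dir = _cohort(cfg) / "regions"
        if regions_dir.is_dir():
            region_sets = {p.stem: io.read_bed(p)
                           for p in sorted(regions_dir.glob("*.bed"))}
            if region_sets:
                summary, tests = region_score_summary(scores, snps,
                                                      region_sets)
                summary["comparison_p"] = [
                    next(iter(tests.values()), float("nan"))
                ] * len(summary)
                rpath = cfg.workdir / f"region_scores_{trait}.tsv"
                io.write_tsv(summary, rpath)
                outputs.append(rpath)
    io.write_tsv(pd.DataFrame(roc_rows, columns=["method", "auc", "n_pos",
                                                 "n_neg"]),
                 cfg.workdir / "roc.tsv")
    outputs.append(cfg.workdir / "roc.tsv")
    _write_manifest(cfg, "evaluate", [], outputs)


def stage_finemap(cfg: PipelineConfig) -> None:
    cohort = _cohort(cfg)
    snps = _load_snps(cfg)
    io.require_files([cohort / "ld.tsv", cohort / "eqtl.tsv",
                      cohort / "windows.fa"])
    ld = io.read_tsv(cohort / "ld.tsv", dtype={"rsid_a": str, "rsid_b": str})
    eqtl = io.read_tsv(cohort / "eqtl.tsv", dtype={"rsid": str,
                                                   "gene_id": str})
    genes = io.read_genes_bed(cohort / "genes.bed")
    windows = io.read_windows_fasta(cohort / "windows.fa")
    motif_hits = scan_windows(windows, snps)
    io.write_tsv(motif_hits, cfg.workdir / "motif_hits.tsv")

    traits = io.snp_traits(snps)
    known = set(snps.rsid)
    blocks = {}
    score_tables = {}
    for trait in traits:
        spath = cfg.workdir / f"scores_{trait}.tsv"
        io.require_files([spath])
        score_tables[trait] = io.read_score_table(spath)
        blocks[trait] = expand_ld_blocks(
            _case_rsids(snps, trait), ld, r2_threshold=cfg.block_r2,
            known_rsids=known)

    primary = traits[0]
    secondary = traits[1] if len(traits) > 1 else traits[0]
    candidates = stratify_candidates(
        blocks[primary], score_tables[primary], score_tables[secondary],
        eqtl, motif_hits, snps, genes=genes,
        top_fraction=cfg.top_fraction)
    io.write_tsv(candidates, cfg.workdir / "candidates.tsv")
    outputs = [cfg.workdir / "motif_hits.tsv",
               cfg.workdir / "candidates.tsv"]

    if len(traits) > 1:
        dual = dual_model_intersection(
            score_tables[primary], score_tables[secondary],
            blocks[primary], blocks[secondary], eqtl, motif_hits, snps,
            genes=genes, top_fraction=cfg.top_fraction)
        io.write_tsv(dual, cfg.workdir / "candidates_dual.tsv")
        outputs.append(cfg.workdir / "candidates_dual.tsv")
    _write_manifest(cfg, "finemap", [cohort / "ld.tsv",
                                     cohort / "eqtl.tsv"], outputs)


def stage_enrich(cfg: PipelineConfig) -> None:
    cohort = _cohort(cfg)
    snps = _load_snps(cfg)
    io.require_files([cohort / "genes.bed", cohort / "sets.gmt"])
    genes = io.read_genes_bed(cohort / "genes.bed")
    gene_sets = io.read_gmt(cohort / "sets.gmt")
    traits = io.snp_traits(snps)
    exclude = {r for t in traits for r in _case_rsids(snps, t)}

    outputs = []
    for trait in traits:
        spath = cfg.workdir / f"scores_{trait}.tsv"
        io.require_files([spath])
        scores = io.read_score_table(spath)
        top = select_top_fraction(scores, fraction=cfg.top1_fraction,
                                  exclude=exclude)
        assign = nearest_gene(snps[snps.rsid.isin(top)], genes)
        selected = assign.gene_id.dropna().unique().tolist()
        res = gene_set_enrichment(selected, gene_sets,
                                  genes.gene_id.tolist(),
                                  fdr_threshold=cfg.fdr)
        epath = cfg.workdir / f"enrichment_{trait}.tsv"
        io.write_tsv(res, epath)
        outputs.append(epath)
    _write_manifest(cfg, "enrich", [cohort / "sets.gmt"], outputs)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "match": stage_match,
    "overlap": stage_overlap,
    "train": stage_train,
    "score": stage_score,
    "evaluate": stage_evaluate,
    "finemap": stage_finemap,
    "enrich": stage_enrich,
}


def run(stage: str, cfg: PipelineConfig) -> None:
    """Run one stage, or ``all`` to chain every stage in order."""
    cfg.validate()
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stage == "all" else (stage,)
    for s in stages:
        if s not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {s!r}; choose from "
                             f"{('all',) + STAGES}")
        t0 = time.monotonic()
        _STAGE_FUNCS[s](cfg)
        log.info("stage %s finished in %.1fs", s, time.monotonic() - t0)
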