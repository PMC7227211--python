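"""Shared fixtures: small synthetic universes reused across test modules."""

import numpy as np
import pytest

import chromlasso as cl


@pytest.fixture(scope="session")
def small_config():
    return cl.SimulationConfig(
        n_snps=3000, n_chroms=2, chrom_length=3_000_000,
        n_features=30, n_enriched_features=6, n_case_snps=40,
        n_genes=60, traits=("plt", "rbc"), seed=101)


@pytest.fixture(scope="session")
def small_universe(small_config):
    return cl.generate_universe(small_config)


@pytest.fixture(scope="session")
def small_tracks(small_universe):
    return cl.generate_feature_tracks(small_universe)


@pytest.fixture(scope="session")
def small_matrix(small_universe, small_tracks):
    return cl.build_overlap_matrix(small_universe.snps, small_tracks)


@pytest.fixture(scope="session")
def small_covariates(small_universe):
    return cl.compute_matching_covariates(
        small_universe.snps, small_universe.genes, small_universe.ld)


@pytest.fixture(scope="session")
def small_fit(small_universe, small_matrix, small_covariates):
    """Matched sets, design, CV path and chromatin-only model for the
    first trait of the small universe."""
    u = small_universe
    matched, unmatched = cl.select_matched_controls(
        u.sentinels("plt"), small_covariates, ld_pairs=u.ld,
        n_controls=15, seed=5)
    assert not unmatched
    design = cl.assemble_design(matched, small_matrix, small_covariates)
    path = cl.fit_lasso_cv(design, k_folds=5, seed=5)
    model = cl.extract_scoring_model(path, "lambda_se", trait="plt", seed=5)
    return {"matched": matched, "design": design, "path": path,
            "model": model}


@pytest.fixture(scope="session")
def small_scores(small_universe, small_matrix, small_fit):
    table = cl.score_snps(small_universe.snps, small_fit["model"],
                          overlap_matrix=small_matrix)
    return cl.percentile_rank(table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
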