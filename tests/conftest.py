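import numpy as np
import pandas as pd
import pytest

from crosstax import synthetic, taxonomy


@pytest.fixture(scope="session")
def small_taxonomy_spec():
    # 2 species x (2 subclasses x 2 types) keeps unit tests fast
    return synthetic.TaxonomySimSpec(
        n_subclasses=2,
        types_per_subclass=2,
        cells_per_type_per_species=30,
        n_genes=250,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_expr(small_taxonomy_spec):
    return synthetic.simulate_taxonomy_counts(small_taxonomy_spec)


@pytest.fixture(scope="session")
def small_landscape():
    return synthetic.simulate_regulatory_landscape(synthetic.RegSimSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_pseudobulk_counts(
    n_genes, n_donors, dispersion, seed, fold_genes=0, fold=1.0, mean_lo=50, mean_hi=2000
):
    """Direct NB pseudobulk sampler used as a DE test harness."""
    from crosstax.species_stats import PseudobulkMatrix

    rng = np.random.default_rng(seed)
    mu = rng.uniform(mean_lo, mean_hi, n_genes)
    theta = 1.0 / dispersion
    rows, meta = [], []
    for sp in ("spA", "spB"):
        for d in range(n_donors):
            m = mu.copy()
            if sp == "spA" and fold_genes:
                m[:fold_genes] *= fold
            rows.append(rng.negative_binomial(theta, theta / (theta + m)))
            meta.append(
                {"species": sp, "donor": f"{sp}_d{d}", "cluster": "c0", "n_cells": 100, "flagged": False}
            )
    counts = pd.DataFrame(np.vstack(rows), columns=[f"g{i}" for i in range(n_genes)])
    meta = pd.DataFrame(meta)
    idx = [f"{r.species}|{r.donor}|c0" for r in meta.itertuples()]
    counts.index = idx
    meta.index = idx
    return PseudobulkMatrix(counts=counts, meta=meta)


def run_consensus_pipeline(seed, k=90, n_subsamples=100, criteria=None):
    """Generator -> over-cluster -> tree -> assess -> prune, returning pieces."""
    spec = synthetic.TaxonomySimSpec(seed=seed)
    expr = synthetic.simulate_taxonomy_counts(spec)
    expr.obs["over_cluster"] = taxonomy.kmeans_overcluster(expr, k=k, seed=seed)
    metacells = taxonomy.aggregate_metacells(expr)
    tree = taxonomy.build_tree(metacells)
    taxonomy.assess_tree(expr, tree, n_subsamples=n_subsamples, seed=seed)
    consensus = taxonomy.prune_to_consensus(tree, criteria)
    return expr, tree, consensus
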