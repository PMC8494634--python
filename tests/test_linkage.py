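import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosstax import linkage, synthetic
from crosstax.linkage import (
    GenomeAnnotation,
    associate_modules,
    candidate_pairs,
    classify_proximity,
    correlate_pairs,
    fit_null_threshold,
    nmf_decompose,
    select_links,
    select_rank,
    shuffled_background,
    sparseness,
)

SIZES = {"chr1": 10_000_000, "chr2": 10_000_000}


def annotation(genes):
    return GenomeAnnotation(genes=pd.DataFrame(genes), chrom_sizes=SIZES)


def peak_frame(records):
    return pd.DataFrame(records, columns=["ccre_id", "chrom", "start", "end"])


class TestFitNullThreshold:
    def test_null_observed_is_calibrated(self):
        rng = np.random.default_rng(0)
        bg = rng.normal(size=5000)
        obs = rng.normal(size=5000)
        null = fit_null_threshold(bg, obs, fdr=0.01)
        frac = (obs >= null.score_threshold).mean()
        assert frac <= 0.02  # <= 2x nominal

    def test_shifted_half_passes(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=2000)
        obs = np.concatenate([rng.normal(size=1000), rng.normal(size=1000) + 5.0])
        null = fit_null_threshold(bg, obs, fdr=0.01)
        passed = obs >= null.score_threshold
        assert passed[1000:].mean() > 0.95
        assert passed[:1000].mean() < 0.05

    def test_fdr_one_threshold_at_minimum(self):
        rng = np.random.default_rng(2)
        obs = rng.normal(size=100)
        null = fit_null_threshold(rng.normal(size=100), obs, fdr=1.0)
        assert null.score_threshold == obs.min()

    def test_degenerate_background_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_null_threshold(np.zeros(100), np.ones(10))

    def test_too_few_background_rejected(self):
        with pytest.raises(ValueError):
            fit_null_threshold(np.arange(10), np.ones(10))


class TestProximityAndPairs:
    def test_close_peak_proximal(self):
        genes = {"gene_id": ["g"], "chrom": ["chr1"], "tss": [10_000], "strand": ["+"]}
        peaks = peak_frame([("c", "chr1", 10_250, 10_751)])  # centre 10500, 500 bp away
        prox = classify_proximity(peaks, annotation(genes))
        assert prox["c"] == "proximal"

    def test_peak_1500bp_away_distal(self):
        genes = {"gene_id": ["g"], "chrom": ["chr1"], "tss": [10_000], "strand": ["+"]}
        peaks = peak_frame([("c", "chr1", 11_250, 11_751)])  # centre 11500
        prox = classify_proximity(peaks, annotation(genes))
        assert prox["c"] == "distal"

    def test_geneless_chromosome_distal(self):
        genes = {"gene_id": ["g"], "chrom": ["chr1"], "tss": [10_000], "strand": ["+"]}
        peaks = peak_frame([("c", "chr2", 9_750, 10_251)])
        assert classify_proximity(peaks, annotation(genes))["c"] == "distal"

    def test_empty_annotation_rejected(self):
        empty = GenomeAnnotation(
            genes=pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand"]),
            chrom_sizes=SIZES,
        )
        with pytest.raises(ValueError, match="empty"):
            classify_proximity(peak_frame([("c", "chr1", 0, 501)]), empty)

    def test_window_inclusion_rules(self):
        genes = {"gene_id": ["g"], "chrom": ["chr1"], "tss": [1_000_000], "strand": ["+"]}
        peaks = peak_frame(
            [
                ("near", "chr1", 1_399_750, 1_400_251),  # 400 kb: included
                ("far", "chr1", 1_599_750, 1_600_251),  # 600 kb: excluded
                ("other", "chr2", 1_000_000, 1_000_501),  # cross-chromosome
            ]
        )
        pairs = candidate_pairs(peaks, annotation(genes))
        assert set(pairs["ccre_id"]) == {"near"}

    def test_strand_flips_distance_sign(self):
        genes = {
            "gene_id": ["gp", "gm"],
            "chrom": ["chr1", "chr2"],
            "tss": [1_000_000, 1_000_000],
            "strand": ["+", "-"],
        }
        peaks = peak_frame(
            [("a", "chr1", 1_099_750, 1_100_251), ("b", "chr2", 1_099_750, 1_100_251)]
        )
        pairs = candidate_pairs(peaks, annotation(genes)).set_index("ccre_id")
        assert pairs.loc["a", "distance_bp"] == 100_000
        assert pairs.loc["b", "distance_bp"] == -100_000

    def test_matches_brute_force_on_toy_genome(self, small_landscape):
        land = small_landscape
        pairs = candidate_pairs(land.ccres, land.annotation)
        got = set(zip(pairs["ccre_id"], pairs["gene_id"]))
        centres = ((land.ccres["start"] + land.ccres["end"]) // 2).to_numpy()
        expected = set()
        for ci, crow in land.ccres.iterrows():
            for _, grow in land.annotation.genes.iterrows():
                if crow["chrom"] == grow["chrom"] and abs(centres[ci] - grow["tss"]) <= 500_000:
                    expected.add((crow["ccre_id"], grow["gene_id"]))
        assert got == expected


class TestCorrelateAndSelect:
    def test_identical_profiles_pcc_one(self):
        acc = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["c"], columns=list("wxyz"))
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"], columns=list("wxyz"))
        pairs = pd.DataFrame({"ccre_id": ["c"], "gene_id": ["g"], "distance_bp": [0]})
        out = correlate_pairs(pairs, acc, expr)
        assert out["pcc"].iloc[0] == pytest.approx(1.0)

    def test_negated_profile_pcc_minus_one_never_passes(self):
        acc = pd.DataFrame([[1.0, 2.0, 3.0]], index=["c"], columns=list("xyz"))
        expr = pd.DataFrame([[-1.0, -2.0, -3.0]], index=["g"], columns=list("xyz"))
        pairs = pd.DataFrame({"ccre_id": ["c"], "gene_id": ["g"], "distance_bp": [0]})
        out = correlate_pairs(pairs, acc, expr)
        assert out["pcc"].iloc[0] == pytest.approx(-1.0)
        null = linkage.NullModel(mu=0.0, sigma=1.0, fdr=0.01, score_threshold=-10.0, background=np.zeros(30))
        links = select_links(out, null)
        assert not links["passes"].any()

    def test_zero_variance_flagged(self):
        acc = pd.DataFrame([[1.0, 1.0, 1.0]], index=["c"], columns=list("xyz"))
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("xyz"))
        pairs = pd.DataFrame({"ccre_id": ["c"], "gene_id": ["g"], "distance_bp": [0]})
        out = correlate_pairs(pairs, acc, expr)
        assert np.isnan(out["pcc"].iloc[0])

    def test_planted_links_high_pcc(self, small_landscape):
        land = small_landscape
        pairs = pd.DataFrame(
            [(c, g, 0) for c, g in land.truth.pairs],
            columns=["ccre_id", "gene_id", "distance_bp"],
        )
        out = correlate_pairs(pairs, land.accessibility, land.expression)
        assert out["pcc"].mean() > 0.8

    def test_noiseless_planted_pcc_exactly_one(self):
        land = synthetic.simulate_regulatory_landscape(
            synthetic.RegSimSpec(noise_sd=0.0, link_effect=1.0, seed=4)
        )
        pairs = pd.DataFrame(
            [(c, g, 0) for c, g in land.truth.pairs],
            columns=["ccre_id", "gene_id", "distance_bp"],
        )
        out = correlate_pairs(pairs, land.accessibility, land.expression)
        assert np.allclose(out["pcc"], 1.0)

    def test_background_mean_near_zero_and_deterministic(self, small_landscape):
        land = small_landscape
        bg1 = shuffled_background(
            land.ccres, land.annotation, land.accessibility, land.expression, 500, seed=9
        )
        bg2 = shuffled_background(
            land.ccres, land.annotation, land.accessibility, land.expression, 500, seed=9
        )
        assert np.array_equal(bg1, bg2)
        assert abs(np.nanmean(bg1)) < 0.05

    def test_background_rejects_degenerate_requests(self, small_landscape):
        land = small_landscape
        with pytest.raises(ValueError):
            shuffled_background(
                land.ccres, land.annotation, land.accessibility, land.expression, 0, seed=0
            )
        one_chrom = land.ccres.assign(chrom="chr1")
        genes_one = land.annotation.genes.assign(chrom="chr1")
        ann = GenomeAnnotation(genes=genes_one, chrom_sizes=SIZES)
        with pytest.raises(ValueError, match="chromosome"):
            shuffled_background(
                one_chrom, ann, land.accessibility, land.expression, 10, seed=0
            )


class TestSparseness:
    def test_one_hot_is_one(self):
        assert sparseness([0, 0, 5, 0]) == pytest.approx(1.0)

    def test_constant_is_zero(self):
        assert sparseness([3.0, 3.0, 3.0]) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_half_support(self):
        assert sparseness([1, 1, 0, 0]) == pytest.approx(2 - np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            sparseness([0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sparseness([1.0, -1.0])

    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=30).filter(lambda v: sum(v) > 1e-3))
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, v):
        s = sparseness(v)
        assert -1e-9 <= s <= 1 + 1e-9


class TestNMF:
    def test_exact_factorization_recovered(self):
        rng = np.random.default_rng(0)
        W0 = rng.uniform(0, 1, (30, 3))
        H0 = rng.uniform(0, 1, (3, 8))
        V = W0 @ H0
        d = nmf_decompose(V, 3, n_runs=5, max_iter=2000, tol=1e-14, seed=1)
        assert d.error / np.linalg.norm(V) < 1e-3

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        V = rng.uniform(0, 1, (25, 10))
        d = nmf_decompose(V, 4, n_runs=3, max_iter=200, tol=0.0, seed=2)
        diffs = np.diff(d.objective_trace)
        assert (diffs <= 1e-8 * max(d.objective_trace[0], 1.0)).all()

    def test_error_nonincreasing_in_rank(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(0, 1, (20, 10))
        errors = [
            nmf_decompose(V, r, n_runs=3, max_iter=500, seed=3).error for r in (1, 3, 5, 10)
        ]
        assert all(errors[i] >= errors[i + 1] - 1e-6 for i in range(len(errors) - 1))

    def test_factors_nonnegative(self):
        rng = np.random.default_rng(3)
        V = rng.uniform(0, 1, (15, 6))
        d = nmf_decompose(V, 2, n_runs=2, seed=4)
        assert (d.W >= 0).all() and (d.H >= 0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            nmf_decompose(np.array([[1.0, -1.0]]), 1)

    def test_rank_grid_of_one(self):
        rng = np.random.default_rng(4)
        V = rng.uniform(0, 1, (10, 5))
        chosen, table = select_rank(V, [3], n_runs=2, seed=0)
        assert chosen == 3 and len(table) == 1

    def test_select_rank_deterministic(self, small_landscape):
        V = small_landscape.accessibility
        a = select_rank(V, [3, 4, 5], n_runs=5, seed=7)
        b = select_rank(V, [3, 4, 5], n_runs=5, seed=7)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])


class TestAssociateModules:
    def test_column_scaling_and_threshold(self):
        decomp = linkage.ModuleDecomposition(
            W=np.array([[5.0, 0.0], [0.0, 2.0]]),
            H=np.array([[10.0, 0.0], [0.0, 4.0]]),
            rank=2,
            error=0.0,
            run_sparseness=np.array([1.0]),
            run_errors=np.array([0.0]),
            objective_trace=np.array([0.0]),
            ccre_ids=["e1", "e2"],
            cluster_ids=["c1", "c2"],
        )
        module_clusters, module_elements = associate_modules(decomp)
        assert module_clusters == {0: {"c1"}, 1: {"c2"}}
        assert module_elements == {0: ["e1"], 1: ["e2"]}

    def test_small_scaled_coefficient_not_associated(self):
        decomp = linkage.ModuleDecomposition(
            W=np.eye(2),
            H=np.array([[1.0, 0.05], [0.0, 1.0]]),  # scaled col2: (0.05, 1.0)
            rank=2,
            error=0.0,
            run_sparseness=np.array([1.0]),
            run_errors=np.array([0.0]),
            objective_trace=np.array([0.0]),
            cluster_ids=["c1", "c2"],
        )
        module_clusters, _ = associate_modules(decomp, coef_threshold=0.1)
        assert module_clusters[0] == {"c1"}  # 0.05 in c2 stays out

    def test_planted_module_cluster_map_recovered(self):
        land = synthetic.simulate_regulatory_landscape(
            synthetic.RegSimSpec(n_true_links=0, noise_sd=0.05, seed=6)
        )
        d = nmf_decompose(land.accessibility, 4, n_runs=10, max_iter=400, seed=6)
        module_clusters, _ = associate_modules(d)
        # match recovered modules to planted ones greedily by Jaccard
        planted = list(land.truth.cluster_activity.values())
        scores = []
        for rec in module_clusters.values():
            best = max(
                len(rec & p) / len(rec | p) if rec | p else 1.0 for p in planted
            )
            scores.append(best)
        assert np.mean(scores) >= 0.9
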