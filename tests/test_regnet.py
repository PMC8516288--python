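"""Importance ranking, core-network extraction, random baseline, bookmarking
scores and group expression contrasts."""

import numpy as np
import pandas as pd
import pytest

from mitowave import (
    ActivityTable,
    ImportanceRanking,
    SiteMatrix,
    build_crn,
    group_expression_contrast,
    importance_scores,
    mitotic_activity_score,
    mitotic_binding_score,
    peak_to_gene,
    random_network_baseline,
    select_core,
)


def planted_driver_problem(rng, n_genes=80, n_motifs=6, n_tau=10):
    """Expression driven almost entirely by motif m0."""
    counts = pd.DataFrame(
        rng.poisson(1.0, size=(n_genes, n_motifs)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"m{j}" for j in range(n_motifs)],
    )
    sites = SiteMatrix(counts=counts)
    A = rng.normal(0, 0.02, size=(n_motifs, n_tau))
    A[0] = np.sin(np.linspace(0, 2 * np.pi, n_tau)) * 2.0
    A -= A.mean(axis=1, keepdims=True)
    e = pd.DataFrame(
        sites.centered.to_numpy() @ A + rng.normal(0, 0.01, (n_genes, n_tau)),
        index=counts.index,
        columns=np.arange(n_tau, dtype=float),
    )
    return sites, e


class TestImportance:
    def test_planted_driver_ranks_first(self, rng):
        sites, e = planted_driver_problem(rng)
        ranking = importance_scores(e, sites, lam=1e-6)
        assert ranking.table.index[0] == "m0"
        assert ranking.table["score"].iloc[0] < 0.5

    def test_constant_column_scores_one(self, rng):
        sites, e = planted_driver_problem(rng)
        counts = sites.counts.copy()
        counts["m_const"] = 3  # centered column is all zero: no influence
        ranking = importance_scores(e, SiteMatrix(counts=counts), lam=1e-6)
        assert ranking.table.loc["m_const", "score"] == pytest.approx(1.0, abs=1e-9)

    def test_scores_bounded_when_full_model_optimal(self, rng):
        # with a negligible penalty the full least-squares fit is optimal per
        # column, so removing a motif can never raise the explained variance
        sites, e = planted_driver_problem(rng)
        ranking = importance_scores(e, sites, lam=1e-8)
        assert (ranking.table["score"] <= 1.0 + 1e-6).all()

    def test_ranking_deterministic(self, rng):
        sites, e = planted_driver_problem(rng)
        r1 = importance_scores(e, sites, lam=0.1)
        r2 = importance_scores(e, sites, lam=0.1)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestSelectCore:
    @staticmethod
    def ranking(n, scores=None):
        ids = [f"m{i:03d}" for i in range(n)]
        sc = np.linspace(0.1, 1.0, n) if scores is None else np.asarray(scores)
        table = (
            pd.DataFrame({"score": sc, "ev_reduced": sc}, index=ids)
            .rename_axis("motif")
            .sort_values(["score", "motif"], kind="stable")
        )
        return ImportanceRanking(table=table, ev_full=1.0)

    def test_five_percent_of_332_motifs_is_16(self):
        assert len(select_core(self.ranking(332), fraction=0.05)) == 16

    def test_fraction_one_selects_all(self):
        assert len(select_core(self.ranking(20), fraction=1.0)) == 20

    def test_ties_broken_lexically(self):
        core = select_core(self.ranking(10, scores=np.ones(10)), fraction=0.3)
        assert core == ["m000", "m001", "m002"]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_core(self.ranking(10), fraction=0.0)


def toy_network():
    # genes encoding the three TFs; hand-placed sites give the adjacency
    #   m1 -> m2 (site for m1 in g2), m2 -> m1, m2 -> m2 (self-loop)
    counts = pd.DataFrame(
        [[0, 2, 0], [1, 1, 0], [0, 0, 0]],
        index=["g1", "g2", "g3"],
        columns=["m1", "m2", "m3"],
    )
    sites = SiteMatrix(counts=counts)
    motif_to_gene = {"m1": "g1", "m2": "g2", "m3": "g3"}
    return sites, motif_to_gene


class TestCoreNetwork:
    def test_edges_match_hand_adjacency(self):
        sites, m2g = toy_network()
        crn = build_crn(["m1", "m2", "m3"], sites, m2g)
        assert set(crn.graph.edges) == {("m1", "m2"), ("m2", "m1"), ("m2", "m2")}
        assert crn.edge_count == 3

    def test_empty_promoters_give_no_edges(self):
        sites, m2g = toy_network()
        crn = build_crn(["m3"], sites, m2g)
        assert crn.edge_count == 0

    def test_unmappable_motif_kept_with_warning(self):
        sites, _ = toy_network()
        with pytest.warns(UserWarning, match="m1"):
            crn = build_crn(["m1"], sites, {})
        assert "m1" in crn.nodes and crn.edge_count == 0

    def test_edge_count_invariant_to_node_order(self):
        sites, m2g = toy_network()
        a = build_crn(["m1", "m2", "m3"], sites, m2g).edge_count
        b = build_crn(["m3", "m1", "m2"], sites, m2g).edge_count
        assert a == b


class TestRandomBaseline:
    def test_full_node_set_has_zero_variance(self):
        sites, m2g = toy_network()
        mean, sd = random_network_baseline(sites, m2g, n_nodes=3, n_draws=10, seed=0)
        assert mean == 3.0 and sd == 0.0

    def test_dense_matrix_baseline_is_quadratic(self):
        counts = pd.DataFrame(
            np.ones((4, 4), dtype=int),
            index=[f"g{i}" for i in range(4)],
            columns=[f"m{i}" for i in range(4)],
        )
        m2g = {f"m{i}": f"g{i}" for i in range(4)}
        mean, sd = random_network_baseline(
            SiteMatrix(counts=counts), m2g, n_nodes=2, n_draws=20, seed=0
        )
        assert mean == 4.0 and sd == 0.0

    def test_planted_core_exceeds_baseline(self, rng):
        # dense co-regulating core of 5 TFs in a sparse 40-motif background
        n = 40
        counts = pd.DataFrame(
            (rng.random((n, n)) < 0.02).astype(int),
            index=[f"g{i}" for i in range(n)],
            columns=[f"m{i}" for i in range(n)],
        )
        core = [f"m{i}" for i in range(5)]
        counts.loc[[f"g{i}" for i in range(5)], core] = 1
        sites = SiteMatrix(counts=counts)
        m2g = {f"m{i}": f"g{i}" for i in range(n)}
        crn = build_crn(core, sites, m2g)
        mean, sd = random_network_baseline(sites, m2g, n_nodes=5, n_draws=200, seed=1)
        assert crn.edge_count > mean + 3 * sd

    def test_too_many_nodes_rejected(self):
        sites, m2g = toy_network()
        with pytest.raises(ValueError):
            random_network_baseline(sites, m2g, n_nodes=5)


class TestMitoticBindingScore:
    def test_weighted_mean_hand_value(self):
        counts = pd.DataFrame([[1, 3]], index=["g"], columns=["m1", "m2"])
        mbf = pd.Series({"m1": 0.2, "m2": 0.8})
        out = mitotic_binding_score(SiteMatrix(counts=counts), mbf)
        assert out.loc["g", "mbs"] == pytest.approx(0.65, abs=1e-10)

    def test_single_motif_promoter_inherits_mbf(self):
        counts = pd.DataFrame([[4, 0]], index=["g"], columns=["m1", "m2"])
        mbf = pd.Series({"m1": 0.3, "m2": 0.9})
        out = mitotic_binding_score(SiteMatrix(counts=counts), mbf)
        assert out.loc["g", "mbs"] == pytest.approx(0.3)

    def test_uniform_mbf_gives_uniform_scores(self, rng):
        counts = pd.DataFrame(
            rng.poisson(1.0, size=(20, 3)) + (np.arange(20) % 2 == 0)[:, None],
            index=[f"g{i}" for i in range(20)],
            columns=["a", "b", "c"],
        )
        mbf = pd.Series(0.4, index=["a", "b", "c"])
        out = mitotic_binding_score(SiteMatrix(counts=counts), mbf)
        np.testing.assert_allclose(out["mbs"], 0.4, atol=1e-12)

    def test_bounded_by_mbf_range_and_zero_denominator_removed(self, rng):
        counts = pd.DataFrame(
            rng.poisson(0.8, size=(30, 2)),
            index=[f"g{i}" for i in range(30)],
            columns=["a", "b"],
        )
        counts.iloc[0] = 0
        mbf = pd.Series({"a": 0.1, "b": 0.9})
        out = mitotic_binding_score(SiteMatrix(counts=counts), mbf)
        assert "g0" not in out.index
        assert out["mbs"].between(0.1, 0.9).all()

    def test_empty_mbf_rejected(self):
        counts = pd.DataFrame([[1]], index=["g"], columns=["m"])
        with pytest.raises(ValueError):
            mitotic_binding_score(SiteMatrix(counts=counts), pd.Series(dtype=float))


class TestMitoticActivityScore:
    @staticmethod
    def activities(values, grid):
        return ActivityTable(
            activities=pd.DataFrame(values, index=["m1"], columns=grid)
        )

    def test_zero_mitotic_activity_gives_zero_scores(self):
        grid = np.arange(0.0, 100.0)
        a = np.zeros(grid.size)
        a[80:] = 1.0  # activity only after mitosis
        act = self.activities([a], grid)
        counts = pd.DataFrame([[2], [5]], index=["g1", "g2"], columns=["m1"])
        out = mitotic_activity_score(SiteMatrix(counts=counts), act, tau_mit=67.0)
        np.testing.assert_allclose(out["mas"], 0.0, atol=1e-12)

    def test_single_motif_score_is_sites_times_mean_activity(self):
        grid = np.arange(0.0, 100.0)
        a = np.full(grid.size, 0.5)
        act = self.activities([a], grid)
        counts = pd.DataFrame([[4]], index=["g"], columns=["m1"])
        out = mitotic_activity_score(SiteMatrix(counts=counts), act, tau_mit=67.0)
        assert out.loc["g", "mas"] == pytest.approx(4 * 0.5)

    def test_high_mas_genes_peak_earlier(self, small_truth):
        # genes loaded with mitotically active motifs were generated with
        # earlier expression; check the decile contrast on the synthetic truth
        truth = small_truth
        out = mitotic_activity_score(
            truth.true_site_matrix,
            truth.true_activities,
            tau_mit=truth.config.true_lag.tau_mit,
        )
        E = truth.true_expression
        peaks = E.to_numpy().argmax(axis=1)
        top = peaks[(out["group"] == "high").to_numpy()]
        bottom = peaks[(out["group"] == "low").to_numpy()]
        assert top.mean() < bottom.mean()


class TestPeakToGene:
    def annotation(self):
        return pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3", "g4"],
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "tss": [100, 500, 900, 300],
            }
        )

    def test_midpoint_on_tss(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [490], "end": [510]})
        assert peak_to_gene(peaks, self.annotation()) == ["g2"]

    def test_equidistant_tie_goes_to_lower_coordinate(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [290], "end": [310]})
        # midpoint 300 equidistant from tss 100 and 500
        assert peak_to_gene(peaks, self.annotation()) == ["g1"]

    def test_hand_layout_assignment(self):
        peaks = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1", "chr2", "chr3"],
                "start": [80, 460, 1000, 0, 5],
                "end": [120, 480, 1100, 10, 15],
            }
        )
        with pytest.warns(UserWarning, match="chr3"):
            genes = peak_to_gene(peaks, self.annotation())
        assert genes == ["g1", "g2", "g3", "g4"]

    def test_unexpressed_genes_ignored_and_duplicates_collapsed(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [490, 510], "end": [510, 530]}
        )
        genes = peak_to_gene(peaks, self.annotation(), expressed=["g1", "g2"])
        assert genes == ["g2"]


class TestGroupContrast:
    def table(self, rng):
        return pd.DataFrame(
            rng.normal(size=(10, 6)), index=[f"g{i}" for i in range(10)]
        )

    def test_all_genes_group_equals_global_mean(self, rng):
        table = self.table(rng)
        out = group_expression_contrast(table, {"all": list(table.index)})
        np.testing.assert_allclose(
            out["all"].loc["mean"].to_numpy(), table.mean(axis=0).to_numpy()
        )

    def test_identical_groups_identical_profiles(self, rng):
        table = self.table(rng)
        members = ["g1", "g3", "g5"]
        out = group_expression_contrast(table, {"a": members, "b": members})
        pd.testing.assert_frame_equal(out["a"], out["b"])

    def test_early_group_peaks_before_late_group(self):
        t = np.arange(50.0)
        early = [np.exp(-((t - 10) ** 2) / 40.0) for _ in range(5)]
        late = [np.exp(-((t - 40) ** 2) / 40.0) for _ in range(5)]
        table = pd.DataFrame(
            early + late, index=[f"g{i}" for i in range(10)], columns=t
        )
        out = group_expression_contrast(
            table, {"early": [f"g{i}" for i in range(5)],
                    "late": [f"g{i}" for i in range(5, 10)]}
        )
        assert (
            out["early"].loc["mean"].to_numpy().argmax()
            < out["late"].loc["mean"].to_numpy().argmax()
        )

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_expression_contrast(self.table(rng), {"none": ["missing"]})
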