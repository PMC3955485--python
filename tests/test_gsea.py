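import numpy as np
import pandas as pd
import pytest

from pathconsensus import (
    SimulationConfig,
    common_pathways,
    expected_detectable_power,
    gene_t_statistics,
    pathway_score,
    permutation_test,
    significant_pathways,
    simulate_study,
)
from pathconsensus.data_io import ExpressionDataset

from conftest import make_collection, make_dataset
from oracles import exhaustive_permutation_p


class TestGeneTStatistics:
    def test_known_pooled_t(self):
        """TUMOR=(4,5,6) vs NORMAL=(1,2,3): t=3.674, df=4, p~0.021."""
        ds = make_dataset([[4, 5, 6, 1, 2, 3]], ["G1"], 3)
        row = gene_t_statistics(ds).loc["G1"]
        assert row["t"] == pytest.approx(3.674, abs=5e-4)
        assert row["df"] == 4
        assert row["p_two_sided"] == pytest.approx(0.0213, abs=2e-3)

    def test_identical_groups_give_zero(self):
        ds = make_dataset([[2, 3, 4, 2, 3, 4]], ["G1"], 3)
        row = gene_t_statistics(ds).loc["G1"]
        assert row["t"] == 0.0
        assert row["p_two_sided"] == 1.0

    def test_label_swap_negates_t(self):
        vals = [[4.1, 5.0, 6.2, 1.5, 2.0, 3.3]]
        fwd = gene_t_statistics(make_dataset(vals, ["G1"], 3)).loc["G1"]
        rev = gene_t_statistics(
            make_dataset([vals[0][3:] + vals[0][:3]], ["G1"], 3)
        ).loc["G1"]
        assert rev["t"] == pytest.approx(-fwd["t"])
        assert rev["p_two_sided"] == pytest.approx(fwd["p_two_sided"])

    def test_degenerate_gene_excluded(self, caplog):
        # constant within groups but different between them: infinite t
        ds = make_dataset([[1, 1, 1, 2, 2, 2], [4, 5, 6, 1, 2, 3]], ["BAD", "OK"], 3)
        with caplog.at_level("WARNING"):
            out = gene_t_statistics(ds)
        assert list(out.index) == ["OK"]
        assert "degenerate" in caplog.text


class TestPathwayScore:
    def test_mean_of_member_ts(self):
        tstats = pd.DataFrame({"t": [2.0, -1.0, 9.0]}, index=["A", "B", "C"])
        assert pathway_score(tstats, {"A", "B"}) == pytest.approx(0.5)

    def test_single_member_identity(self):
        tstats = pd.DataFrame({"t": [1.7]}, index=["A"])
        assert pathway_score(tstats, {"A"}) == pytest.approx(1.7)

    def test_no_members_raises(self):
        tstats = pd.DataFrame({"t": [1.7]}, index=["A"])
        with pytest.raises(ValueError):
            pathway_score(tstats, {"Z"})


def _toy_study(n_per_group: int, seed: int, n_genes: int = 12):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    values = rng.normal(size=(n_genes, 2 * n_per_group))
    values[: n_genes // 3, :n_per_group] += 1.5  # push the first pathway up
    ds = make_dataset(values, genes, n_per_group)
    gsc = make_collection(
        {
            "pwA": genes[: n_genes // 3],
            "pwB": genes[n_genes // 3 : 2 * n_genes // 3],
            "pwC": genes[2 * n_genes // 3 :],
        }
    )
    return ds, gsc


class TestPermutationTest:
    def test_exhaustive_3v3_enumerates_20_assignments(self):
        ds, gsc = _toy_study(3, seed=0)
        res = permutation_test(ds, gsc, exhaustive=True)
        assert (res["n_permutations"] == 20).all()

    def test_exhaustive_unique_maximum_gives_1_over_20(self):
        # one strongly shifted pathway whose observed score tops all relabelings
        ds, gsc = _toy_study(3, seed=1)
        ds.values.iloc[:4, :3] += 10.0
        res = permutation_test(ds, gsc, exhaustive=True).set_index("pathway_id")
        assert res.loc["pwA", "p_up"] == pytest.approx(1 / 20)

    @pytest.mark.parametrize("n_per_group", [3, 4])
    def test_exhaustive_matches_independent_enumeration(self, n_per_group):
        ds, gsc = _toy_study(n_per_group, seed=2)
        res = permutation_test(ds, gsc, exhaustive=True).set_index("pathway_id")
        for pid in gsc.ids():
            p_up, p_down = exhaustive_permutation_p(ds, gsc[pid].genes)
            assert res.loc[pid, "p_up"] == pytest.approx(p_up, abs=1e-12)
            assert res.loc[pid, "p_down"] == pytest.approx(p_down, abs=1e-12)

    def test_random_stream_within_3se_of_exhaustive(self):
        ds, gsc = _toy_study(4, seed=3)
        B = 1000
        mc = permutation_test(ds, gsc, n_permutations=B, seed=5).set_index("pathway_id")
        for pid in gsc.ids():
            p_up, _ = exhaustive_permutation_p(ds, gsc[pid].genes)
            se = np.sqrt(p_up * (1 - p_up) / B)
            assert abs(mc.loc[pid, "p_up"] - p_up) <= 3 * se + 2 / (B + 1)

    def test_identical_seed_identical_pvalues(self):
        ds, gsc = _toy_study(5, seed=4)
        a = permutation_test(ds, gsc, n_permutations=200, seed=9)
        b = permutation_test(ds, gsc, n_permutations=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_pvalues_floored_at_one_over_b_plus_one(self):
        ds, gsc = _toy_study(5, seed=4)
        res = permutation_test(ds, gsc, n_permutations=100, seed=1)
        assert (res["p_up"] >= 1 / 101).all()
        assert (res["p_down"] >= 1 / 101).all()

    def test_negating_matrix_swaps_directions_exactly(self):
        ds, gsc = _toy_study(5, seed=6)
        res = permutation_test(ds, gsc, n_permutations=300, seed=2)
        neg = ExpressionDataset(
            dataset_id=ds.dataset_id,
            values=-ds.values,
            gene_of_probe=ds.gene_of_probe,
            group_of_sample=ds.group_of_sample,
        )
        res_neg = permutation_test(neg, gsc, n_permutations=300, seed=2)
        a = res.set_index("pathway_id")
        b = res_neg.set_index("pathway_id")
        assert np.allclose(a["p_up"], b.loc[a.index, "p_down"])
        assert np.allclose(a["p_down"], b.loc[a.index, "p_up"])

    def test_zero_permutations_rejected(self):
        ds, gsc = _toy_study(3, seed=0)
        with pytest.raises(ValueError):
            permutation_test(ds, gsc, n_permutations=0)


class TestSignificantPathways:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["pathway_id", "p_up", "p_down"]
        )

    def test_alpha_boundary_is_inclusive(self):
        res = self._frame([("A", 0.05, 0.9), ("B", 0.051, 0.9)])
        up, down = significant_pathways(res, alpha=0.05)
        assert up == {"A"} and down == set()

    def test_smaller_p_wins_when_both_pass(self):
        res = self._frame([("A", 0.01, 0.04)])
        up, down = significant_pathways(res, alpha=0.05)
        assert up == {"A"} and down == set()

    def test_empty_results_give_empty_sets(self):
        up, down = significant_pathways(self._frame([]))
        assert up == set() and down == set()


class TestCommonPathways:
    def test_intersection(self):
        per = [({"A", "B"}, set()), ({"B", "C"}, set()), ({"B"}, set())]
        up, down = common_pathways(per)
        assert up == {"B"} and down == set()

    def test_direction_discordance_excludes(self):
        per = [({"A"}, set()), ({"A"}, set()), (set(), {"A"})]
        up, down = common_pathways(per)
        assert up == set() and down == set()

    def test_single_dataset_identity(self):
        up, down = common_pathways([({"X"}, {"Y"})])
        assert up == {"X"} and down == {"Y"}


def test_planted_pathways_recovered_at_least_at_gene_level_power():
    """Pathway-level recovery in a 7v7 cohort beats the single-gene power
    bound predicted by the Monte-Carlo helper (mean-t pools 10 genes)."""
    cfg = SimulationConfig(
        n_datasets=1, samples_per_group=(7,), n_genes=300, n_pathways=30,
        genes_per_pathway=10, probes_per_gene=(1, 1), frac_up_pathways=1 / 3,
        frac_down_pathways=0.0, effect_size=1.0, noise_sd=1.0,
        iqr_decoy_frac=0.0, seed=13,
    )
    (ds,), gsc, truth = simulate_study(cfg)
    res = permutation_test(ds, gsc, n_permutations=1000, seed=21)
    up, _ = significant_pathways(res, alpha=0.05)
    recovered = len(up & truth.up_pathways) / len(truth.up_pathways)
    predicted = expected_detectable_power(cfg, n_sim=2000)
    se = np.sqrt(predicted * (1 - predicted) / len(truth.up_pathways))
    assert recovered >= predicted - 3 * se
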