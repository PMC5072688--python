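import numpy as np
import pandas as pd
import pytest

from powerfate import (
    EvalResult,
    ObservationTable,
    SplitScheme,
    cellline_scores,
    count_joint_threshold,
    cross_cellline,
    dream8_protein_cv,
    generate_influence_dataset,
    generate_powerlaw_dataset,
    iter_folds,
    run_crossval,
    stagger_index_pairs,
    summarize_crossval,
    time_staggered_pairs,
)

INPUT_IDX = range(8)          # signaling measured at grid positions 0..7
OUTPUT_IDX = (0, 6, 7, 8, 9)  # fates measured at 0 and 6..9


class TestFolds:
    def test_kfold_partitions_exactly(self):
        scheme = SplitScheme(kind="kfold", k=5, repeats=3, seed=2)
        folds = list(iter_folds(23, scheme))
        assert len(folds) == 15
        for rep in range(3):
            test_union = np.concatenate(
                [t for _, t in folds[rep * 5:(rep + 1) * 5]])
            assert sorted(test_union) == list(range(23))

    def test_loocv(self):
        folds = list(iter_folds(4, SplitScheme(kind="loocv")))
        assert [list(t) for _, t in folds] == [[0], [1], [2], [3]]

    def test_same_seed_same_folds(self):
        a = [t.tolist() for _, t in iter_folds(30, SplitScheme(seed=9, repeats=2))]
        b = [t.tolist() for _, t in iter_folds(30, SplitScheme(seed=9, repeats=2))]
        assert a == b


class TestRunCrossval:
    def test_five_fold_200_repeats_yield_1000_results(self):
        table, _ = generate_powerlaw_dataset(40, 3, seed=0, noise_sd=0.1)
        scheme = SplitScheme(k=5, repeats=200, seed=1)
        results = run_crossval(table, "death", "powerlaw", scheme,
                               epsilon=1e-6, n_components=3)
        assert len(results) == 1000

    def test_deterministic_given_seed(self):
        table, _ = generate_powerlaw_dataset(30, 3, seed=2, noise_sd=0.1)
        scheme = SplitScheme(k=5, repeats=2, seed=5)
        r1 = run_crossval(table, "death", "powerlaw", scheme, 1e-6, 3)
        r2 = run_crossval(table, "death", "powerlaw", scheme, 1e-6, 3)
        assert r1 == r2

    def test_noise_free_model_gives_perfect_folds(self):
        table, truth = generate_powerlaw_dataset(50, 3, seed=3, noise_sd=0.0)
        scheme = SplitScheme(k=5, repeats=2, seed=0)
        results = run_crossval(table, "death", "powerlaw", scheme,
                               epsilon=truth.epsilon, n_components=3)
        for r in results:
            assert r.valid
            assert r.spearman == pytest.approx(1.0)
            assert r.pearson == pytest.approx(1.0, abs=1e-9)

    def test_powerlaw_beats_linear_on_powerlaw_data(self):
        # headline direction: the nonlinear model clears joint thresholds
        # more often than the linear baseline, across seeds
        wins = 0
        for seed in range(10):
            table, _ = generate_powerlaw_dataset(
                60, 3, beta=np.array([0.9, -0.7, 0.5]), beta0=-1.0,
                epsilon=1e-4, noise_sd=0.1, seed=seed, signal_sigma=0.8)
            scheme = SplitScheme(k=5, repeats=4, seed=seed)
            pl = run_crossval(table, "death", "powerlaw", scheme, 1e-6, 3)
            li = run_crossval(table, "death", "linear", scheme, 1e-6, 3)
            if count_joint_threshold(pl, 0.8) >= count_joint_threshold(li, 0.8):
                wins += 1
        assert wins == 10


class TestJointThreshold:
    def test_counts_by_definition(self):
        results = [EvalResult(0.9, 0.9, 0.1, 0.1, 5),
                   EvalResult(0.6, 0.95, 0.1, 0.1, 5)]
        assert count_joint_threshold(results, 0.7) == 1

    def test_empty_list(self):
        assert count_joint_threshold([], 0.7) == 0

    def test_monotone_nonincreasing_in_tau(self):
        rng = np.random.default_rng(0)
        results = [EvalResult(s, p, 0.1, 0.1, 5)
                   for s, p in rng.uniform(-1, 1, size=(50, 2))]
        counts = [count_joint_threshold(results, tau)
                  for tau in np.linspace(-1, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_results_excluded(self):
        results = [EvalResult(np.nan, np.nan, 0.1, 0.1, 2, valid=False)]
        assert count_joint_threshold(results, 0.0) == 0
        assert summarize_crossval(results)["n_excluded"] == 1


class TestCrossCellline:
    def test_self_transfer_of_perfect_model(self):
        table, truth = generate_powerlaw_dataset(40, 3, seed=4, noise_sd=0.0)
        res = cross_cellline(table, table, "death", "powerlaw",
                             epsilon=truth.epsilon, n_components=3)
        assert res.spearman == pytest.approx(1.0)
        assert res.kl == pytest.approx(0.0, abs=1e-6)

    def test_transfer_is_asymmetric_between_heterogeneous_lines(self):
        t1, _ = generate_powerlaw_dataset(
            40, 3, beta=np.array([0.5, -0.2, 0.3]), seed=5, noise_sd=0.05)
        t2, _ = generate_powerlaw_dataset(
            40, 3, beta=np.array([-0.4, 0.6, 0.1]), seed=6, noise_sd=0.05)
        ab = cross_cellline(t1, t2, "death", "powerlaw", n_components=3)
        ba = cross_cellline(t2, t1, "death", "powerlaw", n_components=3)
        assert ab != ba

    def test_protein_mismatch_rejected(self):
        t1, _ = generate_powerlaw_dataset(20, 3, seed=0)
        t2, _ = generate_powerlaw_dataset(20, 2, seed=0)
        with pytest.raises(ValueError, match="protein"):
            cross_cellline(t1, t2, "death", "powerlaw")


class TestDream8ProteinCV:
    def test_noise_free_influence_system_predicts_well(self):
        control, _ = generate_influence_dataset(36, seed=7, noise_sd=0.01,
                                                fate_noise_sd=0.0)
        res = dream8_protein_cv(control, "powerlaw", seed=0, n_repeats=2,
                                n_components=2)
        # hub and reporters are near-deterministic functions of the rest
        assert res["per_protein"]["prot2"] < 0.1

    def test_deterministic_given_seed(self):
        control, _ = generate_influence_dataset(24, seed=8)
        a = dream8_protein_cv(control, "powerlaw", seed=3, n_repeats=2,
                              n_components=2)
        b = dream8_protein_cv(control, "powerlaw", seed=3, n_repeats=2,
                              n_components=2)
        assert a == b


class TestStagger:
    @pytest.mark.parametrize("degree,expected", [
        (2, {(0, 0), (4, 6), (5, 7), (6, 8), (7, 9)}),
        (3, {(0, 0), (3, 6), (4, 7), (5, 8), (6, 9)}),
        (4, {(0, 0), (2, 6), (3, 7), (4, 8), (5, 9)}),
        (5, {(0, 0), (1, 6), (2, 7), (3, 8), (4, 9)}),
    ])
    def test_design_pairs_for_each_degree(self, degree, expected):
        assert stagger_index_pairs(INPUT_IDX, OUTPUT_IDX, degree) == expected

    def test_oversized_degree_keeps_only_baseline_pair(self):
        assert stagger_index_pairs(INPUT_IDX, OUTPUT_IDX, 50) == {(0, 0)}

    def test_table_join_carries_input_signals_to_output_fates(self):
        grid = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0)
        meta = {"cell_line": "A", "treatment": "ctrl", "replicate": 1}
        sig = pd.DataFrame([{**meta, "time_point": grid[i], "p0": 10.0 + i}
                            for i in INPUT_IDX])
        fat = pd.DataFrame([{**meta, "time_point": grid[o], "death": o / 10}
                            for o in OUTPUT_IDX])
        sig_t = ObservationTable(sig, ("p0",), (),
                                 ("cell_line", "treatment", "replicate", "time_point"))
        fat_t = ObservationTable(fat, (), ("death",),
                                 ("cell_line", "treatment", "replicate", "time_point"))
        out = time_staggered_pairs(sig_t, fat_t, degree=3)
        assert out.n_obs == 5
        row = out.data.set_index("time_point").loc[grid[6]]
        assert row["p0"] == 13.0 and row["death"] == 0.6


class TestCelllineScores:
    @staticmethod
    def combined_two_lines():
        rng = np.random.default_rng(0)
        frames = []
        for name, shift in (("A", 0.0), ("B", 3.0)):
            X = rng.lognormal(shift, 0.3, size=(30, 3))
            df = pd.DataFrame(X, columns=["p0", "p1", "p2"])
            df["death"] = np.exp(-1 + 0.5 * np.log(df["p0"])) + 1e-4
            df["cell_line"] = name
            frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        return ObservationTable(data, ("p0", "p1", "p2"), ("death",),
                                ("cell_line",))

    def test_separable_lines_fully_classified(self):
        res = cellline_scores(self.combined_two_lines(), "powerlaw")
        assert res["n_misclassified"] == 0

    def test_single_line_trivially_classified(self):
        table = self.combined_two_lines()
        only_a = table.subset((table.data["cell_line"] == "A").to_numpy())
        res = cellline_scores(only_a, "powerlaw")
        assert res["n_misclassified"] == 0

    def test_scores_deterministic(self):
        t = self.combined_two_lines()
        r1 = cellline_scores(t, "powerlaw")
        r2 = cellline_scores(t, "powerlaw")
        pd.testing.assert_frame_equal(r1["scores"], r2["scores"])
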