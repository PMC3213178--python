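"""Pareto ranking, annealing acceptance, pattern search, cross-validation
folds and sub-ensemble selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from insulinit.network import ParameterVector
from insulinit.poets import (
    ArchiveEntry,
    EnsembleArchive,
    POETSConfig,
    acceptance_probability,
    dominates,
    make_cv_folds,
    mean_pairwise_correlation,
    parameter_cv,
    pareto_rank,
    pattern_search,
    perturb,
    random_control_parameters,
    run_poets,
    select_subensemble,
)


class TestDominance:
    def test_strict_domination(self):
        assert dominates(np.array([1, 1]), np.array([2, 2]))

    def test_incomparable_pair(self):
        a, b = np.array([1, 2]), np.array([2, 1])
        assert not dominates(a, b) and not dominates(b, a)

    def test_irreflexive(self):
        e = np.array([1.0, 2.0])
        assert not dominates(e, e)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dominates(np.array([1.0]), np.array([1.0, 2.0]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 10), min_size=2, max_size=6),
        st.lists(st.floats(0, 10), min_size=2, max_size=6),
    )
    def test_antisymmetric(self, a, b):
        n = min(len(a), len(b))
        ea, eb = np.array(a[:n]), np.array(b[:n])
        assert not (dominates(ea, eb) and dominates(eb, ea))


class TestParetoRank:
    def test_empty_archive(self):
        assert pareto_rank(np.array([1.0, 2.0]), np.empty((0, 2))) == 0

    def test_counts_dominating_members(self):
        archive = np.array(
            [[0.5, 0.5], [0.9, 0.9], [2.0, 0.1], [0.2, 3.0], [0.9, 1.1]]
        )
        # candidate (1,1): dominated by rows 0 and 1 only
        assert pareto_rank(np.array([1.0, 1.0]), archive) == 2

    def test_matches_brute_force_on_random_vectors(self, rng):
        vecs = rng.uniform(0, 1, size=(100, 4))
        for i in range(100):
            others = np.delete(vecs, i, axis=0)
            expected = sum(dominates(o, vecs[i]) for o in others)
            assert pareto_rank(vecs[i], others) == expected


class TestAcceptanceProbability:
    def test_rank_zero_always_one(self):
        for T in (0.01, 1.0, 100.0):
            assert acceptance_probability(0, T) == 1.0

    def test_closed_form(self):
        assert acceptance_probability(2, 2.0) == pytest.approx(np.exp(-1.0))

    def test_monotone_in_temperature_and_rank(self):
        probs_T = [acceptance_probability(3, T) for T in (4.0, 2.0, 1.0, 0.5)]
        assert all(a > b for a, b in zip(probs_T, probs_T[1:]))
        probs_r = [acceptance_probability(r, 1.0) for r in range(5)]
        assert all(a >= b for a, b in zip(probs_r, probs_r[1:]))

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            acceptance_probability(1, 0.0)


class TestPerturb:
    def _params(self):
        return ParameterVector(np.ones(20), np.full(10, 2.0))

    def test_small_magnitude_limit(self, rng):
        out = perturb(self._params(), 1e-6, rng)
        np.testing.assert_allclose(out.rate_constants, 1.0, rtol=1e-5)

    def test_seeded_determinism(self):
        a = perturb(self._params(), 0.25, np.random.default_rng(7))
        b = perturb(self._params(), 0.25, np.random.default_rng(7))
        np.testing.assert_array_equal(a.as_array(), b.as_array())

    def test_factor_mean_near_one(self):
        rng = np.random.default_rng(0)
        p = ParameterVector(np.ones(10_000), np.empty(0))
        out = perturb(p, 0.25, rng, perturb_initial_conditions=False)
        assert abs(out.rate_constants.mean() - 1.0) < 0.01

    def test_frozen_initial_conditions(self, rng):
        out = perturb(self._params(), 0.25, rng, perturb_initial_conditions=False)
        np.testing.assert_array_equal(out.initial_conditions, np.full(10, 2.0))

    def test_invalid_magnitude(self, rng):
        with pytest.raises(ValueError):
            perturb(self._params(), 1.5, rng)


class TestPatternSearch:
    @staticmethod
    def _quadratic(target):
        def evaluate(p: ParameterVector):
            return np.array([float((p.rate_constants[0] - target) ** 2)])

        return evaluate

    def test_converges_on_quadratic(self):
        p = ParameterVector(np.array([5.0]), np.empty(0))
        out = pattern_search(p, 0, self._quadratic(2.0), steps=200)
        assert abs(out.rate_constants[0] - 2.0) < 1e-3

    def test_zero_steps_is_identity(self):
        p = ParameterVector(np.array([5.0]), np.empty(0))
        out = pattern_search(p, 0, self._quadratic(2.0), steps=0)
        assert out.rate_constants[0] == 5.0

    @pytest.mark.parametrize("seed", range(3))
    def test_never_increases_selected_objective(self, seed):
        rng = np.random.default_rng(seed)
        target = rng.uniform(0.5, 4.0)
        evaluate = self._quadratic(target)
        p = ParameterVector(np.array([rng.uniform(0.1, 8.0)]), np.empty(0))
        before = evaluate(p)[0]
        out = pattern_search(p, 0, evaluate, steps=rng.integers(1, 40))
        assert evaluate(out)[0] <= before


class TestRunPoets:
    @staticmethod
    def _biobjective(a, b):
        """Scalar trade-off family: minimise (k-a)^2 and (k-b)^2."""

        def evaluate(p: ParameterVector):
            k = p.rate_constants[0]
            return np.array([(k - a) ** 2, (k - b) ** 2])

        return evaluate

    def test_rank_zero_front_spans_tradeoff_interval(self):
        a, b = 1.0, 3.0
        evaluate = self._biobjective(a, b)
        config = POETSConfig(
            iterations=600, epoch_size=50, pattern_search_interval=0,
            perturb_initial_conditions=False,
        )
        rng = np.random.default_rng(5)
        archive = run_poets(
            evaluate, ParameterVector(np.array([2.0]), np.empty(0)), config, rng
        )
        archive.recompute_ranks()
        ks = np.array([e.params.rate_constants[0] for e in archive.rank_zero()])
        # the analytic Pareto set is k in [a, b]
        assert ks.min() < a + 0.2
        assert ks.max() > b - 0.2
        assert np.all(ks > a - 0.3) and np.all(ks < b + 0.3)

    def test_seeded_run_reproducible(self):
        evaluate = self._biobjective(1.0, 2.0)
        config = POETSConfig(iterations=100, epoch_size=20,
                             perturb_initial_conditions=False)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            arch = run_poets(
                evaluate, ParameterVector(np.array([1.5]), np.empty(0)), config, rng
            )
            runs.append(arch)
        np.testing.assert_array_equal(
            runs[0].params_matrix(), runs[1].params_matrix()
        )
        np.testing.assert_array_equal(
            runs[0].errors_matrix(), runs[1].errors_matrix()
        )

    def test_stored_ranks_match_brute_force_recomputation(self):
        evaluate = self._biobjective(0.5, 2.5)
        config = POETSConfig(iterations=150, epoch_size=25,
                             perturb_initial_conditions=False)
        rng = np.random.default_rng(3)
        archive = run_poets(
            evaluate, ParameterVector(np.array([1.0]), np.empty(0)), config, rng
        )
        errs = archive.errors_matrix()
        for i, entry in enumerate(archive.entries):
            others = np.delete(errs, i, axis=0)
            expected = sum(dominates(o, entry.errors) for o in others)
            assert entry.rank == expected

    def test_failing_initial_params_rejected(self):
        def evaluate(p):
            return np.array([np.inf, 1.0])

        with pytest.raises(RuntimeError, match="initial"):
            run_poets(
                evaluate,
                ParameterVector(np.array([1.0]), np.empty(0)),
                POETSConfig(iterations=5),
                np.random.default_rng(0),
            )


class TestCVFolds:
    def test_24_objectives_make_8_folds_of_21_3(self, rng):
        ids = [f"O{i:02d}" for i in range(1, 25)]
        folds = make_cv_folds(ids, rng)
        assert len(folds) == 8
        for f in folds:
            assert len(f.train_ids) == 21
            assert len(f.validation_ids) == 3
            assert set(f.train_ids) | set(f.validation_ids) == set(ids)
            assert not set(f.train_ids) & set(f.validation_ids)

    def test_validation_sets_partition_all_ids(self, rng):
        ids = [f"O{i}" for i in range(6)]
        folds = make_cv_folds(ids, rng)
        assert len(folds) == 2
        union = set()
        for f in folds:
            assert not union & set(f.validation_ids)
            union |= set(f.validation_ids)
        assert union == set(ids)

    def test_indivisible_count_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            make_cv_folds(["a", "b", "c", "d"], rng)


def _archive_from(rates_list, errors_list):
    entries = [
        ArchiveEntry(ParameterVector(np.array(r), np.empty(0)), np.array(e))
        for r, e in zip(rates_list, errors_list)
    ]
    return EnsembleArchive(entries, n_reactions=len(rates_list[0]))


class TestSubensembleSelection:
    def test_identical_entries_report_full_correlation(self, rng):
        arch = _archive_from([[1.0, 2.0, 3.0]] * 5, [[0.1, 0.1]] * 5)
        sub = select_subensemble([arch], 3, rng)
        assert sub.mean_pairwise_correlation == pytest.approx(1.0)

    def test_closest_to_origin_preferred(self, rng):
        arch = _archive_from(
            [[1.0, 2.0], [1.0, 2.0]], [[0.1, 0.1], [5.0, 5.0]]
        )
        sub = select_subensemble([arch], 1, rng)
        np.testing.assert_allclose(sub.entries[0].errors, [0.1, 0.1])

    def test_two_cluster_archive_selection_spans_clusters(self, rng):
        # two decorrelated log-parameter clusters
        cluster_a = [[1.0, 10.0, 1.0, 10.0, 1.0, 10.0]] * 10
        cluster_b = [[10.0, 1.0, 10.0, 1.0, 10.0, 1.0]] * 10
        arch = _archive_from(cluster_a + cluster_b, [[0.1, 0.1]] * 20)
        sub = select_subensemble([arch], 6, rng)
        mat = sub.rate_constant_matrix()
        from_a = np.sum(mat[:, 0] < 5)
        from_b = np.sum(mat[:, 0] > 5)
        assert from_a > 0 and from_b > 0
        single = mean_pairwise_correlation(np.array(cluster_a[:6]))
        assert sub.mean_pairwise_correlation < single

    def test_insufficient_rank_zero_selects_all_with_warning(self, rng):
        arch = _archive_from([[1.0], [2.0]], [[0.1], [0.2]])
        with pytest.warns(UserWarning, match="selecting all"):
            sub = select_subensemble([arch], 10, rng)
        assert len(sub) <= 2


class TestParameterCV:
    def test_identical_members_zero_cv(self):
        arch = _archive_from([[1.0, 2.0]] * 4, [[0.1]] * 4)
        np.testing.assert_array_equal(parameter_cv(arch), [0.0, 0.0])

    def test_two_member_sample_convention(self):
        arch = _archive_from([[1.0], [3.0]], [[0.1], [0.1]])
        # sample std of (1, 3) is sqrt(2); mean is 2
        assert parameter_cv(arch)[0] == pytest.approx(np.sqrt(2) / 2)

    def test_needs_two_members(self):
        arch = _archive_from([[1.0]], [[0.1]])
        with pytest.raises(ValueError):
            parameter_cv(arch)


class TestEnsembleIO:
    def test_save_load_round_trip(self, tmp_path):
        arch = _archive_from(
            [[1.0, 2.0], [3.0, 4.0]], [[0.1, 0.2], [0.3, 0.4]]
        )
        arch.seed = 7
        arch.save(tmp_path / "ens")
        back = EnsembleArchive.load(tmp_path / "ens")
        np.testing.assert_allclose(back.params_matrix(), arch.params_matrix())
        np.testing.assert_allclose(back.errors_matrix(), arch.errors_matrix())
        assert back.seed == 7

    def test_flat_file_ingestion(self, tmp_path):
        # one whitespace-separated parameter vector per file
        vecs = [np.array([1.0, 2.0, 3.0, 4.0]), np.array([5.0, 6.0, 7.0, 8.0])]
        paths = []
        for i, v in enumerate(vecs):
            p = tmp_path / f"params_{i}.dat"
            np.savetxt(p, v)
            paths.append(p)
        arch = EnsembleArchive.load_flat_files(paths, n_reactions=3)
        assert len(arch) == 2
        np.testing.assert_allclose(arch.entries[0].params.rate_constants, [1, 2, 3])
        np.testing.assert_allclose(arch.entries[1].params.initial_conditions, [8.0])


def test_random_control_spans_one_decade(rng):
    nominal = ParameterVector(np.ones(5000), np.ones(3))
    ctrl = random_control_parameters(nominal, rng)
    logs = np.log10(ctrl.rate_constants)
    assert logs.min() > -1.0 - 1e-9 and logs.max() < 1.0 + 1e-9
    assert abs(logs.mean()) < 0.05  # log-uniform centred on nominal
    np.testing.assert_array_equal(ctrl.initial_conditions, nominal.initial_conditions)
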