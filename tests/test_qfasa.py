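import numpy as np
import pytest

from fasdiet import synth
from fasdiet.qfasa import (
    DietEstimate,
    PreyBasis,
    bootstrap_diet,
    estimate_diet,
    kl_distance,
    mixture,
)
from fasdiet.signatures import FABinSet, SignatureLibrary, replace_zeros
from helpers import grid_min_kl


@pytest.fixture
def two_prey_basis():
    bins = FABinSet(("a", "b"))
    means = np.array([[0.2, 0.8], [0.6, 0.4]])
    return PreyBasis(("p1", "p2"), means, bins)


@pytest.fixture(scope="module")
def fixture_basis():
    """4-taxon basis from reference means: fish (Perciformes column),
    mollusc, frog, crayfish."""
    models = {m.column: m for m in synth.fixture_models()}
    cols = ("fish_perc", "mollusc", "frog", "crayfish")
    means = np.array([replace_zeros(models[c].mean / 100.0) for c in cols])
    return PreyBasis(("fish", "mollusc", "frog", "crayfish"), means,
                     models["mollusc"].bin_set)


class TestMixture:
    def test_unit_vector_returns_prey_signature(self, two_prey_basis):
        np.testing.assert_allclose(
            mixture(np.array([1.0, 0.0]), two_prey_basis), [0.2, 0.8]
        )

    def test_identical_prey(self):
        bins = FABinSet(("a", "b"))
        means = np.array([[0.3, 0.7], [0.3, 0.7]])
        basis = PreyBasis(("p1", "p2"), means, bins)
        np.testing.assert_allclose(mixture(np.array([0.5, 0.5]), basis), [0.3, 0.7])

    def test_hand_arithmetic(self, two_prey_basis):
        np.testing.assert_allclose(
            mixture(np.array([0.5, 0.5]), two_prey_basis), [0.4, 0.6]
        )

    def test_dimension_mismatch(self, two_prey_basis):
        with pytest.raises(ValueError):
            mixture(np.array([0.5, 0.3, 0.2]), two_prey_basis)

    def test_calibration_applied_and_closed(self):
        bins = FABinSet(("a", "b"))
        basis = PreyBasis(
            ("p1",), np.array([[0.5, 0.5]]), bins, calibration=np.array([2.0, 1.0])
        )
        out = mixture(np.array([1.0]), basis)
        np.testing.assert_allclose(out, [2 / 3, 1 / 3])


class TestKlDistance:
    def test_hand_value(self):
        got = kl_distance(np.array([0.5, 0.5]), np.array([0.9, 0.1]))
        expect = (-0.4) * np.log(5 / 9) + 0.4 * np.log(5)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(0.8789, abs=1e-4)

    def test_properties_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            d = int(rng.integers(2, 12))
            x = rng.dirichlet(np.ones(d)) + 1e-6
            y = rng.dirichlet(np.ones(d)) + 1e-6
            x, y = x / x.sum(), y / y.sum()
            assert kl_distance(x, x) == 0.0
            dxy = kl_distance(x, y)
            assert dxy >= 0
            assert dxy == pytest.approx(kl_distance(y, x), rel=1e-12)

    def test_zero_iff_equal(self):
        rng = np.random.default_rng(5)
        x = rng.dirichlet(np.ones(6))
        y = x.copy()
        y[0] += 1e-4
        y /= y.sum()
        assert kl_distance(x, y) > 0

    def test_nonpositive_entry_instructs_replacement(self):
        with pytest.raises(ValueError, match="replace_zeros"):
            kl_distance(np.array([0.0, 1.0]), np.array([0.5, 0.5]))

    def test_one_sided_form(self):
        x = np.array([0.5, 0.5])
        y = np.array([0.9, 0.1])
        d = kl_distance(x, y, form="one_sided")
        assert d == pytest.approx(0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(5), rel=1e-12)
        assert d != pytest.approx(kl_distance(y, x, form="one_sided"))


class TestEstimateDiet:
    def test_member_recovery(self, fixture_basis):
        est = estimate_diet(fixture_basis.means[2], fixture_basis)
        expect = np.zeros(4)
        expect[2] = 1.0
        np.testing.assert_allclose(est.proportions, expect, atol=1e-6)
        assert est.achieved_distance < 1e-10

    def test_two_prey_recovery_vs_fine_grid(self, two_prey_basis):
        y = mixture(np.array([0.6, 0.4]), two_prey_basis)
        est = estimate_diet(y, two_prey_basis)
        np.testing.assert_allclose(est.proportions, [0.6, 0.4], atol=1e-4)
        grid_best = grid_min_kl(y, two_prey_basis.means, step=1e-4)
        assert est.achieved_distance <= grid_best + 1e-12

    def test_fixture_mixture_recovery(self, fixture_basis):
        truth = np.array([0.377, 0.320, 0.273, 0.030])
        y = mixture(truth, fixture_basis)
        est = estimate_diet(y, fixture_basis)
        np.testing.assert_allclose(est.proportions, truth, atol=1e-3)

    def test_three_taxon_grid_oracle(self, fixture_basis):
        """Optimizer objective never exceeds the dense simplex grid."""
        sub = PreyBasis(
            fixture_basis.taxa[:3], fixture_basis.means[:3], fixture_basis.bin_set
        )
        y = mixture(np.array([0.5, 0.2, 0.3]), sub)
        est = estimate_diet(y, sub)
        assert est.achieved_distance <= grid_min_kl(y, sub.means, 1e-3) + 1e-6

    def test_deterministic_given_seed(self, fixture_basis):
        y = mixture(np.array([0.25, 0.25, 0.25, 0.25]), fixture_basis)
        a = estimate_diet(y, fixture_basis, seed=7)
        b = estimate_diet(y, fixture_basis, seed=7)
        np.testing.assert_array_equal(a.proportions, b.proportions)

    def test_taxon_permutation_equivariance(self, fixture_basis):
        truth = np.array([0.377, 0.320, 0.273, 0.030])
        y = mixture(truth, fixture_basis)
        perm = [2, 0, 3, 1]
        permuted = PreyBasis(
            tuple(fixture_basis.taxa[i] for i in perm),
            fixture_basis.means[perm],
            fixture_basis.bin_set,
        )
        a = estimate_diet(y, fixture_basis)
        b = estimate_diet(y, permuted)
        np.testing.assert_allclose(a.proportions[perm], b.proportions, atol=1e-6)

    def test_one_sided_objective_recovers_noiseless_mixture(self, fixture_basis):
        truth = np.array([0.377, 0.320, 0.273, 0.030])
        y = mixture(truth, fixture_basis)
        est = estimate_diet(y, fixture_basis, form="one_sided")
        np.testing.assert_allclose(est.proportions, truth, atol=1e-3)

    def test_zero_replacement_of_predator(self, fixture_basis):
        y = np.zeros(fixture_basis.bin_set.size)
        y[0] = 0.5
        y[1] = 0.5
        est = estimate_diet(y, fixture_basis)  # zeros replaced internally
        assert est.proportions.sum() == pytest.approx(1.0, abs=1e-8)


class TestBootstrapDiet:
    def _const_libraries(self):
        bins = FABinSet(("a", "b", "c"))
        prey_mat = np.array([[0.6, 0.3, 0.1]] * 4 + [[0.1, 0.3, 0.6]] * 4)
        prey = SignatureLibrary.from_arrays(
            prey_mat, bins, group=["p1"] * 4 + ["p2"] * 4
        )
        pred_mat = np.tile([0.35, 0.3, 0.35], (5, 1))
        preds = SignatureLibrary.from_arrays(pred_mat, bins, group="otter")
        return preds, prey

    def test_zero_variance_gives_zero_se(self):
        preds, prey = self._const_libraries()
        est = bootstrap_diet(preds, prey, reps=20, seed=0)
        np.testing.assert_allclose(est.se, 0.0, atol=1e-12)
        np.testing.assert_allclose(est.proportions, [0.5, 0.5], atol=1e-4)

    def test_reps_below_two_rejected(self):
        preds, prey = self._const_libraries()
        with pytest.raises(ValueError):
            bootstrap_diet(preds, prey, reps=1)

    def test_se_shrinks_with_root_n_predators(self):
        """Doubling predator n shrinks the mean bootstrap SE by ≈ 1/√2."""
        bins = FABinSet(tuple("abcdef"))
        rng = np.random.default_rng(6)
        prey_mat = np.vstack(
            [rng.dirichlet(np.full(6, 20.0), 8), rng.dirichlet(np.full(6, 3.0), 8)]
        )
        prey = SignatureLibrary.from_arrays(
            prey_mat, bins, group=["p1"] * 8 + ["p2"] * 8
        )
        basis = PreyBasis.from_library(prey)
        ratios = []
        for study in range(30):
            srng = np.random.default_rng(100 + study)
            base = mixture(np.array([0.7, 0.3]), basis)
            noise = lambda n: base * np.exp(0.15 * srng.standard_normal((n, 6)))
            small = noise(10)
            large = noise(20)
            lib_small = SignatureLibrary.from_arrays(
                small / small.sum(axis=1, keepdims=True), bins, group="otter"
            )
            lib_large = SignatureLibrary.from_arrays(
                large / large.sum(axis=1, keepdims=True), bins, group="otter"
            )
            se_small = bootstrap_diet(
                lib_small, prey, reps=40, seed=study, resample="predators"
            ).se.mean()
            se_large = bootstrap_diet(
                lib_large, prey, reps=40, seed=1000 + study, resample="predators"
            ).se.mean()
            ratios.append(se_large / se_small)
        mean_ratio = np.mean(ratios)
        assert mean_ratio == pytest.approx(1 / np.sqrt(2), rel=0.2)

    def test_report_shape(self):
        preds, prey = self._const_libraries()
        est = bootstrap_diet(preds, prey, reps=10, seed=0)
        text = est.summary()
        lines = text.splitlines()
        assert len(lines) == 2
        for line in lines:
            assert "±" in line and line.endswith("%")

    def test_empty_taxon_rejected(self):
        preds, prey = self._const_libraries()
        with pytest.raises(ValueError, match="p3"):
            bootstrap_diet(preds, prey, taxa=("p1", "p2", "p3"), reps=5)


class TestDietEstimate:
    def test_simplex_invariant(self):
        with pytest.raises(ValueError):
            DietEstimate(("a", "b"), np.array([0.7, 0.7]), 0.0)
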