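import numpy as np
import pytest
from scipy.stats import norm

from chromcause import (KernelConfig, conditional_mutual_information, mig,
                        mutual_information, pairwise_dependency_table,
                        parzen_density, discretize, MarkMatrix)
from chromcause.errors import ValidationError
from oracles import empirical_entropy, histogram_mi


class TestParzenDensity:
    def test_single_center_equals_gaussian_kernel(self):
        cfg = KernelConfig(bandwidth_rule="fixed", h=0.7)
        samples = np.array([0.0, 0.0])
        q = 1.3
        assert parzen_density(samples, q, cfg) == pytest.approx(
            norm.pdf(q, loc=0.0, scale=0.7))

    @pytest.mark.parametrize("d", [1, 2])
    def test_integrates_to_one(self, d):
        rng = np.random.default_rng(3)
        samples = rng.standard_normal((60, d))
        lo, hi, steps = -6.0, 6.0, 121
        axes = [np.linspace(lo, hi, steps)] * d
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
        dens = np.asarray(parzen_density(samples, grid))
        cell = ((hi - lo) / (steps - 1)) ** d
        assert np.sum(dens) * cell == pytest.approx(1.0, abs=1e-3)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        samples = rng.standard_normal(40)
        cfg = KernelConfig(bandwidth_rule="fixed", h=0.5)
        v0 = parzen_density(samples, 0.4, cfg)
        v1 = parzen_density(samples + 10.0, 10.4, cfg)
        assert v0 == pytest.approx(v1, rel=1e-12)

    def test_strictly_positive_far_from_samples(self):
        assert parzen_density(np.array([0.0, 1.0]), 8.0) > 0.0

    def test_dimension_above_three_rejected(self):
        with pytest.raises(ValidationError, match="unsupported"):
            parzen_density(np.zeros((10, 4)), np.zeros(4))


class TestPluginMI:
    def test_identity_three_categories_is_ln3(self):
        x = np.tile([0, 1, 2], 200)
        assert mutual_information(x, x, estimator="plugin") == pytest.approx(
            np.log(3), abs=1e-12)

    def test_independent_permuted_columns_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 2000)
        y = rng.permutation(x)
        assert abs(mutual_information(x, y, estimator="plugin")) < 0.02

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_independent_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 300)
        y = (x + rng.integers(0, 2, 300)) % 3
        ours = mutual_information(x, y, estimator="plugin")
        assert ours == pytest.approx(histogram_mi(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegative_and_bounded_by_entropies(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.integers(0, 3, 400)
        y = rng.integers(0, 4, 400)
        mi = mutual_information(x, y, estimator="plugin")
        assert -1e-12 <= mi <= min(empirical_entropy(x), empirical_entropy(y)) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            mutual_information(np.zeros(5, dtype=int), np.zeros(6, dtype=int),
                               estimator="plugin")

    def test_small_sample_kernel_warns(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="fewer than 50"):
            mutual_information(rng.standard_normal(20),
                               rng.standard_normal(20), estimator="kernel")


class TestCMI:
    def test_constant_conditioner_is_vacuous(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 400)
        y = (x + rng.integers(0, 2, 400)) % 3
        z = np.full(400, 3.7)
        for est in ("plugin", "kernel"):
            mi = mutual_information(x, y, estimator=est)
            cmi = conditional_mutual_information(x, y, z, estimator=est)
            assert cmi == pytest.approx(mi, abs=1e-9)

    def test_chain_conditioning_removes_dependence(self):
        # x -> z -> y: conditioning on the middle variable d-separates
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.standard_normal(n)
        z = x + 0.5 * rng.standard_normal(n)
        y = z + 0.5 * rng.standard_normal(n)
        cmi = conditional_mutual_information(x, y, z, estimator="kernel")
        assert cmi < 0.03

    def test_data_processing_inequality_on_chain(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.standard_normal(n)
        z = x + 0.5 * rng.standard_normal(n)
        y = z + 0.5 * rng.standard_normal(n)
        mi_xy = mutual_information(x, y, estimator="kernel")
        mi_xz = mutual_information(x, z, estimator="kernel")
        assert mi_xy <= mi_xz + 0.05


class TestMig:
    def test_constant_conditioner_gives_zero_gain(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, 300)
        y = rng.integers(0, 3, 300)
        rec = mig(x, y, np.full(300, 1.0), estimator="plugin")
        assert rec.mig == 0.0
        assert rec.mig == rec.mi - rec.cmi

    def test_fields_consistent(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 3, 500)
        y = rng.integers(0, 3, 500)
        z = rng.standard_normal(500)
        rec = mig(x, y, z, estimator="plugin", mark_a="A", mark_b="B")
        assert rec.mark_a == "A" and rec.mark_b == "B"
        assert rec.mig == pytest.approx(rec.mi - rec.cmi, abs=1e-12)


class TestPairwiseTable:
    @staticmethod
    def _matrix(seed=0, n=200, marks=3):
        rng = np.random.default_rng(seed)
        m = MarkMatrix(gene_ids=[f"g{i}" for i in range(n)],
                       mark_names=[f"M{j}" for j in range(marks)],
                       counts=rng.integers(0, 1000, size=(n, marks)).astype(float),
                       nucpos=rng.exponential(size=n))
        return discretize(m, K=3), m.nucpos

    def test_three_marks_three_records(self):
        d, nuc = self._matrix()
        table = pairwise_dependency_table(d, nuc)
        assert len(table) == 3
        assert {(r.mark_a, r.mark_b) for r in table} == {
            ("M0", "M1"), ("M0", "M2"), ("M1", "M2")}

    def test_symmetric_in_pair_order(self):
        d, nuc = self._matrix()
        swapped = MarkMatrix(
            gene_ids=d.gene_ids,
            mark_names=["M1", "M0", "M2"],
            counts=np.column_stack([d.codes[:, 1], d.codes[:, 0],
                                    d.codes[:, 2]]).astype(float),
            nucpos=nuc)
        table = {frozenset((r.mark_a, r.mark_b)): r
                 for r in pairwise_dependency_table(d, nuc)}
        table_sw = {frozenset((r.mark_a, r.mark_b)): r
                    for r in pairwise_dependency_table(discretize(swapped, K=3), nuc)}
        for key, rec in table.items():
            assert rec.mi == pytest.approx(table_sw[key].mi, abs=1e-12)
            assert rec.mig == pytest.approx(table_sw[key].mig, abs=1e-12)

    def test_plugin_entries_match_contingency_oracle(self):
        d, nuc = self._matrix(seed=5)
        for rec in pairwise_dependency_table(d, nuc, estimator="plugin"):
            i = d.mark_names.index(rec.mark_a)
            j = d.mark_names.index(rec.mark_b)
            assert rec.mi == pytest.approx(
                histogram_mi(d.codes[:, i], d.codes[:, j]), abs=1e-12)

    def test_nucpos_length_mismatch_rejected(self):
        d, nuc = self._matrix()
        with pytest.raises(ValidationError, match="length"):
            pairwise_dependency_table(d, nuc[:-1])
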