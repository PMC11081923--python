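import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from tandemnmr import (
    AlignmentTensor,
    BondVector,
    RdcDataset,
    RdcRecord,
    calc_rdc,
    calc_rdc_angular,
    f_test,
    filter_by_noe,
    fit_tensor_svd,
    fit_two_domain_shared,
    interdomain_angle,
    q_factor,
)
from tandemnmr.dynamics import HetNoeRecord
from tandemnmr.rdc import FitResult
from tandemnmr.synthetic import random_bond_vectors


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestAlignmentTensor:
    def test_traceless_and_parameter_roundtrip(self):
        t = AlignmentTensor.from_parameters(15.0, 0.3, (25.0, 40.0, 15.0))
        assert np.trace(t.saupe) == pytest.approx(0.0, abs=1e-9)
        assert t.da == pytest.approx(15.0)
        assert t.rhombicity == pytest.approx(0.3)

    def test_eigenvalue_ordering_makes_rhombicity_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = rng.normal(size=(3, 3))
            s = s + s.T
            s -= np.eye(3) * np.trace(s) / 3
            t = AlignmentTensor(s)
            vals = np.sort(np.abs(np.linalg.eigvalsh(s)))
            assert abs(2 * t.da) == pytest.approx(vals[2], abs=1e-9)
            assert 0.0 <= t.rhombicity <= 2.0 / 3.0

    def test_non_traceless_rejected(self):
        with pytest.raises(ValueError, match="traceless"):
            AlignmentTensor(np.eye(3))


class TestCalcRdc:
    def test_vector_along_z_gives_twice_da(self):
        t = AlignmentTensor.from_parameters(10.0, 0.0, (0, 0, 0))
        assert calc_rdc(t, BondVector(1, np.array([0.0, 0, 1]))) == pytest.approx(20.0)

    def test_x_axis_at_maximal_rhombicity_vanishes(self):
        t = AlignmentTensor.from_parameters(10.0, 2.0 / 3.0, (0, 0, 0))
        assert calc_rdc(t, BondVector(1, np.array([1.0, 0, 0]))) == pytest.approx(0.0, abs=1e-9)

    def test_magic_angle_vanishes_for_axial_tensor(self):
        t = AlignmentTensor.from_parameters(10.0, 0.0, (0, 0, 0))
        v = BondVector(1, _unit([1, 1, 1]))
        assert calc_rdc(t, v) == pytest.approx(0.0, abs=1e-9)

    def test_contraction_agrees_with_angular_form(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            t = AlignmentTensor.from_parameters(
                rng.uniform(-20, 20), rng.uniform(0, 2 / 3), rng.uniform(-180, 180, 3)
            )
            v = BondVector(1, _unit(rng.normal(size=3)))
            assert calc_rdc(t, v) == pytest.approx(calc_rdc_angular(t, v), abs=1e-10)

    def test_inversion_symmetry(self):
        rng = np.random.default_rng(5)
        t = AlignmentTensor.from_parameters(12.0, 0.4, (10, 70, -30))
        for _ in range(20):
            d = _unit(rng.normal(size=3))
            assert calc_rdc(t, BondVector(1, d)) == pytest.approx(
                calc_rdc(t, BondVector(1, -d)), abs=1e-12
            )


def _synthetic_dataset(tensor, vectors, sigma=1.0, noise=0.0, seed=0, domain="A"):
    rng = np.random.default_rng(seed)
    return RdcDataset(
        [
            RdcRecord(
                v.residue_number,
                calc_rdc(tensor, v) + (rng.normal(0, noise) if noise else 0.0),
                sigma,
                domain,
            )
            for v in vectors
        ]
    )


class TestFitTensorSvd:
    def test_noise_free_roundtrip_to_machine_precision(self):
        truth = AlignmentTensor.from_parameters(15.0, 0.3, (25, 40, 15))
        vectors = random_bond_vectors(50, seed=3)
        fit = fit_tensor_svd(_synthetic_dataset(truth, vectors), vectors)
        assert fit.chi2 < 1e-12
        assert fit.tensors["A"].da == pytest.approx(15.0, abs=1e-9)
        assert fit.tensors["A"].rhombicity == pytest.approx(0.3, abs=1e-9)

    def test_five_records_fully_determined(self):
        truth = AlignmentTensor.from_parameters(12.0, 0.2, (0, 30, 60))
        vectors = random_bond_vectors(5, seed=9)
        fit = fit_tensor_svd(_synthetic_dataset(truth, vectors), vectors)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-9)
        assert fit.n_params == 5

    def test_chi2_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        truth = AlignmentTensor.from_parameters(18.0, 0.5, (80, 20, -40))
        vectors = random_bond_vectors(30, seed=8)
        data = _synthetic_dataset(truth, vectors, sigma=1.3, noise=2.0, seed=2)
        fit = fit_tensor_svd(data, vectors)
        # independent route: explicit normal equations on the same design
        from tandemnmr.rdc import _design_row

        A = np.array([_design_row(v.direction) for v in vectors]) / 1.3
        y = np.array([r.d_exp for r in data.records]) / 1.3
        s = np.linalg.solve(A.T @ A, A.T @ y)
        chi2 = float(np.sum((y - A @ s) ** 2))
        assert fit.chi2 == pytest.approx(chi2, abs=1e-8)

    def test_parameter_recovery_under_noise(self):
        # median over 25 seeds: Da within 2%, R within 0.05, axis within 3 deg
        truth = AlignmentTensor.from_parameters(15.0, 0.3, (25, 40, 15))
        da_err, r_err, ax_err = [], [], []
        for seed in range(25):
            vectors = random_bond_vectors(50, seed=300 + seed)
            data = _synthetic_dataset(truth, vectors, noise=1.0, seed=seed)
            t = fit_tensor_svd(data, vectors).tensors["A"]
            da_err.append(abs(t.da - 15.0) / 15.0)
            r_err.append(abs(t.rhombicity - 0.3))
            cosang = abs(float(t.z_axis @ truth.z_axis))
            ax_err.append(math.degrees(math.acos(min(1.0, cosang))))
        assert np.median(da_err) <= 0.02
        assert np.median(r_err) <= 0.05
        assert np.median(ax_err) <= 3.0

    def test_too_few_records_rejected(self):
        truth = AlignmentTensor.from_parameters(15.0, 0.3, (0, 0, 0))
        vectors = random_bond_vectors(4, seed=1)
        with pytest.raises(ValueError, match=">= 5"):
            fit_tensor_svd(_synthetic_dataset(truth, vectors), vectors)

    def test_degenerate_vectors_rejected(self):
        truth = AlignmentTensor.from_parameters(15.0, 0.3, (0, 0, 0))
        vectors = [BondVector(i, np.array([0.0, 0, 1])) for i in range(1, 8)]
        with pytest.raises(ValueError, match="condition|degenerate"):
            fit_tensor_svd(_synthetic_dataset(truth, vectors), vectors)


class TestFilterByNoe:
    def test_rigid_profile_keeps_everything(self):
        vectors = random_bond_vectors(10, seed=0)
        t = AlignmentTensor.from_parameters(15.0, 0.3, (0, 0, 0))
        data = _synthetic_dataset(t, vectors)
        noe = [HetNoeRecord(i, 0.9, 0.0) for i in range(1, 11)]
        assert len(filter_by_noe(data, noe)) == 10

    def test_flexible_residue_dropped(self):
        vectors = random_bond_vectors(10, seed=0)
        t = AlignmentTensor.from_parameters(15.0, 0.3, (0, 0, 0))
        data = _synthetic_dataset(t, vectors)
        noe = [HetNoeRecord(i, 0.5 if i == 3 else 0.9, 0.0) for i in range(1, 11)]
        kept = filter_by_noe(data, noe)
        assert [r.residue_number for r in kept.records] == [i for i in range(1, 11) if i != 3]

    def test_missing_noe_retained(self):
        vectors = random_bond_vectors(6, seed=0)
        t = AlignmentTensor.from_parameters(15.0, 0.3, (0, 0, 0))
        data = _synthetic_dataset(t, vectors)
        assert len(filter_by_noe(data, [])) == 6


class TestQFactor:
    def test_perfect_fit_is_zero(self):
        assert q_factor([10.0, -5.0], [10.0, -5.0]) == 0.0

    def test_zero_prediction_is_one(self):
        assert q_factor([10.0, -5.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_hand_example(self):
        assert q_factor([10.0, 0.0], [8.0, 0.0]) == pytest.approx(0.2)

    def test_all_zero_experimental_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            q_factor([0.0, 0.0], [1.0, 2.0])

    def test_da_normalization(self):
        q = q_factor([10.0, 0.0], [8.0, 0.0], da=10.0, rhombicity=0.0, normalization="da")
        assert q == pytest.approx(math.sqrt(2.0) / math.sqrt(2 * 100 * 4 / 5))


def _fit_result(chi2, n_params, n_data):
    t = AlignmentTensor.from_parameters(10.0, 0.1, (0, 0, 0))
    return FitResult(
        tensors={"A": t}, chi2=chi2, n_data=n_data, n_params=n_params,
        q_per_domain={"A": 0.1}, q_overall=0.1, residues_used=list(range(n_data)),
    )


class TestFTest:
    def test_equal_chi2_gives_zero(self):
        res = f_test(_fit_result(150.0, 5, 81), _fit_result(150.0, 8, 81))
        assert res.f_value == 0.0
        assert res.probability == 0.0

    def test_arithmetic_example(self):
        res = f_test(_fit_result(200.0, 5, 81), _fit_result(150.0, 8, 81))
        assert res.f_value == pytest.approx((50.0 / 3) / (150.0 / 73), abs=1e-6)
        assert res.f_value == pytest.approx(8.11, abs=0.01)
        assert res.dof == (3, 73)
        assert res.probability == pytest.approx(stats.f.cdf(res.f_value, 3, 73))

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            f_test(_fit_result(200.0, 8, 81), _fit_result(150.0, 5, 81))
        with pytest.raises(ValueError, match="same data"):
            f_test(_fit_result(200.0, 5, 81), _fit_result(150.0, 8, 80))


class TestInterdomainAngle:
    def _two_domain_result(self, tensor_a, tensor_b):
        return FitResult(
            tensors={"A": tensor_a, "B": tensor_b}, chi2=1.0, n_data=20, n_params=8,
            q_per_domain={}, q_overall=0.1, residues_used=list(range(20)),
        )

    def test_identical_tensors_give_zero(self):
        t = AlignmentTensor.from_parameters(15.0, 0.3, (25, 40, 15))
        assert interdomain_angle(self._two_domain_result(t, t)) == pytest.approx(0.0, abs=1e-4)

    def test_constructed_rotation_recovered(self):
        t = AlignmentTensor.from_parameters(15.0, 0.3, (0, 0, 0))
        rot = Rotation.from_euler("x", 30, degrees=True)
        assert interdomain_angle(self._two_domain_result(t, t.rotated(rot))) == pytest.approx(
            30.0, abs=1e-6
        )

    def test_axis_sign_degeneracy_folded(self):
        t = AlignmentTensor.from_parameters(15.0, 0.3, (0, 0, 0))
        flipped = AlignmentTensor(
            Rotation.from_euler("x", 180, degrees=True).as_matrix()
            @ t.saupe
            @ Rotation.from_euler("x", 180, degrees=True).as_matrix().T
        )
        assert interdomain_angle(self._two_domain_result(t, flipped)) == pytest.approx(
            0.0, abs=1e-4
        )

    def test_single_domain_rejected(self):
        with pytest.raises(ValueError, match="two-domain"):
            interdomain_angle(_fit_result(1.0, 5, 20))


def _two_domain_data(rotation_deg, noise, seed, n_per_domain=25):
    tensor = AlignmentTensor.from_parameters(15.0, 0.3, (25, 40, 15))
    vecs_a = random_bond_vectors(n_per_domain, seed=1000 + seed, start_number=1)
    vecs_b = random_bond_vectors(n_per_domain, seed=2000 + seed,
                                 start_number=n_per_domain + 10)
    rot = Rotation.from_rotvec(np.deg2rad(rotation_deg) * tensor.principal_axes[:, 1])
    sol_b = [BondVector(v.residue_number, rot.apply(v.direction)) for v in vecs_b]
    rng = np.random.default_rng(seed)
    records = []
    for v, sol in zip(vecs_a + vecs_b, vecs_a + sol_b):
        d = calc_rdc(tensor, sol) + (rng.normal(0, noise) if noise else 0.0)
        dom = "A" if v.residue_number <= n_per_domain else "B"
        records.append(RdcRecord(v.residue_number, d, max(noise, 0.5), dom))
    return RdcDataset(records), vecs_a + vecs_b


class TestTwoDomainSharedFit:
    def test_common_tensor_collapses_to_pooled_fit(self):
        data, vectors = _two_domain_data(0.0, 0.0, seed=4)
        fit = fit_two_domain_shared(data, vectors)
        assert fit.shared.chi2 == pytest.approx(fit.pooled.chi2, abs=1e-6)
        assert interdomain_angle(fit.shared) < 1.0
        assert fit.shared.n_params == 8
        assert fit.pooled.n_params == 5

    def test_pooled_chi2_never_below_shared(self):
        for seed in range(5):
            data, vectors = _two_domain_data(5.0, 1.0, seed=seed)
            fit = fit_two_domain_shared(data, vectors)
            assert fit.pooled.chi2 >= fit.shared.chi2 - 1e-9

    def test_seven_degree_rotation_recovered(self):
        angles = []
        for seed in range(10):
            data, vectors = _two_domain_data(7.0, 1.0, seed=seed)
            fit = fit_two_domain_shared(data, vectors)
            angles.append(interdomain_angle(fit.shared))
        assert np.median(angles) == pytest.approx(7.0, abs=1.0)

    def test_shared_magnitude_is_single_da_r(self):
        data, vectors = _two_domain_data(7.0, 1.0, seed=1)
        fit = fit_two_domain_shared(data, vectors)
        ta, tb = fit.shared.tensors["A"], fit.shared.tensors["B"]
        assert ta.da == pytest.approx(tb.da, abs=1e-9)
        assert ta.rhombicity == pytest.approx(tb.rhombicity, abs=1e-9)

    def test_requires_two_domains(self):
        tensor = AlignmentTensor.from_parameters(15.0, 0.3, (0, 0, 0))
        vectors = random_bond_vectors(20, seed=0)
        data = _synthetic_dataset(tensor, vectors)
        with pytest.raises(ValueError, match="2 domain"):
            fit_two_domain_shared(data, vectors)
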