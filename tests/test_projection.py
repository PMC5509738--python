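import numpy as np
import pytest

from jointcov import (PhenotypeLabels, classify_and_error, combined_projection,
                      dimension_reduction_projection, fit_fisher, welch_t)
from jointcov.errors import FitError, ValidationError
from jointcov.io import ExpressionTriplet
from jointcov.projection import ProjectionModel, within_class_scatter


def fisher_ratio(w, X1, X2):
    """Independent Fisher criterion (w'S_B w)/(w'S_w w)."""
    m1 = X1.mean(axis=0)
    m2 = X2.mean(axis=0)
    Sw = within_class_scatter(X1, X2)
    num = float(w @ (m1 - m2)) ** 2
    den = float(w @ Sw @ w)
    return num / den


def grid_max_ratio(X1, X2, n_angles=20000):
    thetas = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    best = -np.inf
    for th in thetas:
        w = np.array([np.cos(th), np.sin(th)])
        best = max(best, fisher_ratio(w, X1, X2))
    return best


class TestFitFisher:
    def test_identity_scatter(self):
        # per-group deviations (+-1, +-1) force Sw proportional to identity
        d = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        X1 = np.array([2.0, 0.0]) + d
        X2 = np.array([-2.0, 0.0]) + d
        m = fit_fisher(X1, X2)
        assert m.w[1] == pytest.approx(0.0, abs=1e-12)
        assert m.w[0] > 0
        # midpoint threshold sits at the origin
        assert m.w0 == pytest.approx(0.0, abs=1e-12)

    def test_identical_groups_degenerate(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [0.0, 1.0]])
        m = fit_fisher(X, X)
        assert m.degenerate
        np.testing.assert_array_equal(m.w, [1.0, 0.0])
        er = classify_and_error(m, X, X)
        assert er.er == pytest.approx(0.5)

    def test_small_group_raises(self):
        with pytest.raises(FitError):
            fit_fisher(np.array([[1.0, 2.0]]), np.array([[1.0, 0.0], [2.0, 1.0]]))

    def test_nonfinite_raises(self):
        X1 = np.array([[1.0, np.nan], [2.0, 1.0]])
        with pytest.raises(ValidationError):
            fit_fisher(X1, np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_maximises_fisher_criterion_vs_grid(self):
        rng = np.random.default_rng(2024)
        for _ in range(5):
            X1 = rng.normal(size=(8, 2)) @ rng.normal(size=(2, 2)) + rng.normal(size=2)
            X2 = rng.normal(size=(6, 2)) + rng.normal(size=2)
            m = fit_fisher(X1, X2)
            j_fit = fisher_ratio(m.w, X1, X2)
            j_grid = grid_max_ratio(X1, X2, n_angles=5000)
            assert j_fit >= j_grid * (1 - 1e-3)

    def test_affine_equivariance_of_classification(self):
        rng = np.random.default_rng(5)
        X1 = rng.normal(size=(10, 2)) + [1.0, 0.5]
        X2 = rng.normal(size=(7, 2))
        A = np.array([[2.0, 0.3], [-0.5, 1.2]])
        b = np.array([3.0, -1.0])
        m = fit_fisher(X1, X2)
        mt = fit_fisher(X1 @ A.T + b, X2 @ A.T + b)
        er = classify_and_error(m, X1, X2)
        ert = classify_and_error(mt, X1 @ A.T + b, X2 @ A.T + b)
        assert er.er1 == pytest.approx(ert.er1)
        assert er.er2 == pytest.approx(ert.er2)

    def test_group_means_on_opposite_sides(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            X1 = rng.normal(size=(5, 2)) + rng.normal(size=2)
            X2 = rng.normal(size=(5, 2)) + rng.normal(size=2)
            m = fit_fisher(X1, X2)
            if m.degenerate:
                continue
            thr = -m.w0
            s1 = m.w @ m.m1 - thr
            s2 = m.w @ m.m2 - thr
            assert s1 * s2 < 0


class TestClassifyAndError:
    def test_perfect_separation(self):
        X1 = np.array([[2.0, 0.0], [3.0, 0.1], [2.5, -0.1]])
        X2 = np.array([[-2.0, 0.0], [-3.0, 0.1], [-2.5, -0.1]])
        m = fit_fisher(X1, X2)
        er = classify_and_error(m, X1, X2)
        assert er.er1 == er.er2 == er.er == 0.0

    def test_direct_count(self):
        # hand-built model: w = (1,0), means at +-1 -> threshold 0
        m = ProjectionModel(np.array([1.0, 0.0]), 0.0,
                            np.array([1.0, 0.0]), np.array([-1.0, 0.0]),
                            np.eye(2))
        X1 = np.array([[1.0, 0], [2.0, 0], [0.5, 0], [-1.0, 0]])  # 1 wrong
        X2 = np.array([[-1.0, 0], [1.0, 0]])                      # 1 wrong
        er = classify_and_error(m, X1, X2)
        assert er.er1 == pytest.approx(0.25)
        assert er.er2 == pytest.approx(0.5)
        assert er.er == pytest.approx(0.375)

    def test_balanced_error_invariant_under_group_duplication(self):
        rng = np.random.default_rng(1)
        X1 = rng.normal(size=(8, 2)) + [1, 0]
        X2 = rng.normal(size=(4, 2))
        m = fit_fisher(X1, X2)
        er = classify_and_error(m, X1, X2)
        er_dup = classify_and_error(m, X1, np.vstack([X2, X2, X2]))
        assert er.er == pytest.approx(er_dup.er)


class TestCombinedProjection:
    def _triplet(self, tumor, normal):
        probes = [f"p{i}" for i in range(tumor.shape[0])]
        patients = [f"s{j}" for j in range(tumor.shape[1])]
        return ExpressionTriplet(probes, patients, tumor, normal)

    def test_tumor_weight_nonnegative(self):
        rng = np.random.default_rng(13)
        n = 30
        y = np.array([0] * 20 + [1] * 10)
        # signal carried negatively by the tumour channel: the raw fit wants
        # a negative tumour weight, the convention must flip it back
        tumor = rng.normal(size=(3, n)) - 2.0 * y
        normal = rng.normal(size=(3, n)) * 0.1
        trip = self._triplet(tumor, normal)
        labels = PhenotypeLabels(trip.patient_ids, y)
        for probe in range(3):
            m, proj = combined_projection(trip, labels, probe)
            assert m.w[0] >= 0
            np.testing.assert_allclose(
                proj, np.column_stack([tumor[probe], normal[probe]]) @ m.w)

    def test_separable_constant_offset(self):
        n = 12
        y = np.array([0] * 6 + [1] * 6)
        base = np.linspace(0.0, 1.0, n)
        tumor = (base + 5.0 * y)[None, :]
        normal = tumor + 2.0  # tumour = normal + constant per patient
        trip = self._triplet(tumor, normal)
        labels = PhenotypeLabels(trip.patient_ids, y)
        m, proj = combined_projection(trip, labels, 0)
        assert proj[y == 1].min() > proj[y == 0].max()

    def test_combined_beats_single_tissue_t(self):
        rng = np.random.default_rng(99)
        n1, n2 = 60, 40
        y = np.array([0] * n1 + [1] * n2)
        tumor = rng.normal(size=(1, n1 + n2)) + 1.0 * y
        normal = rng.normal(size=(1, n1 + n2)) + 1.0 * y
        trip = self._triplet(tumor, normal)
        labels = PhenotypeLabels(trip.patient_ids, y)
        _, proj = combined_projection(trip, labels, 0)
        t_proj = abs(welch_t(proj[y == 0], proj[y == 1]).t)
        t_tum = abs(welch_t(tumor[0, y == 0], tumor[0, y == 1]).t)
        t_nor = abs(welch_t(normal[0, y == 0], normal[0, y == 1]).t)
        assert t_proj > max(t_tum, t_nor)


class TestDimensionReduction:
    def _labels(self, n1, n2):
        ids = [f"s{j}" for j in range(n1 + n2)]
        return PhenotypeLabels(ids, np.array([0] * n1 + [1] * n2))

    def test_zero_second_coordinate_reduces_to_scaling(self):
        rng = np.random.default_rng(3)
        labels = self._labels(10, 8)
        ca = rng.normal(size=18) + np.r_[np.zeros(10), np.ones(8)]
        cb = np.zeros(18)
        _, proj = dimension_reduction_projection(ca, cb, labels)
        r = np.corrcoef(proj, ca)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_pair_only_signal_separates(self):
        # groups shifted along (1,-1), shared noise along (1,1): neither
        # coordinate separates marginally but the 2D fit does
        rng = np.random.default_rng(21)
        n1, n2 = 60, 40
        labels = self._labels(n1, n2)
        g = np.r_[np.zeros(n1), np.ones(n2)]
        u = rng.normal(0, 5.0, size=n1 + n2)
        ca = u + 1.5 * g + rng.normal(0, 0.5, size=n1 + n2)
        cb = u - 1.5 * g + rng.normal(0, 0.5, size=n1 + n2)
        m, proj = dimension_reduction_projection(ca, cb, labels)
        X = np.column_stack([ca, cb])
        er = classify_and_error(m, X[:n1], X[n1:])
        assert er.er < 0.1
        # marginals do not separate
        assert abs(welch_t(ca[:n1], ca[n1:]).t) < 3.0
        assert abs(welch_t(cb[:n1], cb[n1:]).t) < 3.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        labels = self._labels(12, 9)
        ca = rng.normal(size=21)
        cb = rng.normal(size=21) + 0.4 * np.r_[np.zeros(12), np.ones(9)]
        ma, pa = dimension_reduction_projection(ca, cb, labels)
        mb, pb = dimension_reduction_projection(cb, ca, labels)
        X_ab = np.column_stack([ca, cb])
        X_ba = np.column_stack([cb, ca])
        er_ab = classify_and_error(ma, X_ab[:12], X_ab[12:])
        er_ba = classify_and_error(mb, X_ba[:12], X_ba[12:])
        assert er_ab.er == pytest.approx(er_ba.er)


def test_two_step_equals_rank_one_bilinear_form():
    """With shared first-stage weights, the two-step projection is u'Xv on
    the per-patient 2x2 tissue-by-probe matrix."""
    rng = np.random.default_rng(17)
    n = 15
    u = np.array([0.7, 0.3])       # shared combined weights
    v = np.array([1.2, -0.8])      # second-stage weights
    Xa = rng.normal(size=(n, 2))   # probe a: (tumour, normal) per patient
    Xb = rng.normal(size=(n, 2))
    ca = Xa @ u
    cb = Xb @ u
    two_step = np.column_stack([ca, cb]) @ v
    bilinear = np.array([u @ np.column_stack([Xa[i], Xb[i]]) @ v for i in range(n)])
    np.testing.assert_allclose(two_step, bilinear, rtol=1e-12)
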