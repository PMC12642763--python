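import numpy as np
import pytest

from whitemap import (
    ParentScan,
    TaskAnnotation,
    TaskScan,
    bures_distance,
    correlation_connectome,
    covariance_connectome,
    dm_distance,
    extract_task_scans,
    fidelity,
    frobenius_distance,
    pairwise_distances,
    psd_sqrt,
)
from whitemap.geometry import Connectome
from whitemap.io_core import ValidationError
from whitemap.synthetic_data import CohortConfig, generate_parent_scan

from .conftest import make_parent, random_correlation, random_spd


def brute_force_pearson(data):
    m, L = data.shape
    C = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            xi, xj = data[i], data[j]
            num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
            den = xi.std(ddof=1) * xj.std(ddof=1) * (L - 1)
            C[i, j] = num / den
    return C


def fidelity_2x2_oracle(A, B):
    """Closed form for 2x2 SPD pairs: tr(AB) + 2 sqrt(det(AB))."""
    AB = A @ B
    return float(np.trace(AB) + 2.0 * np.sqrt(max(np.linalg.det(AB), 0.0)))


class TestCorrelationConnectome:
    def test_affine_rows_perfectly_correlated(self, rng):
        r = rng.standard_normal(50)
        C = correlation_connectome(np.vstack([r, 2 * r + 5])).matrix
        np.testing.assert_allclose(C, np.ones((2, 2)), atol=1e-12)

    def test_anticorrelation(self, rng):
        r = rng.standard_normal(50)
        C = correlation_connectome(np.vstack([r, -r])).matrix
        np.testing.assert_allclose(C, [[1, -1], [-1, 1]], atol=1e-12)

    def test_matches_brute_force(self, rng):
        data = rng.standard_normal((4, 100))
        C = correlation_connectome(data).matrix
        np.testing.assert_allclose(C, brute_force_pearson(data), atol=1e-10)

    def test_constant_row_names_region(self, rng):
        data = rng.standard_normal((3, 30))
        data[1] = 7.0
        with pytest.raises(ValidationError, match="region 1"):
            correlation_connectome(data)

    def test_carries_scan_labels(self, rng):
        scan = TaskScan(rng.standard_normal((3, 30)), "subX", "taskY")
        conn = correlation_connectome(scan)
        assert (conn.subject_id, conn.task_label) == ("subX", "taskY")
        assert conn.kind == "correlation"

    def test_unit_diagonal_and_trace(self, rng):
        conn = correlation_connectome(rng.standard_normal((5, 60)))
        np.testing.assert_allclose(np.diagonal(conn.matrix), 1.0)
        assert np.isclose(np.trace(conn.matrix), 5.0)


class TestPsdSqrt:
    def test_diagonal(self):
        np.testing.assert_allclose(
            psd_sqrt(np.diag([4.0, 9.0])), np.diag([2.0, 3.0]), atol=1e-12
        )

    def test_identity(self):
        np.testing.assert_allclose(psd_sqrt(np.eye(3)), np.eye(3), atol=1e-14)

    def test_multiply_back(self, rng):
        A = random_spd(rng, 6)
        R = psd_sqrt(A)
        assert np.linalg.norm(R @ R - A) / np.linalg.norm(A) < 1e-8

    def test_not_psd_rejected(self):
        with pytest.raises(ValidationError, match="not PSD"):
            psd_sqrt(np.diag([1.0, -1.0]))

    def test_tiny_negative_eigenvalue_clamped(self):
        A = np.diag([1.0, -1e-14])
        R = psd_sqrt(A)
        assert R[1, 1] == 0.0


class TestFidelity:
    def test_self_fidelity_is_squared_trace(self, rng):
        A = random_spd(rng, 4)
        assert np.isclose(fidelity(A, A), np.trace(A) ** 2, rtol=1e-8)
        assert np.isclose(fidelity(np.eye(3), np.eye(3)), 9.0)

    def test_commuting_diagonal_closed_form(self):
        assert np.isclose(fidelity(np.diag([1.0, 4.0]), np.diag([4.0, 1.0])), 16.0)

    def test_2x2_analytic_oracle(self, rng):
        for _ in range(20):
            A, B = random_spd(rng, 2), random_spd(rng, 2)
            assert np.isclose(
                fidelity(A, B), fidelity_2x2_oracle(A, B), rtol=1e-8
            )

    def test_symmetric_in_arguments(self, rng):
        A, B = random_spd(rng, 5), random_spd(rng, 5)
        assert np.isclose(fidelity(A, B), fidelity(B, A), rtol=1e-9)

    def test_size_mismatch(self, rng):
        with pytest.raises(ValidationError, match="mismatch"):
            fidelity(np.eye(2), np.eye(3))


class TestBuresDistance:
    def test_identity_of_indiscernibles(self, rng):
        A = random_spd(rng, 5)
        assert bures_distance(A, A) == 0.0

    def test_commuting_diagonal_closed_form(self):
        # sqrt(sum (sqrt(a_i) - sqrt(b_i))^2)
        assert np.isclose(
            bures_distance(np.diag([1.0, 1.0]), np.diag([4.0, 1.0])), 1.0
        )
        a, b = np.array([2.0, 5.0, 0.5]), np.array([1.0, 3.0, 4.0])
        expected = np.sqrt(np.sum((np.sqrt(a) - np.sqrt(b)) ** 2))
        assert np.isclose(bures_distance(np.diag(a), np.diag(b)), expected)

    def test_correlation_trace_identity(self, rng):
        # for correlation matrices dB^2 = 2m - 2 sqrt(F)
        m = 4
        A, B = random_correlation(rng, m), random_correlation(rng, m)
        dB = bures_distance(A, B)
        assert np.isclose(dB**2, 2 * m - 2 * np.sqrt(fidelity(A, B)), atol=1e-8)

    def test_metric_axioms_on_random_spd(self, rng):
        for _ in range(25):
            A, B, C = (random_spd(rng, 4) for _ in range(3))
            dab, dba = bures_distance(A, B), bures_distance(B, A)
            assert dab >= 0
            assert abs(dab - dba) <= 1e-10
            assert bures_distance(A, A) == 0.0
            assert dab <= bures_distance(A, C) + bures_distance(C, B) + 1e-10

    def test_accepts_connectome_objects(self, rng):
        conn = correlation_connectome(rng.standard_normal((4, 60)))
        assert bures_distance(conn, conn) == 0.0


class TestFrobeniusDistance:
    def test_identical(self, rng):
        A = rng.standard_normal((3, 4))
        assert frobenius_distance(A, A) == 0.0

    def test_constant_shift_closed_form(self):
        # sensitive to a constant offset: sqrt(m*n) * |c|
        A = np.arange(4.0).reshape(2, 2)
        assert np.isclose(frobenius_distance(A, A + 1.0), 2.0)

    def test_single_entry_difference(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        B = np.array([[1.0, 2.0], [3.0, 0.0]])
        assert np.isclose(frobenius_distance(A, B), 4.0)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValidationError, match="mismatch"):
            frobenius_distance(np.ones((2, 3)), np.ones((2, 4)))


class TestDmDistance:
    def test_same_parent_same_interval_is_zero(self, rng):
        parent = make_parent(rng, m=5, n=80)
        assert dm_distance(parent, parent, 0, 0) == 0.0

    def test_row_offsets_removed(self, rng):
        # distinct per-subject, per-region mean offsets make no difference
        parent = make_parent(rng, m=5, n=80)
        offsets = rng.uniform(-300, 300, size=5)[:, None]
        shifted = ParentScan(
            parent.data + offsets, "subB", parent.annotation
        )
        d = dm_distance(parent, shifted, 0, 0)
        assert d < 1e-6

    def test_subject_structure_suppressed_relative_to_raw(self):
        # same task signal, different subject correlation structure
        config = CohortConfig(
            n_subjects=2,
            n_tasks=2,
            m_regions=10,
            timepoints_per_task=60,
            subject_mean_scale=0.0,
            subject_cov_strength=0.9,
            task_signal_strength=2.0,
            seed=5,
        )
        p0 = generate_parent_scan(config, 0)
        p1 = generate_parent_scan(config, 1)
        raw = frobenius_distance(
            extract_task_scans(p0)[0].data, extract_task_scans(p1)[0].data
        )
        dm = dm_distance(p0, p1, 0, 0)
        assert dm / raw < 1.0

    def test_symmetry(self, rng):
        p0 = make_parent(rng, m=4, n=60, subject_id="a")
        p1 = make_parent(rng, m=4, n=60, subject_id="b")
        assert np.isclose(
            dm_distance(p0, p1, 0, 1), dm_distance(p1, p0, 1, 0), atol=1e-10
        )

    def test_bad_interval_index(self, rng):
        parent = make_parent(rng, m=4, n=60)
        with pytest.raises(ValidationError, match="out of range"):
            dm_distance(parent, parent, 0, 5)


class TestPairwiseDistances:
    @pytest.mark.parametrize("metric", ["frobenius_raw", "bures_connectome"])
    def test_identical_scans_zero_matrix(self, rng, metric):
        scan = TaskScan(rng.standard_normal((4, 30)), "s", "t")
        D = pairwise_distances([scan, scan, scan], metric=metric)
        np.testing.assert_allclose(D.values, 0.0, atol=1e-6)

    def test_n2_matches_direct_call_frobenius(self, rng):
        a = TaskScan(rng.standard_normal((4, 30)), "s1", "t")
        b = TaskScan(rng.standard_normal((4, 30)), "s2", "t")
        D = pairwise_distances([a, b], metric="frobenius_raw")
        assert np.isclose(D.values[0, 1], frobenius_distance(a, b))

    def test_n2_matches_direct_call_bures(self, rng):
        a = TaskScan(rng.standard_normal((4, 30)), "s1", "t")
        b = TaskScan(rng.standard_normal((4, 30)), "s2", "t")
        D = pairwise_distances([a, b], metric="bures_connectome")
        expected = bures_distance(
            correlation_connectome(a), correlation_connectome(b)
        )
        assert np.isclose(D.values[0, 1], expected, atol=1e-10)

    def test_entries_equal_per_pair_calls(self, rng):
        scans = [
            TaskScan(rng.standard_normal((3, 25)), f"s{i}", "t")
            for i in range(5)
        ]
        D = pairwise_distances(scans, metric="bures_connectome")
        conns = [correlation_connectome(s) for s in scans]
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert np.isclose(
                        D.values[i, j],
                        bures_distance(conns[i], conns[j]),
                        atol=1e-10,
                    )

    def test_dm_matches_direct_calls(self, rng):
        parents = [make_parent(rng, m=4, n=60, subject_id=f"s{i}") for i in range(3)]
        objects = [(p, i) for p in parents for i in range(2)]
        D = pairwise_distances(objects, metric="dm")
        for a, (pa, ia) in enumerate(objects):
            for b, (pb, ib) in enumerate(objects):
                if a != b:
                    assert np.isclose(
                        D.values[a, b], dm_distance(pa, pb, ia, ib), atol=1e-9
                    )

    def test_within_subject_smaller_than_between_for_mean_offsets(self):
        config = CohortConfig(
            n_subjects=2,
            n_tasks=8,
            m_regions=10,
            timepoints_per_task=30,
            subject_mean_scale=50.0,
            subject_cov_strength=0.0,
            task_signal_strength=0.5,
            seed=3,
        )
        scans = []
        for s in range(2):
            scans.extend(extract_task_scans(generate_parent_scan(config, s)))
        D = pairwise_distances(scans, metric="frobenius_raw").values
        within = [D[i, j] for i in range(8) for j in range(8) if i < j]
        within += [D[i, j] for i in range(8, 16) for j in range(8, 16) if i < j]
        between = [D[i, j] for i in range(8) for j in range(8, 16)]
        assert max(within) < min(between)

    def test_too_few_objects(self, rng):
        with pytest.raises(ValidationError, match="at least 2"):
            pairwise_distances(
                [TaskScan(rng.standard_normal((3, 20)), "s", "t")],
                metric="frobenius_raw",
            )


class TestInvariances:
    def test_bures_invariant_to_row_affine_rescaling(self, rng):
        # correlation connectomes ignore per-row mean and scale changes
        a = rng.standard_normal((4, 50))
        b = rng.standard_normal((4, 50))
        scale = rng.uniform(0.5, 3.0, size=4)[:, None]
        shift = rng.uniform(-10, 10, size=4)[:, None]
        d0 = bures_distance(
            correlation_connectome(a), correlation_connectome(b)
        )
        d1 = bures_distance(
            correlation_connectome(scale * a + shift),
            correlation_connectome(b),
        )
        assert abs(d0 - d1) < 1e-10

    def test_covariance_connectome_available(self, rng):
        conn = covariance_connectome(rng.standard_normal((4, 50)))
        assert conn.kind == "covariance"
        np.testing.assert_allclose(conn.matrix, conn.matrix.T)

    def test_connectome_validation(self):
        with pytest.raises(ValidationError, match="unit diagonal"):
            Connectome(np.diag([2.0, 1.0]), kind="correlation")
        with pytest.raises(ValidationError, match="symmetric"):
            Connectome(np.array([[1.0, 0.5], [0.1, 1.0]]), kind="covariance")
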