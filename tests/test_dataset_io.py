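"""Landmark-table I/O, fluctuations, moments, constraints, angle histograms."""

import io

import numpy as np
import pytest

import facemaxent as fm
from facemaxent.dataset_io import (
    FormatError,
    fluctuations_from_array,
    sym3_multiplicity,
    sym3_to_dense,
    _sym3_indices,
)


def make_csv(rows, n=8):
    header = (
        "subject_id,rep_index,gender,"
        + ",".join(f"x{i}" for i in range(1, n + 1))
        + ","
        + ",".join(f"y{i}" for i in range(1, n + 1))
    )
    return "\n".join([header] + rows) + "\n"


class TestReadWrite:
    def test_wellformed_two_rows(self):
        coords = ",".join(["0.1"] * 16)
        text = make_csv([f"s1,1,F,{coords}", f"s1,2,M,{coords}"])
        ds = fm.read_landmark_table(io.StringIO(text))
        assert ds.n_records == 2
        assert ds.n_landmarks == 8
        assert list(ds.gender) == ["F", "M"]

    def test_missing_gender_column_names_it(self):
        text = "subject_id,rep_index," + ",".join(
            [f"x{i}" for i in range(1, 9)] + [f"y{i}" for i in range(1, 9)]
        )
        text += "\n" + "s1,1," + ",".join(["0"] * 16) + "\n"
        with pytest.raises(FormatError, match="gender"):
            fm.read_landmark_table(io.StringIO(text))

    def test_non_numeric_coordinate_reports_row(self):
        coords_ok = ",".join(["0.1"] * 16)
        coords_bad = ",".join(["0.1"] * 15 + ["oops"])
        text = make_csv([f"s1,1,F,{coords_ok}", f"s2,1,F,{coords_bad}"])
        with pytest.raises(FormatError, match="row 1"):
            fm.read_landmark_table(io.StringIO(text))

    def test_unknown_gender_code_rejected(self):
        coords = ",".join(["0.1"] * 16)
        text = make_csv([f"s1,1,X,{coords}"])
        with pytest.raises(FormatError, match="gender"):
            fm.read_landmark_table(io.StringIO(text))

    def test_roundtrip_preserves_values(self, small_study, tmp_path):
        path = tmp_path / "table.csv"
        fm.write_landmark_table(small_study, path)
        back = fm.read_landmark_table(path)
        assert back.n_records == small_study.n_records
        # 12 significant digits written
        np.testing.assert_allclose(
            back.coords, small_study.coords, rtol=1e-11, atol=1e-13
        )
        assert list(back.subject_ids) == list(small_study.subject_ids)

    def test_adapter_maps_foreign_layout(self):
        cols = (
            ["sid", "trial", "sex"]
            + [f"x{i}" for i in range(1, 9)]
            + [f"y{i}" for i in range(1, 9)]
        )
        row = ["p1", "1", "female"] + ["0.2"] * 16
        text = ",".join(cols) + "\n" + ",".join(row) + "\n"
        ds = fm.read_landmark_table(
            io.StringIO(text),
            column_map={"sid": "subject_id", "trial": "rep_index", "sex": "gender"},
            gender_map={"female": "F", "male": "M"},
        )
        assert ds.gender[0] == "F"

    def test_duplicate_subject_rep_rejected(self):
        coords = ",".join(["0.1"] * 16)
        text = make_csv([f"s1,1,F,{coords}", f"s1,1,F,{coords}"])
        with pytest.raises(ValueError, match="duplicate"):
            fm.read_landmark_table(io.StringIO(text))


class TestFluctuations:
    def test_constant_records_give_zero_deltas(self):
        coords = np.tile(np.arange(16.0), (4, 1))
        ds = fm.LandmarkDataset(
            coords=coords,
            subject_ids=np.array([f"s{i}" for i in range(4)], dtype=object),
            rep_index=np.ones(4, dtype=int),
            gender=np.array(["NA"] * 4, dtype=object),
            n_landmarks=8,
        )
        fl = fm.compute_fluctuations(ds)
        assert np.all(fl.deltas == 0)

    def test_mean_and_deltas_arithmetic(self):
        # two records, n=2: mean (2,2,3,3), deltas +-(1,-1,1,-1)
        coords = np.array([[1.0, 3.0, 2.0, 4.0], [3.0, 1.0, 4.0, 2.0]])
        ds = fm.LandmarkDataset(
            coords=coords,
            subject_ids=np.array(["a", "b"], dtype=object),
            rep_index=np.array([1, 1]),
            gender=np.array(["NA", "NA"], dtype=object),
            n_landmarks=2,
        )
        fl = fm.compute_fluctuations(ds)
        np.testing.assert_allclose(fl.mean, [2, 2, 3, 3])
        np.testing.assert_allclose(fl.deltas, [[-1, 1, -1, 1], [1, -1, 1, -1]])

    def test_column_means_vanish(self, small_study):
        fl = fm.compute_fluctuations(small_study)
        assert np.abs(fl.deltas.mean(axis=0)).max() < 1e-12

    def test_standardize_flags_zero_variance(self):
        coords = np.zeros((3, 4))
        coords[:, 0] = [1.0, 2.0, 3.0]
        ds = fm.LandmarkDataset(
            coords=coords,
            subject_ids=np.array(["a", "b", "c"], dtype=object),
            rep_index=np.array([1, 1, 1]),
            gender=np.array(["NA"] * 3, dtype=object),
            n_landmarks=2,
        )
        fl = fm.compute_fluctuations(ds, standardize=True)
        assert set(fl.zero_variance_columns) == {1, 2, 3}
        assert abs(fl.deltas[:, 0].std() - 1) < 1e-12


class TestMoments:
    def test_odd_symmetric_data_kills_mean_and_third(self):
        v = np.array([1.0, -2.0, 0.5])
        fl = fluctuations_from_array(np.vstack([v, -v]), center=False)
        mom = fm.moment_statistics(fl, max_order=3)
        assert np.abs(mom.mean).max() == 0
        assert np.abs(mom.third_values).max() == 0

    def test_cov_enumeration(self):
        fl = fluctuations_from_array(
            np.array([[1.0, 2.0], [-1.0, -2.0]]), center=False
        )
        mom = fm.moment_statistics(fl, max_order=2)
        np.testing.assert_allclose(mom.cov, [[1, 2], [2, 4]])

    def test_third_tensor_permutation_symmetric(self):
        rng = np.random.default_rng(0)
        fl = fluctuations_from_array(rng.standard_normal((50, 3)))
        mom = fm.moment_statistics(fl, max_order=3)
        dense = mom.third_dense()
        for perm in [(0, 2, 1), (1, 0, 2), (2, 1, 0)]:
            np.testing.assert_allclose(dense, np.transpose(dense, perm))

    def test_recovers_known_gaussian_within_5_se(self):
        rng = np.random.default_rng(3)
        C = np.array([[2.0, 0.6], [0.6, 1.0]])
        S = 10_000
        X = rng.multivariate_normal([0.5, -0.2], C, size=S)
        ds_mean = X.mean(axis=0)
        fl = fluctuations_from_array(X)
        mom = fm.moment_statistics(fl, max_order=2)
        se_mean = np.sqrt(np.diag(C) / S)
        assert np.all(np.abs(ds_mean - [0.5, -0.2]) < 5 * se_mean)
        # cov entries: SE ~ sqrt((C_ii C_jj + C_ij^2)/S)
        for i in range(2):
            for j in range(2):
                se = np.sqrt((C[i, i] * C[j, j] + C[i, j] ** 2) / S)
                assert abs(mom.cov[i, j] - C[i, j]) < 5 * se

    def test_sym3_multiplicities(self):
        idx = _sym3_indices(3)
        mult = sym3_multiplicity(idx)
        lookup = {tuple(t): m for t, m in zip(idx, mult)}
        assert lookup[(0, 0, 0)] == 1
        assert lookup[(0, 0, 1)] == 3
        assert lookup[(0, 1, 2)] == 6
        dense = sym3_to_dense(3, idx, np.arange(len(idx), dtype=float))
        assert dense[0, 1, 2] == dense[2, 1, 0]


class TestConstraints:
    def test_full_rank_identity(self):
        mom = fm.MomentStatistics(mean=np.zeros(3), cov=np.eye(3), n_samples=10)
        basis = fm.find_constraints(mom)
        assert basis.n_constraints == 0
        np.testing.assert_allclose(basis.projector, np.eye(3))

    def test_rank_one_cov_yields_antisymmetric_null_vector(self):
        mom = fm.MomentStatistics(
            mean=np.zeros(2), cov=np.array([[1.0, 1.0], [1.0, 1.0]]), n_samples=10
        )
        basis = fm.find_constraints(mom)
        assert basis.n_constraints == 1
        v = basis.null_vectors[:, 0]
        np.testing.assert_allclose(np.abs(v), [np.sqrt(0.5)] * 2, atol=1e-12)
        assert abs(v[0] + v[1]) < 1e-12  # proportional to (1, -1)

    def test_study_covariance_has_six_null_modes(self, gaussian_fluct):
        _, _, mom, basis = gaussian_fluct
        assert basis.n_constraints == 6
        assert basis.rank == 10
        # projector: symmetric idempotent of rank 10
        P = basis.projector
        np.testing.assert_allclose(P, P.T, atol=1e-12)
        np.testing.assert_allclose(P @ P, P, atol=1e-10)
        assert round(np.trace(P)) == 10
        np.testing.assert_allclose(P @ basis.null_vectors, 0, atol=1e-10)

    def test_zero_covariance_is_degenerate(self):
        mom = fm.MomentStatistics(mean=np.zeros(2), cov=np.zeros((2, 2)), n_samples=5)
        with pytest.raises(ValueError, match="degenerate"):
            fm.find_constraints(mom)

    def test_reduce_gives_unit_variance_full_rank(self, gaussian_fluct):
        _, fl, mom, basis = gaussian_fluct
        red = fm.reduce_and_standardize(fl, basis)
        assert red.dim == 10
        np.testing.assert_allclose(red.deltas.var(axis=0), 1.0, atol=1e-9)
        red_mom = fm.moment_statistics(red, max_order=2)
        assert fm.find_constraints(red_mom).n_constraints == 0

    def test_reduce_idempotent_in_rank(self, gaussian_fluct):
        _, fl, mom, basis = gaussian_fluct
        red = fm.reduce_and_standardize(fl, basis)
        again = fm.find_constraints(fm.moment_statistics(red, 2))
        assert again.n_constraints == 0


class TestAngleHistogram:
    @staticmethod
    def _fluct_from_xy(xy):
        # single landmark pair embedded in an n=2 frame (coords x1,x2,y1,y2)
        X = np.zeros((len(xy), 4))
        X[:, 0] = [p[0] for p in xy]
        X[:, 2] = [p[1] for p in xy]
        return fluctuations_from_array(X, center=False)

    def test_exact_angles(self):
        fl = self._fluct_from_xy([(1.0, 1.0), (-1.0, 0.0)])
        hist = fm.angle_histogram(fl, 0, n_bins=8)
        # angles pi/4 and pi fall in distinct bins; density integrates to 1
        widths = np.diff(hist.bin_edges)
        assert abs(np.sum(hist.densities * widths) - 1) < 1e-9
        centres = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        occupied = centres[hist.densities > 0]
        # pi/4 sits on a bin edge; allow either adjacent bin
        assert np.any(np.abs(occupied - np.pi / 4) <= np.pi / 8 + 1e-12)
        assert np.any(occupied > np.pi * 0.75)

    def test_zero_fluctuation_excluded_and_counted(self):
        fl = self._fluct_from_xy([(1.0, 0.0), (0.0, 0.0)])
        hist = fm.angle_histogram(fl, 0)
        assert hist.n_excluded == 1
        assert hist.n_samples == 1

    def test_all_zero_is_error(self):
        fl = self._fluct_from_xy([(0.0, 0.0)] * 3)
        with pytest.raises(ValueError, match="zero"):
            fm.angle_histogram(fl, 0)

    def test_isotropic_gaussian_is_uniform(self):
        rng = np.random.default_rng(11)
        n = 100_000
        xy = rng.standard_normal((n, 2))
        fl = self._fluct_from_xy(xy)
        hist = fm.angle_histogram(fl, 0, n_bins=24)
        width = 2 * np.pi / 24
        p = 1 / 24
        se = np.sqrt(p * (1 - p) / n) / width  # binomial SE on the density
        assert np.all(np.abs(hist.densities - 1 / (2 * np.pi)) < 4 * se)

    def test_rotation_shifts_histogram_circularly(self):
        rng = np.random.default_rng(4)
        n = 40_000
        xy = rng.standard_normal((n, 2)) @ np.diag([2.0, 0.5])
        n_bins = 12
        psi = 2 * np.pi / n_bins  # one full bin, exact circular shift
        R = np.array([[np.cos(psi), -np.sin(psi)], [np.sin(psi), np.cos(psi)]])
        h0 = fm.angle_histogram(self._fluct_from_xy(xy), 0, n_bins=n_bins)
        h1 = fm.angle_histogram(self._fluct_from_xy(xy @ R.T), 0, n_bins=n_bins)
        np.testing.assert_allclose(np.roll(h0.densities, 1), h1.densities, atol=1e-12)


class TestSerialisation:
    def test_fluctuation_json_roundtrip(self, gaussian_fluct):
        _, fl, _, basis = gaussian_fluct
        back = fm.FluctuationData.from_json(fl.to_json())
        np.testing.assert_allclose(back.deltas, fl.deltas)
        back_basis = fm.ConstraintBasis.from_json(basis.to_json())
        np.testing.assert_allclose(back_basis.projector, basis.projector)
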