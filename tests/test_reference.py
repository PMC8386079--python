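import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcap import (
    OutlierConfig,
    ReferenceModel,
    average_abundance,
    average_cell_size,
    build_reference,
    cell_size,
    cross_subject_variance,
    exclude_outliers,
    relative_abundance,
)
from dcap.data_model import CellTypeIndexSet
from dcap.errors import DegenerateGroupError, MissingGroupError, ValidationError

from conftest import make_sc


class TestRelativeAbundance:
    def test_molecule_fractions(self):
        # two cells of one type: totals per gene 3 and 7 of 10 molecules
        sc = make_sc(
            [[2.0, 1.0], [2.0, 5.0]], ["s1", "s1"], ["A", "A"]
        )
        idx = CellTypeIndexSet.from_dataset(sc)
        theta = relative_abundance(sc, idx, "s1", "A")
        np.testing.assert_allclose(theta, [0.3, 0.7])

    def test_single_gene_cell_is_one_hot(self):
        sc = make_sc([[5.0], [0.0], [0.0]], ["s1"], ["A"])
        idx = CellTypeIndexSet.from_dataset(sc)
        np.testing.assert_array_equal(
            relative_abundance(sc, idx, "s1", "A"), [1.0, 0.0, 0.0]
        )

    def test_all_zero_group_is_degenerate(self):
        sc = make_sc([[0.0, 1.0], [0.0, 1.0]], ["s1", "s1"], ["A", "B"])
        idx = CellTypeIndexSet.from_dataset(sc)
        with pytest.raises(DegenerateGroupError):
            relative_abundance(sc, idx, "s1", "A")

    def test_missing_group(self, tiny_sc):
        idx = CellTypeIndexSet.from_dataset(tiny_sc)
        with pytest.raises(MissingGroupError):
            relative_abundance(tiny_sc, idx, "s1", "nope")


class TestExcludeOutliers:
    def test_far_value_excluded(self):
        kept, center = exclude_outliers(
            [0.10, 0.11, 0.12, 0.90], OutlierConfig(n_clusters=2, rho=0.05)
        )
        np.testing.assert_allclose(sorted(kept), [0.10, 0.11, 0.12])
        assert center == pytest.approx(0.11)

    def test_identical_values_all_kept(self):
        kept, center = exclude_outliers([0.4] * 5, OutlierConfig(rho=0.1))
        assert len(kept) == 5
        assert center == 0.4

    def test_single_value(self):
        kept, center = exclude_outliers([3.0], OutlierConfig(rho=0.1))
        np.testing.assert_array_equal(kept, [3.0])
        assert center == 3.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            exclude_outliers([1.0, np.nan], OutlierConfig(rho=0.1))

    def test_never_empty(self, caplog):
        # threshold smaller than any distance to the centre keeps everything
        with caplog.at_level("WARNING", logger="dcap"):
            kept, _ = exclude_outliers([0.0, 1.0], OutlierConfig(n_clusters=1, rho=1e-12))
        assert len(kept) == 2

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=2, max_size=12),
        st.integers(1, 3),
    )
    def test_exclusion_never_increases_spread(self, values, k):
        kept, _ = exclude_outliers(values, OutlierConfig(n_clusters=k, rho=0.25))
        assert np.var(kept) <= np.var(values) + 1e-12


class TestAveraging:
    def _tensor(self, values):
        # one gene, one type, J subjects
        return np.asarray(values, dtype=float).reshape(-1, 1, 1)

    def test_mean_of_identical_values(self):
        out = average_abundance(self._tensor([0.2, 0.2, 0.2]), OutlierConfig(rho=0.1))
        assert out[0, 0] == pytest.approx(0.2)

    def test_outlier_excluded_before_mean(self):
        out = average_abundance(self._tensor([0.1, 0.1, 0.7]), OutlierConfig(rho=0.3))
        assert out[0, 0] == pytest.approx(0.1)

    def test_single_subject_passthrough(self):
        out = average_abundance(self._tensor([0.45]), OutlierConfig(rho=0.1))
        assert out[0, 0] == pytest.approx(0.45)

    def test_type_absent_everywhere(self):
        tensor = np.full((2, 1, 1), np.nan)
        with pytest.raises(MissingGroupError):
            average_abundance(tensor, OutlierConfig(rho=0.1))

    def test_cell_size_outlier_excluded(self):
        sizes = np.array([[100.0], [110.0], [500.0]])
        out = average_cell_size(sizes, OutlierConfig(n_clusters=2, rho=50.0))
        assert out[0] == pytest.approx(105.0)

    def test_cell_size_single_subject(self):
        out = average_cell_size(np.array([[77.0]]), OutlierConfig(rho=1.0))
        assert out[0] == pytest.approx(77.0)


class TestCrossSubjectVariance:
    def test_identical_subjects_zero(self):
        tensor = np.tile([[0.3], [0.7]], (3, 1, 1)).reshape(3, 2, 1)
        np.testing.assert_allclose(cross_subject_variance(tensor), 0.0, atol=1e-15)

    def test_population_variance(self):
        tensor = np.array([0.2, 0.4]).reshape(2, 1, 1)
        assert cross_subject_variance(tensor)[0, 0] == pytest.approx(0.01)

    def test_single_subject_is_zero(self):
        tensor = np.array([[0.5]]).reshape(1, 1, 1)
        assert cross_subject_variance(tensor)[0, 0] == 0.0


class TestCellSize:
    def test_mean_of_cell_totals(self):
        sc = make_sc([[60.0, 150.0], [40.0, 50.0]], ["s1", "s1"], ["A", "A"])
        idx = CellTypeIndexSet.from_dataset(sc)
        assert cell_size(sc, idx, "s1", "A") == pytest.approx(150.0)

    def test_single_cell(self):
        sc = make_sc([[50.0]], ["s1"], ["A"])
        idx = CellTypeIndexSet.from_dataset(sc)
        assert cell_size(sc, idx, "s1", "A") == pytest.approx(50.0)

    def test_missing_group(self, tiny_sc):
        idx = CellTypeIndexSet.from_dataset(tiny_sc)
        with pytest.raises(MissingGroupError):
            cell_size(tiny_sc, idx, "s3", "A")


class TestBuildReference:
    def test_design_is_size_times_theta(self, synth_ref):
        np.testing.assert_allclose(
            synth_ref.design_matrix,
            synth_ref.theta_avg * synth_ref.cell_size[np.newaxis, :],
        )
        assert (synth_ref.theta_avg >= 0).all()
        assert (synth_ref.var_matrix >= 0).all()

    def test_single_subject_collapses_to_identity_composition(self):
        counts = np.array([[2.0, 1.0, 4.0], [2.0, 5.0, 0.0], [6.0, 4.0, 1.0]])
        sc = make_sc(counts, ["s1"] * 3, ["A", "A", "B"])
        ref = build_reference(sc, OutlierConfig(rho=1e9), OutlierConfig(rho=1e9))
        # independent straight-line recomputation per cell-type group
        a_cols = counts[:, :2]
        theta_a = a_cols.sum(axis=1) / a_cols.sum()
        np.testing.assert_allclose(ref.theta_avg[:, 0], theta_a)
        np.testing.assert_array_equal(ref.var_matrix, 0.0)
        assert ref.cell_size[0] == pytest.approx(a_cols.sum() / 2)
        assert ref.cell_size[1] == pytest.approx(counts[:, 2].sum())

    def test_two_subjects_match_straight_line_composition(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 20, size=(4, 8)).astype(float)
        subjects = ["s1"] * 4 + ["s2"] * 4
        types = ["A", "A", "B", "B"] * 2
        sc = make_sc(counts, subjects, types)
        ref = build_reference(sc, OutlierConfig(rho=1e9), OutlierConfig(rho=1e9))
        # oracle: plain means with no outlier step, composed by hand
        for kk, ctype in enumerate(["A", "B"]):
            thetas, sizes = [], []
            for subj in ["s1", "s2"]:
                mask = [(s == subj and t == ctype) for s, t in zip(subjects, types)]
                grp = counts[:, np.asarray(mask)]
                thetas.append(grp.sum(axis=1) / grp.sum())
                sizes.append(grp.sum() / grp.shape[1])
            np.testing.assert_allclose(ref.theta_avg[:, kk], np.mean(thetas, axis=0))
            np.testing.assert_allclose(ref.var_matrix[:, kk], np.var(thetas, axis=0))
            expected_x = np.mean(sizes) * np.mean(thetas, axis=0)
            np.testing.assert_allclose(ref.design_matrix[:, kk], expected_x)

    def test_per_subject_theta_columns_sum_to_one(self, synth_ref):
        theta = synth_ref.per_subject_theta
        sums = np.nansum(theta, axis=1)
        present = ~np.isnan(theta[:, 0, :])
        np.testing.assert_allclose(sums[present], 1.0, atol=1e-10)

    def test_save_load_round_trip(self, synth_ref, tmp_path):
        synth_ref.save(tmp_path / "ref")
        again = ReferenceModel.load(tmp_path / "ref")
        np.testing.assert_allclose(again.design_matrix, synth_ref.design_matrix)
        np.testing.assert_allclose(again.cell_size, synth_ref.cell_size)
        assert again.cell_types == [str(c) for c in synth_ref.cell_types]
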