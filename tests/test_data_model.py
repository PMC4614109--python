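"""Containers, CSV I/O, curation, standardization, model round-trips."""

import numpy as np
import pytest

from elmqsar import (
    CurationRule,
    DescriptorMatrix,
    ELMModel,
    LabeledDataset,
    Standardizer,
    curate_by_activity,
    load_dataset,
    load_model,
    save_dataset,
    save_model,
    standardize,
)
from elmqsar.errors import (
    CurationError,
    DuplicateCompoundError,
    MissingColumnError,
    ModelFormatError,
    NonNumericCellError,
    StandardizationError,
    UnknownLabelError,
)


class TestLoadDataset:
    def test_string_labels_map_to_codes(self, class_csv):
        ds = load_dataset(str(class_csv), label_column="CLASS")
        assert ds.labels.tolist() == [1, 2, 1]
        assert ds.matrix.compound_ids == ["c1", "c2", "c3"]
        assert ds.matrix.descriptor_names == ["D1", "D2"]

    def test_numeric_codes_accepted(self, tmp_path):
        p = tmp_path / "codes.csv"
        p.write_text("ID,CLASS,X\na,1,0.1\nb,2,0.2\n")
        ds = load_dataset(str(p), label_column="CLASS")
        assert ds.labels.tolist() == [1, 2]

    def test_missing_label_column(self, class_csv):
        with pytest.raises(MissingColumnError):
            load_dataset(str(class_csv), label_column="NOPE")

    def test_duplicate_ids(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("ID,CLASS,X\na,1,0.1\na,2,0.2\n")
        with pytest.raises(DuplicateCompoundError):
            load_dataset(str(p), label_column="CLASS")

    def test_unknown_label_token(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ID,CLASS,X\na,maybe,0.1\nb,2,0.2\n")
        with pytest.raises(UnknownLabelError):
            load_dataset(str(p), label_column="CLASS")

    def test_nan_cell_strict_names_location(self, tmp_path):
        p = tmp_path / "nan.csv"
        p.write_text("ID,CLASS,X,Y\na,1,0.1,oops\nb,2,0.2,0.3\n")
        with pytest.raises(NonNumericCellError, match="'Y'"):
            load_dataset(str(p), label_column="CLASS")

    def test_nan_cell_permissive_drops_column(self, tmp_path):
        p = tmp_path / "nan.csv"
        p.write_text("ID,CLASS,X,Y\na,1,0.1,oops\nb,2,0.2,0.3\n")
        ds = load_dataset(str(p), label_column="CLASS", permissive=True)
        assert ds.matrix.descriptor_names == ["X"]
        assert ds.n_compounds == 2

    def test_pic50_mode_parses_reals(self, tmp_path):
        p = tmp_path / "pic.csv"
        p.write_text("ID,PIC50,X\na,7.0,0.1\nb,4.0,0.2\n")
        ds = load_dataset(str(p), label_column="PIC50", label_kind="pic50")
        assert ds.pic50.tolist() == [7.0, 4.0]

    def test_save_load_round_trip(self, tmp_path, small_synth):
        dataset, _ = small_synth
        p = tmp_path / "rt.csv"
        save_dataset(dataset, str(p))
        back = load_dataset(str(p), label_column="CLASS")
        assert back.matrix.compound_ids == dataset.matrix.compound_ids
        assert back.matrix.descriptor_names == dataset.matrix.descriptor_names
        assert back.labels.tolist() == dataset.labels.tolist()
        np.testing.assert_array_equal(back.matrix.values, dataset.matrix.values)


class TestCuration:
    def _ds(self, pic50):
        n = len(pic50)
        mat = DescriptorMatrix(
            [f"c{i}" for i in range(n)], ["X"], np.arange(n, dtype=float)[:, None]
        )
        labels = np.where(np.asarray(pic50) >= 5.5, 1, 2)
        return LabeledDataset(mat, labels, np.asarray(pic50, dtype=float))

    def test_intermediates_removed_and_relabeled(self):
        curated, report = curate_by_activity(self._ds([7.0, 5.5, 4.0]))
        assert curated.n_compounds == 2
        assert curated.labels.tolist() == [1, 2]
        assert report.n_removed == 1
        assert report.n_input == curated.n_compounds + report.n_removed

    def test_boundaries_are_kept(self):
        curated, _ = curate_by_activity(self._ds([6.0, 5.0]))
        assert curated.labels.tolist() == [1, 2]  # 6.0 active, 5.0 inactive

    def test_empty_class_raises(self):
        with pytest.raises(CurationError):
            curate_by_activity(self._ds([6.5, 6.5]))

    def test_all_removed_raises(self):
        with pytest.raises(CurationError):
            curate_by_activity(self._ds([5.5, 5.5]))

    def test_custom_rule(self):
        rule = CurationRule(low=4.0, high=7.0)
        curated, _ = curate_by_activity(self._ds([8.0, 5.0, 3.0]), rule)
        assert curated.labels.tolist() == [1, 2]
        with pytest.raises(ValueError):
            CurationRule(low=6.0, high=5.0)


class TestStandardize:
    def test_closed_form_column(self):
        mat = DescriptorMatrix(["a", "b", "c"], ["X"], [[1.0], [2.0], [3.0]])
        z, _ = standardize(mat)
        np.testing.assert_allclose(z.values[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_excluded(self):
        mat = DescriptorMatrix(
            ["a", "b", "c"], ["X", "K"], [[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]
        )
        z, stats = standardize(mat)
        assert z.descriptor_names == ["X"]
        assert stats.dropped_names == ["K"]

    def test_all_constant_raises(self):
        mat = DescriptorMatrix(["a", "b"], ["K"], [[5.0], [5.0]])
        with pytest.raises(StandardizationError):
            standardize(mat)

    def test_round_trip_inverse(self, small_synth):
        dataset, _ = small_synth
        z, stats = standardize(dataset.matrix)
        back = stats.inverse_transform(z)
        np.testing.assert_allclose(back.values, dataset.matrix.values, atol=1e-12)

    def test_idempotent(self, small_synth):
        dataset, _ = small_synth
        z1, _ = standardize(dataset.matrix)
        z2, _ = standardize(z1)
        np.testing.assert_allclose(z2.values, z1.values, atol=1e-12)


class TestModelIO:
    def _model(self):
        return ELMModel(
            descriptor_names=["A", "B"],
            weights=np.array([0.123456789012345678, -1.5e-7]),
            threshold=-0.8834567890123456,
            threshold_mode="midpoint",
            standardizer=Standardizer(
                ["A", "B"], np.array([0.1, 0.2]), np.array([1.5, 2.5]), []
            ),
            seed=42,
            config={"population_size": 100},
        )

    def test_round_trip_bit_identical(self, tmp_path):
        model = self._model()
        p = tmp_path / "m.elm"
        save_model(model, str(p))
        back = load_model(str(p))
        assert back.descriptor_names == model.descriptor_names
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.threshold == model.threshold
        assert back.threshold_mode == model.threshold_mode
        np.testing.assert_array_equal(
            back.standardizer.means, model.standardizer.means
        )
        assert back.seed == 42

    def test_truncated_file_raises(self, tmp_path):
        model = self._model()
        p = tmp_path / "m.elm"
        save_model(model, str(p))
        text = p.read_text().splitlines()
        p.write_text("\n".join(text[:3]) + "\n")
        with pytest.raises(ModelFormatError):
            load_model(str(p))

    def test_wrong_version_raises(self, tmp_path):
        p = tmp_path / "m.elm"
        p.write_text("format\telm-model/99\nend\t.\n")
        with pytest.raises(ModelFormatError):
            load_model(str(p))

    def test_empty_subset_refused(self, tmp_path):
        with pytest.raises(ValueError):
            ELMModel(descriptor_names=[], weights=np.array([]), threshold=0.0)
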