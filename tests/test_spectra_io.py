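import numpy as np
import pytest

from nirpls import (
    ConstituentTable,
    SpectraError,
    SpectraMatrix,
    average_duplicates,
    fit_pls,
    load_model,
    predict,
    read_constituents_csv,
    read_spectra_csv,
    save_model,
    write_constituents_csv,
    write_spectra_csv,
)

UNITS = {"glucan": "wt%_dry", "xylan": "wt%_dry", "G.Release": "g_per_g"}


class TestSpectraMatrix:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(SpectraError, match="duplicate sample id"):
            SpectraMatrix(["a", "a"], [1.0, 2.0], [[1, 2], [3, 4]])

    def test_non_uniform_axis_rejected(self):
        with pytest.raises(SpectraError, match="not uniformly spaced"):
            SpectraMatrix(["a"], [1.0, 2.0, 4.0], [[1, 2, 3]])

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(SpectraError, match="monotone"):
            SpectraMatrix(["a"], [1.0, 3.0, 2.0], [[1, 2, 3]])

    def test_decreasing_axis_accepted(self):
        s = SpectraMatrix(["a"], [3.0, 2.0, 1.0], [[1, 2, 3]])
        assert s.spacing == -1.0

    def test_missing_values_rejected(self):
        with pytest.raises(SpectraError, match="non-finite"):
            SpectraMatrix(["a"], [1.0, 2.0], [[1.0, np.nan]])


class TestSpectraCSV:
    def test_round_trip_identity(self, small_spectra, tmp_path):
        path = write_spectra_csv(small_spectra, tmp_path / "s.csv")
        back = read_spectra_csv(path)
        assert back == small_spectra  # bit-exact, including the axis

    def test_round_trip_irregular_floats(self, tmp_path):
        # absorbances with full 53-bit mantissas survive the 17-digit rendering
        rng = np.random.default_rng(1)
        nu = np.round(np.arange(5000.0, 5000.0 + 3.857 * 7, 3.857), 3)
        s = SpectraMatrix(["x"], nu, rng.normal(size=(1, nu.size)) * 1e-3)
        assert read_spectra_csv(write_spectra_csv(s, tmp_path / "s.csv")) == s

    def test_single_sample_file(self, tmp_path):
        s = SpectraMatrix(["only"], [1.0, 2.0], [[5.0, 6.0]])
        assert read_spectra_csv(write_spectra_csv(s, tmp_path / "s.csv")) == s

    def test_duplicate_id_in_file(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,1.000,2.000\na,1,2\na,3,4\n")
        with pytest.raises(SpectraError, match="duplicate sample id"):
            read_spectra_csv(p)

    def test_uneven_axis_in_file(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,1.000,2.000,4.000\na,1,2,3\n")
        with pytest.raises(SpectraError, match="not uniformly spaced"):
            read_spectra_csv(p)

    def test_non_numeric_cell_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,1.000,2.000\na,1,oops\n")
        with pytest.raises(SpectraError, match="row 2"):
            read_spectra_csv(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("sample_id,1.000,2.000\n")
        with pytest.raises(SpectraError, match="no samples"):
            read_spectra_csv(p)


class TestConstituentTable:
    def test_plausible_composition_accepted(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("sample_id,glucan\ns1,33.2\n")
        t = read_constituents_csv(p, UNITS)
        assert t.column("glucan")[0] == 33.2

    def test_weight_percent_over_100_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("sample_id,glucan\ns1,101\n")
        with pytest.raises(SpectraError, match="out of range"):
            read_constituents_csv(p, UNITS)

    def test_negative_release_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("sample_id,G.Release\ns1,-0.1\n")
        with pytest.raises(SpectraError, match="out of range"):
            read_constituents_csv(p, UNITS)

    def test_unknown_constituent_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("sample_id,mystery\ns1,1\n")
        with pytest.raises(SpectraError, match="unknown constituent"):
            read_constituents_csv(p, UNITS)

    def test_round_trip(self, tmp_path):
        t = ConstituentTable(
            ["s1", "s2"], ["glucan", "xylan"],
            [[33.2, 17.8], [40.0, 20.0]],
            {"glucan": "wt%_dry", "xylan": "wt%_dry"},
        )
        p = write_constituents_csv(t, tmp_path / "c.csv")
        assert read_constituents_csv(p, UNITS) == t


class TestAverageDuplicates:
    def test_mean_of_two_replicates(self):
        s = SpectraMatrix(
            ["s1_rep1", "s1_rep2"], [1.0, 2.0, 3.0],
            [[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]],
        )
        out = average_duplicates(s)
        assert out.sample_ids == ["s1"]
        np.testing.assert_array_equal(out.absorbance, [[2.0, 2.0, 2.0]])

    def test_single_replicate_unchanged(self, small_spectra):
        out = average_duplicates(small_spectra)
        assert out == small_spectra

    def test_idempotent(self):
        s = SpectraMatrix(
            ["s1_rep1", "s1_rep2", "s2_rep1"], [1.0, 2.0],
            [[1.0, 2.0], [3.0, 4.0], [0.0, 0.0]],
        )
        once = average_duplicates(s)
        assert average_duplicates(once) == once

    def test_symmetric_replicates_give_mean(self, rng):
        m = rng.normal(size=3)
        r = rng.normal(size=3)
        s = SpectraMatrix(["x_rep1", "x_rep2"], [1.0, 2.0, 3.0],
                          np.vstack([r, 2 * m - r]))
        np.testing.assert_allclose(average_duplicates(s).absorbance[0], m, atol=1e-14)

    def test_explicit_map_overrides_suffix(self):
        s = SpectraMatrix(["u", "v"], [1.0, 2.0], [[0.0, 0.0], [2.0, 2.0]])
        out = average_duplicates(s, replicate_map={"u": "base", "v": "base"})
        assert out.sample_ids == ["base"]
        np.testing.assert_array_equal(out.absorbance, [[1.0, 1.0]])


class TestModelSerialization:
    @pytest.fixture
    def fitted(self, rng):
        X = rng.normal(size=(30, 12))
        Y = X @ rng.normal(size=(12, 2)) + 0.1 * rng.normal(size=(30, 2))
        return X, fit_pls(X, Y, 9, x_weights=1.0 / X.std(axis=0, ddof=1),
                          calibration_ids=[f"s{i}" for i in range(30)],
                          preprocess_provenance={"snv": True, "sg_window": 21})

    def test_round_trip_predictions_bit_exact(self, fitted, tmp_path):
        X, model = fitted
        path = save_model(model, tmp_path / "m.json")
        back = load_model(path)
        np.testing.assert_array_equal(predict(back, X), predict(model, X))

    def test_provenance_preserved(self, fitted, tmp_path):
        _, model = fitted
        back = load_model(save_model(model, tmp_path / "m.json"))
        assert back.preprocess_provenance == {"snv": True, "sg_window": 21}
        assert back.calibration_ids == model.calibration_ids

    def test_truncated_file_rejected(self, fitted, tmp_path):
        _, model = fitted
        path = save_model(model, tmp_path / "m.json")
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(SpectraError, match="corrupt"):
            load_model(path)

    def test_schema_version_mismatch(self, fitted, tmp_path):
        import json

        _, model = fitted
        path = save_model(model, tmp_path / "m.json")
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(SpectraError, match="schema version"):
            load_model(path)
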