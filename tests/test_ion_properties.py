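"""Descriptor table loading, grouping, composites, IQR and rank correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qicar.ion_properties import (MetalIon, PropertyTable, S_BLOCK, TRANSITION,
                                  assign_group, derive_composites,
                                  iqr_of_property, load_property_table,
                                  load_study_properties,
                                  spearman_property_matrix)


class TestLoading:
    def test_bundled_table_shape(self, study_props):
        assert len(study_props) == 17
        assert len(study_props.descriptors) == 16

    def test_bundled_table_with_extension_ions(self):
        table = load_study_properties(include_extension=True)
        assert len(table) == 20
        for ion in ("Al", "Cr", "V"):
            assert ion in table

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="no ions"):
            load_property_table(path)

    def test_header_only_rejected(self, tmp_path):
        path = tmp_path / "hdr.csv"
        path.write_text("ion,charge,AN\n")
        with pytest.raises(ValueError, match="no ions"):
            load_property_table(path)

    def test_duplicate_ion_rows_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("ion,charge,AN\nFe,2,26\nFe,2,26\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_property_table(path)

    def test_non_numeric_cell_names_ion_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ion,charge,AN\nFe,2,oops\n")
        with pytest.raises(ValueError, match="Fe.*AN|AN.*Fe"):
            load_property_table(path)

    def test_single_descriptor_table(self, tmp_path):
        path = tmp_path / "an_only.csv"
        path.write_text("ion,charge,AN\nFe,2,26\nCu,2,29\n")
        table = load_property_table(path)
        assert table.descriptors == ["AN"]
        with pytest.raises(KeyError):
            table.values_of("Xm")

    def test_unknown_columns_ignored_with_warning(self, tmp_path, caplog):
        path = tmp_path / "extra.csv"
        path.write_text("ion,charge,AN,comment\nFe,2,26,hello\n")
        table = load_property_table(path)
        assert "comment" not in table.descriptors

    def test_tsv_dialect_accepted(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("ion\tcharge\tAN\nFe\t2\t26\n")
        assert load_property_table(path).values_of("AN").loc["Fe"] == 26


class TestGroups:
    @pytest.mark.parametrize("symbol,expected", [
        ("Mg", "s-block"), ("Pb", "transition"), ("Fe", "transition"),
        ("Cs", "s-block"), ("Hg", "transition"),
    ])
    def test_known_ions(self, symbol, expected):
        assert assign_group(symbol) == expected

    def test_partition_of_study_roster(self, study_props):
        groups = study_props.groups
        assert (groups == "s-block").sum() == 7
        assert (groups == "transition").sum() == 10
        assert set(groups[groups == "s-block"].index) == set(S_BLOCK)
        assert set(groups[groups == "transition"].index) == set(TRANSITION)

    def test_unknown_ion_without_config_raises(self):
        with pytest.raises(KeyError):
            assign_group("Xx")

    def test_extension_ions_classified_by_config(self):
        assert assign_group("Al") == "transition"
        assert assign_group("Al", extra={"Al": "s-block"}) == "s-block"

    def test_metal_ion_dataclass(self):
        ion = MetalIon("Fe", 2)
        assert ion.group == "transition"
        assert str(ion) == "Fe(II)"
        with pytest.raises(ValueError):
            MetalIon("Fe", 0)


class TestComposites:
    def test_bundled_composites_consistent_within_1pct(self, study_props):
        study_props.check_composites(rel_tol=0.01)  # must not raise

    @pytest.mark.parametrize("row,expected", [
        (dict(charge=2, Z=2, r=0.5), ("Z2_r", 8.0)),
        (dict(charge=1, Z=1, Xm=1.0, r=1.0), ("Xm2r", 1.0)),
        (dict(charge=2, Z=2, AN=26, dIP=13.0), ("AN_dIP", 2.0)),
        (dict(charge=2, Z=2, AR=0.5), ("Z_AR", 4.0)),
    ])
    def test_derivation_values(self, row, expected):
        name, value = expected
        frame = pd.DataFrame([row], index=pd.Index(["Fe"], name="ion"))
        derived = derive_composites(PropertyTable(frame))
        assert derived.values_of(name).loc["Fe"] == pytest.approx(value)

    def test_present_values_never_overwritten(self):
        frame = pd.DataFrame([dict(charge=2, Z=2, r=0.5, Z2_r=8.01)],
                             index=pd.Index(["Fe"], name="ion"))
        derived = derive_composites(PropertyTable(frame))
        assert derived.values_of("Z2_r").loc["Fe"] == 8.01

    def test_inconsistent_stored_composite_rejected(self):
        frame = pd.DataFrame([dict(charge=2, Z=2, r=0.5, Z2_r=9.0)],
                             index=pd.Index(["Fe"], name="ion"))
        with pytest.raises(ValueError, match="inconsistent"):
            PropertyTable(frame)

    def test_zero_primitive_raises(self):
        frame = pd.DataFrame([dict(charge=2, Z=2, AN=26, dIP=0.0)],
                             index=pd.Index(["Fe"], name="ion"))
        with pytest.raises(ZeroDivisionError):
            derive_composites(PropertyTable(frame))


class TestIQR:
    def test_matches_independent_quantile_implementation(self, rng):
        # oracle: scipy.stats.iqr with the same linear-interpolation rule
        for _ in range(20):
            values = rng.normal(size=rng.integers(4, 30))
            assert iqr_of_property(values) == pytest.approx(
                stats.iqr(values, interpolation="linear"))

    def test_four_point_example(self):
        assert iqr_of_property([1, 2, 3, 4]) == pytest.approx(1.5)

    def test_iqr_ignores_a_far_tail_point(self):
        # the IQR is tail-robust: replacing the max by a gross outlier leaves
        # the quartiles (hence the standardization) unchanged; both values
        # verified against the independent implementation
        with_outlier = iqr_of_property([1, 2, 3, 4, 100])
        clean = iqr_of_property([1, 2, 3, 4, 5])
        assert with_outlier == pytest.approx(stats.iqr([1, 2, 3, 4, 100]))
        assert clean == pytest.approx(stats.iqr([1, 2, 3, 4, 5]))
        assert with_outlier == pytest.approx(clean)

    def test_constant_values_give_zero(self):
        assert iqr_of_property([3.0, 3.0, 3.0]) == 0.0

    def test_requires_two_finite_values(self):
        with pytest.raises(ValueError):
            iqr_of_property([1.0])

    def test_alternative_quantile_convention(self):
        # averaged-inverted-cdf on the ten transition atomic numbers
        an = [25, 26, 27, 28, 29, 30, 47, 48, 80, 82]
        assert iqr_of_property(an, method="averaged_inverted_cdf") == pytest.approx(21.0)


class TestSpearman:
    def test_diagonal_symmetry_and_range(self, study_props):
        corr = spearman_property_matrix(study_props)
        on_diag = np.diag(corr.to_numpy())
        assert np.allclose(on_diag[~np.isnan(on_diag)], 1.0)
        assert np.allclose(corr, corr.T, equal_nan=True)
        vals = corr.to_numpy()
        assert np.nanmin(vals) >= -1.0 and np.nanmax(vals) <= 1.0

    def test_strictly_decreasing_gives_minus_one(self):
        frame = pd.DataFrame({"charge": 2, "AN": [1, 2, 3, 4],
                              "MP": [9.0, 7.0, 3.0, 1.0]},
                             index=pd.Index(list("abcd"), name="ion"))
        corr = spearman_property_matrix(PropertyTable(frame))
        assert corr.loc["AN", "MP"] == pytest.approx(-1.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10))
    def test_invariant_under_monotone_transform(self, study_props, shift):
        base = spearman_property_matrix(study_props)
        frame = study_props.frame.copy()
        frame["MP"] = np.exp((frame["MP"] - frame["MP"].mean()) / 500.0) + shift
        transformed = spearman_property_matrix(PropertyTable(frame))
        assert np.allclose(base["MP"].dropna(), transformed["MP"].dropna())

    def test_pairwise_complete_minimum(self):
        frame = pd.DataFrame({"charge": 2, "AN": [1, 2, 3, 4],
                              "MP": [1.0, 2.0, np.nan, np.nan]},
                             index=pd.Index(list("abcd"), name="ion"))
        corr = spearman_property_matrix(PropertyTable(frame), min_periods=3)
        assert np.isnan(corr.loc["AN", "MP"])

    def test_zero_variance_column_undefined(self):
        frame = pd.DataFrame({"charge": 2, "AN": [1, 2, 3, 4],
                              "MP": [5.0, 5.0, 5.0, 5.0]},
                             index=pd.Index(list("abcd"), name="ion"))
        corr = spearman_property_matrix(PropertyTable(frame))
        assert np.isnan(corr.loc["AN", "MP"])
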