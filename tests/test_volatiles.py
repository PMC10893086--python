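"""Volatile peak-table hygiene: every filtering rule at its boundary."""

import numpy as np
import pandas as pd
import pytest

from chemomix import (
    ValidationError,
    average_technical_duplicates,
    blank_subtract,
    class_summary,
    normalise_to_cells,
    normalise_to_internal_standard,
    partition_by_treatment,
    preprocess_volatiles,
    presence_filter,
    remove_contaminants,
)
from chemomix.volatiles import STAGE_ORDER

from conftest import make_samples, make_table


def _blank_table(values, n_blanks):
    samples = make_samples(0, n_blanks=n_blanks)
    return make_table(values, samples, layer="volatile")


class TestInternalStandard:
    def test_division(self):
        samples = make_samples(1)
        table = make_table([[1000.0, 500.0]], samples, layer="volatile")
        is_areas = pd.Series([500.0, 500.0], index=[s.sample_id for s in samples])
        out = normalise_to_internal_standard(table, is_areas)
        assert list(out.abundance.iloc[0]) == [2.0, 1.0]

    def test_scale_invariance(self):
        samples = make_samples(1)
        ids = [s.sample_id for s in samples]
        t1 = make_table([[100.0, 300.0]], samples, layer="volatile")
        t10 = make_table([[1000.0, 3000.0]], samples, layer="volatile")
        out1 = normalise_to_internal_standard(t1, pd.Series(50.0, index=ids))
        out10 = normalise_to_internal_standard(t10, pd.Series(500.0, index=ids))
        assert np.allclose(out1.abundance, out10.abundance)

    def test_zero_is_rejected(self):
        samples = make_samples(1)
        table = make_table([[1.0, 1.0]], samples, layer="volatile")
        with pytest.raises(ValidationError):
            normalise_to_internal_standard(
                table, pd.Series([0.0, 1.0], index=[s.sample_id for s in samples])
            )


class TestAverageTechnicalDuplicates:
    def test_mean_and_single_detection(self):
        samples = make_samples(1, technical_reps=2)  # 4 columns
        values = [
            [2.0, 4.0, 1.0, 1.0],      # plain mean -> 3
            [6.0, np.nan, 2.0, 2.0],   # single detection carries through -> 6
            [np.nan, np.nan, 5.0, 5.0],  # both missing -> missing
        ]
        out = average_technical_duplicates(
            make_table(values, samples, layer="volatile")
        )
        assert out.sample_ids == ["control-1", "heat-1"]
        assert out.abundance.loc["a1", "control-1"] == 3.0
        assert out.abundance.loc["a2", "control-1"] == 6.0
        assert out.detected.loc["a2", "control-1"]
        assert not out.detected.loc["a3", "control-1"]

    def test_uneven_duplicates_warn(self):
        samples = make_samples(1, technical_reps=2)[:3]  # heat-1 has 1 duplicate
        table = make_table([[1.0, 2.0, 3.0]], samples, layer="volatile")
        with pytest.warns(UserWarning, match="duplicate"):
            out = average_technical_duplicates(table)
        assert out.abundance.loc["a1", "heat-1"] == 3.0


class TestRemoveContaminants:
    def test_case_insensitive_exact_match(self):
        samples = make_samples(1)
        table = make_table(
            np.ones((3, 2)), samples, layer="volatile",
            analytes=["Siloxane-X", "benzene", "anisole"],
        )
        out = remove_contaminants(table, ["siloxane-x"])
        assert out.analyte_ids == ["benzene", "anisole"]
        assert out.ladder[-1].parameters["removed"] == ["Siloxane-X"]

    def test_empty_list_identity(self):
        samples = make_samples(1)
        table = make_table(np.ones((2, 2)), samples, layer="volatile")
        assert remove_contaminants(table, []).analyte_ids == table.analyte_ids

    def test_no_substring_matching(self):
        samples = make_samples(1)
        table = make_table(np.ones((1, 2)), samples, layer="volatile",
                           analytes=["methylsiloxane-x"])
        assert remove_contaminants(table, ["siloxane-x"]).n_analytes == 1


class TestBlankSubtract:
    def test_background_flag_and_subtraction(self):
        # detected in 3 of 5 blanks (60% > 50%), mean blank 10:
        # samples {15, 8} -> {5, non-detect}
        samples = make_samples(1)
        table = make_table([[15.0, 8.0]], samples, layer="volatile")
        blanks = _blank_table([[10.0, 10.0, 10.0, np.nan, np.nan]], 5)
        out = blank_subtract(table, blanks)
        assert out.abundance.loc["a1", "control-1"] == 5.0
        assert not out.detected.loc["a1", "heat-1"]

    def test_below_threshold_untouched(self):
        # 2 of 5 blanks (40%) is not background
        samples = make_samples(1)
        table = make_table([[15.0, 8.0]], samples, layer="volatile")
        blanks = _blank_table([[10.0, 10.0, np.nan, np.nan, np.nan]], 5)
        out = blank_subtract(table, blanks)
        assert list(out.abundance.iloc[0]) == [15.0, 8.0]

    def test_absent_from_blanks_untouched(self):
        samples = make_samples(1)
        table = make_table([[15.0, 8.0]], samples, layer="volatile")
        blanks = _blank_table([[np.nan] * 5], 5)
        out = blank_subtract(table, blanks)
        assert list(out.abundance.iloc[0]) == [15.0, 8.0]

    def test_remove_mode(self):
        samples = make_samples(1)
        table = make_table([[15.0, 8.0], [3.0, 4.0]], samples, layer="volatile")
        blanks = _blank_table([[1.0] * 5, [np.nan] * 5], 5)
        out = blank_subtract(table, blanks, mode="remove")
        assert out.analyte_ids == ["a2"]

    def test_no_blanks_error(self):
        samples = make_samples(1)
        table = make_table([[1.0, 1.0]], samples, layer="volatile")
        empty = make_table(np.empty((1, 0)), [], layer="volatile")
        with pytest.raises(ValidationError):
            blank_subtract(table, empty)

    def test_never_increases_abundance(self, default_study):
        table = average_technical_duplicates(default_study.volatiles)
        out = blank_subtract(table, default_study.blanks)
        a, b = table.filled(0.0).to_numpy(), out.filled(0.0).to_numpy()
        assert (b <= a + 1e-12).all()


class TestPresenceFilter:
    def _table(self, det_control, det_heat):
        samples = make_samples(6)
        row = [1.0 if d else np.nan for d in det_control + det_heat]
        return make_table([row], samples, layer="volatile")

    def test_four_of_six_in_one_group_retained(self):
        t = self._table([False] * 6, [True] * 4 + [False] * 2)
        assert presence_filter(t).n_analytes == 1

    def test_three_of_six_both_groups_removed(self):
        t = self._table([True] * 3 + [False] * 3, [True] * 3 + [False] * 3)
        assert presence_filter(t).n_analytes == 0

    def test_full_detection_retained(self):
        t = self._table([True] * 6, [True] * 6)
        assert presence_filter(t).n_analytes == 1

    def test_never_increases_count(self, default_study):
        table = average_technical_duplicates(default_study.volatiles)
        assert presence_filter(table).n_analytes <= table.n_analytes


class TestNormaliseToCells:
    def test_division_by_density(self):
        samples = make_samples(1, cell_density=1e5)
        out = normalise_to_cells(make_table([[2.0, 2.0]], samples, layer="volatile"))
        assert np.allclose(out.abundance.to_numpy(), 2e-5)

    def test_inverse_scaling(self):
        s1 = make_samples(1, cell_density=1e5)
        s2 = make_samples(1, cell_density=2e5)
        o1 = normalise_to_cells(make_table([[2.0, 2.0]], s1, layer="volatile"))
        o2 = normalise_to_cells(make_table([[2.0, 2.0]], s2, layer="volatile"))
        assert np.allclose(o1.abundance.to_numpy(), 2 * o2.abundance.to_numpy())


class TestPartitionAndClasses:
    def test_partition_sets(self):
        samples = make_samples(2)
        values = [
            [1.0, 1.0, np.nan, np.nan],  # control only
            [np.nan, np.nan, 1.0, 1.0],  # heat only
            [1.0, np.nan, np.nan, 1.0],  # shared
        ]
        t = make_table(values, samples, layer="volatile")
        p = partition_by_treatment(t)
        assert p["unique_to_control"] == {"a1"}
        assert p["unique_to_heat"] == {"a2"}
        assert p["shared"] == {"a3"}

    def test_partition_conservation(self, default_study):
        table = presence_filter(
            blank_subtract(
                average_technical_duplicates(default_study.volatiles),
                default_study.blanks,
            )
        )
        p = partition_by_treatment(table)
        union = p["unique_to_heat"] | p["unique_to_control"] | p["shared"]
        assert union == set(table.analyte_ids)
        assert not (p["unique_to_heat"] & p["unique_to_control"])
        assert not (p["shared"] & (p["unique_to_heat"] | p["unique_to_control"]))

    def test_planted_unique_sets_recovered(self, default_study):
        table = presence_filter(
            blank_subtract(
                average_technical_duplicates(default_study.volatiles),
                default_study.blanks,
            )
        )
        p = partition_by_treatment(table)
        truth = default_study.truth
        retained_uh = truth.unique_to_heat_ids & set(table.analyte_ids)
        assert p["unique_to_heat"] >= retained_uh
        # structurally absent analytes can never land in shared
        assert not (p["shared"] & truth.unique_to_heat_ids)
        assert not (p["shared"] & truth.unique_to_control_ids)

    def test_class_summary_counts(self):
        samples = make_samples(2)
        values = [
            [np.nan, np.nan, 1.0, 1.0],
            [np.nan, np.nan, 1.0, 1.0],
            [np.nan, np.nan, 1.0, 1.0],
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 1.0],
        ]
        t = make_table(values, samples, layer="volatile",
                       classes=["alkene"] * 5)
        summary = class_summary(t, partition_by_treatment(t))
        assert summary.loc["alkene", "heat_only"] == 3
        assert summary.loc["alkene", "shared"] == 2
        # 3 of 5 alkenes heat-only -> 60% heat-only share
        assert summary.loc["alkene"].sum() == 5

    def test_empty_table_empty_summary(self):
        t = make_table(np.empty((0, 4)), make_samples(2), layer="volatile")
        summary = class_summary(t, partition_by_treatment(t))
        assert summary.empty


class TestFullChain:
    def test_stage_order_in_ladder(self, default_study):
        out = preprocess_volatiles(
            default_study.volatiles,
            default_study.blanks,
            default_study.volatile_is,
            blank_is_areas=default_study.blank_is,
            exclusion_list=default_study.known_artefacts,
        )
        steps = [s for s in out.ladder_steps() if s in STAGE_ORDER]
        assert steps == STAGE_ORDER

    def test_planted_contaminants_flagged(self, default_study):
        out = preprocess_volatiles(
            default_study.volatiles,
            default_study.blanks,
            default_study.volatile_is,
            blank_is_areas=default_study.blank_is,
        )
        flagged = next(
            s.parameters["background"]
            for s in out.ladder
            if s.step_name == "blank_subtract"
        )
        assert set(flagged) == default_study.truth.contaminant_ids
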