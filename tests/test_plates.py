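"""Plate layouts: dilution arithmetic, screen/combination geometry,
virtual-plate assembly and serialisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoscreen.plates import (
    MICROMOLAR,
    PlateLayout,
    ScreenAnnotation,
    WellAddress,
    WellAssignment,
    assemble_virtual_plate,
    build_combination_layout,
    build_dilution_series,
    build_screen_layout,
    column_to_concentration,
)


class TestDilutionSeries:
    def test_two_fold_ladder_from_4uM_ends_at_quarter_uM(self):
        series = build_dilution_series(4 * MICROMOLAR, 2.0, 5)
        assert np.allclose(
            series.concentrations,
            np.array([4, 2, 1, 0.5, 0.25]) * MICROMOLAR,
        )

    def test_single_level_is_identity(self):
        assert build_dilution_series(10.0, 3.0, 1).concentrations == (10.0,)

    def test_ten_threefold_dilutions_span_to_5e4_of_gi50(self):
        # screening ladder: 10x GI50 down to ~5.08e-4 x GI50
        gi50 = 1.0
        series = build_dilution_series(10 * gi50, 3.0, 10)
        assert series.concentrations[-1] == pytest.approx(10 / 3**9)
        assert series.concentrations[-1] == pytest.approx(5.08e-4, rel=5e-3)

    @pytest.mark.parametrize(
        "start,fold,n", [(-1.0, 3.0, 5), (0.0, 3.0, 5), (1.0, 1.0, 5), (1.0, 3.0, 0)]
    )
    def test_invalid_arguments_rejected(self, start, fold, n):
        with pytest.raises(ValueError):
            build_dilution_series(start, fold, n)

    @given(
        start=st.floats(1e-9, 1e-3),
        fold=st.floats(1.5, 10.0),
        n=st.integers(1, 12),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_and_monotonicity(self, start, fold, n):
        series = build_dilution_series(start, fold, n)
        concs = np.array(series.concentrations)
        assert len(concs) == n
        assert np.all(np.diff(concs) < 0) or n == 1
        assert concs[0] / concs[-1] == pytest.approx(fold ** (n - 1), rel=1e-12)


class TestColumnToConcentration:
    @pytest.mark.parametrize(
        "dm,expected",
        [(2, 10.0), (4, 10.0 / 3.0), (9, 10.0 * 3.0 ** (-3.5))],
    )
    def test_half_effect_column_formula(self, dm, expected):
        ann = ScreenAnnotation("drug", gi50=1.0, dm_column=dm)
        assert column_to_concentration(ann) == pytest.approx(expected, rel=1e-12)

    def test_scales_with_gi50(self):
        ann = ScreenAnnotation("drug", gi50=2.5e-6, dm_column=9)
        assert column_to_concentration(ann) == pytest.approx(
            2.5e-6 * 10 * 3 ** (-3.5)
        )
        # printed rounding of the worked example
        assert column_to_concentration(
            ScreenAnnotation("drug", gi50=1.0, dm_column=9)
        ) == pytest.approx(0.2138, abs=5e-5)

    def test_missing_dm_column_rejected(self):
        with pytest.raises(ValueError):
            column_to_concentration(ScreenAnnotation("drug", gi50=1.0))


class TestScreenLayout:
    def test_one_drug_ten_levels_duplicates_and_controls(self):
        controls = [WellAddress("P", c) for c in range(1, 5)]
        layout = build_screen_layout(
            [ScreenAnnotation("d1", gi50=1e-6)],
            n_levels=10, duplicates=2, control_wells=controls,
        )
        assert len(layout.wells) == 24
        assert len(layout.treated_wells) == 20
        assert len(layout.control_wells) == 4

    def test_no_drugs_gives_controls_only(self):
        controls = [WellAddress("A", 1)]
        layout = build_screen_layout([], control_wells=controls)
        assert layout.control_wells == controls
        assert layout.treated_wells == []

    def test_sixteen_drugs_fill_a_384_plate(self):
        drugs = [ScreenAnnotation(f"d{i}", gi50=1e-6) for i in range(16)]
        layout = build_screen_layout(drugs, n_levels=10, duplicates=2)
        assert len(layout.treated_wells) == 320
        assert len(layout.wells) <= layout.capacity

    def test_capacity_exceeded_rejected_with_counts(self):
        drugs = [ScreenAnnotation(f"d{i}", gi50=1e-6) for i in range(17)]
        with pytest.raises(ValueError, match="17"):
            build_screen_layout(drugs, n_levels=10, duplicates=2)

    def test_each_concentration_appears_duplicates_times(self):
        layout = build_screen_layout(
            [ScreenAnnotation("d1", gi50=1e-6)], n_levels=10, duplicates=2
        )
        groups = layout.replicate_groups()
        treated = {g: ws for g, ws in groups.items() if g != "control"}
        assert len(treated) == 10
        assert all(len(ws) == 2 for ws in treated.values())

    def test_no_double_assignment(self):
        layout = build_screen_layout(
            [ScreenAnnotation(f"d{i}", gi50=1e-6) for i in range(4)],
            control_wells=[WellAddress("P", 1)],
        )
        assert len(layout.wells) == len(set(layout.wells))


class TestCombinationLayout:
    def test_5x5_core_with_duplicates_is_50_wells(self):
        layout = build_combination_layout(
            ScreenAnnotation("A", gi50=1e-6), ScreenAnnotation("B", gi50=1e-6),
            centerA=1e-6, centerB=1e-6, n_levels=5, duplicates=2,
        )
        core = [
            w for w, a in layout.wells.items()
            if a.role == "treated" and len(a.drugs) == 2
        ]
        assert len(core) == 50

    def test_2x2_single_replicate_core(self):
        layout = build_combination_layout(
            ScreenAnnotation("A", gi50=1e-6), ScreenAnnotation("B", gi50=1e-6),
            centerA=1e-6, centerB=1e-6, n_levels=2, duplicates=1,
        )
        core = [a for a in layout.wells.values() if len(a.drugs) == 2]
        assert len(core) == 4

    def test_default_ladder_spans_fold_range_around_center(self):
        layout = build_combination_layout(
            ScreenAnnotation("A", gi50=1e-6), ScreenAnnotation("B", gi50=1e-6),
            centerA=1 * MICROMOLAR, centerB=1 * MICROMOLAR,
            fold=2.0, n_levels=5, duplicates=2,
        )
        concsA = sorted(
            {a.concentrations[0] for a in layout.wells.values() if a.drugs[:1] == ("A",)}
        )
        assert np.allclose(concsA, np.array([0.25, 0.5, 1, 2, 4]) * MICROMOLAR)

    def test_explicit_start_reproduces_4_to_quarter_uM(self):
        layout = build_combination_layout(
            ScreenAnnotation("A", gi50=1e-6), ScreenAnnotation("B", gi50=1e-6),
            centerA=1e-6, centerB=1e-6, fold=2.0, n_levels=5, duplicates=2,
            startA=4 * MICROMOLAR, startB=4 * MICROMOLAR,
        )
        concs = sorted(
            {a.concentrations[0] for a in layout.wells.values() if a.drugs[:1] == ("A",)}
        )
        assert concs[-1] == pytest.approx(4 * MICROMOLAR)
        assert concs[0] == pytest.approx(0.25 * MICROMOLAR)


class TestVirtualPlate:
    def test_duplicates_average(self):
        layout = PlateLayout("p")
        for col, score in ((1, 2.0), (2, 4.0)):
            layout.assign(
                WellAddress("A", col),
                WellAssignment("treated", ("d",), (1e-6,), "d|L0"),
            )
        scores = {WellAddress("A", 1): 2.0, WellAddress("A", 2): 4.0}
        virtual = assemble_virtual_plate(scores, layout)
        assert virtual.loc[0, "score"] == pytest.approx(3.0)
        assert virtual.loc[0, "n_wells"] == 2

    def test_singleton_group_is_identity(self):
        layout = PlateLayout("p")
        layout.assign(WellAddress("A", 1), WellAssignment("treated", ("d",), (1e-6,), "g"))
        virtual = assemble_virtual_plate({WellAddress("A", 1): 7.5}, layout)
        assert virtual.loc[0, "score"] == 7.5

    def test_order_invariance(self):
        layout = PlateLayout("p")
        for col in (1, 2, 3):
            layout.assign(
                WellAddress("A", col),
                WellAssignment("treated", ("d",), (1e-6,), "g"),
            )
        s1 = {WellAddress("A", c): v for c, v in ((1, 1.0), (2, 2.0), (3, 6.0))}
        s2 = {WellAddress("A", c): v for c, v in ((3, 6.0), (1, 1.0), (2, 2.0))}
        assert assemble_virtual_plate(s1, layout).equals(assemble_virtual_plate(s2, layout))

    def test_missing_wells_listed(self):
        layout = PlateLayout("p")
        layout.assign(WellAddress("A", 1), WellAssignment("treated", ("d",), (1e-6,), "g"))
        layout.assign(WellAddress("A", 2), WellAssignment("treated", ("d",), (1e-6,), "g"))
        with pytest.raises(ValueError, match="A02"):
            assemble_virtual_plate({WellAddress("A", 1): 1.0}, layout)

    def test_combination_layout_collapses_to_grid_plus_edges(self):
        layout = build_combination_layout(
            ScreenAnnotation("A", gi50=1e-6), ScreenAnnotation("B", gi50=1e-6),
            centerA=1e-6, centerB=1e-6, n_levels=5, duplicates=2,
        )
        scores = {w: 1.0 for w in layout.wells}
        virtual = assemble_virtual_plate(scores, layout)
        pairs = virtual[(virtual["drug_1"] == "A") & (virtual["drug_2"] == "B")]
        singleA = virtual[(virtual["drug_1"] == "A") & (virtual["drug_2"] == "")]
        singleB = virtual[(virtual["drug_1"] == "B") & (virtual["drug_2"] == "")]
        assert len(pairs) == 25
        assert len(singleA) == 5 and len(singleB) == 5


class TestSerialisation:
    def test_csv_round_trip(self, tmp_path):
        layout = build_combination_layout(
            ScreenAnnotation("A", gi50=1e-6), ScreenAnnotation("B", gi50=1e-6),
            centerA=1e-6, centerB=2e-6,
        )
        path = tmp_path / "layout.csv"
        layout.to_csv(path)
        back = PlateLayout.from_csv(path, plate_id=layout.plate_id)
        assert set(back.wells) == set(layout.wells)
        w = layout.treated_wells[0]
        assert back.wells[w].drugs == layout.wells[w].drugs
        assert back.wells[w].concentrations == pytest.approx(
            layout.wells[w].concentrations
        )

    def test_json_round_trip(self, tmp_path):
        layout = build_screen_layout(
            [ScreenAnnotation("d", gi50=1e-6)],
            control_wells=[WellAddress("P", 1)],
        )
        path = tmp_path / "layout.json"
        layout.to_json(path)
        back = PlateLayout.from_json(path)
        assert set(back.wells) == set(layout.wells)

    def test_reader_rejects_invalid_roles(self, tmp_path):
        import pandas as pd

        frame = pd.DataFrame(
            [{"well": "A01", "role": "bogus", "drug_1": "", "conc_1": "",
              "drug_2": "", "conc_2": "", "replicate_group": ""}]
        )
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError):
            PlateLayout.from_csv(path)
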