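"""Orthogonal array structure, treatment fixture, irrigation model, range analysis."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fertigation_mcda import (
    IrrigationSchedule,
    OrthogonalDesign,
    build_l9_design,
    input_reduction,
    irrigation_requirement,
    load_treatment_table,
    range_analysis,
)

response_vectors = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=9, max_size=9
)


class TestL9Array:
    def test_column_balance(self, design):
        for j in range(4):
            counts = np.bincount(design.runs[:, j], minlength=4)[1:]
            assert list(counts) == [3, 3, 3]

    def test_pairwise_orthogonality(self, design):
        for a, b in product(range(4), range(4)):
            if a >= b:
                continue
            pairs = set(zip(design.runs[:, a], design.runs[:, b]))
            assert len(pairs) == 9

    def test_t5_row_matches_treatment_code(self, design):
        # T5 = mild deficit irrigation with stage rates 750 / 937.5 / 562.5
        row = list(design.run_ids).index("T5")
        assert design.level_value(row, 0) == 0.75
        assert design.level_value(row, 1) == 750.0
        assert design.level_value(row, 2) == 937.5
        assert design.level_value(row, 3) == 562.5

    def test_unbalanced_array_rejected(self):
        runs = build_l9_design().runs.copy()
        runs[0, 0] = 2
        with pytest.raises(ValueError, match="unbalanced"):
            OrthogonalDesign(runs=runs)

    def test_any_two_runs_agree_in_exactly_one_column(self, design):
        # strength-2 structure used by the dominant-scenario construction
        for a, b in product(range(9), range(9)):
            if a < b:
                assert (design.runs[a] == design.runs[b]).sum() == 1


class TestTreatmentTable:
    def test_fixture_volumes_and_totals(self, treatment_by_id):
        assert treatment_by_id["T7"].irrigation_volume[2023] == 3050
        assert treatment_by_id["T7"].irrigation_volume[2024] == 2950
        assert treatment_by_id["T5"].total_fertilizer == 2250.0
        assert treatment_by_id["T3"].total_fertilizer == 2812.5

    def test_nine_treatments_two_years(self, treatments):
        assert len(treatments) == 9
        assert all(len(t.irrigation_volume) == 2 for t in treatments)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_treatment_table(tmp_path / "nope.csv")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="no treatment rows"):
            load_treatment_table(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "id,year,irrigation_m3_ha,fert1_kg_ha,fert2_kg_ha,fert3_kg_ha\n"
            "T1,2023,abc,562.5,562.5,562.5\n"
        )
        with pytest.raises(ValueError, match="non-numeric"):
            load_treatment_table(p)

    def test_duplicate_id_year(self, tmp_path, treatments):
        import pandas as pd

        rows = []
        for t in treatments:
            for y, v in t.irrigation_volume.items():
                rows.append([t.id, y, v, t.fert_stage1, t.fert_stage2, t.fert_stage3])
        rows.append(rows[0])
        df = pd.DataFrame(
            rows,
            columns=["id", "year", "irrigation_m3_ha", "fert1_kg_ha", "fert2_kg_ha", "fert3_kg_ha"],
        )
        p = tmp_path / "dup.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_treatment_table(p)


class TestIrrigationRequirement:
    def test_stage_pan_coefficients(self):
        s = IrrigationSchedule(pan_evaporation_mm=10, area_m2=1, stage="flowering")
        assert s.kcp == 1.3
        assert IrrigationSchedule(10, 1, stage="seedling").kcp == 0.6
        assert IrrigationSchedule(10, 1, stage="peak_fruit").kcp == 1.1

    def test_forced_arithmetic(self):
        s = IrrigationSchedule(pan_evaporation_mm=100, area_m2=10, stage="flowering")
        assert irrigation_requirement(s) == pytest.approx(1300.0)

    def test_zero_evaporation(self):
        s = IrrigationSchedule(pan_evaporation_mm=0, area_m2=30, stage="seedling")
        assert irrigation_requirement(s) == 0.0

    def test_negative_evaporation_rejected(self):
        with pytest.raises(ValueError):
            IrrigationSchedule(pan_evaporation_mm=-1, area_m2=1)


def brute_force_range(design, y, direction):
    """Independent oracle: explicit group-by level means."""
    out = {}
    for j, fac in enumerate(design.factors):
        kbar = []
        for level in (1, 2, 3):
            vals = [y[i] for i in range(9) if design.runs[i, j] == level]
            kbar.append(sum(vals) / len(vals))
        best = max(range(3), key=lambda l: kbar[l]) if direction == "benefit" else min(
            range(3), key=lambda l: kbar[l]
        )
        out[fac.name] = (kbar, max(kbar) - min(kbar), best + 1)
    return out


class TestRangeAnalysis:
    def test_level_index_response(self, design):
        # responses equal to factor 1's level index: that factor fully explains
        # the response and balance forces the others' level means to be equal
        y = design.runs[:, 0].astype(float)
        res = range_analysis(design, y)
        assert np.allclose(res.level_means["IA"], [1, 2, 3])
        assert res.ranges["IA"] == pytest.approx(2.0)
        for f in ("FI", "FII", "FIII"):
            assert np.allclose(res.level_means[f], [2, 2, 2])
            assert res.ranges[f] == pytest.approx(0.0)
        assert res.factor_order[0] == "IA"

    def test_constant_responses(self, design):
        res = range_analysis(design, np.full(9, 7.5))
        assert all(r == 0 for r in res.ranges.values())
        assert res.factor_order == ("IA", "FI", "FII", "FIII")  # stable

    def test_wrong_length_rejected(self, design):
        with pytest.raises(ValueError, match="9 responses"):
            range_analysis(design, [1.0] * 8)

    @given(response_vectors, st.sampled_from(["benefit", "cost"]))
    def test_matches_brute_force_oracle(self, y, direction):
        design = build_l9_design()
        res = range_analysis(design, y, direction=direction)
        oracle = brute_force_range(design, y, direction)
        for f in design.factor_names:
            kbar, rng_, best = oracle[f]
            assert np.allclose(res.level_means[f], kbar)
            assert res.ranges[f] == pytest.approx(rng_, abs=1e-9)
            # argmax/argmin tie-break may differ only when level means tie
            if len({round(v, 9) for v in kbar}) == 3:
                assert res.optimal_level[f] == best

    @given(response_vectors)
    def test_grand_mean_identity(self, y):
        design = build_l9_design()
        res = range_analysis(design, y)
        grand = np.mean(y)
        for f in design.factor_names:
            assert np.mean(res.level_means[f]) == pytest.approx(grand, rel=1e-9, abs=1e-9)


class TestInputReduction:
    def test_optimal_vs_full_irrigation(self, treatment_by_id):
        red = input_reduction(treatment_by_id["T5"], treatment_by_id["T7"])
        assert red["water_pct_2023"] == pytest.approx(25.0)
        assert red["water_pct_2024"] == pytest.approx(25.0)

    def test_fertilizer_vs_maximum(self, treatment_by_id):
        red = input_reduction(treatment_by_id["T5"], treatment_by_id["T3"])
        assert red["fert_pct"] == pytest.approx(20.0)

    def test_identical_treatments(self, treatment_by_id):
        red = input_reduction(treatment_by_id["T5"], treatment_by_id["T5"])
        assert all(v == pytest.approx(0.0) for v in red.values())

    def test_scale_invariance(self, treatment_by_id):
        from fertigation_mcda import Treatment

        t5, t7 = treatment_by_id["T5"], treatment_by_id["T7"]
        scale = 3.7
        s5 = Treatment(
            "T5", {y: v * scale for y, v in t5.irrigation_volume.items()},
            t5.fert_stage1, t5.fert_stage2, t5.fert_stage3,
        )
        s7 = Treatment(
            "T7", {y: v * scale for y, v in t7.irrigation_volume.items()},
            t7.fert_stage1, t7.fert_stage2, t7.fert_stage3,
        )
        assert input_reduction(s5, s7)["water_pct_2023"] == pytest.approx(
            input_reduction(t5, t7)["water_pct_2023"]
        )
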