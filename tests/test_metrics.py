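import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import t as t_dist

from wntscreen import (HitThresholds, call_hits, compare_context_toxicity,
                       delta_delta_ct, normalize_plate, qc_screen,
                       response_slope, simulate_qpcr, vehicle_comparison_test,
                       wnt_score, z_factor)
from wntscreen.data import WELL_COLUMNS


def make_plate(ratios, roles=None, renillas=None, plate="P01", day=1):
    n = len(ratios)
    roles = roles or ["vehicle"] + ["test"] * (n - 1)
    renillas = renillas if renillas is not None else [500.0] * n
    return pd.DataFrame({
        "plate_id": plate, "well": [f"A{i+1}" for i in range(n)],
        "chemical_id": [("VEHICLE" if r == "vehicle" else f"C{i}")
                        for i, r in enumerate(roles)],
        "concentration_uM": [0.0 if r == "vehicle" else 1.0 for r in roles],
        "firefly": [r * ren for r, ren in zip(ratios, renillas)],
        "renilla": renillas, "replicate_day": day, "role": roles,
    })


class TestNormalizePlate:
    def test_median_centering_of_ratios(self):
        out = normalize_plate(make_plate([1.0, 2.0, 4.0]))
        assert sorted(out.wnt_ratio) == [0.5, 1.0, 2.0]

    def test_identical_wells_normalize_to_unity(self):
        out = normalize_plate(make_plate([3.0] * 5))
        assert (out.wnt_ratio == 1.0).all()
        assert (out.cell_health == 1.0).all()
        assert (out.log2fc == 0.0).all()

    def test_log2fc_against_vehicle_mean(self):
        # two vehicle wells at the plate median, one test well at twice it
        out = normalize_plate(
            make_plate([1.0, 1.0, 2.0], roles=["vehicle", "vehicle", "test"]))
        assert out.loc[out.role == "test", "log2fc"].iloc[0] == pytest.approx(1.0)

    def test_plate_median_exactly_one(self, small_results):
        norm = small_results.normalized
        for _, g in norm.groupby(["plate_id", "replicate_day"]):
            assert g.wnt_ratio.median() == pytest.approx(1.0, abs=1e-12)
            assert g.cell_health.median() == pytest.approx(1.0, abs=1e-12)

    def test_no_vehicle_wells_is_an_error(self):
        plate = make_plate([1.0, 2.0], roles=["test", "test"])
        with pytest.raises(ValueError, match="vehicle"):
            normalize_plate(plate)

    def test_dead_well_excluded_with_warning(self, caplog):
        plate = make_plate([1.0, 2.0, 3.0], renillas=[500.0, 0.0, 500.0])
        plate.loc[1, "firefly"] = 0.0
        with caplog.at_level("WARNING"):
            out = normalize_plate(plate)
        assert len(out) == 2
        assert "dead" in caplog.text


class TestVehicleComparison:
    def test_identical_groups_give_p_one(self):
        assert vehicle_comparison_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 1.0

    def test_matches_textbook_welch_formula(self):
        a = np.array([1.0, 1.1, 0.9, 1.0])
        b = np.array([0.0, 0.1, -0.1, 0.0])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        expected = 2 * t_dist.sf(abs(t), df)
        assert vehicle_comparison_test(a, b) == pytest.approx(expected,
                                                              abs=1e-9)

    def test_single_observation_reports_absent_p(self):
        assert math.isnan(vehicle_comparison_test([1.0], [0.0, 0.1, 0.2]))

    def test_degenerate_variance_with_different_means_not_fabricated(self):
        assert math.isnan(vehicle_comparison_test([1.0, 1.0], [0.0, 0.0]))


class TestSlopesAndScore:
    def test_constant_values_have_zero_slope(self):
        assert response_slope([2.0, 2.0, 2.0], [0.1, 1.0, 10.0]) == 0.0

    def test_least_squares_slope_closed_form(self):
        # Sxy/Sxx for cell health {1, 0.5, 0.25} over three decades
        assert response_slope([1.0, 0.5, 0.25],
                              [1.0, 10.0, 100.0]) == pytest.approx(-0.375)

    def test_unit_slope_per_decade(self):
        assert response_slope([1.0, 2.0, 3.0],
                              [1.0, 10.0, 100.0]) == pytest.approx(1.0)

    def test_single_concentration_slope_absent(self):
        assert math.isnan(response_slope([1.0, 2.0], [5.0, 5.0]))

    def test_wnt_score_identity_and_penalty(self):
        assert wnt_score(1.0, 1.0) == 1.0
        assert wnt_score(2.0, 0.2) == pytest.approx(0.4)
        assert wnt_score(0.0, 0.5) == 0.0

    def test_slope_variant_multiplies_all_three(self):
        assert wnt_score(2.0, 0.5, slope=0.5, variant="slope") == pytest.approx(0.5)
        with pytest.raises(ValueError):
            wnt_score(1.0, 1.0, variant="bogus")


def score_row(**kw):
    base = dict(chemical_id="C", mean_log2fc_all_conc=0.0,
                mean_cell_health_all_conc=1.0, mean_ch_log2fc_all_conc=0.0,
                response_slope=0.0, toxicity_slope=0.0, wnt_score=0.0,
                min_p=1.0, min_p_cell_health=1.0)
    base.update(kw)
    return base


class TestCallHits:
    @pytest.mark.parametrize("row,expected", [
        (dict(min_p=0.01, mean_log2fc_all_conc=1.5, wnt_score=0.9), "activator"),
        (dict(min_p=0.2, mean_log2fc_all_conc=1.5, wnt_score=0.9), "none"),
        (dict(min_p=0.01, mean_log2fc_all_conc=-1.5, wnt_score=-0.8), "inhibitor"),
        (dict(min_p=0.01, mean_log2fc_all_conc=1.5, wnt_score=0.3), "none"),
        (dict(min_p=0.01, mean_log2fc_all_conc=0.5, wnt_score=0.9), "none"),
    ])
    def test_threshold_logic(self, row, expected):
        out = call_hits(pd.DataFrame([score_row(**row)]))
        assert out.hit_class.iloc[0] == expected

    def test_toxicity_takes_precedence_but_facts_retained(self):
        row = score_row(min_p=0.01, mean_log2fc_all_conc=1.5, wnt_score=0.9,
                        mean_ch_log2fc_all_conc=-1.5, min_p_cell_health=0.01)
        out = call_hits(pd.DataFrame([row]))
        assert out.hit_class.iloc[0] == "toxic"
        assert bool(out.is_activator.iloc[0])

    def test_bh_correction_adds_labeled_column(self):
        rows = [score_row(chemical_id=f"C{i}", min_p=p)
                for i, p in enumerate([0.01, 0.02, 0.5])]
        out = call_hits(pd.DataFrame(rows), bh_correction=True)
        # BH: sorted p * n / rank, cummin from the largest
        np.testing.assert_allclose(out.q_value_bh, [0.03, 0.03, 0.5])


class TestZFactor:
    def test_perfect_assay(self):
        assert z_factor([10.0, 10.0, 10.0], [0.0, 0.0, 0.0]) == 1.0

    def test_textbook_value(self):
        pos = [9.0, 10.0, 11.0]
        neg = [-1.0, 0.0, 1.0]
        assert z_factor(pos, neg) == pytest.approx(0.4)

    def test_identical_distributions_fail_with_sentinel(self):
        assert z_factor([1.0, 2.0], [1.5, 1.5]) == float("-inf")

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=10),
           st.lists(st.floats(-100, 100), min_size=2, max_size=10))
    def test_agrees_with_closed_form_on_any_samples(self, pos, neg):
        p, n = np.array(pos), np.array(neg)
        if p.mean() == n.mean():
            return
        expected = 1 - 3 * (p.std(ddof=1) + n.std(ddof=1)) / abs(p.mean() - n.mean())
        assert z_factor(pos, neg) == pytest.approx(expected, abs=1e-12)
        assert z_factor(pos, neg) <= 1.0


class TestQcScreen:
    def test_well_separated_controls_pass(self, small_results):
        qc = small_results.qc
        assert not qc.missing_controls.any()
        assert qc.activators_pass_sign.all()
        assert qc.inhibitors_pass_sign.all()
        assert (qc.z_factor_activators > 0).all()
        assert (qc.z_factor_inhibitors > 0).all()

    def test_planted_control_swap_is_flagged(self, small_screen):
        _, wells, _ = small_screen
        swapped = wells.copy()
        act = swapped.role == "control_activator"
        inh = swapped.role == "control_inhibitor"
        swapped.loc[act, "role"] = "control_inhibitor"
        swapped.loc[inh, "role"] = "control_activator"
        from wntscreen import normalize_screen

        qc = qc_screen(normalize_screen(swapped))
        assert not qc.activators_pass_sign.any()
        assert not qc.inhibitors_pass_sign.any()

    def test_plate_without_controls_flagged_not_fatal(self):
        plate = make_plate([1.0, 2.0, 0.5, 1.0])
        qc = qc_screen(normalize_plate(plate))
        assert qc.missing_controls.iloc[0]


class TestCompareContextToxicity:
    def make(self, values):
        return pd.DataFrame({"chemical_id": list(values),
                             "toxicity": list(values.values())})

    def test_identical_tables_give_zero_differences(self):
        a = self.make({"c1": 1.0, "c2": 0.5, "c3": 2.0})
        out = compare_context_toxicity(a, a.copy())
        np.testing.assert_allclose(out.difference, 0.0, atol=1e-15)

    def test_context_specific_toxicant_tops_ranking(self):
        a = self.make({"c1": 1.0, "c2": 1.0, "c3": 1.0})
        b = self.make({"c1": 1.0, "c2": 1.0, "c3": 0.2})
        out = compare_context_toxicity(a, b)
        assert out.chemical_id.iloc[0] == "c3"

    def test_non_overlapping_ids_dropped(self):
        a = self.make({"c1": 1.0, "c2": 0.5})
        b = self.make({"c2": 1.0, "c9": 0.5})
        out = compare_context_toxicity(a, b)
        assert set(out.chemical_id) == {"c2"}

    def test_empty_overlap_is_error(self):
        with pytest.raises(ValueError, match="overlap"):
            compare_context_toxicity(self.make({"c1": 1.0}),
                                     self.make({"c2": 1.0}))


class TestDeltaDeltaCt:
    def test_planted_two_fold_change_recovered_exactly(self):
        ct = simulate_qpcr({"CALB1": 2.0})
        out = delta_delta_ct(ct).set_index("gene")
        assert out.loc["CALB1", "fold_change"] == pytest.approx(2.0, abs=1e-12)

    def test_equal_cts_give_unit_fold_change(self):
        ct = simulate_qpcr({"AXIN2": 1.0})
        out = delta_delta_ct(ct).set_index("gene")
        assert out.loc["AXIN2", "fold_change"] == 1.0

    def test_reference_gene_self_normalizes(self):
        ct = simulate_qpcr({"CALB1": 4.0})
        out = delta_delta_ct(ct).set_index("gene")
        assert out.loc["EIF4A2", "fold_change"] == pytest.approx(1.0, abs=1e-12)

    def test_missing_reference_gene_is_error(self):
        ct = simulate_qpcr({"CALB1": 2.0})
        with pytest.raises(ValueError, match="GAPDH"):
            delta_delta_ct(ct, reference_gene="GAPDH")

    def test_per_replicate_fold_changes_average_to_planted_value(self):
        ct = simulate_qpcr({"CALB1": 2.0}, noise_sd=0.0)
        out = delta_delta_ct(ct)
        reps = out.loc[out.gene == "CALB1", "replicate_fold_changes"].iloc[0]
        assert np.mean(reps) == pytest.approx(2.0, abs=1e-12)
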