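import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bruisepose.compare_stats import (
    PowerSpec,
    achieved_power,
    build_report,
    cohort_out_of_range_summary,
    format_p_value,
    format_proportion,
    matched_flexion_comparison,
    paired_t_test,
    range_exceedance,
    required_sample_size,
    table_difference,
)
from bruisepose.errors import InsufficientData, NoEffect
from bruisepose.knee_frames import pose_from_parameters
from bruisepose.squat_kinematics import RangeOfMotion


def rom_from(**limits):
    base = {
        "flexion": (10.0, 100.0),
        "ap": (15.0, 21.0),
        "pd": (24.0, 28.0),
        "ie": (4.0, 13.0),
        "vv": (-7.0, -5.5),
    }
    base.update(limits)
    return RangeOfMotion(base)


class TestRangeExceedance:
    def test_within_has_zero_distance(self):
        pose = pose_from_parameters(flexion=46, vv=-6, ie=7, ap=18, pd=26)
        recs = {r.parameter: r for r in range_exceedance(pose, rom_from())}
        assert all(r.classification == "within" for r in recs.values())
        assert all(r.signed_distance == 0.0 for r in recs.values())

    def test_beyond_upper_signed_distance(self):
        pose = pose_from_parameters(flexion=46, vv=-6, ie=7, ap=24.0, pd=26)
        rec = {r.parameter: r for r in range_exceedance(pose, rom_from())}["ap"]
        assert rec.classification == "beyond_upper"
        assert rec.signed_distance == pytest.approx(3.0)  # bb = max + 3

    def test_beyond_lower_signed_distance_is_negative(self):
        pose = pose_from_parameters(flexion=46, vv=-6, ie=7, ap=18, pd=-3.0)
        rec = {r.parameter: r for r in range_exceedance(pose, rom_from())}["pd"]
        assert rec.classification == "beyond_lower"
        assert rec.signed_distance == pytest.approx(-27.0)

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_invariant_to_common_shift(self, shift):
        pose = pose_from_parameters(flexion=46, vv=-6, ie=7, ap=25.0, pd=26)
        base = {r.parameter: r for r in range_exceedance(pose, rom_from())}["ap"]
        lo, hi = 15.0 + shift, 21.0 + shift
        pose2 = pose_from_parameters(flexion=46, vv=-6, ie=7, ap=25.0 + shift, pd=26)
        rec = {r.parameter: r for r in range_exceedance(pose2, rom_from(ap=(lo, hi)))}["ap"]
        assert rec.classification == base.classification
        assert rec.signed_distance == pytest.approx(base.signed_distance, abs=1e-9)


class TestCohortSummary:
    def test_all_within_cohort_counts_zero_exceedances(self):
        pose = pose_from_parameters(flexion=46, vv=-6, ie=7, ap=18, pd=26)
        subj = {f"s{i}": range_exceedance(pose, rom_from()) for i in range(4)}
        counts = cohort_out_of_range_summary(subj)
        for par in counts:
            assert counts[par]["beyond_upper"] == counts[par]["beyond_lower"] == 0
            assert counts[par]["within"] == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        subj = {}
        for i in range(12):
            pose = pose_from_parameters(
                flexion=rng.uniform(20, 90),
                vv=rng.uniform(-12, 3),
                ie=rng.uniform(-5, 18),
                ap=rng.uniform(10, 28),
                pd=rng.uniform(-5, 30),
            )
            subj[f"s{i:02d}"] = range_exceedance(pose, rom_from())
        counts = cohort_out_of_range_summary(subj)
        for par in ("ap", "pd", "ie", "vv", "flexion"):
            recount = {"within": 0, "beyond_upper": 0, "beyond_lower": 0}
            for recs in subj.values():  # independent recount
                rec = next(r for r in recs if r.parameter == par)
                if rec.bb_value > rec.squat_max:
                    recount["beyond_upper"] += 1
                elif rec.bb_value < rec.squat_min:
                    recount["beyond_lower"] += 1
                else:
                    recount["within"] += 1
            assert counts[par] == recount


class TestPairedT:
    def test_all_zero_differences(self):
        res = paired_t_test(np.zeros(7))
        assert res["t"] == 0.0
        assert res["p"] == 1.0
        assert res["ci95"] == (0.0, 0.0)

    def test_textbook_formula_oracle(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_t_test(d)
        # independently coded textbook formulas
        from scipy import stats as ss

        n = 5
        mean, sd = 3.0, np.sqrt(2.5)
        t = mean / (sd / np.sqrt(n))
        p = 2 * (1 - ss.t.cdf(abs(t), n - 1))
        half = ss.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        assert res["mean"] == pytest.approx(3.0, abs=1e-12)
        assert res["t"] == pytest.approx(t, abs=1e-9)
        assert res["p"] == pytest.approx(p, abs=1e-9)
        assert res["ci95"][0] == pytest.approx(3.0 - half, abs=1e-9)
        assert res["ci95"][1] == pytest.approx(3.0 + half, abs=1e-9)
        # independent library cross-check
        t_sp, p_sp = ss.ttest_1samp(d, 0.0)
        assert res["t"] == pytest.approx(t_sp, abs=1e-9)
        assert res["p"] == pytest.approx(p_sp, abs=1e-9)

    def test_df_contract_for_cohort_of_seven(self, rng):
        d = rng.normal(10.5, 3.0, size=7)
        res = paired_t_test(d)
        assert res["df"] == 6
        from scipy import stats as ss

        half = res["ci95"][1] - res["mean"]
        assert half == pytest.approx(ss.t.ppf(0.975, 6) * res["sd"] / np.sqrt(7), abs=1e-9)

    def test_degenerate_zero_sd_flagged(self):
        res = paired_t_test(np.full(5, 2.5))
        assert res["degenerate"]
        assert res["p"] < 1e-300

    def test_insufficient_data(self):
        with pytest.raises(InsufficientData):
            paired_t_test([1.0])


class TestPower:
    def test_apriori_anchor_seven_subjects(self):
        spec = PowerSpec(mean_difference=22.0, sd=14.0, alpha=0.05, power=0.9)
        assert required_sample_size(spec) == 7

    def test_monotone_in_power_and_effect(self):
        n_90 = required_sample_size(PowerSpec(22.0, 14.0, power=0.9))
        n_80 = required_sample_size(PowerSpec(22.0, 14.0, power=0.8))
        assert n_80 <= n_90
        n_small = required_sample_size(PowerSpec(10.0, 14.0, power=0.9))
        assert n_small >= n_90

    @pytest.mark.parametrize("d,power", [(0.5, 0.8), (1.0, 0.9), (0.8, 0.95)])
    def test_matches_statsmodels_solver(self, d, power):
        from statsmodels.stats.power import TTestPower

        n_mine = required_sample_size(PowerSpec(d, 1.0, power=power))
        n_sm = TTestPower().solve_power(effect_size=d, power=power, alpha=0.05)
        assert n_mine == int(np.ceil(n_sm))

    def test_achieved_power_matches_oracle(self):
        from statsmodels.stats.power import TTestPower

        mine = achieved_power(PowerSpec(1.0, 1.0, n=10))
        ref = TTestPower().power(effect_size=1.0, nobs=10, alpha=0.05)
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_zero_effect_power_equals_alpha(self):
        assert achieved_power(PowerSpec(0.0, 1.0, n=12)) == pytest.approx(0.05, abs=1e-9)

    def test_inverse_consistency(self):
        for n in (5, 8, 15):
            p = achieved_power(PowerSpec(9.0, 10.0, n=n))
            assert required_sample_size(PowerSpec(9.0, 10.0, power=p)) <= n

    def test_zero_effect_sample_size_undefined(self):
        with pytest.raises(NoEffect):
            required_sample_size(PowerSpec(0.0, 1.0, power=0.9))


class TestFormatting:
    def test_screening_proportion(self):
        assert format_proportion(7, 62) == "11%"
        assert format_proportion(35, 62) == "56%"

    def test_p_value_floor(self):
        assert format_p_value(3e-6) == "< 0.0001"
        assert format_p_value(0.0425) == "0.0425"

    def test_table_difference_is_magnitude(self):
        assert table_difference(46.9, 18.5) == pytest.approx(28.4)
        assert table_difference(-22.9, 26.5) == pytest.approx(49.4)


class TestReport:
    def _cohort(self, rng, n=7):
        bb, squat, exceed = {}, {}, {}
        for i in range(n):
            s = f"subject_{i + 1:02d}"
            bb[s] = pose_from_parameters(
                flexion=rng.normal(46, 4), vv=rng.normal(4, 2), ie=rng.normal(-6, 3),
                ap=rng.normal(47, 3), pd=rng.normal(-3, 1),
            )
            squat[s] = pose_from_parameters(
                flexion=bb[s].flexion, vv=rng.normal(-6, 2), ie=rng.normal(7, 2),
                ap=rng.normal(18, 2), pd=rng.normal(26, 2),
            )
            exceed[s] = range_exceedance(bb[s], rom_from())
        return bb, squat, exceed

    def test_bundle_schema_and_round_trip(self, rng, tmp_path):
        bb, squat, exceed = self._cohort(rng)
        comps = matched_flexion_comparison(bb, squat)
        report = build_report(exceed, comps, tmp_path, make_figure=False)
        import pandas as pd

        table = pd.read_csv(tmp_path / "paired_comparison.csv")
        assert list(table["parameter"]) == ["ap", "pd", "ie", "vv"]
        with open(tmp_path / "report.json") as fh:
            back = json.load(fh)
        assert back["paired_comparison"]["ap"]["mean_difference"] == pytest.approx(
            report["paired_comparison"]["ap"]["mean_difference"]
        )

    def test_differences_recomputed_independently(self, rng, tmp_path):
        bb, squat, exceed = self._cohort(rng)
        comps = matched_flexion_comparison(bb, squat)
        for name, key in (("ap", "ap_mm"), ("pd", "pd_mm"), ("ie", "ie_deg"), ("vv", "vv_deg")):
            c = comps[name]
            for i, s in enumerate(sorted(bb)):
                want = bb[s].parameters()[key] - squat[s].parameters()[key]
                assert c.differences[i] == pytest.approx(want, abs=1e-12)
            assert c.mean_difference == pytest.approx(np.mean(c.differences), abs=1e-12)
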