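import numpy as np
import pandas as pd
import pytest

from psychosense.design import DesignConfig
from psychosense.effects import (
    align_to_optimal,
    classify_groups,
    exclude_participants,
    rt_trim_and_mean,
    slope_differences,
    threshold_differences,
)

SALIENCES = (31.5, 35.5, 39.5, 47.5, 55.0)


def _fits_frame(pid, thr_bl, thr_ip, thr_op, slope=1.0):
    """Minimal fits table: one BL row plus IP/OP rows at each salience."""
    rows = [
        {"participant_id": pid, "condition": "BL", "salience_db": np.nan,
         "threshold75": thr_bl, "slope": slope}
    ]
    for cond, thrs in (("IP", thr_ip), ("OP", thr_op)):
        for s, t in zip(SALIENCES, thrs):
            rows.append(
                {"participant_id": pid, "condition": cond, "salience_db": s,
                 "threshold75": t, "slope": slope}
            )
    return pd.DataFrame(rows)


def _effects_frame(pid, blip, log_bl=-0.35):
    """Effects table with prescribed BL-IP values (OP rows zeroed)."""
    return pd.DataFrame(
        {
            "participant_id": pid,
            "salience_db": SALIENCES,
            "log10_bl_threshold": log_bl,
            "BL-IP": blip,
            "OP-BL": 0.0,
            "OP-IP": blip,
        }
    )


class TestThresholdDifferences:
    def test_closed_forms_and_identity(self):
        fits = _fits_frame("A", 0.5, [0.25] * 5, [0.5] * 5)
        eff = threshold_differences(fits)
        assert np.allclose(eff["BL-IP"], np.log10(2))
        assert np.allclose(eff["OP-BL"], 0.0)
        # three-way identity holds exactly, not just approximately
        assert (eff["BL-IP"] + eff["OP-BL"] == eff["OP-IP"]).all()

    def test_equal_thresholds_give_zero(self):
        fits = _fits_frame("A", 0.5, [0.5] * 5, [0.5] * 5)
        eff = threshold_differences(fits)
        assert (eff[["BL-IP", "OP-BL", "OP-IP"]] == 0).all().all()

    def test_missing_cell_named_in_error(self):
        fits = _fits_frame("A", 0.5, [0.25] * 5, [0.5] * 5)
        fits = fits[~((fits.condition == "IP") & (fits.salience_db == 39.5))]
        with pytest.raises(ValueError, match="IP at 39.5"):
            threshold_differences(fits)

    def test_identity_exact_on_fitted_cohort(self, small_effects):
        assert (
            small_effects["BL-IP"] + small_effects["OP-BL"]
            == small_effects["OP-IP"]
        ).all()


class TestSlopeDifferences:
    def test_orientation_matches_threshold_convention(self):
        fits = _fits_frame("A", 0.5, [0.25] * 5, [0.5] * 5)
        fits.loc[fits.condition == "BL", "slope"] = 1.2
        fits.loc[fits.condition == "IP", "slope"] = 1.5
        sl = slope_differences(fits)
        assert np.allclose(sl["BL-IP"], -0.3)
        assert (sl["BL-IP"] + sl["OP-BL"] == sl["OP-IP"]).all()


class TestRtTrim:
    def test_no_outlier_untouched(self):
        assert rt_trim_and_mean([500, 510, 520]) == pytest.approx(510.0)

    def test_slow_outlier_removed(self):
        rts = [400, 410, 420, 430, 440, 450, 460, 470, 480, 2000]
        # oracle: recompute the one-sided cut by hand on the raw values
        arr = np.array(rts, float)
        cut = arr.mean() + 2 * arr.std(ddof=1)
        assert (arr > cut).sum() == 1 and arr[arr > cut][0] == 2000
        assert rt_trim_and_mean(rts) == pytest.approx(440.0)

    def test_fast_outlier_kept(self):
        # the rule is one-sided: only *slower* trials are excluded
        assert rt_trim_and_mean([100, 500, 510, 520]) == pytest.approx(407.5)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            rt_trim_and_mean([500])


class TestExclusion:
    def test_clean_cohort_keeps_everyone(self):
        eff = pd.concat(
            [_effects_frame(f"P{i}", [0.01 * i] * 5, log_bl=-0.35 + 0.01 * i)
             for i in range(6)],
            ignore_index=True,
        )
        kept, reports = exclude_participants(eff)
        assert not reports
        assert kept["participant_id"].nunique() == 6

    def test_baseline_outlier_removed_first(self, rng):
        base = rng.normal(-0.352, 0.1, 19)
        effs = [_effects_frame(f"P{i:02d}", [0.0] * 5, log_bl=b)
                for i, b in enumerate(base)]
        mean, sd = base.mean(), base.std(ddof=1)
        effs.append(_effects_frame("OUT", [0.0] * 5, log_bl=mean + 3 * sd * 2))
        kept, reports = exclude_participants(pd.concat(effs, ignore_index=True))
        assert [r.participant_id for r in reports] == ["OUT"]
        assert reports[0].criterion == "baseline"
        assert abs(reports[0].z) > 2

    def test_midsalience_blip_outlier_removed_second(self, rng):
        effs = [
            _effects_frame(f"P{i:02d}", rng.normal(0, 0.05, 5))
            for i in range(19)
        ]
        effs.append(_effects_frame("OUT", [0.0, 0.0, 5.0, 0.0, 0.0]))
        kept, reports = exclude_participants(pd.concat(effs, ignore_index=True))
        ids = [r.participant_id for r in reports]
        assert "OUT" in ids
        assert reports[ids.index("OUT")].criterion == "mid_salience_blip"

    def test_second_pass_removes_no_more_than_first(self, rng):
        effs = [
            _effects_frame(f"P{i:02d}", rng.normal(0, 0.1, 5),
                           log_bl=rng.normal(-0.35, 0.2))
            for i in range(20)
        ]
        kept, first = exclude_participants(pd.concat(effs, ignore_index=True))
        kept2, second = exclude_participants(kept)
        assert len(second) <= len(first)

    def test_tiny_cohort_rejected(self):
        eff = pd.concat(
            [_effects_frame("A", [0] * 5), _effects_frame("B", [0] * 5)],
            ignore_index=True,
        )
        with pytest.raises(ValueError):
            exclude_participants(eff)


class TestClassifyGroups:
    def test_sign_rule(self):
        eff = pd.concat(
            [
                _effects_frame("ENH", [0, 0, 0.10, 0, 0]),
                _effects_frame("SUP", [0, 0, -0.10, 0, 0]),
            ],
            ignore_index=True,
        )
        groups = classify_groups(eff)
        assert groups["ENH"] == "enhancement"
        assert groups["SUP"] == "suppression"

    def test_exact_zero_is_enhancement_with_warning(self):
        eff = _effects_frame("TIE", [0.1, 0.0, 0.0, 0.0, 0.0])
        with pytest.warns(RuntimeWarning, match="zero"):
            groups = classify_groups(eff)
        assert groups["TIE"] == "enhancement"

    def test_unknown_grouping_salience(self):
        with pytest.raises(ValueError):
            classify_groups(_effects_frame("A", [0.1] * 5), grouping_salience_db=42.0)


class TestAlignToOptimal:
    def test_central_optimum_averages_flanks(self):
        aligned = align_to_optimal(_effects_frame("A", [0.0, 0.1, 0.3, 0.1, 0.0]))
        row = aligned.iloc[0]
        assert row["optimal_salience_index"] == 3
        assert row["BL-IP_optimal"] == pytest.approx(0.3)
        assert row["BL-IP_pm1"] == pytest.approx(0.1)
        assert row["BL-IP_pm2"] == pytest.approx(0.0)

    def test_edge_optimum_uses_single_existing_bins(self):
        aligned = align_to_optimal(_effects_frame("A", [0.3, 0.1, 0.0, 0.0, 0.0]))
        row = aligned.iloc[0]
        assert row["optimal_salience_index"] == 1
        assert row["BL-IP_pm1"] == pytest.approx(0.1)  # level 2 only
        assert row["BL-IP_pm2"] == pytest.approx(0.0)  # level 3 only

    def test_constant_profile_tie_breaks_low_with_warning(self):
        with pytest.warns(RuntimeWarning, match="tied"):
            aligned = align_to_optimal(_effects_frame("A", [0.2] * 5))
        row = aligned.iloc[0]
        assert row["optimal_salience_index"] == 1
        assert row["BL-IP_optimal"] == row["BL-IP_pm1"] == row["BL-IP_pm2"]

    def test_same_index_anchors_all_comparisons(self):
        eff = _effects_frame("A", [0.0, 0.1, 0.3, 0.1, 0.0])
        eff["OP-BL"] = [1.0, 2.0, 3.0, 4.0, 5.0]
        eff["OP-IP"] = eff["BL-IP"] + eff["OP-BL"]
        row = align_to_optimal(eff).iloc[0]
        # optimal index comes from BL-IP (bin 3), not from OP-BL's own max
        assert row["OP-BL_optimal"] == pytest.approx(3.0)
        assert row["OP-BL_pm1"] == pytest.approx(3.0)
        assert row["OP-BL_pm2"] == pytest.approx(3.0)

    def test_optimal_bin_dominates_by_construction(self, rng):
        for _ in range(20):
            aligned = align_to_optimal(_effects_frame("A", rng.normal(0, 1, 5)))
            row = aligned.iloc[0]
            assert row["BL-IP_optimal"] >= row["BL-IP_pm1"]
            assert row["BL-IP_optimal"] >= row["BL-IP_pm2"]
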