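"""Developmental timing: D50 estimation, exclusions, group comparisons."""

import itertools
import math

import numpy as np
import pytest

from gnotodiet.dev import (
    CENSOR_DAY,
    Condition,
    D50Result,
    PupariationRecord,
    apply_exclusions,
    classify_requirement,
    compare_to_control,
    compute_d50,
    correlate_load_vs_d50,
    interpolate_d50,
    summarize_condition,
)
from gnotodiet.simulate import SimulationConfig, gen_pupariation


def record(daily, n_eggs=40, medium="HD", association="GF", replicate="1"):
    return PupariationRecord(
        condition=Condition(medium=medium, association=association),
        replicate=replicate,
        n_eggs=n_eggs,
        daily_pupae=daily,
    )


class TestComputeD50:
    def test_degenerate_step_all_on_one_day(self):
        assert compute_d50(record({9: 40})) == pytest.approx(9.0)

    def test_no_pupae_is_censored_not_an_exception(self):
        assert math.isnan(compute_d50(record({})))

    def test_linear_interpolation_oracle(self):
        """Cumulative 10,20,30,40 over days 7-10: the 50% crossing sits at
        day 8 exactly, and the forced fallback agrees with the closed form."""
        rec = record({7: 10, 8: 10, 9: 10, 10: 10})
        forced = compute_d50(rec, force_interpolation=True)
        assert forced == pytest.approx(8.0)
        fitted = compute_d50(rec)
        assert 7.0 <= fitted <= 9.0

    def test_interpolation_closed_form_off_grid(self):
        days = np.array([5.0, 9.0])
        frac = np.array([0.2, 0.8])
        # crossing: 5 + (0.5-0.2)/(0.8-0.2) * 4 = 7
        assert interpolate_d50(days, frac) == pytest.approx(7.0)

    def test_shift_equivariance(self):
        base = {6: 4, 7: 10, 8: 14, 9: 8, 10: 4}
        d0 = compute_d50(record(base))
        for k in (1, 3, 7):
            shifted = {day + k: n for day, n in base.items()}
            assert compute_d50(record(shifted)) == pytest.approx(d0 + k, abs=1e-6)

    def test_d50_within_observed_event_window(self):
        rec = record({6: 1, 12: 39})
        d = compute_d50(rec)
        assert 6.0 <= d <= 12.0

    def test_invariant_to_splitting_counts_across_replicates(self):
        """Fraction-based D50 does not change when a cohort is split into
        identical half-size replicates."""
        whole = record({7: 10, 8: 20, 9: 10})
        half = record({7: 5, 8: 10, 9: 5}, n_eggs=20)
        assert compute_d50(whole) == pytest.approx(compute_d50(half), abs=1e-9)

    def test_recovery_of_known_d50(self):
        """100 simulated 5-replicate cohorts (logistic, D50=8.4 d, scale 1 d)
        recover the planted D50 within 0.2 d on average."""
        cfg = SimulationConfig(seed=11, true_d50=8.4, logistic_scale=1.0, n_eggs=40,
                               n_replicates=5, survival=1.0)
        rng = cfg.rng()
        means = []
        for _ in range(100):
            res = summarize_condition(gen_pupariation(cfg, rng=rng))[0]
            means.append(res.mean)
        assert np.mean(means) == pytest.approx(8.4, abs=0.2)


class TestExclusions:
    def test_low_survival_replicate_excluded(self):
        low = record({12: 9})  # 9/40 < 25%
        ok = record({9: 40}, replicate="2")
        kept, verdicts = apply_exclusions([low, ok])
        assert kept == [ok]
        assert verdicts[low.condition] is True  # mean survival (9+40)/80 >= 0.25

    def test_condition_fails_when_mean_survival_low(self):
        survivals = [4, 6, 8, 2, 8]  # fractions 0.10,0.15,0.20,0.05,0.20 -> mean 0.14
        records = [record({15: s}, replicate=str(i)) for i, s in enumerate(survivals)]
        kept, verdicts = apply_exclusions(records)
        assert kept == []
        assert verdicts[records[0].condition] is False

    def test_exclusion_is_idempotent(self):
        records = [record({12: 9}), record({9: 40}, replicate="2")]
        kept1, v1 = apply_exclusions(records)
        kept2, v2 = apply_exclusions(kept1)
        assert kept1 == kept2

    def test_replicate_relabeling_does_not_change_summary(self):
        daily = {7: 10, 8: 20, 9: 10}
        a = [record(daily, replicate=str(i)) for i in (1, 2, 3)]
        b = [record(daily, replicate=str(i)) for i in (9, 7, 8)]
        ra = summarize_condition(a)[0]
        rb = summarize_condition(b)[0]
        assert ra.mean == pytest.approx(rb.mean)

    def test_mismatched_n_eggs_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions([record({9: 20}), record({9: 20}, n_eggs=30, replicate="2")])


class TestClassifyRequirement:
    def make_result(self, mean, developed=True):
        cond = Condition(medium="HDΔX", association="GF")
        return D50Result(condition=cond, d50s=[mean] * 5 if developed else [],
                         n_replicates_used=5 if developed else 0,
                         developed=developed, survival=0.8 if developed else 0.05)

    def test_failure_to_develop_is_essential(self):
        complete = self.make_result(10.1)
        assert classify_requirement(self.make_result(0, developed=False), complete, p_value=1.0) == "essential"

    def test_significant_delay_is_limiting(self):
        complete = self.make_result(10.1)
        assert classify_requirement(self.make_result(14.0), complete, p_value=0.001) == "limiting"

    def test_same_rate_is_dispensable(self):
        complete = self.make_result(10.1)
        assert classify_requirement(self.make_result(10.3), complete, p_value=0.7) == "dispensable"

    def test_faster_development_is_not_limiting(self):
        complete = self.make_result(10.1)
        assert classify_requirement(self.make_result(8.0), complete, p_value=0.001) == "dispensable"

    def test_undeveloped_reference_is_configuration_error(self):
        with pytest.raises(ValueError):
            classify_requirement(self.make_result(9.0), self.make_result(0, developed=False), 0.5)


class TestCompareToControl:
    def test_identical_groups_no_rejections(self):
        groups = {"control": [8.0, 8.5, 9.0, 8.2], "a": [8.0, 8.5, 9.0, 8.2], "b": [8.0, 8.5, 9.0, 8.2]}
        df = compare_to_control(groups, "control")
        assert df.attrs["kruskal_h"] == pytest.approx(0.0, abs=1e-9)
        assert (df["p_raw"] > 0.05).all()

    def test_fully_separated_groups_reach_minimal_p(self):
        """With complete rank separation the Dunn z is the most extreme over
        all permutations of group labels, so the reported p is the smallest
        achievable for these group sizes (exact enumeration oracle)."""
        a = [1.0, 2.0, 3.0, 4.0]
        c = [10.0, 11.0, 12.0, 13.0]
        observed = compare_to_control({"control": c, "a": a}, "control")["p_raw"].iloc[0]
        pooled = a + c
        ps = []
        for combo in itertools.combinations(range(8), 4):
            ga = [pooled[i] for i in combo]
            gc = [pooled[i] for i in range(8) if i not in combo]
            ps.append(compare_to_control({"control": gc, "a": ga}, "control")["p_raw"].iloc[0])
        assert observed == pytest.approx(min(ps))

    def test_small_group_flagged_not_testable(self):
        df = compare_to_control({"control": [1.0, 2.0, 3.0], "tiny": [5.0]}, "control")
        row = df[df.group == "tiny"].iloc[0]
        assert not row.testable and math.isnan(row.p_raw)

    def test_adjustment_is_monotone(self):
        rng = np.random.default_rng(1)
        groups = {"control": list(rng.normal(size=5)), "a": list(rng.normal(2.0, size=5)),
                  "b": list(rng.normal(size=5))}
        raw = compare_to_control(groups, "control", adjust="none")
        adj = compare_to_control(groups, "control", adjust="holm")
        assert (adj["p_adj"].to_numpy() >= raw["p_adj"].to_numpy() - 1e-12).all()

    def test_deterministic(self):
        groups = {"control": [8.1, 8.3, 9.0, 8.7], "a": [9.5, 10.1, 9.9, 10.4]}
        d1 = compare_to_control(groups, "control")
        d2 = compare_to_control(groups, "control")
        assert d1.equals(d2)


class TestCorrelation:
    def test_exact_line_gives_r_one(self):
        pairs = [(1.0, 2.0), (2.0, 4.0), (3.0, 6.0)]
        r, p = correlate_load_vs_d50(pairs)
        assert r == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # pairs (1,1),(2,2),(3,2): r = cov/sd product = 0.5/(1*0.577...) = sqrt(3)/2
        r, _ = correlate_load_vs_d50([(1.0, 1.0), (2.0, 2.0), (3.0, 2.0)])
        assert r == pytest.approx(math.sqrt(3) / 2)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate_load_vs_d50([(1.0, 5.0), (2.0, 5.0), (3.0, 5.0)])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_load_vs_d50([(1.0, 2.0), (2.0, 3.0)])

    def test_null_rejection_rate_near_alpha(self):
        """Independent pairs (n=12): |r| exceeds the 5% critical value in
        about 5% of draws."""
        rng = np.random.default_rng(42)
        hits = 0
        n_draws = 1000
        for _ in range(n_draws):
            pairs = list(zip(rng.normal(size=12), rng.normal(size=12)))
            _, p = correlate_load_vs_d50(pairs)
            hits += int(p < 0.05)
        se = math.sqrt(0.05 * 0.95 / n_draws)
        assert abs(hits / n_draws - 0.05) < 1.96 * se + 1e-9
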