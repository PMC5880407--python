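"""Three-rule trajectory classification, inflection detection, curation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spindlequant.classify import (
    classify,
    classify_population,
    detect_inflection,
    rule_flags,
)
from spindlequant.params import ClassifierConfig, PhenotypeParams
from spindlequant.simulate import simulate_population
from tests.conftest import make_traj, plateau_ramp


def brute_force_flags(times, lengths):
    """Independent per-sample scan of the three rules."""
    r10 = r15 = reach6 = False
    for t, y in zip(times, lengths):
        if 0 < t <= 10 and y > 2.0:
            r10 = True
        if 0 < t <= 15 and y > 2.5:
            r15 = True
        if 0 < t <= 60 and y >= 6.0:
            reach6 = True
    return r10, r15, reach6


class TestRuleFlags:
    def test_constant_short_trace_below_all_thresholds(self):
        f = rule_flags(make_traj(np.full(61, 1.5)))
        assert (f.r10, f.r15, f.reach6) == (False, False, False)

    def test_linear_ramp_crossing_times(self):
        # 1 + 0.5 t: crosses 2 μm at t = 2 (so > 2 from t = 3), 6 μm at t = 10
        f = rule_flags(make_traj(1 + 0.5 * np.arange(61.0)))
        assert (f.r10, f.r15, f.reach6) == (True, True, True)

    def test_late_shallow_crossing_misses_both_rules(self):
        # reaches 2.2 μm only at t = 12 then plateaus: below 2 in (0,10],
        # below 2.5 in (0,15]
        y = np.minimum(1.0 + 0.1 * np.arange(61.0), 2.2)
        f = rule_flags(make_traj(y))
        assert (f.r10, f.r15, f.reach6) == (False, False, False)

    def test_strictness_of_thresholds(self):
        # exactly 2.0 at every early point does not trip the strict rule;
        # exactly 6.0 does trip the inclusive reach6
        y = np.concatenate([np.full(20, 2.0), np.full(41, 6.0)])
        f = rule_flags(make_traj(y))
        assert not f.r10
        assert f.reach6

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="15 min"):
            rule_flags(make_traj(np.full(11, 1.0)))

    def test_subhour_trace_warns_on_reach6(self):
        with pytest.warns(UserWarning, match="reach6"):
            rule_flags(make_traj(np.full(31, 1.0)))

    @given(
        seed=st.integers(0, 2**32 - 1),
        n_segments=st.integers(1, 5),
    )
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_brute_force_scan(self, seed, n_segments):
        """rule_flags equals a brute-force per-sample scan on random
        piecewise-linear trajectories."""
        rng = np.random.default_rng(seed)
        knots_t = np.sort(np.concatenate([[0, 60], rng.uniform(0, 60, n_segments - 1)]))
        knots_y = rng.uniform(0, 9, n_segments + 1)
        t = np.arange(61.0)
        y = np.interp(t, knots_t, knots_y)
        f = rule_flags(make_traj(y))
        assert (f.r10, f.r15, f.reach6) == brute_force_flags(t, y)


class TestInflection:
    def test_plateau_then_ramp_found(self):
        traj = make_traj(plateau_ramp(1.5, 20, 1.0))
        report = detect_inflection(traj)
        assert report.clear
        assert report.breakpoint_time == pytest.approx(20, abs=1.5)
        assert report.post_slope > report.pre_slope

    def test_exhaustive_breakpoint_oracle(self):
        """The chosen breakpoint matches an exhaustive search over all
        candidate hinges done independently here."""
        # gentle ramp that never reaches the terminal plateau
        traj = make_traj(plateau_ramp(1.3, 25, 0.15, plateau_cap=99.0))
        report = detect_inflection(traj)
        t, y = traj.times, traj.lengths
        best_tb, best_sse = None, np.inf
        for tb in t[2:-3]:
            X = np.column_stack([np.ones_like(t), t, np.maximum(t - tb, 0)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(((y - X @ beta) ** 2).sum())
            if sse < best_sse:
                best_sse, best_tb = sse, tb
        assert report.breakpoint_time == best_tb

    def test_single_ramp_not_clear(self):
        report = detect_inflection(make_traj(1 + 0.3 * np.arange(61.0)))
        assert not report.clear

    def test_constant_trace_not_clear(self):
        report = detect_inflection(make_traj(np.full(61, 1.5)))
        assert not report.clear

    def test_pure_noise_rarely_clear(self):
        rng = np.random.default_rng(7)
        false_alarms = sum(
            detect_inflection(
                make_traj(np.clip(1.5 + rng.normal(0, 0.1, 61), 0.05, None))
            ).clear
            for _ in range(200)
        )
        assert false_alarms <= 10  # ≥ 95% of draws not 'clear'

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="6 samples"):
            detect_inflection(make_traj([1, 1, 1, 1, 1]))


class TestClassify:
    def test_never_reaching_six_um_is_failed(self):
        res = classify(make_traj(np.full(61, 1.5)))
        assert res.label == "failed"
        assert not res.flags.reach6

    def test_wild_type_like_trace_is_normal(self):
        res = classify(make_traj(plateau_ramp(1.3, 22, 1.0)))
        assert res.label == "normal"
        assert res.conflict == "none"

    def test_monotone_ramp_is_immediate(self):
        # 1 + 0.25 t crosses 2 at t = 4, 2.5 at t = 6, 6 at t = 20
        res = classify(make_traj(np.minimum(1 + 0.25 * np.arange(61.0), 8.0)))
        assert res.label == "immediate"
        assert res.conflict == "none"

    def test_transient_spike_with_clear_inflection_curated_normal(self):
        """r10 fires on a single-frame 2.1 μm excursion but a clear anaphase
        inflection at t = 25 identifies the cell as normal."""
        y = plateau_ramp(1.6, 25, 1.0)
        y[8] = 2.1
        res = classify(make_traj(y))
        assert res.conflict == "immediate/normal"
        assert res.label == "normal"
        assert res.curation_rule_applied == "curated_single_point_crossing_with_inflection"

    def test_no_inflection_with_shortening_curated_immediate(self):
        """r10 fires, no clear inflection, spindle shortens between 10 and
        15 min → immediate."""
        t = np.arange(61.0)
        y = np.minimum(1.0 + 0.22 * t, 2.3)  # rises past 2 μm before t = 10
        y[12:] = np.minimum(2.05 + 0.092 * (t[12:] - 12), 6.5)  # drop then slow rise
        res = classify(make_traj(y))
        assert res.flags.r10 and not res.flags.r15
        assert res.label == "immediate"
        assert res.curation_rule_applied == "curated_no_inflection_shortening_10_15"

    def test_anaphase_onset_between_10_and_15_curated_normal(self):
        """r15 fires because anaphase began at t = 12; the clear inflection
        in [10, 15] identifies the cell as normal."""
        res = classify(make_traj(plateau_ramp(1.8, 12, 1.0)))
        assert res.conflict == "normal/immediate"
        assert res.label == "normal"
        assert res.curation_rule_applied == "curated_anaphase_onset_10_15"

    def test_slow_continuous_elongation_curated_immediate(self):
        """r15 fires without r10 on a slowly accelerating trace with no clear
        inflection → immediate."""
        t = np.arange(61.0)
        y = np.where(t <= 10, 1.0 + 0.095 * t, 1.95 + 0.12 * (t - 10))
        res = classify(make_traj(np.minimum(y, 8.0)))
        assert res.conflict == "normal/immediate"
        assert res.label == "immediate"
        assert res.curation_rule_applied in (
            "curated_slow_continuous_elongation",
            "unresolved_default_r15",
        )

    def test_deterministic(self):
        y = plateau_ramp(1.5, 18, 1.0)
        a, b = classify(make_traj(y)), classify(make_traj(y))
        assert a.label == b.label
        assert a.curation_rule_applied == b.curation_rule_applied

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            classify(make_traj(np.full(12, 1.0)))

    @given(seed=st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_uniform_shift_never_flips_immediate_to_normal(self, seed):
        """Adding +1 μm everywhere can only make a trace more 'immediate'."""
        rng = np.random.default_rng(seed)
        knots_t = np.sort(np.concatenate([[0, 60], rng.uniform(0, 60, 3)]))
        knots_y = rng.uniform(0, 8, 5)
        y = np.interp(np.arange(61.0), knots_t, knots_y)
        base = classify(make_traj(y)).label
        shifted = classify(make_traj(y + 1.0)).label
        assert not (base == "immediate" and shifted == "normal")


class TestPopulation:
    def test_pure_immediate_population_recovered(self):
        params = PhenotypeParams(length_noise_sd=0.1)
        cells = simulate_population(params, 100, seed=3, cls="immediate")
        table, fractions = classify_population(cells)
        # binomial 95% CI of 1.0 at n = 100 collapses to [0.97, 1]
        assert fractions["fractions"]["immediate"] >= 0.97

    def test_unambiguous_population_has_no_conflicts(self):
        params = PhenotypeParams(length_noise_sd=0.0, metaphase_duration_min=15.5)
        cells = simulate_population(params, 100, seed=5)
        _, fractions = classify_population(cells)
        assert fractions["conflict_fraction"] == 0.0

    def test_mixed_population_fraction_recovered(self):
        params = PhenotypeParams(
            class_probs={"normal": 0.5, "immediate": 0.5, "failed": 0.0},
            metaphase_duration_min=15.5,
        )
        cells = simulate_population(params, 500, seed=11)
        table, fractions = classify_population(cells)
        true_frac = np.mean([c.true_class == "immediate" for c in cells])
        # classified fraction within the binomial 95% CI of the drawn fraction
        assert abs(fractions["fractions"]["immediate"] - true_frac) <= 1.96 * np.sqrt(
            0.25 / 500
        )

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            classify_population([])
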