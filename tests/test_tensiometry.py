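import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdlens.synth import gen_tension
from crowdlens.tensiometry import (
    TensionTrace,
    anova_posthoc,
    classify_interaction,
    condition_stats,
    final_pressure,
    initial_rate,
    to_surface_pressure,
)


def _trace(gammas, dt=1.0, condition="c", drop="d1"):
    g = np.asarray(gammas, dtype=float)
    return TensionTrace(condition, drop, np.arange(len(g)) * dt, g)


class TestSurfacePressure:
    def test_constant_gamma_zero_pressure(self):
        tr = _trace(np.full(10, 72.0))
        assert to_surface_pressure(tr) == pytest.approx(np.zeros(10))

    def test_subtraction(self):
        tr = _trace([72.0, 70.0, 69.0])
        assert to_surface_pressure(tr).tolist() == [0.0, 2.0, 3.0]

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        tr = _trace(72.0 - np.cumsum(rng.random(50)))
        pi = to_surface_pressure(tr)
        assert pi + tr.gamma == pytest.approx(np.full(50, tr.gamma[0]))

    def test_too_short(self):
        with pytest.raises(ValueError):
            to_surface_pressure(_trace([72.0]))


class TestInitialRate:
    def test_linear_pressure(self):
        t = np.arange(0.0, 200.0, 9.0)
        pi = 0.05 * t
        slopes = initial_rate(t, pi)
        assert slopes == pytest.approx(np.full(len(slopes), 3.0))

    def test_zero_pressure(self):
        t = np.arange(0.0, 200.0, 9.0)
        assert initial_rate(t, np.zeros_like(t)) == pytest.approx(
            np.zeros((t <= 100).sum())
        )

    def test_quadratic_matches_dense_grid_oracle(self):
        a, b = 0.03, 1e-4
        t = np.arange(0.0, 2400.0, 1.0 / 0.11)  # 0.11 fps
        pi = a * t + b * t**2
        mean_slope = initial_rate(t, pi).mean()
        td = np.arange(0.0, 100.0, 1e-3)
        oracle = np.gradient(a * td + b * td**2, td).mean() * 60.0
        # one sampling-interval correction term of slack
        assert mean_slope == pytest.approx(oracle, abs=b * (1 / 0.11) * 60)

    def test_too_few_early_samples(self):
        with pytest.raises(ValueError):
            initial_rate(np.array([0.0, 60.0, 150.0]), np.zeros(3))


class TestFinalPressure:
    def test_plateau(self):
        t = np.arange(0.0, 2400.0, 10.0)
        pi = np.where(t >= t[-1] - 240.0, 12.5, 3.0)
        assert final_pressure(t, pi).mean() == pytest.approx(12.5)

    def test_linear_trace_arithmetic(self):
        # mean of t/60 over [2160, 2400] = ((2160+2400)/2)/60 = 38.0
        t = np.arange(0.0, 2400.0 + 1, 1.0)
        vals = final_pressure(t, t / 60.0)
        assert vals.mean() == pytest.approx(38.0, abs=0.01)

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 200.0, 1.0)
        with pytest.raises(ValueError):
            final_pressure(t, np.zeros_like(t))


class TestAnovaPosthoc:
    def test_identical_groups(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = anova_posthoc(g)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_corrected == pytest.approx(np.ones(3))

    def test_sums_of_squares_oracle(self):
        groups = {"a": [1.0, 2, 3], "b": [2.0, 3, 4], "c": [5.0, 6, 7]}
        res = anova_posthoc(groups)
        # textbook one-way ANOVA by explicit sums of squares
        allv = np.concatenate([np.asarray(v, float) for v in groups.values()])
        grand = allv.mean()
        ss_between = sum(
            len(v) * (np.mean(v) - grand) ** 2 for v in groups.values()
        )
        ss_within = sum(
            ((np.asarray(v, float) - np.mean(v)) ** 2).sum() for v in groups.values()
        )
        df_b = len(groups) - 1
        df_w = len(allv) - len(groups)
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        from scipy.stats import f as fdist

        p_oracle = fdist.sf(f_oracle, df_b, df_w)
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-12)

    def test_two_groups_t_squared_equals_f(self):
        g = {"a": [1.0, 2, 3, 5], "b": [2.0, 4, 5, 7]}
        res = anova_posthoc(g)
        from scipy.stats import ttest_ind

        t, _ = ttest_ind(g["a"], g["b"], equal_var=True)
        assert t**2 == pytest.approx(res.f_statistic, rel=1e-12)

    def test_all_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            anova_posthoc({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.lists(st.floats(-10, 10), min_size=3, max_size=8),
            min_size=2,
            max_size=5,
        ),
        jitter=st.integers(0, 10**6),
    )
    def test_oracle_property_on_random_instances(self, data, jitter):
        rng = np.random.default_rng(jitter)
        groups = {
            f"g{i}": np.asarray(v, float) + rng.normal(0, 1e-3, len(v))
            for i, v in enumerate(data)
        }
        res = anova_posthoc(groups)
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_b = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_w = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        df_b = len(groups) - 1
        df_w = len(allv) - len(groups)
        if ss_w <= 0:
            return
        f_oracle = (ss_b / df_b) / (ss_w / df_w)
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-9, abs=1e-9)


def _stats_for(condition, pi_final, rate_per_min, seed, n_drops=3, noise=0.05):
    rc = pi_final * 60.0 / rate_per_min
    traces = gen_tension(72.0, pi_final, rc, n_drops=n_drops, noise_sd=noise,
                         seed=seed, condition=condition)
    return condition_stats(traces)


class TestClassification:
    def test_final_higher_rate_ns_is_repulsive(self):
        mix = _stats_for("a:bl", 16.0, 3.5, 1)
        ctrl = _stats_for("a", 12.0, 3.5, 2)
        call = classify_interaction(mix, ctrl, rate_p=0.9, final_p=0.001)
        assert call.label == "repulsive"

    def test_both_lower_is_attractive(self):
        mix = _stats_for("bh:g", 8.0, 1.3, 3)
        ctrl = _stats_for("g", 10.0, 3.5, 4)
        call = classify_interaction(mix, ctrl, rate_p=0.001, final_p=0.001)
        assert call.label == "attractive"

    def test_no_significant_differences(self):
        mix = _stats_for("m", 12.0, 3.5, 5)
        ctrl = _stats_for("c", 12.0, 3.5, 6)
        call = classify_interaction(mix, ctrl, rate_p=0.5, final_p=0.5)
        assert call.label == "none"


class TestInteractionNetwork:
    def test_reproduces_expected_network(self):
        """Engineered condition set yields one attractive edge and the four
        repulsive edges, nothing else."""
        # (final pressure, initial rate mN/m/min) per condition
        params = {
            "alpha": (12.0, 3.5),
            "beta_h": (8.0, 1.3),
            "beta_l": (13.0, 3.5),
            "gamma": (10.0, 3.5),
            "alpha:gamma": (15.0, 4.0),
            "beta_l:gamma": (16.0, 4.0),
            "alpha:beta_l": (16.0, 4.0),
            "beta_h:beta_l": (16.0, 4.5),
            "beta_h:gamma": (8.0, 1.3),  # mirrors beta_h, sits below gamma
        }
        stats = {
            name: _stats_for(name, pf, rate, seed=10 + k)
            for k, (name, (pf, rate)) in enumerate(params.items())
        }
        rate_an = anova_posthoc({c: s.rate_points for c, s in stats.items()})
        fin_an = anova_posthoc({c: s.final_points for c, s in stats.items()})
        assert rate_an.p_value < 0.05 and fin_an.p_value < 0.05

        calls = {}
        for mix in params:
            if ":" not in mix:
                continue
            for ctrl in mix.split(":"):
                call = classify_interaction(
                    stats[mix], stats[ctrl],
                    rate_an.p_for(mix, ctrl), fin_an.p_for(mix, ctrl),
                )
                calls[(mix, ctrl)] = call.label

        attractive = {k for k, v in calls.items() if v == "attractive"}
        assert attractive == {("beta_h:gamma", "gamma")}
        for mix in ("alpha:gamma", "beta_l:gamma", "alpha:beta_l", "beta_h:beta_l"):
            for ctrl in mix.split(":"):
                assert calls[(mix, ctrl)] == "repulsive", (mix, ctrl)
        assert calls[("beta_h:gamma", "beta_h")] == "none"
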