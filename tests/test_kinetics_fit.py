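"""Bell-Evans fits, dwell-time mixtures, log-binned histograms, maturation."""

import math

import numpy as np
import pandas as pd
import pytest

from mechanokin import presets
from mechanokin.core_model import (
    BellEvansParams,
    ForceSense,
    TalinFoldingParams,
    bell_evans_rate,
    binding_rate,
)
from mechanokin.kinetics_fit import (
    binding_probability,
    fit_bell_evans,
    fit_biphasic_binding,
    fit_dwell_mixture,
    fit_maturation,
    fit_maturation_from_dwells,
    sqrt_histogram,
)
from mechanokin.simulator import (
    KineticScheme,
    Transition,
    simulate_maturation_experiment,
)

ACC = ForceSense.force_accelerated
SUP = ForceSense.force_suppressed


class TestFitBellEvans:
    def test_noiseless_inversion(self, therm):
        truth = BellEvansParams(6.6e-3, 0.72, ACC)
        pts = [(f, bell_evans_rate(truth, f, therm)) for f in (10, 15, 20, 25)]
        fit = fit_bell_evans(pts, ACC, therm)
        assert fit.params.k0_per_s == pytest.approx(6.6e-3, rel=1e-9)
        assert fit.params.x_dagger_nm == pytest.approx(0.72, rel=1e-9)

    def test_k0_scaling_leaves_x_dagger(self, therm):
        for k0 in (1e-3, 1e-1):
            truth = BellEvansParams(k0, 0.5, ACC)
            pts = [(f, bell_evans_rate(truth, f, therm)) for f in (5, 10, 15)]
            fit = fit_bell_evans(pts, ACC, therm)
            assert fit.params.x_dagger_nm == pytest.approx(0.5, rel=1e-9)

    def test_order_invariance(self, therm):
        truth = BellEvansParams(1e-2, 0.6, ACC)
        rng = np.random.default_rng(0)
        pts = [(f, bell_evans_rate(truth, f, therm) * rng.lognormal(0, 0.1), 0.1)
               for f in (5, 10, 15, 20)]
        a = fit_bell_evans(pts, ACC, therm)
        b = fit_bell_evans(pts[::-1], ACC, therm)
        assert a.params.k0_per_s == pytest.approx(b.params.k0_per_s, rel=1e-10)
        assert a.params.x_dagger_nm == pytest.approx(b.params.x_dagger_nm, rel=1e-10)

    def test_parameter_recovery_from_dwell_sampling(self, therm):
        """Rates from 200 dwells at 5 forces recover the generating law."""
        truth = presets.FLV_UNBINDING
        rng = np.random.default_rng(2024)
        pts = []
        for f in (10.0, 12.5, 15.0, 17.5, 20.0):
            dwells = rng.exponential(1 / bell_evans_rate(truth, f, therm), 200)
            rate = 1.0 / dwells.mean()
            pts.append((f, rate, rate / math.sqrt(200)))
        fit = fit_bell_evans(pts, ACC, therm)
        assert fit.params.x_dagger_nm == pytest.approx(0.72, rel=0.10)
        assert fit.params.k0_per_s == pytest.approx(6.6e-3, rel=0.50)

    def test_too_few_forces_rejected(self, therm):
        with pytest.raises(ValueError):
            fit_bell_evans([(5, 1.0), (5, 1.1), (10, 2.0)], ACC, therm)

    def test_nonpositive_rate_rejected(self, therm):
        with pytest.raises(ValueError):
            fit_bell_evans([(5, 1.0), (10, 0.0), (15, 2.0)], ACC, therm)


class TestFitBiphasicBinding:
    def test_exact_recovery(self, therm):
        model = presets.DEFAULT_BINDING_MODEL
        pts = [(f, binding_rate(model, f, therm)) for f in np.linspace(4, 30, 10)]
        fit = fit_biphasic_binding(pts, model.talin, therm)
        assert fit.params.k0_per_s == pytest.approx(model.bind.k0_per_s, rel=1e-6)
        assert fit.params.x_dagger_nm == pytest.approx(model.bind.x_dagger_nm,
                                                       rel=1e-6)

    def test_reduces_to_bell_evans_when_always_unfolded(self, therm):
        talin = TalinFoldingParams(
            unfold=BellEvansParams(1.0, 1.0, ACC),
            fold=BellEvansParams(1e-300, 1.0, SUP),
        )
        truth = BellEvansParams(0.8, 0.9, SUP)
        pts = [(f, bell_evans_rate(truth, f, therm)) for f in (5.0, 10.0, 15.0, 20.0)]
        bi = fit_biphasic_binding(pts, talin, therm)
        be = fit_bell_evans(pts, SUP, therm)
        assert bi.params.k0_per_s == pytest.approx(be.params.k0_per_s, rel=1e-4)
        assert bi.params.x_dagger_nm == pytest.approx(be.params.x_dagger_nm, abs=1e-4)

    def test_noisy_recovery_rate(self, therm):
        """10% relative noise: parameters within 20% in >= 90% of reps."""
        model = presets.DEFAULT_BINDING_MODEL
        forces = np.linspace(4, 30, 10)
        clean = np.array([binding_rate(model, f, therm) for f in forces])
        ok = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            noisy = clean * rng.normal(1.0, 0.10, clean.size)
            pts = np.column_stack([forces, noisy, 0.1 * clean])
            try:
                fit = fit_biphasic_binding(pts, model.talin, therm)
            except RuntimeError:
                continue
            if (
                abs(fit.params.k0_per_s / model.bind.k0_per_s - 1) < 0.2
                and abs(fit.params.x_dagger_nm / model.bind.x_dagger_nm - 1) < 0.2
            ):
                ok += 1
        assert ok / reps >= 0.90


class TestSqrtHistogram:
    def test_mode_bin_contains_log_timescale(self, rng):
        t = rng.exponential(1.0, 10_000)
        h = sqrt_histogram(t)
        mode_center = h.bin_centers[np.argmax(h.density)]
        assert abs(mode_center - 0.0) <= h.bin_width

    def test_mode_density_is_inverse_e(self, rng):
        """Single-exponential g at its mode equals exp(-1)."""
        t = rng.exponential(2.5, 50_000)
        h = sqrt_histogram(t, bins_per_decade=10)
        assert h.density.max() == pytest.approx(math.exp(-1), rel=0.06)

    def test_shift_equivariance_under_rescaling(self, rng):
        t = rng.exponential(1.0, 5000)
        c = 7.3
        h1 = sqrt_histogram(t)
        h2 = sqrt_histogram(c * t)
        assert h2.bin_width == h1.bin_width
        assert np.allclose(h2.bin_centers, h1.bin_centers + math.log(c), atol=1e-9)
        assert np.allclose(h2.density, h1.density)
        assert np.array_equal(h2.counts, h1.counts)

    @pytest.mark.parametrize("bins_per_decade", [4, 8, 16])
    def test_density_normalization_any_width(self, rng, bins_per_decade):
        t = rng.exponential(0.8, 3000)
        h = sqrt_histogram(t, bins_per_decade=bins_per_decade)
        assert float(h.density.sum() * h.bin_width) == pytest.approx(1.0, abs=1e-6)
        assert int(h.counts.sum()) == 3000

    def test_censored_dwells_excluded(self):
        df = pd.DataFrame(
            {"dwell_s": np.linspace(0.1, 2.0, 40), "censored": [False] * 30 + [True] * 10}
        )
        assert sqrt_histogram(df).n == 30

    def test_too_few_dwells_rejected(self, rng):
        with pytest.raises(ValueError):
            sqrt_histogram(rng.exponential(1.0, 5))


class TestDwellMixture:
    def test_pure_exponential_selects_one_component(self):
        """Model selection: k=1 chosen in >= 95% of 200 replicates."""
        chosen_one = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            t = r.exponential(1.3, 150)
            if fit_dwell_mixture(t, seed=0).k == 1:
                chosen_one += 1
        assert chosen_one / 200 >= 0.95

    def test_two_mode_recovery(self, rng):
        """Weak/mature two-mode sample: k=2 and slow timescale within 20%."""
        n = 2000
        t = np.where(
            rng.random(n) < presets.WEAK_MODE_WEIGHT,
            rng.exponential(presets.WEAK_UNBINDING_TIMESCALE_AT_PROBE_S, n),
            rng.exponential(presets.MATURE_UNBINDING_TIMESCALE_AT_PROBE_S, n),
        )
        fit = fit_dwell_mixture(t, seed=0)
        assert fit.k == 2
        assert fit.timescales_s[1] == pytest.approx(7.4, rel=0.20)
        assert fit.timescales_s[0] == pytest.approx(0.4, rel=0.25)

    def test_duplication_invariance(self, rng):
        t = rng.exponential(1.0, 100) + rng.exponential(3.0, 100)
        a = fit_dwell_mixture(t, seed=0)
        b = fit_dwell_mixture(np.concatenate([t, t]), seed=0)
        assert np.allclose(a.timescales_s, b.timescales_s, rtol=1e-4)
        assert np.allclose(a.amplitudes, b.amplitudes, atol=1e-4)

    def test_amplitudes_normalized_and_timescales_sorted(self, rng):
        t = np.concatenate([rng.exponential(0.4, 500), rng.exponential(7.4, 300)])
        fit = fit_dwell_mixture(rng.permutation(t), seed=1)
        assert fit.amplitudes.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(fit.timescales_s) > 0)

    def test_peak_positions_are_log_timescales(self, rng):
        t = rng.exponential(2.0, 400)
        fit = fit_dwell_mixture(t, seed=0)
        assert fit.peak_positions == pytest.approx(np.log(fit.timescales_s))

    def test_too_few_dwells_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_dwell_mixture(rng.exponential(1.0, 10))


class TestFitMaturation:
    @staticmethod
    def model(t, t_w, t_m, tau):
        return t_w + (t_m - t_w) * (1 - np.exp(-t / tau))

    def test_limits(self):
        assert self.model(0.0, 0.4, 7.4, 37.0) == pytest.approx(0.4)
        assert self.model(1e9, 0.4, 7.4, 37.0) == pytest.approx(7.4)

    def test_noiseless_recovery(self):
        t = np.array([2, 5, 10, 20, 40, 80, 150], dtype=float)
        fit = fit_maturation(np.column_stack([t, self.model(t, 0.4, 7.4, 37.0)]))
        assert fit.t_weak_s == pytest.approx(0.4, rel=1e-5)
        assert fit.t_mature_s == pytest.approx(7.4, rel=1e-5)
        assert fit.tau_maturation_s == pytest.approx(37.0, rel=1e-5)

    def test_logistic_variant_runs(self):
        t = np.array([2, 5, 10, 20, 40, 80, 150], dtype=float)
        y = 0.4 + 7.0 / (1 + 37.0 / t)
        fit = fit_maturation(np.column_stack([t, y]), model="logistic")
        assert fit.model == "logistic"
        assert fit.tau_maturation_s == pytest.approx(37.0, rel=1e-4)

    def test_degenerate_order_rejected(self):
        t = np.array([2, 5, 10, 20, 40], dtype=float)
        y = np.full_like(t, 3.0)
        y[0] = 8.0  # decreasing: t_m < t_w at optimum
        with pytest.raises(RuntimeError):
            fit_maturation(np.column_stack([t, y]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_maturation([[1.0, 0.5], [2.0, 0.6], [3.0, 0.7]])

    def test_recovery_from_simulated_experiment(self, therm):
        """Hold-and-probe simulation at the design conditions recovers tau."""
        df = simulate_maturation_experiment(
            presets.weak_unbinding_at_probe(),
            presets.mature_unbinding_at_probe(),
            presets.MATURATION_RATE_PER_S,
            presets.HOLD_FORCE_PN,
            presets.PROBE_FORCE_PN,
            presets.MATURATION_LIFETIME_DESIGN,
            reps=presets.MATURATION_REPS_PER_ENTRY,
            seed=7,
            therm=therm,
        )
        fit = fit_maturation_from_dwells(df)
        assert fit.tau_maturation_s == pytest.approx(37.0, rel=0.25)
        assert fit.t_weak_s < fit.t_mature_s


class TestBindingProbability:
    def test_zero_binding_rate_gives_zero(self, therm):
        scheme = KineticScheme(
            states=("off", "on"),
            transitions=(Transition("on", "off", 1.0), Transition("off", "on", 0.0)),
        )
        p, se = binding_probability(scheme, 9.0, 50.0, 50, seed=0, therm=therm,
                                    bound_states=("on",), initial_state="off")
        assert p == 0.0

    def test_fast_binding_no_unbinding_saturates(self, therm):
        scheme = KineticScheme(
            states=("off", "on"),
            transitions=(Transition("off", "on", 10.0),),
        )
        p, _ = binding_probability(scheme, 9.0, 50.0, 50, seed=1, therm=therm,
                                   bound_states=("on",), initial_state="off")
        assert p == 1.0

    def test_two_state_occupancy_closed_form(self, therm):
        """P(bound at t) = r_B/(r_B+r_U) (1 - e^{-(r_B+r_U) t}) within 3 SE."""
        r_b, r_u, t = 0.08, 0.12, 20.0
        scheme = KineticScheme(
            states=("off", "on"),
            transitions=(Transition("off", "on", r_b), Transition("on", "off", r_u)),
        )
        n = 800
        p, se = binding_probability(scheme, 9.0, t, n, seed=3, therm=therm,
                                    bound_states=("on",), initial_state="off")
        expected = r_b / (r_b + r_u) * (1 - math.exp(-(r_b + r_u) * t))
        assert abs(p - expected) <= 3 * max(se, math.sqrt(expected * (1 - expected) / n))

    def test_ever_bound_definition_dominates(self, therm):
        scheme = KineticScheme(
            states=("off", "on"),
            transitions=(Transition("off", "on", 0.1), Transition("on", "off", 0.5)),
        )
        p_end, _ = binding_probability(scheme, 9.0, 30.0, 200, seed=4, therm=therm,
                                       bound_states=("on",), initial_state="off")
        p_ever, _ = binding_probability(scheme, 9.0, 30.0, 200, seed=4, therm=therm,
                                        definition="ever", bound_states=("on",),
                                        initial_state="off")
        assert p_ever >= p_end
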