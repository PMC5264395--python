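"""Model primitives: half-normal rates, log-linear baseline, Poisson
likelihoods (against brute-force oracles), telemetry likelihood and priors."""

import math
from itertools import product

import numpy as np
import pytest
from scipy.stats import norm, poisson

from carnidens.design import StateSpace
from carnidens.model import (LatentState, ModelParams, ModelSpec, PriorSpec,
                             encounter_rate, expected_count, log_baseline,
                             log_prior, loglik_marked, loglik_telemetry,
                             loglik_unmarked, sigma_prior_from_home_range)
from carnidens.survey import EncounterData


def _enc(y, n, effort, tt, t, model_class, dead=None):
    m = y.shape[0]
    K = n.shape[1]
    return EncounterData(
        model_class=model_class, y=y, n=n,
        dead=np.zeros((m, K), np.int8) if dead is None else dead,
        Lb=np.zeros((m, K), np.int8), tt=tt, t=t, effort=effort,
        device_xy=_DEV_XY[: n.shape[0]],
        individual_ids=[f"i{r}" for r in range(m)])


_DEV_XY = np.array([[0.0, 0.0], [500.0, 0.0], [0.0, 500.0]])


class TestEncounterRate:
    def test_at_centre(self):
        assert encounter_rate([0, 0], [0, 0], 2.0, 400.0) == pytest.approx(2.0)

    def test_at_one_sigma(self):
        r = encounter_rate([0, 0], [400.0, 0.0], 1.0, 400.0)
        assert r == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_at_two_sigma(self):
        r = encounter_rate([0, 0], [800.0, 0.0], 2.0, 400.0)
        assert r == pytest.approx(2 * math.exp(-2), abs=1e-10)

    def test_bounded_by_lambda0(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-2000, 2000, (50, 2))
        r = encounter_rate([0, 0], pts, 0.7, 300.0)
        assert np.all(r >= 0) and np.all(r <= 0.7)


class TestLogBaseline:
    def test_null_model(self):
        p = ModelParams(alpha0=-1.0, w1=0, w2=0, w3=0, b1=5, b2=5, b3=5)
        assert log_baseline(p, tt_j=1.0, Lb_ik=1.0, t_k=1.0) == pytest.approx(
            math.exp(-1.0))

    def test_camera_trap_contrast(self):
        # a stone-marten-like device effect: lambda0 multiplied by e^2.75
        p = ModelParams(alpha0=math.log(0.1), b2=2.75, w1=0, w3=0)
        assert log_baseline(p, tt_j=1.0) == pytest.approx(0.1 * math.exp(2.75))
        assert log_baseline(p, tt_j=0.0) == pytest.approx(0.1)

    def test_occasion_trend(self):
        p = ModelParams(alpha0=0.0, b3=-1.13, w1=0, w2=0)
        assert log_baseline(p, tt_j=0.0, t_k=1.0) == pytest.approx(
            math.exp(-1.13))


class TestExpectedCount:
    def test_zero_effort(self):
        assert expected_count(0.5, 0.0) == 0.0

    def test_removed_from_dead_occasion_on(self):
        dead = np.array([0, 0, 0, 0, 1, 1, 1])
        mu = expected_count(0.5, np.full(7, 7.0), dead_ik=dead)
        assert (mu[4:] == 0).all() and (mu[:4] == 0.5 * 7).all()

    def test_rate_times_effort(self):
        assert expected_count(0.05, 7.0) == pytest.approx(0.35)

    def test_zero_when_excluded(self):
        assert expected_count(0.5, 7.0, z_i=0) == 0.0


class TestLoglikMarked:
    def test_single_cell_poisson(self):
        y = np.zeros((1, 3, 2), np.int64)
        y[0, 0, 0] = 1
        enc = _enc(y, np.zeros((3, 2), np.int64), np.full((3, 2), 7.0),
                   tt=np.zeros(3), t=np.zeros(2), model_class="SCR")
        # centre on device 0, huge sigma: mu = 0.05*7 = 0.35 at every cell
        params = ModelParams(alpha0=math.log(0.05), sigma=1e9,
                             w1=0, w2=0, w3=0)
        lat = LatentState(s=np.array([[0.0, 0.0]]), z=np.array([1]),
                          n_identified=1)
        expected = poisson.logpmf(enc.y, 0.35).sum()
        assert loglik_marked(enc, params, lat) == pytest.approx(expected)
        assert expected == pytest.approx(math.log(0.35) - 0.35 * 6, abs=1e-9)

    def test_all_zero_with_zero_rate(self):
        enc = _enc(np.zeros((1, 3, 2), np.int64), np.zeros((3, 2), np.int64),
                   np.zeros((3, 2)), np.zeros(3), np.zeros(2), "SCR")
        params = ModelParams(alpha0=-1.0, w1=0, w2=0, w3=0)
        lat = LatentState(s=np.array([[0.0, 0.0]]), z=np.array([1]),
                          n_identified=1)
        assert loglik_marked(enc, params, lat) == 0.0

    def test_impossible_datum_is_minus_inf(self):
        y = np.zeros((1, 3, 2), np.int64)
        y[0, 0, 0] = 1
        eff = np.full((3, 2), 7.0)
        enc = _enc(y, np.zeros((3, 2), np.int64), eff,
                   np.zeros(3), np.zeros(2), "SCR")
        enc.effort = eff.copy()
        enc.effort[0, 0] = 0.0          # bypass validation: effort zeroed late
        params = ModelParams(alpha0=-1.0, w1=0, w2=0, w3=0, sigma=400.0)
        lat = LatentState(s=np.array([[0.0, 0.0]]), z=np.array([1]),
                          n_identified=1)
        assert loglik_marked(enc, params, lat) == -np.inf


def brute_force_unmarked_loglik(n, mu):
    """Independent oracle: P(n[j,k]) by enumerating per-individual Poisson
    counts and convolving their pmfs (no superposition shortcut)."""
    I = mu.shape[0]
    total = 0.0
    for j, k in product(range(n.shape[0]), range(n.shape[1])):
        target = n[j, k]
        prob = 0.0
        for combo in product(range(target + 1), repeat=I):
            if sum(combo) != target:
                continue
            prob += np.prod([poisson.pmf(c, mu[i, j, k])
                             for i, c in enumerate(combo)])
        total += np.log(prob) if prob > 0 else -np.inf
    return total


class TestLoglikUnmarked:
    def _sc_enc(self, n, eff=None):
        eff = np.full(n.shape, 7.0) if eff is None else eff
        return _enc(np.zeros((0,) + n.shape, np.int64), n, eff,
                    np.zeros(n.shape[0]), np.zeros(n.shape[1]), "SC")

    def test_two_latents_superpose(self):
        # two individuals contributing mu = 0.2 each: n=1 ~ Poisson(0.4)
        n = np.zeros((1, 1), np.int64)
        n[0, 0] = 1
        enc = self._sc_enc(n, eff=np.full((1, 1), 1.0))
        enc.device_xy = np.array([[0.0, 0.0]])
        params = ModelParams(alpha0=math.log(0.2), sigma=1e9, w1=0, w2=0, w3=0)
        lat = LatentState(s=np.zeros((2, 2)), z=np.ones(2, np.int8))
        ll = loglik_unmarked(enc, params, lat)
        assert ll == pytest.approx(poisson.logpmf(1, 0.4), abs=1e-10)
        assert ll == pytest.approx(math.log(0.4) - 0.4, abs=1e-10)

    def test_matches_brute_force_enumeration(self):
        # <=3 individuals, <=2 devices, counts <=2: exact agreement
        rng = np.random.default_rng(8)
        for trial in range(5):
            n = rng.integers(0, 3, size=(2, 2)).astype(np.int64)
            enc = self._sc_enc(n)
            enc.device_xy = np.array([[0.0, 0.0], [500.0, 0.0]])
            s = rng.uniform(-200, 700, size=(3, 2))
            params = ModelParams(alpha0=math.log(0.05), sigma=400.0,
                                 w1=0, w2=0, w3=0)
            lat = LatentState(s=s, z=np.ones(3, np.int8))
            d2 = ((s[:, None, :] - enc.device_xy[None, :, :]) ** 2).sum(-1)
            mu = (0.05 * np.exp(-d2 / (2 * 400.0**2))[:, :, None]
                  * enc.effort[None, :, :])
            assert loglik_unmarked(enc, params, lat) == pytest.approx(
                brute_force_unmarked_loglik(n, mu), abs=1e-10)

    def test_split_rate_invariance(self):
        # one individual with rate mu vs two with mu/2: identical likelihood
        n = np.array([[2]], dtype=np.int64)
        enc = self._sc_enc(n, eff=np.full((1, 1), 1.0))
        enc.device_xy = np.array([[0.0, 0.0]])
        one = LatentState(s=np.zeros((1, 2)), z=np.ones(1, np.int8))
        two = LatentState(s=np.zeros((2, 2)), z=np.ones(2, np.int8))
        p_one = ModelParams(alpha0=math.log(0.6), sigma=1e9, w1=0, w2=0, w3=0)
        p_two = ModelParams(alpha0=math.log(0.3), sigma=1e9, w1=0, w2=0, w3=0)
        assert loglik_unmarked(enc, p_one, one) == pytest.approx(
            loglik_unmarked(enc, p_two, two), abs=1e-12)

    def test_counts_without_rate_minus_inf(self):
        n = np.array([[3]], dtype=np.int64)
        enc = self._sc_enc(n)
        lat = LatentState(s=np.zeros((2, 2)), z=np.zeros(2, np.int8))
        params = ModelParams(alpha0=0.0, sigma=400.0, w1=0, w2=0, w3=0)
        assert loglik_unmarked(enc, params, lat) == -np.inf

    def test_indicator_gates_coefficient(self):
        # with w2=0 the likelihood is invariant to b2
        n = np.array([[2, 1], [0, 3]], dtype=np.int64)
        enc = self._sc_enc(n)
        enc.tt = np.array([1.0, 0.0])
        lat = LatentState(s=np.array([[100.0, 0.0], [400.0, 300.0]]),
                          z=np.ones(2, np.int8))
        lls = [loglik_unmarked(enc, ModelParams(alpha0=-2.0, b2=b2, w2=0,
                                                w1=0, w3=0, sigma=400.0), lat)
               for b2 in (-3.0, 0.0, 4.0)]
        assert lls[0] == lls[1] == lls[2]


class TestLoglikTelemetry:
    def test_single_fix_at_centre(self):
        sigma = 300.0
        ll = loglik_telemetry([[10.0, -5.0]], [10.0, -5.0], sigma)
        assert ll == pytest.approx(-math.log(2 * math.pi * sigma**2))

    def test_mle_recovers_sigma(self):
        rng = np.random.default_rng(12)
        sigma = 400.0
        reps = 200
        s2_hats = []
        for _ in range(reps):
            locs = sigma * rng.standard_normal((25, 2))
            s2_hats.append((locs**2).sum() / (2 * 25))
        # sigma^2-hat is unbiased with sd sigma^2/sqrt(L*reps)
        se = sigma**2 / math.sqrt(25 * reps)
        assert abs(np.mean(s2_hats) - sigma**2) < 3 * se

    def test_concentrated_data_prefers_small_sigma(self):
        rng = np.random.default_rng(5)
        locs = 100.0 * rng.standard_normal((25, 2))
        assert loglik_telemetry(locs, [0, 0], 150.0) > \
            loglik_telemetry(locs, [0, 0], 300.0)


class TestPriors:
    def test_home_range_prior_badger(self):
        spec = sigma_prior_from_home_range(975, 475, 1475)
        mode, loc, scale = spec.sigma_prior
        assert mode == "truncnormal"
        assert loc == pytest.approx(719.72, abs=0.01)
        assert scale == pytest.approx(95.72, abs=0.01)

    def test_home_range_prior_mongoose_location(self):
        _, loc, _ = sigma_prior_from_home_range(300, 150, 450).sigma_prior
        assert loc == pytest.approx(399.23, abs=0.01)

    def test_degenerate_range_is_near_point(self):
        _, loc, scale = sigma_prior_from_home_range(
            300, 300 - 1e-3, 300 + 1e-3).sigma_prior
        assert scale < 1e-3 and loc == pytest.approx(399.23, abs=0.01)

    def test_unordered_inputs(self):
        with pytest.raises(ValueError):
            sigma_prior_from_home_range(300, 400, 500)

    def test_uniform_coefficient_prior(self):
        spec = PriorSpec(coef_prior="uniform", sigma_prior=("uniform", 1000.0))
        assert spec.coef_logpdf(0.0) == pytest.approx(-math.log(200))
        assert spec.coef_logpdf(150.0) == -np.inf

    def test_normal_precision_prior_density(self):
        # BUGS norm(0, 0.1): precision 0.1, sd sqrt(10)
        spec = PriorSpec(coef_prior="normal")
        assert spec.coef_logpdf(0.0) == pytest.approx(
            norm.logpdf(0.0, 0.0, math.sqrt(10)))
        # -0.5 * ln(2 pi * 10)
        assert spec.coef_logpdf(0.0) == pytest.approx(-2.07023, abs=1e-4)

    def test_sigma_below_truncation(self):
        spec = sigma_prior_from_home_range(975, 475, 1475)
        params = ModelParams(sigma=1e-12)
        assert spec.sigma_logpdf(-5.0) == -np.inf
        assert np.isfinite(spec.sigma_logpdf(700.0))

    def test_log_prior_sums_terms(self):
        spec = PriorSpec(coef_prior="uniform", sigma_prior=("uniform", 1000.0))
        p = ModelParams(alpha0=0.0, b1=0.0, b2=0.0, b3=0.0, sigma=500.0,
                        psi=0.3)
        expected = 4 * -math.log(200) - math.log(1000)
        assert log_prior(p, spec) == pytest.approx(expected)

    def test_model_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(model_class="SC", covariates=("Lb",))
        with pytest.raises(ValueError):
            ModelSpec(covariates=("bogus",))
        with pytest.raises(ValueError):
            ModelSpec(selection="stepwise")


class TestModelSpecYaml:
    def test_round_trip(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(
            "model_class: SMR\n"
            "covariates: [tt, t]\n"
            "selection: kuo_mallick\n"
            "sigma_init: 400\n"
            "priors:\n"
            "  coefficients: uniform\n"
            "  sigma: {mode: home_range, mean_ha: 975, low_ha: 475, "
            "high_ha: 1475}\n"
            "sampler: {n_iter: 500, burn_in: 100}\n")
        spec, sampler = ModelSpec.from_yaml(cfg)
        assert spec.model_class == "SMR"
        assert spec.covariates == ("tt", "t")
        assert spec.selection == "kuo_mallick"
        assert spec.priors.coef_prior == "uniform"
        assert spec.priors.sigma_prior[0] == "truncnormal"
        assert sampler == {"n_iter": 500, "burn_in": 100}
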