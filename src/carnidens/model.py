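"""Likelihoods and priors of the unified SCR/SMR/SC hierarchical model.

Observation model
-----------------
Each individual i has a latent activity centre ``s_i`` uniform on the state
space S.  Counts at device j in occasion k are Poisson with mean

    mu[i,j,k] = z_i * (1 - dead[i,k]) * lambda0[i,j,k]
                * exp(-||s_i - x_j||^2 / (2 sigma^2)) * e[j,k]

where ``e[j,k]`` is effort in days, ``z_i`` the data-augmentation inclusion
indicator, and the baseline encounter rate per device-day is log-linear in
the covariates,

    log lambda0[i,j,k] = alpha0 + w1*b1*Lb[i,k] + w2*b2*tt[j] + w3*b3*t[k],

with binary inclusion indicators ``w`` (Kuo-Mallick model selection).
Identified individuals contribute their full capture history ``y[i,j,k]``;
the unidentified/unmarked pool contributes only device-by-occasion totals
``n[j,k]``, which by Poisson superposition are Poisson with mean
``Lambda[j,k] = sum_i mu[i,j,k]`` over the latent unmarked individuals.
Telemetry fixes of collared individuals are bivariate normal around the
shared activity centre with per-axis sd sigma.

These are straightforward (vectorised numpy/scipy) implementations; the MCMC
engine re-implements the same quantities in a compiled kernel, and the test
suite holds the two routes to each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.special import gammaln
from scipy.stats import norm, poisson, truncnorm

from .design import sigma_from_home_range

COVARIATES = ("Lb", "tt", "t")   # order of b1, b2, b3 / w1, w2, w3


@dataclass
class ModelParams:
    """Parameter point of the encounter model."""

    alpha0: float = 0.0
    b1: float = 0.0          # behavioural response (Lb)
    b2: float = 0.0          # device type (tt: camera=1, trap=0)
    b3: float = 0.0          # occasion trend (t)
    w1: int = 1
    w2: int = 1
    w3: int = 1
    sigma: float = 400.0
    psi: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")

    @property
    def b(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3], dtype=float)

    @property
    def w(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3], dtype=int)


@dataclass
class LatentState:
    """Activity centres and inclusion indicators for the augmented population.

    The first ``n_identified`` rows correspond to the identified individuals
    (z pinned at 1); the remainder is the augmented unmarked pool.
    """

    s: np.ndarray            # (M, 2)
    z: np.ndarray            # (M,) 0/1
    n_identified: int = 0

    def __post_init__(self) -> None:
        self.s = np.atleast_2d(np.asarray(self.s, dtype=float))
        self.z = np.asarray(self.z, dtype=np.int8)
        if self.z.shape[0] != self.s.shape[0]:
            raise ValueError("s and z length mismatch")
        if np.any(self.z[: self.n_identified] != 1):
            raise ValueError("identified individuals must have z = 1")


@dataclass
class PriorSpec:
    """Prior configuration.

    ``coef_prior`` applies to alpha0 and the b coefficients: ``"normal"`` is
    Normal(0, precision 0.1) in the BUGS convention (sd = sqrt(10)), and
    ``"uniform"`` is Uniform(-100, 100).  ``sigma_prior`` is one of

    * ``("uniform", upper)`` — noninformative, Uniform(0, upper);
    * ``("truncnormal", loc, scale)`` — home-range-informative, a normal
      truncated to sigma > 0 (see :func:`sigma_prior_from_home_range`).

    psi always carries its Beta(1, 1) data-augmentation prior.
    """

    coef_prior: str = "normal"
    sigma_prior: tuple = ("uniform", 5000.0)
    spike_sd: float = 0.1    # spike component sd for spike-and-slab selection

    COEF_SD_NORMAL = math.sqrt(10.0)   # precision 0.1
    COEF_HALF_RANGE = 100.0

    def __post_init__(self) -> None:
        if self.coef_prior not in ("normal", "uniform"):
            raise ValueError(f"unknown coefficient prior {self.coef_prior!r}")
        mode = self.sigma_prior[0]
        if mode == "uniform":
            if self.sigma_prior[1] <= 0:
                raise ValueError("sigma prior upper bound must be positive")
        elif mode == "truncnormal":
            if self.sigma_prior[1] <= 0 or self.sigma_prior[2] <= 0:
                raise ValueError("truncated-normal sigma prior needs positive "
                                 "location and scale")
        else:
            raise ValueError(f"unknown sigma prior {mode!r}")

    def coef_logpdf(self, value: float) -> float:
        if self.coef_prior == "normal":
            return float(norm.logpdf(value, 0.0, self.COEF_SD_NORMAL))
        if abs(value) > self.COEF_HALF_RANGE:
            return -np.inf
        return -math.log(2.0 * self.COEF_HALF_RANGE)

    def sigma_logpdf(self, sigma: float) -> float:
        if sigma <= 0:
            return -np.inf
        if self.sigma_prior[0] == "uniform":
            upper = self.sigma_prior[1]
            return -math.log(upper) if sigma < upper else -np.inf
        _, loc, scale = self.sigma_prior
        a = (0.0 - loc) / scale
        return float(truncnorm.logpdf(sigma, a, np.inf, loc=loc, scale=scale))


def sigma_prior_from_home_range(mean_ha: float, low_ha: float,
                                high_ha: float, alpha: float = 0.05) -> PriorSpec:
    """Informative sigma prior from a literature home range and its range.

    The endpoints are pushed through the home-range inversion
    ``sigma = sqrt(HR / (pi q))`` and a truncated normal is centred at
    sigma(mean) with scale (sigma(high) - sigma(low)) / 4, i.e. the stated
    range spans roughly +/- 2 prior sd.
    """
    if not 0 < low_ha < mean_ha < high_ha:
        raise ValueError("need 0 < low < mean < high home-range areas")
    loc = sigma_from_home_range(mean_ha * 1e4, alpha)
    lo = sigma_from_home_range(low_ha * 1e4, alpha)
    hi = sigma_from_home_range(high_ha * 1e4, alpha)
    return PriorSpec(sigma_prior=("truncnormal", loc, (hi - lo) / 4.0))


@dataclass
class ModelSpec:
    """What to fit: model class, covariates, selection mode, priors, M."""

    model_class: str = "SCR"
    covariates: tuple = ()             # subset of ("Lb", "tt", "t")
    selection: str = "none"            # none | kuo_mallick | spike_slab
    priors: PriorSpec = field(default_factory=PriorSpec)
    M: int | None = None               # superpopulation size; None -> auto
    sigma_init: float = 400.0          # design-stage sigma-hat

    def __post_init__(self) -> None:
        if self.model_class not in ("SCR", "SMR", "SC"):
            raise ValueError(f"unknown model class {self.model_class!r}")
        unknown = set(self.covariates) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        if "Lb" in self.covariates and self.model_class == "SC":
            raise ValueError("behaviour covariate requires identified "
                             "individuals (not available in SC)")
        if self.selection not in ("none", "kuo_mallick", "spike_slab"):
            raise ValueError(f"unknown selection mode {self.selection!r}")

    @classmethod
    def from_yaml(cls, path) -> tuple["ModelSpec", dict]:
        """Load a model spec (and any sampler overrides) from a YAML file."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        pr = cfg.get("priors", {})
        sp = pr.get("sigma", {"mode": "noninformative"})
        if sp.get("mode") == "home_range":
            priors = sigma_prior_from_home_range(
                sp["mean_ha"], sp["low_ha"], sp["high_ha"])
        else:
            upper = sp.get("upper", 5.0 * cfg.get("sigma_init", 400.0))
            priors = PriorSpec(sigma_prior=("uniform", float(upper)))
        priors = replace(priors, coef_prior=pr.get("coefficients", "normal"),
                         spike_sd=float(pr.get("spike_sd", 0.1)))
        spec = cls(
            model_class=cfg.get("model_class", "SCR"),
            covariates=tuple(cfg.get("covariates", ())),
            selection=cfg.get("selection", "none"),
            priors=priors,
            M=cfg.get("M"),
            sigma_init=float(cfg.get("sigma_init", 400.0)),
        )
        return spec, cfg.get("sampler", {})


# ---------------------------------------------------------------------------
# model primitives (reference implementations)
# ---------------------------------------------------------------------------

def encounter_rate(center, device_xy, lambda0: float, sigma: float) -> np.ndarray:
    """Half-normal encounter rate lambda0 * exp(-d^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if lambda0 < 0:
        raise ValueError("lambda0 must be non-negative")
    center = np.asarray(center, dtype=float)
    device_xy = np.asarray(device_xy, dtype=float)
    d2 = np.sum((np.atleast_2d(device_xy) - center) ** 2, axis=-1)
    out = lambda0 * np.exp(-d2 / (2.0 * sigma**2))
    return out if out.size > 1 else float(out[0])


def log_baseline(params: ModelParams, tt_j, Lb_ik=0.0, t_k=0.0) -> np.ndarray:
    """Baseline rate lambda0[i,j,k] under the log-linear covariate model."""
    lin = (params.alpha0
           + params.w1 * params.b1 * np.asarray(Lb_ik, dtype=float)
           + params.w2 * params.b2 * np.asarray(tt_j, dtype=float)
           + params.w3 * params.b3 * np.asarray(t_k, dtype=float))
    return np.exp(lin)


def expected_count(rate_ijk, effort_jk, dead_ik=0, z_i=1) -> np.ndarray:
    """Poisson mean mu = z * (1 - dead) * rate * effort."""
    mu = (np.asarray(z_i, dtype=float)
          * (1.0 - np.asarray(dead_ik, dtype=float))
          * np.asarray(rate_ijk, dtype=float)
          * np.asarray(effort_jk, dtype=float))
    return mu


def _rate_cube(enc, params: ModelParams, s: np.ndarray,
               with_Lb: bool) -> np.ndarray:
    """mu[i,j,k] for centres s (rows aligned with enc's identified block)."""
    d2 = ((s[:, None, :] - enc.device_xy[None, :, :]) ** 2).sum(-1)   # (m, J)
    kern = np.exp(-d2 / (2.0 * params.sigma**2))
    Lb = enc.Lb if with_Lb else np.zeros((s.shape[0], enc.n_occasions))
    lam0 = log_baseline(params, enc.tt[None, :, None],
                        np.asarray(Lb, dtype=float)[:, None, :],
                        enc.t[None, None, :])
    return lam0 * kern[:, :, None] * enc.effort[None, :, :]


def loglik_marked(enc, params: ModelParams, latent: LatentState) -> float:
    """Poisson log likelihood of the identified capture histories y."""
    m = enc.n_identified
    if m == 0:
        return 0.0
    mu = _rate_cube(enc, params, latent.s[:m], with_Lb=True)
    mu *= (1.0 - enc.dead.astype(float))[:, None, :]
    return float(poisson.logpmf(enc.y, mu).sum())


def loglik_unmarked(enc, params: ModelParams, latent: LatentState) -> float:
    """Poisson-superposition log likelihood of the unidentified counts n."""
    if enc.model_class == "SCR" and not enc.n.any():
        pool = latent.s[enc.n_identified:]
        z = latent.z[enc.n_identified:]
        if pool.shape[0] == 0:
            return 0.0
        mu = _rate_cube(enc, params, pool, with_Lb=False)
        return float(-(mu * z[:, None, None]).sum())   # all-zero histories
    pool = latent.s[enc.n_identified:]
    z = latent.z[enc.n_identified:]
    if pool.shape[0] == 0:
        lam = np.zeros_like(enc.n, dtype=float)
    else:
        mu = _rate_cube(enc, params, pool, with_Lb=False)
        lam = (mu * z[:, None, None]).sum(axis=0)
    return float(poisson.logpmf(enc.n, lam).sum())


def loglik_telemetry(locs, center, sigma: float) -> float:
    """Log likelihood of telemetry fixes, iid N(center, sigma^2 I_2)."""
    locs = np.atleast_2d(np.asarray(locs, dtype=float))
    center = np.asarray(center, dtype=float)
    L = locs.shape[0]
    q = float(((locs - center) ** 2).sum())
    return -L * math.log(2.0 * math.pi * sigma**2) - q / (2.0 * sigma**2)


def log_prior(params: ModelParams, spec: PriorSpec,
              include: tuple = COVARIATES) -> float:
    """Joint log prior density of (alpha0, included b's, sigma, psi).

    psi ~ Beta(1, 1) contributes 0 on [0, 1]; indicator priors
    (Bernoulli(1/2)) are constant and omitted.
    """
    lp = spec.coef_logpdf(params.alpha0)
    for name, val in zip(COVARIATES, (params.b1, params.b2, params.b3)):
        if name in include:
            lp += spec.coef_logpdf(val)
    lp += spec.sigma_logpdf(params.sigma)
    if not 0.0 <= params.psi <= 1.0:
        return -np.inf
    return float(lp)


def joint_log_density(enc, params: ModelParams, latent: LatentState,
                      prior: PriorSpec, telemetry=None,
                      telemetry_links=None) -> float:
    """Reference joint log density (likelihoods + parameter priors).

    ``telemetry`` is a list of TelemetryData; ``telemetry_links`` maps each
    entry to a row of ``latent.s`` (identified individuals share centres).
    Activity-centre priors (uniform on S) and z|psi terms are constant or
    handled by Gibbs steps and omitted here.
    """
    ll = loglik_marked(enc, params, latent)
    ll += loglik_unmarked(enc, params, latent)
    if telemetry:
        for tel, row in zip(telemetry, telemetry_links):
            ll += loglik_telemetry(tel.locations, latent.s[row], params.sigma)
    include = tuple(
        nm for nm, w in zip(COVARIATES, params.w) if w
    )
    return ll + log_prior(params, prior, include=include)
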