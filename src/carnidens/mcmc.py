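"""Multi-chain Metropolis-within-Gibbs orchestration.

``run_chains`` prepares the compiled kernel's inputs from an
:class:`~carnidens.survey.EncounterData`, a state space, a
:class:`~carnidens.model.ModelSpec` and a :class:`SamplerConfig`, runs the
requested number of independent chains with distinct seeds, and collects the
draws into a :class:`PosteriorResult`.

Population size is handled by data augmentation: the identified individuals
(z pinned at 1) are topped up with an augmented pool to a superpopulation of
size M, and N = (number identified) + sum(z) over the pool.  By default
M = max(100, 5 * number of identified individuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _kernel
from .design import StateSpace
from .model import COVARIATES, ModelSpec, PriorSpec
from .survey import EncounterData, TelemetryData

_SEL_CODE = {"none": _kernel.SEL_NONE,
             "kuo_mallick": _kernel.SEL_KUO_MALLICK,
             "spike_slab": _kernel.SEL_SPIKE_SLAB}

PARAM_NAMES = ("alpha0", "b1", "b2", "b3", "w1", "w2", "w3",
               "sigma", "psi", "N")
_ACC_BLOCKS = ("centers_identified", "centers_augmented", "alpha0",
               "b1", "b2", "b3", "sigma")


@dataclass
class SamplerConfig:
    """MCMC run configuration (test-scale defaults; raise for production)."""

    n_chains: int = 3
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 1
    step_center: float = 250.0
    step_coef: float = 0.15
    step_log_sigma: float = 0.08
    adapt_interval: int = 50
    prior_only: bool = False
    keep_centers: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def chain_seed(self, c: int) -> int:
        return int((self.seed + 7919 * c) % (2**31 - 1))


@dataclass
class ChainOutput:
    """Draws and diagnostics from one chain."""

    draws: dict                   # name -> 1-d array of retained draws
    s_draws: np.ndarray | None    # (n_draws, m, 2) identified-centre draws
    acceptance: dict
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.draws["N"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws)


@dataclass
class PosteriorResult:
    """Multi-chain posterior with the state space used for density."""

    chains: list
    state_space: StateSpace
    model_spec: ModelSpec
    individual_ids: list = field(default_factory=list)
    n_removed: int = 0
    M: int = 0

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("need at least one chain")
        lens = {c.n_draws for c in self.chains}
        if len(lens) != 1:
            raise ValueError("chains have unequal draw counts")

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def parameter(self, name: str, pooled: bool = True):
        """Draws of one monitored scalar, pooled or as a per-chain list."""
        per_chain = [np.asarray(c.draws[name]) for c in self.chains]
        return np.concatenate(per_chain) if pooled else per_chain


def _prepare_arrays(enc: EncounterData, telemetry, spec: ModelSpec):
    """Flatten EncounterData into the kernel's array arguments."""
    m, J, K = enc.n_identified, enc.n_devices, enc.n_occasions
    ii, jj, kk = np.nonzero(enc.y)
    order = np.argsort(ii, kind="stable")
    yi = ii[order].astype(np.int64)
    yjj = jj[order].astype(np.int64)
    ykk = kk[order].astype(np.int64)
    yv = enc.y[ii, jj, kk][order].astype(np.float64)
    yptr = np.zeros(m + 1, dtype=np.int64)
    np.add.at(yptr, yi + 1, 1)
    yptr = np.cumsum(yptr)

    eff = enc.effort.astype(np.float64)
    with np.errstate(divide="ignore"):
        log_e = np.where(eff > 0, np.log(np.maximum(eff, 1e-300)), 0.0)
    nmat = enc.n.astype(np.float64)
    Nj = nmat.sum(axis=1)
    Sn = float(nmat.sum())
    Sntt = float((nmat * enc.tt[:, None]).sum())
    Sntk = float((nmat * enc.t[None, :]).sum())
    Snloge = float((nmat * log_e).sum())
    ll_const = float(-gammaln(yv + 1.0).sum() - gammaln(nmat + 1.0).sum())

    # telemetry sufficient statistics; fixes of identified individuals share
    # that individual's activity centre
    tel = telemetry or []
    T = len(tel)
    telL = np.zeros(T)
    telsx = np.zeros(T)
    telsy = np.zeros(T)
    telss = np.zeros(T)
    tel_link = np.full(T, -1, dtype=np.int64)
    for t, td in enumerate(tel):
        locs = td.locations
        telL[t] = locs.shape[0]
        telsx[t] = locs[:, 0].sum()
        telsy[t] = locs[:, 1].sum()
        telss[t] = (locs ** 2).sum()
        if td.individual_id in enc.individual_ids:
            tel_link[t] = enc.individual_ids.index(td.individual_id)
    tel_of_ind = np.full(m, -1, dtype=np.int64)
    for t in range(T):
        if tel_link[t] >= 0:
            tel_of_ind[tel_link[t]] = t

    use = np.zeros(3, dtype=np.int8)
    for idx, name in enumerate(COVARIATES):
        if name in spec.covariates:
            use[idx] = 1
    if m == 0:
        use[0] = 0          # behaviour needs identified individuals

    return dict(
        yi=yi, yj=yjj, yk=ykk, yv=yv, yptr=yptr,
        alive=(1.0 - enc.dead.astype(np.float64)),
        Lb=enc.Lb.astype(np.float64),
        tt=enc.tt.astype(np.float64), tk=enc.t.astype(np.float64),
        eff=eff, log_e=log_e,
        Nj=Nj, Sn=Sn, Sntt=Sntt, Sntk=Sntk, Snloge=Snloge,
        ll_const=ll_const,
        dev_x=enc.device_xy[:, 0].astype(np.float64),
        dev_y=enc.device_xy[:, 1].astype(np.float64),
        telL=telL, telsx=telsx, telsy=telsy, telss=telss,
        tel_link=tel_link, tel_of_ind=tel_of_ind, use=use,
    )


def _initial_state(enc: EncounterData, space: StateSpace, spec: ModelSpec,
                   arrays: dict, Ma: int, rng: np.random.Generator):
    """Starting values: identified centres at their detection centroid,
    augmented centres uniform on S, alpha0 at the crude event rate."""
    m, J = enc.n_identified, enc.n_devices
    sm0 = np.empty((m, 2))
    ycounts = enc.y.sum(axis=2)                      # (m, J)
    for i in range(m):
        wts = ycounts[i].astype(float)
        if wts.sum() > 0:
            sm0[i] = (enc.device_xy * wts[:, None]).sum(0) / wts.sum()
        else:
            sm0[i] = [rng.uniform(space.xmin, space.xmax),
                      rng.uniform(space.ymin, space.ymax)]
    sa0 = np.column_stack([rng.uniform(space.xmin, space.xmax, Ma),
                           rng.uniform(space.ymin, space.ymax, Ma)])
    z0 = (rng.random(Ma) < 0.5).astype(np.int8)
    if enc.n.any() and z0.sum() == 0:
        z0[0] = 1
    s_tel0 = np.zeros((len(arrays["telL"]), 2))
    for t in range(len(arrays["telL"])):
        L = arrays["telL"][t]
        s_tel0[t] = (arrays["telsx"][t] / L, arrays["telsy"][t] / L)

    total_events = enc.total_events()
    total_effort = max(enc.effort.sum(), 1.0)
    alpha0_0 = float(np.log(max(total_events, 1) / total_effort))
    b0 = np.zeros(3)
    w0 = arrays["use"].copy()
    gsel0 = arrays["use"].copy()
    return sm0, sa0, z0, s_tel0, alpha0_0, b0, w0, gsel0


def run_chains(enc: EncounterData, space: StateSpace, spec: ModelSpec,
               config: SamplerConfig | None = None,
               telemetry: list[TelemetryData] | None = None) -> PosteriorResult:
    """Run independent MCMC chains and collect a PosteriorResult.

    Chains are reproducible bit-for-bit from ``config.seed``; each chain gets
    a distinct derived seed for both its initialisation and its kernel RNG.
    """
    config = config or SamplerConfig()
    if not np.all(space.contains(enc.device_xy)):
        raise ValueError("state space does not contain every device")
    arrays = _prepare_arrays(enc, telemetry, spec)
    m = enc.n_identified
    M = spec.M if spec.M is not None else max(100, 5 * m)
    if M <= m:
        raise ValueError(f"superpopulation M={M} must exceed the "
                         f"{m} identified individuals")
    Ma = M - m

    sp = spec.priors.sigma_prior
    sp_type = 0 if sp[0] == "uniform" else 1
    sp1 = float(sp[1])
    sp2 = float(sp[2]) if sp_type == 1 else 0.0
    coef_code = 0 if spec.priors.coef_prior == "normal" else 1
    sigma0 = spec.sigma_init
    if sp_type == 1:
        sigma0 = sp1
    elif sigma0 >= sp1:
        sigma0 = 0.5 * sp1

    chains = []
    for c in range(config.n_chains):
        seed_c = config.chain_seed(c)
        rng = np.random.default_rng(seed_c)
        sm0, sa0, z0, s_tel0, alpha0_0, b0, w0, gsel0 = _initial_state(
            enc, space, spec, arrays, Ma, rng)
        res = _kernel.run_chain(
            seed_c, config.n_iter, config.burn_in, config.thin,
            np.int8(config.prior_only), _SEL_CODE[spec.selection],
            arrays["use"], np.int8(coef_code), float(spec.priors.spike_sd),
            np.int8(sp_type), sp1, sp2,
            arrays["yi"], arrays["yj"], arrays["yk"], arrays["yv"],
            arrays["yptr"],
            arrays["alive"], arrays["Lb"], arrays["tt"], arrays["tk"],
            arrays["eff"], arrays["log_e"],
            arrays["Nj"], arrays["Sn"], arrays["Sntt"], arrays["Sntk"],
            arrays["Snloge"], arrays["ll_const"],
            arrays["dev_x"], arrays["dev_y"],
            space.xmin, space.xmax, space.ymin, space.ymax,
            sm0, sa0, z0,
            arrays["telL"], arrays["telsx"], arrays["telsy"], arrays["telss"],
            arrays["tel_link"], s_tel0, arrays["tel_of_ind"],
            alpha0_0, b0, w0.astype(np.int8), gsel0.astype(np.int8),
            float(sigma0), 0.5,
            config.step_center, config.step_center,
            config.step_coef, np.full(3, config.step_coef),
            config.step_log_sigma, config.adapt_interval,
        )
        status, a0d, bd, wd, sigd, psid, Nd, sd, accr, llc, llf = res
        if status == _kernel.BAD_INIT:
            raise RuntimeError("bad initialization: initial state has "
                               "log likelihood -inf")
        if not config.prior_only:
            scale = max(abs(llf), 1.0)
            if abs(llc - llf) > 1e-6 * scale:
                raise RuntimeError(
                    "sampler bookkeeping error: cached log likelihood "
                    f"{llc} != recomputed {llf}")
        draws = {
            "alpha0": a0d, "b1": bd[:, 0], "b2": bd[:, 1], "b3": bd[:, 2],
            "w1": wd[:, 0].astype(np.int64),
            "w2": wd[:, 1].astype(np.int64),
            "w3": wd[:, 2].astype(np.int64),
            "sigma": sigd, "psi": psid, "N": Nd,
        }
        chains.append(ChainOutput(
            draws=draws,
            s_draws=sd if config.keep_centers else None,
            acceptance=dict(zip(_ACC_BLOCKS, accr)),
            seed=seed_c,
        ))

    result = PosteriorResult(
        chains=chains, state_space=space, model_spec=spec,
        individual_ids=list(enc.individual_ids),
        n_removed=int(enc.dead.any(axis=1).sum()) if enc.dead.size else 0,
        M=M,
    )
    Npool = result.parameter("N")
    if np.mean(Npool > 0.9 * M) > 0.05:
        warnings.warn(
            f"posterior of N presses the augmentation ceiling M={M} "
            "(P(N > 0.9 M) > 0.05); rerun with a larger M", stacklevel=2)
    return result


def reference_loglik(enc: EncounterData, space: StateSpace, spec: ModelSpec,
                     alpha0, b, w, sigma, sm, sa, z,
                     telemetry=None) -> float:
    """Kernel-route data log likelihood of an explicit state (for testing)."""
    arrays = _prepare_arrays(enc, telemetry, spec)
    use = arrays["use"]
    sel = _SEL_CODE[spec.selection]
    c = [0.0, 0.0, 0.0]
    for idx in range(3):
        if use[idx]:
            c[idx] = b[idx] if sel == _kernel.SEL_SPIKE_SLAB else b[idx] * w[idx]
    T = len(arrays["telL"])
    s_tel = np.zeros((T, 2))
    for t in range(T):
        L = arrays["telL"][t]
        s_tel[t] = (arrays["telsx"][t] / L, arrays["telsy"][t] / L)
    return float(_kernel.state_loglik(
        float(alpha0), c[0], c[1], c[2], float(sigma),
        np.asarray(sm, dtype=float).reshape(-1, 2),
        np.asarray(sa, dtype=float).reshape(-1, 2),
        np.asarray(z, dtype=np.int8),
        arrays["dev_x"], arrays["dev_y"], arrays["tt"], arrays["tk"],
        arrays["eff"], arrays["log_e"], arrays["alive"], arrays["Lb"],
        arrays["yi"], arrays["yj"], arrays["yk"], arrays["yv"],
        arrays["Nj"], arrays["Sn"], arrays["Sntt"], arrays["Sntk"],
        arrays["Snloge"], arrays["ll_const"],
        s_tel, arrays["telL"], arrays["telsx"], arrays["telsy"],
        arrays["telss"], arrays["tel_link"],
    ))
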