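"""Posterior post-processing: density, credible intervals, convergence,
model weights and activity-centre summaries.

Density is reported on the data-augmentation superpopulation over the state
space, D = N / area(S) in individuals/km^2, summarised by the posterior
mean, sample sd, equal-tailed 95% credible interval (2.5/97.5 percentiles)
and the coefficient of variation CV = sd/mean.  Convergence is assessed with
the classic Gelman-Rubin potential scale reduction factor (no split, no
degrees-of-freedom correction), with R-hat < 1.1 read as converged.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .model import COVARIATES

RHAT_THRESHOLD = 1.1
#: slot order of the M(...) model labels, matching the coefficient table
#: convention (device type tt, behaviour Lb, occasion t)
_LABEL_SLOTS = (("tt", 1), ("Lb", 0), ("t", 2))


@dataclass(frozen=True)
class DensitySummary:
    """Posterior summary of a scalar (density in individuals/km^2)."""

    mean: float
    sd: float
    bci_low: float
    bci_high: float
    cv: float

    def __post_init__(self) -> None:
        if self.bci_low > self.bci_high:
            raise ValueError("credible interval bounds out of order")

    def as_dict(self) -> dict:
        return asdict(self)


def density_posterior(result, pooled: bool = True):
    """Per-draw density D = N / area(S), individuals per km^2."""
    area = result.state_space.area_km2
    if area <= 0:
        raise ValueError("state space has zero area")
    N = result.parameter("N", pooled=pooled)
    if pooled:
        return N / area
    return [n / area for n in N]


def summarize(draws) -> DensitySummary:
    """Mean, sample sd, equal-tailed 95% BCI and CV of posterior draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws to summarise")
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    cv = sd / mean if mean != 0 else np.inf
    return DensitySummary(mean=mean, sd=sd, bci_low=float(lo),
                          bci_high=float(hi), cv=float(cv))


def gelman_rubin(chains_of_scalar) -> float:
    """Classic potential scale reduction factor R-hat.

    With c chains of length n: W = mean within-chain variance, B = n * the
    variance of the chain means, V-hat = (n-1)/n * W + B/n and
    R-hat = sqrt(V-hat / W).  Sample variances use ddof=1.
    """
    chains = [np.asarray(ch, dtype=float) for ch in chains_of_scalar]
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    n = len(chains[0])
    if n < 2 or any(len(ch) != n for ch in chains):
        raise ValueError("chains must have equal length >= 2")
    W = float(np.mean([ch.var(ddof=1) for ch in chains]))
    if W == 0.0:
        raise ValueError("degenerate chains (zero within-chain variance)")
    means = np.array([ch.mean() for ch in chains])
    B = n * float(means.var(ddof=1))
    vhat = (n - 1) / n * W + B / n
    return float(np.sqrt(vhat / W))


def rhat_table(result, params=("N", "sigma", "alpha0")) -> pd.DataFrame:
    """R-hat per monitored parameter, with the <1.1 convergence verdict."""
    rows = []
    for p in params:
        per_chain = result.parameter(p, pooled=False)
        if result.n_chains < 2:
            raise ValueError("R-hat needs at least 2 chains")
        r = gelman_rubin(per_chain)
        rows.append({"parameter": p, "rhat": r,
                     "converged": bool(r < RHAT_THRESHOLD)})
    return pd.DataFrame(rows)


def model_weights(indicator_draws, present=(True, True, True)) -> pd.DataFrame:
    """Posterior model weights from inclusion-indicator draws.

    ``indicator_draws`` is (n_draws, 3) of the (w1, w2, w3) = (Lb, tt, t)
    indicators (or slab memberships).  Covariates not offered to selection
    (``present`` False) are dropped from the labels.  Weights are the
    relative frequencies of the visited indicator combinations over all
    2^m candidate models, labelled M(tt, Lb, t)-style with "." for an
    excluded term; they sum to one.
    """
    wd = np.atleast_2d(np.asarray(indicator_draws, dtype=int))
    if wd.shape[1] != 3:
        raise ValueError("indicator draws must have 3 columns (w1, w2, w3)")
    present = np.asarray(present, dtype=bool)
    slots = [(nm, col) for nm, col in _LABEL_SLOTS if present[col]]
    combos = {}
    n = wd.shape[0]
    for row in wd:
        key = tuple(int(row[col]) for _, col in slots)
        combos[key] = combos.get(key, 0) + 1
    # enumerate every candidate model so absent ones report weight 0
    from itertools import product
    rows = []
    for key in product((0, 1), repeat=len(slots)):
        label = "M(" + ", ".join(
            nm if on else "." for (nm, _), on in zip(slots, key)) + ")"
        rows.append({"model": label, "weight": combos.get(key, 0) / n})
    df = pd.DataFrame(rows).sort_values("weight", ascending=False,
                                        kind="stable").reset_index(drop=True)
    return df


def selected_model(weights: pd.DataFrame) -> str:
    """Label of the highest-weight model."""
    return str(weights.iloc[0]["model"])


def activity_center_summary(result) -> pd.DataFrame:
    """Posterior mean and 95% quantile box of each observed individual's
    activity centre (augmented never-detected individuals are excluded)."""
    chains = [c.s_draws for c in result.chains]
    if any(s is None for s in chains):
        raise ValueError("activity-centre draws were not retained")
    s = np.concatenate(chains, axis=0)            # (draws, m, 2)
    rows = []
    for i, ind in enumerate(result.individual_ids):
        xs, ys = s[:, i, 0], s[:, i, 1]
        rows.append({
            "individual_id": ind,
            "x_mean": xs.mean(), "y_mean": ys.mean(),
            "x_low": np.percentile(xs, 2.5), "x_high": np.percentile(xs, 97.5),
            "y_low": np.percentile(ys, 2.5), "y_high": np.percentile(ys, 97.5),
        })
    return pd.DataFrame(rows)


def summarize_posterior(result) -> dict:
    """Machine-readable posterior report (the summarise-CLI payload)."""
    D = density_posterior(result)
    N = result.parameter("N")
    out = {
        "model_class": result.model_spec.model_class,
        "area_km2": result.state_space.area_km2,
        "density": summarize(D).as_dict(),
        "N": summarize(N).as_dict(),
        "N_end_of_survey": summarize(N - result.n_removed).as_dict(),
        "sigma": summarize(result.parameter("sigma")).as_dict(),
        "alpha0": summarize(result.parameter("alpha0")).as_dict(),
        "n_removed": result.n_removed,
    }
    if result.n_chains >= 2:
        tbl = rhat_table(result)
        out["rhat"] = {r["parameter"]: r["rhat"] for _, r in tbl.iterrows()}
        out["converged"] = bool(tbl["converged"].all())
    if result.model_spec.selection != "none":
        present = [nm in result.model_spec.covariates for nm in COVARIATES]
        wd = np.column_stack([result.parameter(f"w{i+1}") for i in range(3)])
        wt = model_weights(wd, present=present)
        out["model_weights"] = dict(zip(wt["model"], wt["weight"]))
        out["selected_model"] = selected_model(wt)
    return out
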