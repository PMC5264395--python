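"""Synthetic camera + live-trap surveys with the statistical structure the
analysis assumes.

The generator emulates a study-like design: ~66 cameras on a regular 500-m
grid with ~69 interleaved live traps, a 98-day window binned into 14 weekly
occasions, device downtime (cameras mostly on, traps operated in short
bursts), Poisson half-normal encounters with optional covariate effects on
the baseline rate, a marked subset per species, known removals triggered by
live-trap captures, and bivariate-normal telemetry fixes for collared
individuals.  Everything is reproducible from ``SimTruth.seed`` and can be
round-tripped through the CSV dialects of :mod:`carnidens.survey`.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StateSpace, make_state_space, preliminary_buffer
from .survey import (DeviceTable, EffortMatrix, EncounterData, OccasionGrid,
                     TelemetryData, build_behavior_matrix, bin_occasions,
                     build_effort)

DEFAULT_SURVEY_START = date(2013, 1, 15)


@dataclass
class SimTruth:
    """True parameter values of a simulated survey."""

    N: int = 40
    sigma: float = 400.0                     # m
    alpha0: float = math.log(0.05)           # log baseline rate per device-day
    b1: float = 0.0                          # behavioural response (Lb)
    b2: float = 0.0                          # device type (camera vs trap)
    b3: float = 0.0                          # occasion trend
    marked_fraction: float = 1.0
    removal_prob: float = 0.0                # per live-trap capture
    n_collared: int = 0
    telemetry_n_locs: int = 25
    species: str = "species_a"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.marked_fraction <= 1.0:
            raise ValueError("marked_fraction must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class SimulatedSurvey:
    """A complete simulated survey plus its generating truth."""

    truth: SimTruth
    devices: DeviceTable
    grid: OccasionGrid
    effort: EffortMatrix
    space: StateSpace
    centres: np.ndarray              # (N, 2) true activity centres
    scr: EncounterData               # truth-level SCR-complete data (all N)
    enc: EncounterData               # analysis-ready data (SCR/SMR/SC)
    marked_ids: list = field(default_factory=list)
    removals: dict = field(default_factory=dict)   # ind id -> removal day
    telemetry: list = field(default_factory=list)


def simulate_landscape(n_cameras: int = 66, n_traps: int = 69,
                       spacing_m: float = 500.0, n_days: int = 98,
                       survey_start: date = DEFAULT_SURVEY_START,
                       camera_downtime_prob: float = 0.5,
                       seed: int = 0) -> DeviceTable:
    """Regular camera grid with interleaved live traps and operation logs.

    Cameras sit on a ``spacing_m`` grid and run all survey long except that
    with probability ``camera_downtime_prob`` a camera loses one contiguous
    block of 20-46 days (study-like ~83% uptime); traps operate one short
    burst of 14-28 days each (~21% uptime), as in live-capture campaigns.
    """
    if n_cameras < 0 or n_traps < 0 or n_cameras + n_traps == 0:
        raise ValueError("need a positive number of devices")
    rng = np.random.default_rng(seed)
    ids, xy, cls = [], [], []
    ncol = max(1, math.ceil(math.sqrt(2.0 * n_cameras)))
    for i in range(n_cameras):
        r, c = divmod(i, ncol)
        ids.append(f"cam{i:03d}")
        xy.append((c * spacing_m, r * spacing_m))
        cls.append("camera")
    ncol_t = max(1, math.ceil(math.sqrt(2.0 * n_traps)))
    for i in range(n_traps):
        r, c = divmod(i, ncol_t)
        ids.append(f"trap{i:03d}")
        xy.append((c * spacing_m + spacing_m / 2.0,
                   r * spacing_m + spacing_m / 2.0))
        cls.append("trap")

    operation = np.zeros((len(ids), n_days), dtype=bool)
    for j in range(n_cameras):
        operation[j, :] = True
        if rng.random() < camera_downtime_prob:
            length = int(rng.integers(20, 47))
            start = int(rng.integers(0, max(n_days - length, 1)))
            operation[j, start:start + length] = False
    for j in range(n_cameras, len(ids)):
        length = min(int(rng.integers(14, 29)), n_days)
        start = int(rng.integers(0, n_days - length + 1))
        operation[j, start:start + length] = True
    # keep the overall window anchored: first and last day must be covered
    if n_cameras == 0 and len(ids) > 0:
        operation[0, 0] = True
        operation[-1, n_days - 1] = True
    return DeviceTable(ids=ids, xy=np.asarray(xy, dtype=float),
                       device_class=np.asarray(cls), survey_start=survey_start,
                       operation=operation)


def simulate_population(space: StateSpace, truth: SimTruth,
                        rng=None) -> np.ndarray:
    """N_true activity centres iid uniform on the state space."""
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    x = rng.uniform(space.xmin, space.xmax, truth.N)
    y = rng.uniform(space.ymin, space.ymax, truth.N)
    return np.column_stack([x, y])


def simulate_encounters(centres: np.ndarray, devices: DeviceTable,
                        effort: EffortMatrix, truth: SimTruth,
                        grid: OccasionGrid | None = None,
                        rng=None) -> tuple[EncounterData, dict]:
    """Draw SCR-complete Poisson encounter histories for every individual.

    Counts are generated occasion by occasion so the behavioural covariate
    (prior capture anywhere) and live-trap removals feed forward: an
    individual captured at a trap is extracted with ``truth.removal_prob``,
    stays at risk through that occasion, and is dead afterwards.

    Returns the encounter data (all N rows) and {individual_id: removal day}.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    e = effort.e
    J, K = e.shape
    if grid is None:
        grid = bin_occasions(devices.n_days, effort.occasion_length,
                             survey_start=devices.survey_start)
    N = centres.shape[0]
    d2 = ((centres[:, None, :] - devices.xy[None, :, :]) ** 2).sum(-1)
    kern = np.exp(-d2 / (2.0 * truth.sigma ** 2))
    tt = devices.tt
    tcov = grid.t_covariate
    is_trap = devices.device_class == "trap"

    ids = [f"{truth.species}_{i:03d}" for i in range(N)]
    y = np.zeros((N, J, K), dtype=np.int64)
    dead = np.zeros((N, K), dtype=np.int8)
    captured_before = np.zeros(N, dtype=bool)
    removals: dict = {}
    for k in range(K):
        alive = 1.0 - dead[:, k]
        lam0 = np.exp(truth.alpha0
                      + truth.b1 * captured_before[:, None]
                      + truth.b2 * tt[None, :]
                      + truth.b3 * tcov[k])
        mu = alive[:, None] * lam0 * kern * e[None, :, k]
        y[:, :, k] = rng.poisson(mu)
        trapped = (y[:, is_trap, k].sum(axis=1) > 0) & (dead[:, k] == 0)
        for i in np.flatnonzero(trapped):
            if truth.removal_prob > 0 and rng.random() < truth.removal_prob:
                dead[i, k + 1:] = 1
                days = [d for d in grid.occasion_days(k)]
                removals[ids[i]] = int(rng.choice(days))
        captured_before |= y[:, :, k].sum(axis=1) > 0

    enc = EncounterData(
        model_class="SCR", y=y, n=np.zeros((J, K), dtype=np.int64),
        dead=dead, Lb=np.zeros((N, K), dtype=np.int8),
        tt=tt, t=tcov, effort=e, device_xy=devices.xy,
        individual_ids=ids, species=truth.species,
    )
    enc.Lb = build_behavior_matrix(enc)
    return enc, removals


def observed_subset(enc: EncounterData) -> EncounterData:
    """Restrict SCR data to the individuals actually detected."""
    seen = enc.y.sum(axis=(1, 2)) > 0
    idx = np.flatnonzero(seen)
    return EncounterData(
        model_class=enc.model_class, y=enc.y[idx], n=enc.n,
        dead=enc.dead[idx], Lb=enc.Lb[idx], tt=enc.tt, t=enc.t,
        effort=enc.effort, device_xy=enc.device_xy,
        individual_ids=[enc.individual_ids[i] for i in idx],
        species=enc.species,
    )


def degrade_to_smr(scr_data: EncounterData, marked_fraction: float,
                   seed: int = 0) -> tuple[EncounterData, list]:
    """Collapse a uniform random subset of individuals into unmarked counts.

    Individuals with a removal record are always kept marked (a removal
    implies the animal was physically captured, hence identifiable); the rest
    of the marked subset is a uniform draw.  Marked individuals keep their
    identified histories ``y`` (including all-zero ones: marked animals are
    known even when never resighted); everyone else's counts collapse into
    the device-by-occasion totals ``n``.  Total event count is conserved.
    Returns (encounter data, marked individual ids); the result is SC when no
    individual stays marked.
    """
    if not 0.0 <= marked_fraction <= 1.0:
        raise ValueError("marked_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    N = scr_data.n_identified
    forced = np.zeros(N, dtype=bool)
    if scr_data.dead.size:
        forced = scr_data.dead.any(axis=1)
    n_marked = int(round(marked_fraction * N))
    marked = forced.copy()
    pool = np.flatnonzero(~forced)
    extra = max(n_marked - int(forced.sum()), 0)
    if extra > 0 and pool.size:
        marked[rng.choice(pool, size=min(extra, pool.size), replace=False)] = True

    midx = np.flatnonzero(marked)
    uidx = np.flatnonzero(~marked)
    n = scr_data.n + scr_data.y[uidx].sum(axis=0)
    if midx.size == 0:
        enc = EncounterData(
            model_class="SC", y=np.zeros((0,) + scr_data.n.shape, np.int64),
            n=n, dead=np.zeros((0, scr_data.n_occasions), np.int8),
            Lb=np.zeros((0, scr_data.n_occasions), np.int8),
            tt=scr_data.tt, t=scr_data.t, effort=scr_data.effort,
            device_xy=scr_data.device_xy, individual_ids=[],
            species=scr_data.species)
        return enc, []
    y = scr_data.y[midx]
    enc = EncounterData(
        model_class="SCR" if marked_fraction >= 1.0 else "SMR",
        y=y, n=n if marked_fraction < 1.0 else np.zeros_like(n),
        dead=scr_data.dead[midx], Lb=scr_data.Lb[midx],
        tt=scr_data.tt, t=scr_data.t, effort=scr_data.effort,
        device_xy=scr_data.device_xy,
        individual_ids=[scr_data.individual_ids[i] for i in midx],
        species=scr_data.species)
    return enc, [scr_data.individual_ids[i] for i in midx]


def simulate_telemetry(centre, sigma_true: float, n_locs: int = 25,
                       seed: int = 0, individual_id: str = "collared",
                       rng=None) -> TelemetryData:
    """Bivariate-normal fixes around an activity centre (per-axis sd sigma)."""
    if n_locs < 1:
        raise ValueError("need at least one location")
    rng = rng if rng is not None else np.random.default_rng(seed)
    centre = np.asarray(centre, dtype=float)
    locs = centre + sigma_true * rng.standard_normal((n_locs, 2))
    return TelemetryData(individual_id=individual_id, locations=locs)


def simulate_survey(truth: SimTruth, n_cameras: int = 66, n_traps: int = 69,
                    spacing_m: float = 500.0, n_days: int = 98,
                    occasion_length: int = 7,
                    buffer_m: float | None = None,
                    devices: DeviceTable | None = None) -> SimulatedSurvey:
    """End-to-end simulation: landscape, population, encounters, degradation.

    ``marked_fraction = 1`` yields SCR data restricted to the detected
    individuals, ``0 < f < 1`` spatial mark-resight, ``f = 0`` spatial counts.
    The state space buffers the device box by 3 x true sigma by default.
    """
    if devices is None:
        devices = simulate_landscape(n_cameras, n_traps, spacing_m, n_days,
                                     seed=truth.seed)
    grid = bin_occasions(devices.n_days, occasion_length,
                         survey_start=devices.survey_start)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")     # silent about all-off devices
        effort = build_effort(devices, grid)
    if buffer_m is None:
        buffer_m = preliminary_buffer(truth.sigma, 3.0)
    space = make_state_space(devices, buffer_m)
    rng = np.random.default_rng(truth.seed)
    centres = simulate_population(space, truth, rng=rng)
    scr, removals = simulate_encounters(centres, devices, effort, truth,
                                        grid=grid, rng=rng)
    if truth.marked_fraction >= 1.0:
        enc = observed_subset(scr)
        marked_ids = list(enc.individual_ids)
    else:
        enc, marked_ids = degrade_to_smr(scr, truth.marked_fraction,
                                         seed=truth.seed + 1)
    telemetry = []
    if truth.n_collared > 0 and marked_ids:
        collared = marked_ids[: truth.n_collared]
        for cid in collared:
            i = scr.individual_ids.index(cid)
            telemetry.append(simulate_telemetry(
                centres[i], truth.sigma, truth.telemetry_n_locs,
                individual_id=cid, rng=rng))
    return SimulatedSurvey(truth=truth, devices=devices, grid=grid,
                           effort=effort, space=space, centres=centres,
                           scr=scr, enc=enc, marked_ids=marked_ids,
                           removals=removals, telemetry=telemetry)


# ---------------------------------------------------------------------------
# fixture serialisation (CSV dialects of carnidens.survey)
# ---------------------------------------------------------------------------

def _operation_to_windows(op_row: np.ndarray, start: date):
    """Encode a daily on/off log as (active_from, active_to, downtime)."""
    on = np.flatnonzero(op_row)
    if on.size == 0:
        raise ValueError("cannot serialise an all-off device")
    a_from, a_to = int(on[0]), int(on[-1])
    gaps = []
    run = None
    for d in range(a_from, a_to + 1):
        if not op_row[d]:
            run = [d, d] if run is None else [run[0], d]
        elif run is not None:
            gaps.append(tuple(run))
            run = None
    if run is not None:
        gaps.append(tuple(run))
    fmt = lambda d: (start + timedelta(days=d)).isoformat()
    downtime = ";".join(f"{fmt(lo)}:{fmt(hi)}" for lo, hi in gaps)
    return fmt(a_from), fmt(a_to), downtime


def _schedule_events(enc: EncounterData, devices: DeviceTable,
                     grid: OccasionGrid, rng) -> pd.DataFrame:
    """Place simulated counts as timestamped events, >= 31 min apart within
    each (device, species, individual-or-unmarked) stream so the
    independence filter is exercised but lossless."""
    start = devices.survey_start
    rows = []

    def _times(j, k, c):
        days = [d for d in grid.occasion_days(k) if devices.operation[j, d]]
        # round-robin over operative days; 46 half-hour-spaced slots per day
        per_day = np.zeros(len(days), dtype=int)
        for q in range(c):
            per_day[q % len(days)] += 1
        if per_day.max() > 46:
            raise ValueError("too many events to schedule independently")
        order = rng.permutation(len(days))
        for pos in order:
            cd = int(per_day[pos])
            if cd == 0:
                continue
            d = days[pos]
            base = rng.uniform(0, 24 * 60 - 31.0 * cd)
            for q in range(cd):
                yield (pd.Timestamp(start + timedelta(days=d))
                       + pd.Timedelta(minutes=float(base + 31.0 * q)))

    for i in range(enc.n_identified):
        jj, kk = np.nonzero(enc.y[i])
        for j, k in zip(jj, kk):
            for ts in _times(j, k, int(enc.y[i, j, k])):
                rows.append((devices.ids[j], ts.isoformat(), enc.species,
                             enc.individual_ids[i], True, 1))
    jj, kk = np.nonzero(enc.n)
    for j, k in zip(jj, kk):
        for ts in _times(j, k, int(enc.n[j, k])):
            rows.append((devices.ids[j], ts.isoformat(), enc.species,
                         "", False, 1))
    df = pd.DataFrame(rows, columns=["device_id", "timestamp", "species",
                                     "individual_id", "marked", "n_animals"])
    return df.sort_values(["timestamp", "device_id"],
                          kind="stable").reset_index(drop=True)


def write_fixture(sim, out_dir) -> dict:
    """Serialise one or several simulated surveys (shared landscape) to the
    CSV dialects plus ``truth.json``; reading the files back reproduces the
    simulated arrays exactly.  Returns the written paths."""
    sims = sim if isinstance(sim, (list, tuple)) else [sim]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    devices = sims[0].devices
    start = devices.survey_start

    dev_rows = []
    for j, did in enumerate(devices.ids):
        a_from, a_to, downtime = _operation_to_windows(
            devices.operation[j], start)
        dev_rows.append((did, devices.xy[j, 0], devices.xy[j, 1],
                         devices.device_class[j], a_from, a_to, downtime))
    dev_df = pd.DataFrame(dev_rows, columns=[
        "device_id", "x", "y", "class", "active_from", "active_to",
        "downtime_ranges"])

    events, marks, tel_rows, truths = [], [], [], {}
    for s in sims:
        rng = np.random.default_rng(s.truth.seed + 104729)
        events.append(_schedule_events(s.enc, devices, s.grid, rng))
        for ind in s.enc.individual_ids:
            rd = s.removals.get(ind)
            marks.append((ind, s.enc.species, start.isoformat(),
                          (start + timedelta(days=rd)).isoformat()
                          if rd is not None else ""))
        for td in s.telemetry:
            for L in range(td.n_locations):
                ts = pd.Timestamp(start) + pd.Timedelta(days=3 * L)
                tel_rows.append((td.individual_id, ts.isoformat(),
                                 td.locations[L, 0], td.locations[L, 1]))
        truths[s.enc.species] = {
            **dataclasses.asdict(s.truth),
            "model_class": s.enc.model_class,
            "marked_ids": s.marked_ids,
            "area_km2": s.space.area_km2,
        }

    paths = {
        "devices": out / "devices.csv",
        "events": out / "events.csv",
        "marks": out / "marks.csv",
        "telemetry": out / "telemetry.csv",
        "truth": out / "truth.json",
    }
    dev_df.to_csv(paths["devices"], index=False)
    pd.concat(events, ignore_index=True).to_csv(paths["events"], index=False)
    pd.DataFrame(marks, columns=["individual_id", "species", "mark_date",
                                 "removal_date"]).to_csv(paths["marks"],
                                                         index=False)
    pd.DataFrame(tel_rows, columns=["individual_id", "timestamp", "x", "y"]
                 ).to_csv(paths["telemetry"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    return paths


def paper_like_preset(seed: int = 7) -> list[SimulatedSurvey]:
    """Six-species community preset mirroring a Mediterranean carnivore
    survey: shared 135-device landscape, 14 weekly occasions, one SCR
    species with removals, four mark-resight species and one count-only
    species, at low densities (~0.1-0.45 individuals/km^2)."""
    devices = simulate_landscape(seed=seed)
    configs = [
        SimTruth(N=16, marked_fraction=0.25, b2=2.0, species="red_fox",
                 n_collared=2, seed=seed + 11),
        SimTruth(N=10, marked_fraction=0.0, b2=2.0, species="egyptian_mongoose",
                 seed=seed + 12),
        SimTruth(N=10, marked_fraction=1.0, removal_prob=0.5,
                 species="feral_cat", seed=seed + 13),
        SimTruth(N=9, marked_fraction=0.4, b2=2.0, species="stone_marten",
                 seed=seed + 14),
        SimTruth(N=5, marked_fraction=0.2, species="badger",
                 n_collared=1, seed=seed + 15),
        SimTruth(N=3, marked_fraction=0.6, species="common_genet",
                 n_collared=1, seed=seed + 16),
    ]
    return [simulate_survey(t, devices=devices) for t in configs]
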