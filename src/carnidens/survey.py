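"""Reading, validation and transformation of raw survey tables.

The pipeline starts from four plain-CSV tables (all UTF-8, header required):

* ``devices.csv`` — ``device_id,x,y,class,active_from,active_to[,downtime_ranges]``
  with coordinates in projected metres, ``class`` in {camera, trap}, and
  optional downtime ranges as ``YYYY-MM-DD:YYYY-MM-DD`` pairs separated by
  ``;`` (inclusive on both ends).
* ``events.csv`` — ``device_id,timestamp,species,individual_id,marked,n_animals``;
  one row per picture/capture, ``individual_id`` empty iff the animal could
  not be identified, ``n_animals`` the number of animals in the picture.
* ``marks.csv`` — ``individual_id,species,mark_date,removal_date`` (removal
  date empty if the animal was never extracted).
* ``telemetry.csv`` — ``individual_id,timestamp,x,y`` VHF/GPS fixes.

From these the module produces the model-ready arrays: weekly-occasion
effort (days each device operated per occasion), identified encounter counts
``y[i, j, k]``, unidentified counts ``n[j, k]``, the removal matrix
``dead[i, k]`` and the prior-capture behaviour matrix ``Lb[i, k]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

DEVICE_CLASSES = ("camera", "trap")
MODEL_CLASSES = ("SCR", "SMR", "SC")

#: minimum telemetry fixes recommended per collared individual
MIN_TELEMETRY_LOCS = 25


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DeviceTable:
    """Deployed survey devices with per-calendar-day operation logs."""

    ids: list
    xy: np.ndarray                 # (J, 2) projected metres
    device_class: np.ndarray       # (J,) str in DEVICE_CLASSES
    survey_start: date
    operation: np.ndarray          # (J, n_days) bool

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.operation = np.asarray(self.operation, dtype=bool)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate device_id")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-numeric or non-finite device coordinates")
        bad = set(self.device_class) - set(DEVICE_CLASSES)
        if bad:
            raise ValueError(f"unknown device_class: {sorted(bad)}")
        if self.operation.shape[0] != len(self.ids):
            raise ValueError("operation log row count != device count")

    @property
    def n_devices(self) -> int:
        return len(self.ids)

    @property
    def n_days(self) -> int:
        return self.operation.shape[1]

    @property
    def tt(self) -> np.ndarray:
        """Binary device covariate: 1 for cameras, 0 for live traps."""
        return (self.device_class == "camera").astype(float)

    def index_of(self, device_id) -> int:
        return self.ids.index(device_id)


@dataclass(frozen=True)
class OccasionGrid:
    """Sequential binning of the survey window into equal-length occasions."""

    survey_days: int
    occasion_length: int = 7
    survey_start: date | None = None

    def __post_init__(self) -> None:
        if self.survey_days < 1:
            raise ValueError("survey_days must be >= 1")
        if self.occasion_length < 1:
            raise ValueError("occasion_length must be >= 1")

    @property
    def n_occasions(self) -> int:
        return math.ceil(self.survey_days / self.occasion_length)

    def occasion_of_day(self, day_index: int) -> int:
        """0-based occasion containing a 0-based day offset from survey start."""
        if not 0 <= day_index < self.survey_days:
            raise ValueError(f"day index {day_index} outside survey window")
        return day_index // self.occasion_length

    def occasion_days(self, k: int) -> range:
        start = k * self.occasion_length
        return range(start, min(start + self.occasion_length, self.survey_days))

    @property
    def t_covariate(self) -> np.ndarray:
        """Standardised linear occasion trend t[k] (zero mean, unit sd)."""
        k = np.arange(self.n_occasions, dtype=float)
        if self.n_occasions < 2:
            return np.zeros_like(k)
        return (k - k.mean()) / k.std(ddof=0)


@dataclass
class EffortMatrix:
    """e[j, k]: days device j operated within occasion k."""

    e: np.ndarray
    occasion_length: int = 7

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        if np.any(self.e < 0) or np.any(self.e > self.occasion_length):
            raise ValueError("effort outside [0, occasion_length]")


@dataclass
class EncounterData:
    """Model-ready encounter arrays for one species.

    ``y[i, j, k]`` are counts for identified (marked/recognisable)
    individuals, ``n[j, k]`` counts of unidentified events; ``dead[i, k]`` is
    1 from the first occasion an extracted individual is no longer at risk.
    """

    model_class: str
    y: np.ndarray            # (m, J, K) int
    n: np.ndarray            # (J, K) int
    dead: np.ndarray         # (m, K) int8
    Lb: np.ndarray           # (m, K) int8
    tt: np.ndarray           # (J,)
    t: np.ndarray            # (K,)
    effort: np.ndarray       # (J, K) days
    device_xy: np.ndarray    # (J, 2)
    individual_ids: list = field(default_factory=list)
    species: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.validate()

    @property
    def n_identified(self) -> int:
        return self.y.shape[0]

    @property
    def n_devices(self) -> int:
        return self.n.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.n.shape[1]

    def validate(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model_class {self.model_class!r}")
        if self.model_class == "SCR" and self.n.any():
            raise ValueError("SCR data must have no unidentified counts")
        if self.model_class == "SC" and self.y.size:
            raise ValueError("SC data must have no identified individuals")
        if np.any(self.y < 0) or np.any(self.n < 0):
            raise ValueError("negative counts")
        # no counts where the device never operated
        zero_eff = self.effort == 0
        if np.any(self.n[zero_eff] > 0) or np.any(self.y[:, zero_eff] > 0):
            raise ValueError("counts recorded where effort is zero")
        # dead must be monotone along occasions, and no detections once dead
        if self.dead.size:
            if np.any(np.diff(self.dead.astype(int), axis=1) < 0):
                raise ValueError("dead matrix must be monotone along occasions")
            after = self.y * self.dead[:, None, :]
            if after.any():
                raise ValueError("identified event recorded after removal")

    def total_events(self) -> int:
        return int(self.y.sum() + self.n.sum())


@dataclass
class TelemetryData:
    """Telemetry fixes for one collared individual."""

    individual_id: str
    locations: np.ndarray    # (L, 2) metres

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        if self.locations.shape[0] < 1:
            raise ValueError("telemetry needs at least one location")
        if self.locations.shape[0] < MIN_TELEMETRY_LOCS:
            warnings.warn(
                f"individual {self.individual_id!r} has only "
                f"{self.locations.shape[0]} telemetry locations "
                f"(< {MIN_TELEMETRY_LOCS} recommended)",
                stacklevel=2,
            )

    @property
    def n_locations(self) -> int:
        return self.locations.shape[0]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_date(x) -> date:
    if isinstance(x, date) and not isinstance(x, datetime):
        return x
    return pd.Timestamp(x).date()


def read_device_table(path) -> DeviceTable:
    """Read ``devices.csv`` and expand activity windows into daily on/off logs.

    The survey window spans min(active_from)..max(active_to) over all
    devices; days outside a device's own activity window, and any days in
    its ``downtime_ranges``, are marked non-operative.
    """
    try:
        df = pd.read_csv(path, dtype={"device_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError("no devices") from None
    if df.empty:
        raise ValueError("no devices")
    required = {"device_id", "x", "y", "class", "active_from", "active_to"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"devices table missing columns: {sorted(missing)}")
    if df["device_id"].duplicated().any():
        dups = df.loc[df["device_id"].duplicated(), "device_id"].tolist()
        raise ValueError(f"duplicate device_id: {dups}")
    xy = df[["x", "y"]].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(xy)):
        raise ValueError("non-numeric device coordinates")

    a_from = df["active_from"].map(_parse_date)
    a_to = df["active_to"].map(_parse_date)
    start = min(a_from)
    n_days = (max(a_to) - start).days + 1
    operation = np.zeros((len(df), n_days), dtype=bool)
    for r in range(len(df)):
        d0 = (a_from.iloc[r] - start).days
        d1 = (a_to.iloc[r] - start).days
        operation[r, d0:d1 + 1] = True
        ranges = df["downtime_ranges"].iloc[r] if "downtime_ranges" in df else None
        if isinstance(ranges, str) and ranges.strip():
            for rng in ranges.split(";"):
                lo, hi = rng.split(":")
                i0 = (_parse_date(lo) - start).days
                i1 = (_parse_date(hi) - start).days
                operation[r, max(i0, 0):i1 + 1] = False
    return DeviceTable(
        ids=df["device_id"].tolist(),
        xy=xy,
        device_class=df["class"].str.strip().str.lower().to_numpy(),
        survey_start=start,
        operation=operation,
    )


def read_event_table(path, devices: DeviceTable | None = None) -> pd.DataFrame:
    """Read ``events.csv`` into a validated event DataFrame."""
    df = pd.read_csv(path, dtype={"device_id": str, "individual_id": str})
    required = {"device_id", "timestamp", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if "individual_id" not in df:
        df["individual_id"] = pd.NA
    if "marked" not in df:
        df["marked"] = df["individual_id"].notna()
    df["marked"] = df["marked"].astype(bool)
    if "n_animals" not in df:
        df["n_animals"] = 1
    df["n_animals"] = df["n_animals"].astype(int)
    if (df["n_animals"] < 1).any():
        raise ValueError("n_animals must be a positive integer")
    if devices is not None:
        unknown = set(df["device_id"]) - set(devices.ids)
        if unknown:
            raise ValueError(f"events at unlisted devices: {sorted(unknown)}")
        end = devices.survey_start + timedelta(days=devices.n_days)
        ts = df["timestamp"]
        if ((ts < pd.Timestamp(devices.survey_start)) | (ts >= pd.Timestamp(end))).any():
            raise ValueError("event timestamps outside survey window")
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def read_marks_table(path) -> pd.DataFrame:
    """Read ``marks.csv`` (marked-individual registry with removal dates)."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = {"individual_id", "species", "mark_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marks table missing columns: {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        raise ValueError("duplicate individual_id in marks table")
    df["mark_date"] = pd.to_datetime(df["mark_date"]).dt.date
    if "removal_date" in df:
        df["removal_date"] = pd.to_datetime(df["removal_date"]).dt.date
    else:
        df["removal_date"] = pd.NaT
    return df


def read_telemetry_table(path) -> list[TelemetryData]:
    """Read ``telemetry.csv`` into per-individual fix sets."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = {"individual_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"telemetry table missing columns: {sorted(missing)}")
    out = []
    for ind, grp in df.groupby("individual_id", sort=True):
        out.append(TelemetryData(ind, grp[["x", "y"]].to_numpy(float)))
    return out


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def _stream_key(row) -> tuple:
    ind = row["individual_id"]
    if pd.isna(ind):
        ind = "__unmarked__"
    return (row["device_id"], row["species"], ind)


def filter_independent_events(events: pd.DataFrame,
                              window_minutes: float = 30.0) -> pd.DataFrame:
    """Keep only temporally independent events within each detection stream.

    A stream is (device, species, individual-or-unmarked).  Within a stream,
    a row is retained iff its timestamp exceeds the *last retained* row's by
    strictly more than ``window_minutes`` (the first row is always kept).
    Anchoring on the last retained row makes the filter idempotent.  A
    retained row with ``n_animals = c`` represents c independent events (one
    per animal in the picture).
    """
    if events.empty:
        return events.copy()
    window = pd.Timedelta(minutes=window_minutes)
    df = events.sort_values("timestamp", kind="stable")
    keep = np.zeros(len(df), dtype=bool)
    pos = {k: p for p, k in enumerate(df.columns)}
    last: dict[tuple, pd.Timestamp] = {}
    for ridx, row in enumerate(df.itertuples(index=False)):
        ind = row[pos["individual_id"]]
        key = (row[pos["device_id"]], row[pos["species"]],
               "__unmarked__" if pd.isna(ind) else ind)
        ts = row[pos["timestamp"]]
        if key not in last or ts - last[key] > window:
            keep[ridx] = True
            last[key] = ts
    return df.loc[keep].reset_index(drop=True)


def n_events(events: pd.DataFrame) -> int:
    """Number of independent events represented by an event table."""
    if events.empty:
        return 0
    return int(events["n_animals"].sum()) if "n_animals" in events else len(events)


def bin_occasions(survey_days: int, occasion_length: int = 7,
                  survey_start: date | None = None) -> OccasionGrid:
    """Bin a survey window into sequential occasions (last may be short)."""
    return OccasionGrid(survey_days=int(survey_days),
                        occasion_length=int(occasion_length),
                        survey_start=survey_start)


def build_effort(devices: DeviceTable, grid: OccasionGrid) -> EffortMatrix:
    """Count operative days of each device within each occasion."""
    if devices.n_days < grid.survey_days:
        raise ValueError("operation logs do not cover the occasion grid")
    K = grid.n_occasions
    e = np.zeros((devices.n_devices, K), dtype=float)
    for k in range(K):
        days = grid.occasion_days(k)
        e[:, k] = devices.operation[:, days.start:days.stop].sum(axis=1)
    silent = np.flatnonzero(e.sum(axis=1) == 0)
    for j in silent:
        warnings.warn(f"device {devices.ids[j]!r} was never operative; "
                      "retained with zero effort", stacklevel=2)
    return EffortMatrix(e=e, occasion_length=grid.occasion_length)


def build_encounter_data(events: pd.DataFrame, devices: DeviceTable,
                         grid: OccasionGrid, marks: pd.DataFrame | None,
                         model_class: str, species: str | None = None,
                         effort: EffortMatrix | None = None) -> EncounterData:
    """Accumulate filtered events into model-ready encounter arrays.

    Identified events (non-null ``individual_id``) go into ``y``; events of
    unidentifiable animals into ``n``.  An individual with a removal date is
    at risk through the occasion containing that date and ``dead`` from the
    next occasion on; identified events after that are an error.
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"unknown model_class {model_class!r}")
    ev = events
    if species is not None:
        ev = ev[ev["species"] == species]
    elif len(ev) and ev["species"].nunique() > 1:
        raise ValueError("events contain multiple species; pass species=")
    else:
        species = ev["species"].iloc[0] if len(ev) else ""

    unknown = set(ev["device_id"]) - set(devices.ids)
    if unknown:
        raise ValueError(f"event at unlisted device: {sorted(unknown)}")

    if effort is None:
        effort = build_effort(devices, grid)
    J, K = devices.n_devices, grid.n_occasions
    dev_index = {d: j for j, d in enumerate(devices.ids)}
    start = pd.Timestamp(devices.survey_start)

    # universe of identified individuals: registry first, then any extra ids
    reg = marks
    if reg is not None and species:
        reg = reg[reg["species"] == species]
    ids: list[str] = list(reg["individual_id"]) if reg is not None else []
    ev_ids = [i for i in ev["individual_id"].dropna().unique() if i not in ids]
    ids = ids + sorted(ev_ids)
    if model_class == "SC":
        ids = []  # identity is discarded: every event is a latent-history count
    ind_index = {i: r for r, i in enumerate(ids)}
    m = len(ids)

    dead = np.zeros((m, K), dtype=np.int8)
    if reg is not None:
        for _, row in reg.iterrows():
            rd = row["removal_date"]
            if pd.isna(rd) or row["individual_id"] not in ind_index:
                continue
            day = (pd.Timestamp(rd) - start).days
            day = min(max(day, 0), grid.survey_days - 1)
            k_rm = grid.occasion_of_day(day)
            dead[ind_index[row["individual_id"]], k_rm + 1:] = 1

    y = np.zeros((m, J, K), dtype=np.int64)
    n = np.zeros((J, K), dtype=np.int64)
    for row in ev.itertuples(index=False):
        j = dev_index[row.device_id]
        day = (row.timestamp - start).days
        k = grid.occasion_of_day(day)
        c = int(getattr(row, "n_animals", 1))
        if model_class == "SC" or pd.isna(row.individual_id):
            if model_class == "SCR":
                raise ValueError("SCR data cannot contain unidentified events")
            n[j, k] += c
        else:
            i = ind_index[row.individual_id]
            if dead[i, k]:
                raise ValueError(
                    f"identified event for {row.individual_id!r} after removal")
            y[i, j, k] += c

    enc = EncounterData(
        model_class=model_class, y=y, n=n, dead=dead,
        Lb=np.zeros((m, K), dtype=np.int8),
        tt=devices.tt, t=grid.t_covariate, effort=effort.e,
        device_xy=devices.xy, individual_ids=ids, species=species or "",
    )
    if model_class != "SC":
        enc.Lb = build_behavior_matrix(enc)
    return enc


def build_behavior_matrix(encounter: EncounterData) -> np.ndarray:
    """Prior-capture behaviour matrix: Lb[i, k] = 1 iff i was caught before k.

    Defined from capture *anywhere* (a global behavioural response), so the
    matrix is constant across devices and broadcast over j in the model.
    """
    if encounter.model_class == "SC":
        raise ValueError("behaviour covariate requires identified individuals")
    caught = encounter.y.sum(axis=1) > 0            # (m, K) any device
    Lb = np.zeros_like(caught, dtype=np.int8)
    if caught.shape[1] > 1:
        Lb[:, 1:] = np.cumsum(caught[:, :-1], axis=1) > 0
    return Lb
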