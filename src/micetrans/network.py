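"""Co-detection social networks from RFID logger streams.

Raw detections (individual, logger, timestamp) are filtered to the
nocturnal activity window, deduplicated to unique minutes, binned into
logging nights, and turned into a lifespan-adjusted simple-ratio-index
(SRI) association network:

    adjusted SRI = X / (X + y_AB + y_A + y_B)

where, over the nights both individuals were known alive, X counts
nights with a same-logger detection pair within ``window_h`` hours,
y_AB counts nights where both were observed but not associated, and
y_A / y_B count nights where only one of them was observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Start hour of a logging night (inclusive).
NIGHT_START_HOUR = 16
#: End hour of a logging night (exclusive).
NIGHT_END_HOUR = 8

_COLUMN_ALIASES = {"tag_id": "individual", "logger_id": "logger", "mouse": "individual"}


def read_detections(path) -> pd.DataFrame:
    """Read a detections CSV with columns tag_id/logger_id/timestamp."""
    df = pd.read_csv(path)
    df = df.rename(columns=_COLUMN_ALIASES)
    missing = {"individual", "logger", "timestamp"} - set(df.columns)
    if missing:
        raise ValueError(f"detections file {path} missing columns: {sorted(missing)}")
    return df


class DetectionParseError(ValueError):
    """A detection record could not be parsed; carries the row number."""

    def __init__(self, row: int, value):
        self.row = row
        super().__init__(f"unparseable timestamp at row {row}: {value!r}")


def filter_detections(raw: pd.DataFrame) -> pd.DataFrame:
    """Restrict detections to the activity window and unique minutes.

    Keeps records with wall-clock time in [16:00, 08:00), deduplicates to
    one record per (individual, logger, calendar minute) and assigns each
    record a ``night`` (the calendar date of the 16:00 boundary it
    follows, so a 02:00 record on date d belongs to night d-1).
    """
    df = raw.copy()
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise DetectionParseError(bad, df["timestamp"].iloc[bad])
    df["timestamp"] = ts
    in_window = (ts.dt.hour >= NIGHT_START_HOUR) | (ts.dt.hour < NIGHT_END_HOUR)
    df = df.loc[in_window].copy()
    df["minute"] = df["timestamp"].dt.floor("min")
    df = df.drop_duplicates(subset=["individual", "logger", "minute"])
    df["night"] = (df["timestamp"] - pd.Timedelta(hours=NIGHT_END_HOUR)).dt.normalize()
    return df.drop(columns="minute").reset_index(drop=True)


@dataclass(frozen=True)
class AliveWindows:
    """Per-individual first/last known-alive nights."""

    windows: dict  # individual -> (first_night, last_night) as pd.Timestamp

    def __post_init__(self):
        for ind, (first, last) in self.windows.items():
            if first > last:
                raise ValueError(f"alive window for {ind}: first {first} > last {last}")

    @classmethod
    def from_detections(cls, filtered: pd.DataFrame) -> "AliveWindows":
        """Default windows: [first detection night, last detection night]."""
        grouped = filtered.groupby("individual")["night"].agg(["min", "max"])
        return cls({ind: (row["min"], row["max"]) for ind, row in grouped.iterrows()})

    def alive_on(self, individual, night) -> bool:
        if individual not in self.windows:
            return False
        first, last = self.windows[individual]
        return first <= night <= last

    @property
    def individuals(self):
        return list(self.windows)


@dataclass(frozen=True)
class AssociationTally:
    """Per-pair night classification counts."""

    x: int
    y_ab: int
    y_a: int
    y_b: int

    def __post_init__(self):
        if min(self.x, self.y_ab, self.y_a, self.y_b) < 0:
            raise ValueError("tally counts must be non-negative")


def adjusted_sri(t) -> float:
    """X / (X + y_AB + y_A + y_B); 0.0 on an empty denominator."""
    denom = t.x + t.y_ab + t.y_a + t.y_b
    if t.x < 0 or t.y_ab < 0 or t.y_a < 0 or t.y_b < 0:
        raise ValueError("negative tally")
    if denom == 0:
        return 0.0
    return t.x / denom


@dataclass
class AssociationMatrix:
    """Symmetric adjusted-SRI matrix with its tally components."""

    ids: list
    sri: np.ndarray
    x: np.ndarray = None
    y_ab: np.ndarray = None
    y_a: np.ndarray = None
    y_b: np.ndarray = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {ind: k for k, ind in enumerate(self.ids)}

    def value(self, a, b) -> float:
        return float(self.sri[self._index[a], self._index[b]])

    def reindex(self, ids) -> "AssociationMatrix":
        """Restrict/reorder to the given individuals (must all be present)."""
        idx = np.array([self._index[i] for i in ids])
        sub = lambda m: None if m is None else m[np.ix_(idx, idx)]
        return AssociationMatrix(list(ids), sub(self.sri), sub(self.x),
                                 sub(self.y_ab), sub(self.y_a), sub(self.y_b))

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "id_a": self.ids[i], "id_b": self.ids[j],
                    "sri": self.sri[i, j],
                    "x": None if self.x is None else int(self.x[i, j]),
                    "y_ab": None if self.y_ab is None else int(self.y_ab[i, j]),
                    "y_a": None if self.y_a is None else int(self.y_a[i, j]),
                    "y_b": None if self.y_a is None else int(self.y_a[j, i]),
                })
        return pd.DataFrame(rows)


def _night_association(night_df: pd.DataFrame, index: dict, window_h: float) -> np.ndarray:
    """Boolean matrix of same-logger-within-window association for one night."""
    n = len(index)
    assoc = np.zeros((n, n), dtype=bool)
    delta = pd.Timedelta(hours=window_h)
    for _, ldf in night_df.groupby("logger"):
        stats = ldf.groupby("individual")["timestamp"].agg(["min", "max"])
        if len(stats) < 2:
            continue
        idx = np.array([index[i] for i in stats.index])
        tmin = stats["min"].to_numpy()
        tmax = stats["max"].to_numpy()
        # min |tA - tB| = max(0, max(tmin) - min(tmax)) over the two intervals
        gap = np.maximum(tmin[:, None], tmin[None, :]) - np.minimum(tmax[:, None], tmax[None, :])
        hit = gap <= np.timedelta64(delta)
        assoc[np.ix_(idx, idx)] |= hit
    np.fill_diagonal(assoc, False)
    return assoc


def _night_same_logger(night_df: pd.DataFrame, index: dict) -> np.ndarray:
    n = len(index)
    same = np.zeros((n, n), dtype=bool)
    for _, ldf in night_df.groupby("logger"):
        idx = np.array([index[i] for i in ldf["individual"].unique()])
        same[np.ix_(idx, idx)] = True
    np.fill_diagonal(same, False)
    return same


def tally_all(filtered: pd.DataFrame, alive: AliveWindows, window_h: float = 12.0,
              night_range=None, mode: str = "broad"):
    """Classify every night for every pair; return (ids, X, Y_AB, Y_only).

    ``Y_only[i, j]`` counts nights where i was observed, j was alive but
    unobserved (the directed y_A term). ``mode='broad'`` counts y_AB on
    nights both were observed anywhere without an association event;
    ``mode='narrow'`` additionally requires a same-logger co-detection.
    """
    if mode not in ("broad", "narrow"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = sorted(alive.individuals)
    index = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    X = np.zeros((n, n), dtype=np.int64)
    Y_AB = np.zeros((n, n), dtype=np.int64)
    Y_only = np.zeros((n, n), dtype=np.int64)

    df = filtered[filtered["individual"].isin(index)]
    if night_range is not None:
        lo, hi = pd.Timestamp(night_range[0]), pd.Timestamp(night_range[1])
        df = df[(df["night"] >= lo) & (df["night"] <= hi)]
        nights = pd.date_range(lo, hi, freq="D")
    elif len(df):
        nights = pd.date_range(df["night"].min(), df["night"].max(), freq="D")
    else:
        nights = []

    first = np.array([alive.windows[i][0] for i in ids])
    last = np.array([alive.windows[i][1] for i in ids])
    by_night = dict(tuple(df.groupby("night"))) if len(df) else {}

    for night in nights:
        live = (first <= night) & (night <= last)
        if live.sum() < 1:
            continue
        night_df = by_night.get(night)
        obs = np.zeros(n, dtype=bool)
        if night_df is not None:
            for ind in night_df["individual"].unique():
                obs[index[ind]] = True
        obs &= live  # detections outside an alive window do not count
        pair_alive = np.outer(live, live)
        if night_df is not None and obs.sum() >= 2:
            assoc = _night_association(night_df, index, window_h) & pair_alive
            both_obs = np.outer(obs, obs)
            if mode == "narrow":
                both_obs &= _night_same_logger(night_df, index)
            X += assoc
            Y_AB += both_obs & ~assoc
        Y_only += np.outer(obs, live & ~obs)
    return ids, X, Y_AB, Y_only


def tally_pair(filtered: pd.DataFrame, alive: AliveWindows, a, b,
               window_h: float = 12.0, mode: str = "broad") -> AssociationTally:
    """Night-classification tally for one pair (A, B)."""
    ids, X, Y_AB, Y_only = tally_all(filtered, alive, window_h=window_h, mode=mode)
    i, j = ids.index(a), ids.index(b)
    return AssociationTally(x=int(X[i, j]), y_ab=int(Y_AB[i, j]),
                            y_a=int(Y_only[i, j]), y_b=int(Y_only[j, i]))


def build_network(filtered: pd.DataFrame, alive: AliveWindows = None,
                  night_range=None, window_h: float = 12.0,
                  mode: str = "broad") -> AssociationMatrix:
    """Adjusted-SRI association matrix over all individuals alive in range."""
    if alive is None:
        if not len(filtered):
            logger.warning("empty detection table: returning 0x0 matrix")
            return AssociationMatrix([], np.zeros((0, 0)))
        alive = AliveWindows.from_detections(filtered)
    ids, X, Y_AB, Y_only = tally_all(filtered, alive, window_h=window_h,
                                     night_range=night_range, mode=mode)
    denom = X + Y_AB + Y_only + Y_only.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(denom > 0, X / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(sri, 0.0)
    if not len(filtered):
        logger.warning("empty detection table: zero association matrix")
    nz = sri[np.triu_indices_from(sri, k=1)]
    nz = nz[nz > 0]
    degree = (sri > 0).sum(axis=1)
    logger.info("network: %d individuals, mean degree %.2f, mean non-zero SRI %.3f",
                len(ids), degree.mean() if len(ids) else 0.0,
                nz.mean() if len(nz) else 0.0)
    return AssociationMatrix(ids, sri, X, Y_AB, Y_only, Y_only.T)


def season_windows(filtered: pd.DataFrame) -> dict:
    """Split the observed night span into two equal halves (spring/autumn)."""
    lo, hi = filtered["night"].min(), filtered["night"].max()
    mid = lo + (hi - lo) / 2
    mid = pd.Timestamp(mid).normalize()
    return {"full": (lo, hi), "spring": (lo, mid), "autumn": (mid + pd.Timedelta(days=1), hi)}
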