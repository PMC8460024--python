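"""Column schemas for the tabular sensor streams, and small containers.

Raw sensor data arrive as three delimited tables:

``events``
    dyadic proximity-sensor encounters: ``bat_a, bat_b, start_s,
    duration_s, max_signal``.  Times are integer seconds from the study
    epoch; ``max_signal`` is the peak received signal strength of the
    encounter (arbitrary units, larger = closer).
``stations``
    bat-to-base-station contacts: ``bat, station_id, start_s, duration_s``.
``bats``
    per-bat metadata: ``bat_id, type`` with type in
    {control, previously_captive, captive_born}.

Dyads are stored with ``bat_a < bat_b`` lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EVENT_COLS = ["bat_a", "bat_b", "start_s", "duration_s", "max_signal"]
STATION_COLS = ["bat", "station_id", "start_s", "duration_s"]
BAT_COLS = ["bat_id", "type"]
BOUT_COLS = ["bat", "night", "depart_s", "return_s", "censored"]
COFEED_COLS = ["night", "hour", "bat_a", "bat_b"]

BAT_TYPES = ("control", "previously_captive", "captive_born")

#: context labels assigned to every classified encounter (a partition)
CONTEXTS = ("roosting", "foraging", "excluded_near_roost", "excluded_transition")
#: nested proximity classes, by increasing closeness
PROXIMITY_CLASSES = ("association", "close_contact")

ROOST_STATION = "roost"


def order_dyads(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with bat_a < bat_b enforced on every row."""
    out = df.copy()
    swap = out["bat_a"] > out["bat_b"]
    if swap.any():
        a = out.loc[swap, "bat_a"].to_numpy()
        out.loc[swap, "bat_a"] = out.loc[swap, "bat_b"].to_numpy()
        out.loc[swap, "bat_b"] = a
    return out


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        EVENT_COLS, [str, str, np.int64, np.int64, float])})


def empty_stations() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        STATION_COLS, [str, str, np.int64, np.int64])})


def empty_bouts() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        BOUT_COLS, [str, np.int64, np.int64, np.int64, bool])})


@dataclass
class HourlyCoforagingTable:
    """Hour-binned presence/absence co-foraging records.

    ``records`` holds one row per (night, hour, dyad) with at least one
    foraging encounter starting in that clock hour; ``outside`` maps each
    (night, hour) stratum to the sorted array of bats outside the roost
    during that hour (their foraging bout overlaps the hour by >= 1 s).

    The invariant is that a dyad can only be marked in a stratum where
    both members are outside, so per-dyad totals are bounded by the
    dyad's number of shared outside-hours.
    """

    ids: list[str]
    records: pd.DataFrame  # columns: night, hour, bat_a, bat_b
    outside: dict[tuple[int, int], np.ndarray]

    def __post_init__(self) -> None:
        for _, r in self.records.iterrows():
            out = self.outside.get((r["night"], r["hour"]))
            if out is None or r["bat_a"] not in out or r["bat_b"] not in out:
                raise ValueError(
                    f"dyad ({r['bat_a']}, {r['bat_b']}) marked in stratum "
                    f"({r['night']}, {r['hour']}) where not both outside")

    def dyad_totals(self) -> "pd.Series":
        """Distinct marked (night, hour) bins per dyad, over all dyads that
        share at least one outside-hour (unmarked such dyads count 0)."""
        totals: dict[tuple[str, str], int] = {}
        for bats in self.outside.values():
            bats = sorted(bats)
            for i in range(len(bats)):
                for j in range(i + 1, len(bats)):
                    totals.setdefault((bats[i], bats[j]), 0)
        for _, r in self.records.iterrows():
            key = tuple(sorted((r["bat_a"], r["bat_b"])))
            totals[key] = totals.get(key, 0) + 1
        idx = pd.MultiIndex.from_tuples(sorted(totals), names=["bat_a", "bat_b"])
        return pd.Series([totals[k] for k in sorted(totals)], index=idx, name="count")

    def shared_outside_hours(self) -> "pd.Series":
        shared: dict[tuple[str, str], int] = {}
        for bats in self.outside.values():
            bats = sorted(bats)
            for i in range(len(bats)):
                for j in range(i + 1, len(bats)):
                    shared[(bats[i], bats[j])] = shared.get((bats[i], bats[j]), 0) + 1
        idx = pd.MultiIndex.from_tuples(sorted(shared), names=["bat_a", "bat_b"])
        return pd.Series([shared[k] for k in sorted(shared)], index=idx, name="hours")
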