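"""Sensor-stream processing: durations, proximity classes, bouts, contexts.

This stage turns raw proximity-sensor and base-station streams into the
classified encounters the networks are built from.  The rules are the
study's filtering conventions:

* encounters shorter than two successive 2-s beacons are recorded with a
  duration of 1 s;
* two nested signal-strength thresholds define "association" (~50 cm) and
  "close contact" (~2 cm); thresholds are inclusive;
* a foraging bout runs from the moment a bat loses the roost base station
  (confirmed by its count of distinct tagged associates collapsing from
  many to few) until the symmetric return;
* an encounter counts as a *foraging* encounter only if, for both bats, it
  starts more than one minute after departure and ends more than one
  minute before return, and neither bat has a concurrent roost-station
  contact (which would place the pair at the roost entrance).

Every encounter receives exactly one context label, so context counts
partition the input stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import BOUT_COLS, ROOST_STATION

DAY_SECONDS = 86400


class NoRoostContactError(ValueError):
    """Raised when a bat has no roost base-station contacts at all: its
    bouts are undefined (it may have been away the whole study) and must
    be flagged by the caller, not silently inferred."""


def normalize_duration(raw_duration_s: float) -> int:
    """Encounters shorter than two successive beacons get duration 1 s."""
    if raw_duration_s < 0:
        raise ValueError("duration must be non-negative")
    if raw_duration_s < 2:
        return 1
    return int(round(raw_duration_s))


def classify_proximity(max_signal: float, thresholds: dict) -> str | None:
    """Map peak signal strength to a proximity class (or None = too far).

    Boundaries are inclusive: a signal exactly at a threshold qualifies.
    """
    assoc = thresholds["assoc_min_signal"]
    close = thresholds["close_min_signal"]
    if close < assoc:
        raise ValueError("close_min_signal must be >= assoc_min_signal")
    if max_signal >= close:
        return "close_contact"
    if max_signal >= assoc:
        return "association"
    return None


@dataclass
class BoutConfig:
    """Departure/return detection knobs.

    ``many``/``few`` bound the associate-count drop that confirms a true
    departure (a count collapsing from >= many down to <= few); ``window``
    is the trailing window the counts are evaluated in, ``min_away`` the
    minimum credible absence, and ``min_roost_s`` the minimum sustained
    roost-station presence — shorter contacts are blips from passing the
    roost entrance and do not terminate a bout.
    """

    many: int = 4
    few: int = 3
    min_away: int = 300
    window: int = 120
    lookback: int = 3600
    min_roost_s: int = 600
    roost_station: str = ROOST_STATION


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _partner_count(bat: str, events: pd.DataFrame, t0: float, t1: float) -> int:
    """Distinct associates of ``bat`` with an encounter overlapping [t0, t1]."""
    sub = events[(events["bat_a"] == bat) | (events["bat_b"] == bat)]
    if sub.empty:
        return 0
    start = sub["start_s"].to_numpy()
    end = start + sub["duration_s"].to_numpy()
    # open at the endpoints: an event ending exactly at t0 or starting
    # exactly at t1 does not overlap (t0, t1)
    hit = (end > t0) & (start < t1)
    if not hit.any():
        return 0
    sub = sub[hit]
    partners = set(sub["bat_a"]).union(sub["bat_b"]) - {bat}
    return len(partners)


def detect_bouts(bat: str, stations: pd.DataFrame, events: pd.DataFrame,
                 cfg: BoutConfig | None = None,
                 stream_end: int | None = None) -> pd.DataFrame:
    """Infer foraging bouts of one bat from roost-station gaps.

    A candidate bout is a gap of at least ``cfg.min_away`` seconds in the
    bat's (blip-filtered, merged) roost-station coverage.  The departure
    endpoint is confirmed if the bat's distinct-associate count falls from
    >= ``cfg.many`` (trailing window before the gap) to <= ``cfg.few``
    (within the first ``min_away`` seconds of the gap); the return endpoint
    is confirmed symmetrically.  A trailing gap that never ends is a
    censored bout (no return confirmation possible).
    """
    cfg = cfg or BoutConfig()
    mine = stations[(stations["bat"] == bat)
                    & (stations["station_id"] == cfg.roost_station)]
    if mine.empty:
        raise NoRoostContactError(
            f"bat {bat} has no roost-station contacts; cannot infer bouts")
    iv = _merge_intervals(list(zip(mine["start_s"],
                                   mine["start_s"] + mine["duration_s"])))
    iv = [x for x in iv if x[1] - x[0] >= cfg.min_roost_s] or iv
    if stream_end is None:
        stream_end = int(max(
            (stations["start_s"] + stations["duration_s"]).max(),
            (events["start_s"] + events["duration_s"]).max()
            if len(events) else 0))
    ev = events[(events["bat_a"] == bat) | (events["bat_b"] == bat)]

    gaps: list[tuple[int, int, bool]] = []  # (start, end, censored)
    for (s0, e0), (s1, _) in zip(iv, iv[1:]):
        if s1 - e0 >= cfg.min_away:
            gaps.append((e0, s1, False))
    if stream_end - iv[-1][1] >= cfg.min_away:
        gaps.append((iv[-1][1], stream_end, True))

    rows = []
    for g0, g1, censored in gaps:
        # the "many" reference level may be established in the trailing
        # window or, failing that (e.g. the night's last departer, after
        # every other tagged bat has left), over a longer lookback
        if (_partner_count(bat, ev, g0 - cfg.window, g0) < cfg.many
                and _partner_count(bat, ev, g0 - cfg.lookback, g0) < cfg.many):
            continue
        if _partner_count(bat, ev, g0, g0 + cfg.min_away) > cfg.few:
            continue
        if not censored:
            if _partner_count(bat, ev, g1 - cfg.min_away, g1) > cfg.few:
                continue
            if (_partner_count(bat, ev, g1, g1 + cfg.window) < cfg.many
                    and _partner_count(bat, ev, g1, g1 + cfg.lookback)
                    < cfg.many):
                continue
        night = int(g0 // DAY_SECONDS) + 1
        rows.append((bat, night, int(g0), int(g1), censored))
    return pd.DataFrame(rows, columns=BOUT_COLS)


def detect_all_bouts(stations: pd.DataFrame, events: pd.DataFrame,
                     bats: list[str], cfg: BoutConfig | None = None
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Run :func:`detect_bouts` for every bat; returns (bouts, flagged)
    where ``flagged`` lists bats with no roost contact at all."""
    frames, flagged = [], []
    stream_end = int(max(
        (stations["start_s"] + stations["duration_s"]).max(),
        (events["start_s"] + events["duration_s"]).max() if len(events) else 0))
    for b in bats:
        try:
            frames.append(detect_bouts(b, stations, events, cfg, stream_end))
        except NoRoostContactError:
            flagged.append(b)
    bouts = pd.concat(frames, ignore_index=True) if frames \
        else pd.DataFrame(columns=BOUT_COLS)
    return bouts, flagged


def classify_context(events: pd.DataFrame, bouts: pd.DataFrame,
                     stations: pd.DataFrame, margin_s: int = 60,
                     roost_station: str = ROOST_STATION) -> pd.DataFrame:
    """Assign exactly one context label to every encounter.

    Labels: ``foraging`` (mid-bout for both bats, outside the one-minute
    transition margins, no concurrent roost contact), ``excluded_transition``
    (within a margin of either bat's departure or return),
    ``excluded_near_roost`` (mid-bout but a roost-station contact of either
    bat overlaps the encounter — the pair was at the roost entrance), and
    ``roosting`` (everything else).  The transition rule is applied before
    the roost-contact rule.
    """
    out = events.copy()
    bout_ix: dict[str, list[tuple[int, int]]] = {}
    for _, r in bouts.iterrows():
        bout_ix.setdefault(r["bat"], []).append((r["depart_s"], r["return_s"]))
    roost = stations[stations["station_id"] == roost_station]
    roost_ix: dict[str, np.ndarray] = {}
    for b, g in roost.groupby("bat"):
        roost_ix[b] = np.column_stack([g["start_s"].to_numpy(),
                                       (g["start_s"] + g["duration_s"]).to_numpy()])

    def enclosing(bat: str, s: int, e: int):
        for d, r in bout_ix.get(bat, ()):
            if d <= s and e <= r:
                return d, r
        return None

    def roost_overlap(bat: str, s: int, e: int) -> bool:
        iv = roost_ix.get(bat)
        if iv is None:
            return False
        return bool(((iv[:, 1] >= s) & (iv[:, 0] <= e)).any())

    labels = []
    for _, r in out.iterrows():
        s = int(r["start_s"])
        e = s + int(r["duration_s"])
        ba = enclosing(r["bat_a"], s, e)
        bb = enclosing(r["bat_b"], s, e)
        if ba is None or bb is None:
            labels.append("roosting")
            continue
        in_margin = (s <= ba[0] + margin_s or s <= bb[0] + margin_s
                     or e >= ba[1] - margin_s or e >= bb[1] - margin_s)
        if in_margin:
            labels.append("excluded_transition")
        elif roost_overlap(r["bat_a"], s, e) or roost_overlap(r["bat_b"], s, e):
            labels.append("excluded_near_roost")
        else:
            labels.append("foraging")
    out["context"] = labels
    return out


def co_departures(bouts: pd.DataFrame, window_s: int) -> pd.DataFrame:
    """All same-night dyads departing within ``window_s`` of each other."""
    rows = []
    for night, g in bouts.groupby("night"):
        recs = sorted(zip(g["bat"], g["depart_s"]), key=lambda x: x[1])
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                gap = recs[j][1] - recs[i][1]
                if gap > window_s:
                    break
                a, b = sorted((recs[i][0], recs[j][0]))
                rows.append((int(night), a, b, int(gap)))
    return pd.DataFrame(rows, columns=["night", "bat_a", "bat_b", "gap_s"])
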