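"""Dyadic network construction from classified encounters and bouts.

Edge definitions:

* roosting networks — rate: summed roosting-context encounter seconds at a
  proximity level, divided by the dyad's co-presence seconds in the roost
  (from roost-station contacts); dyads never co-present are structurally
  missing, not zero;
* foraging networks — total foraging-encounter seconds, or the number of
  distinct nights with at least one foraging encounter;
* hourly co-foraging — presence/absence of an encounter per clock hour in
  which both bats were outside (two meetings in one hour still count once);
* bout overlap — total seconds a dyad was simultaneously outside, the
  covariate that controls for opportunity;
* degree centrality — per-period count of distinct partners, with periods
  in which a bat had no encounters treated as missing, never as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrices import DayStratifiedNetwork, DyadicMatrix, masked_for_presence
from .records import HourlyCoforagingTable, ROOST_STATION
from .sensors import classify_proximity

DAY_SECONDS = 86400
HOUR = 3600


def _night_of(start_s) -> np.ndarray:
    return np.asarray(start_s) // DAY_SECONDS + 1


def _pair_index(ids: list[str]) -> dict[str, int]:
    return {b: i for i, b in enumerate(ids)}


# ---------------------------------------------------------------------------
# roosting rate networks

def _roost_intervals_by_day(stations: pd.DataFrame, day: int, day_s: int
                            ) -> dict[str, list[tuple[int, int]]]:
    d0 = (day - 1) * DAY_SECONDS
    d1 = d0 + day_s
    out: dict[str, list[tuple[int, int]]] = {}
    roost = stations[stations["station_id"] == ROOST_STATION]
    for b, g in roost.groupby("bat"):
        s = np.maximum(g["start_s"].to_numpy(), d0)
        e = np.minimum((g["start_s"] + g["duration_s"]).to_numpy(), d1)
        iv = [(int(a), int(z)) for a, z in zip(s, e) if z > a]
        if iv:
            out[b] = iv
    return out


def _overlap_seconds(iv_a, iv_b) -> int:
    tot = 0
    for a0, a1 in iv_a:
        for b0, b1 in iv_b:
            tot += max(0, min(a1, b1) - max(a0, b0))
    return tot


def roosting_network(encounters: pd.DataFrame, stations: pd.DataFrame,
                     ids: list[str], level: str = "association",
                     window: str = "aggregate", n_days: int | None = None,
                     day_s: int = 43200,
                     thresholds: dict | None = None):
    """Within-roost association (or close-contact) rate network.

    Rate = summed roosting-context encounter seconds at >= ``level``,
    divided by the dyad's co-presence seconds in the window.  ``window``
    is ``aggregate`` (one :class:`DyadicMatrix`) or ``per_day`` (a
    :class:`DayStratifiedNetwork` whose per-period presence sets are the
    bats with roost-station time that day).
    """
    if level not in ("association", "close_contact"):
        raise ValueError(f"unknown proximity level {level!r}")
    if thresholds is None:
        from .synthetic import DEFAULT_THRESHOLDS
        thresholds = DEFAULT_THRESHOLDS
    if n_days is None:
        n_days = int(_night_of(stations["start_s"]).max())
    idx = _pair_index(ids)
    n = len(ids)

    enc = encounters
    if "context" in enc.columns:
        enc = enc[enc["context"] == "roosting"]
    # roosting networks are daytime networks: in-roost contacts at night
    # (pre-departure / post-return) have no daytime co-presence denominator
    enc = enc[(enc["start_s"] % DAY_SECONDS) < day_s]
    cls = enc["max_signal"].map(lambda s: classify_proximity(s, thresholds))
    keep = cls == "close_contact" if level == "close_contact" else cls.notna()
    enc = enc[keep.to_numpy(dtype=bool)]

    num = np.zeros((n_days, n, n))
    den = np.zeros((n_days, n, n))
    day_of = _night_of(enc["start_s"].to_numpy()) if len(enc) else []
    for (a, b, dur, d) in zip(enc["bat_a"], enc["bat_b"],
                              enc["duration_s"], day_of):
        if 1 <= d <= n_days:
            i, j = idx[a], idx[b]
            num[d - 1, i, j] += dur
            num[d - 1, j, i] += dur
    presence: dict[str, set[str]] = {}
    for d in range(1, n_days + 1):
        iv = _roost_intervals_by_day(stations, d, day_s)
        present = [b for b in ids if b in iv]
        presence[f"day{d}"] = set(present)
        for i, a in enumerate(present):
            for b in present[present.index(a) + 1:]:
                ov = _overlap_seconds(iv[a], iv[b])
                ia, ib = idx[a], idx[b]
                den[d - 1, ia, ib] = den[d - 1, ib, ia] = ov

    if window == "per_day":
        layers = {}
        for d in range(1, n_days + 1):
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(den[d - 1] > 0, num[d - 1]
                                / np.maximum(den[d - 1], 1), 0.0)
            lay = DyadicMatrix(ids, vals, role="rate",
                               missing=(den[d - 1] == 0)
                               & ~np.eye(n, dtype=bool))
            layers[f"day{d}"] = lay
        return DayStratifiedNetwork(periods=[f"day{d}"
                                             for d in range(1, n_days + 1)],
                                    layers=layers, presence=presence)
    if window == "aggregate":
        tot_num = num.sum(axis=0)
        tot_den = den.sum(axis=0)
        vals = np.where(tot_den > 0, tot_num / np.maximum(tot_den, 1), 0.0)
        return DyadicMatrix(ids, vals, role="rate",
                            missing=(tot_den == 0) & ~np.eye(n, dtype=bool))
    raise ValueError(f"unknown window {window!r}")


# ---------------------------------------------------------------------------
# foraging response networks

def _foraging_only(encounters: pd.DataFrame) -> pd.DataFrame:
    if "context" in encounters.columns:
        return encounters[encounters["context"] == "foraging"]
    return encounters


def foraging_seconds_network(encounters: pd.DataFrame,
                             ids: list[str]) -> DyadicMatrix:
    """Total foraging-encounter seconds per dyad."""
    enc = _foraging_only(encounters)
    idx = _pair_index(ids)
    n = len(ids)
    m = np.zeros((n, n))
    for a, b, dur in zip(enc["bat_a"], enc["bat_b"], enc["duration_s"]):
        m[idx[a], idx[b]] += dur
        m[idx[b], idx[a]] += dur
    return DyadicMatrix(ids, m, role="seconds")


def foraging_nights_network(encounters: pd.DataFrame, ids: list[str],
                            n_nights: int) -> DyadicMatrix:
    """Number of distinct nights with >= 1 foraging encounter per dyad."""
    enc = _foraging_only(encounters)
    idx = _pair_index(ids)
    n = len(ids)
    m = np.zeros((n, n))
    if len(enc):
        nights = _night_of(enc["start_s"].to_numpy())
        seen = {(a, b, int(d)) for a, b, d in zip(enc["bat_a"], enc["bat_b"],
                                                  nights)}
        for a, b, d in seen:
            if 1 <= d <= n_nights:
                m[idx[a], idx[b]] += 1
                m[idx[b], idx[a]] += 1
    return DyadicMatrix(ids, m, role="count")


def nightly_foraging_networks(encounters: pd.DataFrame, bouts: pd.DataFrame,
                              ids: list[str], n_nights: int,
                              kind: str = "seconds") -> DayStratifiedNetwork:
    """Per-night foraging layers; presence = bats with a bout that night."""
    enc = _foraging_only(encounters)
    idx = _pair_index(ids)
    n = len(ids)
    nights = _night_of(enc["start_s"].to_numpy()) if len(enc) else []
    per = {d: np.zeros((n, n)) for d in range(1, n_nights + 1)}
    marked: set[tuple[str, str, int]] = set()
    for (a, b, dur, d) in zip(enc["bat_a"], enc["bat_b"], enc["duration_s"],
                              nights):
        d = int(d)
        if not 1 <= d <= n_nights:
            continue
        i, j = idx[a], idx[b]
        if kind == "seconds":
            per[d][i, j] += dur
            per[d][j, i] += dur
        elif kind == "binary":
            if (a, b, d) not in marked:
                marked.add((a, b, d))
                per[d][i, j] = per[d][j, i] = 1
        else:
            raise ValueError(f"unknown kind {kind!r}")
    layers, presence = {}, {}
    for d in range(1, n_nights + 1):
        present = set(bouts.loc[bouts["night"] == d, "bat"])
        presence[f"night{d}"] = present
        layers[f"night{d}"] = masked_for_presence(
            ids, per[d], present, role="seconds" if kind == "seconds"
            else "count")
    return DayStratifiedNetwork(periods=[f"night{d}"
                                         for d in range(1, n_nights + 1)],
                                layers=layers, presence=presence)


# ---------------------------------------------------------------------------
# hourly co-foraging and bout overlap

def hourly_coforaging(encounters: pd.DataFrame,
                      bouts: pd.DataFrame) -> HourlyCoforagingTable:
    """Hour-binned presence/absence co-foraging table.

    A bat is outside in a clock hour if one of its bouts overlaps the hour
    by at least a second; a dyad is marked in an hour if at least one of
    its foraging encounters *starts* in that hour (an encounter spanning
    an hour boundary belongs to its start hour only).
    """
    enc = _foraging_only(encounters)
    outside: dict[tuple[int, int], set] = {}
    for _, r in bouts.iterrows():
        h0 = int(r["depart_s"]) // HOUR
        h1 = (int(r["return_s"]) - 1) // HOUR
        for h in range(h0, h1 + 1):
            night = int(h * HOUR // DAY_SECONDS) + 1
            outside.setdefault((night, h), set()).add(r["bat"])
    recs: set[tuple[int, int, str, str]] = set()
    for a, b, s in zip(enc["bat_a"], enc["bat_b"], enc["start_s"]):
        h = int(s) // HOUR
        night = int(s) // DAY_SECONDS + 1
        aa, bb = sorted((a, b))
        recs.add((night, h, aa, bb))
    records = pd.DataFrame(sorted(recs),
                           columns=["night", "hour", "bat_a", "bat_b"])
    ids = sorted(set(bouts["bat"]))
    out_arr = {k: np.array(sorted(v)) for k, v in outside.items()}
    return HourlyCoforagingTable(ids=ids, records=records, outside=out_arr)


def bout_overlap(bouts: pd.DataFrame, ids: list[str]) -> DyadicMatrix:
    """Total seconds each dyad was simultaneously outside the roost."""
    idx = _pair_index(ids)
    n = len(ids)
    m = np.zeros((n, n))
    for _, g in bouts.groupby("night"):
        recs = list(zip(g["bat"], g["depart_s"], g["return_s"]))
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, a0, a1 = recs[i]
                b, b0, b1 = recs[j]
                ov = max(0, min(a1, b1) - max(a0, b0))
                if ov and a != b:
                    m[idx[a], idx[b]] += ov
                    m[idx[b], idx[a]] += ov
    return DyadicMatrix(ids, m, role="overlap")


def cofeeding_network(events: pd.DataFrame, ids: list[str]) -> DyadicMatrix:
    """Dyadic co-feeding event counts."""
    from .inference import cofeeding_counts
    return cofeeding_counts(events, ids)


# ---------------------------------------------------------------------------
# degree centrality

def degree_centrality_profiles(network: DayStratifiedNetwork,
                               weighted: bool = False
                               ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-bat, per-period degree, and each bat's mean over non-missing
    periods.

    Degree is the number of distinct partners with a positive edge in that
    period (or summed edge weight when ``weighted``).  A period in which a
    bat was absent *or had no encounters* is missing — never zero — so the
    mean reflects only periods with social data.
    """
    ids = network.ids
    rows = []
    for p in network.periods:
        lay = network.layers[p]
        adj = np.where(lay.missing, 0.0, lay.values)
        for i, b in enumerate(ids):
            if b not in network.presence.get(p, set(ids)):
                deg = np.nan
            else:
                row = adj[i]
                deg = row.sum() if weighted else float((row > 0).sum())
                if deg == 0:
                    deg = np.nan
            rows.append((b, p, deg))
    prof = pd.DataFrame(rows, columns=["bat", "period", "degree"])
    mean = prof.groupby("bat")["degree"].mean()
    mean.name = "mean_degree"
    return prof, mean
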