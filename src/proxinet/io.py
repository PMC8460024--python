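"""Reading and writing the pipeline's delimited-table formats.

A dataset directory holds: ``events.csv`` (dyadic proximity events),
``stations.csv`` (bat/base-station contacts), ``bats.csv`` (metadata),
``kinship.csv`` / ``grooming.csv`` / ``sharing.csv`` (long-form dyadic),
``cofeeding_events.csv`` + ``cofeeding_attendance.csv`` (captive feeder
observations), and for synthetic data ``truth.json`` + ``true_bouts.csv``
with the generator's ground truth.  All times are integer seconds from
the study epoch; all dyads are stored with ``bat_a < bat_b``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .matrices import DyadicMatrix
from .records import BAT_COLS, EVENT_COLS, STATION_COLS
from .synthetic import (CofeedingData, ColonyParams, SyntheticTruth,
                        simulate_captive_feeding, simulate_colony,
                        simulate_foraging_nights, simulate_roosting_days,
                        true_bouts)


def dyadic_to_long(m: DyadicMatrix) -> pd.DataFrame:
    df = m.to_long()
    return df[~df["missing"]][["bat_a", "bat_b", "value"]]


def long_to_dyadic(df: pd.DataFrame, ids: list[str],
                   role: str) -> DyadicMatrix:
    return DyadicMatrix.from_long(df, ids, role=role)


def write_dataset(outdir: str | Path, truth: SyntheticTruth,
                  include_truth: bool = True) -> dict:
    """Simulate all streams from ``truth`` and write the dataset directory.

    Returns a dict of row counts per table (handy for logging/reports).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    day_ev, day_st = simulate_roosting_days(truth)
    night_ev, night_st, bouts = simulate_foraging_nights(truth)

    events = pd.concat([day_ev, night_ev[EVENT_COLS]], ignore_index=True)
    events = events.sort_values(["start_s", "bat_a", "bat_b"],
                                kind="stable").reset_index(drop=True)
    stations = pd.concat([day_st, night_st], ignore_index=True)
    stations = stations.sort_values(["start_s", "bat"],
                                    kind="stable").reset_index(drop=True)
    bats = pd.DataFrame({"bat_id": truth.ids,
                         "type": [truth.types[b] for b in truth.ids]})
    events.to_csv(out / "events.csv", index=False)
    stations.to_csv(out / "stations.csv", index=False)
    bats.to_csv(out / "bats.csv", index=False)
    dyadic_to_long(truth.kinship).to_csv(out / "kinship.csv", index=False)
    if truth.grooming is not None:
        dyadic_to_long(truth.grooming).to_csv(out / "grooming.csv",
                                              index=False)
        dyadic_to_long(truth.sharing).to_csv(out / "sharing.csv", index=False)

    counts = {"events": len(events), "stations": len(stations),
              "bats": len(bats)}
    try:
        feeding = simulate_captive_feeding(truth)
    except ValueError:
        feeding = None
    if feeding is not None:
        feeding.events.to_csv(out / "cofeeding_events.csv", index=False)
        feeding.attendance.to_csv(out / "cofeeding_attendance.csv",
                                  index=False)
        counts["cofeeding_events"] = len(feeding.events)

    if include_truth:
        bouts.to_csv(out / "true_bouts.csv", index=False)
        night_ev.to_csv(out / "true_night_events.csv", index=False)
        truth_doc = {
            "params": _params_doc(truth.params),
            "ids": truth.ids,
            "types": truth.types,
            "relationship": truth.relationship.values.tolist(),
            "kinship": truth.kinship.values.tolist(),
            "depart_intercepts": truth.depart_intercepts,
            "bout_intercepts": truth.bout_intercepts,
            "dropout_nights": truth.dropout_nights,
        }
        (out / "truth.json").write_text(
            json.dumps(truth_doc, sort_keys=True, indent=1))
    return counts


def _params_doc(params: ColonyParams) -> dict:
    doc = dataclasses.asdict(params)
    doc["kin_pairs"] = [list(t) for t in (params.kin_pairs or [])]
    return doc


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    return df


def read_stations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STATION_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"stations table missing columns {sorted(missing)}")
    return df


def read_bats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BAT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"bats table missing columns {sorted(missing)}")
    return df


def read_dataset(indir: str | Path) -> dict:
    """Read a dataset directory into a dict of DataFrames (present files)."""
    d = Path(indir)
    out = {
        "events": read_events(d / "events.csv"),
        "stations": read_stations(d / "stations.csv"),
        "bats": read_bats(d / "bats.csv"),
    }
    for name in ("kinship", "grooming", "sharing"):
        p = d / f"{name}.csv"
        if p.exists():
            out[name] = pd.read_csv(p)
    for name in ("cofeeding_events", "cofeeding_attendance", "true_bouts"):
        p = d / f"{name}.csv"
        if p.exists():
            out[name] = pd.read_csv(p)
    return out
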