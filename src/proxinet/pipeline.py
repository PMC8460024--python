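"""End-to-end runner: simulate -> process -> networks -> inference.

The pipeline is deterministic under its master seed: every stage draws
from a named substream derived from it, so the same config and seed give
byte-identical reports.  Stage failures are recorded in the report and
later independent stages still run.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import networks as nw
from . import sensors
from .inference import (UndefinedStatisticError, centrality_consistency_test,
                        daynight_paired_qap, differentiation_test,
                        double_permutation_test, icc_unadjusted, mantel_test,
                        qap_regression)
from .io import read_dataset, write_dataset
from .matrices import DyadicMatrix
from .records import BAT_TYPES, ROOST_STATION
from .synthetic import DEFAULT_THRESHOLDS, ColonyParams, simulate_colony

REPORT_SCHEMA_VERSION = 1

ALL_TESTS = ("differentiation", "qap", "mrqap", "daynight", "centrality",
             "mantel", "icc", "double_perm")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML round-trippable)."""

    seed: int = 0
    n_bats: int = 20
    n_nights: int = 6
    n_perm: int = 1000
    margin_s: int = 60
    codeparture_window_s: int = 5
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    colony_overrides: dict = field(default_factory=dict)
    tests: list[str] = field(default_factory=lambda: list(ALL_TESTS))

    def __post_init__(self) -> None:
        unknown = set(self.tests) - set(ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    def colony_params(self) -> ColonyParams:
        return ColonyParams(n_bats=self.n_bats, n_nights=self.n_nights,
                            seed=self.seed, **self.colony_overrides)


def _stage_seed(master: int, name: str) -> int:
    # stable across processes (str.hash is salted, so not usable here)
    tag = zlib.crc32(name.encode())
    ss = np.random.SeedSequence([int(master), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_tables(indir: str | Path) -> list[dict]:
    """Schema and convention checks; returns machine-readable diagnostics."""
    d = Path(indir)
    diags: list[dict] = []

    def diag(table, kind, detail, row=None):
        diags.append({"table": table, "kind": kind, "detail": detail,
                      "row": row})

    required = {"events.csv": ["bat_a", "bat_b", "start_s", "duration_s",
                               "max_signal"],
                "stations.csv": ["bat", "station_id", "start_s",
                                 "duration_s"],
                "bats.csv": ["bat_id", "type"]}
    frames = {}
    for fname, cols in required.items():
        p = d / fname
        if not p.exists():
            diag(fname, "missing_table", "file not found")
            continue
        df = pd.read_csv(p)
        frames[fname] = df
        for c in cols:
            if c not in df.columns:
                diag(fname, "missing_column", c)
    bats = frames.get("bats.csv")
    known = set(bats["bat_id"]) if bats is not None else set()
    if bats is not None:
        bad = bats[~bats["type"].isin(BAT_TYPES)]
        for i in bad.index:
            diag("bats.csv", "unknown_type", str(bats.loc[i, "type"]), int(i))
    ev = frames.get("events.csv")
    if ev is not None and {"bat_a", "bat_b"} <= set(ev.columns):
        rev = ev[ev["bat_a"] >= ev["bat_b"]]
        for i in rev.index[:20]:
            diag("events.csv", "dyad_ordering",
                 f"{ev.loc[i, 'bat_a']} >= {ev.loc[i, 'bat_b']}", int(i))
        if "start_s" in ev.columns and (ev["start_s"] < 0).any():
            diag("events.csv", "negative_time", "start_s < 0")
        if known:
            stray = set(ev["bat_a"]).union(ev["bat_b"]) - known
            for b in sorted(stray):
                diag("events.csv", "unknown_bat", b)
    for fname in ("kinship.csv", "grooming.csv", "sharing.csv"):
        p = d / fname
        if not p.exists():
            continue
        df = pd.read_csv(p)
        dup = df.duplicated(subset=["bat_a", "bat_b"])
        for i in df.index[dup][:20]:
            diag(fname, "duplicate_dyad",
                 f"{df.loc[i, 'bat_a']},{df.loc[i, 'bat_b']}", int(i))
        rev = df[df["bat_a"] >= df["bat_b"]]
        for i in rev.index[:20]:
            diag(fname, "dyad_ordering",
                 f"{df.loc[i, 'bat_a']} >= {df.loc[i, 'bat_b']}", int(i))
    return diags


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full chain and write ``report.json`` under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "config": dataclasses.asdict(config),
                    "stages": {}, "errors": {}}

    # ---- simulate -------------------------------------------------------
    params = config.colony_params()
    truth = simulate_colony(params)
    data_dir = out / "data"
    counts = write_dataset(data_dir, truth)
    report["stages"]["simulate"] = {"counts": counts,
                                    "seed": params.seed,
                                    "n_bats": params.n_bats,
                                    "n_nights": params.n_nights}
    data = read_dataset(data_dir)
    ids = list(data["bats"]["bat_id"])

    # ---- process --------------------------------------------------------
    bouts, flagged = sensors.detect_all_bouts(data["stations"],
                                              data["events"], ids)
    classified = sensors.classify_context(data["events"], bouts,
                                          data["stations"],
                                          margin_s=config.margin_s)
    codep = sensors.co_departures(bouts, config.codeparture_window_s)
    ctx_counts = classified["context"].value_counts().to_dict()
    classified.to_csv(out / "encounters_classified.csv", index=False)
    bouts.to_csv(out / "bouts.csv", index=False)
    report["stages"]["process"] = {
        "n_bouts": int(len(bouts)), "flagged_no_roost_contact": flagged,
        "context_counts": {k: int(v) for k, v in sorted(ctx_counts.items())},
        "n_codepartures": int(len(codep)),
        "partition_ok": int(sum(ctx_counts.values())) == len(classified)}

    # ---- networks -------------------------------------------------------
    n_nights = config.n_nights
    assoc_daily = nw.roosting_network(classified, data["stations"], ids,
                                      level="association", window="per_day",
                                      n_days=n_nights,
                                      thresholds=config.thresholds)
    assoc_agg = nw.roosting_network(classified, data["stations"], ids,
                                    level="association", window="aggregate",
                                    n_days=n_nights,
                                    thresholds=config.thresholds)
    close_agg = nw.roosting_network(classified, data["stations"], ids,
                                    level="close_contact", window="aggregate",
                                    n_days=n_nights,
                                    thresholds=config.thresholds)
    forage_sec = nw.foraging_seconds_network(classified, ids)
    forage_nights = nw.foraging_nights_network(classified, ids, n_nights)
    forage_strat = nw.nightly_foraging_networks(classified, bouts, ids,
                                                n_nights)
    overlap = nw.bout_overlap(bouts, ids)
    table = nw.hourly_coforaging(classified, bouts)
    kinship = DyadicMatrix.from_long(data["kinship"], ids, role="kinship")
    report["stages"]["networks"] = {
        "foraging_seconds_total": float(forage_sec.vectorize().sum() ),
        "foraging_nights_max": float(forage_nights.vectorize().max())
        if forage_nights.vectorize().size else 0.0,
        "coforaging_records": int(len(table.records)),
        "assoc_rate_mean": float(np.nanmean(assoc_agg.vectorize()))
        if assoc_agg.vectorize().size else 0.0}

    # ---- inference ------------------------------------------------------
    res: dict = {}
    n_perm = config.n_perm

    def stage(name, fn):
        try:
            res[name] = fn()
        except (ValueError, UndefinedStatisticError, KeyError) as err:
            report["errors"][name] = f"{type(err).__name__}: {err}"

    if "differentiation" in config.tests:
        stage("differentiation", lambda: differentiation_test(
            table, n_perm=n_perm,
            seed=_stage_seed(config.seed, "differentiation")).summary())
    if "qap" in config.tests:
        nights_strat = nw.nightly_foraging_networks(classified, bouts, ids,
                                                    n_nights, kind="binary")
        stage("qap_kinship_nights", lambda: qap_regression(
            nights_strat, {"kinship": kinship}, n_perm=n_perm,
            seed=_stage_seed(config.seed, "qap_kin")).summary())
        stage("qap_association_seconds", lambda: qap_regression(
            forage_strat, {"association": assoc_agg}, n_perm=n_perm,
            seed=_stage_seed(config.seed, "qap_assoc")).summary())
    if "mrqap" in config.tests:
        stage("mrqap_association_overlap", lambda: qap_regression(
            forage_sec, {"association": assoc_agg}, covariate=overlap,
            n_perm=n_perm, mode="dsp",
            seed=_stage_seed(config.seed, "mrqap")).summary())
    if "daynight" in config.tests:
        def _daynight():
            r = daynight_paired_qap(assoc_daily, nw.nightly_foraging_networks(
                classified, bouts, ids, n_nights, kind="binary"),
                n_perm=min(n_perm, 1000),
                seed=_stage_seed(config.seed, "daynight"))
            return {"mean_slope": r["mean_slope"], "ci": list(r["ci"]),
                    "n_days_used": len(r["slopes"]),
                    "skipped": [list(map(str, s)) for s in r["skipped"]]}
        stage("daynight", _daynight)
    if "centrality" in config.tests:
        def _centrality():
            _, roost_mean = nw.degree_centrality_profiles(assoc_daily)
            fprof, _ = nw.degree_centrality_profiles(forage_strat)
            return centrality_consistency_test(
                roost_mean, fprof, n_perm=n_perm,
                seed=_stage_seed(config.seed, "centrality")).summary()
        stage("centrality", _centrality)
    if "icc" in config.tests:
        def _icc():
            merged = bouts.merge(data["bats"], left_on="bat",
                                 right_on="bat_id")
            night0 = (merged["night"] - 1) * 86400 + config.colony_params().day_s
            merged["depart_after_sunset"] = merged["depart_s"] - night0
            out = {}
            for t, g in merged.groupby("type"):
                try:
                    out[t] = icc_unadjusted(g["depart_after_sunset"],
                                            g["bat"]).summary()
                except UndefinedStatisticError as err:
                    out[t] = {"error": str(err)}
            return out
        stage("icc_departure_by_type", _icc)
    if "mantel" in config.tests and "grooming" in data and "sharing" in data:
        def _mantel():
            cap = sorted(set(data["grooming"]["bat_a"])
                         | set(data["grooming"]["bat_b"]))
            g = DyadicMatrix.from_long(data["grooming"], cap, role="rate")
            s = DyadicMatrix.from_long(data["sharing"], cap, role="rate")
            return mantel_test(g, s, n_perm=n_perm,
                               seed=_stage_seed(config.seed,
                                                "mantel")).summary()
        stage("mantel_grooming_sharing", _mantel)
    if "double_perm" in config.tests and "cofeeding_events" in data:
        def _dp():
            cap = sorted(set(data["cofeeding_attendance"]["bat"]))
            gro = DyadicMatrix.from_long(data["grooming"], cap, role="rate") \
                if "grooming" in data else None
            if gro is None:
                raise ValueError("no grooming predictor available")
            adj, r = double_permutation_test(
                data["cofeeding_events"], data["cofeeding_attendance"], gro,
                n_perm=n_perm, seed=_stage_seed(config.seed, "double_perm"))
            return {"correlation": r.summary(),
                    "mean_abs_adjusted": float(
                        np.abs(adj.vectorize()).mean())}
        stage("double_perm_cofeeding_grooming", _dp)

    report["stages"]["inference"] = res
    (out / "report.json").write_text(json.dumps(report, sort_keys=True,
                                                indent=1))
    return report
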