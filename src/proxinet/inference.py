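"""Constrained-permutation inference for dyadic social networks.

The observational unit here is a dyad, so rows of a design matrix are not
exchangeable and ordinary regression p-values are invalid.  Every test in
this module therefore draws its null distribution from permutations that
respect the structure of the data collection:

* **data-stream permutations** randomize raw observation records within
  their (night, hour) stratum — either swapping one member of each marked
  dyad to another bat outside in the same hour (social differentiation),
  or relabelling the identities of the bats seen at the feeders within
  each hour (co-feeding);
* **constrained node-label permutations** relabel individuals within each
  day/night layer, restricted to the bats present in that period, and are
  the null model for QAP / MRQAP network regressions and the centrality
  consistency test;
* the **double permutation test** combines both: dyadic rates are first
  adjusted by subtracting their median under stream permutations, then the
  adjusted matrix is tested with node-label permutations.

All p-values use the add-one convention (1 + exceedances) / (1 + n_perm),
so p = 0 is impossible and the smallest attainable p is 1 / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import DayStratifiedNetwork, DyadicMatrix
from .records import HourlyCoforagingTable


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined on this input (e.g. the
    coefficient of variation of an all-zero vector)."""


# ---------------------------------------------------------------------------
# results

@dataclass
class PermutationResult:
    observed_stat: float
    null_draws: np.ndarray
    n_perm: int
    seed: int | None
    p_value: float
    tail: str
    centered_stat: float | None = None

    def summary(self) -> dict:
        q = np.quantile(self.null_draws, [0.025, 0.5, 0.975])
        return {"observed": float(self.observed_stat),
                "p_value": float(self.p_value), "tail": self.tail,
                "n_perm": int(self.n_perm), "seed": self.seed,
                "null_q025": float(q[0]), "null_median": float(q[1]),
                "null_q975": float(q[2]),
                "centered": None if self.centered_stat is None
                else float(self.centered_stat)}


@dataclass
class QAPResult:
    predictors: list[str]
    coefficients: dict[str, float]
    intercept: float
    null_draws: dict[str, np.ndarray]
    p_values: dict[str, float]
    n_perm: int
    seed: int | None
    mode: str
    tail: str = "two_sided"
    n_dyads: int = 0
    n_nodes: int = 0

    def summary(self) -> dict:
        return {"mode": self.mode, "n_perm": self.n_perm, "seed": self.seed,
                "tail": self.tail, "n_dyads": self.n_dyads,
                "n_nodes": self.n_nodes, "intercept": float(self.intercept),
                "coefficients": {k: float(v)
                                 for k, v in self.coefficients.items()},
                "p_values": {k: float(v) for k, v in self.p_values.items()}}


@dataclass
class ICCResult:
    icc: float
    between_var: float
    within_var: float
    n_groups: int
    group_sizes: list[int] = field(default_factory=list)

    def summary(self) -> dict:
        return {"icc": float(self.icc), "between_var": float(self.between_var),
                "within_var": float(self.within_var),
                "n_groups": int(self.n_groups)}


# ---------------------------------------------------------------------------
# shared primitives

def p_value(null_draws: np.ndarray, observed: float, tail: str) -> float:
    """Permutation p with the add-one convention.

    ``greater`` counts null >= observed, ``less`` counts null <= observed,
    ``two_sided`` doubles the smaller tail (capped at 1).
    """
    null_draws = np.asarray(null_draws, dtype=float)
    n = null_draws.size
    if n < 1:
        raise ValueError("need at least one null draw")
    pg = (1 + int((null_draws >= observed).sum())) / (1 + n)
    pl = (1 + int((null_draws <= observed).sum())) / (1 + n)
    if tail == "greater":
        return pg
    if tail == "less":
        return pl
    if tail == "two_sided":
        return min(1.0, 2 * min(pg, pl))
    raise ValueError(f"unknown tail {tail!r}")


def cv_statistic(values) -> float:
    """Coefficient of variation (sample SD over mean) of dyadic values.

    High values mean a few dyads concentrate the encounters — the social
    differentiation statistic.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise UndefinedStatisticError("need >= 2 non-missing dyads")
    m = v.mean()
    if m <= 0:
        raise UndefinedStatisticError("CV undefined for mean <= 0")
    return float(v.std(ddof=1) / m)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    den = np.sqrt((x * x).sum() * (y * y).sum())
    if den == 0:
        raise UndefinedStatisticError("correlation undefined: constant input")
    return float((x * y).sum() / den)


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with intercept prepended; returns [intercept, betas...]."""
    Z = np.column_stack([np.ones(len(y)), X])
    cond = np.linalg.cond(Z)
    if cond > 1e10:
        raise ValueError(f"collinear predictors (condition number {cond:.2g})")
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return beta


# ---------------------------------------------------------------------------
# social differentiation (data-stream permutation on hourly records)

def _stream_perm_draws(table: HourlyCoforagingTable, n_perm: int,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray, list]:
    """Null co-foraging totals under constrained dyad-member swaps.

    Every marked (night, hour, dyad) record independently has one randomly
    chosen member replaced by a uniformly random other bat (never the kept
    member) outside the roost in that same night and hour.  Returns
    ``(totals, observed_totals, low_freedom)`` where ``totals`` is
    (n_perm, n_universe) over the universe of dyads with at least one
    shared outside-hour, and ``low_freedom`` lists strata with < 3 bats
    outside (their records cannot move).
    """
    obs = table.dyad_totals()
    universe = list(obs.index)
    upos = {d: i for i, d in enumerate(universe)}
    nu = len(universe)

    totals = np.zeros((n_perm, nu))
    low_freedom = []
    groups = table.records.groupby(["night", "hour"], sort=True)
    for (night, hour), g in groups:
        out = np.array(sorted(table.outside[(night, hour)]))
        m = out.size
        opos = {b: i for i, b in enumerate(out)}
        if m < 3:
            low_freedom.append((night, hour))
            # no randomization freedom: records stay as-is
            for _, r in g.iterrows():
                d = tuple(sorted((r["bat_a"], r["bat_b"])))
                totals[:, upos[d]] += 1
            continue
        k = len(g)
        pa = np.array([opos[b] for b in g["bat_a"]])
        pb = np.array([opos[b] for b in g["bat_b"]])
        keep_a = rng.random((n_perm, k)) < 0.5
        kept = np.where(keep_a, pa, pb)
        cand = rng.integers(0, m - 1, size=(n_perm, k))
        cand = cand + (cand >= kept)          # uniform over others
        lo = np.minimum(kept, cand)
        hi = np.maximum(kept, cand)
        # map (lo, hi) bat-position pairs to universe positions
        pair_pos = np.empty((m, m), dtype=int)
        for i in range(m):
            for j in range(i + 1, m):
                pair_pos[i, j] = upos[(out[i], out[j])]
        flat = pair_pos[lo, hi]
        # presence/absence semantics: two records landing on the same dyad
        # within one hour still mark that hour only once
        srt = np.sort(flat, axis=1)
        first = np.ones_like(srt, dtype=bool)
        first[:, 1:] = srt[:, 1:] != srt[:, :-1]
        rows = np.repeat(np.arange(n_perm), k)
        np.add.at(totals, (rows[first.ravel()], srt[first]), 1)
    return totals, obs.to_numpy(dtype=float), low_freedom


def differentiation_test(table: HourlyCoforagingTable, n_perm: int = 5000,
                         seed: int | None = None) -> PermutationResult:
    """Is co-foraging more differentiated than random reunions allow?

    Observed statistic: CV of per-dyad co-foraging totals over all dyads
    that share at least one outside-hour.  Null: the constrained hourly
    partner swaps of :func:`_stream_perm_draws`.  One-tailed (greater): the
    alternative is that some pairs repeat encounters more than chance.
    """
    rng = np.random.default_rng(seed)
    totals, obs_totals, _ = _stream_perm_draws(table, n_perm, rng)
    observed = cv_statistic(obs_totals)
    means = totals.mean(axis=1)
    if (means <= 0).any():
        raise UndefinedStatisticError("a null draw has zero mean count")
    null = totals.std(axis=1, ddof=1) / means
    p = p_value(null, observed, "greater")
    return PermutationResult(observed_stat=observed, null_draws=null,
                             n_perm=n_perm, seed=seed, p_value=p,
                             tail="greater",
                             centered_stat=observed - float(np.median(null)))


# ---------------------------------------------------------------------------
# captive co-feeding: within-hour identity permutation + double permutation

def cofeeding_counts(events: pd.DataFrame, ids: list[str]) -> DyadicMatrix:
    idx = {b: i for i, b in enumerate(ids)}
    n = len(ids)
    m = np.zeros((n, n))
    for a, b in zip(events["bat_a"], events["bat_b"]):
        m[idx[a], idx[b]] += 1
        m[idx[b], idx[a]] += 1
    return DyadicMatrix(ids, m, role="count")


def within_hour_identity_permutation(events: pd.DataFrame,
                                     attendance: pd.DataFrame,
                                     ids: list[str], n_perm: int = 5000,
                                     seed: int | None = None) -> np.ndarray:
    """Null co-feeding count matrices under within-hour identity relabelling.

    For each permutation and each observation hour, the identities of the
    bats seen in that hour are relabelled by a uniform random permutation
    (of the bats seen that hour); events follow their labels.  Returns an
    array of shape (n_perm, n, n) of null count matrices.
    """
    rng = np.random.default_rng(seed)
    idx = {b: i for i, b in enumerate(ids)}
    n = len(ids)
    nulls = np.zeros((n_perm, n, n))
    seen_by_hour = {k: np.array(sorted(g["bat"].map(idx)))
                    for k, g in attendance.groupby(["night", "hour"])}
    for key, g in events.groupby(["night", "hour"]):
        seen = seen_by_hour.get(key)
        if seen is None:
            raise ValueError(f"events in hour {key} but no attendance record")
        m = seen.size
        spos = {b: i for i, b in enumerate(seen)}
        try:
            ea = np.array([spos[idx[b]] for b in g["bat_a"]])
            eb = np.array([spos[idx[b]] for b in g["bat_b"]])
        except KeyError as err:
            raise ValueError(f"event in hour {key} names a bat not seen "
                             f"that hour: {err}") from None
        # one random permutation of the seen bats per null draw
        perms = np.argsort(rng.random((n_perm, m)), axis=1)
        na = seen[perms[:, ea]]
        nb = seen[perms[:, eb]]
        rows = np.repeat(np.arange(n_perm), len(g))
        np.add.at(nulls, (rows, na.ravel(), nb.ravel()), 1)
        np.add.at(nulls, (rows, nb.ravel(), na.ravel()), 1)
    return nulls


def double_permutation_test(events: pd.DataFrame, attendance: pd.DataFrame,
                            predictor: DyadicMatrix, n_perm: int = 5000,
                            seed: int | None = None, tail: str = "greater"
                            ) -> tuple[DyadicMatrix, PermutationResult]:
    """Two-stage test of a dyadic predictor against co-feeding counts.

    Stage 1 adjusts each dyad's count by subtracting its median under
    within-hour identity permutations (removing what shared feeder time
    alone explains); stage 2 correlates the adjusted matrix with the
    predictor, with significance from node-label permutations of the
    adjusted matrix.
    """
    ids = predictor.ids
    rng = np.random.default_rng(seed)
    observed = cofeeding_counts(events, ids)
    nulls = within_hour_identity_permutation(events, attendance, ids,
                                             n_perm=n_perm, seed=seed)
    med = np.median(nulls, axis=0)
    np.fill_diagonal(med, 0.0)
    adj_vals = observed.values - med
    adjusted = DyadicMatrix(ids, adj_vals, role="adjusted",
                            missing=predictor.missing.copy())
    mask = adjusted.observed_upper_mask() & predictor.observed_upper_mask()
    iu, ju = adjusted.upper_indices()
    x = predictor.values[iu, ju][mask]
    if np.allclose(x, x[0]):
        raise UndefinedStatisticError("predictor is constant")
    y = adj_vals[iu, ju][mask]
    r_obs = _pearson(x, y)
    n = len(ids)
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        yp = adj_vals[np.ix_(perm, perm)][iu, ju][mask]
        null[t] = _pearson(x, yp)
    p = p_value(null, r_obs, tail)
    res = PermutationResult(observed_stat=r_obs, null_draws=null,
                            n_perm=n_perm, seed=seed, p_value=p, tail=tail,
                            centered_stat=r_obs - float(np.median(null)))
    return adjusted, res


# ---------------------------------------------------------------------------
# QAP / MRQAP network regression

def _constrained_perm(rng: np.random.Generator, n: int,
                      present_pos: np.ndarray) -> np.ndarray:
    """Identity permutation except a uniform shuffle of the present nodes."""
    perm = np.arange(n)
    perm[present_pos] = present_pos[rng.permutation(present_pos.size)]
    return perm


def _vectorize_masked(mats: list[DyadicMatrix]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack upper triangles of matrices on their joint observed mask."""
    iu, ju = mats[0].upper_indices()
    mask = np.ones(iu.size, dtype=bool)
    for m in mats:
        mask &= ~m.missing[iu, ju]
    cols = [m.values[iu, ju][mask] for m in mats]
    return np.column_stack(cols), mask


def qap_regression(response, predictors: dict[str, DyadicMatrix],
                   covariate: DyadicMatrix | None = None,
                   n_perm: int = 5000, seed: int | None = None,
                   mode: str = "node_label_constrained",
                   tail: str = "two_sided") -> QAPResult:
    """(MR)QAP regression of a dyadic response on dyadic predictors.

    The observed coefficients are ordinary least squares on the vectorized
    non-missing dyads of the aggregate response.  Null distributions:

    ``node_label_constrained``
        one independent node relabelling per period, drawn uniformly over
        the bats *present* in that period, applied to that period's
        response layer; layers are re-aggregated and the model refit.
        With a plain (unstratified) response matrix this reduces to whole
        -matrix node-label permutation.  Used for any number of predictors.
    ``dsp``
        Dekker-style double semi-partialling for 2+ predictors on an
        aggregate matrix: the focal predictor's residuals (given the other
        predictors) are node-label permuted and the response refit on the
        permuted residuals, per focal predictor.
    """
    if covariate is not None:
        predictors = {**predictors, "bout_overlap": covariate}
    names = list(predictors)
    stratified = isinstance(response, DayStratifiedNetwork)
    agg = response.aggregate() if stratified else response
    ids = agg.ids
    n = len(ids)
    rng = np.random.default_rng(seed)

    pred_mats = [predictors[k] for k in names]
    for m in pred_mats:
        if m.ids != ids:
            raise ValueError("predictor and response id universes differ")
    X, _ = _vectorize_masked([agg] + pred_mats)
    y, X = X[:, 0], X[:, 1:]
    if y.size == 0:
        raise ValueError("no non-missing dyads after masking")
    beta_obs = _ols(X, y)
    coefs = dict(zip(names, beta_obs[1:]))
    iu, ju = agg.upper_indices()
    pred_mask = np.ones(iu.size, dtype=bool)
    for m in pred_mats:
        pred_mask &= ~m.missing[iu, ju]
    Xfull = np.column_stack([m.values[iu, ju] for m in pred_mats])

    null: dict[str, np.ndarray] = {k: np.empty(n_perm) for k in names}
    if mode == "node_label_constrained":
        if stratified:
            present_pos = {
                p: np.array([i for i, b in enumerate(ids)
                             if b in response.presence.get(p, set(ids))])
                for p in response.periods}
        for t in range(n_perm):
            if stratified:
                total = np.zeros((n, n))
                allmiss = np.ones((n, n), dtype=bool)
                for p in response.periods:
                    lay = response.layers[p]
                    perm = _constrained_perm(rng, n, present_pos[p])
                    sel = np.ix_(perm, perm)
                    vals = lay.values[sel]
                    miss = lay.missing[sel]
                    obs = ~miss
                    total[obs] += vals[obs]
                    allmiss &= miss
            else:
                perm = rng.permutation(n)
                sel = np.ix_(perm, perm)
                total = agg.values[sel]
                allmiss = agg.missing[sel]
            mask = pred_mask & ~allmiss[iu, ju]
            bt = _ols(Xfull[mask], total[iu, ju][mask])
            for j, k in enumerate(names):
                null[k][t] = bt[1 + j]
    elif mode == "dsp":
        if len(names) < 2:
            raise ValueError("dsp mode needs >= 2 predictors")
        mask = pred_mask & agg.observed_upper_mask()
        yv = agg.values[iu, ju][mask]
        for j, k in enumerate(names):
            others = np.delete(Xfull[mask], j, axis=1)
            g = _ols(others, Xfull[mask][:, j])
            resid = Xfull[mask][:, j] - np.column_stack(
                [np.ones(mask.sum()), others]) @ g
            E = np.zeros((n, n))
            E[iu[mask], ju[mask]] = resid
            E += E.T
            for t in range(n_perm):
                perm = rng.permutation(n)
                ep = E[np.ix_(perm, perm)][iu, ju][mask]
                Z = np.column_stack([others, ep])
                bt = _ols(Z, yv)
                null[k][t] = bt[-1]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pvals = {k: p_value(null[k], coefs[k], tail) for k in names}
    return QAPResult(predictors=names, coefficients=coefs,
                     intercept=float(beta_obs[0]), null_draws=null,
                     p_values=pvals, n_perm=n_perm, seed=seed, mode=mode,
                     tail=tail, n_dyads=int(y.size), n_nodes=n)


def daynight_paired_qap(roosting: DayStratifiedNetwork,
                        foraging: DayStratifiedNetwork,
                        n_perm: int = 1000, seed: int | None = None,
                        n_boot: int = 5000, min_shared: int = 3
                        ) -> dict:
    """Per-day QAP of each night's foraging network on that day's roosting
    network, with a bootstrap (days resampled as units) percentile CI of
    the mean slope.

    Days with fewer than ``min_shared`` bats present in both periods are
    skipped and reported.
    """
    if len(roosting.periods) < 2 or len(foraging.periods) < 2:
        raise ValueError("need >= 2 paired day/night layers")
    rng = np.random.default_rng(seed)
    results, slopes, skipped = [], [], []
    for day_p, night_p in zip(roosting.periods, foraging.periods):
        shared = sorted(roosting.presence.get(day_p, set(roosting.ids))
                        & foraging.presence.get(night_p, set(foraging.ids)))
        if len(shared) < min_shared:
            skipped.append((day_p, night_p, len(shared)))
            continue
        x = roosting.layers[day_p].subset(shared)
        ymat = foraging.layers[night_p].subset(shared)
        try:
            res = qap_regression(ymat, {"roosting": x},
                                 n_perm=n_perm,
                                 seed=int(rng.integers(2**31)),
                                 mode="node_label_constrained")
        except (ValueError, UndefinedStatisticError):
            skipped.append((day_p, night_p, len(shared)))
            continue
        results.append((day_p, res))
        slopes.append(res.coefficients["roosting"])
    if not slopes:
        raise ValueError("no usable day/night pairs")
    slopes = np.array(slopes)
    draws = rng.integers(0, slopes.size, size=(n_boot, slopes.size))
    boot_means = slopes[draws].mean(axis=1)
    lo, hi = np.quantile(boot_means, [0.025, 0.975])
    return {"per_day": results, "slopes": slopes,
            "mean_slope": float(slopes.mean()),
            "ci": (float(lo), float(hi)), "n_boot": n_boot,
            "skipped": skipped, "seed": seed}


# ---------------------------------------------------------------------------
# centrality consistency

def centrality_consistency_test(roost_mean: pd.Series,
                                forage_profiles: pd.DataFrame,
                                n_perm: int = 5000,
                                seed: int | None = None,
                                tail: str = "greater"
                                ) -> PermutationResult:
    """Do bats with more roosting partners also meet more foraging partners?

    ``roost_mean``: per-bat mean daytime degree (index = bat id).
    ``forage_profiles``: long frame (bat, period, degree) of nightly
    foraging degrees, missing rows omitted.  The slope is estimated with
    night effects absorbed (within-night centering of both variables);
    the null permutes foraging degrees among bats within each night.  The
    p-value is one-tailed (default: greater, the hypothesized positive
    consistency) and rank-based against the null distribution, whose
    center need not be zero because presence time links the two
    centralities even under the null.
    """
    rng = np.random.default_rng(seed)
    df = forage_profiles.dropna(subset=["degree"]).copy()
    df = df[df["bat"].isin(roost_mean.dropna().index)]
    if df.empty:
        raise UndefinedStatisticError("no overlapping centrality data")
    df["x"] = df["bat"].map(roost_mean)
    df = df.reset_index(drop=True)
    groups = [g.index.to_numpy() for _, g in df.groupby("period")]
    x = df["x"].to_numpy(dtype=float)
    xc = np.empty_like(x)
    for gi in groups:
        xc[gi] = x[gi] - x[gi].mean()
    den = float((xc * xc).sum())
    if den == 0:
        raise UndefinedStatisticError("no within-period variation in x")
    def slope(y: np.ndarray) -> float:
        num = 0.0
        for gi in groups:
            num += (xc[gi] * (y[gi] - y[gi].mean())).sum()
        return num / den

    y0 = df["degree"].to_numpy(dtype=float)
    observed = slope(y0)
    null = np.empty(n_perm)
    for t in range(n_perm):
        yp = y0.copy()
        for gi in groups:
            yp[gi] = yp[gi][rng.permutation(gi.size)]
        null[t] = slope(yp)
    center = float(np.median(null))
    p = p_value(null, observed, tail)
    return PermutationResult(observed_stat=float(observed), null_draws=null,
                             n_perm=n_perm, seed=seed, p_value=p, tail=tail,
                             centered_stat=float(observed) - center)


# ---------------------------------------------------------------------------
# Mantel test and repeatability

def mantel_test(a: DyadicMatrix, b: DyadicMatrix, n_perm: int = 5000,
                seed: int | None = None, tail: str = "two_sided"
                ) -> PermutationResult:
    """Matrix correlation with node-label permutations of ``b``."""
    if a.ids != b.ids:
        raise ValueError("matrices must share an id universe")
    rng = np.random.default_rng(seed)
    iu, ju = a.upper_indices()
    mask = a.observed_upper_mask() & b.observed_upper_mask()
    x = a.values[iu, ju][mask]
    y = b.values[iu, ju][mask]
    r_obs = _pearson(x, y)
    n = len(a.ids)
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        null[t] = _pearson(x, b.values[np.ix_(perm, perm)][iu, ju][mask])
    p = p_value(null, r_obs, tail)
    return PermutationResult(observed_stat=r_obs, null_draws=null,
                             n_perm=n_perm, seed=seed, p_value=p, tail=tail,
                             centered_stat=r_obs - float(np.median(null)))


def icc_unadjusted(values, groups) -> ICCResult:
    """Unadjusted repeatability (one-way ANOVA intraclass correlation).

    Between-group variance is the method-of-moments estimate
    (MSB - MSW) / n0, truncated at zero, so ICC = 0 is attainable when
    individuals are no more consistent than the population.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)}).dropna()
    sizes = df.groupby("g").size()
    k = len(sizes)
    N = len(df)
    if k < 2:
        raise UndefinedStatisticError("need >= 2 groups")
    if (sizes < 2).all():
        raise UndefinedStatisticError("all groups are singletons")
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k) if N > k else 0.0
    n0 = (N - float((sizes ** 2).sum()) / N) / (k - 1)
    sb2 = max(0.0, (msb - msw) / n0)
    sw2 = msw
    if sb2 + sw2 == 0:
        raise UndefinedStatisticError("total variance is zero")
    return ICCResult(icc=sb2 / (sb2 + sw2), between_var=sb2, within_var=sw2,
                     n_groups=k, group_sizes=sizes.tolist())
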