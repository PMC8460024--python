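"""Symmetric dyadic matrices and day/night-stratified stacks of them.

Every network quantity in the pipeline — association rates, foraging
encounter seconds, co-foraging counts, kinship, bout overlap — is a
symmetric bat-by-bat matrix with a zero diagonal.  Structural missingness
(a dyad that was never observable, e.g. the two bats were never co-present)
is tracked separately from a true zero, because permutation regressions
must drop unobservable dyads rather than treat them as empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: allowed semantic roles for a dyadic matrix
ROLES = ("rate", "seconds", "count", "kinship", "overlap", "adjusted")


@dataclass
class DyadicMatrix:
    """Symmetric dyad-level values over a fixed set of individuals.

    Parameters
    ----------
    ids
        Ordered individual identifiers (row/column labels).
    values
        Square symmetric array, zero diagonal.  Entries under ``missing``
        are ignored wherever the matrix is vectorized.
    role
        Semantic tag; every role except ``adjusted`` requires non-negative
        values (``adjusted`` matrices are residual-like and may be negative).
    missing
        Boolean mask of structurally unobservable dyads (symmetric).
    """

    ids: list[str]
    values: np.ndarray
    role: str = "count"
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("values must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if self.missing is None:
            self.missing = np.zeros((n, n), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (n, n):
                raise ValueError("missing mask shape mismatch")
            if not (self.missing == self.missing.T).all():
                raise ValueError("missing mask must be symmetric")
        obs = self.values[~self.missing]
        if self.role != "adjusted" and obs.size and np.nanmin(obs) < 0:
            raise ValueError(f"role {self.role!r} forbids negative values")

    # -- construction ----------------------------------------------------

    @classmethod
    def zeros(cls, ids: Sequence[str], role: str = "count") -> "DyadicMatrix":
        n = len(ids)
        return cls(list(ids), np.zeros((n, n)), role=role)

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        ids: Sequence[str],
        value_col: str = "value",
        role: str = "count",
    ) -> "DyadicMatrix":
        """Build from long-form rows (bat_a, bat_b, value); symmetrized."""
        idx = {b: i for i, b in enumerate(ids)}
        n = len(ids)
        m = np.zeros((n, n))
        for a, b, v in zip(df["bat_a"], df["bat_b"], df[value_col]):
            i, j = idx[a], idx[b]
            m[i, j] = v
            m[j, i] = v
        return cls(list(ids), m, role=role)

    # -- accessors -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    def upper_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n, k=1)

    def vectorize(self, drop_missing: bool = True) -> np.ndarray:
        """Upper-triangle values; missing dyads dropped by default."""
        iu, ju = self.upper_indices()
        v = self.values[iu, ju]
        if drop_missing:
            v = v[~self.missing[iu, ju]]
        return v

    def observed_upper_mask(self) -> np.ndarray:
        iu, ju = self.upper_indices()
        return ~self.missing[iu, ju]

    def subset(self, keep: Sequence[str]) -> "DyadicMatrix":
        pos = [self.ids.index(b) for b in keep]
        sel = np.ix_(pos, pos)
        return DyadicMatrix(list(keep), self.values[sel], role=self.role,
                            missing=self.missing[sel])

    def relabelled(self, perm: np.ndarray) -> "DyadicMatrix":
        """Apply a node-label permutation: node i takes the row/col of perm[i]."""
        sel = np.ix_(perm, perm)
        return DyadicMatrix(self.ids, self.values[sel], role=self.role,
                            missing=self.missing[sel])

    def to_long(self, period: str | None = None) -> pd.DataFrame:
        iu, ju = self.upper_indices()
        df = pd.DataFrame({
            "bat_a": [self.ids[i] for i in iu],
            "bat_b": [self.ids[j] for j in ju],
            "value": self.values[iu, ju],
            "missing": self.missing[iu, ju],
        })
        if period is not None:
            df["period"] = period
        return df


@dataclass
class DayStratifiedNetwork:
    """Ordered day- or night-indexed layers of :class:`DyadicMatrix`.

    This is the unit constrained node-label permutations act on: each layer
    carries its own presence set, and a relabelling of a layer is only ever
    drawn among the individuals present in that period.
    """

    periods: list[str]
    layers: dict[str, DyadicMatrix] = field(default_factory=dict)
    presence: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = None
        for p in self.periods:
            lay = self.layers[p]
            if ids is None:
                ids = lay.ids
            elif lay.ids != ids:
                raise ValueError("all layers must share an identical id order")
            absent = set(ids) - set(self.presence.get(p, set(ids)))
            # absent bats must be structurally missing, not zero
            off_diag = ~np.eye(len(ids), dtype=bool)
            for b in absent:
                i = ids.index(b)
                if not lay.missing[i, off_diag[i]].all():
                    raise ValueError(f"bat {b} absent in {p} must be masked missing")

    @property
    def ids(self) -> list[str]:
        return self.layers[self.periods[0]].ids

    def aggregate(self, role: str | None = None) -> DyadicMatrix:
        """Sum layers; a dyad is missing only if missing in every layer."""
        ids = self.ids
        n = len(ids)
        total = np.zeros((n, n))
        all_missing = np.ones((n, n), dtype=bool)
        for p in self.periods:
            lay = self.layers[p]
            obs = ~lay.missing
            total[obs] += lay.values[obs]
            all_missing &= lay.missing
        return DyadicMatrix(ids, total, role=role or self.layers[self.periods[0]].role,
                            missing=all_missing)


def masked_for_presence(ids: Sequence[str], values: np.ndarray,
                        present: Iterable[str], role: str) -> DyadicMatrix:
    """Wrap ``values`` masking every dyad that touches an absent individual."""
    ids = list(ids)
    absent = [i for i, b in enumerate(ids) if b not in set(present)]
    missing = np.zeros((len(ids), len(ids)), dtype=bool)
    missing[absent, :] = True
    missing[:, absent] = True
    np.fill_diagonal(missing, False)
    vals = values.copy()
    vals[missing] = 0.0
    return DyadicMatrix(ids, vals, role=role, missing=missing)
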