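"""Descriptor/activity tables, correlation pruning, and the sphere-exclusion
train/test split used before model building.

Activities are handled as log10 IC50 in µM; the loader converts a raw IC50
column at load time and keeps both columns. Rows with missing descriptor
values are excluded (with a logged count), never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACTIVITY_COL = "log_ic50"
IC50_COL = "ic50_uM"
ID_COL = "compound_id"
SMILES_COL = "smiles"
_RESERVED = {ID_COL, SMILES_COL, ACTIVITY_COL, IC50_COL}


@dataclass
class ActivityTable:
    """A table of compounds x (descriptors + observed activity).

    ``df`` is indexed by unique compound id; descriptor columns are
    ``descriptor_names``; the modeled response is ``log_ic50`` (log10 µM).
    """

    df: pd.DataFrame
    descriptor_names: list[str]
    n_dropped: int = 0

    def __post_init__(self):
        if not self.df.index.is_unique:
            dupes = self.df.index[self.df.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound ids: {dupes}")
        missing = [c for c in self.descriptor_names if c not in self.df.columns]
        if missing:
            raise ValueError(f"descriptor columns absent from table: {missing}")

    @property
    def ids(self) -> list:
        return list(self.df.index)

    @property
    def has_activity(self) -> bool:
        return ACTIVITY_COL in self.df.columns

    def X(self, names: Optional[Sequence[str]] = None) -> pd.DataFrame:
        return self.df[list(names or self.descriptor_names)]

    def y(self) -> pd.Series:
        if not self.has_activity:
            raise ValueError("table carries no activity column")
        return self.df[ACTIVITY_COL]

    def subset(self, ids: Sequence) -> "ActivityTable":
        return ActivityTable(self.df.loc[list(ids)], list(self.descriptor_names))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        descriptor_names: Optional[Sequence[str]] = None,
    ) -> "ActivityTable":
        """Build a table from a DataFrame with a ``compound_id`` column (or a
        named index), optional ``smiles``, and either ``log_ic50`` or
        ``ic50_uM`` activity columns."""
        df = df.copy()
        if ID_COL in df.columns:
            df = df.set_index(ID_COL)
        if IC50_COL in df.columns and ACTIVITY_COL not in df.columns:
            df[ACTIVITY_COL] = np.log10(df[IC50_COL].astype(float))
        if ACTIVITY_COL in df.columns and IC50_COL not in df.columns:
            df[IC50_COL] = 10.0 ** df[ACTIVITY_COL].astype(float)
        if descriptor_names is None:
            descriptor_names = [c for c in df.columns if c not in _RESERVED]
        descriptor_names = list(descriptor_names)
        n0 = len(df)
        keep = df[descriptor_names].notna().all(axis=1)
        if ACTIVITY_COL in df.columns:
            keep &= np.isfinite(df[ACTIVITY_COL].astype(float))
        df = df[keep]
        dropped = n0 - len(df)
        if dropped:
            logger.warning("excluded %d row(s) with missing descriptor/activity values", dropped)
        return cls(df, descriptor_names, n_dropped=dropped)

    @classmethod
    def from_csv(cls, path, descriptor_names: Optional[Sequence[str]] = None) -> "ActivityTable":
        return cls.from_dataframe(pd.read_csv(path), descriptor_names)

    def to_csv(self, path) -> None:
        self.df.reset_index(names=ID_COL).to_csv(path, index=False)


@dataclass
class DataSplit:
    """A train/test assignment from sphere exclusion.

    ``standardization`` holds per-descriptor (mean, sd) computed on the
    training set, for downstream scaling.
    """

    train_ids: list
    test_ids: list
    radius: float
    seed: int
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, "train") for i in self.train_ids] + [(i, "test") for i in self.test_ids]
        return pd.DataFrame(rows, columns=[ID_COL, "assignment"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, radius: float = float("nan"), seed: int = 0) -> "DataSplit":
        df = pd.read_csv(path)
        train = df.loc[df["assignment"] == "train", ID_COL].tolist()
        test = df.loc[df["assignment"] == "test", ID_COL].tolist()
        return cls(train, test, radius, seed)


def correlation_prune(
    table: ActivityTable, cutoff: float
) -> tuple[list[str], pd.DataFrame, list[str]]:
    """Greedy removal of highly intercorrelated descriptors.

    While any retained pair has |Pearson r| > cutoff, the pair with the
    largest |r| is resolved by dropping the member with the lower
    |correlation to activity| (ties: the higher column index goes).
    Zero-variance descriptors are dropped first.

    Returns (retained names, full correlation matrix, dropped names).
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if len(table.df) < 2:
        raise ValueError("correlation pruning needs at least 2 rows")
    X = table.X().astype(float)
    corr = X.corr()

    names = list(table.descriptor_names)
    dropped = [c for c in names if X[c].std(ddof=0) == 0]
    if dropped:
        logger.warning("dropping zero-variance descriptors: %s", dropped)
    retained = [c for c in names if c not in dropped]

    if table.has_activity:
        y = table.y().astype(float)
        act_corr = {c: abs(X[c].corr(y)) if X[c].std(ddof=0) > 0 else 0.0 for c in names}
        act_corr = {c: (0.0 if np.isnan(v) else v) for c, v in act_corr.items()}
    else:
        act_corr = {c: 0.0 for c in names}
    col_index = {c: i for i, c in enumerate(names)}

    while True:
        worst: Optional[tuple[float, str, str]] = None
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = abs(corr.loc[a, b])
                if r > cutoff and (worst is None or r > worst[0]):
                    worst = (r, a, b)
        if worst is None:
            break
        _, a, b = worst
        if act_corr[a] != act_corr[b]:
            victim = a if act_corr[a] < act_corr[b] else b
        else:
            victim = a if col_index[a] > col_index[b] else b
        retained.remove(victim)
        dropped.append(victim)
    return retained, corr, dropped


def sphere_exclusion_split(table: ActivityTable, radius: float, seed: int = 0) -> DataSplit:
    """Activity-ordered sphere-exclusion split.

    Descriptors are z-standardized (whole-table statistics) for the Euclidean
    geometry. Compounds are visited in decreasing activity order (seeded
    shuffle breaks exact-activity ties); each unassigned visit becomes a
    TRAIN point and every unassigned compound within ``radius`` of it goes to
    TEST. Radius 0 therefore yields an all-train split.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if len(table.df) < 2:
        raise ValueError("need at least 2 compounds to split")
    X = table.X().to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    y = table.y().to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(len(y))  # tie-break only
    order = np.lexsort((jitter, -y))

    assigned = np.zeros(len(y), dtype=bool)
    is_train = np.zeros(len(y), dtype=bool)
    for idx in order:
        if assigned[idx]:
            continue
        assigned[idx] = True
        is_train[idx] = True
        d = np.linalg.norm(Z - Z[idx], axis=1)
        captured = (~assigned) & (d <= radius)
        assigned |= captured

    ids = np.array(table.ids, dtype=object)
    train_ids = [i for i, t in zip(ids, is_train) if t]
    test_ids = [i for i, t in zip(ids, is_train) if not t]
    train_X = table.df.loc[train_ids, table.descriptor_names].astype(float)
    standardization = {
        c: (float(train_X[c].mean()), float(train_X[c].std(ddof=0)))
        for c in table.descriptor_names
    }
    return DataSplit(train_ids, test_ids, float(radius), seed, standardization)


def radius_for_train_fraction(
    table: ActivityTable,
    target: float = 0.8,
    seed: int = 0,
    tol: float = 0.02,
    max_iter: int = 60,
) -> float:
    """Bisection helper: a radius whose split puts roughly ``target`` of the
    compounds in the training set."""
    if not 0 < target <= 1:
        raise ValueError("target fraction must be in (0, 1]")
    lo, hi = 0.0, 1.0
    n = len(table.df)
    # grow hi until train fraction falls below target
    for _ in range(30):
        frac = len(sphere_exclusion_split(table, hi, seed).train_ids) / n
        if frac < target:
            break
        hi *= 2
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        frac = len(sphere_exclusion_split(table, mid, seed).train_ids) / n
        if abs(frac - target) <= tol:
            return mid
        if frac > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def unicolumn_stats(table: ActivityTable, split: DataSplit) -> dict:
    """Per-set {mean, max, min, sd} for activity and every descriptor, plus a
    range-coverage verdict: "covered" iff the test activity range lies inside
    the train activity range (inclusive)."""
    cols = [ACTIVITY_COL] + list(table.descriptor_names) if table.has_activity else list(
        table.descriptor_names
    )

    def stats_for(ids):
        sub = table.df.loc[list(ids), cols].astype(float)
        return {
            c: {
                "mean": float(sub[c].mean()),
                "max": float(sub[c].max()),
                "min": float(sub[c].min()),
                "sd": float(sub[c].std(ddof=0)),
            }
            for c in cols
        }

    out: dict = {"train": stats_for(split.train_ids)}
    if not split.test_ids:
        out["test"] = None
        out["verdict"] = "not applicable"
        return out
    out["test"] = stats_for(split.test_ids)
    if table.has_activity:
        tr = out["train"][ACTIVITY_COL]
        te = out["test"][ACTIVITY_COL]
        covered = te["max"] <= tr["max"] and te["min"] >= tr["min"]
        out["verdict"] = "covered" if covered else "not covered"
    else:
        out["verdict"] = "not applicable"
    return out
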