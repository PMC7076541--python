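"""Core data model for multi-environment half-diallel trials.

A half diallel crosses ``p`` parents in all unordered combinations, without
reciprocals.  Griffing's method 4 analyses the ``p(p-1)/2`` F1 crosses only;
method 2 additionally includes the ``p`` selfed parents, giving
``p(p+1)/2`` entries.  Entries are grown in a randomized complete block
design (RCBD) with ``r`` replicates, repeated across ``E`` environments.

This module holds the design description, the long-format plot records,
entry-mean (cross-table) construction, balance validation and the
skewness/kurtosis/Q-Q normality checks applied before any ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiallelDesign",
    "PlotRecord",
    "CrossMeansMatrix",
    "BalanceReport",
    "QCStats",
    "REC_COLS",
    "read_phenotype_table",
    "write_phenotype_table",
    "records_from_frame",
    "read_distance_csv",
    "validate_design",
    "entry_means",
    "qc_normality",
]

Method = Literal["method2", "method4"]
TraitDirection = Literal["higher_better", "lower_better"]

#: canonical column order of a long-format record table
REC_COLS = ["env", "block", "parent_a", "parent_b", "trait", "value"]

# traits where a smaller value is agronomically better (earliness expressed
# as days to ripening); everything else defaults to higher_better
_LOWER_BETTER_DEFAULTS = {"dtr", "earliness", "days_to_ripening"}


@dataclass(frozen=True)
class DiallelDesign:
    """Description of a half-diallel mating design in an RCBD.

    Parameters
    ----------
    parents
        Ordered parent identifiers; order fixes entry canonicalization
        and rank tie-breaking.
    method
        ``"method4"`` (crosses only) or ``"method2"`` (crosses + selfs);
        reciprocals are never included.
    n_reps
        Number of complete blocks ``r`` per environment.
    environments
        Ordered environment identifiers.
    trait_directions
        Optional map trait name -> ``higher_better``/``lower_better``.
        DTR/earliness default to ``lower_better``, all else to
        ``higher_better``.
    """

    parents: tuple[str, ...]
    method: Method = "method4"
    n_reps: int = 3
    environments: tuple[str, ...] = ("env1",)
    trait_directions: dict[str, TraitDirection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(str(p) for p in self.parents))
        object.__setattr__(self, "environments", tuple(str(e) for e in self.environments))
        if len(set(self.parents)) != len(self.parents):
            raise ValueError("duplicate parent identifiers")
        if self.n_parents < 3:
            raise ValueError("a diallel needs at least 3 parents")
        if self.method not in ("method2", "method4"):
            raise ValueError(f"unknown Griffing method {self.method!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")
        if len(set(self.environments)) != len(self.environments):
            raise ValueError("duplicate environment identifiers")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def n_entries(self) -> int:
        p = self.n_parents
        return p * (p + 1) // 2 if self.method == "method2" else p * (p - 1) // 2

    def entries(self) -> list[tuple[str, str]]:
        """Canonical (parent_a, parent_b) pairs; selfs included for method 2."""
        p = self.parents
        out = [(p[i], p[j]) for i in range(len(p)) for j in range(i + 1, len(p))]
        if self.method == "method2":
            out = [(a, a) for a in p] + out
        return out

    def crosses(self) -> list[tuple[str, str]]:
        p = self.parents
        return [(p[i], p[j]) for i in range(len(p)) for j in range(i + 1, len(p))]

    def canonical_pair(self, a: str, b: str) -> tuple[str, str]:
        """Order an unordered parent pair by position in ``parents``."""
        idx = {name: i for i, name in enumerate(self.parents)}
        if a not in idx:
            raise KeyError(f"unknown parent {a!r}")
        if b not in idx:
            raise KeyError(f"unknown parent {b!r}")
        return (a, b) if idx[a] <= idx[b] else (b, a)

    def direction(self, trait: str) -> TraitDirection:
        if trait in self.trait_directions:
            return self.trait_directions[trait]
        if trait.lower() in _LOWER_BETTER_DEFAULTS:
            return "lower_better"
        return "higher_better"


class PlotRecord(NamedTuple):
    """One observation of one entry in one block of one environment."""

    env: str
    block: str
    parent_a: str
    parent_b: str
    trait: str
    value: float


# ---------------------------------------------------------------------------
# record I/O


def records_from_frame(frame: pd.DataFrame, design: DiallelDesign) -> pd.DataFrame:
    """Canonicalize and validate a long-format record table.

    Enforces known parents (naming the offending row), finite values, and
    uniqueness of (env, block, entry, trait).  ``(b, a)`` pairs are silently
    reordered to the canonical ``(a, b)``.
    """
    df = frame.loc[:, REC_COLS].copy()
    idx = {name: i for i, name in enumerate(design.parents)}
    for col in ("parent_a", "parent_b"):
        df[col] = df[col].astype(str)
        unknown = ~df[col].isin(idx)
        if unknown.any():
            row = df.index[unknown][0]
            raise ValueError(
                f"unknown parent {df.loc[row, col]!r} in row {row} (column {col})"
            )
    swap = df["parent_a"].map(idx).to_numpy() > df["parent_b"].map(idx).to_numpy()
    a = df["parent_a"].to_numpy().copy()
    df.loc[swap, "parent_a"] = df.loc[swap, "parent_b"].to_numpy()
    df.loc[swap, "parent_b"] = a[swap]
    df["env"] = df["env"].astype(str)
    df["block"] = df["block"].astype(str)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    n_missing = int(df["value"].isna().sum())
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    if not np.isfinite(df["value"]).all():
        raise ValueError("non-finite trait value encountered")

    key = ["env", "block", "parent_a", "parent_b", "trait"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].tolist()
        raise ValueError(f"duplicate observation for (env, block, entry, trait) = {first}")
    df.attrs["n_records"] = len(df)
    df.attrs["n_missing_cells"] = n_missing
    return df


def read_phenotype_table(path: str | Path, design: DiallelDesign) -> pd.DataFrame:
    """Read a wide phenotype CSV into the canonical long record table.

    The file must carry header columns ``env, block, parent_a, parent_b``
    followed by one column per trait.  Missing trait cells are tolerated
    (dropped and counted in ``.attrs['n_missing_cells']``); unknown parents
    and duplicated plots are hard errors.
    """
    wide = pd.read_csv(path)
    required = ["env", "block", "parent_a", "parent_b"]
    missing = [c for c in required if c not in wide.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required columns {missing}")
    traits = [c for c in wide.columns if c not in required]
    if not traits:
        raise ValueError("phenotype table has no trait columns")
    long = wide.melt(id_vars=required, value_vars=traits, var_name="trait", value_name="value")
    return records_from_frame(long, design)


def write_phenotype_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write long records back to the wide CSV layout of ``read_phenotype_table``."""
    wide = records.pivot_table(
        index=["env", "block", "parent_a", "parent_b"],
        columns="trait",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    wide.to_csv(path, index=False)


def read_distance_csv(path: str | Path) -> pd.DataFrame:
    """Read a labelled symmetric matrix CSV (first row/column = parent names)."""
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    if list(m.index) != list(m.columns):
        raise ValueError("distance matrix row and column labels differ")
    if not np.allclose(m.to_numpy(), m.to_numpy().T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    return m


# ---------------------------------------------------------------------------
# balance validation


@dataclass
class BalanceReport:
    """Per environment x trait completeness of the RCBD layout."""

    balanced: bool
    missing: list[tuple[str, str, tuple[str, str], str]]
    diagonal_absent: bool = False

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.balanced


def validate_design(
    records: pd.DataFrame,
    design: DiallelDesign,
    traits: Sequence[str] | None = None,
) -> BalanceReport:
    """Check that every entry appears once in every block of every environment.

    Returns a report (never raises); the ANOVA stages require
    ``report.balanced`` and refuse otherwise.  For a method-2 design with no
    selfed records at all, the ``diagonal_absent`` flag is set.
    """
    if records.empty:
        raise ValueError("no records supplied")
    traits = list(traits) if traits is not None else sorted(records["trait"].unique())
    entries = design.entries()
    missing: list[tuple[str, str, tuple[str, str], str]] = []
    grouped = records.groupby(["trait", "env", "block", "parent_a", "parent_b"]).size()
    for trait in traits:
        sub = records[records["trait"] == trait]
        envs = [e for e in design.environments if e in set(sub["env"])]
        for env in envs:
            blocks = sorted(sub.loc[sub["env"] == env, "block"].unique())
            for block in blocks:
                for entry in entries:
                    if (trait, env, block, entry[0], entry[1]) not in grouped.index:
                        missing.append((env, block, entry, trait))
    diagonal_absent = False
    if design.method == "method2":
        selfs = records[records["parent_a"] == records["parent_b"]]
        diagonal_absent = selfs.empty
    return BalanceReport(balanced=not missing and not diagonal_absent,
                         missing=missing, diagonal_absent=diagonal_absent)


# ---------------------------------------------------------------------------
# entry means


@dataclass
class CrossMeansMatrix:
    """``p x p`` symmetric table of entry means for one trait x environment.

    ``values.iloc[i, j]`` is the mean of cross i x j over replicates; the
    diagonal holds selfed-parent means for method 2 and is NaN for method 4.
    In a balanced RCBD the arithmetic entry mean equals the least-squares
    mean (LsM).
    """

    values: pd.DataFrame
    method: Method
    n_reps: int = 1

    def __post_init__(self) -> None:
        v = self.values
        if list(v.index) != list(v.columns):
            raise ValueError("cross-means matrix must share row and column labels")
        off = ~np.eye(len(v), dtype=bool)
        arr = v.to_numpy(dtype=float)
        if not np.allclose(arr[off], arr.T[off], equal_nan=True):
            raise ValueError("cross-means matrix must be symmetric")
        if self.method == "method2" and np.isnan(np.diag(arr)).any():
            raise ValueError("method-2 matrix requires selfed-parent diagonal")

    @property
    def parents(self) -> list[str]:
        return list(self.values.index)

    @property
    def p(self) -> int:
        return len(self.values)

    def cross_row_totals(self) -> pd.Series:
        """X_i. : per-parent total over its crosses (diagonal excluded)."""
        arr = self.values.to_numpy(dtype=float).copy()
        np.fill_diagonal(arr, 0.0)
        return pd.Series(np.nansum(arr, axis=1), index=self.values.index)

    def cross_total(self) -> float:
        """X.. : grand total over the p(p-1)/2 crosses."""
        return float(self.cross_row_totals().sum() / 2.0)

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.values.to_numpy(dtype=float)), index=self.values.index)

    def cross_series(self) -> pd.Series:
        """Off-diagonal values as a Series indexed by canonical (a, b) pairs."""
        p = self.parents
        data = {
            (p[i], p[j]): float(self.values.iloc[i, j])
            for i in range(len(p))
            for j in range(i + 1, len(p))
        }
        return pd.Series(data)


def entry_means(
    records: pd.DataFrame,
    trait: str,
    environment: str,
    design: DiallelDesign,
) -> CrossMeansMatrix:
    """Average each entry over replicates into a :class:`CrossMeansMatrix`.

    Requires a balanced layout for that environment x trait (checked with
    :func:`validate_design`); under balance the arithmetic mean equals the
    entry's least-squares mean.
    """
    sub = records[(records["trait"] == trait) & (records["env"] == environment)]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r} in environment {environment!r}")
    report = validate_design(sub, design, traits=[trait])
    if not report.balanced:
        raise ValueError(
            "unbalanced layout for "
            f"{trait!r} in {environment!r}; run validate_design for details"
        )
    n_blocks = sub["block"].nunique()
    means = sub.groupby(["parent_a", "parent_b"])["value"].mean()
    p = design.parents
    mat = pd.DataFrame(np.nan, index=list(p), columns=list(p))
    for (a, b), v in means.items():
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    return CrossMeansMatrix(values=mat, method=design.method, n_reps=n_blocks)


# ---------------------------------------------------------------------------
# distribution QC


@dataclass
class QCStats:
    """Moment-based normality diagnostics for one trait x environment."""

    n: int
    mean: float
    skewness: float
    excess_kurtosis: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    zero_variance: bool = False


def qc_normality(records: pd.DataFrame, trait: str, environment: str) -> QCStats:
    """Skewness g1 = m3/m2^1.5, excess kurtosis g2 = m4/m2^2 - 3, and Q-Q pairs.

    The Q-Q pairs are (standard-normal theoretical quantile, sorted sample
    value) for an external plot.  Zero-variance samples are flagged with
    NaN moments rather than raising.
    """
    x = records.loc[
        (records["trait"] == trait) & (records["env"] == environment), "value"
    ].to_numpy(dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("qc_normality needs at least 4 observations")
    order = np.sort(x)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    if np.ptp(x) == 0.0:
        return QCStats(n, float(x.mean()), np.nan, np.nan, theo, order, zero_variance=True)
    g1 = float(stats.skew(x, bias=True))
    g2 = float(stats.kurtosis(x, fisher=True, bias=True))
    return QCStats(n, float(x.mean()), g1, g2, theo, order)
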