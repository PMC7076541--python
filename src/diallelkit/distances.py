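"""Phenotypic distance matrices and the Mantel permutation test.

Supports the matrix-correlation workflow of diallel studies: build
Euclidean (on standardized trait profiles) and Mahalanobis D2 (via the
pooled within-group covariance, equivalently canonical-variate space)
distance matrices between parents, arrange per-cross statistics (LsM, SCA,
MPH, BPH) as parent x parent matrices, and correlate any two matrices with
the Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import DiallelDesign

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "euclidean_matrix",
    "mahalanobis_matrix",
    "cross_statistic_to_matrix",
    "mantel",
]

Kind = Literal["genetic", "euclidean", "mahalanobis", "cross_statistic"]


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix with zero diagonal.

    True distances (genetic / euclidean / mahalanobis) must be nonnegative;
    ``cross_statistic`` matrices hold signed per-cross quantities and are
    exempt.
    """

    values: pd.DataFrame
    kind: Kind

    def __post_init__(self) -> None:
        v = self.values
        if list(v.index) != list(v.columns):
            raise ValueError("distance matrix labels mismatch")
        arr = v.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal must be zero")
        if self.kind != "cross_statistic" and (arr < -1e-10).any():
            raise ValueError(f"{self.kind} distances must be nonnegative")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) values in canonical label order."""
        arr = self.values.to_numpy(dtype=float)
        return arr[np.triu_indices(len(arr), 1)]


@dataclass
class MantelResult:
    r: float
    n_perm: int
    p_value: float
    seed: int | None
    alternative: str


def euclidean_matrix(profiles: pd.DataFrame, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distances between per-parent trait vectors.

    ``profiles`` is parents x traits.  Traits are z-scored first (sample SD,
    ddof=1) so kg-scale traits cannot dominate Brix-scale ones; parents with
    any missing trait value are excluded with a warning attribute.
    """
    prof = profiles.astype(float)
    dropped = prof.index[prof.isna().any(axis=1)].tolist()
    prof = prof.dropna()
    if len(prof) < 2:
        raise ValueError("need at least 2 complete parent profiles")
    if standardize:
        sd = prof.std(ddof=1)
        sd = sd.replace(0.0, 1.0)  # constant traits carry no distance
        prof = (prof - prof.mean()) / sd
    d = squareform(pdist(prof.to_numpy(), metric="euclidean"))
    out = DistanceMatrix(
        values=pd.DataFrame(d, index=prof.index, columns=prof.index),
        kind="euclidean",
    )
    out.values.attrs["excluded_parents"] = dropped
    return out


def mahalanobis_matrix(
    records: pd.DataFrame,
    traits: list[str],
    env: str,
    design: DiallelDesign,
    squared: bool = True,
) -> DistanceMatrix:
    """Mahalanobis D2 between selfed parents from replicate-level records.

    Each parent's replicates (one multivariate observation per block) form a
    group; W is the pooled within-group covariance and
    D2_ab = (xbar_a - xbar_b)' W^-1 (xbar_a - xbar_b), i.e. the squared
    Euclidean distance between group means in canonical-variate space.
    """
    sub = records[(records["env"] == env)
                  & (records["parent_a"] == records["parent_b"])
                  & (records["trait"].isin(traits))]
    if sub.empty:
        raise ValueError("no selfed-parent records for the requested traits/environment")
    wide = sub.pivot_table(index=["parent_a", "block"], columns="trait", values="value")
    wide = wide.reindex(columns=traits).dropna()
    groups = [p for p in design.parents if p in wide.index.get_level_values(0)]
    if len(groups) < 2:
        raise ValueError("need at least 2 parents with complete replicate profiles")
    means = {}
    W = np.zeros((len(traits), len(traits)))
    n_within = 0
    for g in groups:
        block = wide.loc[g].to_numpy(dtype=float)
        means[g] = block.mean(axis=0)
        dev = block - block.mean(axis=0)
        W += dev.T @ dev
        n_within += len(block) - 1
    if n_within < len(traits):
        raise ValueError("too few replicates to estimate the within-group covariance; "
                         "reduce the trait set")
    W /= n_within
    try:
        Winv = np.linalg.inv(W)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled covariance; reduce the trait set") from exc
    M = np.array([means[g] for g in groups])
    diff = M[:, None, :] - M[None, :, :]
    d2 = np.einsum("abi,ij,abj->ab", diff, Winv, diff)
    d2 = (d2 + d2.T) / 2.0
    np.fill_diagonal(d2, 0.0)
    vals = d2 if squared else np.sqrt(np.maximum(d2, 0.0))
    return DistanceMatrix(
        values=pd.DataFrame(vals, index=groups, columns=groups),
        kind="mahalanobis",
    )


def cross_statistic_to_matrix(
    values: Mapping[tuple[str, str], float] | pd.Series,
    parents: list[str],
) -> DistanceMatrix:
    """Arrange one value per unordered cross as a symmetric parent x parent matrix."""
    if isinstance(values, pd.Series):
        values = dict(values.items())
    mat = pd.DataFrame(0.0, index=parents, columns=parents)
    seen = set()
    for (a, b), v in values.items():
        if a not in parents or b not in parents:
            raise KeyError(f"unknown parent in cross ({a}, {b})")
        mat.loc[a, b] = v
        mat.loc[b, a] = v
        seen.add(frozenset((a, b)))
    expect = {frozenset((parents[i], parents[j]))
              for i in range(len(parents)) for j in range(i + 1, len(parents))}
    missing = expect - seen
    if missing:
        pair = sorted(next(iter(missing)))
        raise ValueError(f"missing cross value, e.g. {tuple(pair)}")
    return DistanceMatrix(values=mat, kind="cross_statistic")


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: Literal["greater", "two-sided"] = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation correlation between two labelled matrices.

    r is the Pearson correlation of the p(p-1)/2 upper-triangle pairs; the
    null distribution comes from jointly permuting rows and columns of B.
    p = (#{r_perm >= r_obs} + 1)/(n_perm + 1) for the upper tail (the
    default, testing for positive matrix correlation); ``two-sided``
    compares |r_perm| >= |r_obs|.  With ``exact=True`` every one of the n!
    relabelings is enumerated (small matrices only) and
    p = #{r_perm >= r_obs}/n! with the identity included.
    """
    if A.labels != B.labels:
        raise ValueError("matrices must share labels and order")
    n = len(A.labels)
    a = A.condensed()
    b_full = B.values.to_numpy(dtype=float)
    iu = np.triu_indices(n, 1)

    def corr(bvec: np.ndarray) -> float:
        return float(np.corrcoef(a, bvec)[0, 1])

    r_obs = corr(b_full[iu])
    if exact:
        from itertools import permutations
        from math import factorial

        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = 0
        for perm in permutations(range(n)):
            idx = np.array(perm)
            r_p = corr(b_full[np.ix_(idx, idx)][iu])
            if alternative == "greater":
                count += r_p >= r_obs - 1e-12
            else:
                count += abs(r_p) >= abs(r_obs) - 1e-12
        total = factorial(n)
        return MantelResult(r=r_obs, n_perm=total, p_value=count / total,
                            seed=seed, alternative=alternative)
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b_full[np.ix_(perm, perm)][iu]
        r_p = corr(bp)
        if alternative == "greater":
            count += r_p >= r_obs - 1e-12
        else:
            count += abs(r_p) >= abs(r_obs) - 1e-12
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, n_perm=n_perm, p_value=float(p),
                        seed=seed, alternative=alternative)
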