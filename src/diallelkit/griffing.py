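"""Griffing combining-ability estimation and diallel ANOVA.

Implements the classical fixed-genotype ("Model B": genotypes fixed,
replicates random) analysis of a half diallel:

* method 4 (crosses only) and method 2 (crosses + selfed parents) effect
  estimates — grand mean ``m``, general combining abilities ``g_i`` and
  specific combining abilities ``s_ij`` — from the table of entry means;
* the RCBD ANOVA per environment with the entry sum of squares partitioned
  into GCA and SCA via Griffing's sums, and the combined multi-environment
  ANOVA with Env x GCA / Env x SCA interactions;
* the orthogonal hybrids-vs-parents contrast whose significance indicates
  average heterosis;
* ranking of effects honoring the trait direction.

The decomposition is saturated: ``m + g_i + g_j + s_ij`` reproduces every
entry mean exactly, and SS(GCA) + SS(SCA) = SS(Entries).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core import CrossMeansMatrix, DiallelDesign, TraitDirection, entry_means, validate_design

__all__ = [
    "EffectsResult",
    "AnovaTable",
    "ContrastResult",
    "griffing4_effects",
    "griffing2_effects",
    "anova_single_env",
    "anova_combined",
    "anova_from_mean_squares",
    "parents_vs_hybrids_contrast",
    "rank_effects",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Conventional significance flags at 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class EffectsResult:
    """Saturated combining-ability decomposition of a cross-means table.

    ``g`` sums to zero; for method 4 every SCA row sums to zero over mates,
    for method 2 the Griffing constraint is ``sum_j s_ij + s_ii = 0``.
    Standard errors are filled when an error mean square is available.
    """

    method: Literal["method2", "method4"]
    m: float
    g: pd.Series
    s: pd.DataFrame
    n_reps: int | None = None
    error_ms: float | None = None
    se_g: float | None = None
    se_s: float | None = None
    se_diff_g: float | None = None

    def fitted(self) -> pd.DataFrame:
        """Reconstruct the entry-mean table from m + g_i + g_j + s_ij."""
        gi = self.g.to_numpy()
        fit = self.m + gi[:, None] + gi[None, :] + self.s.to_numpy()
        return pd.DataFrame(fit, index=self.s.index, columns=self.s.columns)


@dataclass
class AnovaTable:
    """ANOVA table plus the design constants the EMS back-solve needs."""

    table: pd.DataFrame  # columns: source, df, SS, MS, F, p
    method: Literal["method2", "method4"]
    n_parents: int
    n_reps: int
    n_envs: int = 1

    def __getitem__(self, source: str) -> pd.Series:
        row = self.table[self.table["source"] == source]
        if row.empty:
            raise KeyError(f"ANOVA table has no source {source!r}")
        return row.iloc[0]

    def has(self, source: str) -> bool:
        return (self.table["source"] == source).any()

    @property
    def error_ms(self) -> float:
        return float(self["Error"]["MS"])

    @property
    def error_df(self) -> float:
        return float(self["Error"]["df"])


@dataclass
class ContrastResult:
    """Hybrids-minus-parents orthogonal contrast on entry means."""

    estimate: float
    se: float
    t: float
    p: float
    df: float
    n_hybrids: int
    n_parents: int


# ---------------------------------------------------------------------------
# effect estimators


def _attach_ses(res: EffectsResult, error_ms: float | None, n_reps: int | None) -> EffectsResult:
    if error_ms is None or n_reps is None or n_reps < 1:
        return res
    p = len(res.g)
    Me, r = float(error_ms), int(n_reps)
    if res.method == "method4":
        se_g = np.sqrt((p - 1) * Me / (p * (p - 2) * r))
        se_s = np.sqrt((p - 3) * Me / ((p - 1) * r))
        se_diff_g = np.sqrt(2 * Me / ((p - 2) * r))
    else:
        se_g = np.sqrt((p - 1) * Me / (p * (p + 2) * r))
        se_s = np.sqrt((p * p + p + 2) * Me / ((p + 1) * (p + 2) * r))
        se_diff_g = np.sqrt(2 * Me / ((p + 2) * r))
    return replace(res, error_ms=Me, n_reps=r,
                   se_g=float(se_g), se_s=float(se_s), se_diff_g=float(se_diff_g))


def griffing4_effects(
    x: CrossMeansMatrix,
    error_ms: float | None = None,
    n_reps: int | None = None,
) -> EffectsResult:
    """Griffing method-4 effects from the cross-means table (selfs excluded).

    g_i = (p X_i. - 2 X..) / (p (p-2)),
    s_ij = x_ij - (X_i. + X_j.)/(p-2) + 2 X.. / ((p-1)(p-2)),
    m = 2 X.. / (p (p-1)).

    Pass ``error_ms`` (the ANOVA error mean square Me) and ``n_reps`` to get
    the standard errors se(g) = sqrt((p-1)Me/(p(p-2)r)) and
    se(s) = sqrt((p-3)Me/((p-1)r)).
    """
    p = x.p
    if p < 4:
        raise ValueError("method 4 needs p >= 4 (SCA df is p(p-3)/2)")
    Xi = x.cross_row_totals()
    Xdd = x.cross_total()
    m = 2.0 * Xdd / (p * (p - 1))
    g = (p * Xi - 2.0 * Xdd) / (p * (p - 2))
    gi = Xi.to_numpy()
    s = (
        x.values.to_numpy(dtype=float)
        - (gi[:, None] + gi[None, :]) / (p - 2)
        + 2.0 * Xdd / ((p - 1) * (p - 2))
    )
    np.fill_diagonal(s, np.nan)
    res = EffectsResult(
        method="method4",
        m=float(m),
        g=g,
        s=pd.DataFrame(s, index=x.values.index, columns=x.values.columns),
        n_reps=n_reps if n_reps is not None else x.n_reps,
    )
    return _attach_ses(res, error_ms, res.n_reps)


def griffing2_effects(
    x: CrossMeansMatrix,
    error_ms: float | None = None,
    n_reps: int | None = None,
) -> EffectsResult:
    """Griffing method-2 effects from the full table including selfs.

    With row totals R_i = sum_j x_ij (diagonal counted once) and half-table
    total T = sum_{i<=j} x_ij:

    g_i = (R_i + x_ii - 2T/p) / (p+2),
    s_ij = x_ij - (R_i + x_ii + R_j + x_jj)/(p+2) + 2T/((p+1)(p+2)),
    m = 2T / (p (p+1)).
    """
    arr = x.values.to_numpy(dtype=float)
    if np.isnan(np.diag(arr)).any():
        raise ValueError("method 2 requires selfed-parent means on the diagonal")
    p = x.p
    diag = np.diag(arr)
    R = arr.sum(axis=1)  # full row sum, diagonal once
    T = (R.sum() + diag.sum()) / 2.0  # half-table total incl. diagonal
    m = 2.0 * T / (p * (p + 1))
    gvec = (R + diag - 2.0 * T / p) / (p + 2)
    q = R + diag
    s = arr - (q[:, None] + q[None, :]) / (p + 2) + 2.0 * T / ((p + 1) * (p + 2))
    res = EffectsResult(
        method="method2",
        m=float(m),
        g=pd.Series(gvec, index=x.values.index),
        s=pd.DataFrame(s, index=x.values.index, columns=x.values.columns),
        n_reps=n_reps if n_reps is not None else x.n_reps,
    )
    return _attach_ses(res, error_ms, res.n_reps)


# ---------------------------------------------------------------------------
# Griffing sums of squares (entry-mean basis; multiply by r for plot basis)


def _griffing_ss_means(x: CrossMeansMatrix) -> tuple[float, float]:
    """(SS_GCA, SS_SCA) on the entry-mean basis for the matrix's method."""
    arr = x.values.to_numpy(dtype=float)
    p = x.p
    if x.method == "method4":
        Xi = x.cross_row_totals().to_numpy()
        Xdd = x.cross_total()
        iu = np.triu_indices(p, 1)
        ss_g = (Xi**2).sum() / (p - 2) - 4.0 * Xdd**2 / (p * (p - 2))
        ss_s = (
            (arr[iu] ** 2).sum()
            - (Xi**2).sum() / (p - 2)
            + 2.0 * Xdd**2 / ((p - 1) * (p - 2))
        )
    else:
        diag = np.diag(arr)
        R = arr.sum(axis=1)
        T = (R.sum() + diag.sum()) / 2.0
        q = R + diag
        iu = np.triu_indices(p)
        ss_g = ((q**2).sum() - 4.0 * T**2 / p) / (p + 2)
        ss_s = (arr[iu] ** 2).sum() - (q**2).sum() / (p + 2) + 2.0 * T**2 / ((p + 1) * (p + 2))
    return float(ss_g), float(ss_s)


def _gca_sca_df(p: int, method: str) -> tuple[int, int]:
    if method == "method4":
        return p - 1, p * (p - 3) // 2
    return p - 1, p * (p - 1) // 2


def _finish_table(rows: list[dict], error_ms: float, error_df: float) -> pd.DataFrame:
    for row in rows:
        if row["source"] in ("Error", "Blocks", "Blocks(Env)") or error_ms <= 0:
            row["F"] = np.nan
            row["p"] = np.nan
        else:
            row["F"] = row["MS"] / error_ms
            row["p"] = float(stats.f.sf(row["F"], row["df"], error_df))
    return pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"])


def _plot_ss(sub: pd.DataFrame) -> tuple[float, float, float, float, int, int]:
    """RCBD plot-level decomposition: (SS_total, SS_blocks, SS_entries, SS_error, n, r)."""
    piv = sub.pivot_table(
        index=["parent_a", "parent_b"], columns="block", values="value", aggfunc="first"
    )
    y = piv.to_numpy(dtype=float)
    n, r = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_blocks = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_entries = r * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_error = ss_total - ss_blocks - ss_entries
    return ss_total, ss_blocks, ss_entries, max(ss_error, 0.0), n, r


def anova_single_env(
    records: pd.DataFrame,
    trait: str,
    env: str,
    method: Literal["method2", "method4"],
    design: DiallelDesign,
) -> AnovaTable:
    """Single-environment RCBD ANOVA with the GCA/SCA partition of entries.

    All F-tests are against the plot error (Model B); entry SS is split by
    the r-scaled Griffing sums so that SS(GCA)+SS(SCA)=SS(Entries).
    """
    d = design if design.method == method else replace(design, method=method)
    sub = records[(records["trait"] == trait) & (records["env"] == env)]
    if method == "method4":
        sub = sub[sub["parent_a"] != sub["parent_b"]]
    if sub.empty:
        raise ValueError(f"no records for {trait!r} in {env!r}")
    report = validate_design(sub, d, traits=[trait])
    if not report.balanced:
        raise ValueError("unbalanced RCBD; run validate_design for details")
    _, ss_blocks, ss_entries, ss_error, n, r = _plot_ss(sub)
    x = entry_means(sub, trait, env, d)
    ss_g_mean, ss_s_mean = _griffing_ss_means(x)
    p = d.n_parents
    df_g, df_s = _gca_sca_df(p, method)
    df_err = (n - 1) * (r - 1)
    rows = [
        {"source": "Blocks", "df": r - 1, "SS": ss_blocks},
        {"source": "Entries", "df": n - 1, "SS": ss_entries},
        {"source": "GCA", "df": df_g, "SS": r * ss_g_mean},
        {"source": "SCA", "df": df_s, "SS": r * ss_s_mean},
        {"source": "Error", "df": df_err, "SS": ss_error},
    ]
    for row in rows:
        row["MS"] = row["SS"] / row["df"] if row["df"] > 0 else np.nan
    me = ss_error / df_err
    return AnovaTable(
        table=_finish_table(rows, me, df_err),
        method=method, n_parents=p, n_reps=r, n_envs=1,
    )


def anova_combined(
    records: pd.DataFrame,
    trait: str,
    method: Literal["method2", "method4"],
    design: DiallelDesign,
    environments: list[str] | None = None,
) -> AnovaTable:
    """Combined ANOVA across environments sharing the entry set.

    Sources: Environments, Blocks(Env), Entries, GCA, SCA, Env x Entries,
    Env x GCA, Env x SCA, Error (pooled within-environment RCBD residual).
    Interaction SS are obtained by applying the Griffing partition within
    each environment and subtracting the pooled-mean partition; every F is
    against the pooled error.
    """
    d = design if design.method == method else replace(design, method=method)
    sub = records[records["trait"] == trait]
    if method == "method4":
        sub = sub[sub["parent_a"] != sub["parent_b"]]
    envs = environments or [e for e in d.environments if e in set(sub["env"])]
    if len(envs) < 2:
        raise ValueError("combined ANOVA needs at least 2 environments")
    per_env_x: list[CrossMeansMatrix] = []
    ss_blocks = ss_error = 0.0
    env_means = []
    n = r = None
    for env in envs:
        s_env = sub[sub["env"] == env]
        report = validate_design(s_env, d, traits=[trait])
        if not report.balanced:
            raise ValueError(f"environment {env!r} unbalanced; run validate_design")
        _, sb, _, se_, n_e, r_e = _plot_ss(s_env)
        if n is None:
            n, r = n_e, r_e
        elif (n_e, r_e) != (n, r):
            raise ValueError("environments differ in entry or block counts")
        ss_blocks += sb
        ss_error += se_
        x = entry_means(s_env, trait, env, d)
        per_env_x.append(x)
        env_means.append(x.values.to_numpy()[~np.isnan(x.values.to_numpy())].mean()
                         if method == "method4" else None)
    E = len(envs)
    p = d.n_parents

    pooled_vals = sum(x.values for x in per_env_x) / E
    pooled = CrossMeansMatrix(values=pooled_vals, method=method, n_reps=r * E)

    def entry_vec(x: CrossMeansMatrix) -> np.ndarray:
        arr = x.values.to_numpy(dtype=float)
        if method == "method4":
            return arr[np.triu_indices(p, 1)]
        return arr[np.triu_indices(p)]

    per_env_entries = np.column_stack([entry_vec(x) for x in per_env_x])  # n x E
    grand = per_env_entries.mean()
    env_bar = per_env_entries.mean(axis=0)
    pooled_bar = per_env_entries.mean(axis=1)

    ss_env = r * n * ((env_bar - grand) ** 2).sum()
    ss_entries = r * E * ((pooled_bar - grand) ** 2).sum()
    ss_env_entries = (
        r * ((per_env_entries - env_bar[None, :] - pooled_bar[:, None] + grand) ** 2).sum()
    )
    ss_g_pooled, ss_s_pooled = _griffing_ss_means(pooled)
    ss_g_env = sum(_griffing_ss_means(x)[0] for x in per_env_x)
    ss_s_env = sum(_griffing_ss_means(x)[1] for x in per_env_x)
    ss_gca = r * E * ss_g_pooled
    ss_sca = r * E * ss_s_pooled
    ss_env_gca = r * ss_g_env - ss_gca
    ss_env_sca = r * ss_s_env - ss_sca

    df_g, df_s = _gca_sca_df(p, method)
    df_err = E * (n - 1) * (r - 1)
    rows = [
        {"source": "Environments", "df": E - 1, "SS": ss_env},
        {"source": "Blocks(Env)", "df": E * (r - 1), "SS": ss_blocks},
        {"source": "Entries", "df": n - 1, "SS": ss_entries},
        {"source": "GCA", "df": df_g, "SS": ss_gca},
        {"source": "SCA", "df": df_s, "SS": ss_sca},
        {"source": "Env x Entries", "df": (E - 1) * (n - 1), "SS": ss_env_entries},
        {"source": "Env x GCA", "df": (E - 1) * df_g, "SS": max(ss_env_gca, 0.0)},
        {"source": "Env x SCA", "df": (E - 1) * df_s, "SS": max(ss_env_sca, 0.0)},
        {"source": "Error", "df": df_err, "SS": ss_error},
    ]
    for row in rows:
        row["MS"] = row["SS"] / row["df"] if row["df"] > 0 else np.nan
    me = ss_error / df_err
    return AnovaTable(
        table=_finish_table(rows, me, df_err),
        method=method, n_parents=p, n_reps=r, n_envs=E,
    )


def anova_from_mean_squares(
    mean_squares: dict[str, float],
    degrees_of_freedom: dict[str, float],
    method: Literal["method2", "method4"],
    n_parents: int,
    n_reps: int,
    n_envs: int = 1,
) -> AnovaTable:
    """Build an :class:`AnovaTable` from published mean squares.

    Useful for re-deriving variance components and standard errors from a
    printed ANOVA when the raw plot data are unavailable.  F and p are
    filled against the supplied Error mean square.
    """
    if "Error" not in mean_squares:
        raise ValueError("mean_squares must include an 'Error' entry")
    rows = []
    for source, ms in mean_squares.items():
        df = degrees_of_freedom.get(source, np.nan)
        rows.append({"source": source, "df": df, "SS": ms * df, "MS": ms})
    me = mean_squares["Error"]
    df_err = degrees_of_freedom.get("Error", np.nan)
    return AnovaTable(
        table=_finish_table(rows, me, df_err),
        method=method, n_parents=n_parents, n_reps=n_reps, n_envs=n_envs,
    )


# ---------------------------------------------------------------------------
# hybrids vs parents


def parents_vs_hybrids_contrast(
    records: pd.DataFrame,
    trait: str,
    env: str,
    design: DiallelDesign,
    anova: AnovaTable | None = None,
) -> ContrastResult:
    """Orthogonal contrast mean(hybrid entries) - mean(selfed parents).

    A significant contrast indicates average (mid-parent) heterosis; for
    lower-better traits such as days to ripening a *negative* estimate means
    hybrids are earlier than their parents.  SE = sqrt(Me (1/n_h + 1/n_p)/r)
    with Me from the method-2 RCBD ANOVA of the same environment.
    """
    d = replace(design, method="method2")
    sub = records[(records["trait"] == trait) & (records["env"] == env)]
    if sub[sub["parent_a"] == sub["parent_b"]].empty:
        raise ValueError("no selfed-parent records; contrast needs method-2-style data")
    if anova is None:
        anova = anova_single_env(records, trait, env, "method2", d)
    x = entry_means(sub, trait, env, d)
    hybrid_means = x.cross_series()
    parent_means = x.diagonal()
    estimate = float(hybrid_means.mean() - parent_means.mean())
    n_h, n_p = len(hybrid_means), len(parent_means)
    me, r = anova.error_ms, anova.n_reps
    se = float(np.sqrt(me * (1.0 / n_h + 1.0 / n_p) / r))
    t = estimate / se if se > 0 else np.nan
    pval = float(2.0 * stats.t.sf(abs(t), anova.error_df)) if np.isfinite(t) else np.nan
    return ContrastResult(estimate, se, t, pval, anova.error_df, n_h, n_p)


# ---------------------------------------------------------------------------
# ranking


@dataclass
class RankedEffects:
    """Direction-aware ranks of GCA and SCA effects (1 = most favorable)."""

    g_rank: pd.Series
    s_rank: pd.Series  # indexed by canonical cross pairs
    ties: bool


def rank_effects(effects: EffectsResult, trait_direction: TraitDirection) -> RankedEffects:
    """Rank effects with rank 1 = best for the trait direction.

    ``higher_better`` ranks the largest effect first; ``lower_better`` (e.g.
    days to ripening) ranks the most negative first.  Ties keep parent
    order and set the ``ties`` flag.
    """
    ascending = trait_direction == "lower_better"
    g_rank = effects.g.rank(ascending=ascending, method="first").astype(int)
    parents = list(effects.s.index)
    pairs = {}
    for i, a in enumerate(parents):
        for j in range(i + 1, len(parents)):
            pairs[(a, parents[j])] = effects.s.iloc[i, j]
    s_series = pd.Series(pairs)
    s_rank = s_series.rank(ascending=ascending, method="first").astype(int)
    ties = bool(effects.g.duplicated().any() or s_series.duplicated().any())
    return RankedEffects(g_rank=g_rank, s_rank=s_rank, ties=ties)
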