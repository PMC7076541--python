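"""Synthetic multi-environment half-diallel trials with known truth.

The generative model mirrors the random ("Model 2") decomposition that the
estimators target:

    y_ijlk = mu + e_l + b_lk + g_i + g_j + s_ij + gE_il + gE_jl + sE_ijl + eps

with selfed entries (method 2) receiving ``2 g_i + s_ii + 2 gE_il + delta``
— ``delta`` is a self penalty emulating inbreeding depression, so a
negative ``delta`` on a higher-better trait produces positive mid-parent
heterosis.  GCA effects are drawn i.i.d. normal and sum-to-zero centered; main-effect
SCA draws are symmetric and projected onto the row-sum-to-zero space over
mates, matching the identifiability constraints of the Griffing estimators
so that effect recovery is well defined.  The SCA x Env draws are kept
i.i.d. (only stratum-mean centered): the random-model expected mean
squares count their GCA content in the Env x GCA line, so projecting them
would bias the variance-component back-solve.  Environment main effects
are fixed offsets by default (``random_env=True`` draws them instead, for
heritability simulation studies).

Default parameters are the conditions of an eight-parent melon half
diallel grown in six Italian environments with three blocks: yield-scale
grand mean 10 kg/plant and variance components
sigma2_g = 1.888, sigma2_s = 0.242, sigma2_gE = 0.204, sigma2_sE = 0.436,
sigma2_e = 2.86 (kg^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import REC_COLS, DiallelDesign
from .griffing import EffectsResult

__all__ = ["SimulationSpec", "TrueEffects", "default_design",
           "simulate_diallel", "true_effect_summary"]


def default_design(method: str = "method4", n_envs: int = 6,
                   n_parents: int = 8, n_reps: int = 3) -> DiallelDesign:
    """Melon-trial-sized design: 8 parents, 3 blocks, 6 environments."""
    return DiallelDesign(
        parents=tuple(f"P{i}" for i in range(1, n_parents + 1)),
        method=method,  # type: ignore[arg-type]
        n_reps=n_reps,
        environments=tuple(f"E{i}" for i in range(1, n_envs + 1)),
    )


@dataclass
class SimulationSpec:
    """Parameters of one simulated trait in a half-diallel RCBD trial."""

    design: DiallelDesign = field(default_factory=default_design)
    trait: str = "yield"
    mu: float = 10.0
    env_effects: tuple[float, ...] | None = None  # fixed offsets e_l; zeros if None
    sigma2_env: float = 0.0  # used only when random_env
    random_env: bool = False
    sigma2_g: float = 1.888
    sigma2_s: float = 0.242
    sigma2_gE: float = 0.204
    sigma2_sE: float = 0.436
    sigma2_block: float = 0.25
    sigma2_e: float = 2.86
    delta_self: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_env", "sigma2_g", "sigma2_s", "sigma2_gE",
                     "sigma2_sE", "sigma2_block", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.env_effects is not None and len(self.env_effects) != len(self.design.environments):
            raise ValueError("env_effects length must match the design environments")


@dataclass
class TrueEffects:
    """The drawn generative effects, in estimator-compatible shape."""

    mu: float
    g: pd.Series  # sums to zero
    s: pd.DataFrame  # symmetric; rows sum to zero over mates (off-diagonal)
    gE: pd.DataFrame  # parents x environments, column-centered
    sE: dict[str, pd.DataFrame]
    env_effects: pd.Series
    block_effects: pd.DataFrame  # environments x blocks
    delta_self: float
    seed: int


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _project_sca(s: np.ndarray) -> np.ndarray:
    """Project a symmetric off-diagonal matrix onto the SCA constraint space
    (every row sums to zero over mates); the diagonal is centered separately."""
    p = s.shape[0]
    off = s.copy()
    np.fill_diagonal(off, 0.0)
    rows = off.sum(axis=1)
    total = rows.sum() / 2.0
    out = off - (rows[:, None] + rows[None, :]) / (p - 2) + 2.0 * total / ((p - 1) * (p - 2))
    np.fill_diagonal(out, 0.0)
    diag = np.diag(s).copy()
    if np.any(diag):
        diag = _center(diag)
    out = out + np.diag(diag)
    return out


def simulate_diallel(spec: SimulationSpec) -> tuple[pd.DataFrame, TrueEffects]:
    """Draw one trial; identical spec and seed give identical records."""
    d = spec.design
    p, r = d.n_parents, d.n_reps
    envs = list(d.environments)
    E = len(envs)
    rng = np.random.default_rng(spec.seed)

    g = _center(rng.normal(0.0, np.sqrt(spec.sigma2_g), p)) if spec.sigma2_g > 0 else np.zeros(p)

    def draw_sym(sigma2: float, with_diag: bool) -> np.ndarray:
        if sigma2 <= 0:
            return np.zeros((p, p))
        raw = rng.normal(0.0, np.sqrt(sigma2), (p, p))
        sym = np.triu(raw, 1)
        sym = sym + sym.T
        if with_diag:
            sym += np.diag(np.diag(raw))
        return sym

    def center_sym(sym: np.ndarray) -> np.ndarray:
        """Remove the grand mean of the off-diagonal cells (stratum centering)."""
        if not sym.any():
            return sym
        off = ~np.eye(p, dtype=bool)
        out = sym.copy()
        out[off] -= sym[off].mean()
        diag = np.diag(sym)
        if diag.any():
            out[np.eye(p, dtype=bool)] = _center(diag)
        return out

    with_diag = d.method == "method2"
    # main-effect SCA is projected onto the estimator's identifiable space
    # (rows sum to zero over mates) so noise-free recovery is exact
    s = _project_sca(draw_sym(spec.sigma2_s, with_diag))

    gE = np.zeros((p, E))
    if spec.sigma2_gE > 0:
        gE = rng.normal(0.0, np.sqrt(spec.sigma2_gE), (p, E))
        gE = gE - gE.mean(axis=0, keepdims=True)
    # SCA x Env draws stay i.i.d. apart from stratum centering: the EMS chain
    # expects their GCA content to feed the Env x GCA mean square
    sE = {env: center_sym(draw_sym(spec.sigma2_sE, with_diag)) for env in envs}

    if spec.env_effects is not None:
        e = np.asarray(spec.env_effects, dtype=float)
    elif spec.random_env and spec.sigma2_env > 0:
        e = _center(rng.normal(0.0, np.sqrt(spec.sigma2_env), E))
    else:
        e = np.zeros(E)

    if spec.sigma2_block > 0:
        b = rng.normal(0.0, np.sqrt(spec.sigma2_block), (E, r))
        b = b - b.mean(axis=1, keepdims=True)
    else:
        b = np.zeros((E, r))

    entries = d.entries()
    idx = {name: i for i, name in enumerate(d.parents)}
    rows = []
    for l, env in enumerate(envs):
        sE_l = sE[env]
        for k in range(r):
            block = f"B{k + 1}"
            for a, bname in entries:
                i, j = idx[a], idx[bname]
                if i == j:
                    gen = 2 * g[i] + s[i, i] + 2 * gE[i, l] + sE_l[i, i] + spec.delta_self
                else:
                    gen = g[i] + g[j] + s[i, j] + gE[i, l] + gE[j, l] + sE_l[i, j]
                noise = rng.normal(0.0, np.sqrt(spec.sigma2_e)) if spec.sigma2_e > 0 else 0.0
                rows.append((env, block, a, bname, spec.trait,
                             spec.mu + e[l] + b[l, k] + gen + noise))
    records = pd.DataFrame(rows, columns=REC_COLS)
    records.attrs["n_records"] = len(records)
    truth = TrueEffects(
        mu=spec.mu,
        g=pd.Series(g, index=list(d.parents)),
        s=pd.DataFrame(s, index=list(d.parents), columns=list(d.parents)),
        gE=pd.DataFrame(gE, index=list(d.parents), columns=envs),
        sE={env: pd.DataFrame(sE[env], index=list(d.parents), columns=list(d.parents))
            for env in envs},
        env_effects=pd.Series(e, index=envs),
        block_effects=pd.DataFrame(b, index=envs, columns=[f"B{k + 1}" for k in range(r)]),
        delta_self=spec.delta_self,
        seed=spec.seed,
    )
    return records, truth


def true_effect_summary(effects: TrueEffects, method: str = "method4") -> EffectsResult:
    """Package the drawn g and s like the estimator output for comparison."""
    s = effects.s.copy()
    if method == "method4":
        arr = s.to_numpy().copy()
        np.fill_diagonal(arr, np.nan)
        s = pd.DataFrame(arr, index=s.index, columns=s.columns)
    return EffectsResult(method=method, m=effects.mu, g=effects.g.copy(), s=s)  # type: ignore[arg-type]
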