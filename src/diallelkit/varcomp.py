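"""Variance components and heritabilities from expected mean squares.

Under the fully random model ("Model 2") the diallel ANOVA mean squares
have the expectations (method 4, r replicates, p parents, E environments):

single environment::

    E[MS_SCA] = sigma2_e + r sigma2_s
    E[MS_GCA] = sigma2_e + r sigma2_s + r (p-2) sigma2_g

combined::

    E[Me]        = sigma2_e
    E[MS_ExSCA]  = sigma2_e + r sigma2_sE
    E[MS_ExGCA]  = sigma2_e + r sigma2_sE + r (p-2) sigma2_gE
    E[MS_SCA]    = sigma2_e + r sigma2_sE + r E sigma2_s
    E[MS_GCA]    = sigma2_e + r sigma2_sE + r (p-2) sigma2_gE
                   + r E sigma2_s + r E (p-2) sigma2_g

The chain is back-solved in the order sigma2_sE, sigma2_gE, sigma2_s,
sigma2_g, truncating each component at zero.  Derived quantities follow the
diallel convention sigma2_A = 2 sigma2_g, sigma2_D = sigma2_s and the
plot-basis phenotypic variance sigma2_P = sigma2_A + sigma2_D + sigma2_e
(the error variance enters untouched, not divided by r).  Heritabilities
are h2_N = sigma2_A / sigma2_P and h2_B = (sigma2_A + sigma2_D) / sigma2_P.

Method-2 tables are accepted and processed with the same EMS template;
the coefficients are exact only for method 4, so method-2 components carry
an ``ems_template_approximate`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .griffing import AnovaTable, significance_stars

__all__ = [
    "VarianceComponents",
    "components_single_env",
    "components_combined",
    "component_significance",
]


@dataclass
class VarianceComponents:
    """Random-model variance components with derived genetic summaries.

    All components are truncated at zero.  ``ratio`` (sigma2_g / sigma2_s)
    is NaN when sigma2_s truncates to zero, mirroring the convention of
    printing "-" in that case.
    """

    sigma2_g: float
    sigma2_s: float
    sigma2_e: float
    sigma2_gE: float | None = None
    sigma2_sE: float | None = None
    significance: dict[str, str] = field(default_factory=dict)
    ems_template_approximate: bool = False

    @property
    def sigma2_A(self) -> float:
        return 2.0 * self.sigma2_g

    @property
    def sigma2_D(self) -> float:
        return self.sigma2_s

    @property
    def sigma2_P(self) -> float:
        return self.sigma2_A + self.sigma2_D + self.sigma2_e

    @property
    def ratio(self) -> float:
        return self.sigma2_g / self.sigma2_s if self.sigma2_s > 0 else np.nan

    @property
    def h2_narrow(self) -> float:
        return self.sigma2_A / self.sigma2_P if self.sigma2_P > 0 else np.nan

    @property
    def h2_broad(self) -> float:
        return (self.sigma2_A + self.sigma2_D) / self.sigma2_P if self.sigma2_P > 0 else np.nan

    def as_dict(self) -> dict[str, float]:
        out = {
            "sigma2_g": self.sigma2_g,
            "sigma2_s": self.sigma2_s,
            "sigma2_e": self.sigma2_e,
            "sigma2_A": self.sigma2_A,
            "sigma2_D": self.sigma2_D,
            "sigma2_P": self.sigma2_P,
            "gca_sca_ratio": self.ratio,
            "h2_narrow": self.h2_narrow,
            "h2_broad": self.h2_broad,
        }
        if self.sigma2_gE is not None:
            out["sigma2_gE"] = self.sigma2_gE
        if self.sigma2_sE is not None:
            out["sigma2_sE"] = self.sigma2_sE
        return out


def _ems_k(anova: AnovaTable) -> float:
    """GCA coefficient multiplier: p-2 for method 4, p+2 for method 2."""
    return anova.n_parents - 2 if anova.method == "method4" else anova.n_parents + 2


def components_single_env(anova: AnovaTable) -> VarianceComponents:
    """Back-solve the single-environment EMS chain.

    sigma2_s = (MS_SCA - Me)/r;  sigma2_g = (MS_GCA - MS_SCA)/(r k) with
    k = p-2 (method 4).  Truncation at zero is applied after solving, and
    the GCA difference keeps MS_SCA even when sigma2_s truncates.
    """
    for source in ("GCA", "SCA", "Error"):
        if not anova.has(source):
            raise ValueError(f"ANOVA table lacks source {source!r}")
    r = anova.n_reps
    k = _ems_k(anova)
    ms_g, ms_s, me = (float(anova[s]["MS"]) for s in ("GCA", "SCA", "Error"))
    sigma2_s = max((ms_s - me) / r, 0.0)
    sigma2_g = max((ms_g - ms_s) / (r * k), 0.0)
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_s=sigma2_s,
        sigma2_e=me,
        significance=component_significance(anova),
        ems_template_approximate=anova.method == "method2",
    )


def components_combined(anova: AnovaTable) -> VarianceComponents:
    """Back-solve the combined EMS chain (order sE, gE, s, g; truncate at 0)."""
    for source in ("GCA", "SCA", "Env x GCA", "Env x SCA", "Error"):
        if not anova.has(source):
            raise ValueError(f"ANOVA table lacks source {source!r}")
    # E = 1 with interaction MS equal to Me degenerates to the
    # single-environment back-solve, so small E is allowed
    r, E = anova.n_reps, anova.n_envs
    k = _ems_k(anova)
    ms_g = float(anova["GCA"]["MS"])
    ms_s = float(anova["SCA"]["MS"])
    ms_ge = float(anova["Env x GCA"]["MS"])
    ms_se = float(anova["Env x SCA"]["MS"])
    me = anova.error_ms
    sigma2_sE = max((ms_se - me) / r, 0.0)
    sigma2_gE = max((ms_ge - ms_se) / (r * k), 0.0)
    sigma2_s = max((ms_s - ms_se) / (r * E), 0.0)
    sigma2_g = max((ms_g - ms_ge - ms_s + ms_se) / (r * E * k), 0.0)
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_s=sigma2_s,
        sigma2_e=me,
        sigma2_gE=sigma2_gE,
        sigma2_sE=sigma2_sE,
        significance=component_significance(anova),
        ems_template_approximate=anova.method == "method2",
    )


def component_significance(anova: AnovaTable) -> dict[str, str]:
    """Star annotations for each component from EMS-chain F ratios.

    Each component's numerator mean square is tested against the next mean
    square in the back-solve order (e.g. sigma2_g: MS_GCA vs MS_SCA in a
    single environment; sigma2_sE: MS_ExSCA vs Me in the combined model).
    """
    pairs: dict[str, tuple[str, str]] = {}
    if anova.has("Env x SCA"):
        pairs = {
            "sigma2_g": ("GCA", "SCA"),
            "sigma2_s": ("SCA", "Env x SCA"),
            "sigma2_gE": ("Env x GCA", "Env x SCA"),
            "sigma2_sE": ("Env x SCA", "Error"),
        }
    else:
        pairs = {
            "sigma2_g": ("GCA", "SCA"),
            "sigma2_s": ("SCA", "Error"),
        }
    out: dict[str, str] = {}
    for comp, (num, den) in pairs.items():
        if not (anova.has(num) and anova.has(den)):
            continue
        num_row, den_row = anova[num], anova[den]
        if den_row["MS"] <= 0 or not np.isfinite(den_row["MS"]):
            out[comp] = ""
            continue
        f = num_row["MS"] / den_row["MS"]
        p = float(stats.f.sf(f, num_row["df"], den_row["df"]))
        out[comp] = significance_stars(p)
    return out
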