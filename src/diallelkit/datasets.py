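"""Published summaries of an eight-parent melon half-diallel trial.

A half diallel of eight melon (*Cucumis melo* L.) inbred lines — 28 F1
hybrids, no reciprocals — was grown in a three-block RCBD in six
environments of Central Italy (Latina and Perugia, 2014-2016), scoring
yield per plant (kg), total soluble solids (TSS, Brix, fruit level) and
earliness (days to ripening, DTR).  The raw plot data were not deposited;
what is available are the published summary tables: per-cross yield
least-squares means for the environments with a significant SCA mean
square, and the single-environment and combined ANOVA mean squares.

These summaries are sufficient inputs for several estimators in this
package (method-4 combining abilities from a cross-means table,
EMS variance components and heritabilities from mean squares, heterosis
standard errors from the error mean square), and this module exposes them
in the package's native containers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CrossMeansMatrix, DiallelDesign
from .griffing import AnovaTable, anova_from_mean_squares

__all__ = [
    "melon_parents",
    "melon_design",
    "melon_yield_lsm",
    "melon_anova",
    "melon_combined_anova",
]

PARENTS = (
    "Vedrantais",        # 1
    "Ita1",              # 2
    "Ogen",              # 3
    "Top Mark",          # 4
    "Magyar Kincs",      # 5
    "Hale's Best Jumbo", # 6
    "PI414723",          # 7
    "PI161375",          # 8
)

ENVIRONMENTS = (
    "latina_2014", "perugia_2014",
    "latina_2015", "perugia_2015",
    "latina_2016", "perugia_2016",
)

# Per-cross yield LsM (kg/plant), crosses in canonical order
# (1,2), (1,3), ..., (1,8), (2,3), ..., (7,8).
_YIELD_LSM = {
    "latina_2015": [
        8.08, 10.29, 9.48, 9.42, 9.39, 12.44, 8.62,
        9.45, 8.56, 11.27, 9.34, 12.91, 13.42,
        9.56, 8.28, 9.34, 13.48, 9.93,
        10.71, 10.73, 7.56, 12.14,
        9.01, 11.12, 13.09,
        10.54, 11.88,
        14.11,
    ],
    "perugia_2015": [
        4.56, 5.07, 4.65, 4.44, 6.35, 9.55, 7.33,
        4.46, 4.04, 5.51, 6.37, 9.45, 7.31,
        5.86, 6.12, 7.07, 9.97, 8.70,
        5.55, 5.61, 9.69, 11.31,
        7.19, 9.77, 7.32,
        8.49, 7.92,
        8.06,
    ],
    "latina_2016": [
        10.78, 11.84, 10.58, 11.13, 11.05, 14.88, 10.89,
        13.35, 10.00, 10.91, 11.27, 17.17, 17.67,
        12.60, 10.05, 13.50, 16.11, 17.52,
        11.46, 11.32, 13.72, 15.16,
        15.91, 15.75, 17.54,
        13.52, 16.44,
        19.03,
    ],
}

# Single-environment ANOVA mean squares (MS) and degrees of freedom.
# Yield and DTR are plot-level; TSS is fruit-level (large error df), but the
# published variance components use r = 3 in the EMS chain for every trait.
_SINGLE_ENV_MS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    # trait -> env -> source -> (df, MS)
    "yield": {
        "latina_2014":  {"Entries": (27, 10.93), "GCA": (7, 32.12), "SCA": (20, 3.52), "Error": (54, 2.83)},
        "perugia_2014": {"Entries": (27, 8.20),  "GCA": (7, 28.11), "SCA": (20, 1.23), "Error": (54, 0.72)},
        "latina_2015":  {"Entries": (27, 9.98),  "GCA": (7, 17.60), "SCA": (20, 7.32), "Error": (54, 4.04)},
        "perugia_2015": {"Entries": (27, 12.04), "GCA": (7, 32.50), "SCA": (20, 4.87), "Error": (54, 2.01)},
        "latina_2016":  {"Entries": (27, 23.03), "GCA": (7, 65.67), "SCA": (20, 8.11), "Error": (54, 4.41)},
        "perugia_2016": {"Entries": (27, 23.73), "GCA": (7, 79.26), "SCA": (20, 4.30), "Error": (54, 3.04)},
    },
    "tss": {
        "latina_2014":  {"Entries": (27, 128.38), "GCA": (7, 12.53), "SCA": (20, 1.08), "Error": (2730, 3.44)},
        "perugia_2014": {"Entries": (27, 70.66),  "GCA": (7, 14.52), "SCA": (20, 1.11), "Error": (1438, 3.08)},
        "latina_2015":  {"Entries": (27, 171.44), "GCA": (7, 20.47), "SCA": (20, 1.42), "Error": (2415, 2.98)},
        "perugia_2015": {"Entries": (27, 179.98), "GCA": (7, 31.61), "SCA": (20, 0.92), "Error": (1706, 3.51)},
        "latina_2016":  {"Entries": (27, 291.74), "GCA": (7, 30.37), "SCA": (20, 1.76), "Error": (2880, 5.71)},
    },
    "dtr": {
        "latina_2014":  {"Entries": (27, 77.08),  "GCA": (7, 49.42),  "SCA": (20, 3.49),  "Error": (385, 1.17)},
        "perugia_2014": {"Entries": (27, 139.21), "GCA": (7, 77.24),  "SCA": (20, 10.55), "Error": (390, 5.56)},
        "latina_2015":  {"Entries": (27, 162.67), "GCA": (7, 111.41), "SCA": (20, 4.93),  "Error": (390, 1.32)},
        "perugia_2015": {"Entries": (27, 143.21), "GCA": (7, 86.72),  "SCA": (20, 8.32),  "Error": (390, 6.58)},
        "latina_2016":  {"Entries": (27, 144.14), "GCA": (7, 98.26),  "SCA": (20, 4.58),  "Error": (390, 2.39)},
        "perugia_2016": {"Entries": (27, 269.13), "GCA": (7, 128.15), "SCA": (20, 27.81), "Error": (390, 10.55)},
    },
}

# Combined (across environments) method-4 ANOVA mean squares.
_COMBINED_MS: dict[str, dict[str, tuple[float, float]]] = {
    "yield": {
        "Environments": (5, 763.43), "Entries": (27, 62.32),
        "GCA": (7, 216.06), "SCA": (20, 8.51),
        "Env x Entries": (135, 5.12), "Env x GCA": (35, 7.84),
        "Env x SCA": (100, 4.17), "Error": (324, 2.86),
    },
    "tss": {
        "Environments": (4, 6504.65), "Entries": (27, 634.81),
        "GCA": (7, 86.73), "SCA": (20, 3.64),
        "Env x Entries": (108, 54.38), "Env x GCA": (28, 5.67),
        "Env x SCA": (80, 0.66), "Error": (11169, 3.89),
    },
    "dtr": {
        "Environments": (5, 3696.62), "Entries": (27, 712.42),
        "GCA": (7, 456.55), "SCA": (20, 32.16),
        "Env x Entries": (135, 44.62), "Env x GCA": (35, 18.93),
        "Env x SCA": (100, 5.50), "Error": (2335, 4.61),
    },
}

_COMBINED_N_ENVS = {"yield": 6, "tss": 5, "dtr": 6}


def melon_parents() -> tuple[str, ...]:
    """The eight parental inbred lines, in trial numbering order."""
    return PARENTS


def melon_design(method: str = "method4") -> DiallelDesign:
    return DiallelDesign(
        parents=PARENTS,
        method=method,  # type: ignore[arg-type]
        n_reps=3,
        environments=ENVIRONMENTS,
        trait_directions={"yield": "higher_better", "tss": "higher_better",
                          "dtr": "lower_better"},
    )


def melon_yield_lsm(env: str) -> CrossMeansMatrix:
    """Published per-cross yield LsM table as a method-4 cross-means matrix."""
    if env not in _YIELD_LSM:
        raise KeyError(f"yield LsM available for {sorted(_YIELD_LSM)}, not {env!r}")
    vals = _YIELD_LSM[env]
    p = len(PARENTS)
    mat = pd.DataFrame(np.nan, index=list(PARENTS), columns=list(PARENTS))
    k = 0
    for i in range(p):
        for j in range(i + 1, p):
            mat.iloc[i, j] = mat.iloc[j, i] = vals[k]
            k += 1
    return CrossMeansMatrix(values=mat, method="method4", n_reps=3)


def melon_anova(trait: str, env: str) -> AnovaTable:
    """Published single-environment method-4 ANOVA as an :class:`AnovaTable`."""
    trait = trait.lower()
    if trait not in _SINGLE_ENV_MS:
        raise KeyError(f"trait must be one of {sorted(_SINGLE_ENV_MS)}")
    if env not in _SINGLE_ENV_MS[trait]:
        raise KeyError(f"no published ANOVA for {trait!r} in {env!r}")
    entry = _SINGLE_ENV_MS[trait][env]
    return anova_from_mean_squares(
        mean_squares={src: ms for src, (df, ms) in entry.items()},
        degrees_of_freedom={src: df for src, (df, ms) in entry.items()},
        method="method4", n_parents=len(PARENTS), n_reps=3, n_envs=1,
    )


def melon_combined_anova(trait: str) -> AnovaTable:
    """Published combined method-4 ANOVA across environments."""
    trait = trait.lower()
    if trait not in _COMBINED_MS:
        raise KeyError(f"trait must be one of {sorted(_COMBINED_MS)}")
    entry = _COMBINED_MS[trait]
    return anova_from_mean_squares(
        mean_squares={src: ms for src, (df, ms) in entry.items()},
        degrees_of_freedom={src: df for src, (df, ms) in entry.items()},
        method="method4", n_parents=len(PARENTS), n_reps=3,
        n_envs=_COMBINED_N_ENVS[trait],
    )
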