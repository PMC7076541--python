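"""Mid-parent and best-parent heterosis with design-based standard errors.

For a cross with F1 mean ``F1`` and selfed-parent means ``P1``, ``P2``:

    MPH% = 100 (F1 - MP) / MP,   MP = (P1 + P2) / 2
    BPH% = 100 (F1 - Ph) / Ph

where ``Ph`` is the mean of the *better* parent for the trait direction —
the larger parent for higher-better traits, the smaller for lower-better
traits such as days to ripening (so negative BPH there means the hybrid is
earlier than its earliest parent).

Significance uses the classical RCBD standard errors built from the error
mean square Me of the method-2 ANOVA and the number of replicate
observations r behind each entry mean:

    SE(MPH) = sqrt(3 Me / (2 r)),   SE(BPH) = sqrt(2 Me / r)

Both are in trait units; t-statistics divide the unit-scale deviation
(F1 - MP, F1 - Ph) by the corresponding SE and are referred to the error
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core import DiallelDesign, TraitDirection
from .griffing import AnovaTable, anova_single_env, significance_stars

__all__ = ["HeterosisTable", "mph", "bph", "heterosis_se", "heterosis_table"]


def mph(F1: float, P1: float, P2: float) -> float:
    """Mid-parent heterosis percent; NaN (flagged) when the mid-parent is 0."""
    mid = (P1 + P2) / 2.0
    if mid == 0:
        return np.nan
    return 100.0 * (F1 - mid) / mid


def bph(F1: float, P1: float, P2: float, trait_direction: TraitDirection) -> float:
    """Best-parent heterosis percent with a direction-aware better parent."""
    ph = max(P1, P2) if trait_direction == "higher_better" else min(P1, P2)
    if ph == 0:
        return np.nan
    return 100.0 * (F1 - ph) / ph


def heterosis_se(error_ms: float, n_reps: int) -> tuple[float, float]:
    """(SE_MPH, SE_BPH) in trait units: sqrt(3Me/(2r)) and sqrt(2Me/r)."""
    if error_ms < 0:
        raise ValueError("error mean square must be nonnegative")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    return (
        float(np.sqrt(3.0 * error_ms / (2.0 * n_reps))),
        float(np.sqrt(2.0 * error_ms / n_reps)),
    )


@dataclass
class HeterosisTable:
    """Per-cross heterosis table plus the table-level standard errors."""

    table: pd.DataFrame
    se_mph: float
    se_bph: float
    error_df: float
    n_reps: int
    trait_direction: TraitDirection


def heterosis_table(
    records: pd.DataFrame,
    trait: str,
    env: str,
    design: DiallelDesign,
    anova: AnovaTable | None = None,
    trait_direction: TraitDirection | None = None,
) -> HeterosisTable:
    """Full MPH/BPH table for one trait x environment.

    Requires selfed-parent records (method-2-style data).  ``r`` in the SE
    formulas is taken from the data as the number of replicate observations
    behind each entry mean.  A parent without selfed records flags its
    crosses (NaN heterosis) rather than dropping them.
    """
    from dataclasses import replace

    d = replace(design, method="method2")
    direction = trait_direction or design.direction(trait)
    sub = records[(records["trait"] == trait) & (records["env"] == env)]
    selfs = sub[sub["parent_a"] == sub["parent_b"]]
    if selfs.empty:
        raise ValueError("heterosis needs selfed-parent records")
    missing_selfs = set(design.parents) - set(selfs["parent_a"])
    if anova is None:
        # a parent without selfed records breaks method-2 balance; fall back
        # to the crosses-only ANOVA for the error mean square in that case
        if missing_selfs:
            anova = anova_single_env(records, trait, env, "method4", d)
        else:
            anova = anova_single_env(records, trait, env, "method2", d)
    means = sub.groupby(["parent_a", "parent_b"])["value"].mean()
    # replicate observations per entry mean, computed from the data
    r = int(round(sub.groupby(["parent_a", "parent_b"]).size().mean()))
    se_mph_u, se_bph_u = heterosis_se(anova.error_ms, r)

    parent_means = means.loc[[(p, p) for p in design.parents if p not in missing_selfs]]
    parent_means.index = [a for a, _ in parent_means.index]
    rows = []
    parents = list(design.parents)
    for i, a in enumerate(parents):
        for b in parents[i + 1:]:
            f1 = float(means[(a, b)])
            flagged = a in missing_selfs or b in missing_selfs
            p1 = float(parent_means[a]) if a not in missing_selfs else np.nan
            p2 = float(parent_means[b]) if b not in missing_selfs else np.nan
            mid = (p1 + p2) / 2.0
            ph = (max(p1, p2) if direction == "higher_better" else min(p1, p2))
            mph_pct = mph(f1, p1, p2) if not flagged else np.nan
            bph_pct = bph(f1, p1, p2, direction) if not flagged else np.nan
            t_mph = (f1 - mid) / se_mph_u if se_mph_u > 0 and not flagged else np.nan
            t_bph = (f1 - ph) / se_bph_u if se_bph_u > 0 and not flagged else np.nan
            p_mph = 2.0 * stats.t.sf(abs(t_mph), anova.error_df) if np.isfinite(t_mph) else np.nan
            p_bph = 2.0 * stats.t.sf(abs(t_bph), anova.error_df) if np.isfinite(t_bph) else np.nan
            rows.append({
                "parent_a": a, "parent_b": b,
                "F1": f1, "P1": p1, "P2": p2, "MP": mid, "Ph": ph,
                "MPH": mph_pct, "BPH": bph_pct,
                "t_MPH": t_mph, "t_BPH": t_bph,
                "p_MPH": p_mph, "p_BPH": p_bph,
                "sig_MPH": significance_stars(p_mph) if np.isfinite(p_mph) else "",
                "sig_BPH": significance_stars(p_bph) if np.isfinite(p_bph) else "",
                "flagged": flagged,
            })
    return HeterosisTable(
        table=pd.DataFrame(rows),
        se_mph=se_mph_u,
        se_bph=se_bph_u,
        error_df=anova.error_df,
        n_reps=r,
        trait_direction=direction,
    )
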