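"""GGE-biplot analysis of a diallel entry x tester table.

Each genotype of a method-2 diallel acts both as an entry (row) and as a
tester (column); the cell is the mean of entry x tester.  The table is
*tester-centered* — each column has its tester mean subtracted — and a
rank-2 singular value decomposition gives entry and tester scores:

    entry scores  = U_2 S_2^f,   tester scores = V_2 S_2^(1-f)

with the singular-value partition f in [0, 1] (f = 0.5 by default, which
splits the scale symmetrically and preserves entry-tester inner products).

The average tester coordinate (ATC) axis points toward the mean of the
tester scores; entry projections on the ATC abscissa approximate Griffing
GCA effects, projections on the ATC ordinate approximate SCA behavior.
The polygon ("which-won-where") view joins the entries furthest from the
origin into a convex hull; rays perpendicular to the hull edges cut the
plane into sectors, and the hull vertex of a sector "wins" (maximizes the
inner product with) every tester inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .core import CrossMeansMatrix

__all__ = [
    "BiplotModel",
    "PolygonView",
    "build_entry_tester_matrix",
    "center_by_tester",
    "svd_biplot",
    "polygon_sectors",
]


@dataclass
class BiplotModel:
    """Rank-2 biplot of a tester-centered diallel table."""

    entry_scores: pd.DataFrame  # p x 2, columns PC1/PC2
    tester_scores: pd.DataFrame
    singular_values: np.ndarray
    explained: np.ndarray  # proportion of centered variation per component
    atc_direction: np.ndarray | None  # unit vector, None when degenerate
    atc_abscissa: pd.Series  # entry projection on ATC (GCA-like)
    atc_ordinate: pd.Series  # signed orthogonal projection (SCA-like)
    f: float
    degenerate: bool = False


@dataclass
class PolygonView:
    """Which-won-where decomposition of the entry-score polygon."""

    hull_entries: list[str]
    sector_of_tester: pd.Series  # tester -> winning hull entry
    boundary_rays: np.ndarray  # one perpendicular unit ray per hull edge
    tester_in_own_sector: pd.Series  # bool per tester with a same-named entry


def build_entry_tester_matrix(x: CrossMeansMatrix) -> pd.DataFrame:
    """Entry x tester table from a method-2 cross-means matrix.

    Rows are entries, columns testers; the complete symmetric table (selfs
    on the diagonal) is the entry x tester matrix itself.
    """
    arr = x.values.to_numpy(dtype=float)
    if np.isnan(np.diag(arr)).any():
        raise ValueError("entry x tester table needs selfed-parent means (method 2)")
    return x.values.astype(float).copy()


def center_by_tester(M: pd.DataFrame) -> pd.DataFrame:
    """Subtract each tester (column) mean; columns of the result sum to zero."""
    return M - M.mean(axis=0)


def svd_biplot(centered: pd.DataFrame, f: float = 0.5) -> BiplotModel:
    """Rank-2 SVD of the tester-centered table with scaling exponent ``f``."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("scaling exponent f must be in [0, 1]")
    A = centered.to_numpy(dtype=float)
    U, sing, Vt = np.linalg.svd(A, full_matrices=False)
    total = float((sing**2).sum())
    degenerate = total <= 1e-12
    explained = sing**2 / total if not degenerate else np.zeros_like(sing)
    U2, s2, V2 = U[:, :2], sing[:2], Vt[:2].T
    entry = U2 * s2**f
    tester = V2 * s2 ** (1.0 - f)
    entry_scores = pd.DataFrame(entry, index=centered.index, columns=["PC1", "PC2"])
    tester_scores = pd.DataFrame(tester, index=centered.columns, columns=["PC1", "PC2"])
    atc_mean = tester.mean(axis=0)
    norm = np.linalg.norm(atc_mean)
    if degenerate or norm <= 1e-12:
        atc = None
        absc = pd.Series(np.nan, index=centered.index)
        ordi = pd.Series(np.nan, index=centered.index)
        degenerate = True
    else:
        atc = atc_mean / norm
        perp = np.array([-atc[1], atc[0]])
        absc = pd.Series(entry @ atc, index=centered.index)
        ordi = pd.Series(entry @ perp, index=centered.index)
    return BiplotModel(
        entry_scores=entry_scores,
        tester_scores=tester_scores,
        singular_values=sing,
        explained=explained,
        atc_direction=atc,
        atc_abscissa=absc,
        atc_ordinate=ordi,
        f=f,
        degenerate=degenerate,
    )


def polygon_sectors(model: BiplotModel) -> PolygonView:
    """Convex hull of entry scores, sector boundaries and sector winners.

    A tester belongs to the sector of the hull vertex that maximizes its
    inner product with the tester's score vector; that vertex entry is the
    predicted best mate ("winner") for the tester.  The report also says,
    per tester, whether it falls in its own entry's sector — the
    "selfing beats crossing" diagnostic.
    """
    pts = model.entry_scores.to_numpy()
    if len(pts) < 3:
        raise ValueError("polygon view needs at least 3 entries")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull raises on collinear input
        raise ValueError("entry scores are collinear; polygon view undefined") from exc
    hull_idx = list(hull.vertices)
    entries = list(model.entry_scores.index)
    hull_entries = [entries[i] for i in hull_idx]

    # perpendicular rays from the origin to each hull edge
    rays = []
    for k in range(len(hull_idx)):
        a = pts[hull_idx[k]]
        b = pts[hull_idx[(k + 1) % len(hull_idx)]]
        edge = b - a
        ray = np.array([edge[1], -edge[0]])
        n = np.linalg.norm(ray)
        rays.append(ray / n if n > 0 else ray)
    rays_arr = np.array(rays)

    hull_pts = pts[hull_idx]
    t_scores = model.tester_scores.to_numpy()
    winner_idx = np.argmax(t_scores @ hull_pts.T, axis=1)
    winners = pd.Series(
        [hull_entries[i] for i in winner_idx], index=model.tester_scores.index
    )
    own = pd.Series(
        [winners[t] == t for t in model.tester_scores.index],
        index=model.tester_scores.index,
    )
    return PolygonView(
        hull_entries=hull_entries,
        sector_of_tester=winners,
        boundary_rays=rays_arr,
        tester_in_own_sector=own,
    )
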