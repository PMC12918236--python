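"""Spatial organization statistics for organoid sections.

Organoid sections develop a hypoxic core: oxygen and nutrients reach the
interior only by diffusion, so glycolysis/hypoxia-response genes rise with
depth.  A six-gene metabolic index (P4HA1, STC2, PGK1, VEGFA, EGLN3, PFKP)
summarizes this per cell, and thresholding it at the 60th percentile splits
each section into "interior" (high index) and "exterior" zones without any
geometric input.  The geometric validation computes each centroid's
perpendicular distance to the section's convex hull.

Cell-type co-localization is tested on a 50 µm square grid: the Pearson
correlation between the two types' binned abundances is compared with a
null built by shuffling type labels within the section, and sections are
combined with an exact paired signed-rank test of observed correlation
against the null summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.spatial import ConvexHull, QhullError

from .stats import rank_sum_exact, signed_rank_exact, ExactTestResult

__all__ = [
    "METABOLIC_GENES",
    "ColocResult",
    "metabolic_index",
    "binarize_zone",
    "zone_proportion_test",
    "edge_distance",
    "density_difference",
    "grid_colocalization",
    "cohort_colocalization",
]

#: Glycolysis/hypoxia panel genes defining the metabolic index.
METABOLIC_GENES = ("P4HA1", "STC2", "PGK1", "VEGFA", "EGLN3", "PFKP")


def metabolic_index(
    expr: pd.DataFrame, gene_set: Sequence[str] = METABOLIC_GENES
) -> pd.Series:
    """Per-cell metabolic index: arithmetic mean of normalized expression
    over the gene set.  ``expr`` is cells x genes."""
    missing = [g for g in gene_set if g not in expr.columns]
    if missing:
        raise KeyError(f"genes missing from expression matrix: {missing}")
    return expr[list(gene_set)].mean(axis=1).rename("metabolic_index")


def binarize_zone(index: pd.Series, percentile: float = 60.0) -> pd.Series:
    """Binarize a metabolic index into interior/exterior zones.

    Cells strictly above the given percentile of the index distribution are
    called interior (the hypoxic core expresses the index genes most
    strongly); ties at the threshold go to exterior.  With distinct values
    the interior fraction equals 1 - percentile/100 up to one cell.
    """
    if index.size < 2:
        raise ValueError("zone binarization requires >= 2 cells")
    vals = index.to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        warnings.warn("all metabolic indices equal; calling every cell exterior",
                      stacklevel=2)
        return pd.Series("exterior", index=index.index, name="zone")
    thr = np.percentile(vals, percentile)
    zone = np.where(vals > thr, "interior", "exterior")
    return pd.Series(zone, index=index.index, name="zone")


def zone_proportion_test(
    proportions: pd.DataFrame,
    organoid_col: str = "organoid",
    zone_col: str = "zone",
    type_col: str = "cell_type",
    value_col: str = "proportion",
) -> pd.DataFrame:
    """Per-type interior-vs-exterior proportion comparison across organoids.

    ``proportions`` holds one row per (organoid, image, zone, cell type)
    with the cell-type proportion within that zone.  Image-level rows are
    averaged per organoid first, then each cell type's per-organoid interior
    proportions are compared with the exterior ones by the exact two-sided
    Wilcoxon rank-sum test.
    """
    per_org = (
        proportions.groupby([organoid_col, zone_col, type_col])[value_col]
        .mean()
        .reset_index()
    )
    rows = []
    for ct, sub in per_org.groupby(type_col):
        a = sub.loc[sub[zone_col] == "interior", value_col].to_numpy()
        b = sub.loc[sub[zone_col] == "exterior", value_col].to_numpy()
        if a.size < 2 or b.size < 2:
            warnings.warn(f"cell type {ct!r}: fewer than 2 organoids per zone; skipped",
                          stacklevel=2)
            continue
        res = rank_sum_exact(a, b)
        rows.append({"cell_type": ct, "n_interior": a.size, "n_exterior": b.size,
                     "statistic": res.statistic, "p": res.p, "method": res.method})
    return pd.DataFrame(rows)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points p (n,2) to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(p - a, axis=1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def edge_distance(
    centroids: np.ndarray | pd.DataFrame, exclude_beyond_um: float = 400.0
) -> pd.DataFrame:
    """Perpendicular distance from each centroid to the convex-hull boundary.

    The hull of all centroids approximates the section edge; each cell's
    distance is the minimum over hull segments.  Cells deeper than
    ``exclude_beyond_um`` are flagged for exclusion from edge-validation
    summaries (deep cells often sit against a truncated field-of-view
    boundary rather than real tissue edge).
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centroids must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("convex hull requires >= 3 centroids")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError("degenerate (collinear) centroid configuration") from e
    dmin = np.full(pts.shape[0], np.inf)
    verts = hull.vertices
    for i in range(len(verts)):
        a = pts[verts[i]]
        b = pts[verts[(i + 1) % len(verts)]]
        dmin = np.minimum(dmin, _point_segment_distance(pts, a, b))
    idx = centroids.index if isinstance(centroids, pd.DataFrame) else None
    return pd.DataFrame(
        {"edge_distance_um": dmin, "excluded": dmin > exclude_beyond_um}, index=idx
    )


def density_difference(
    points_a: np.ndarray,
    points_b: np.ndarray,
    grid_n: int = 100,
    bandwidth_rule: str = "scott",
) -> dict:
    """Z-scored kernel-density difference map between two point sets.

    Each set gets a bivariate Gaussian KDE (normal-reference bandwidth per
    ``bandwidth_rule``) evaluated on a shared ``grid_n`` x ``grid_n`` grid
    spanning the joint bounding box; each density layer is z-scored over
    grid nodes, and the difference A - B is returned.  Positive values mark
    territory where set A concentrates relative to set B.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each point set needs >= 2 points for a KDE")
    allpts = np.vstack([a, b])
    xg = np.linspace(allpts[:, 0].min(), allpts[:, 0].max(), grid_n)
    yg = np.linspace(allpts[:, 1].min(), allpts[:, 1].max(), grid_n)
    xx, yy = np.meshgrid(xg, yg)
    grid = np.vstack([xx.ravel(), yy.ravel()])

    def _z(points: np.ndarray) -> np.ndarray:
        kde = _sps.gaussian_kde(points.T, bw_method=bandwidth_rule)
        dens = kde(grid).reshape(grid_n, grid_n)
        return (dens - dens.mean()) / dens.std()

    za, zb = _z(a), _z(b)
    return {"x": xg, "y": yg, "z_a": za, "z_b": zb, "difference": za - zb}


@dataclass
class ColocResult:
    """Grid-binned co-localization permutation test for one section."""

    observed_r: float
    null_r: np.ndarray
    p: float
    bin_um: float
    n_bins: int
    n_perm: int
    seed: int | None

    @property
    def null_median(self) -> float:
        return float(np.median(self.null_r))

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_r))

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed_r": self.observed_r,
            "p": self.p,
            "bin_um": self.bin_um,
            "n_bins": self.n_bins,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_median": self.null_median,
            "null_mean": self.null_mean,
        }
        if include_null:
            d["null_r"] = self.null_r.tolist()
        return d


def grid_colocalization(
    points_a: np.ndarray,
    points_b: np.ndarray,
    bin_um: float = 50.0,
    n_perm: int = 10_000,
    seed: int | None = None,
    side: Literal["less", "greater"] = "less",
) -> ColocResult:
    """Permutation test of spatial co-localization between two cell types.

    The section is divided into ``bin_um`` squares anchored at the joint
    bounding-box minimum; bins containing at least one cell of either type
    enter the statistic.  The observed Pearson correlation between the two
    types' binned abundances is compared with a null built by shuffling the
    type labels of the pooled cells (group sizes preserved) ``n_perm``
    times.  One-sided p with the add-one correction; ``side='less'`` asks
    whether the types co-localize *less* than label exchange predicts
    (spatial segregation).
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both point sets must be non-empty")
    pooled = np.vstack([a, b])
    origin = pooled.min(axis=0)
    idx2 = np.floor((pooled - origin) / bin_um).astype(int)
    n_cols = idx2[:, 0].max() + 1
    flat = idx2[:, 1] * n_cols + idx2[:, 0]
    # bins occupied by >= 1 cell of either set; empty bins would inflate r
    occupied, inv = np.unique(flat, return_inverse=True)
    n_bins = occupied.size
    if n_bins < 2:
        raise ValueError("need >= 2 occupied bins")
    is_a = np.zeros(pooled.shape[0], dtype=bool)
    is_a[: a.shape[0]] = True

    def _r(mask_a: np.ndarray) -> float:
        ca = np.bincount(inv, weights=mask_a, minlength=n_bins)
        cb = np.bincount(inv, weights=~mask_a, minlength=n_bins)
        if ca.std() == 0 or cb.std() == 0:
            return 0.0
        return float(np.corrcoef(ca, cb)[0, 1])

    observed = _r(is_a)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    lab = is_a.copy()
    for i in range(n_perm):
        rng.shuffle(lab)
        null[i] = _r(lab)
    if side == "less":
        hits = int((null <= observed).sum())
    else:
        hits = int((null >= observed).sum())
    p = (1 + hits) / (n_perm + 1)
    return ColocResult(observed, null, p, bin_um, n_bins, n_perm, seed)


def cohort_colocalization(
    results: Sequence[ColocResult],
    null_summary: Literal["median", "mean"] = "median",
) -> tuple[ExactTestResult, pd.DataFrame]:
    """Cohort-level paired comparison of observed vs null co-localization.

    For each section, pairs the observed correlation with the chosen summary
    of its permutation null (median by default; mean available) and applies
    the exact two-sided paired signed-rank test to the differences.
    """
    if len(results) < 2:
        raise ValueError("cohort comparison requires >= 2 sections")
    rows = []
    for i, r in enumerate(results):
        if r.null_r.size == 0:
            raise ValueError(f"section {i} has an empty permutation null")
        summ = r.null_median if null_summary == "median" else r.null_mean
        rows.append({"section": i, "observed_r": r.observed_r, "null_summary": summ,
                     "difference": r.observed_r - summ})
    table = pd.DataFrame(rows)
    test = signed_rank_exact(table["difference"].to_numpy())
    return test, table
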