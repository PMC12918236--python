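"""Cell-identity scoring and gene-set analyses.

Covers the single-cell side of the organoid characterization: rank-based
gene-signature scores (a Mann-Whitney-U score normalized to [0, 1]), the
ventral/dorsal midbrain ventrality index built from them, regional marker
filtering from differential-expression tables, timepoint merging and
Mann-Kendall trend testing of regional proportions, TH+ co-transmission
profiling, Parkinson's-disease gene panels and risk-gene enrichment,
cell-class correlation, k-nearest-neighbor majority label transfer, and
Jaccard/connected-component deduplication of enriched term sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .stats import TrendResult, bonferroni, fisher_greater, mann_kendall

__all__ = [
    "COTRANS_MARKERS",
    "DEFAULT_TIMEPOINT_MERGE",
    "signature_score",
    "ventrality_call",
    "regional_marker_filter",
    "merge_timepoints",
    "trend_test",
    "cotransmission_profile",
    "gene_panel_matrix",
    "risk_enrichment",
    "class_correlation",
    "majority_neighbor_transfer",
    "dedup_term_sets",
    "scrna_qc",
]


def signature_score(
    expr: pd.DataFrame, gene_set: Sequence[str], r_max: int = 1500
) -> pd.Series:
    """Rank-based signature score per cell (UCell-style).

    Genes are ranked per cell by expression, descending, with average ranks
    for ties; ranks beyond ``r_max`` are truncated to ``r_max + 1`` so that
    depth differences among undetected genes cannot move the score.  With
    ``U = sum(signature ranks) - n_g (n_g + 1) / 2`` the score is
    ``max(0, 1 - U / (n_g * r_max))``: 1 when the signature occupies the top
    ranks, 0 when it is entirely buried below the cap.

    ``expr`` is cells x genes (any monotone normalization; the score is
    rank-based and invariant to monotone transforms).
    """
    gene_set = list(gene_set)
    if len(gene_set) == 0:
        raise ValueError("empty gene signature")
    missing = [g for g in gene_set if g not in expr.columns]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    n_g = len(gene_set)
    vals = expr.to_numpy(dtype=float)
    # rank descending per cell, average ties
    ranks = _sps.rankdata(-vals, axis=1)
    ranks = np.minimum(ranks, r_max + 1)
    cols = [expr.columns.get_loc(g) for g in gene_set]
    u = ranks[:, cols].sum(axis=1) - n_g * (n_g + 1) / 2
    score = np.maximum(0.0, 1.0 - u / (n_g * r_max))
    return pd.Series(score, index=expr.index, name="signature_score")


def ventrality_call(
    ventral_score: pd.Series,
    dorsal_score: pd.Series,
    ambiguous_quantile: float = 0.25,
) -> pd.DataFrame:
    """Classify cells as ventral / dorsal / ambiguous midbrain identity.

    The ventrality index V is the ratio of ventral to dorsal signature
    score.  Cells with V > 1 are ventral, V <= 1 dorsal (a ventral score
    with zero dorsal score gives V = +inf, hence ventral), except that a
    cell whose ventral AND dorsal scores both fall below their respective
    ``ambiguous_quantile`` cutoffs (computed over all input cells) is
    called ambiguous regardless of V — neither signature is credibly
    expressed.  Setting the quantile to 0 eliminates ambiguous calls.
    """
    v = ventral_score.to_numpy(dtype=float)
    d = dorsal_score.to_numpy(dtype=float)
    if v.shape != d.shape:
        raise ValueError("ventral and dorsal scores must cover the same cells")
    with np.errstate(divide="ignore", invalid="ignore"):
        vi = np.where(d > 0, v / np.where(d > 0, d, 1.0), np.where(v > 0, np.inf, np.nan))
    v_cut = np.quantile(v, ambiguous_quantile) if ambiguous_quantile > 0 else -np.inf
    d_cut = np.quantile(d, ambiguous_quantile) if ambiguous_quantile > 0 else -np.inf
    ambiguous = (v < v_cut) & (d < d_cut)
    call = np.where(np.nan_to_num(vi, nan=0.0) > 1, "ventral", "dorsal")
    call = np.where(ambiguous, "ambiguous", call)
    return pd.DataFrame(
        {
            "ventral_score": v,
            "dorsal_score": d,
            "ventrality_index": vi,
            "call": call,
        },
        index=ventral_score.index,
    )


def regional_marker_filter(
    de_table: pd.DataFrame,
    p_adj_max: float = 0.05,
    base_mean_min: float = 200.0,
    abs_log2fc_min: float = 3.0,
    positive_is_ventral: bool = True,
) -> tuple[list[str], list[str]]:
    """Select ventral and dorsal regional markers from a DE table.

    Keeps genes with adjusted p below ``p_adj_max``, base mean at least
    ``base_mean_min`` and |log2 fold change| above ``abs_log2fc_min``, then
    splits by fold-change sign (``positive_is_ventral`` declares the sign
    convention of the contrast).
    """
    required = {"gene", "p_adj", "base_mean", "log2fc"}
    missing = required - set(de_table.columns)
    if missing:
        raise KeyError(f"DE table missing columns: {sorted(missing)}")
    kept = de_table[
        (de_table["p_adj"] < p_adj_max)
        & (de_table["base_mean"] >= base_mean_min)
        & (de_table["log2fc"].abs() > abs_log2fc_min)
    ]
    pos = kept.loc[kept["log2fc"] > 0, "gene"].tolist()
    neg = kept.loc[kept["log2fc"] < 0, "gene"].tolist()
    return (pos, neg) if positive_is_ventral else (neg, pos)


#: Adjacent collection days merged to a single nominal age (days).
DEFAULT_TIMEPOINT_MERGE: dict[int, int] = {
    65: 65, 70: 65,
    99: 102, 105: 102,
    120: 123, 126: 123,
    150: 153, 156: 153,
}


def merge_timepoints(
    ages: Sequence[int],
    merge_map: Mapping[int, int] = DEFAULT_TIMEPOINT_MERGE,
    strict: bool = False,
) -> list[int]:
    """Map sample collection ages onto merged nominal timepoints."""
    out = []
    for a in ages:
        if a in merge_map:
            out.append(merge_map[a])
        elif strict:
            raise KeyError(f"age {a} not covered by the timepoint merge map")
        else:
            out.append(a)
    return out


def trend_test(values: Sequence[float]) -> TrendResult:
    """Mann-Kendall trend test on a time-ordered series of proportions."""
    return mann_kendall(values)


#: Neurotransmitter machinery markers for TH+ co-transmission profiling.
COTRANS_MARKERS = ("TH", "GAD2", "TPH1", "SLC17A6")


def cotransmission_profile(
    expr: pd.DataFrame,
    markers: Sequence[str] = COTRANS_MARKERS,
    positivity_threshold: float = 1.0,
) -> pd.Series:
    """Proportions of TH+ cells co-expressing other transmitter machinery.

    Positivity is depth-corrected count >= ``positivity_threshold``.  Cells
    negative for all of TH, TPH1 and GAD2 are excluded first; among TH+
    cells, those positive for two or more of the partner markers (GAD2,
    TPH1, SLC17A6) are excluded as unresolvable multi-transmitting; the
    remaining TH+ cells are profiled as TH-only / TH+GAD2 / TH+TPH1 /
    TH+SLC17A6 proportions.
    """
    th, gad2, tph1, slc = markers
    for g in (th, gad2, tph1):
        if g not in expr.columns:
            raise KeyError(f"marker {g} absent from matrix")
    pos = expr.reindex(columns=list(markers), fill_value=0.0) >= positivity_threshold
    included = pos[th] | pos[tph1] | pos[gad2]
    th_pos = pos[th] & included
    partners = pos.loc[th_pos, [gad2, tph1, slc]]
    multi = partners.sum(axis=1) >= 2
    kept = partners[~multi]
    denom = len(kept)
    if denom == 0:
        raise ValueError("no TH+ cells remain after the co-transmission exclusion")
    n_gad2 = int(kept[gad2].sum())
    n_tph1 = int(kept[tph1].sum())
    n_slc = int(kept[slc].sum())
    return pd.Series(
        {
            "TH-only": (denom - n_gad2 - n_tph1 - n_slc) / denom,
            f"TH+{gad2}": n_gad2 / denom,
            f"TH+{tph1}": n_tph1 / denom,
            f"TH+{slc}": n_slc / denom,
        },
        name="proportion",
    )


def gene_panel_matrix(
    expr: pd.DataFrame,
    genes: Sequence[str],
    groups: pd.Series,
    linkage_method: str = "average",
) -> dict:
    """Per-group averaged, log1p, column-z-scored gene panel heatmap matrix.

    Depth-corrected counts are averaged per group (cell type), log1p
    transformed, and z-scored per column (gene); rows and columns are then
    ordered by hierarchical clustering on Euclidean distance
    (``linkage_method`` linkage).  Genes absent from the matrix are reported
    and skipped; a single group (zero column variance) yields zeros with a
    warning.
    """
    genes = list(genes)
    present = [g for g in genes if g in expr.columns]
    skipped = [g for g in genes if g not in expr.columns]
    if skipped:
        warnings.warn(f"genes absent from matrix, skipped: {skipped}", stacklevel=2)
    if not present:
        raise ValueError("none of the requested genes are present")
    mean = expr[present].groupby(groups).mean()
    mat = np.log1p(mean)
    sd = mat.std(axis=0, ddof=0)
    if (sd == 0).any() or len(mat) < 2:
        warnings.warn("degenerate z-scores (constant column or single group) set to 0",
                      stacklevel=2)
    z = (mat - mat.mean(axis=0)) / sd.replace(0, np.nan)
    z = z.fillna(0.0)

    def _order(m: np.ndarray) -> np.ndarray:
        if m.shape[0] < 2:
            return np.arange(m.shape[0])
        link = hierarchy.linkage(pdist(m, metric="euclidean"), method=linkage_method)
        return np.asarray(hierarchy.leaves_list(link))

    row_order = _order(z.to_numpy())
    col_order = _order(z.to_numpy().T)
    return {
        "matrix": z,
        "row_order": z.index[row_order].tolist(),
        "col_order": z.columns[col_order].tolist(),
        "skipped_genes": skipped,
        "linkage": linkage_method,
    }


def risk_enrichment(
    expr: pd.DataFrame,
    groups: pd.Series,
    risk_genes: Iterable[str],
    baseline: float = 1.0,
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cell-type enrichment of disease-risk genes among expressed genes.

    A gene counts as expressed in a cell type when its mean depth-corrected
    count per cell exceeds ``baseline``.  For each type, a one-sided
    (greater) Fisher exact test asks whether the risk set is
    over-represented among that type's expressed genes relative to the gene
    universe (all genes in the matrix unless ``universe`` is given);
    Bonferroni adjustment is over the number of types tested.
    """
    risk = set(risk_genes)
    if not risk:
        raise ValueError("risk gene set is empty")
    genes = list(expr.columns) if universe is None else list(universe)
    risk_in = risk & set(genes)
    rows = []
    for ct, sub in expr.groupby(groups):
        mean = sub[genes].mean(axis=0)
        expressed = set(mean.index[mean > baseline])
        k = len(risk_in & expressed)
        p = fisher_greater(k, len(risk_in), len(expressed), len(genes))
        rows.append(
            {
                "cell_type": ct,
                "n_expressed": len(expressed),
                "k_overlap": k,
                "n_risk": len(risk_in),
                "n_universe": len(genes),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("cell_type")
    out["p_bonferroni"] = bonferroni(out["p"].to_numpy(), m=len(out))
    return out


def class_correlation(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    hvg: Sequence[str],
) -> pd.DataFrame:
    """Spearman correlation matrix between cell-class expression profiles.

    ``profiles_*`` are class x gene matrices of per-class mean (normalized)
    expression; correlation is computed over the shared highly-variable
    gene list ``hvg``.
    """
    hvg = list(hvg)
    if len(hvg) < 3:
        raise ValueError("need >= 3 highly variable genes")
    missing = [g for g in hvg if g not in profiles_a.columns or g not in profiles_b.columns]
    if missing:
        raise KeyError(f"HVGs missing from profiles: {missing[:5]}")
    a = profiles_a[hvg].to_numpy(dtype=float)
    b = profiles_b[hvg].to_numpy(dtype=float)
    out = np.empty((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            out[i, j] = _sps.spearmanr(a[i], b[j]).statistic
    return pd.DataFrame(out, index=profiles_a.index, columns=profiles_b.index)


def majority_neighbor_transfer(
    reference_embedding: np.ndarray,
    reference_labels: Sequence[str],
    query_embedding: np.ndarray,
    k: int = 100,
    per_label_downsample: int | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Transfer labels to query cells by k-nearest-neighbor plurality vote.

    The reference may first be downsampled to ``per_label_downsample`` cells
    per label (seeded, without replacement) to remove class-imbalance bias.
    Each query cell receives the most common label among its ``k`` nearest
    reference cells in the shared embedding (Euclidean distance); an exact
    tie between top labels yields a missing value (the cell is excluded).
    """
    from sklearn.neighbors import NearestNeighbors

    ref = np.asarray(reference_embedding, dtype=float)
    labels = np.asarray(reference_labels)
    qry = np.asarray(query_embedding, dtype=float)
    if ref.shape[0] != labels.shape[0]:
        raise ValueError("reference embedding and labels disagree in length")
    if per_label_downsample is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if idx.size > per_label_downsample:
                idx = rng.choice(idx, size=per_label_downsample, replace=False)
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        ref, labels = ref[keep], labels[keep]
    if k > ref.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {ref.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    _, neigh = nn.kneighbors(qry)
    out = []
    for row in neigh:
        vals, counts = np.unique(labels[row], return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        out.append(winners[0] if winners.size == 1 else None)
    return pd.Series(out, dtype=object, name="transferred_label")


def dedup_term_sets(
    term_sets: Mapping[str, Iterable[str]],
    min_genes: int = 6,
    jaccard_threshold: float = 0.2,
) -> pd.DataFrame:
    """Deduplicate enriched term sets by Jaccard-graph connected components.

    Terms with fewer than ``min_genes`` genes are dropped.  An edge joins
    two terms when the Jaccard index of their gene sets exceeds
    ``jaccard_threshold``; connected components define clusters, and each
    cluster's representative is the term with the largest gene set (ties
    broken by lexicographically smallest id).
    """
    import networkx as nx

    sets = {t: frozenset(g) for t, g in term_sets.items() if len(set(g)) >= min_genes}
    graph = nx.Graph()
    graph.add_nodes_from(sets)
    terms = sorted(sets)
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1 :]:
            inter = len(sets[t1] & sets[t2])
            union = len(sets[t1] | sets[t2])
            if union and inter / union > jaccard_threshold:
                graph.add_edge(t1, t2)
    rows = []
    for ci, comp in enumerate(sorted(nx.connected_components(graph), key=sorted)):
        # max gene count; tie -> lexicographically smallest id
        best = sorted(comp, key=lambda t: (-len(sets[t]), t))[0]
        for t in sorted(comp):
            rows.append(
                {"term": t, "cluster": ci, "n_genes": len(sets[t]),
                 "representative": best, "is_representative": t == best}
            )
    return pd.DataFrame(rows)


def scrna_qc(
    cells: pd.DataFrame,
    min_genes: int = 1000,
    max_genes: int = 10_000,
    min_mito_frac: float = 0.01,
    max_mito_frac: float = 0.10,
) -> tuple[pd.DataFrame, dict]:
    """Threshold quality control for single-cell RNA-seq cell tables.

    Keeps cells detecting between ``min_genes`` and ``max_genes`` genes and
    with mitochondrial fraction in [``min_mito_frac``, ``max_mito_frac``):
    high mitochondrial content marks damaged cells, while near-zero content
    marks stripped nuclei rather than whole cells.
    """
    for col in ("n_genes", "mito_frac"):
        if col not in cells.columns:
            raise KeyError(f"cell table missing column {col!r}")
    keep = (
        (cells["n_genes"] >= min_genes)
        & (cells["n_genes"] <= max_genes)
        & (cells["mito_frac"] >= min_mito_frac)
        & (cells["mito_frac"] < max_mito_frac)
    )
    report = {
        "n_input": len(cells),
        "removed_low_genes": int((cells["n_genes"] < min_genes).sum()),
        "removed_high_genes": int((cells["n_genes"] > max_genes).sum()),
        "removed_high_mito": int((cells["mito_frac"] >= max_mito_frac).sum()),
        "removed_low_mito_nuclei": int((cells["mito_frac"] < min_mito_frac).sum()),
        "n_kept": int(keep.sum()),
    }
    return cells[keep], report
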