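"""Seeded synthetic organoid data with the structure the analyses assume.

The generators plant exactly the features the downstream statistics are
designed to detect, with known ground truth, so every stage of the
pipeline is testable without deposited data:

* ``gen_section`` — a disk-shaped organoid section.  Cells are uniform
  over the disk by area; a radial "hypoxia" gradient drives six metabolic
  genes up with depth from the edge; dopaminergic (DaN) and GABAergic
  (GabaN) neurons are drawn from angular sectors separated by a
  configurable angle, emulating ventral/dorsal territorial segregation.
* ``gen_timecourse`` — a series of timepoints whose ventral-cell fraction
  follows a supplied trajectory, with ventral/dorsal marker genes enriched
  in the matching cells.
* ``gen_spot_reads`` — barcode reads from a codebook with i.i.d. per-bit
  flip errors and recorded truth, to exercise the decoder.
* ``gen_label_mask`` — a nuclear segmentation label image painted from
  cell centroids, to exercise spot-to-cell assignment.

Counts are negative-binomial (fixed dispersion over a type+depth mean
model), matching the overdispersion of real single-cell counts without
fitting any.  Truth depth is defined analytically as (R - r) / R so that
it stays independent of the convex-hull estimator under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codec import Codebook
from .spatial import METABOLIC_GENES

__all__ = [
    "SectionSpec",
    "TimecourseSpec",
    "VENTRAL_MARKERS",
    "DORSAL_MARKERS",
    "gen_section",
    "gen_timecourse",
    "gen_spot_reads",
    "gen_label_mask",
]

#: Synthetic ventral / dorsal midbrain marker panels used by gen_timecourse.
VENTRAL_MARKERS = ("LMX1A", "FOXA2", "EN1", "NR4A2", "PITX3")
DORSAL_MARKERS = ("PAX3", "PAX7", "GATA3", "OTX2", "BARHL1")

_HOUSEKEEPING = tuple(f"HK{i}" for i in range(1, 9))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu**2."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


@dataclass
class SectionSpec:
    """Parameters of one synthetic disk-shaped organoid section.

    ``hypoxia_slope`` is the log-linear gain of metabolic-gene expression
    with normalized depth (0 at the edge, 1 at the center): mean counts
    scale as exp(slope * depth).  ``segregation_angle`` separates the
    angular sector centers of DaNs and GabaNs; each sector spans pi
    radians, so an angle of pi makes the two supports disjoint half-disks.
    ``count_noise`` is the negative-binomial dispersion.
    """

    radius_um: float = 1000.0
    n_cells: int = 6000
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"DaN": 0.25, "GabaN": 0.25, "Prog": 0.3, "RG": 0.2}
    )
    segregation_angle: float = np.pi
    hypoxia_slope: float = 2.0
    count_noise: float = 0.3
    sample_id: str = "S1"
    timepoint: int = 60
    genotype: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        total = float(sum(self.type_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type proportions must sum to 1, got {total}")


def gen_section(spec: SectionSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic section.

    Returns ``(cells, counts, truth)``: a cell table (centroids in µm,
    areas, sample metadata, type label), a cells x genes count matrix, and
    the ground truth (latent depth and true type) kept separate from the
    observables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    types = list(spec.type_proportions)
    probs = np.array([spec.type_proportions[t] for t in types], dtype=float)
    type_idx = rng.choice(len(types), size=n, p=probs)
    labels = np.array(types, dtype=object)[type_idx]

    # radius by sqrt(u) -> uniform over disk area; angle by population sector
    r = spec.radius_um * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(-np.pi, np.pi, size=n)
    half = np.pi / 2
    is_dan = labels == "DaN"
    is_gaba = labels == "GabaN"
    theta[is_dan] = rng.uniform(-half, half, size=int(is_dan.sum()))
    theta[is_gaba] = spec.segregation_angle + rng.uniform(
        -half, half, size=int(is_gaba.sum())
    )
    x = spec.radius_um + r * np.cos(theta)
    y = spec.radius_um + r * np.sin(theta)
    depth = (spec.radius_um - r) / spec.radius_um

    genes = list(METABOLIC_GENES) + ["TH", "GAD2", "TPH1", "SLC17A6"] + list(_HOUSEKEEPING)
    base = pd.DataFrame(1.0, index=range(n), columns=genes)
    for g in METABOLIC_GENES:
        base[g] = 2.0 * np.exp(spec.hypoxia_slope * depth)
    base.loc[is_dan, "TH"] = 20.0
    base.loc[is_gaba, "GAD2"] = 20.0
    base.loc[:, list(_HOUSEKEEPING)] = 5.0
    counts = pd.DataFrame(
        _nb_counts(rng, base.to_numpy(), spec.count_noise),
        index=[f"cell_{i + 1}" for i in range(n)],
        columns=genes,
    )

    nucleus_area = rng.normal(420.0, 60.0, size=n).clip(80.0)
    cell_area = nucleus_area * rng.uniform(2.2, 3.4, size=n)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "x_um": x,
            "y_um": y,
            "cell_area_px": cell_area,
            "nucleus_area_px": nucleus_area,
            "sample_id": spec.sample_id,
            "timepoint": spec.timepoint,
            "genotype": spec.genotype,
            "type_label": labels,
        },
        index=counts.index,
    )
    truth = pd.DataFrame(
        {"depth": depth, "true_type": labels, "seed": spec.seed}, index=counts.index
    )
    return cells, counts, truth


@dataclass
class TimecourseSpec:
    """Parameters of a synthetic regionalization timecourse.

    ``ventral_fractions`` gives the planted probability that a cell carries
    ventral identity at each timepoint; ``marker_effect`` is the log2-fold
    enrichment of ventral (dorsal) markers in ventral (dorsal) cells.
    """

    timepoints: Sequence[int] = (65, 102, 123, 138, 153)
    ventral_fractions: Sequence[float] = (0.45, 0.55, 0.65, 0.75, 0.85)
    cells_per_timepoint: int = 2000
    marker_effect: float = 3.0
    count_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.ventral_fractions):
            raise ValueError("timepoints and ventral_fractions must align")
        for f in self.ventral_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"ventral fraction {f} outside [0, 1]")
        if self.cells_per_timepoint < 1:
            raise ValueError("cells_per_timepoint must be >= 1")


def gen_timecourse(
    spec: TimecourseSpec,
) -> list[tuple[pd.DataFrame, pd.Series, int]]:
    """Generate one expression matrix per timepoint.

    Returns a list of ``(expr, truth_labels, timepoint)``: a cells x genes
    matrix (ventral markers, dorsal markers and background genes), the true
    per-cell identity, and the timepoint label.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(VENTRAL_MARKERS) + list(DORSAL_MARKERS) + [f"BG{i}" for i in range(1, 41)]
    out = []
    gain = 2.0 ** spec.marker_effect
    for tp, frac in zip(spec.timepoints, spec.ventral_fractions):
        n = spec.cells_per_timepoint
        is_ventral = rng.uniform(size=n) < frac
        base = pd.DataFrame(2.0, index=range(n), columns=genes)
        base.loc[is_ventral, list(VENTRAL_MARKERS)] = 2.0 * gain
        base.loc[~is_ventral, list(DORSAL_MARKERS)] = 2.0 * gain
        expr = pd.DataFrame(
            _nb_counts(rng, base.to_numpy(), spec.count_noise),
            index=[f"d{tp}_cell_{i + 1}" for i in range(n)],
            columns=genes,
        )
        labels = pd.Series(
            np.where(is_ventral, "ventral", "dorsal"), index=expr.index, name="true_identity"
        )
        out.append((expr, labels, tp))
    return out


def gen_spot_reads(
    codebook: Codebook,
    n_spots: int,
    error_rate: float,
    seed: int = 0,
    extent_um: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate barcode reads: true gene codewords with i.i.d. bit flips.

    Spots draw their true identity uniformly from the codebook's gene
    entries and their position uniformly over a square of side
    ``extent_um``.  Returns ``(spots, truth)`` where spots carry the
    measured word and truth records the true gene and flip count per spot.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_entries = [e for e in codebook.entries if e.role == "gene"]
    if not gene_entries:
        raise ValueError("codebook has no gene entries")
    cols = ["spot_id", "x_um", "y_um", "word"]
    if n_spots == 0:
        return (
            pd.DataFrame(columns=cols),
            pd.DataFrame(columns=["spot_id", "true_gene", "n_flips"]),
        )
    pick = rng.integers(0, len(gene_entries), size=n_spots)
    words = np.array(
        [[int(c) for c in gene_entries[i].word] for i in pick], dtype=np.int8
    )
    flips = rng.uniform(size=words.shape) < error_rate
    measured = words ^ flips.astype(np.int8)
    spots = pd.DataFrame(
        {
            "spot_id": np.arange(1, n_spots + 1),
            "x_um": rng.uniform(0, extent_um, size=n_spots),
            "y_um": rng.uniform(0, extent_um, size=n_spots),
            "word": ["".join(map(str, row)) for row in measured],
        }
    )
    truth = pd.DataFrame(
        {
            "spot_id": spots["spot_id"],
            "true_gene": [gene_entries[i].name for i in pick],
            "n_flips": flips.sum(axis=1).astype(int),
        }
    )
    return spots, truth


def gen_label_mask(
    cells: pd.DataFrame,
    pixel_size_um: float = 1.0,
    nucleus_radius_px: int = 5,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Paint a nuclear label image from cell centroids.

    Each cell is a disk of ``nucleus_radius_px`` carrying its integer
    ``cell_id``; background is 0, and a pixel contested by overlapping
    disks goes to the nearer centroid.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    col = cells["x_um"].to_numpy() / pixel_size_um
    row = cells["y_um"].to_numpy() / pixel_size_um
    ids = cells["cell_id"].to_numpy().astype(int)
    if shape is None:
        h = int(np.ceil(row.max())) + nucleus_radius_px + 2
        w = int(np.ceil(col.max())) + nucleus_radius_px + 2
        shape = (h, w)
    if (row < 0).any() or (col < 0).any() or (row >= shape[0]).any() or (col >= shape[1]).any():
        raise ValueError("cell centroids fall outside the image bounds")
    mask = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    for cid, cy, cx in zip(ids, row, col):
        r0 = max(int(np.floor(cy)) - nucleus_radius_px, 0)
        r1 = min(int(np.ceil(cy)) + nucleus_radius_px + 1, shape[0])
        c0 = max(int(np.floor(cx)) - nucleus_radius_px, 0)
        c1 = min(int(np.ceil(cx)) + nucleus_radius_px + 1, shape[1])
        rr, cc = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(rr - cy, cc - cx)
        inside = d <= nucleus_radius_px
        closer = d < best[r0:r1, c0:c1]
        take = inside & closer
        mask[r0:r1, c0:c1][take] = cid
        best[r0:r1, c0:c1][take] = d[take]
    return mask
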