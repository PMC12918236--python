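"""Readers, writers, run configuration and the two analysis pipelines.

Conventions: coordinates are in µm with the origin at the section top-left
and y increasing downward (image convention).  All tabular I/O is UTF-8
TSV/CSV with a header row; counts travel as MatrixMarket MTX with
genes.tsv/cells.tsv sidecars; masks as single-channel integer TIFF;
codebooks and run reports as JSON; run configuration as YAML.  Every
report carries the configuration hash and seeds for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import io as _spio
from scipy import sparse

from . import codec, scoring, spatial, synth

__all__ = [
    "CELL_TABLE_COLUMNS",
    "RunConfig",
    "read_cell_table",
    "write_cell_table",
    "read_counts",
    "write_counts",
    "read_codebook",
    "write_codebook",
    "read_spots",
    "write_spots",
    "read_mask",
    "write_mask",
    "run_spatial_pipeline",
    "run_scoring_pipeline",
]

CELL_TABLE_COLUMNS = [
    "cell_id", "x_um", "y_um", "cell_area_px", "nucleus_area_px",
    "sample_id", "timepoint", "genotype", "type_label",
]


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} missing columns: {missing}")
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_counts(mtx_dir: str | Path) -> pd.DataFrame:
    """Read a counts matrix from MTX + genes.tsv + cells.tsv sidecars.

    Returns a dense cells x genes DataFrame (panels here are small).
    """
    mtx_dir = Path(mtx_dir)
    mat = _spio.mmread(mtx_dir / "matrix.mtx")
    if (mat.data < 0).any():
        raise ValueError("count matrix contains negative entries")
    genes = pd.read_csv(mtx_dir / "genes.tsv", sep="\t", header=None)[0].tolist()
    cellids = pd.read_csv(mtx_dir / "cells.tsv", sep="\t", header=None)[0].tolist()
    dense = np.asarray(mat.todense())
    if dense.shape != (len(genes), len(cellids)):
        raise ValueError("matrix dimensions disagree with sidecar files")
    return pd.DataFrame(dense.T, index=cellids, columns=genes)


def write_counts(counts: pd.DataFrame, mtx_dir: str | Path) -> None:
    """Write a cells x genes DataFrame as genes x cells MTX + sidecars."""
    mtx_dir = Path(mtx_dir)
    mtx_dir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(counts.to_numpy().T)
    _spio.mmwrite(mtx_dir / "matrix.mtx", mat)
    pd.Series(counts.columns).to_csv(mtx_dir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.index).to_csv(mtx_dir / "cells.tsv", sep="\t", index=False, header=False)


def read_codebook(path: str | Path) -> codec.Codebook:
    return codec.Codebook.from_json(Path(path).read_text())


def write_codebook(cb: codec.Codebook, path: str | Path) -> None:
    Path(path).write_text(cb.to_json())


def read_spots(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"word": str})
    for c in ("spot_id", "x_um", "y_um", "word"):
        if c not in df.columns:
            raise ValueError(f"spot table {path} missing column {c!r}")
    return df


def write_spots(spots: pd.DataFrame, path: str | Path) -> None:
    spots.to_csv(path, index=False)


def read_mask(path: str | Path) -> np.ndarray:
    import tifffile

    mask = tifffile.imread(path)
    if mask.ndim != 2 or not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be a 2-D integer label image")
    return mask


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with the field's standard defaults:
    50 µm co-localization bins, 10,000 permutations, 60th-percentile zone
    cut, rank cap 1500, Jaccard 0.2, k = 100 neighbors, baseline count 1."""

    seed: int = 0
    n_sections: int = 3
    section: dict = field(default_factory=dict)
    bin_um: float = 50.0
    n_perm: int = 10_000
    zone_percentile: float = 60.0
    dilation_px: int = 10
    correct_single_bit: bool = True
    r_max: int = 1500
    jaccard_threshold: float = 0.2
    k_neighbors: int = 100
    baseline: float = 1.0
    timecourse: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        obj = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**obj)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def run_spatial_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Synthetic MERFISH spatial pipeline: simulate sections, decode spot
    reads, call interior/exterior zones, and run the per-section and cohort
    co-localization tests.  Returns a JSON-serializable report."""
    rng = np.random.default_rng(config.seed)
    words = codec.build_codebook()
    genes = list(spatial.METABOLIC_GENES) + ["TH", "GAD2", "TPH1", "SLC17A6"]
    cb = codec.assign_barcodes(words, genes, n_blanks=4, seed=config.seed)

    sections = []
    coloc_results = []
    for i in range(config.n_sections):
        sec_seed = int(rng.integers(0, 2**31 - 1))
        spec = synth.SectionSpec(seed=sec_seed, **config.section)
        cells, counts, truth = synth.gen_section(spec)

        spots, spot_truth = synth.gen_spot_reads(cb, n_spots=2000, error_rate=0.01,
                                                 seed=sec_seed)
        decoded = codec.decode_spots(spots, cb, config.correct_single_bit)
        fdr = codec.blank_fdr(decoded, cb)

        norm = counts.div(counts.sum(axis=1).replace(0, 1), axis=0) * counts.sum(axis=1).mean()
        mindex = spatial.metabolic_index(norm)
        zones = spatial.binarize_zone(mindex, config.zone_percentile)

        dan = cells.loc[cells["type_label"] == "DaN", ["x_um", "y_um"]].to_numpy()
        gaba = cells.loc[cells["type_label"] == "GabaN", ["x_um", "y_um"]].to_numpy()
        coloc = spatial.grid_colocalization(
            dan, gaba, bin_um=config.bin_um, n_perm=config.n_perm, seed=sec_seed
        )
        coloc_results.append(coloc)
        sections.append(
            {
                "seed": sec_seed,
                "n_cells": len(cells),
                "blank_fdr": fdr,
                "interior_fraction": float((zones == "interior").mean()),
                "coloc": coloc.to_dict(),
            }
        )
    cohort_test, cohort_table = spatial.cohort_colocalization(coloc_results)
    report = {
        "pipeline": "spatial",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sections": sections,
        "cohort": {
            "p": cohort_test.p,
            "statistic": cohort_test.statistic,
            "method": cohort_test.method,
            "pairs": cohort_table.to_dict(orient="records"),
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "spatial_report.json").write_text(json.dumps(report, indent=1))
    return report


def run_scoring_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Synthetic scoring pipeline: simulate a regionalization timecourse,
    score ventral/dorsal signatures, call ventrality, and trend-test the
    ventral fraction over timepoints."""
    spec = synth.TimecourseSpec(seed=config.seed, **config.timecourse)
    series = synth.gen_timecourse(spec)
    fracs, tps = [], []
    for expr, _, tp in series:
        v = scoring.signature_score(expr, synth.VENTRAL_MARKERS, config.r_max)
        d = scoring.signature_score(expr, synth.DORSAL_MARKERS, config.r_max)
        calls = scoring.ventrality_call(v, d)
        resolved = calls[calls["call"] != "ambiguous"]
        fracs.append(float((resolved["call"] == "ventral").mean()))
        tps.append(tp)
    trend = scoring.trend_test(fracs)
    report = {
        "pipeline": "scoring",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timepoints": tps,
        "ventral_fractions": fracs,
        "trend": trend.to_dict(),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "scoring_report.json").write_text(json.dumps(report, indent=1))
    return report
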