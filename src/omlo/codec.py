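"""MERFISH barcode codebook construction, decoding, spot assignment and QC.

MERFISH reads each RNA species out as a 16-bit binary word over sequential
imaging rounds.  The codebook is a constant-weight binary code: every
codeword has Hamming weight 4 and every pair of codewords differs in at
least 4 bits (the MHD4 code).  Weight 4 keeps per-round signal density
uniform; distance 4 allows any single bit flip to be corrected uniquely
and any double flip to be detected and discarded.  A handful of codewords
are reserved as "blanks" — assigned to no gene — so that the rate at which
spots decode to blanks estimates the misidentification rate of the whole
panel.

This module builds the maximal (16, 4, 4) code constructively from the
extended Hamming code, decodes measured words with optional single-bit
correction, assigns decoded spots to segmented cells after per-cell mask
dilation, and applies the cell-level quality-control and bulk-RNA-seq
validation steps.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as _sps

__all__ = [
    "Codebook",
    "CodebookEntry",
    "ProbeRegion",
    "build_codebook",
    "assign_barcodes",
    "decode_word",
    "decode_spots",
    "blank_fdr",
    "dilate_labels",
    "assign_spots",
    "merfish_cell_qc",
    "panel_bulk_correlation",
    "specificity_index",
    "filter_probe_regions",
]

UNASSIGNED = "UNASSIGNED"


def _word_to_str(word: int, n_bits: int) -> str:
    return format(word, f"0{n_bits}b")


def _str_to_word(s: str) -> int:
    if set(s) - {"0", "1"}:
        raise ValueError(f"word string must be binary, got {s!r}")
    return int(s, 2)


@dataclass(frozen=True)
class CodebookEntry:
    name: str
    role: Literal["gene", "blank"]
    word: str  # n_bits-character 0/1 string


@dataclass
class Codebook:
    """Named constant-weight barcode set.

    Invariants (checked on construction): every word has exactly ``weight``
    ones, all pairwise Hamming distances are >= ``min_distance``, and names
    and words are unique.
    """

    n_bits: int
    weight: int
    min_distance: int
    entries: list[CodebookEntry]
    seed: int | None = None

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("codebook entry names must be unique")
        words = [_str_to_word(e.word) for e in self.entries]
        if len(set(words)) != len(words):
            raise ValueError("codebook words must be unique")
        for e, w in zip(self.entries, words):
            if len(e.word) != self.n_bits:
                raise ValueError(f"word for {e.name} has wrong length")
            if bin(w).count("1") != self.weight:
                raise ValueError(f"word for {e.name} has weight != {self.weight}")
        for (wa, ea), (wb, eb) in itertools.combinations(zip(words, self.entries), 2):
            if bin(wa ^ wb).count("1") < self.min_distance:
                raise ValueError(
                    f"words for {ea.name} and {eb.name} violate minimum distance"
                )

    @property
    def genes(self) -> list[str]:
        return [e.name for e in self.entries if e.role == "gene"]

    @property
    def blanks(self) -> list[str]:
        return [e.name for e in self.entries if e.role == "blank"]

    def word_map(self) -> dict[int, CodebookEntry]:
        return {_str_to_word(e.word): e for e in self.entries}

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_bits": self.n_bits,
                "weight": self.weight,
                "min_distance": self.min_distance,
                "seed": self.seed,
                "entries": [
                    {"name": e.name, "role": e.role, "word": e.word}
                    for e in self.entries
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Codebook":
        obj = json.loads(text)
        return cls(
            n_bits=obj["n_bits"],
            weight=obj["weight"],
            min_distance=obj["min_distance"],
            seed=obj.get("seed"),
            entries=[CodebookEntry(e["name"], e["role"], e["word"]) for e in obj["entries"]],
        )


def _extended_hamming_weight4_words() -> list[int]:
    """Weight-4 codewords of the [16, 11, 4] extended Hamming code.

    A 16-bit word with support S (bit positions 0..15) is a codeword iff
    the XOR of the positions in S is zero (each position read as a 4-bit
    vector) and |S| is even.  For |S| = 4 both conditions reduce to the
    XOR-zero constraint; there are exactly 140 such words.
    """
    words = []
    for positions in itertools.combinations(range(16), 4):
        acc = 0
        for p in positions:
            acc ^= p
        if acc == 0:
            w = 0
            for p in positions:
                w |= 1 << p
            words.append(w)
    return sorted(words)


def build_codebook(n_bits: int = 16, weight: int = 4, min_distance: int = 4) -> list[str]:
    """Construct a constant-weight code as a list of bit-string words.

    For the canonical (16, 4, 4) parameters the code is taken constructively
    as the 140 weight-4 codewords of the length-16 extended Hamming code and
    verified exhaustively (pairwise distances, plus maximality against all
    C(16,4) = 1820 weight-4 words).  Other parameter sets fall back to a
    deterministic lexicographic greedy construction, which is verified but
    not guaranteed maximal.
    """
    if weight > n_bits:
        raise ValueError("weight cannot exceed n_bits")
    if min_distance < 2 or min_distance % 2 != 0:
        raise ValueError("min_distance must be even and >= 2")

    if (n_bits, weight, min_distance) == (16, 4, 4):
        words = _extended_hamming_weight4_words()
    else:
        words = []
        for positions in itertools.combinations(range(n_bits), weight):
            w = 0
            for p in positions:
                w |= 1 << p
            if all(bin(w ^ v).count("1") >= min_distance for v in words):
                words.append(w)
    if not words:
        raise ValueError(f"no ({n_bits},{weight},{min_distance}) code exists")

    for wa, wb in itertools.combinations(words, 2):
        if bin(wa ^ wb).count("1") < min_distance:
            raise AssertionError("constructed code violates minimum distance")
    return [_word_to_str(w, n_bits) for w in sorted(words)]


def verify_maximal(words: Sequence[str], n_bits: int = 16, weight: int = 4,
                   min_distance: int = 4) -> bool:
    """Exhaustively check that no further constant-weight word can be added."""
    have = {_str_to_word(w) for w in words}
    for positions in itertools.combinations(range(n_bits), weight):
        w = 0
        for p in positions:
            w |= 1 << p
        if w in have:
            continue
        if all(bin(w ^ v).count("1") >= min_distance for v in have):
            return False
    return True


def assign_barcodes(
    words: Sequence[str],
    gene_names: Sequence[str],
    n_blanks: int = 4,
    seed: int | None = None,
) -> Codebook:
    """Assign code words to genes plus ``n_blanks`` blank barcodes.

    Blank words are chosen by a seeded draw and the remaining words are
    shuffled onto the genes, so the gene→word mapping is reproducible from
    the seed recorded in the codebook.
    """
    gene_names = list(gene_names)
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("gene names must be unique")
    if len(gene_names) + n_blanks > len(words):
        raise ValueError(
            f"codebook capacity exceeded: {len(gene_names)} genes + {n_blanks} blanks "
            f"> {len(words)} words"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(words))
    blank_words = [words[i] for i in order[:n_blanks]]
    gene_words = [words[i] for i in order[n_blanks : n_blanks + len(gene_names)]]
    if not (len(words[0]) and all(len(w) == len(words[0]) for w in words)):
        raise ValueError("all words must share a length")
    n_bits = len(words[0])
    weight = words[0].count("1")
    entries = [
        CodebookEntry(f"Blank-{i + 1}", "blank", w) for i, w in enumerate(blank_words)
    ] + [CodebookEntry(g, "gene", w) for g, w in zip(gene_names, gene_words)]
    # min distance inferred by scan so the Codebook invariant check is honest
    min_d = n_bits
    word_ints = [_str_to_word(w) for w in words]
    for wa, wb in itertools.combinations(word_ints, 2):
        min_d = min(min_d, bin(wa ^ wb).count("1"))
    return Codebook(n_bits=n_bits, weight=weight, min_distance=min_d,
                    entries=entries, seed=seed)


def decode_word(
    word: str, codebook: Codebook, correct_single_bit: bool = True
) -> tuple[str, int]:
    """Decode one measured word against the codebook.

    Exact codeword match wins with 0 corrections.  Otherwise, if single-bit
    correction is enabled and exactly one codeword lies at Hamming distance
    1, that entry is returned with 1 correction (uniqueness is guaranteed by
    minimum distance 4).  Anything else is UNASSIGNED.
    """
    if len(word) != codebook.n_bits:
        raise ValueError(f"word length {len(word)} != {codebook.n_bits}")
    w = _str_to_word(word)
    wmap = codebook.word_map()
    hit = wmap.get(w)
    if hit is not None:
        return hit.name, 0
    if correct_single_bit:
        for bit in range(codebook.n_bits):
            hit = wmap.get(w ^ (1 << bit))
            if hit is not None:
                return hit.name, 1
    return UNASSIGNED, 0


def decode_spots(
    spots: pd.DataFrame, codebook: Codebook, correct_single_bit: bool = True
) -> pd.DataFrame:
    """Decode the ``word`` column of a spot table; adds ``decoded`` and
    ``n_corrected_bits`` columns (UNASSIGNED where no codeword qualifies)."""
    wmap = {w: e.name for w, e in codebook.word_map().items()}
    near = {}
    if correct_single_bit:
        for w, name in wmap.items():
            for bit in range(codebook.n_bits):
                near[w ^ (1 << bit)] = name
    decoded, ncorr = [], []
    for s in spots["word"].astype(str):
        if len(s) != codebook.n_bits:
            raise ValueError(f"word length {len(s)} != {codebook.n_bits}")
        w = _str_to_word(s)
        if w in wmap:
            decoded.append(wmap[w])
            ncorr.append(0)
        elif w in near:
            decoded.append(near[w])
            ncorr.append(1)
        else:
            decoded.append(UNASSIGNED)
            ncorr.append(0)
    out = spots.copy()
    out["decoded"] = decoded
    out["n_corrected_bits"] = ncorr
    return out


def blank_fdr(spots: pd.DataFrame, codebook: Codebook) -> float:
    """Misidentification-rate estimate from blank barcodes.

    Ratio of the mean decoded count per blank barcode to the mean decoded
    count per gene barcode.  Error-free data give 0; fully random words give
    a ratio near 1 by symmetry.
    """
    if "decoded" not in spots.columns:
        raise ValueError("spots must be decoded first (missing 'decoded' column)")
    counts = spots["decoded"].value_counts()
    gene_counts = [counts.get(g, 0) for g in codebook.genes]
    blank_counts = [counts.get(b, 0) for b in codebook.blanks]
    if not codebook.genes or not codebook.blanks:
        raise ValueError("codebook must contain both gene and blank entries")
    mean_gene = float(np.mean(gene_counts))
    if mean_gene == 0:
        raise ValueError("no spots decoded to gene barcodes; rate undefined")
    return float(np.mean(blank_counts)) / mean_gene


def dilate_labels(mask: np.ndarray, dilation_px: int,
                  centroids: Mapping[int, tuple[float, float]] | None = None) -> np.ndarray:
    """Dilate every label in an integer mask by ``dilation_px`` pixels.

    Each label grows into background pixels within Euclidean distance
    ``dilation_px`` of its original footprint.  A pixel reachable by more
    than one label goes to the label whose original centroid (row, col; or
    the supplied centroid map) is nearer.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    labels = [int(l) for l in np.unique(mask) if l != 0]
    if centroids is None:
        cents = ndimage.center_of_mass(mask > 0, mask, labels)
        centroids = {l: c for l, c in zip(labels, cents)}
    out = mask.copy()
    best_d = np.full(mask.shape, np.inf)
    rr, cc = np.indices(mask.shape)
    for lab in labels:
        ys, xs = np.nonzero(mask == lab)
        r0 = max(int(ys.min()) - dilation_px, 0)
        r1 = min(int(ys.max()) + dilation_px + 1, mask.shape[0])
        c0 = max(int(xs.min()) - dilation_px, 0)
        c1 = min(int(xs.max()) + dilation_px + 1, mask.shape[1])
        sub = mask[r0:r1, c0:c1] == lab
        dist = ndimage.distance_transform_edt(~sub)
        cy, cx = centroids[lab]
        cd = np.hypot(rr[r0:r1, c0:c1] - cy, cc[r0:r1, c0:c1] - cx)
        take = (
            (dist > 0)
            & (dist <= dilation_px)
            & (mask[r0:r1, c0:c1] == 0)      # only background pixels grow
            & (cd < best_d[r0:r1, c0:c1])    # contested -> nearer centroid
        )
        out[r0:r1, c0:c1][take] = lab
        best_d[r0:r1, c0:c1][take] = cd[take]
    return out


def assign_spots(
    spots: pd.DataFrame,
    mask: np.ndarray,
    dilation_px: int = 10,
    pixel_size_um: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign decoded spots to cells via a dilated segmentation mask.

    Nuclear labels are dilated by ``dilation_px`` to stand in for cytoplasm;
    each spot maps to the label under its pixel (``floor(coord_um /
    pixel_size_um)``, origin at the image top-left).  Spots over background
    after dilation get cell id 0 and are excluded from the returned
    gene-by-cell count matrix; UNASSIGNED decodes are likewise excluded.

    Returns the spot table with a ``cell_id`` column and a counts DataFrame
    (rows = decoded names incl. blanks, columns = cell ids).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    dilated = dilate_labels(mask, dilation_px)
    col = np.floor(spots["x_um"].to_numpy() / pixel_size_um).astype(int)
    row = np.floor(spots["y_um"].to_numpy() / pixel_size_um).astype(int)
    h, w = dilated.shape
    if ((row < 0) | (row >= h) | (col < 0) | (col >= w)).any():
        raise ValueError("spot coordinates fall outside the mask image")
    out = spots.copy()
    out["cell_id"] = dilated[row, col]
    kept = out[(out["cell_id"] > 0)]
    if "decoded" in kept.columns:
        kept = kept[kept["decoded"] != UNASSIGNED]
        counts = (
            kept.groupby(["decoded", "cell_id"]).size().unstack(fill_value=0)
        )
    else:
        counts = kept.groupby("cell_id").size().to_frame("n_spots").T
    return out, counts


def merfish_cell_qc(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    blank_names: Iterable[str] = (),
    area_quantiles: tuple[float, float] = (0.025, 0.975),
    min_genes: int = 10,
    min_reads: int = 13,
    frozen_thresholds: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cell-level MERFISH quality control.

    Blank barcode columns are dropped from the counts first.  A cell is kept
    when its nucleus area AND cell area lie strictly inside the (2.5%,
    97.5%) quantile band of each metric, it expresses at least ``min_genes``
    distinct genes, and carries at least ``min_reads`` total reads.

    ``frozen_thresholds`` ({'nucleus_area_px': (lo, hi), 'cell_area_px':
    (lo, hi)}) re-applies quantile cutoffs from a previous pass, making the
    filter idempotent; otherwise quantiles are recomputed from the input.

    Returns (filtered cells, filtered counts rows=cells, report dict).
    """
    if len(cells) < 2:
        raise ValueError("quantile QC requires at least 2 cells")
    counts = counts.drop(columns=[b for b in blank_names if b in counts.columns])
    counts = counts.loc[cells.index]

    report: dict = {"n_input": len(cells)}
    keep = pd.Series(True, index=cells.index)
    thresholds = {}
    for metric in ("nucleus_area_px", "cell_area_px"):
        if frozen_thresholds is not None:
            lo, hi = frozen_thresholds[metric]
        else:
            lo = float(cells[metric].quantile(area_quantiles[0]))
            hi = float(cells[metric].quantile(area_quantiles[1]))
        thresholds[metric] = (lo, hi)
        ok = (cells[metric] > lo) & (cells[metric] < hi)
        report[f"removed_{metric}"] = int((~ok & keep).sum())
        keep &= ok
    n_genes = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    ok = n_genes >= min_genes
    report["removed_min_genes"] = int((~ok & keep).sum())
    keep &= ok
    ok = total >= min_reads
    report["removed_min_reads"] = int((~ok & keep).sum())
    keep &= ok
    report["n_kept"] = int(keep.sum())
    report["thresholds"] = thresholds
    return cells[keep], counts[keep], report


def panel_bulk_correlation(
    merfish_totals: Mapping[str, float] | pd.Series,
    bulk_fpkm: Mapping[str, float] | pd.Series,
    log_transform: bool = False,
) -> float:
    """Pearson correlation of per-gene MERFISH totals vs bulk FPKM over the
    shared panel genes.  ``log_transform`` applies log1p to both sides."""
    a = pd.Series(merfish_totals, dtype=float)
    b = pd.Series(bulk_fpkm, dtype=float)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    x, y = a[shared].to_numpy(), b[shared].to_numpy()
    if log_transform:
        x, y = np.log1p(x), np.log1p(y)
    return float(_sps.pearsonr(x, y).statistic)


@dataclass
class ProbeRegion:
    """One candidate encoding-probe target region on a transcript."""

    gene: str
    sequence: str
    tm_celsius: float | None = None
    specificity_index: float = 1.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if set(self.sequence.upper()) - set("ACGT"):
            raise ValueError(f"non-ACGT characters in sequence for {self.gene}")
        self.sequence = self.sequence.upper()

    @property
    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    def melting_temp(self) -> float:
        if self.tm_celsius is not None:
            return self.tm_celsius
        from Bio.SeqUtils import MeltingTemp

        # nearest-neighbor thermodynamics at default 50 mM Na+
        return float(MeltingTemp.Tm_NN(self.sequence))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def specificity_index(
    region: "ProbeRegion", transcriptome: Mapping[str, str], k: int = 15
) -> float:
    """Fraction of a region's k-mers unique to its own gene.

    A stand-in for probe-design specificity: each of the region's 15-mers
    is looked up in the other genes' transcript sequences; the index is the
    fraction found nowhere else (1 = fully specific, 0 = non-specific).
    """
    own = _kmers(region.sequence, k)
    if not own:
        return 1.0
    others: set[str] = set()
    for gene, seq in transcriptome.items():
        if gene != region.gene:
            others |= _kmers(seq.upper(), k)
    return len(own - others) / len(own)


def filter_probe_regions(
    regions: Sequence[ProbeRegion],
    offtarget_seqs: Iterable[str] = (),
    min_regions: int = 64,
    gc_range: tuple[float, float] = (0.35, 0.75),
    tm_range: tuple[float, float] = (60.0, 80.0),
    min_specificity: float = 0.9,
    max_offtarget_homology_nt: int = 15,
    transcriptome: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Filter candidate probe target regions and call per-gene feasibility.

    A region passes when its GC fraction lies in ``gc_range``, melting
    temperature in ``tm_range`` (°C), specificity index exceeds
    ``min_specificity``, and it shares no exact substring longer than
    ``max_offtarget_homology_nt`` with any off-target sequence (rRNA/tRNA).
    A gene is feasible when at least ``min_regions`` of its regions pass.

    When a gene→transcript ``transcriptome`` is supplied, the specificity
    index is computed as the fraction of the region's 15-mers unique to its
    gene (see :func:`specificity_index`); otherwise the value carried by
    each region is used.

    Returns (per-region table with pass flags, gene→feasible map).
    """
    k = max_offtarget_homology_nt + 1
    bad_kmers: set[str] = set()
    for seq in offtarget_seqs:
        bad_kmers |= _kmers(seq.upper(), k)
    rows = []
    for r in regions:
        gc_ok = gc_range[0] <= r.gc_fraction <= gc_range[1]
        tm = r.melting_temp()
        tm_ok = tm_range[0] <= tm <= tm_range[1]
        spec = (
            specificity_index(r, transcriptome)
            if transcriptome is not None
            else r.specificity_index
        )
        spec_ok = spec > min_specificity
        homol_ok = not (bad_kmers and (_kmers(r.sequence, k) & bad_kmers))
        rows.append(
            {
                "gene": r.gene,
                "gc": r.gc_fraction,
                "tm": tm,
                "specificity": spec,
                "gc_ok": gc_ok,
                "tm_ok": tm_ok,
                "spec_ok": spec_ok,
                "homology_ok": homol_ok,
                "passes": gc_ok and tm_ok and spec_ok and homol_ok,
            }
        )
    table = pd.DataFrame(rows)
    gene_pass = {
        g: int(sub["passes"].sum()) >= min_regions
        for g, sub in table.groupby("gene")
    }
    return table, gene_pass
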