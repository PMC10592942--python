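"""TSS-centered feature windows, training tensors, and metagene profiles.

Each gene contributes a (marks x W) matrix of signal centered on its TSS;
with the default 10 kb context at 25 bp bins, W = 2*(10000 // 50) + 1 = 401.
Minus-strand genes have the bin axis reversed so "downstream of the TSS"
always points right, which makes gene-body patterns (e.g. H3K36me3)
comparable across strands.  Windows running past a chromosome end are
zero-padded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .tracks_io import (
    HISTONE_MARKS,
    BinnedTrack,
    ExpressionTable,
    GeneRecord,
    GeneSet,
)

DEFAULT_CONTEXT_BP = 10_000


class FeatureError(ValueError):
    """Raised for malformed feature requests."""


def window_width(context_bp: int = DEFAULT_CONTEXT_BP, bin_size: int = 25) -> int:
    """Number of bins in a TSS-centered window: always odd, 401 by default."""
    return 2 * (context_bp // (2 * bin_size)) + 1


@dataclass
class FeatureWindow:
    """Per-gene (marks x W) signal matrix centered at the TSS."""

    gene_id: str
    cell_type: str
    marks: Tuple[str, ...]
    values: np.ndarray  # (n_marks, W)
    scale: str
    bin_size: int = 25

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.marks):
            raise FeatureError("row count must match number of marks")
        if self.values.shape[1] % 2 != 1:
            raise FeatureError("window width W must be odd")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def center(self) -> int:
        return self.width // 2

    def mark_row(self, mark: str) -> np.ndarray:
        try:
            return self.values[self.marks.index(mark)]
        except ValueError as exc:
            raise FeatureError(f"window has no mark {mark!r}") from exc

    def copy(self) -> "FeatureWindow":
        return dataclasses.replace(self, values=self.values.copy())


@dataclass
class Dataset:
    """Stacked training tensor with aligned targets and row metadata."""

    X: np.ndarray               # (n_rows, n_marks, W)
    y: np.ndarray               # (n_rows,) log expression
    gene_ids: np.ndarray        # (n_rows,) str
    cell_types: np.ndarray      # (n_rows,) str
    chroms: np.ndarray          # (n_rows,) str
    marks: Tuple[str, ...] = HISTONE_MARKS

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for name in ("y", "gene_ids", "cell_types", "chroms"):
            if getattr(self, name).shape[0] != n:
                raise FeatureError(f"{name} misaligned with feature tensor")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise FeatureError("non-finite values in dataset")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "Dataset":
        return Dataset(self.X[mask], self.y[mask], self.gene_ids[mask],
                       self.cell_types[mask], self.chroms[mask], self.marks)

    def save(self, directory) -> None:
        """Serialize as a directory: binary tensor + TSV manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "tensor.npy", self.X)
        pd.DataFrame({
            "gene_id": self.gene_ids, "cell_type": self.cell_types,
            "chrom": self.chroms, "target": self.y,
        }).to_csv(d / "manifest.tsv", sep="\t", index=False)
        (d / "marks.json").write_text(json.dumps(list(self.marks)))

    @classmethod
    def load(cls, directory) -> "Dataset":
        d = Path(directory)
        X = np.load(d / "tensor.npy")
        m = pd.read_csv(d / "manifest.tsv", sep="\t")
        marks = tuple(json.loads((d / "marks.json").read_text()))
        return cls(X, m["target"].to_numpy(float), m["gene_id"].to_numpy(str),
                   m["cell_type"].to_numpy(str), m["chrom"].to_numpy(str), marks)


def extract_window(
    tracks: Mapping[str, BinnedTrack],
    gene: GeneRecord,
    context_bp: int = DEFAULT_CONTEXT_BP,
    marks: Sequence[str] = HISTONE_MARKS,
) -> FeatureWindow:
    """Extract the TSS-centered (marks x W) window for one gene.

    The center bin is ``tss // bin_size``; out-of-chromosome bins are
    zero-padded; minus-strand genes are mirrored.
    """
    missing = [m for m in marks if m not in tracks]
    if missing:
        raise FeatureError(f"missing track(s) for mark(s): {missing}")
    ref = tracks[marks[0]]
    bin_size = ref.bin_size
    scales = {tracks[m].scale for m in marks}
    cts = {tracks[m].cell_type for m in marks}
    if len(cts) != 1:
        raise FeatureError(f"tracks span multiple cell types: {sorted(cts)}")
    if len(scales) != 1:
        raise FeatureError(f"tracks span multiple scales: {sorted(scales)}")
    W = window_width(context_bp, bin_size)
    half = W // 2
    center = gene.tss // bin_size
    out = np.zeros((len(marks), W), dtype=np.float64)
    for r, mark in enumerate(marks):
        vec = tracks[mark].values[gene.chrom]
        lo, hi = center - half, center + half + 1
        src_lo, src_hi = max(lo, 0), min(hi, vec.size)
        if src_lo < src_hi:
            out[r, src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
    if gene.strand == "-":
        out = out[:, ::-1]
    return FeatureWindow(gene.gene_id, ref.cell_type, tuple(marks), out,
                         scale=scales.pop(), bin_size=bin_size)


def build_dataset(
    gene_set: GeneSet,
    tracks_by_cell_type: Mapping[str, Mapping[str, BinnedTrack]],
    expression: ExpressionTable,
    context_bp: int = DEFAULT_CONTEXT_BP,
    marks: Sequence[str] = HISTONE_MARKS,
) -> Dataset:
    """Assemble one row per (gene, cell type), ordered canonically.

    Rows are sorted by (gene_id, cell_type) so the emitted tensor does not
    depend on input ordering.  Every (gene, cell type) pair must have all
    requested marks and an expression value.
    """
    cell_types = sorted(tracks_by_cell_type)
    if not cell_types:
        raise FeatureError("no cell types provided")
    for ct in cell_types:
        if ct not in expression.cell_types:
            raise FeatureError(f"expression table lacks cell type {ct!r}")
    missing = [g.gene_id for g in gene_set if g.gene_id not in expression.gene_ids]
    if missing:
        raise FeatureError(f"gene(s) missing from expression table: {missing[:5]}")

    rows, ys, gids, cts_out, chroms = [], [], [], [], []
    for gene in sorted(gene_set, key=lambda g: g.gene_id):
        for ct in cell_types:
            win = extract_window(tracks_by_cell_type[ct], gene, context_bp, marks)
            rows.append(win.values)
            ys.append(expression.value(gene.gene_id, ct))
            gids.append(gene.gene_id)
            cts_out.append(ct)
            chroms.append(gene.chrom)
    return Dataset(np.stack(rows), np.array(ys), np.array(gids),
                   np.array(cts_out), np.array(chroms), tuple(marks))


def split_by_chromosome(dataset: Dataset, held_out_chroms: Sequence[str]) -> Tuple[Dataset, Dataset]:
    """Train/test split by chromosome: held-out chromosomes' genes go to test."""
    held = set(held_out_chroms)
    if not held:
        raise FeatureError("held_out_chroms must be non-empty")
    unknown = held - set(np.unique(dataset.chroms))
    if unknown:
        raise FeatureError(f"held-out chromosome(s) absent from dataset: {sorted(unknown)}")
    test_mask = np.isin(dataset.chroms, list(held))
    if not test_mask.any() or test_mask.all():
        raise FeatureError("split leaves an empty train or test set")
    return dataset.subset(~test_mask), dataset.subset(test_mask)


def metagene_profiles(
    gene_set: GeneSet,
    tracks: Mapping[str, BinnedTrack],
    expression: ExpressionTable,
    cell_type: str,
    n_quantiles: int = 4,
    context_bp: int = DEFAULT_CONTEXT_BP,
    marks: Sequence[str] = HISTONE_MARKS,
) -> Dict[str, np.ndarray]:
    """Positionwise mean signal per expression quantile (metagene plot data).

    Genes are ranked by expression in ``cell_type`` (ties broken by
    gene_id) and cut into ``n_quantiles`` equal-count groups; group 0 is
    the lowest-expression quartile.  Returns mark -> (n_quantiles, W).
    """
    if n_quantiles < 2:
        raise FeatureError("n_quantiles must be >= 2")
    if len(gene_set) < n_quantiles:
        raise FeatureError("need at least n_quantiles genes")
    gene_ids = np.array(sorted(g.gene_id for g in gene_set))
    expr = np.array([expression.value(g, cell_type) for g in gene_ids])
    order = np.lexsort((gene_ids, expr))  # expression ascending, gene_id tie-break
    groups = np.array_split(order, n_quantiles)

    windows = {
        g.gene_id: extract_window(tracks, g, context_bp, marks) for g in gene_set
    }
    W = window_width(context_bp, tracks[marks[0]].bin_size)
    out: Dict[str, np.ndarray] = {}
    for mi, mark in enumerate(marks):
        prof = np.zeros((n_quantiles, W))
        for q, idx in enumerate(groups):
            prof[q] = np.mean(
                [windows[gene_ids[i]].values[mi] for i in idx], axis=0
            )
        out[mark] = prof
    return out
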