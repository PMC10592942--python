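"""Binned genomic signal tracks, gene annotations, and expression tables.

All coordinates are 0-based half-open (BED convention); a genomic position
``pos`` falls in bin ``pos // bin_size``.  ChIP-seq tracks carry MACS2-style
-log10(p-value) signal; uncovered positions are 0 (no evidence), never
missing.  The log compression used everywhere in the package -- for both
signal tracks and TPM expression values -- is ln(1 + x).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Iterator, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Histone marks used as model features, in fixed feature order.
HISTONE_MARKS = ("H3K27ac", "H3K4me3", "H3K4me1", "H3K36me3", "H3K27me3", "H3K9me3")

#: All assays a BinnedTrack may carry (the six marks plus MNase-seq coverage).
ASSAYS = HISTONE_MARKS + ("MNase",)

#: Valid track scales.
SCALES = ("neglog10p", "transformed", "normalized", "log_input", "coverage")

DEFAULT_BIN_SIZE = 25


class TrackError(ValueError):
    """Raised for malformed tracks or track files."""


@dataclass
class BinnedTrack:
    """Dense per-chromosome signal vectors at a fixed bin size.

    Parameters
    ----------
    assay : str
        One of :data:`ASSAYS`.
    cell_type : str
        Sample label (e.g. ``"IMR-90"``).
    values : dict of str -> ndarray
        Per-chromosome vectors of non-negative finite signal.  The vector
        length must equal ``ceil(chrom_length / bin_size)``.
    scale : str
        One of :data:`SCALES`; records which pipeline stage produced the
        values.
    bin_size : int
        Bin width in base pairs (default 25).
    imputed : bool
        Whether the track came from imputation rather than experiment
        (imputed tracks use a top-k rather than FDR peak definition).
    """

    assay: str
    cell_type: str
    values: Dict[str, np.ndarray]
    scale: str = "neglog10p"
    bin_size: int = DEFAULT_BIN_SIZE
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise TrackError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.scale not in SCALES:
            raise TrackError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.bin_size <= 0:
            raise TrackError("bin_size must be positive")
        clean: Dict[str, np.ndarray] = {}
        for chrom, vec in self.values.items():
            arr = np.asarray(vec, dtype=np.float64)
            if arr.ndim != 1:
                raise TrackError(f"{chrom}: values must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise TrackError(f"{chrom}: non-finite values in track")
            if np.any(arr < 0):
                raise TrackError(f"{chrom}: negative values in track")
            clean[chrom] = arr
        self.values = clean

    @property
    def chroms(self) -> List[str]:
        return list(self.values)

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.values.values()))

    def concat(self) -> np.ndarray:
        """All bins concatenated in chromosome-insertion order."""
        return np.concatenate([self.values[c] for c in self.chroms])

    def domain(self) -> List[tuple]:
        """All (chrom, bin index) pairs of the track, in order."""
        return [(c, i) for c in self.chroms for i in range(self.values[c].size)]

    def with_values(self, values: Dict[str, np.ndarray], scale: Optional[str] = None) -> "BinnedTrack":
        return dataclasses.replace(self, values=values, scale=scale or self.scale)


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchor: id, chromosome, TSS, strand and gene end.

    ``tss`` and ``gene_end`` are 0-based; ``gene_end`` is exclusive.  For a
    + strand gene ``tss < gene_end``; for a - strand gene ``gene_end < tss``.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TrackError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise TrackError(f"{self.gene_id}: negative TSS")
        if self.strand == "+" and not self.tss < self.gene_end:
            raise TrackError(f"{self.gene_id}: + strand requires tss < gene_end")
        if self.strand == "-" and not self.gene_end < self.tss:
            raise TrackError(f"{self.gene_id}: - strand requires gene_end < tss")


class GeneSet:
    """An ordered collection of :class:`GeneRecord` with unique ids."""

    def __init__(self, genes: Sequence[GeneRecord]):
        ids = [g.gene_id for g in genes]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise TrackError(f"duplicate gene_id(s): {sorted(dup)}")
        self.genes: List[GeneRecord] = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    @property
    def chroms(self) -> List[str]:
        seen: List[str] = []
        for g in self.genes:
            if g.chrom not in seen:
                seen.append(g.chrom)
        return seen

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.chrom, g.tss, g.strand, g.gene_end) for g in self.genes],
            columns=["gene_id", "chrom", "tss", "strand", "gene_end"],
        )


@dataclass
class ExpressionTable:
    """Log-expression matrix, rows = gene_id, columns = cell_type.

    Values are ln(1 + TPM); ``log_base`` records the convention (natural
    log, a fixed constant of the package).
    """

    log_tpm: pd.DataFrame
    log_base: float = float(np.e)

    def __post_init__(self) -> None:
        if self.log_tpm.index.has_duplicates:
            raise TrackError("duplicate gene_id in expression table")
        if not np.all(np.isfinite(self.log_tpm.to_numpy())):
            raise TrackError("non-finite expression values")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.log_tpm.index)

    @property
    def cell_types(self) -> List[str]:
        return list(self.log_tpm.columns)

    def value(self, gene_id: str, cell_type: str) -> float:
        try:
            return float(self.log_tpm.at[gene_id, cell_type])
        except KeyError as exc:
            raise TrackError(f"missing expression for gene {gene_id!r} / cell type {cell_type!r}") from exc


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, length = line.split()[:2]
            sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def _n_bins(chrom_length: int, bin_size: int) -> int:
    return -(-chrom_length // bin_size)  # ceil division


def read_bedgraph(
    path,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    assay: str = "H3K27ac",
    cell_type: str = "NA",
    scale: str = "neglog10p",
    imputed: bool = False,
) -> BinnedTrack:
    """Read a bedGraph file into fixed-size bins.

    Interval values are averaged into bins weighted by the overlap length;
    uncovered positions contribute 0 to the average.  Intervals must be
    0-based half-open and non-overlapping within a chromosome.
    """
    per_chrom: Dict[str, list] = {c: [] for c in chrom_sizes}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end, value = line.split()[:4]
            start, end, value = int(start), int(end), float(value)
            if chrom not in chrom_sizes:
                raise TrackError(f"{path} line {ln}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom] or start < 0:
                raise TrackError(
                    f"{path} line {ln}: interval {chrom}:{start}-{end} outside "
                    f"chromosome of length {chrom_sizes[chrom]}"
                )
            if end <= start:
                raise TrackError(f"{path} line {ln}: empty or inverted interval")
            per_chrom[chrom].append((start, end, value))

    values: Dict[str, np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        nb = _n_bins(length, bin_size)
        acc = np.zeros(nb, dtype=np.float64)
        ivs = sorted(per_chrom[chrom])
        for i in range(1, len(ivs)):
            if ivs[i][0] < ivs[i - 1][1]:
                a, b = ivs[i - 1], ivs[i]
                raise TrackError(
                    f"overlapping intervals on {chrom}: "
                    f"{a[0]}-{a[1]} and {b[0]}-{b[1]}"
                )
        for start, end, value in ivs:
            b0, b1 = start // bin_size, (end - 1) // bin_size
            if b0 == b1:
                acc[b0] += value * (end - start)
            else:
                acc[b0] += value * ((b0 + 1) * bin_size - start)
                acc[b1] += value * (end - b1 * bin_size)
                if b1 > b0 + 1:
                    acc[b0 + 1 : b1] += value * bin_size
        values[chrom] = acc / bin_size
    return BinnedTrack(assay=assay, cell_type=cell_type, values=values,
                       scale=scale, bin_size=bin_size, imputed=imputed)


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a track as bedGraph, merging runs of equal-valued bins.

    Zero-valued bins are omitted (uncovered = 0 on read), so write->read
    round-trips values to the printing precision (6 decimals).
    """
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vec = track.values[chrom]
            if vec.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v == 0.0:
                    continue
                fh.write(f"{chrom}\t{s * track.bin_size}\t{e * track.bin_size}\t{v:.6f}\n")


def bin_and_log(track: BinnedTrack) -> BinnedTrack:
    """Compress signal with ln(1 + x), producing a ``log_input`` track."""
    if track.scale not in ("neglog10p", "normalized", "transformed", "coverage"):
        raise TrackError(f"cannot log-compress a track on scale {track.scale!r}")
    out = {c: np.log1p(v) for c, v in track.values.items()}
    return track.with_values(out, scale="log_input")


def read_annotation(path) -> GeneSet:
    """Read a gene annotation TSV with columns gene_id, chrom, tss, strand, gene_end."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "tss", "strand", "gene_end"}
    missing = required - set(df.columns)
    if missing:
        raise TrackError(f"annotation missing columns: {sorted(missing)}")
    genes = [
        GeneRecord(r.gene_id, r.chrom, int(r.tss), r.strand, int(r.gene_end))
        for r in df.itertuples(index=False)
    ]
    return GeneSet(genes)


def write_annotation(genes: GeneSet, path) -> None:
    genes.to_frame().to_csv(path, sep="\t", index=False)


def read_expression(path) -> ExpressionTable:
    """Read a TPM table (rows genes, columns cell types) as ln(1 + TPM)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise TrackError(f"duplicate gene_id(s) in expression table: {dups}")
    if df.shape[1] == 0:
        raise TrackError("expression table has no cell type columns")
    tpm = df.to_numpy(dtype=np.float64)
    if np.any(tpm < 0) or not np.all(np.isfinite(tpm)):
        raise TrackError("TPM values must be finite and non-negative")
    return ExpressionTable(pd.DataFrame(np.log1p(tpm), index=df.index, columns=df.columns))


def write_expression_tpm(table: ExpressionTable, path) -> None:
    """Write the table back on the TPM scale (inverse of the read transform)."""
    tpm = np.expm1(table.log_tpm.to_numpy())
    pd.DataFrame(tpm, index=table.log_tpm.index, columns=table.log_tpm.columns).to_csv(
        path, sep="\t", index_label="gene_id", float_format="%.6f"
    )
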