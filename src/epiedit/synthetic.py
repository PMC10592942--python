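"""Synthetic multi-cell-type epigenome generator.

Emulates, at desk scale, the structure of the real study inputs: several
cell types sharing a gene annotation; six histone-mark tracks on a MACS2
-log10(p) scale whose promoter or gene-body signal covaries (positively
or negatively) with expression; MNase occupancy with a nucleosome-depleted
region (NDR) over the TSS of expressed genes and ~190 bp periodicity;
optional multiplicative/power batch distortions between cell types; and a
ground-truth edit response for validating the dCas9-p300 pipeline
end-to-end.

The causal story of the generator runs activity -> marks -> expression:
each (gene, cell type) draws a promoter activity a in (0, 1) (partially
shared across cell types), marks are bumps whose amplitude increases (or,
for repressive marks, decreases) with activity, and log expression is an
explicit function of the noiseless H3K27ac promoter signal (plus a
gene-body term).  Because expression is a function of the marks, the same
function evaluated on in-silico-perturbed windows yields self-consistent
"measured" fold changes for edit-response simulations.

Two generative expression functions are available: ``"linear"`` (log
expression monotone in the log promoter signal; recoverable by ridge) and
``"interaction"`` (a thresholded promoter-activity x gene-body product
that a linear model cannot fully capture).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import editing
from .features import FeatureWindow, window_width
from .tracks_io import (
    ASSAYS,
    HISTONE_MARKS,
    BinnedTrack,
    ExpressionTable,
    GeneRecord,
    GeneSet,
)

DEFAULT_EFFECT_SIZES = {
    "H3K27ac": 1.0,
    "H3K4me3": 0.9,
    "H3K4me1": 0.3,
    "H3K36me3": 0.8,   # gene-body mark
    "H3K27me3": -0.7,  # repressive
    "H3K9me3": -0.5,   # repressive
}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings.  Defaults give a small but fully structured genome."""

    n_chroms: int = 5
    chrom_length: int = 500_000           # bp, multiple of bin_size
    n_genes: int = 100
    n_cell_types: int = 13
    bin_size: int = 25
    effect_sizes: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    noise_sd: float = 0.3                 # half-normal track noise, -log10(p) scale
    amp_scale: float = 6.0                # peak amplitude at activity 1, effect 1
    promoter_sd_bp: float = 400.0         # promoter bump width
    repressive_sd_bp: float = 600.0       # TSS-proximal repressive bump width
    nucleosome_period_bp: float = 190.0
    ndr_width_bp: float = 150.0
    mnase_depth_scale: float = 5.0        # coverage units
    signal_extent_bp: int = 5_000         # max reach of one gene's planted signal
    activity_share: float = 0.7           # cross-cell-type correlation of activity
    expression_function: str = "linear"   # "linear" | "interaction"
    response_gain: float = 2.5            # log-expression per log promoter signal
    body_gain: float = 1.0                # gene-body contribution to expression
    repression_gain: float = 0.8          # log-expression lost per unit repressive latent
    baseline_log_expression: float = 0.8  # offset keeping log expression non-negative
    interaction_scale: float = 4.0
    expression_noise_sd: float = 0.05
    margin_bp: int = 10_000               # gene placement margin
    batch_params: Optional[Dict[str, Tuple[float, float]]] = None  # ct -> (c, d)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length % self.bin_size:
            raise SimulationError("chrom_length must be a multiple of bin_size")
        if self.expression_function not in ("linear", "interaction"):
            raise SimulationError(f"unknown expression_function {self.expression_function!r}")
        if self.n_cell_types < 1:
            raise SimulationError("need at least one cell type")

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def cell_type_names(self) -> List[str]:
        return [f"ct{i:02d}" for i in range(self.n_cell_types)]

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class Simulation:
    """The generator's full output bundle."""

    config: SimConfig
    annotation: GeneSet
    tracks: Dict[str, Dict[str, BinnedTrack]]  # cell type -> assay -> track
    expression: ExpressionTable
    activity: pd.DataFrame                     # promoter activity a, gene x cell type
    body_activity: pd.DataFrame                # gene-body latent u2, gene x cell type

    def log_tracks(self, cell_type: str) -> Dict[str, BinnedTrack]:
        """ln(1+x)-compressed mark tracks for model-input extraction."""
        from .tracks_io import bin_and_log
        return {m: bin_and_log(self.tracks[cell_type][m]) for m in HISTONE_MARKS}


def generate_annotation(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GeneSet:
    """Place genes round-robin over chromosomes on an even grid.

    Genes alternate strand; lengths are log-uniform in 2-50 kb (clipped to
    the chromosome); TSSs sit on bin boundaries at evenly spaced slots with
    >= ``margin_bp`` clearance of the chromosome ends so feature windows
    never overlap an end by construction at the default density.
    """
    rng = rng or np.random.default_rng(config.seed)
    if config.n_genes == 0:
        return GeneSet([])
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: List[GeneRecord] = []
    idx = 0
    for ci, chrom in enumerate(config.chrom_names):
        n = per_chrom[ci]
        if n == 0:
            continue
        usable = config.chrom_length - 2 * config.margin_bp
        slot = usable / n
        if slot < 2 * config.bin_size:
            raise SimulationError(
                f"infeasible gene density: {n} genes on a {config.chrom_length} bp "
                f"chromosome with {config.margin_bp} bp margins"
            )
        for k in range(n):
            tss = config.margin_bp + int((k + 0.5) * slot)
            tss -= tss % config.bin_size
            strand = "+" if idx % 2 == 0 else "-"
            length = int(np.exp(rng.uniform(np.log(2_000), np.log(50_000))))
            if strand == "+":
                end = min(tss + length, config.chrom_length)
            else:
                end = max(tss - length, 0)
            genes.append(GeneRecord(f"g{idx:05d}", chrom, tss, strand, end))
            idx += 1
    return GeneSet(genes)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gaussian_bump(centers_rel_bp: np.ndarray, sd_bp: float) -> np.ndarray:
    return np.exp(-(centers_rel_bp ** 2) / (2.0 * sd_bp ** 2))


def _promoter_weights(width: int, bin_size: int, sd_bp: float = 400.0) -> np.ndarray:
    off = (np.arange(width) - width // 2) * float(bin_size)
    w = _gaussian_bump(off, sd_bp)
    return w / w.sum()


def true_log_expression(
    window_values: np.ndarray,
    marks: Sequence[str],
    config: SimConfig,
    body_latent: float = 0.0,
) -> float:
    """The generative expression function evaluated on a (marks x W) window.

    Linear mode: response_gain * ln(1 + promoter-weighted H3K27ac signal),
    plus body_gain * body_latent.  This is the ground truth against which
    simulated edit responses are scored.
    """
    W = window_values.shape[1]
    bin_size = config.bin_size
    w = _promoter_weights(W, bin_size, config.promoter_sd_bp)
    k27 = window_values[list(marks).index("H3K27ac")]
    prom = float(np.dot(w, k27))
    return config.response_gain * float(np.log1p(prom)) + config.body_gain * body_latent


def simulate_cell_type(
    config: SimConfig,
    annotation: GeneSet,
    cell_index: int,
    shared_activity: Optional[np.ndarray] = None,
    shared_body: Optional[np.ndarray] = None,
) -> Tuple[Dict[str, BinnedTrack], pd.Series, pd.Series, pd.Series]:
    """Tracks for the 6 marks + MNase plus the expression column of one cell type.

    Returns (tracks, log_expression, activity, body_activity).  Activity is
    a mixture of the shared (cross-cell-type) latent and a cell-specific
    draw, weighted by ``config.activity_share``.
    """
    rng = np.random.default_rng((config.seed, 7919, cell_index))
    n = len(annotation)
    rho = config.activity_share
    z_shared = shared_activity if shared_activity is not None else rng.standard_normal(n)
    z_own = rng.standard_normal(n)
    z = np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * z_own
    a = _sigmoid(1.2 * z)  # promoter activity in (0, 1)
    # repressive latents: anti-correlated with activity but with independent
    # variation of their own, one per repressive mark, so each (negative)
    # causal effect on expression is identifiable -- neither collinear with
    # the activating marks nor with the other repressive mark
    r1 = _sigmoid(1.2 * (-0.6 * z + 0.8 * rng.standard_normal(n)))  # H3K27me3
    r2 = _sigmoid(1.2 * (-0.6 * z + 0.8 * rng.standard_normal(n)))  # H3K9me3
    # activating co-marks track activity with their own jitter (no exact
    # collinearity with the causal H3K27ac amplitude)
    a4me3 = _sigmoid(1.2 * (0.8 * z + 0.6 * rng.standard_normal(n)))
    a4me1 = _sigmoid(1.2 * (0.8 * z + 0.6 * rng.standard_normal(n)))
    if config.expression_function == "interaction":
        u_shared = shared_body if shared_body is not None else rng.random(n)
        u_own = rng.random(n)
        u2 = rho * u_shared + (1 - rho) * u_own  # gene-body latent
    else:
        # gene-body latent: correlated with activity, with its own variation
        u2 = _sigmoid(1.2 * (0.6 * z + 0.8 * rng.standard_normal(n)))

    nb = config.chrom_length // config.bin_size
    centers = (np.arange(nb) + 0.5) * config.bin_size
    tracks: Dict[str, np.ndarray] = {}
    for assay in ASSAYS:
        sd = config.noise_sd if assay != "MNase" else 0.1
        tracks[assay] = {
            c: np.abs(rng.normal(0.0, sd, size=nb)) for c in config.chrom_names
        }
    # MNase baseline occupancy (before scaling to coverage units)
    occ = {c: np.full(nb, 0.8) for c in config.chrom_names}

    amp = config.amp_scale
    for gi, gene in enumerate(annotation):
        d = centers - (gene.tss + 0.5 * config.bin_size)  # signed bp offset of bin centers
        if gene.strand == "-":
            d = -d
        # confine each gene's planted signal to its own feature window: with
        # the default 10 kb margins and 5 kb extent, neighboring genes'
        # windows stay free of cross-contamination
        near = np.abs(d) < config.signal_extent_bp
        body_lo, body_hi = 0.0, abs(gene.gene_end - gene.tss)
        for mark, eff in config.effect_sizes.items():
            if eff == 0.0:
                continue
            if mark == "H3K27ac":
                drive, shape = a[gi], _gaussian_bump(d[near], config.promoter_sd_bp)
            elif mark == "H3K4me3":
                drive, shape = a4me3[gi], _gaussian_bump(d[near], config.promoter_sd_bp)
            elif mark == "H3K4me1":
                shape = (_gaussian_bump(d[near] - 1500, 500.0)
                         + _gaussian_bump(d[near] + 1500, 500.0))
                drive = a4me1[gi]
            elif mark == "H3K36me3":
                db = d[near]
                ramp = np.clip(db / 2_000.0, 0.0, 1.0) * (db <= body_hi)
                shape, drive = ramp, u2[gi]
            elif mark == "H3K27me3":
                drive, shape = r1[gi], _gaussian_bump(d[near], config.repressive_sd_bp)
            else:  # H3K9me3
                drive, shape = r2[gi], _gaussian_bump(d[near], config.repressive_sd_bp)
            tracks[mark][gene.chrom][near] += amp * abs(eff) * drive * shape
        # nucleosome periodicity + NDR around the TSS
        local = np.abs(d) < 2_000
        phase = 0.6 + 0.4 * np.cos(2 * np.pi * d[local] / config.nucleosome_period_bp)
        depth = 0.35 + 0.55 * a[gi]
        ndr = 1.0 - depth * _gaussian_bump(d[local], config.ndr_width_bp)
        occ[gene.chrom][local] = phase * ndr

    for c in config.chrom_names:
        tracks["MNase"][c] += config.mnase_depth_scale * occ[c]

    out: Dict[str, BinnedTrack] = {}
    ct = config.cell_type_names[cell_index]
    for assay in ASSAYS:
        scale = "coverage" if assay == "MNase" else "neglog10p"
        out[assay] = BinnedTrack(assay=assay, cell_type=ct, values=tracks[assay],
                                 scale=scale, bin_size=config.bin_size)

    # expression from the noiseless generative function
    y = np.empty(n)
    W = window_width(10_000, config.bin_size)
    w = _promoter_weights(W, config.bin_size, config.promoter_sd_bp)
    kappa = float((w * _gaussian_bump((np.arange(W) - W // 2) * config.bin_size,
                                      config.promoter_sd_bp)).sum())
    eff27 = abs(config.effect_sizes.get("H3K27ac", 1.0))
    for gi in range(n):
        prom = amp * eff27 * a[gi] * kappa  # noiseless promoter-weighted H3K27ac
        if config.expression_function == "linear":
            y[gi] = (config.baseline_log_expression
                     + config.response_gain * np.log1p(prom)
                     + config.body_gain * u2[gi]
                     - config.repression_gain * (0.6 * r1[gi] + 0.4 * r2[gi]))
        else:
            # thresholded interaction: the gene-body mark only matters once
            # promoter activity clears the threshold
            y[gi] = (config.interaction_scale * float(a[gi] > 0.5) * u2[gi]
                     + 0.3 * a[gi])
    y += rng.normal(0.0, config.expression_noise_sd, size=n)
    y = np.maximum(y, 0.0)
    ids = annotation.gene_ids
    return out, pd.Series(y, index=ids), pd.Series(a, index=ids), pd.Series(u2, index=ids)


def apply_batch_distortion(track: BinnedTrack, c: float, d: float) -> BinnedTrack:
    """Multiplicative/power batch effect y = c * x**d (ground truth recorded by caller)."""
    if c <= 0 or d <= 0:
        raise SimulationError("batch distortion parameters c, d must be positive")
    out = {ch: c * np.power(v, d) for ch, v in track.values.items()}
    return track.with_values(out)


def simulate(config: SimConfig) -> Simulation:
    """Run the full generator: annotation, all cell types, expression table.

    If ``config.batch_params`` maps cell types to (c, d) pairs, the mark
    tracks of those cell types are distorted accordingly (MNase is left
    alone); downstream normalization should undo the distortion.
    """
    rng = np.random.default_rng(config.seed)
    annotation = generate_annotation(config, rng)
    n = len(annotation)
    z_shared = rng.standard_normal(n)
    u_shared = rng.random(n)
    tracks: Dict[str, Dict[str, BinnedTrack]] = {}
    ycols, acols, ucols = {}, {}, {}
    for ci, ct in enumerate(config.cell_type_names):
        t, y, a, u2 = simulate_cell_type(config, annotation, ci, z_shared, u_shared)
        if config.batch_params and ct in config.batch_params:
            c, d = config.batch_params[ct]
            for mark in HISTONE_MARKS:
                t[mark] = apply_batch_distortion(t[mark], c, d)
        tracks[ct] = t
        ycols[ct], acols[ct], ucols[ct] = y, a, u2
    expr = ExpressionTable(pd.DataFrame(ycols))
    return Simulation(config, annotation, tracks, expr,
                      pd.DataFrame(acols), pd.DataFrame(ucols))


def simulate_edit_response(
    config: SimConfig,
    gene: GeneRecord,
    window: FeatureWindow,
    m_window: np.ndarray,
    guides: Sequence[editing.GuideRNA],
    spec: editing.EditSpec,
    body_latent: float = 0.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> List[editing.GuideRNA]:
    """Ground-truth "measured" fold changes for a set of guides on one gene.

    Applies the same deposition model as the editing module to the gene's
    endogenous pre-log window, evaluates the generative expression function
    before and after, and multiplies by lognormal noise (sd on the log
    scale).  Returns copies of the guides with ``measured_fc`` filled.
    """
    rng = np.random.default_rng((seed, 104729))
    base = true_log_expression(window.values, window.marks, config, body_latent)
    out: List[editing.GuideRNA] = []
    for guide in guides:
        j = editing.guide_window_bin(gene, guide, window.width, window.bin_size)
        pert = editing.apply_edit(window, m_window, j, spec)
        y_pert = true_log_expression(pert.values, window.marks, config, body_latent)
        fc = float(np.exp(y_pert - base)) * float(np.exp(rng.normal(0.0, noise_sd)))
        out.append(dataclasses.replace(guide, measured_fc=fc))
    return out
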