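"""The dCas9-p300 epigenome-editing model and fold-change prediction.

dCas9-p300 targeted to position j is assumed to deposit H3K27ac locally.
The deposited signal at window position i combines three factors:

* steric hindrance of dCas9 by nucleosomes at the guide site, exp(-c * m_j)
  with c = 5 by default, m the MNase-derived occupancy scaled to [0, 1];
* a Gaussian footprint exp(-(i - j)^2 / (2 sigma^2)) with sigma in base
  pairs (CUT&RUN data suggest the spread is at least ~1000 bp, the default);
* the requirement that acetylation lands on existing histones, a pointwise
  product with m_i.

The overall deposition strength is a free parameter lambda.  The perturbed
H3K27ac window is fed through a trained expression model and the predicted
fold change is exp(yhat_perturbed - yhat_endogenous).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import spearmanr

from .features import FeatureWindow
from .models import ExpressionModel, ensemble_predict
from .tracks_io import BinnedTrack, GeneRecord

DEFAULT_SIGMA_BP = 1000.0
DEFAULT_SIGMA_GRID = (250.0, 500.0, 1000.0, 2000.0)
DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(1, 4, 7))
DEFAULT_STERIC = 5.0
DEFAULT_MNASE_QUANTILE = 0.99


class EditingError(ValueError):
    pass


@dataclass(frozen=True)
class GuideRNA:
    """A gRNA target: genomic position j plus an optional measured fold change."""

    guide_id: str
    gene_id: str
    target_pos: int  # genomic bp, 0-based
    measured_fc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.measured_fc is not None and self.measured_fc <= 0:
            raise EditingError(f"{self.guide_id}: measured_fc must be positive")


@dataclass
class EditSpec:
    """Deposition-model parameters."""

    sigma_bp: float = DEFAULT_SIGMA_BP
    lam: float = 1000.0
    steric_coefficient: float = DEFAULT_STERIC
    mnase_quantile: float = DEFAULT_MNASE_QUANTILE

    def __post_init__(self) -> None:
        if self.sigma_bp <= 0:
            raise EditingError("sigma must be positive")
        if self.lam < 0:
            raise EditingError("lambda must be >= 0")


@dataclass
class EditResult:
    guide_id: str
    gene_id: str
    predicted_fc: float
    spec: EditSpec
    perturbed_window: Optional[FeatureWindow] = None
    measured_fc: Optional[float] = None


def scale_mnase(track: BinnedTrack, quantile: float = DEFAULT_MNASE_QUANTILE) -> BinnedTrack:
    """Scale MNase coverage to occupancy m in [0, 1].

    m = min(x / q, 1) where q is the given quantile of the strictly
    positive coverage values (whole track).  An all-zero track passes
    through unchanged.
    """
    if not (0.0 < quantile <= 1.0):
        raise EditingError(f"quantile must be in (0, 1], got {quantile}")
    allv = track.concat()
    pos = allv[allv > 0]
    if pos.size == 0:
        return track.with_values({c: v.copy() for c, v in track.values.items()})
    q = float(np.quantile(pos, quantile))
    out = {c: np.minimum(v / q, 1.0) for c, v in track.values.items()}
    return track.with_values(out)


def deposition_profile(
    m: np.ndarray, j_bin: int, spec: EditSpec, bin_size: int = 25
) -> np.ndarray:
    """Additive H3K27ac profile over a window for a guide at bin j.

    add_i = lambda * exp(-c * m_j) * exp(-(i-j)^2 / (2 sigma^2)) * m_i,
    with i - j measured in base pairs (bin offsets times bin_size).
    """
    m = np.asarray(m, dtype=np.float64)
    if not 0 <= j_bin < m.size:
        raise EditingError(f"guide bin {j_bin} outside window of {m.size} bins")
    offsets_bp = (np.arange(m.size) - j_bin) * float(bin_size)
    kernel = np.exp(-(offsets_bp ** 2) / (2.0 * spec.sigma_bp ** 2))
    steric = np.exp(-spec.steric_coefficient * m[j_bin])
    return spec.lam * steric * kernel * m


def apply_edit(
    window: FeatureWindow, m_window: np.ndarray, j_bin: int, spec: EditSpec
) -> FeatureWindow:
    """Add the deposition profile to the H3K27ac row of a pre-log window."""
    if window.scale not in ("normalized", "neglog10p", "transformed"):
        raise EditingError(f"edits apply on the pre-log signal scale, got {window.scale!r}")
    m_window = np.asarray(m_window, dtype=np.float64)
    if m_window.size != window.width:
        raise EditingError("MNase window misaligned with feature window")
    add = deposition_profile(m_window, j_bin, spec, window.bin_size)
    out = window.copy()
    out.values[window.marks.index("H3K27ac")] += add
    return out


def guide_window_bin(gene: GeneRecord, guide: GuideRNA, width: int, bin_size: int = 25) -> int:
    """Window bin of a genomic guide position, honoring strand orientation."""
    offset_bins = guide.target_pos // bin_size - gene.tss // bin_size
    if gene.strand == "-":
        offset_bins = -offset_bins
    j = width // 2 + offset_bins
    if not 0 <= j < width:
        raise EditingError(
            f"guide {guide.guide_id} at {guide.target_pos} falls outside the "
            f"{width}-bin window of gene {gene.gene_id}"
        )
    return j


def predict_edit_fold_change(
    models: Sequence[ExpressionModel],
    gene: GeneRecord,
    window: FeatureWindow,
    m_window: np.ndarray,
    guide: GuideRNA,
    spec: EditSpec,
    keep_window: bool = False,
) -> EditResult:
    """Predicted expression fold change for one guide.

    ``window`` is the endogenous pre-log feature window of the gene; the
    gene must have been excluded from the models' training set.  With
    lambda = 0 the perturbed window equals the endogenous one and the fold
    change is exactly 1.
    """
    for mdl in models:
        if gene.gene_id in mdl.training_genes:
            raise EditingError(
                f"gene {gene.gene_id} was in the training set of a supplied model"
            )
    j = guide_window_bin(gene, guide, window.width, window.bin_size)
    perturbed = apply_edit(window, m_window, j, spec)
    if spec.lam == 0.0:
        fc = 1.0
    else:
        base = ensemble_predict(models, np.log1p(window.values[None]))[0]
        pert = ensemble_predict(models, np.log1p(perturbed.values[None]))[0]
        fc = float(np.exp(pert - base))
    return EditResult(guide.guide_id, gene.gene_id, fc, spec,
                      perturbed_window=perturbed if keep_window else None,
                      measured_fc=guide.measured_fc)


def rank_concordance(results: Sequence[EditResult], mode: str = "inter_gene"):
    """Spearman concordance of predicted vs measured fold changes.

    ``inter_gene``: aggregate one value per gene (the maximum measured FC
    paired with the maximum predicted FC) and return one rho across genes.
    ``intra_gene``: per-gene rho across its guides (>= 3 guides required);
    returns {gene_id: rho}.
    """
    scored = [r for r in results if r.measured_fc is not None]
    if mode == "inter_gene":
        by_gene: Dict[str, List[EditResult]] = {}
        for r in scored:
            by_gene.setdefault(r.gene_id, []).append(r)
        if len(by_gene) < 3:
            raise EditingError("need at least 3 genes with measured fold changes")
        meas = [max(r.measured_fc for r in rs) for rs in by_gene.values()]
        pred = [max(r.predicted_fc for r in rs) for rs in by_gene.values()]
        rho = spearmanr(meas, pred).statistic
        if not np.isfinite(rho):
            raise EditingError("rank concordance undefined (constant fold changes)")
        return float(rho)
    if mode == "intra_gene":
        by_gene = {}
        for r in scored:
            by_gene.setdefault(r.gene_id, []).append(r)
        out: Dict[str, float] = {}
        for gid, rs in by_gene.items():
            if len(rs) < 3:
                raise EditingError(f"gene {gid} has fewer than 3 scored guides")
            rho = spearmanr([r.measured_fc for r in rs],
                            [r.predicted_fc for r in rs]).statistic
            if np.isfinite(rho):
                out[gid] = float(rho)
        return out
    raise EditingError(f"unknown mode {mode!r}")
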