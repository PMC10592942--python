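"""Cross-cell-type normalization of -log10(p) tracks against a reference.

The procedure adapts the core S3norm idea: choose one reference cell type
(default IMR-90), call peaks in both reference and target, and fit a scale
factor alpha and a power beta so that after the map x -> alpha * x**beta the
target's mean signal matches the reference's mean signal simultaneously over
*common peaks* (peak bins in both) and *common background* (bins that are
background in both).  In log space alpha shifts the target and beta rotates
it; the two moment conditions pin down the unique (alpha, beta) pair.

Peaks are the 25 bp bins with Benjamini-Hochberg-adjusted p < 0.05; for
imputed tracks, the 1000 bins with the strongest imputed signal.  Because
-log10(p) values can be < 1, values entering the fit are first transformed
to 1 + x / min(x) over each bin set (background additionally clamped at 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .tracks_io import BinnedTrack

Bin = Tuple[str, int]

DEFAULT_REFERENCE = "IMR-90"


class NormalizationError(ValueError):
    """Raised when peak calling or the alpha/beta fit cannot proceed."""


class FitError(NormalizationError):
    """Non-convergence of the alpha/beta fit; carries the residuals."""

    def __init__(self, message: str, residuals: Tuple[float, float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class PeakSet:
    """Bins called as peaks for one (assay, cell type) track."""

    assay: str
    cell_type: str
    bins: Set[Bin]
    kind: str  # "fdr_peaks" | "topk_imputed"


@dataclass
class NormalizationFit:
    """A fitted (alpha, beta) pair for one (assay, target cell type)."""

    assay: str
    target: str
    reference: str
    alpha: float
    beta: float
    common_peaks: Set[Bin]
    common_background: Set[Bin]
    residuals: Tuple[float, float]
    #: minimum positive value over common peaks + background of each track,
    #: used for the genome-wide transform before applying the fit
    ref_min: float = 1.0
    target_min: float = 1.0


def call_peaks_fdr(track: BinnedTrack, fdr: float = 0.05) -> PeakSet:
    """Call peak bins at Benjamini-Hochberg adjusted p < ``fdr``.

    The adjustment family is the full track domain (all chromosomes
    jointly), matching genome-wide peak calling.
    """
    if not (0.0 < fdr < 1.0):
        raise NormalizationError(f"fdr must be in (0, 1), got {fdr}")
    if track.scale != "neglog10p":
        raise NormalizationError(f"peak calling expects a neglog10p track, got {track.scale!r}")
    pvals = np.power(10.0, -track.concat())
    _, adjusted, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    domain = track.domain()
    # strict inequality: adjusted p-values *less than* the threshold
    bins = {domain[i] for i in np.flatnonzero(adjusted < fdr)}
    return PeakSet(track.assay, track.cell_type, bins, "fdr_peaks")


def call_peaks_topk(track: BinnedTrack, k: int = 1000) -> PeakSet:
    """Peaks of an imputed track: the k bins with the largest signal.

    Ties are broken by (chrom, bin index) ascending.
    """
    if not track.imputed:
        raise NormalizationError("top-k peak calling applies to imputed tracks only")
    if k > track.n_bins:
        raise NormalizationError(f"k={k} exceeds the {track.n_bins} bins of the track")
    if k < 1:
        raise NormalizationError("k must be >= 1")
    vals = track.concat()
    # stable sort on (-value, position): argsort of -value with kind="stable"
    order = np.argsort(-vals, kind="stable")[:k]
    domain = track.domain()
    return PeakSet(track.assay, track.cell_type, {domain[i] for i in order}, "topk_imputed")


def common_sets(
    peaks_ref: PeakSet, peaks_tgt: PeakSet, domain: Iterable[Bin]
) -> Tuple[Set[Bin], Set[Bin]]:
    """Common peaks (in both peak sets) and common background (in neither)."""
    domain = set(domain)
    common_peaks = peaks_ref.bins & peaks_tgt.bins
    common_background = domain - peaks_ref.bins - peaks_tgt.bins
    if not common_peaks:
        raise NormalizationError("no common peaks between reference and target; fit impossible")
    if not common_background:
        raise NormalizationError("no common background between reference and target; fit impossible")
    return common_peaks, common_background


def _min_positive(values: np.ndarray) -> float:
    pos = values[values > 0]
    if pos.size == 0:
        raise NormalizationError("all values are zero; the min-scaling transform is undefined")
    return float(pos.min())


def transform_values(values: np.ndarray, clamp: bool = False) -> np.ndarray:
    """Map a bin-set's values x to 1 + x / min(x).

    The minimum is taken over strictly positive members (division by an
    exact zero is undefined).  ``clamp=True`` applies the background rule's
    additional lower clamp at 0; for non-negative input it is inactive.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise NormalizationError("cannot transform an empty bin set")
    out = 1.0 + values / _min_positive(values)
    if clamp:
        out = np.maximum(out, 0.0)
    return out


def fit_alpha_beta(
    ref_peaks: np.ndarray,
    ref_background: np.ndarray,
    tgt_peaks: np.ndarray,
    tgt_background: np.ndarray,
    tol: float = 1e-10,
    max_residual: float = 1e-6,
    max_restarts: int = 5,
    bounds: Tuple[float, float] = (1e-3, 1e3),
) -> Tuple[float, float, Tuple[float, float]]:
    """Fit (alpha, beta) so the target's transformed means match the reference's.

    Minimizes r1^2 + r2^2 with Powell's method started at (1, 1), where

        r1 = ln mean(alpha * tgt_peaks**beta)      - ln mean(ref_peaks)
        r2 = ln mean(alpha * tgt_background**beta) - ln mean(ref_background)

    The log-space residuals keep the objective scale-free in alpha and beta.
    Returns (alpha, beta, (|r1|, |r2|)); raises :class:`FitError` if neither
    the initial fit nor up to ``max_restarts`` jittered restarts reach
    ``max_residual``.
    """
    for name, arr in (("ref_peaks", ref_peaks), ("ref_background", ref_background),
                      ("tgt_peaks", tgt_peaks), ("tgt_background", tgt_background)):
        arr = np.asarray(arr, dtype=np.float64)
        if arr.size == 0:
            raise NormalizationError(f"{name} is empty")
    lp_ref = np.log(np.mean(ref_peaks))
    lb_ref = np.log(np.mean(ref_background))
    ltp, ltb = np.log(tgt_peaks), np.log(tgt_background)

    def residuals(params: np.ndarray) -> Tuple[float, float]:
        la, beta = params  # optimize log(alpha) for symmetry
        r1 = la + logsumexp(beta * ltp) - np.log(ltp.size) - lp_ref
        r2 = la + logsumexp(beta * ltb) - np.log(ltb.size) - lb_ref
        return r1, r2

    def objective(params: np.ndarray) -> float:
        r1, r2 = residuals(params)
        return r1 * r1 + r2 * r2

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    opt_bounds = [(lo, hi), (bounds[0], bounds[1])]
    rng = np.random.default_rng(0)
    best = None
    x0 = np.array([0.0, 1.0])
    for attempt in range(max_restarts + 1):
        res = minimize(objective, x0, method="Powell", bounds=opt_bounds,
                       options={"xtol": tol, "ftol": tol, "maxiter": 10000})
        r1, r2 = residuals(res.x)
        cand = (abs(r1) + abs(r2), res.x, (abs(r1), abs(r2)))
        if best is None or cand[0] < best[0]:
            best = cand
        if max(best[2]) <= max_residual:
            break
        x0 = np.array([rng.normal(0.0, 0.5), np.exp(rng.normal(0.0, 0.3))])
    _, x, (a1, a2) = best
    if max(a1, a2) > max_residual:
        raise FitError(
            f"alpha/beta fit did not converge: residuals ({a1:.3g}, {a2:.3g}) "
            f"exceed {max_residual:g}", (a1, a2),
        )
    return float(np.exp(x[0])), float(x[1]), (float(a1), float(a2))


def apply_fit(track: BinnedTrack, fit: NormalizationFit) -> BinnedTrack:
    """Apply x -> alpha * x**beta to a genome-wide transformed track."""
    if fit.alpha <= 0 or fit.beta <= 0:
        raise NormalizationError("alpha and beta must be positive")
    if track.scale != "transformed":
        raise NormalizationError(f"apply_fit expects a transformed track, got {track.scale!r}")
    out = {c: fit.alpha * np.power(v, fit.beta) for c, v in track.values.items()}
    return track.with_values(out, scale="normalized")


def transform_track(track: BinnedTrack, min_value: float) -> BinnedTrack:
    """Genome-wide 1 + x/min transform with a precomputed minimum."""
    if min_value <= 0:
        raise NormalizationError("min_value must be positive")
    out = {c: 1.0 + v / min_value for c, v in track.values.items()}
    return track.with_values(out, scale="transformed")


def _extract(track: BinnedTrack, bins: Set[Bin]) -> np.ndarray:
    per_chrom: Dict[str, List[int]] = {}
    for chrom, idx in bins:
        per_chrom.setdefault(chrom, []).append(idx)
    parts = [track.values[c][sorted(ix)] for c, ix in sorted(per_chrom.items())]
    return np.concatenate(parts) if parts else np.array([])


def normalize_track(
    target: BinnedTrack,
    reference: BinnedTrack,
    fdr: float = 0.05,
    topk: int = 1000,
    **fit_kwargs,
) -> Tuple[BinnedTrack, NormalizationFit]:
    """Full normalization of one target track against the reference.

    Calls peaks in both tracks (FDR rule, or top-k for imputed tracks),
    forms common peaks/background, fits (alpha, beta) on the per-set
    transformed values, then applies the genome-wide transform (dividing by
    the minimum positive value over common peaks and background together)
    followed by alpha * x**beta.  Returns the normalized target track and
    the fit record.
    """
    if target.assay != reference.assay:
        raise NormalizationError("target and reference must share the assay")
    peaks_t = call_peaks_topk(target, topk) if target.imputed else call_peaks_fdr(target, fdr)
    peaks_r = call_peaks_topk(reference, topk) if reference.imputed else call_peaks_fdr(reference, fdr)
    domain = reference.domain()
    cp, cb = common_sets(peaks_r, peaks_t, domain)

    rp, rb = _extract(reference, cp), _extract(reference, cb)
    tp, tb = _extract(target, cp), _extract(target, cb)
    alpha, beta, resid = fit_alpha_beta(
        transform_values(rp), transform_values(rb, clamp=True),
        transform_values(tp), transform_values(tb, clamp=True),
        **fit_kwargs,
    )
    tgt_min = _min_positive(np.concatenate([tp, tb]))
    ref_min = _min_positive(np.concatenate([rp, rb]))
    fit = NormalizationFit(
        assay=target.assay, target=target.cell_type, reference=reference.cell_type,
        alpha=alpha, beta=beta, common_peaks=cp, common_background=cb,
        residuals=resid, ref_min=ref_min, target_min=tgt_min,
    )
    normalized = apply_fit(transform_track(target, tgt_min), fit)
    return normalized, fit


def reference_transformed(reference: BinnedTrack, fit: NormalizationFit) -> BinnedTrack:
    """The reference track on the same transformed footing as normalized targets."""
    return reference_passthrough(reference, fit.ref_min)


def reference_passthrough(reference: BinnedTrack, ref_min: float) -> BinnedTrack:
    track = transform_track(reference, ref_min)
    return track.with_values(track.values, scale="normalized")
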