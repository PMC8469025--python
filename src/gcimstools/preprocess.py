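"""Signal pre-processing for GC-IMS sample matrices.

The pipeline runs six steps, drift axis first, then retention axis:

1. Savitzky–Golay smoothing of each drift spectrum;
2. asymmetric least-squares (Psalsa) baseline removal per spectrum;
3. multiplicative drift-time alignment of the reactant-ion peak (RIP)
   against a reference sample;
4. Savitzky–Golay smoothing of each retention chromatogram;
5. Psalsa baseline removal per chromatogram;
6. retention-time alignment of the total ion chromatogram (TIC) by
   correlation-optimized warping (COW), with the warp then applied to every
   drift column of the matrix.

Psalsa is an asymmetric Whittaker smoother: it minimizes
``sum w_i (y_i - z_i)^2 + lambda * sum (d2 z)^2`` with weights that
exponentially discount points far above the current baseline estimate, so
tall peaks barely attract the baseline.  COW stretches or shrinks
fixed-length signal segments within a slack budget, choosing the segment
boundary placement that maximizes the summed per-segment Pearson
correlation with the reference; the optimum is found by dynamic
programming over boundary offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .io import Dataset, SampleMatrix

__all__ = [
    "SGParams", "PsalsaParams", "WarpFunction", "PreprocessParams",
    "sg_smooth", "select_sg_params", "psalsa_baseline",
    "correct_baseline_matrix", "detect_rip_position",
    "align_drift_multiplicative", "compute_tic", "cow_align",
    "optimize_cow_params", "apply_warp_to_matrix", "preprocess_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SGParams:
    """Savitzky–Golay filter: window length ``n`` (odd), degree ``d < n``."""
    n: int = 19
    d: int = 2

    def __post_init__(self):
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError(f"filter length n={self.n} must be odd and >= 3")
        if self.d >= self.n:
            raise ValueError(f"polynomial degree d={self.d} must be < n={self.n}")


@dataclass(frozen=True)
class PsalsaParams:
    """Psalsa baseline parameters.

    ``lam`` penalizes baseline curvature, ``p`` is the asymmetry weight for
    points above the baseline, and ``k`` (intensity units) sets how quickly
    tall peaks are discounted.  All three are scale dependent and should be
    chosen for the data's intensity units.
    """
    lam: float = 1e-4
    p: float = 5e-3
    k: float = 200.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.k <= 0:
            raise ValueError("k must be > 0")


def sg_smooth(signal, params: SGParams) -> np.ndarray:
    """Savitzky–Golay smoothing of a 1D signal (edges by polynomial fit)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < params.n:
        raise ValueError(
            f"signal length {signal.size} shorter than filter length {params.n}"
        )
    return savgol_filter(signal, params.n, params.d, mode="interp")


def select_sg_params(reference_signal, candidate_grid,
                     max_apex_loss: float = 0.01) -> SGParams:
    """Pick the strongest smoother that keeps the apex within tolerance.

    Among candidates whose smoothed global maximum stays at or above
    ``(1 - max_apex_loss)`` of the original maximum, returns the one with
    the largest window, ties broken by the lowest degree.
    """
    reference_signal = np.asarray(reference_signal, dtype=float)
    apex = reference_signal.max()
    best, best_loss = None, np.inf
    for cand in candidate_grid:
        if reference_signal.size < cand.n:
            continue
        loss = 1.0 - sg_smooth(reference_signal, cand).max() / apex
        best_loss = min(best_loss, loss)
        if loss <= max_apex_loss:
            if best is None or (cand.n, -cand.d) > (best.n, -best.d):
                best = cand
    if best is None:
        raise ValueError(
            f"no smoother in the grid keeps apex loss <= {max_apex_loss:.3g}; "
            f"best achievable loss {best_loss:.3g}"
        )
    return best


@lru_cache(maxsize=32)
def _d2_penalty_bands(n: int) -> np.ndarray:
    """Upper-banded form of D2'D2 (second-difference penalty) for length n."""
    ab = np.zeros((3, n))
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    if n == 3:
        main[1] = 4.0
    else:
        main[[1, -2]] = 5.0
    sup1 = np.full(n, -4.0)
    sup1[1] = sup1[-1] = -2.0
    sup2 = np.ones(n)
    ab[0, 2:] = sup2[2:]
    ab[1, 1:] = sup1[1:]
    ab[2] = main
    return ab


def psalsa_baseline(signal, params: PsalsaParams | None = None,
                    max_iter: int = 50, tol: float = 1e-6) -> np.ndarray:
    """Estimate a baseline with the peaked-signal asymmetric least squares
    (Psalsa) Whittaker smoother.

    Weights are ``p * exp(-(y - z)/k)`` where the signal exceeds the current
    baseline and ``1 - p`` elsewhere; iteration stops when the baseline moves
    less than ``tol`` times the signal range.
    """
    params = params or PsalsaParams()
    y = np.asarray(signal, dtype=float)
    n = y.size
    if n < 3:
        return y.copy()
    pen = params.lam * _d2_penalty_bands(n)
    yrange = float(y.max() - y.min())
    thresh = tol * yrange if yrange > 0 else 1e-300
    w = np.ones(n)
    z = y.copy()
    for it in range(max_iter):
        ab = pen.copy()
        ab[2] += w
        z_new = solveh_banded(ab, w * y)
        delta = np.abs(z_new - z).max() if it > 0 else np.inf
        z = z_new
        r = y - z
        w = np.where(r > 0, params.p * np.exp(-r / params.k), 1.0 - params.p)
        if delta < thresh:
            break
    else:
        logger.warning("psalsa did not converge in %d iterations "
                       "(last step %.3g)", max_iter, delta)
    return z


def correct_baseline_matrix(m: SampleMatrix, params: PsalsaParams | None = None,
                            axis: str = "drift", max_iter: int = 50,
                            tol: float = 1e-6) -> SampleMatrix:
    """Subtract a Psalsa baseline from every 1D slice along ``axis``.

    ``axis="drift"`` corrects each spectrum (row), ``axis="retention"``
    corrects each chromatogram (column).  Sign is preserved: corrected
    traces may go negative (the RIP chromatogram typically does after
    retention-axis correction).
    """
    if axis not in ("drift", "retention"):
        raise ValueError(f"axis must be 'drift' or 'retention', got {axis!r}")
    grid = m.intensities
    out = np.empty_like(grid)
    n_slices = grid.shape[0] if axis == "drift" else grid.shape[1]
    for i in range(n_slices):
        sl = grid[i] if axis == "drift" else grid[:, i]
        try:
            base = psalsa_baseline(sl, params, max_iter=max_iter, tol=tol)
        except Exception as exc:  # annotate which slice broke
            raise RuntimeError(f"baseline failed on {axis} slice {i}") from exc
        if axis == "drift":
            out[i] = sl - base
        else:
            out[:, i] = sl - base
    return m.with_intensities(out)


def detect_rip_position(m: SampleMatrix, retention_window: tuple[float, float],
                        refine: bool = True) -> float:
    """Mean drift position (ms) of the per-spectrum global maximum within a
    quiet retention window (one where no compound elutes, so the maximum is
    the RIP).  With ``refine`` the apex is interpolated to sub-sample
    precision by a three-point parabola.
    """
    lo, hi = retention_window
    mask = (m.retention_axis >= lo) & (m.retention_axis <= hi)
    if not mask.any():
        raise ValueError(
            f"retention window [{lo}, {hi}] selects no spectra "
            f"(axis spans {m.retention_axis[0]}..{m.retention_axis[-1]})"
        )
    rows = m.intensities[mask]
    period = float(np.mean(np.diff(m.drift_axis)))
    positions = []
    for row in rows:
        j = int(np.argmax(row))
        pos = m.drift_axis[j]
        if refine and 0 < j < row.size - 1:
            denom = row[j - 1] - 2 * row[j] + row[j + 1]
            if denom < 0:
                delta = 0.5 * (row[j - 1] - row[j + 1]) / denom
                pos += np.clip(delta, -0.5, 0.5) * period
        positions.append(pos)
    return float(np.mean(positions))


def align_drift_multiplicative(m: SampleMatrix, reference_rip: float,
                               own_rip: float) -> SampleMatrix:
    """Scale the drift axis so the sample's RIP lands on the reference RIP,
    then re-interpolate every spectrum onto the original drift grid."""
    if own_rip <= 0:
        raise ValueError("own_rip must be > 0")
    query = m.drift_axis * (own_rip / reference_rip)
    out = np.stack([np.interp(query, m.drift_axis, row)
                    for row in m.intensities])
    return m.with_intensities(out, drift_scale_applied=reference_rip / own_rip)


def compute_tic(m: SampleMatrix) -> np.ndarray:
    """Total ion chromatogram: sum over the drift axis per retention point."""
    return m.intensities.sum(axis=1)


@dataclass
class WarpFunction:
    """Piecewise-linear monotone map between reference and sample retention
    indices, defined by matched segment boundaries."""

    ref_boundaries: np.ndarray
    sample_boundaries: np.ndarray
    n: int
    total_correlation: float = np.nan

    def __post_init__(self):
        self.ref_boundaries = np.asarray(self.ref_boundaries, dtype=float)
        self.sample_boundaries = np.asarray(self.sample_boundaries, dtype=float)
        if np.any(np.diff(self.sample_boundaries) < 0):
            raise ValueError("warp boundaries must be monotone non-decreasing")

    @classmethod
    def identity(cls, n: int) -> "WarpFunction":
        return cls(np.array([0.0, n - 1.0]), np.array([0.0, n - 1.0]), n)

    def __call__(self, ref_positions) -> np.ndarray:
        """Sample index supplying the value for each reference index."""
        return np.interp(ref_positions, self.ref_boundaries,
                         self.sample_boundaries)

    def warp_signal(self, signal) -> np.ndarray:
        signal = np.asarray(signal, dtype=float)
        if signal.size != self.n:
            raise ValueError(f"signal length {signal.size} != warp length {self.n}")
        return np.interp(self(np.arange(self.n)), np.arange(self.n), signal)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(a @ b / (na * nb))


def _segment_benefit(sample: np.ndarray, b0: float, b1: float,
                     ref_lo: int, ref_hi: int, ref: np.ndarray,
                     overlap: int = 0) -> float:
    """Correlation of the linearly resampled sample segment with the
    reference segment (inclusive endpoints).

    With ``overlap`` both windows are extended by a margin on each side
    (the sample margin scaled by the segment's stretch factor), so a peak
    sitting exactly on a boundary still informs the placement of that
    boundary.
    """
    n = ref.size
    lo, hi = ref_lo, ref_hi
    if overlap > 0:
        stretch = (b1 - b0) / max(ref_hi - ref_lo, 1)
        lo = max(0, ref_lo - overlap)
        hi = min(n - 1, ref_hi + overlap)
        b0 = b0 - (ref_lo - lo) * stretch
        b1 = b1 + (hi - ref_hi) * stretch
    pos = np.linspace(b0, b1, hi - lo + 1)
    resampled = np.interp(np.clip(pos, 0, n - 1), np.arange(sample.size),
                          sample)
    return _pearson(resampled, ref[lo:hi + 1])


def cow_align(sample_tic, reference_tic, segment_length: int = 25,
              slack: int = 10, segment_weights: str = "sd",
              segment_overlap: int = 0) -> WarpFunction:
    """Correlation-optimized warping of a sample TIC onto a reference TIC.

    The reference is divided into ``floor(N / segment_length)`` segments;
    each internal sample boundary may shift by up to ``slack`` points
    (segment lengths stay within ``segment_length ± slack``).  The dynamic
    program maximizes the summed per-segment Pearson correlation and is
    exact: it matches exhaustive enumeration of boundary placements.

    With ``segment_weights="sd"`` (default) each segment's correlation is
    weighted by the reference segment's standard deviation, so segments
    that actually contain chromatographic features steer the warp;
    correlation is scale-free, and on sparse chromatograms near-flat
    segments would otherwise chase residual structure at the expense of
    their peaked neighbors.  ``"uniform"`` gives the plain equal-weight
    objective.
    """
    sample = np.asarray(sample_tic, dtype=float)
    ref = np.asarray(reference_tic, dtype=float)
    if sample.size != ref.size:
        raise ValueError("sample and reference must have equal length")
    if not 1 <= slack < segment_length:
        raise ValueError(
            f"need segment_length > slack >= 1, got I={segment_length}, t={slack}"
        )
    if segment_weights not in ("sd", "uniform"):
        raise ValueError("segment_weights must be 'sd' or 'uniform'")
    n = ref.size
    n_seg = max(1, n // segment_length)
    ref_b = np.round(np.linspace(0, n - 1, n_seg + 1)).astype(int)
    offsets = np.arange(-slack, slack + 1)

    def positions(j: int) -> np.ndarray:
        if j == 0 or j == n_seg:
            return np.array([ref_b[j]])
        return np.clip(ref_b[j] + offsets, 1, n - 2)

    # DP forward pass over boundary offsets
    prev_pos = positions(0)
    score = {int(prev_pos[0]): 0.0}
    back: list[dict[int, int]] = []
    for j in range(1, n_seg + 1):
        ref_lo, ref_hi = int(ref_b[j - 1]), int(ref_b[j])
        ref_len = ref_hi - ref_lo
        weight = (float(ref[ref_lo:ref_hi + 1].std())
                  if segment_weights == "sd" else 1.0)
        cur: dict[int, float] = {}
        choice: dict[int, int] = {}
        for b1 in np.unique(positions(j)):
            best, arg = -np.inf, None
            for b0, s0 in score.items():
                seg_len = b1 - b0
                if seg_len < max(2, ref_len - slack) or seg_len > ref_len + slack:
                    continue
                val = s0 + weight * _segment_benefit(
                    sample, b0, int(b1), ref_lo, ref_hi, ref,
                    overlap=segment_overlap)
                if val > best:
                    best, arg = val, b0
            if arg is not None:
                cur[int(b1)] = best
                choice[int(b1)] = arg
        if not cur:
            raise RuntimeError("COW dynamic program has no feasible path")
        score = cur
        back.append(choice)

    # backtrack
    b = max(score, key=lambda kk: score[kk])
    total = score[b]
    bounds = [b]
    for choice in reversed(back):
        b = choice[b]
        bounds.append(b)
    bounds.reverse()
    return WarpFunction(ref_b.astype(float), np.array(bounds, dtype=float),
                        n, total_correlation=total)


def optimize_cow_params(tics, reference_tic, grid) -> tuple[int, int]:
    """Pick the (segment length, slack) pair maximizing the mean Pearson
    correlation of warped TICs to the reference.  Ties favor the smaller
    segment, then the smaller slack."""
    grid = sorted(set((int(i), int(t)) for i, t in grid))
    if not grid:
        raise ValueError("empty parameter grid")
    ref = np.asarray(reference_tic, dtype=float)
    best, best_score = None, -np.inf
    for seg, slk in grid:
        corrs = []
        for tic in tics:
            w = cow_align(tic, ref, segment_length=seg, slack=slk)
            corrs.append(_pearson(w.warp_signal(tic), ref))
        mean_corr = float(np.mean(corrs))
        if mean_corr > best_score + 1e-12:
            best, best_score = (seg, slk), mean_corr
    return best


def apply_warp_to_matrix(m: SampleMatrix, w: WarpFunction) -> SampleMatrix:
    """Re-interpolate every drift column along retention by the same warp."""
    nr = m.intensities.shape[0]
    if w.n != nr:
        raise ValueError(f"warp built for length {w.n}, matrix has {nr} rows")
    pos = np.clip(w(np.arange(nr)), 0, nr - 1)
    i0 = np.minimum(pos.astype(int), nr - 2)
    frac = (pos - i0)[:, None]
    grid = m.intensities
    out = grid[i0] * (1 - frac) + grid[i0 + 1] * frac
    return m.with_intensities(out)


@dataclass
class PreprocessParams:
    """Everything the six-step pipeline needs.

    The Savitzky–Golay defaults (drift 19/2, retention 27/2), the Psalsa
    defaults, the RIP reference window and the COW defaults follow standard
    GC-IMS practice for instrument-scale intensity units; Psalsa parameters
    should be re-chosen when intensity units differ.
    """

    sg_drift: SGParams = field(default_factory=lambda: SGParams(19, 2))
    sg_retention: SGParams = field(default_factory=lambda: SGParams(27, 2))
    psalsa_drift: PsalsaParams = field(default_factory=PsalsaParams)
    psalsa_retention: PsalsaParams = field(default_factory=PsalsaParams)
    psalsa_max_iter: int = 50
    psalsa_tol: float = 1e-6
    rip_retention_window: tuple[float, float] = (180.0, 200.0)
    cow_segment: int = 25
    cow_slack: int = 10
    cow_overlap: int = 0
    optimize_cow: bool = False
    cow_grid: tuple = ((25, 5), (25, 10), (50, 10), (50, 20))
    # drift window (ms) the alignment TIC is summed over; None = full axis.
    # Excluding the RIP region is useful when RIP depletion mirrors the
    # analyte signal so closely that the full-axis sum self-cancels.
    tic_drift_window: tuple[float, float] | None = None
    # extra smoothing of the alignment TIC itself (never of the matrix);
    # raises the effective SNR of the correlation objective
    cow_tic_smooth: SGParams | None = None


def preprocess_dataset(ds: Dataset, params: PreprocessParams | None = None
                       ) -> tuple[Dataset, dict]:
    """Run the full six-step pipeline on a dataset.

    The reference sample (``ds.reference_index``) anchors both alignments.
    Returns the processed dataset and a log of the decisions taken (RIP
    positions, applied drift scales, COW parameters, per-sample TIC
    correlation to the reference before and after warping).
    """
    params = params or PreprocessParams()
    ds.assert_uniform_shape()
    log: dict = {"steps": []}

    # (i) smoothing along drift, (ii) baseline per spectrum
    samples = []
    for s in ds.samples:
        sm = s.with_intensities(
            savgol_filter(s.intensities, params.sg_drift.n, params.sg_drift.d,
                          axis=1, mode="interp"))
        sm = correct_baseline_matrix(sm, params.psalsa_drift, axis="drift",
                                     max_iter=params.psalsa_max_iter,
                                     tol=params.psalsa_tol)
        samples.append(sm)
    log["steps"] += ["sg_drift", "psalsa_drift"]

    # (iii) multiplicative drift alignment on the RIP position
    ref_rip = detect_rip_position(samples[ds.reference_index],
                                  params.rip_retention_window)
    log["reference_rip_ms"] = ref_rip
    rip_positions, scales = [], []
    aligned = []
    for i, s in enumerate(samples):
        own = detect_rip_position(s, params.rip_retention_window)
        rip_positions.append(own)
        scales.append(ref_rip / own)
        aligned.append(align_drift_multiplicative(s, ref_rip, own)
                       if i != ds.reference_index else s)
    samples = aligned
    log["rip_positions_ms"] = rip_positions
    log["drift_scales_applied"] = scales
    log["steps"].append("align_drift")

    # (iv) smoothing along retention, (v) baseline per chromatogram
    out = []
    for s in samples:
        sm = s.with_intensities(
            savgol_filter(s.intensities, params.sg_retention.n,
                          params.sg_retention.d, axis=0, mode="interp"))
        sm = correct_baseline_matrix(sm, params.psalsa_retention,
                                     axis="retention",
                                     max_iter=params.psalsa_max_iter,
                                     tol=params.psalsa_tol)
        out.append(sm)
    samples = out
    log["steps"] += ["sg_retention", "psalsa_retention"]

    # (vi) COW retention alignment on the TIC
    if params.tic_drift_window is not None:
        lo, hi = params.tic_drift_window
        cols = (samples[0].drift_axis >= lo) & (samples[0].drift_axis <= hi)
        if not cols.any():
            raise ValueError("tic_drift_window selects no drift columns")
        tics = [s.intensities[:, cols].sum(axis=1) for s in samples]
    else:
        tics = [compute_tic(s) for s in samples]
    if params.cow_tic_smooth is not None:
        tics = [sg_smooth(t, params.cow_tic_smooth) for t in tics]
    ref_tic = tics[ds.reference_index]
    seg, slk = params.cow_segment, params.cow_slack
    if params.optimize_cow:
        others = [t for i, t in enumerate(tics) if i != ds.reference_index]
        seg, slk = optimize_cow_params(others, ref_tic, params.cow_grid)
    log["cow_segment"], log["cow_slack"] = seg, slk
    corr_before, corr_after = [], []
    final = []
    for i, s in enumerate(samples):
        if i == ds.reference_index:
            final.append(s)
            continue
        corr_before.append(_pearson(tics[i], ref_tic))
        w = cow_align(tics[i], ref_tic, segment_length=seg, slack=slk,
                      segment_overlap=params.cow_overlap)
        corr_after.append(_pearson(w.warp_signal(tics[i]), ref_tic))
        final.append(apply_warp_to_matrix(s, w))
    log["tic_correlation_before"] = corr_before
    log["tic_correlation_after"] = corr_after
    log["steps"].append("cow_retention")

    processed = Dataset(samples=final, labels=ds.labels.copy(),
                        reference_index=ds.reference_index)
    return processed, log
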