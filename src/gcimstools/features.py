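"""Feature extraction from pre-processed GC-IMS sample matrices.

Four strategies, ordered by how much of the raw measurement they keep:

1. ``ric_area`` — the trapezoidal area under the reactant-ion chromatogram
   (RIC), a single scalar per sample measuring total volatile content as
   sensed through RIP depletion;
2. ``ric`` — the full RIC trace, one feature per retention point;
3. ``full_matrix`` — the unfolded (row-major) pre-processed sample matrix;
4. ``peak_table`` — 2D peak detection, intensity filtering, within-sample
   clustering, across-sample matching, and apex-intensity readout into a
   samples x clusters table.

The RIC is defined from the RIP trace as ``RIC(tr) = max(RIP) - RIP(tr)``:
wherever analytes elute they capture charge from the reagent ions, so the
depletion of the RIP mirrors the eluting analyte load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import Dataset, SampleMatrix

__all__ = [
    "Peak", "PeakCluster", "PeakTable", "FeatureMatrix", "PeakPickingParams",
    "extract_rip_trace", "ric_from_rip", "ric_area", "unfold_matrix",
    "refold_vector", "detect_peaks_2d", "filter_peaks_by_intensity",
    "cluster_peaks", "match_peaks_across_samples", "build_peak_table",
    "extract_features",
]

METHODS = ("ric_area", "ric", "full_matrix", "peak_table")


@dataclass(frozen=True)
class Peak:
    """A local maximum: grid indices plus its intensity."""
    tr_index: int
    td_index: int
    intensity: float


@dataclass
class PeakCluster:
    """A group of nearby peaks with a representative member.

    The representative is the geometric median restricted to member points
    (the medoid under summed Euclidean distance), so it is always a real
    detected position.
    """
    members: list
    rep_tr: int
    rep_td: int
    cluster_id: int = -1
    sample_members: dict = field(default_factory=dict)  # sample idx -> [Peak]


@dataclass
class PeakTable:
    """Samples x matched-ion-clusters intensity table."""
    values: np.ndarray          # (n_samples, n_clusters)
    tr_indices: np.ndarray      # per-cluster representative row
    td_indices: np.ndarray      # per-cluster representative column
    tr_seconds: np.ndarray
    td_ms: np.ndarray
    detected: np.ndarray        # bool (n_samples, n_clusters); False = fallback
    cluster_ids: np.ndarray

    @property
    def fallback_fraction(self) -> float:
        return float(1.0 - self.detected.mean())

    def to_frame(self) -> pd.DataFrame:
        cols = [f"c{cid}" for cid in self.cluster_ids]
        return pd.DataFrame(self.values, columns=cols)

    def to_csv(self, path, flags_path=None) -> None:
        header = pd.DataFrame({
            "cluster_id": self.cluster_ids,
            "tr_index": self.tr_indices,
            "td_index": self.td_indices,
            "tr_seconds": self.tr_seconds,
            "td_ms": self.td_ms,
        })
        with open(path, "w", encoding="utf-8") as fh:
            header.T.to_csv(fh, header=False)
            self.to_frame().to_csv(fh, index_label="sample")
        if flags_path is not None:
            pd.DataFrame(self.detected.astype(int),
                         columns=[f"c{c}" for c in self.cluster_ids]
                         ).to_csv(flags_path, index_label="sample")


@dataclass
class FeatureMatrix:
    """Samples x features block plus feature metadata."""
    values: np.ndarray
    kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values).to_csv(path, index_label="sample")


@dataclass
class PeakPickingParams:
    """Knobs of the peak-table pipeline.

    Clustering caps (12-point linkage distance with 6/15 axis caps) and the
    5/10 assignment window are expressed in grid indices; ``noise_floor``
    is in intensity units (``None`` means five robust SDs of the matrix).
    ``exclude_drift_below_ms`` masks the RIP ridge out of peak picking.
    """
    min_separation: tuple[int, int] = (3, 5)
    noise_floor: float | None = None
    median_prefilter: bool = True
    max_dist: float = 12.0
    axis_caps: tuple[int, int] = (6, 15)
    assign_window: tuple[int, int] = (5, 10)
    exclude_drift_below_ms: float | None = None
    mode: str = "per_sample"          # or "average"


def extract_rip_trace(m: SampleMatrix, rip_window: tuple[float, float]
                      ) -> np.ndarray:
    """RIP intensity along retention: per-retention-point maximum within a
    drift window (ms) that contains the RIP."""
    lo, hi = rip_window
    mask = (m.drift_axis >= lo) & (m.drift_axis <= hi)
    if not mask.any():
        raise ValueError(f"drift window [{lo}, {hi}] selects no columns")
    return m.intensities[:, mask].max(axis=1)


def ric_from_rip(rip: np.ndarray) -> np.ndarray:
    """Reactant-ion chromatogram: ``max(RIP) - RIP`` elementwise."""
    rip = np.asarray(rip, dtype=float)
    if rip.size == 0:
        raise ValueError("empty RIP trace")
    return rip.max() - rip


def ric_area(ric: np.ndarray, retention_axis: np.ndarray) -> float:
    """Area under the RIC by the trapezoidal rule (the WTVC scalar)."""
    retention_axis = np.asarray(retention_axis, dtype=float)
    if retention_axis.size > 1 and not np.all(np.diff(retention_axis) > 0):
        raise ValueError("retention axis must be strictly increasing")
    return float(np.trapezoid(np.asarray(ric, dtype=float), retention_axis))


def unfold_matrix(m: SampleMatrix) -> np.ndarray:
    """Row-major (retention-major) flattening; cell (i, j) lands at
    ``i * n_drift + j`` so VIP vectors can be refolded exactly."""
    return m.intensities.ravel(order="C")


def refold_vector(vec: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`unfold_matrix` for a matrix of the given shape."""
    return np.asarray(vec).reshape(shape, order="C")


def detect_peaks_2d(m: SampleMatrix, min_separation: tuple[int, int] = (3, 5),
                    noise_floor: float = 0.0,
                    median_prefilter: bool = True,
                    drift_mask: np.ndarray | None = None,
                    exclude_border: bool = True) -> list:
    """Find 2D peaks as the union of two detectors.

    (a) cells equal to the local maximum of a
    ``(2*dtr+1) x (2*dtd+1)`` neighborhood and above ``noise_floor``
    (a maxima-filter detector robust to noise), and (b) strict
    8-neighbor local maxima.  Detection runs on an optionally 3x3
    median-filtered copy; reported intensities come from the input matrix.
    With ``exclude_border`` maxima within the min-separation margin of the
    grid edge are dropped (their neighborhood is truncated there, so edge
    artifacts of smoothing and baseline removal masquerade as peaks).
    """
    dtr, dtd = min_separation
    work = m.intensities
    if median_prefilter:
        work = ndimage.median_filter(work, size=3, mode="nearest")

    footprint = np.ones((2 * dtr + 1, 2 * dtd + 1), dtype=bool)
    local_max = ndimage.maximum_filter(work, footprint=footprint,
                                       mode="nearest")
    mask_a = (work == local_max) & (work > noise_floor)
    # plateau dedup: keep only the first cell of any connected plateau
    if mask_a.any():
        lab, nlab = ndimage.label(mask_a)
        keep = np.zeros_like(mask_a)
        for sl_idx, sl in enumerate(ndimage.find_objects(lab), start=1):
            cells = np.argwhere(lab[sl] == sl_idx)
            i, j = cells[0]
            keep[sl[0].start + i, sl[1].start + j] = True
        mask_a = keep

    neigh = np.ones((3, 3), dtype=bool)
    neigh[1, 1] = False
    nb_max = ndimage.maximum_filter(work, footprint=neigh, mode="constant",
                                    cval=-np.inf)
    mask_b = (work > nb_max) & (work > noise_floor)

    mask = mask_a | mask_b
    if drift_mask is not None:
        mask &= drift_mask[None, :]
    if exclude_border:
        nr, nd = mask.shape
        mask[:min(dtr, nr), :] = False
        mask[max(nr - dtr, 0):, :] = False
        mask[:, :min(dtd, nd)] = False
        mask[:, max(nd - dtd, 0):] = False
    coords = np.argwhere(mask)
    return [Peak(int(i), int(j), float(m.intensities[i, j]))
            for i, j in coords]


def filter_peaks_by_intensity(peaks: list, near_equal_tol: float = 0.05) -> list:
    """Keep only the most intense peaks, by the largest-jump rule.

    Intensities are sorted ascending; the index ``i*`` of the largest first
    difference marks where peak intensities depart clearly from noise;
    peaks with ascending rank at or above ``ceil(0.8 * i*)`` are retained.
    A near-constant list (spread below ``near_equal_tol`` of its maximum)
    has no such departure point and is returned whole — this covers the
    all-equal degenerate case without being fooled by round-off-scale
    differences.
    """
    if len(peaks) < 2:
        return list(peaks)
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].intensity)
    intens = np.array([peaks[i].intensity for i in order])
    spread = intens[-1] - intens[0]
    if spread <= 0 or spread <= near_equal_tol * abs(intens[-1]):
        return list(peaks)
    i_star = int(np.argmax(np.diff(intens)))
    cut = int(np.ceil(0.8 * i_star))
    return [peaks[i] for i in order[cut:]]


def _medoid(points: np.ndarray, intensities: np.ndarray) -> int:
    """Index of the geometric-median member: minimal summed Euclidean
    distance, ties to higher intensity then lower (tr, td)."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    total = d.sum(axis=1)
    best = None
    for i in range(points.shape[0]):
        key = (total[i], -intensities[i], points[i, 0], points[i, 1])
        if best is None or key < best[0]:
            best = (key, i)
    return best[1]


def cluster_peaks(peaks: list, max_dist: float = 12.0,
                  axis_caps: tuple[int, int] = (6, 15)) -> list:
    """Single-linkage clustering of peak positions.

    Two peaks are linkable iff their Euclidean index distance is at most
    ``max_dist`` AND their per-axis offsets are within the retention/drift
    caps; connected components form the clusters.  The result is invariant
    to input order (components and the medoid tie-break are both
    order-free).
    """
    if not peaks:
        return []
    pts = np.array([[p.tr_index, p.td_index] for p in peaks], dtype=float)
    intens = np.array([p.intensity for p in peaks])
    cap_tr, cap_td = axis_caps
    dtr = np.abs(pts[:, 0, None] - pts[None, :, 0])
    dtd = np.abs(pts[:, 1, None] - pts[None, :, 1])
    adj = (np.hypot(dtr, dtd) <= max_dist) & (dtr <= cap_tr) & (dtd <= cap_td)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        mi = idx[_medoid(pts[idx], intens[idx])]
        clusters.append(PeakCluster(
            members=[peaks[i] for i in idx],
            rep_tr=int(pts[mi, 0]), rep_td=int(pts[mi, 1])))
    clusters.sort(key=lambda cl: (cl.rep_tr, cl.rep_td))
    for i, cl in enumerate(clusters):
        cl.cluster_id = i
    return clusters


def match_peaks_across_samples(per_sample_clusters: list,
                               max_dist: float = 12.0,
                               axis_caps: tuple[int, int] = (6, 15)) -> list:
    """Match ion clusters across samples.

    Pools every sample's cluster representatives, re-clusters them with the
    same caps, and records which samples contributed to each dataset-level
    cluster.  The dataset representative is again the medoid.
    """
    pooled, owner = [], []
    for s_idx, clusters in enumerate(per_sample_clusters):
        for cl in clusters:
            rep_int = max(p.intensity for p in cl.members)
            pooled.append(Peak(cl.rep_tr, cl.rep_td, rep_int))
            owner.append(s_idx)
    matched = cluster_peaks(pooled, max_dist=max_dist, axis_caps=axis_caps)
    pos_to_owner = {}
    for pk, s_idx in zip(pooled, owner):
        pos_to_owner.setdefault((pk.tr_index, pk.td_index, pk.intensity),
                                []).append(s_idx)
    for cl in matched:
        contrib: dict[int, list] = {}
        for pk in cl.members:
            for s_idx in pos_to_owner[(pk.tr_index, pk.td_index, pk.intensity)]:
                contrib.setdefault(s_idx, []).append(pk)
        cl.sample_members = contrib
    return matched


def build_peak_table(ds: Dataset, dataset_clusters: list,
                     assign_window: tuple[int, int] = (5, 10)) -> PeakTable:
    """Read apex intensities into a samples x clusters table.

    A sample that contributed a detected peak to a cluster gets the maximum
    intensity within ``±assign_window`` of the representative; a sample
    with no detected peak there falls back to its intensity at the
    representative cell (flagged).  The table therefore has no empty cells.
    """
    ds.assert_uniform_shape()
    nr, nd = ds.reference.shape
    wtr, wtd = assign_window
    n_s, n_c = len(ds), len(dataset_clusters)
    values = np.empty((n_s, n_c))
    detected = np.zeros((n_s, n_c), dtype=bool)
    tr_idx = np.array([c.rep_tr for c in dataset_clusters])
    td_idx = np.array([c.rep_td for c in dataset_clusters])
    if np.any((tr_idx < 0) | (tr_idx >= nr) | (td_idx < 0) | (td_idx >= nd)):
        raise ValueError("cluster representative outside the sample grid")
    for ci, cl in enumerate(dataset_clusters):
        r, d = cl.rep_tr, cl.rep_td
        r0, r1 = max(0, r - wtr), min(nr, r + wtr + 1)
        d0, d1 = max(0, d - wtd), min(nd, d + wtd + 1)
        for si, s in enumerate(ds.samples):
            if si in cl.sample_members:
                values[si, ci] = s.intensities[r0:r1, d0:d1].max()
                detected[si, ci] = True
            else:
                values[si, ci] = s.intensities[r, d]
    ref = ds.reference
    return PeakTable(
        values=values, tr_indices=tr_idx, td_indices=td_idx,
        tr_seconds=ref.retention_axis[tr_idx], td_ms=ref.drift_axis[td_idx],
        detected=detected,
        cluster_ids=np.array([c.cluster_id for c in dataset_clusters]),
    )


def _auto_noise_floor(grid: np.ndarray) -> float:
    """Robust default detection floor: median + 2 robust SDs.

    Deliberately permissive — a thin tail of noise maxima should survive
    detection so the downstream largest-jump intensity filter can locate
    the noise/peak departure point it keys on.
    """
    med = np.median(grid)
    mad = np.median(np.abs(grid - med))
    return float(med + 2.0 * 1.4826 * mad)


def peak_pipeline(ds: Dataset, params: PeakPickingParams | None = None
                  ) -> tuple[PeakTable, list]:
    """detect → filter → cluster → match → table, per the configured mode."""
    params = params or PeakPickingParams()
    ds.assert_uniform_shape()
    ref = ds.reference
    drift_mask = None
    if params.exclude_drift_below_ms is not None:
        drift_mask = ref.drift_axis >= params.exclude_drift_below_ms

    def detect(m: SampleMatrix) -> list:
        floor = params.noise_floor
        if floor is None:
            floor = _auto_noise_floor(m.intensities)
        pks = detect_peaks_2d(m, min_separation=params.min_separation,
                              noise_floor=floor,
                              median_prefilter=params.median_prefilter,
                              drift_mask=drift_mask)
        return filter_peaks_by_intensity(pks)

    if params.mode == "average":
        mean = ref.with_intensities(
            np.mean([s.intensities for s in ds.samples], axis=0))
        clusters = cluster_peaks(detect(mean), params.max_dist,
                                 params.axis_caps)
        for cl in clusters:
            cl.sample_members = {si: cl.members for si in range(len(ds))}
        matched = clusters
    elif params.mode == "per_sample":
        per_sample = [cluster_peaks(detect(s), params.max_dist,
                                    params.axis_caps) for s in ds.samples]
        matched = match_peaks_across_samples(per_sample, params.max_dist,
                                             params.axis_caps)
    else:
        raise ValueError(f"unknown peak picking mode {params.mode!r}")
    table = build_peak_table(ds, matched, params.assign_window)
    return table, matched


def extract_features(ds: Dataset, method: str,
                     rip_window: tuple[float, float] | None = None,
                     peak_params: PeakPickingParams | None = None
                     ) -> FeatureMatrix:
    """Dispatch to one of the four feature-extraction strategies.

    ``rip_window`` (drift ms) is required for the RIC-based methods; the
    peak-table method takes its knobs from ``peak_params``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    ds.assert_uniform_shape()
    if method in ("ric_area", "ric"):
        if rip_window is None:
            raise ValueError(f"method {method!r} needs a rip_window")
        rics = [ric_from_rip(extract_rip_trace(s, rip_window))
                for s in ds.samples]
        if method == "ric_area":
            vals = np.array([[ric_area(r, s.retention_axis)]
                             for r, s in zip(rics, ds.samples)])
            return FeatureMatrix(vals, "ric_area",
                                 {"rip_window": rip_window})
        return FeatureMatrix(np.stack(rics), "ric", {
            "rip_window": rip_window,
            "retention_axis": ds.reference.retention_axis.copy(),
        })
    if method == "full_matrix":
        vals = np.stack([unfold_matrix(s) for s in ds.samples])
        return FeatureMatrix(vals, "full_matrix",
                             {"shape": ds.reference.shape})
    table, clusters = peak_pipeline(ds, peak_params)
    return FeatureMatrix(table.values, "peak_table", {
        "peak_table": table,
        "clusters": clusters,
        "fallback_fraction": table.fallback_fraction,
    })
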