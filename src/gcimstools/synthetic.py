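"""Synthetic GC-IMS data with known ground truth.

The generator emulates the phenomenology of a drift-tube GC-IMS measurement
of a volatile-rich food sample:

* a reactant-ion peak (RIP) — a tall Gaussian ridge at a fixed drift time —
  whose amplitude is depleted wherever analytes elute, because eluting
  molecules capture charge from the hydrated-proton reagent ions;
* analyte ion peaks that are Gaussian along retention time and tailed along
  drift time (exponentially modified Gaussian), mimicking the tailing that
  drift-tube spectra show;
* a smooth baseline: exponential decay along drift plus a slow linear drift
  along retention;
* per-sample instrumental misalignment: a multiplicative drift-time scale
  (pressure/temperature drift) and a smooth, monotone, endpoint-fixed warp
  of the retention axis (flow drift);
* i.i.d. Gaussian noise.

Two sample classes share one peak catalog; a chosen subset of "marker" peaks
has its class-1 amplitude multiplied by a known effect factor.  Everything
planted is recorded in :class:`GroundTruth` so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .io import Dataset, SampleMatrix

__all__ = ["SynthConfig", "GroundTruth", "simulate_sample", "simulate_dataset"]


@dataclass
class SynthConfig:
    """Study conditions for the simulator.

    Defaults describe a two-class volatolomics study at desk scale: a
    600 x 200 grid (retention 1 s/row, drift 5–15 ms at 0.05 ms/column),
    RIP at 6.4 ms, a 30-peak catalog of which 15 are class markers with a
    2-fold effect, peak amplitudes 150–400 over noise sigma 15 (SNR 10 at
    the weakest peak), up to ±2% drift-scale jitter and an up-to-8-sample
    retention warp.
    """

    n_per_class: tuple[int, int] = (26, 27)
    n_retention: int = 600
    n_drift: int = 200
    retention_period: float = 1.0      # s per retention row
    drift_origin: float = 5.0          # ms of first drift column
    drift_period: float = 0.05         # ms per drift column

    rip_drift_ms: float = 6.4
    rip_amplitude: float = 1500.0
    rip_sigma_ms: float = 0.12
    rip_depletion_alpha: float = 4e-4  # fractional depletion per summed amplitude
    rip_depletion_floor: float = 0.2

    peak_catalog_size: int = 30
    marker_count: int = 15
    marker_effect: float = 2.0
    amplitude_range: tuple[float, float] = (150.0, 400.0)
    amplitude_jitter: float = 0.08     # per-sample lognormal-ish spread
    sigma_tr: float = 4.0              # retention peak width, samples
    sigma_td: float = 1.5              # drift peak width, samples
    drift_tail_tau: float = 2.0        # exponential drift tail, samples

    baseline_offset: float = 10.0
    baseline_drift_amp: float = 80.0       # exp decay along drift
    baseline_drift_tau_ms: float = 2.0
    baseline_retention_slope: float = 0.02  # per second

    noise_sd: float = 15.0
    drift_scale_jitter: float = 0.02
    retention_warp_amplitude: float = 8.0  # samples

    # catalog placement lattice (guarantees separations beyond the
    # peak-matching caps); unique_tr additionally forbids co-elution
    # (at most one peak per retention slot), giving fully separable TICs
    min_tr_margin: int = 40
    tr_spacing: int = 20
    td_spacing: int = 24
    unique_tr: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_per_class) <= 0:
            raise ValueError("n_per_class entries must be > 0")
        if self.marker_effect <= 0:
            raise ValueError("marker_effect must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.drift_scale_jitter < 0.1:
            raise ValueError("drift_scale_jitter must be in [0, 0.1)")
        if self.marker_count > self.peak_catalog_size:
            raise ValueError("marker_count exceeds peak_catalog_size")

    @property
    def drift_axis(self) -> np.ndarray:
        return self.drift_origin + self.drift_period * np.arange(self.n_drift)

    @property
    def retention_axis(self) -> np.ndarray:
        return self.retention_period * np.arange(self.n_retention)


@dataclass
class GroundTruth:
    """Bookkeeping of everything the simulator planted."""

    peak_tr: np.ndarray            # catalog apex retention index (reference frame)
    peak_td: np.ndarray            # catalog apex drift index (reference frame)
    amplitudes_class0: np.ndarray
    amplitudes_class1: np.ndarray
    marker_indices: np.ndarray
    drift_scales: list = field(default_factory=list)        # per sample
    warp_displacements: list = field(default_factory=list)  # per sample, samples
    sample_peak_tr: list = field(default_factory=list)      # per sample realized apex rows
    sample_peak_td: list = field(default_factory=list)      # per sample realized apex cols
    sample_amplitudes: list = field(default_factory=list)
    baselines: list = field(default_factory=list)           # per sample true surface


def _emg_profile(n: int, center: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-apex exponentially-modified Gaussian on an integer grid."""
    x = np.arange(n, dtype=float)
    g = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    if tau > 0:
        klen = max(int(8 * tau), 4)
        kern = np.exp(-np.arange(klen) / tau)
        g = fftconvolve(g, kern)[:n]
    m = g.max()
    return g / m if m > 0 else g


def _gauss_profile(n: int, center: float, sigma: float) -> np.ndarray:
    x = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _catalog_slots(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Lattice of admissible apex positions.

    Slots are spaced so that any two catalog peaks are farther apart than the
    peak-matching caps, which makes cluster identity unambiguous.
    """
    rip_idx = (cfg.rip_drift_ms - cfg.drift_origin) / cfg.drift_period
    td_lo = int(rip_idx + 20)          # clear of the RIP ridge
    td_hi = cfg.n_drift - 12           # keep the drift tail on the grid
    tr_lo, tr_hi = cfg.min_tr_margin, cfg.n_retention - 25
    trs = np.arange(tr_lo, tr_hi, cfg.tr_spacing)
    tds = np.arange(td_lo, td_hi, cfg.td_spacing)
    grid_tr, grid_td = np.meshgrid(trs, tds, indexing="ij")
    return grid_tr.ravel(), grid_td.ravel()


def build_catalog(cfg: SynthConfig) -> GroundTruth:
    """Draw the shared peak catalog and marker set (deterministic in seed)."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5EED]))
    slot_tr, slot_td = _catalog_slots(cfg)
    if slot_tr.size < cfg.peak_catalog_size:
        raise ValueError(
            f"grid admits only {slot_tr.size} separated peak slots, "
            f"catalog needs {cfg.peak_catalog_size}"
        )
    if cfg.unique_tr:
        order = rng.permutation(slot_tr.size)
        pick, seen = [], set()
        for i in order:
            if slot_tr[i] not in seen:
                pick.append(i)
                seen.add(slot_tr[i])
            if len(pick) == cfg.peak_catalog_size:
                break
        pick = np.array(pick)
        if pick.size < cfg.peak_catalog_size:
            raise ValueError(
                f"only {pick.size} distinct retention slots available, "
                f"catalog needs {cfg.peak_catalog_size}"
            )
    else:
        pick = rng.permutation(slot_tr.size)[:cfg.peak_catalog_size]
    # jitter within the slot, keeping the separation guarantee
    tr = slot_tr[pick] + rng.integers(-4, 5, size=pick.size)
    td = slot_td[pick] + rng.integers(-2, 3, size=pick.size)
    order = np.lexsort((td, tr))
    tr, td = tr[order], td[order]
    lo, hi = cfg.amplitude_range
    amp0 = rng.uniform(lo, hi, size=cfg.peak_catalog_size)
    amp1 = amp0.copy()
    markers = np.sort(rng.permutation(cfg.peak_catalog_size)[:cfg.marker_count])
    amp1[markers] = amp0[markers] * cfg.marker_effect
    return GroundTruth(
        peak_tr=tr, peak_td=td,
        amplitudes_class0=amp0, amplitudes_class1=amp1,
        marker_indices=markers,
    )


def _smooth_warp(n: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Monotone endpoint-fixed warp displacement built from a cumulative sum
    of a smooth perturbation, rescaled so max |displacement| hits the target."""
    if amplitude <= 0:
        return np.zeros(n)
    x = np.arange(n) / (n - 1)
    pert = np.zeros(n)
    for k in range(1, 4):
        pert += rng.normal() * np.cos(np.pi * k * x)
    disp = np.cumsum(pert)
    disp -= disp[0] + (disp[-1] - disp[0]) * x  # pin both endpoints to 0
    peak = np.abs(disp).max()
    if peak < 1e-12:
        return np.zeros(n)
    target = amplitude * rng.uniform(0.5, 1.0)
    disp *= target / peak
    # keep the warped index map strictly monotone
    step = np.diff(disp)
    worst = np.abs(step).max()
    if worst >= 0.9:
        disp *= 0.9 / worst
    return disp


def simulate_sample(cfg: SynthConfig, class_code: int,
                    rng: np.random.Generator,
                    catalog: GroundTruth | None = None,
                    misaligned: bool = True) -> tuple[SampleMatrix, dict]:
    """Render one sample; returns the matrix and its ground-truth slice.

    ``misaligned=False`` renders in the reference frame (used for the
    dataset's reference sample).
    """
    cfg.validate()
    gt = catalog if catalog is not None else build_catalog(cfg)
    nr, nd = cfg.n_retention, cfg.n_drift

    if misaligned:
        scale = 1.0 + rng.uniform(-cfg.drift_scale_jitter, cfg.drift_scale_jitter)
        disp = _smooth_warp(nr, cfg.retention_warp_amplitude, rng)
    else:
        scale, disp = 1.0, np.zeros(nr)

    amps_class = (gt.amplitudes_class1 if class_code == 1
                  else gt.amplitudes_class0)
    amps = amps_class * np.exp(rng.normal(0.0, cfg.amplitude_jitter,
                                          size=amps_class.size))

    signal = np.zeros((nr, nd))
    elution = np.zeros(nr)   # summed analyte amplitude profile over retention
    tr_apex = np.empty(gt.peak_tr.size, dtype=int)
    td_apex = np.empty(gt.peak_td.size, dtype=int)
    for k in range(gt.peak_tr.size):
        tr_c = gt.peak_tr[k] + disp[gt.peak_tr[k]]
        td_ms = cfg.drift_origin + cfg.drift_period * gt.peak_td[k]
        td_c = (td_ms * scale - cfg.drift_origin) / cfg.drift_period
        prof_tr = _gauss_profile(nr, tr_c, cfg.sigma_tr)
        prof_td = _emg_profile(nd, td_c, cfg.sigma_td, cfg.drift_tail_tau)
        signal += amps[k] * np.outer(prof_tr, prof_td)
        elution += amps[k] * prof_tr
        tr_apex[k] = int(np.argmax(prof_tr))
        td_apex[k] = int(np.argmax(prof_td))

    # RIP ridge with charge-depletion: amplitude drops where analytes elute
    depletion = np.maximum(1.0 - cfg.rip_depletion_alpha * elution,
                           cfg.rip_depletion_floor)
    rip_center = (cfg.rip_drift_ms * scale - cfg.drift_origin) / cfg.drift_period
    rip_prof = _gauss_profile(nd, rip_center, cfg.rip_sigma_ms / cfg.drift_period)
    signal += cfg.rip_amplitude * np.outer(depletion, rip_prof)

    td_ms_axis = cfg.drift_axis
    baseline = (cfg.baseline_offset
                + cfg.baseline_drift_amp
                * np.exp(-(td_ms_axis - cfg.drift_origin) / cfg.baseline_drift_tau_ms)
                + cfg.baseline_retention_slope * cfg.retention_axis[:, None])
    baseline = np.broadcast_to(baseline, (nr, nd)).copy()

    noise = rng.normal(0.0, cfg.noise_sd, size=(nr, nd)) if cfg.noise_sd > 0 else 0.0
    m = SampleMatrix(signal + baseline + noise,
                     cfg.retention_axis, td_ms_axis)
    slice_gt = {
        "drift_scale": scale,
        "warp_displacement": disp,
        "peak_tr": tr_apex,
        "peak_td": td_apex,
        "amplitudes": amps,
        "baseline": baseline,
    }
    return m, slice_gt


def simulate_dataset(cfg: SynthConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate a full two-class dataset.

    Sample 0 (the first class-0 sample) is rendered without misalignment and
    serves as the alignment reference.  Labels come out as
    ``[0]*n0 + [1]*n1``.
    """
    cfg.validate()
    gt = build_catalog(cfg)
    n0, n1 = cfg.n_per_class
    streams = np.random.SeedSequence([int(cfg.seed), 0xDA7A]).spawn(n0 + n1)
    samples, labels = [], []
    idx = 0
    for class_code, count in ((0, n0), (1, n1)):
        for _ in range(count):
            rng = np.random.default_rng(streams[idx])
            m, sl = simulate_sample(cfg, class_code, rng, catalog=gt,
                                    misaligned=idx != 0)
            m.sample_id = f"synth-{idx:03d}"
            m.meta["class"] = str(class_code)
            samples.append(m)
            labels.append(class_code)
            gt.drift_scales.append(sl["drift_scale"])
            gt.warp_displacements.append(sl["warp_displacement"])
            gt.sample_peak_tr.append(sl["peak_tr"])
            gt.sample_peak_td.append(sl["peak_td"])
            gt.sample_amplitudes.append(sl["amplitudes"])
            gt.baselines.append(sl["baseline"])
            idx += 1
    return Dataset(samples=samples, labels=np.array(labels),
                   reference_index=0), gt
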