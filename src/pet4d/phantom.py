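"""Synthetic multi-subject dynamic PET phantom.

Generates the ingredients of a desk-scale replicate study: a Feng-type
arterial input function, a 2-D brain-like phantom with per-region 1TC truth
parameters, between-subject biological variation (lognormal region factors),
Poisson sinogram frames under the 21-frame schedule, and gated count
downsampling into 20%/10%/5% replicate sets.

The downsampling emulates list-mode gating at the count level: every sinogram
bin count is multinomially partitioned into 20 equal-probability gates
(50-ms-gate analogue), and replicates are disjoint unions of gates — each
5th gate for 20% (5 replicates), each 10th for 10% (10 replicates), and 10
single gates for 5% (10 replicates).  For Poisson data this partition is
statistically exact: replicate bins are independent Poisson with the thinned
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import (C11_LAMBDA, FrameSchedule, InputFunction,
                       convolve_exponential, frame_average)

__all__ = [
    "PhantomSpec",
    "ScanGeometry",
    "SinogramStack",
    "ReplicateSet",
    "SubjectTruth",
    "make_input_function",
    "make_phantom_labels",
    "make_population",
    "simulate_dynamic_counts",
    "expected_sinogram",
    "downsample_replicates",
    "REPLICATES_PER_LEVEL",
]

# replicate counts per count level (full counts has the single parent scan)
REPLICATES_PER_LEVEL = {1.0: 1, 0.2: 5, 0.1: 10, 0.05: 10}
_N_GATES = 20


def make_input_function(peak_time: float = 1.0, peak_value: float = 3.5e4,
                        tail_amplitudes: tuple[float, float] = (0.30, 0.12),
                        tail_rates: tuple[float, float] = (0.12, 0.012),
                        duration: float = 60.0, dt: float = 0.01) -> InputFunction:
    """Feng-type plasma input function: bolus rise then multi-exponential decay.

    Cp(t) = S * [ (t/Tp) e^{1 - t/Tp} + a1 (e^{-l1 t} - e^{-t/Tp})
                                      + a2 (e^{-l2 t} - e^{-t/Tp}) ]

    The bolus term peaks exactly at ``peak_time`` = Tp; the curve is scaled so
    its maximum equals ``peak_value`` (Bq ml^-1).  Cp(0) = 0 by construction.
    Sampled at ``dt``-minute resolution (default 0.01) over ``duration`` min.
    """
    if peak_time <= 0 or peak_value <= 0:
        raise ValueError("peak_time and peak_value must be positive")
    a1, a2 = tail_amplitudes
    l1, l2 = tail_rates
    if a1 < 0 or a2 < 0 or l1 <= 0 or l2 <= 0:
        raise ValueError("tail parameters must be nonnegative (rates positive)")
    t = np.arange(int(round(duration / dt)) + 1) * dt
    lb = 1.0 / peak_time
    bolus = (t * lb) * np.exp(1.0 - t * lb)
    eb = np.exp(-t * lb)
    c = bolus + a1 * (np.exp(-l1 * t) - eb) + a2 * (np.exp(-l2 * t) - eb)
    c = np.clip(c, 0.0, None)
    c *= peak_value / c.max()
    c[0] = 0.0
    return InputFunction(t, c)


# region labels: 0 background, 1 cortex ring, 2 white matter, 3/4 striatal
# blobs, 5 small nigra-like blob
REGION_NAMES = {1: "cortex", 2: "white_matter", 3: "striatum_left",
                4: "striatum_right", 5: "nigra"}
GM_REGIONS = ("cortex", "striatum_left", "striatum_right", "nigra")

# template kinetic truth (ml/min/cm3, ml/cm3); nigra VT follows the reported
# PD substantia-nigra group mean of 6.41 ml/cm3
DEFAULT_K1 = {"cortex": 0.30, "white_matter": 0.15, "striatum_left": 0.35,
              "striatum_right": 0.35, "nigra": 0.30}
DEFAULT_VT = {"cortex": 15.0, "white_matter": 5.0, "striatum_left": 18.0,
              "striatum_right": 18.0, "nigra": 6.41}


def make_phantom_labels(n: int = 64) -> np.ndarray:
    """Integer label map: cortical ring, interior WM, two striatal blobs, nigra."""
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    labels = np.zeros((n, n), dtype=np.int16)
    r_out = 0.45 * n
    r_in = 0.33 * n
    labels[r < r_out] = 1                      # cortex ring (outer disc first)
    labels[r < r_in] = 2                       # white matter interior
    # striatal blobs (ellipses left/right of centre)
    for lab, sx in ((3, -0.14), (4, 0.14)):
        ex = (xx - (cx + sx * n)) / (0.08 * n)
        ey = (yy - (cy - 0.05 * n)) / (0.11 * n)
        labels[(ex**2 + ey**2 < 1.0) & (labels == 2)] = lab
    # small nigra-like blob below centre
    en = ((xx - cx) / (0.05 * n))**2 + ((yy - (cy + 0.18 * n)) / (0.05 * n))**2
    labels[(en < 1.0) & (labels == 2)] = 5
    # guarantee every region survives coarse grids (seed voxel at its centre)
    seeds = {3: (int(cy - 0.05 * n), int(cx - 0.14 * n)),
             4: (int(cy - 0.05 * n), int(cx + 0.14 * n)),
             5: (int(cy + 0.18 * n), int(cx))}
    for lab, (iy, ix) in seeds.items():
        if not np.any(labels == lab):
            labels[iy, ix] = lab
    return labels


@dataclass(frozen=True)
class PhantomSpec:
    """Synthetic population definition.

    ``between_subject_cv`` is the lognormal coefficient of variation applied
    independently to each region's K1 and VT per subject (default 0.15, a
    typical between-subject spread for PET kinetic parameters).
    """

    grid_size: int = 64
    voxel_size_mm: float = 2.0
    n_subjects: int = 8
    between_subject_cv: float = 0.15
    region_k1: dict = field(default_factory=lambda: dict(DEFAULT_K1))
    region_vt: dict = field(default_factory=lambda: dict(DEFAULT_VT))

    def __post_init__(self):
        if self.between_subject_cv < 0:
            raise ValueError("between-subject CV must be nonnegative")
        if any(v <= 0 for v in self.region_k1.values()) or \
           any(v <= 0 for v in self.region_vt.values()):
            raise ValueError("regional K1 and VT must be positive")

    def labels(self) -> np.ndarray:
        return make_phantom_labels(self.grid_size)


@dataclass(frozen=True)
class ScanGeometry:
    """Desk-scale 2-D parallel-beam scan geometry with image-space PSF."""

    n_angles: int = 120
    n_bins: int = 95
    psf_fwhm_mm: float = 2.5
    voxel_size_mm: float = 2.0
    calibration: float = 3e7  # expected total prompts at full counts

    def __post_init__(self):
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be nonnegative")
        if self.n_angles < 1 or self.n_bins < 2:
            raise ValueError("invalid geometry")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / self.voxel_size_mm


@dataclass
class SubjectTruth:
    """Per-subject ground-truth parameter maps and region values."""

    subject_id: int
    labels: np.ndarray
    K1: np.ndarray
    VT: np.ndarray
    k2: np.ndarray
    region_params: dict  # name -> (K1, k2, VT)


def make_population(spec: PhantomSpec, seed: int) -> list[SubjectTruth]:
    """Draw per-subject truth maps with lognormal between-subject variation.

    Each region's template K1 and VT are multiplied by independent lognormal
    factors with unit mean and the configured CV; k2 = K1/VT.
    """
    if spec.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    labels = spec.labels()
    cv = spec.between_subject_cv
    sig2 = np.log1p(cv**2)
    sig = np.sqrt(sig2)
    subjects = []
    for s in range(spec.n_subjects):
        K1 = np.zeros(labels.shape)
        VT = np.zeros(labels.shape)
        k2 = np.zeros(labels.shape)
        region_params = {}
        for lab, name in REGION_NAMES.items():
            fk = np.exp(rng.normal(-0.5 * sig2, sig)) if cv > 0 else 1.0
            fv = np.exp(rng.normal(-0.5 * sig2, sig)) if cv > 0 else 1.0
            rk1 = spec.region_k1[name] * fk
            rvt = spec.region_vt[name] * fv
            rk2 = rk1 / rvt
            m = labels == lab
            K1[m] = rk1
            VT[m] = rvt
            k2[m] = rk2
            region_params[name] = (rk1, rk2, rvt)
        subjects.append(SubjectTruth(s, labels, K1, VT, k2, region_params))
    return subjects


@dataclass
class SinogramStack:
    """Per-frame projection counts for one scan.

    ``counts`` has shape (n_frames, n_angles, n_bins); ``frame_scales`` maps
    decay-corrected activity images to expected counts (duration x decay x
    global calibration x count level), shared with the reconstructions.
    """

    counts: np.ndarray
    schedule: FrameSchedule
    geometry: ScanGeometry
    frame_scales: np.ndarray
    image_size: int = 64
    count_level: float = 1.0
    subject_id: int = 0
    replicate_id: int = 0

    def __post_init__(self):
        if self.counts.ndim != 3:
            raise ValueError("counts must be (frame, angle, bin)")
        if self.counts.shape[0] != self.schedule.n_frames:
            raise ValueError("frame axis must match the schedule")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class ReplicateSet:
    """Disjoint low-count replicates of a parent scan at one count level."""

    count_level: float
    replicates: list

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def simulate_dynamic_counts(truth: SubjectTruth, input_function: InputFunction,
                            schedule: FrameSchedule, geometry: ScanGeometry,
                            seed: int, fine_dt: float = 0.01) -> SinogramStack:
    """Poisson sinogram frames of a 1TC truth phantom.

    Per frame i the expected sinogram is the PSF-blurred forward projection of
    the frame-averaged activity, times dt_i x exp(-lambda t_mid,i) (C-11
    decay), globally scaled so the total expected prompts equal the geometry
    calibration.  Counts are drawn Poisson per (frame, angle, bin).
    """
    from .projector import Projector

    rng = np.random.default_rng(seed)
    mean, base = expected_sinogram(truth, input_function, schedule, geometry,
                                   fine_dt)
    total = mean.sum()
    cal = geometry.calibration / total if total > 0 else 0.0
    mean *= cal
    counts = rng.poisson(mean).astype(np.int64) if cal > 0 else \
        np.zeros_like(mean, dtype=np.int64)
    return SinogramStack(counts=counts, schedule=schedule, geometry=geometry,
                         frame_scales=base * cal, image_size=truth.labels.shape[0],
                         count_level=1.0, subject_id=truth.subject_id, replicate_id=0)


def expected_sinogram(truth: SubjectTruth, input_function: InputFunction,
                      schedule: FrameSchedule, geometry: ScanGeometry,
                      fine_dt: float = 0.01):
    """Pre-calibration expected sinogram and per-frame scale factors.

    Returns ``(mean, base)`` where ``mean[f] = base[f] * forward(activity_f)``
    with ``base = durations * decay`` — linear in the truth K1 maps.
    """
    from .projector import Projector

    proj = Projector(truth.labels.shape[0], geometry)
    nf = schedule.n_frames
    # region TACs at exact k2 (a handful of distinct kinetics per subject)
    frames_img = np.zeros(truth.labels.shape + (nf,))
    for lab, name in REGION_NAMES.items():
        k1r, k2r, _ = truth.region_params[name]
        t, v = convolve_exponential(input_function, k2r, fine_dt,
                                    t_end=schedule.total_duration)
        tac = k1r * frame_average(t, v, schedule)
        frames_img[truth.labels == lab] = tac
    decay = np.exp(-C11_LAMBDA * schedule.midpoints)
    base = schedule.durations * decay
    mean = np.stack([proj.forward(frames_img[..., i]) * base[i]
                     for i in range(nf)])
    return mean, base


def _gate_indices(count_level: float) -> list[np.ndarray]:
    if np.isclose(count_level, 0.2):
        return [np.arange(r, _N_GATES, 5) for r in range(5)]
    if np.isclose(count_level, 0.1):
        return [np.arange(r, _N_GATES, 10) for r in range(10)]
    if np.isclose(count_level, 0.05):
        return [np.array([g]) for g in range(10)]
    raise ValueError(f"unsupported count level {count_level!r}")


def downsample_replicates(full_stack: SinogramStack, count_level: float,
                          seed: int) -> ReplicateSet:
    """Gated count downsampling into disjoint replicates.

    Every bin count is multinomially split into 20 equal-probability gates;
    replicates take every 5th gate (20%, 5 replicates), every 10th gate
    (10%, 10 replicates) or one gate each (5%, first 10 gates).  The 20% and
    10% replicate sets therefore sum bin-for-bin to the parent stack.
    """
    groups = _gate_indices(count_level)
    rng = np.random.default_rng(seed)
    flat = full_stack.counts.ravel()
    gates = rng.multinomial(flat, np.full(_N_GATES, 1.0 / _N_GATES))
    reps = []
    for r, idx in enumerate(groups):
        c = gates[:, idx].sum(axis=1).reshape(full_stack.counts.shape)
        reps.append(replace(
            full_stack, counts=c.astype(np.int64),
            frame_scales=full_stack.frame_scales * count_level,
            count_level=count_level, replicate_id=r))
    return ReplicateSet(count_level=count_level, replicates=reps)
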