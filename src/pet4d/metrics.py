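"""Within-/between-subject variability metrics for parametric-map ensembles.

For an ensemble theta[j, r, s] (voxel j, noisy replicate r, subject s) the
within-subject statistics are the per-subject mean and sample SD across
replicates, averaged over subjects — the SD by root-mean-variance:

    m_js = mean_r theta_jrs          sigma_js = SD_r theta_jrs   (ddof=1)
    m_j  = mean_s m_js               sigma_j  = sqrt(mean_s sigma_js^2)

The between-subject statistics interchange the roles of r and s.  Because the
mean is linear, the within- and between-subject means coincide.

Variability is reported as a percent coefficient of variation with a *fixed*
reference denominator — the ROI value from the indirect reconstruction at
full counts, iteration 2 — so that %CV values are comparable across methods,
count levels and iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ParametricEnsemble",
    "ROISet",
    "within_subject_stats",
    "between_subject_stats",
    "roi_voxelwise_cv",
    "roi_level_stats",
    "boundary_hit_fraction",
    "iteration_change",
]


@dataclass
class ParametricEnsemble:
    """One parameter's values over (voxel, replicate, subject).

    ``theta`` has shape (n_voxels, N_R, N_S); voxels are the flattened grid.
    """

    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 3:
            raise ValueError("theta must be (voxel, replicate, subject)")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("ensemble contains non-finite values")

    @property
    def n_replicates(self) -> int:
        return self.theta.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.theta.shape[2]

    def swap_axes(self) -> "ParametricEnsemble":
        return ParametricEnsemble(np.swapaxes(self.theta, 1, 2))


@dataclass
class ROISet:
    """Named voxel masks plus the frozen %CV reference means.

    ``reference_means[param][roi]`` holds the IR full-count iteration-2 ROI
    value used as the fixed %CV denominator.
    """

    masks: dict
    reference_means: dict

    def __post_init__(self):
        flat = {k: np.asarray(v, dtype=bool).ravel() for k, v in self.masks.items()}
        total = np.zeros_like(next(iter(flat.values())), dtype=int)
        for v in flat.values():
            total += v
        if np.any(total > 1):
            raise ValueError("ROI masks must be disjoint")
        self.masks = flat

    @classmethod
    def from_labels(cls, labels: np.ndarray, names: dict,
                    reference_means: dict | None = None) -> "ROISet":
        masks = {name: labels == lab for lab, name in names.items()}
        return cls(masks, reference_means or {})

    def reference(self, param: str, roi: str) -> float:
        ref = self.reference_means[param][roi]
        if ref <= 0:
            raise ValueError("reference means must be positive")
        return ref


def within_subject_stats(ensemble: ParametricEnsemble):
    """Per-voxel within-subject mean m_j and SD sigma_j (replicate spread,
    subject-averaged by root-mean-variance)."""
    if ensemble.n_replicates < 2:
        raise ValueError("within-subject SD needs at least 2 replicates")
    th = ensemble.theta
    m_js = th.mean(axis=1)                     # (J, S)
    sd_js = th.std(axis=1, ddof=1)             # (J, S)
    m_j = m_js.mean(axis=1)
    sigma_j = np.sqrt((sd_js**2).mean(axis=1))
    return m_j, sigma_j


def between_subject_stats(ensemble: ParametricEnsemble):
    """Per-voxel between-subject mean and SD: r and s interchanged."""
    if ensemble.n_subjects < 2:
        raise ValueError("between-subject SD needs at least 2 subjects")
    return within_subject_stats(ensemble.swap_axes())


def roi_voxelwise_cv(m_j: np.ndarray, sigma_j: np.ndarray, roi_set: ROISet,
                     param: str) -> pd.DataFrame:
    """ROI-average the per-voxel stats; %CV against the fixed reference mean."""
    rows = []
    for roi, mask in roi_set.masks.items():
        if mask.sum() == 0:
            raise ValueError(f"empty ROI {roi!r}")
        m = float(m_j[mask].mean())
        sd = float(sigma_j[mask].mean())
        ref = roi_set.reference(param, roi)
        rows.append({"roi": roi, "mode": "voxel-wise", "mean": m, "sd": sd,
                     "cv_pct": 100.0 * sd / ref, "reference_mean": ref})
    return pd.DataFrame(rows)


def roi_level_stats(ensemble: ParametricEnsemble, roi_set: ROISet, param: str,
                    kind: str = "within") -> pd.DataFrame:
    """ROI-average theta per (replicate, subject) first, then the within- or
    between-subject machinery on the resulting N_R x N_S table."""
    rows = []
    for roi, mask in roi_set.masks.items():
        if mask.sum() == 0:
            raise ValueError(f"empty ROI {roi!r}")
        table = ensemble.theta[mask].mean(axis=0)[None, :, :]  # (1, R, S)
        sub = ParametricEnsemble(table)
        if kind == "within":
            m, sd = within_subject_stats(sub)
        elif kind == "between":
            m, sd = between_subject_stats(sub)
        else:
            raise ValueError("kind must be 'within' or 'between'")
        ref = roi_set.reference(param, roi)
        rows.append({"roi": roi, "mode": "roi-level", "mean": float(m[0]),
                     "sd": float(sd[0]), "cv_pct": 100.0 * float(sd[0]) / ref,
                     "reference_mean": ref})
    return pd.DataFrame(rows)


def boundary_hit_fraction(parametric_image, roi_mask: np.ndarray) -> float:
    """Percent of ROI voxels whose fitted k2 sits on the lower grid boundary."""
    mask = np.asarray(roi_mask, dtype=bool)
    flags = np.asarray(parametric_image.hit_lower_bound, dtype=bool).reshape(mask.shape)
    n = mask.sum()
    if n == 0:
        raise ValueError("empty ROI")
    return 100.0 * float(flags[mask].sum()) / float(n)


def iteration_change(values_by_iteration) -> np.ndarray:
    """Percent change per iteration step: 100 * (v[i+1] - v[i]) / v[i]."""
    v = np.asarray(values_by_iteration, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 iterations")
    if np.any(v[:-1] == 0):
        raise ValueError("zero denominator in percent change")
    return 100.0 * np.diff(v) / v[:-1]
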