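"""Sparse 2-D parallel-beam projector with matched adjoint and image-space PSF.

EM-type reconstruction needs a forward/back projector pair that is an exact
adjoint pair (filtered backprojection routines are not), so the system matrix
is built explicitly: each voxel centre is projected onto the detector axis at
every angle and its value is spread over the two nearest radial bins by
linear interpolation.  Resolution modelling is a spatially invariant Gaussian
applied in image space before projection and (being symmetric under
zero-padding) after backprojection — the same PSF used by the simulator and
both reconstruction arms.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

__all__ = ["Projector"]


class Projector:
    """System model A = P @ G for an n x n image.

    P is the sparse line projector (n_angles * n_bins rows), G the Gaussian
    PSF.  Subset views (angle-interleaved) expose per-subset forward/back
    operators and sensitivity images for OSEM.
    """

    def __init__(self, n: int, geometry):
        self.n = n
        self.geometry = geometry
        self.n_angles = geometry.n_angles
        self.n_bins = geometry.n_bins
        self.sigma = geometry.psf_sigma_px
        self._A = self._build_matrix()
        self._AT = self._A.T.tocsr()
        self._subset_cache: dict[int, list] = {}
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        self.fov_mask = np.hypot(yy - c, xx - c) <= (n / 2.0 - 0.5)

    def _build_matrix(self) -> sparse.csr_matrix:
        n, na, nb = self.n, self.n_angles, self.n_bins
        angles = np.arange(na) * np.pi / na
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        x = (xx - c).ravel()
        y = (yy - c).ravel()
        rows, cols, vals = [], [], []
        centre = (nb - 1) / 2.0
        vox = np.arange(n * n)
        for a, th in enumerate(angles):
            s = x * np.cos(th) + y * np.sin(th) + centre
            s0 = np.floor(s).astype(int)
            f = s - s0
            for off, wt in ((0, 1.0 - f), (1, f)):
                b = s0 + off
                ok = (b >= 0) & (b < nb) & (wt > 0)
                rows.append(a * nb + b[ok])
                cols.append(vox[ok])
                vals.append(wt[ok])
        A = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(na * nb, n * n))
        return A.tocsr()

    # -- PSF -----------------------------------------------------------------
    def blur(self, img: np.ndarray) -> np.ndarray:
        if self.sigma <= 0:
            return img
        return gaussian_filter(img, self.sigma, mode="constant")

    # -- full operators ------------------------------------------------------
    def forward(self, img: np.ndarray) -> np.ndarray:
        """PSF-blurred forward projection -> sinogram (n_angles, n_bins)."""
        return (self._A @ self.blur(img).ravel()).reshape(self.n_angles, self.n_bins)

    def backward(self, sino: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        return self.blur((self._AT @ sino.ravel()).reshape(self.n, self.n))

    # -- subset views ----------------------------------------------------------
    def subset_angles(self, n_subsets: int) -> list[np.ndarray]:
        """Angle-interleaved subsets: angle a belongs to subset a % n_subsets."""
        if self.n_angles % n_subsets != 0:
            raise ValueError("n_angles must be divisible by n_subsets")
        return [np.arange(s, self.n_angles, n_subsets) for s in range(n_subsets)]

    def _subsets(self, n_subsets: int):
        if n_subsets not in self._subset_cache:
            mats = []
            for angles in self.subset_angles(n_subsets):
                rows = (angles[:, None] * self.n_bins +
                        np.arange(self.n_bins)[None, :]).ravel()
                As = self._A[rows]
                sens = self.blur((As.T @ np.ones(As.shape[0])).reshape(self.n, self.n))
                mats.append((angles, As, As.T.tocsr(), sens))
            self._subset_cache[n_subsets] = mats
        return self._subset_cache[n_subsets]

    def subset_forward(self, img: np.ndarray, n_subsets: int, s: int) -> np.ndarray:
        _, As, _, _ = self._subsets(n_subsets)[s]
        na = self.n_angles // n_subsets
        return (As @ self.blur(img).ravel()).reshape(na, self.n_bins)

    def subset_backward(self, sino_sub: np.ndarray, n_subsets: int, s: int) -> np.ndarray:
        _, _, AsT, _ = self._subsets(n_subsets)[s]
        return self.blur((AsT @ sino_sub.ravel()).reshape(self.n, self.n))

    def subset_sensitivity(self, n_subsets: int, s: int) -> np.ndarray:
        """Backprojection of ones over the subset (unit frame scale)."""
        return self._subsets(n_subsets)[s][3]

    def subset_counts(self, sino: np.ndarray, n_subsets: int, s: int) -> np.ndarray:
        angles = self._subsets(n_subsets)[s][0]
        return sino[angles]
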