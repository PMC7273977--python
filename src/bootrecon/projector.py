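"""Matched forward/back projection pair for 2D parallel-beam tomography.

The system model ``A`` is the composition of an (optional) image-space
Gaussian point-spread function and a pixel-driven discrete Radon transform:
each pixel centre is mapped to its signed radial offset
``t = x cos(phi) + y sin(phi)`` and its value is split between the two
nearest radial bins with linear interpolation weights.  The back projector
is the exact adjoint ``A^T`` — it is built from the very same sparse matrix
— so that inner-product (adjoint) identities, EM monotonicity and KKT
conditions hold to machine precision.

``A`` is never materialised against a dense image; a sparse matrix per
geometry is cached and applied to flattened images/sinograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

__all__ = [
    "Geometry",
    "forward_project",
    "back_project",
    "sensitivity_image",
    "fbp",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry for a 2D parallel-beam scan.

    Parameters
    ----------
    n_angles
        Number of azimuthal angles, uniformly spanning [0, 180) degrees.
    n_bins
        Number of radial bins; bin 0 sits at the most negative offset.
    bin_size
        Radial bin width in mm.
    image_shape
        (rows, cols) of the reconstruction grid.
    pixel_size
        Pixel side length in mm.
    psf_fwhm
        FWHM in mm of the isotropic Gaussian resolution model applied in
        image space before projection (0 disables it).
    """

    n_angles: int
    n_bins: int
    bin_size: float
    image_shape: tuple[int, int]
    pixel_size: float
    psf_fwhm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_bins < 1:
            raise ValueError("n_angles and n_bins must be >= 1")
        if self.bin_size <= 0 or self.pixel_size <= 0:
            raise ValueError("bin_size and pixel_size must be positive")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be non-negative")
        object.__setattr__(self, "image_shape", tuple(int(s) for s in self.image_shape))

    @property
    def sino_shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_bins)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * (180.0 / self.n_angles)

    @property
    def psf_sigma_px(self) -> float:
        """PSF standard deviation in pixel units."""
        return self.psf_fwhm * _FWHM_TO_SIGMA / self.pixel_size


def desk_geometry(psf_fwhm: float = 0.0) -> Geometry:
    """Small geometry used throughout the test-scale experiments."""
    return Geometry(
        n_angles=60,
        n_bins=95,
        bin_size=2.0,
        image_shape=(64, 64),
        pixel_size=2.0,
        psf_fwhm=psf_fwhm,
    )


def full2d_geometry(psf_fwhm: float = 3.0) -> Geometry:
    """Full-scale 2D geometry: 180 angles x 185 radial bins of 2 mm."""
    return Geometry(
        n_angles=180,
        n_bins=185,
        bin_size=2.0,
        image_shape=(128, 128),
        pixel_size=2.0,
        psf_fwhm=psf_fwhm,
    )


@lru_cache(maxsize=8)
def _radon_matrix(
    n_angles: int,
    n_bins: int,
    bin_size: float,
    image_shape: tuple[int, int],
    pixel_size: float,
) -> sp.csr_matrix:
    """Sparse pixel-driven Radon matrix of shape (n_angles*n_bins, n_pixels)."""
    ny, nx = image_shape
    # pixel centres, image centre at grid centre, y axis pointing up
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size
    ys = ((ny - 1) / 2.0 - np.arange(ny)) * pixel_size
    xg, yg = np.meshgrid(xs, ys)
    xg = xg.ravel()
    yg = yg.ravel()
    n_pix = ny * nx

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    t0 = -(n_bins - 1) / 2.0 * bin_size
    pix_idx = np.arange(n_pix)
    for a in range(n_angles):
        phi = np.deg2rad(a * 180.0 / n_angles)
        t = xg * np.cos(phi) + yg * np.sin(phi)
        f = (t - t0) / bin_size
        i0 = np.floor(f).astype(np.int64)
        w1 = f - i0
        for i_bin, w in ((i0, 1.0 - w1), (i0 + 1, w1)):
            ok = (i_bin >= 0) & (i_bin < n_bins) & (w > 0)
            rows.append(a * n_bins + i_bin[ok])
            cols.append(pix_idx[ok])
            vals.append(w[ok])
    mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_angles * n_bins, n_pix),
    )
    mat.sum_duplicates()
    return mat


def _matrix(geom: Geometry) -> sp.csr_matrix:
    return _radon_matrix(
        geom.n_angles, geom.n_bins, geom.bin_size, geom.image_shape, geom.pixel_size
    )


def _blur(img: np.ndarray, geom: Geometry) -> np.ndarray:
    # zero-padded correlation with a symmetric kernel: exactly self-adjoint
    if geom.psf_fwhm <= 0:
        return img
    return gaussian_filter(img, sigma=geom.psf_sigma_px, mode="constant", cval=0.0)


def _check_image(img: np.ndarray, geom: Geometry) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.shape != geom.image_shape:
        raise ValueError(f"image shape {img.shape} does not match geometry {geom.image_shape}")
    return img


def _check_sino(sino: np.ndarray, geom: Geometry) -> np.ndarray:
    sino = np.asarray(sino, dtype=float)
    if sino.shape != geom.sino_shape:
        raise ValueError(f"sinogram shape {sino.shape} does not match geometry {geom.sino_shape}")
    return sino


def forward_project(img: np.ndarray, geom: Geometry) -> np.ndarray:
    """Apply the system model A: PSF blur followed by the Radon transform.

    Returns a mean-value sinogram of shape ``(n_angles, n_bins)``.  Linear
    in ``img`` and non-negativity preserving.
    """
    img = _check_image(img, geom)
    blurred = _blur(img, geom)
    return (_matrix(geom) @ blurred.ravel()).reshape(geom.sino_shape)


def back_project(sino: np.ndarray, geom: Geometry) -> np.ndarray:
    """Apply the exact adjoint A^T: transpose Radon followed by PSF blur."""
    sino = _check_sino(sino, geom)
    img = (_matrix(geom).T @ sino.ravel()).reshape(geom.image_shape)
    return _blur(img, geom)


def sensitivity_image(geom: Geometry) -> np.ndarray:
    """Sensitivity s = A^T 1, the EM normaliser.

    Strictly positive inside the scanner field of view; pixels where it is
    zero must be excluded from multiplicative updates.
    """
    return back_project(np.ones(geom.sino_shape), geom)


def _ramp_filter(sino: np.ndarray, bin_size: float) -> np.ndarray:
    n = sino.shape[1]
    n_pad = int(2 ** np.ceil(np.log2(2 * n)))
    padded = np.zeros((sino.shape[0], n_pad))
    padded[:, :n] = sino
    freqs = np.fft.fftfreq(n_pad, d=bin_size)
    filtered = np.fft.ifft(np.fft.fft(padded, axis=1) * np.abs(freqs), axis=1).real
    return filtered[:, :n]


def fbp(sino: np.ndarray, geom: Geometry, clip_negative: bool = False) -> np.ndarray:
    """Filtered backprojection with a plain ramp filter.

    Used for guide, reference and mask images.  The raw output retains
    negative ringing; pass ``clip_negative=True`` when the result serves as
    a guide or reference image.  The PSF model is deliberately bypassed:
    FBP reconstructions here are analytic references, not model-matched.
    """
    sino = _check_sino(sino, geom)
    filtered = _ramp_filter(sino, geom.bin_size)
    geom0 = Geometry(
        geom.n_angles, geom.n_bins, geom.bin_size, geom.image_shape, geom.pixel_size, 0.0
    )
    img = back_project(filtered, geom0)
    # pixel-driven projector measures sums of pixel samples, not line
    # integrals; the scale below restores sample units (derivation in docs)
    img *= np.pi * geom.pixel_size**2 / (geom.n_angles * geom.bin_size)
    if clip_negative:
        img = np.clip(img, 0.0, None)
    return img
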