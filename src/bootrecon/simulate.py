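"""Digital phantoms and the 2D PET acquisition simulator.

The simulator emulates a simple but complete emission acquisition: the
phantom is blurred by the intrinsic scanner resolution, projected to a
parallel-beam sinogram of true coincidences, a scattered-photon component
(radially blurred copy of the trues) and a random-coincidence component
(uniform) are added as mean backgrounds, the whole mean sinogram is scaled
to a target expected total count, and Poisson noise is drawn per bin.

Default study conditions: 4.5 mm FWHM intrinsic blur, scatter blurred with
a 10-radial-bin standard deviation Gaussian, 20% scatter fraction, 20%
randoms fraction (both relative to the total expected counts), count
levels 3.5e5 / 3.5e6 / 3.5e7.  The background means are returned exactly
(the simulation-study idealisation of perfectly known scatter/randoms
estimates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .projector import Geometry, fbp, forward_project, _FWHM_TO_SIGMA

__all__ = [
    "AcquisitionSpec",
    "SimulatedDataset",
    "COUNT_LEVELS",
    "make_phantom",
    "simulate_acquisition",
    "thin_counts",
]

#: low / mid / high mean total counts of the 2D study conditions
COUNT_LEVELS: dict[str, float] = {"low": 3.5e5, "mid": 3.5e6, "high": 3.5e7}


@dataclass(frozen=True)
class AcquisitionSpec:
    """Noise and background conditions of one simulated acquisition."""

    total_counts_mean: float = 3.5e6
    scatter_fraction: float = 0.2
    randoms_fraction: float = 0.2
    intrinsic_blur_fwhm: float = 4.5  # mm
    scatter_blur_sigma_bins: float = 10.0
    scatter_blur_2d: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_counts_mean <= 0:
            raise ValueError("total_counts_mean must be positive")
        if not (0.0 <= self.scatter_fraction + self.randoms_fraction < 1.0):
            raise ValueError("scatter_fraction + randoms_fraction must lie in [0, 1)")
        if min(self.scatter_fraction, self.randoms_fraction) < 0:
            raise ValueError("fractions must be non-negative")


@dataclass
class SimulatedDataset:
    """One simulated acquisition: counts, known background and provenance."""

    m: np.ndarray  # measured Poisson counts (n_angles, n_bins)
    b: np.ndarray  # mean background (scatter + randoms)
    true_mean: np.ndarray  # mean trues
    phantom: np.ndarray
    guide: np.ndarray  # noise/background/blur-free FBP of the phantom
    geom: Geometry
    spec: AcquisitionSpec = field(default=None)  # type: ignore[assignment]
    scatter_mean: np.ndarray | None = None
    randoms_mean: np.ndarray | None = None


def stream(seed: int, purpose: str) -> np.random.Generator:
    """Independent generator derived from a user seed and a purpose label."""
    label = sum(purpose.encode())  # stable across runs, unlike hash()
    return np.random.default_rng(np.random.SeedSequence([int(seed), label]))


def make_phantom(
    kind: str,
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Procedural 2D activity phantoms on a head-shaped support.

    ``disc``
        Uniform unit disc of radius 0.4 * min(shape).
    ``ellipses``
        Elliptical body with two hot and one cold internal lesions.
    ``brain_like``
        FDG-like contrast: high-uptake cortical ribbon, mid-uptake interior
        (with ventricle-like cold regions), low background rim.
    """
    ny, nx = shape
    if min(ny, nx) < 32:
        raise ValueError("phantom grid must be at least 32x32")
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y = (yy - cy) / (min(ny, nx) / 2.0)
    x = (xx - cx) / (min(ny, nx) / 2.0)
    r = np.hypot(x, y)

    if kind == "disc":
        return np.where(r <= 0.8, 1.0, 0.0)

    if kind == "ellipses":
        img = np.zeros(shape)
        body = (x / 0.85) ** 2 + (y / 0.7) ** 2 <= 1.0
        img[body] = 1.0
        img[((x - 0.3) / 0.18) ** 2 + ((y - 0.2) / 0.18) ** 2 <= 1.0] = 2.5
        img[((x + 0.35) / 0.14) ** 2 + ((y + 0.1) / 0.22) ** 2 <= 1.0] = 2.0
        img[(x / 0.12) ** 2 + ((y + 0.35) / 0.12) ** 2 <= 1.0] = 0.3
        img[~body] = 0.0
        return img

    if kind == "brain_like":
        rng = stream(seed, "phantom")
        img = np.zeros(shape)
        head = (x / 0.82) ** 2 + (y / 0.95) ** 2 <= 1.0
        e = np.sqrt((x / 0.82) ** 2 + (y / 0.95) ** 2)
        img[head] = 0.35  # white-matter-like interior
        img[(e <= 1.0) & (e >= 0.78)] = 1.0  # cortical grey-matter ribbon
        # deep grey nuclei
        img[((x - 0.18) / 0.14) ** 2 + ((y - 0.05) / 0.2) ** 2 <= 1.0] = 0.9
        img[((x + 0.18) / 0.14) ** 2 + ((y - 0.05) / 0.2) ** 2 <= 1.0] = 0.9
        # ventricles (cold)
        img[((x - 0.08) / 0.06) ** 2 + ((y + 0.12) / 0.25) ** 2 <= 1.0] = 0.05
        img[((x + 0.08) / 0.06) ** 2 + ((y + 0.12) / 0.25) ** 2 <= 1.0] = 0.05
        # a few random small hot foci in the cortex for texture
        ribbon = np.argwhere((e <= 0.98) & (e >= 0.8))
        for iy, ix in ribbon[rng.choice(len(ribbon), size=4, replace=False)]:
            blob = (yy - iy) ** 2 + (xx - ix) ** 2 <= 2.5**2
            img[blob & head] = 1.3
        img[~head] = 0.0
        return img

    raise ValueError(f"unknown phantom kind: {kind!r}")


def simulate_acquisition(
    phantom: np.ndarray,
    geom: Geometry,
    spec: AcquisitionSpec,
) -> SimulatedDataset:
    """Generate one noisy acquisition of ``phantom`` under ``spec``.

    The intrinsic resolution blur is applied explicitly here, so the
    projection itself is done with a PSF-free system model; reconstruction
    may then use whatever PSF model it chooses, independent of the data
    generation.
    """
    phantom = np.asarray(phantom, dtype=float)
    if not np.any(phantom > 0):
        raise ValueError("phantom is identically zero")

    geom0 = Geometry(
        geom.n_angles, geom.n_bins, geom.bin_size, geom.image_shape, geom.pixel_size, 0.0
    )
    sigma_px = spec.intrinsic_blur_fwhm * _FWHM_TO_SIGMA / geom.pixel_size
    blurred = gaussian_filter(phantom, sigma_px, mode="constant") if sigma_px > 0 else phantom
    trues = forward_project(blurred, geom0)

    total = spec.total_counts_mean
    trues_frac = 1.0 - spec.scatter_fraction - spec.randoms_fraction
    trues *= trues_frac * total / trues.sum()

    if spec.scatter_fraction > 0:
        if spec.scatter_blur_2d:
            scatter = gaussian_filter(trues, spec.scatter_blur_sigma_bins, mode="constant")
        else:
            scatter = gaussian_filter1d(
                trues, spec.scatter_blur_sigma_bins, axis=1, mode="constant"
            )
        scatter *= spec.scatter_fraction * total / scatter.sum()
    else:
        scatter = np.zeros_like(trues)

    if spec.randoms_fraction > 0:
        randoms = np.full(geom.sino_shape, spec.randoms_fraction * total / trues.size)
    else:
        randoms = np.zeros_like(trues)

    b = scatter + randoms
    rng = stream(spec.seed, "noise")
    m = rng.poisson(trues + b).astype(np.int64)

    guide = fbp(forward_project(phantom, geom0), geom0, clip_negative=True)
    return SimulatedDataset(
        m=m,
        b=b,
        true_mean=trues,
        phantom=phantom,
        guide=guide,
        geom=geom,
        spec=spec,
        scatter_mean=scatter,
        randoms_mean=randoms,
    )


def thin_counts(m: np.ndarray, retain_prob: float, seed: int = 0) -> np.ndarray:
    """Binomial thinning: keep each recorded count with ``retain_prob``.

    Thinning a Poisson sinogram yields a Poisson sinogram at the reduced
    mean, which is how reduced-count datasets are derived from a
    high-count acquisition.
    """
    if not (0.0 < retain_prob <= 1.0):
        raise ValueError("retain_prob must lie in (0, 1]")
    m = np.asarray(m)
    if not np.issubdtype(m.dtype, np.integer):
        raise ValueError("thin_counts requires integer counts")
    if retain_prob == 1.0:
        return m.copy()
    rng = stream(seed, "thin")
    return rng.binomial(m, retain_prob)
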