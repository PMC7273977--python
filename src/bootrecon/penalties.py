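"""Quadratic penalty machinery: neighbourhood weights and derived fields.

The roughness penalty is R(theta) = 1/4 sum_j sum_{l in N_j} w_jl
(theta_j - theta_l)^2 over a fixed stencil of pixel offsets.  Two weight
choices are provided: uniform (all in-image weights 1) and Bowsher-guided
(per pixel, only the B neighbours most similar in a guide image keep
weight 1).  The module also builds the per-pixel quantities the modified
EM update needs: the weight sums, nu_j = (sum_l w_jl)/s_j with s the
sensitivity image, and the locally smoothed image

    theta_reg_j = sum_l w_jl (theta_l + theta_j) / (2 sum_l w_jl).

Weight bookkeeping convention: the uniform stencil includes the centre
offset, so an interior 5x5 sum is 25 (the centre adds nothing to R but
does enter the weight sums above).  Bowsher candidates are neighbours
only, so an interior sum at B=10 is 10.  Out-of-image neighbours simply
carry zero weight; border sums are truncated accordingly and every
normalisation runs through the actual per-pixel sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightMap",
    "PenaltyContext",
    "uniform_weights",
    "bowsher_weights",
    "penalty_value",
    "penalty_gradient",
    "compute_nu",
    "smoothed_image",
    "make_context",
]


def stencil_offsets(size: int, include_centre: bool) -> np.ndarray:
    """(dy, dx) offsets of a size x size stencil in row-major order."""
    if size < 1 or size % 2 == 0:
        raise ValueError("stencil size must be odd and positive")
    h = size // 2
    offs = [
        (dy, dx)
        for dy in range(-h, h + 1)
        for dx in range(-h, h + 1)
        if include_centre or (dy, dx) != (0, 0)
    ]
    return np.array(offs, dtype=np.int64)


@dataclass
class WeightMap:
    """Per-pixel, per-offset weights w_jl on a fixed offset stencil."""

    offsets: np.ndarray  # (L, 2) of (dy, dx)
    weights: np.ndarray  # (L, ny, nx), zero where the neighbour is off-image

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.weights.shape[1:]

    def sum_w(self) -> np.ndarray:
        """Per-pixel weight sum, truncated at borders."""
        return self.weights.sum(axis=0)

    def symmetrised(self) -> "WeightMap":
        """(w + w^T)/2 over pixel pairs, as De Pierro's derivation assumes."""
        sym = np.empty_like(self.weights)
        lut = {tuple(o): i for i, o in enumerate(self.offsets)}
        for i, (dy, dx) in enumerate(self.offsets):
            j = lut.get((-dy, -dx))
            if j is None:
                raise ValueError("stencil is not symmetric under negation")
            # partner weight: the neighbour at +l pointing back along -l
            sym[i] = 0.5 * (self.weights[i] + _shift(self.weights[j], dy, dx))
        return WeightMap(self.offsets.copy(), sym)


@dataclass
class PenaltyContext:
    """Everything the regularised update needs besides beta."""

    weights: WeightMap
    nu: np.ndarray  # (sum_l w_jl) / s_j, zero where s_j = 0
    sum_w: np.ndarray
    support: np.ndarray  # boolean, s_j > 0


def _shift(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """out[y, x] = arr[y + dy, x + dx], zero where that falls off-image."""
    ny, nx = arr.shape
    out = np.zeros_like(arr)
    ys = slice(max(0, -dy), min(ny, ny - dy))
    xs = slice(max(0, -dx), min(nx, nx - dx))
    yt = slice(max(0, dy), min(ny, ny + dy))
    xt = slice(max(0, dx), min(nx, nx + dx))
    out[ys, xs] = arr[yt, xt]
    return out


def _validity(offsets: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean (L, ny, nx): neighbour at each offset lies inside the image."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    valid = np.empty((len(offsets), ny, nx), dtype=bool)
    for i, (dy, dx) in enumerate(offsets):
        valid[i] = (yy + dy >= 0) & (yy + dy < ny) & (xx + dx >= 0) & (xx + dx < nx)
    return valid


def uniform_weights(
    shape: tuple[int, int], stencil: int = 5, include_centre: bool = True
) -> WeightMap:
    """Unweighted quadratic penalty: every in-image weight is 1.

    With the default centre inclusion an interior pixel of a 5x5 map has
    weight sum 25; corner pixels see only the 3x3 in-image overlap (sum 9).
    """
    offsets = stencil_offsets(stencil, include_centre)
    return WeightMap(offsets, _validity(offsets, shape).astype(float))


def bowsher_weights(
    guide: np.ndarray,
    stencil: int = 5,
    B: int = 10,
    symmetrise: bool = False,
) -> WeightMap:
    """Guided weights: keep the B neighbours most similar in the guide.

    Similarity is the squared difference of guide values; the centre pixel
    is not a candidate.  Ties break deterministically by stencil offset
    order.  Border pixels keep min(B, available neighbours).  Weights are
    directed (pixel j may select l without l selecting j); pass
    ``symmetrise=True`` for (w + w^T)/2.
    """
    guide = np.asarray(guide, dtype=float)
    offsets = stencil_offsets(stencil, include_centre=False)
    if not (1 <= B <= len(offsets)):
        raise ValueError(f"B must lie in [1, {len(offsets)}]")
    valid = _validity(offsets, guide.shape)
    diff = np.full((len(offsets),) + guide.shape, np.inf)
    for i, (dy, dx) in enumerate(offsets):
        d = _shift(guide, dy, dx) - guide
        diff[i, valid[i]] = (d**2)[valid[i]]
    order = np.argsort(diff, axis=0, kind="stable")
    ranked_valid = np.take_along_axis(np.isfinite(diff), order, axis=0)
    w = np.zeros_like(diff)
    np.put_along_axis(w, order[:B], ranked_valid[:B].astype(float), axis=0)
    wm = WeightMap(offsets, w)
    return wm.symmetrised() if symmetrise else wm


def _pairwise_diffs(theta: np.ndarray, wm: WeightMap) -> np.ndarray:
    """(L, ny, nx) of theta_j - theta_{j+l}, zeroed where weight is zero."""
    d = np.empty_like(wm.weights)
    for i, (dy, dx) in enumerate(wm.offsets):
        d[i] = theta - _shift(theta, dy, dx)
    d[wm.weights == 0] = 0.0
    return d


def penalty_value(theta: np.ndarray, wm: WeightMap) -> float:
    """R(theta) = 1/4 sum_j sum_l w_jl (theta_j - theta_l)^2."""
    theta = _check_shape(theta, wm)
    d = _pairwise_diffs(theta, wm)
    return 0.25 * float(np.sum(wm.weights * d**2))


def penalty_gradient(theta: np.ndarray, wm: WeightMap) -> np.ndarray:
    """Analytic dR/dtheta_j, valid for directed (asymmetric) weights."""
    theta = _check_shape(theta, wm)
    d = _pairwise_diffs(theta, wm)
    term1 = np.sum(wm.weights * d, axis=0)
    term2 = np.zeros_like(theta)
    for i, (dy, dx) in enumerate(wm.offsets):
        term2 += _shift(-(wm.weights[i] * d[i]), -dy, -dx)
    return 0.5 * (term1 + term2)


def compute_nu(wm: WeightMap, sens: np.ndarray) -> np.ndarray:
    """nu_j = (sum_l w_jl) / s_j; zero (and masked out) where s_j = 0."""
    sens = _check_shape(sens, wm)
    sw = wm.sum_w()
    nu = np.zeros_like(sw)
    ok = sens > 0
    nu[ok] = sw[ok] / sens[ok]
    return nu


def smoothed_image(theta: np.ndarray, wm: WeightMap) -> np.ndarray:
    """Local average paired with the centre value:

    theta_reg_j = sum_l w_jl (theta_l + theta_j) / (2 sum_l w_jl),
    with theta_j passed through unchanged where the weight sum is zero.
    Preserves constants and never leaves [min(theta), max(theta)].
    """
    theta = _check_shape(theta, wm)
    sw = wm.sum_w()
    num = np.zeros_like(theta)
    for i, (dy, dx) in enumerate(wm.offsets):
        num += wm.weights[i] * (_shift(theta, dy, dx) + theta)
    out = theta.copy()
    ok = sw > 0
    out[ok] = num[ok] / (2.0 * sw[ok])
    return out


def make_context(wm: WeightMap, sens: np.ndarray) -> PenaltyContext:
    return PenaltyContext(
        weights=wm,
        nu=compute_nu(wm, sens),
        sum_w=wm.sum_w(),
        support=np.asarray(sens) > 0,
    )


def _check_shape(arr: np.ndarray, wm: WeightMap) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != wm.image_shape:
        raise ValueError(f"shape {arr.shape} does not match weight map {wm.image_shape}")
    return arr
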