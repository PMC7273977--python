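"""Quantitative evaluation over ensembles of noise realisations.

Error metrics are normalised to a reference image over an object mask
Omega and decompose as RMSE^2 = SD^2 + Bias^2:

    Bias = sqrt( sum_Omega (mean_j - ref_j)^2 / sum_Omega ref_j^2 )
    SD   = sqrt( (1/S) sum_s sum_Omega (mean_j - theta_j^(s))^2
                 / sum_Omega ref_j^2 )

where mean_j is the voxelwise average over the S realisations.  The
reference is the FBP reconstruction of the noise-free, background-free,
resolution-unblurred projection of the phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .penalties import PenaltyContext
from .projector import Geometry, fbp, forward_project
from .recon import mapem_fixed_beta

__all__ = [
    "EnsembleMetrics",
    "ensemble_metrics",
    "make_reference",
    "make_mask",
    "grid_search_experiment",
]


@dataclass
class EnsembleMetrics:
    rmse: float
    bias: float
    sd: float
    S: int
    region: np.ndarray


def ensemble_metrics(
    recons: list[np.ndarray] | np.ndarray,
    ref: np.ndarray,
    mask: np.ndarray,
) -> EnsembleMetrics:
    """Bias / SD / RMSE of a stack of reconstructions against a reference."""
    stack = np.asarray(recons, dtype=float)
    S = stack.shape[0]
    if S < 2:
        raise ValueError("need at least 2 realisations for the SD term")
    ref = np.asarray(ref, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.shape[1:] != ref.shape or ref.shape != mask.shape:
        raise ValueError("shape mismatch between reconstructions, reference and mask")
    norm = float(np.sum(ref[mask] ** 2))
    if norm == 0:
        raise ValueError("reference is zero on the mask")
    mean_img = stack.mean(axis=0)
    bias = np.sqrt(np.sum((mean_img[mask] - ref[mask]) ** 2) / norm)
    sd = np.sqrt(np.sum((mean_img[None, :, :] - stack) ** 2, axis=0)[mask].sum() / (S * norm))
    rmse = np.sqrt(sd**2 + bias**2)
    return EnsembleMetrics(rmse=float(rmse), bias=float(bias), sd=float(sd), S=S, region=mask)


def make_reference(
    phantom: np.ndarray, geom: Geometry, counts_scale: float | None = None
) -> np.ndarray:
    """Reference image: clipped FBP of the clean, unblurred projection.

    Reconstructions from count data live on the count scale, not the
    phantom's arbitrary activity units; pass ``counts_scale`` (the expected
    total true counts) to put the reference on the same scale before
    computing normalised errors.
    """
    geom0 = Geometry(
        geom.n_angles, geom.n_bins, geom.bin_size, geom.image_shape, geom.pixel_size, 0.0
    )
    proj = forward_project(np.asarray(phantom, dtype=float), geom0)
    if counts_scale is not None:
        proj = proj * (counts_scale / proj.sum())
    return fbp(proj, geom0, clip_negative=True)


def reference_for_dataset(ds) -> np.ndarray:
    """Reference on the count scale of a SimulatedDataset's trues."""
    return make_reference(ds.phantom, ds.geom, counts_scale=float(ds.true_mean.sum()))


def make_mask(img: np.ndarray, threshold_frac: float = 0.10) -> np.ndarray:
    """Object ('head') mask: single threshold at ``threshold_frac`` of the
    99th percentile, morphological hole filling, largest connected
    component.  Idempotent on its own output."""
    img = np.asarray(img, dtype=float)
    if np.any(img < 0):
        raise ValueError("mask input must be non-negative (clip FBP output first)")
    level = threshold_frac * np.percentile(img, 99)
    if level <= 0:
        raise ValueError("image is empty; cannot derive an object mask")
    binary = img > level
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no object found above the threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def grid_search_experiment(
    datasets: list,
    beta_grid: np.ndarray,
    ctx: PenaltyContext,
    n_iter: int,
    geom: Geometry,
    ref: np.ndarray,
    mask: np.ndarray,
) -> pd.DataFrame:
    """End-iteration ensemble RMSE of fixed-beta MAPEM over a beta grid.

    ``datasets`` is a list of SimulatedDataset realisations of the same
    phantom/count level.  Returns a tidy frame (beta, rmse, bias, sd); the
    argmin row is the grid-searched optimum that the bootstrap-optimised
    method is compared against.
    """
    rows = []
    for beta in np.asarray(beta_grid, dtype=float):
        recons = [
            mapem_fixed_beta(
                ds.m, ds.b, geom, ctx, beta, n_iter, track_objective=False
            ).image
            for ds in datasets
        ]
        if len(recons) == 1:  # single realisation: no SD term
            norm = float(np.sum(ref[mask] ** 2))
            bias = float(np.sqrt(np.sum((recons[0][mask] - ref[mask]) ** 2) / norm))
            rows.append({"beta": beta, "rmse": bias, "bias": bias, "sd": 0.0})
        else:
            metrics = ensemble_metrics(recons, ref, mask)
            rows.append(
                {"beta": beta, "rmse": metrics.rmse, "bias": metrics.bias, "sd": metrics.sd}
            )
    return pd.DataFrame(rows)
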