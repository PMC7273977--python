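"""Iterative update engines: MLEM and the De Pierro modified-EM denoiser.

The unregularised Poisson EM (MLEM) update is

    theta' = theta / (A^T 1) * A^T( m / (A theta + b) ),

and the quadratically penalised (MAPEM) update factorises as a denoising
operator F_beta applied to the MLEM update: per pixel, F_beta returns the
positive root of

    beta nu x^2 + xi x - theta_em = 0,
    xi = 1 - beta nu theta_reg,

where theta_reg is the locally smoothed previous iterate and
nu = (sum_l w_jl)/s_j.  With symmetric weights this scheme monotonically
increases the penalised log-likelihood and converges to the MAP estimate
for fixed beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .penalties import PenaltyContext, penalty_value, smoothed_image
from .projector import Geometry, back_project, forward_project, sensitivity_image

__all__ = [
    "ReconResult",
    "mlem_update",
    "depierro_denoise",
    "mapem_fixed_beta",
    "poisson_loglik",
    "map_objective",
]


@dataclass
class ReconResult:
    """Final image plus per-iteration diagnostics of a reconstruction run."""

    image: np.ndarray
    objective: np.ndarray  # per-iteration penalised log-likelihood
    beta_trace: "object | None" = None  # BetaState, for the driven method
    diagnostics: dict = field(default_factory=dict)


def poisson_loglik(
    theta: np.ndarray, m: np.ndarray, b: np.ndarray, geom: Geometry
) -> float:
    """Poisson log-likelihood sum_i [ m_i log(q_i) - q_i ], q = A theta + b.

    Bins with q = 0 and m = 0 contribute zero (the 0 log 0 limit)."""
    q = forward_project(theta, geom) + b
    ll = -q.sum()
    pos = q > 0
    m = np.asarray(m, dtype=float)
    if np.any((m > 0) & ~pos):
        return -np.inf
    ll += float(np.sum(m[pos] * np.log(q[pos])))
    return float(ll)


#: The modified-EM update built on nu = (sum_l w_jl)/s_j ascends the
#: penalised likelihood in which the quarter-convention roughness R enters
#: with strength beta/2 (solve the separable surrogate optimality condition
#: to see the factor).  The objective below includes that factor so that
#: fixed-beta MAPEM is provably monotone in it and its maximiser satisfies
#: the corresponding KKT conditions.
PENALTY_STRENGTH_FACTOR = 0.5


def map_objective(
    theta: np.ndarray,
    m: np.ndarray,
    b: np.ndarray,
    geom: Geometry,
    beta: float,
    ctx: PenaltyContext,
) -> float:
    """Penalised log-likelihood the fixed-beta MAPEM iteration maximises:

    Poisson log-likelihood minus (beta/2) R(theta), with R in the
    quarter-sum convention of :func:`bootrecon.penalties.penalty_value`.
    """
    return poisson_loglik(theta, m, b, geom) - (
        PENALTY_STRENGTH_FACTOR * beta * penalty_value(theta, ctx.weights)
    )


def mlem_update(
    theta: np.ndarray,
    m: np.ndarray,
    b: np.ndarray,
    geom: Geometry,
    sens: np.ndarray | None = None,
) -> np.ndarray:
    """One multiplicative EM step toward the maximum-likelihood image.

    ``sens`` may be supplied to avoid recomputing A^T 1 every call.
    Division guards: bins with zero model mean and zero counts contribute
    nothing; a bin with counts but zero model mean is a model inconsistency
    and is signalled.  Pixels with zero sensitivity stay at zero.
    """
    theta = np.asarray(theta, dtype=float)
    m = np.asarray(m, dtype=float)
    b = np.asarray(b, dtype=float)
    if sens is None:
        sens = sensitivity_image(geom)
    q = forward_project(theta, geom) + b
    bad = (m > 0) & (q == 0)
    if np.any(bad):
        raise ValueError("measured counts in a bin with zero model mean (A theta + b = 0)")
    ratio = np.zeros_like(q)
    pos = q > 0
    ratio[pos] = m[pos] / q[pos]
    bp = back_project(ratio, geom)
    out = np.zeros_like(theta)
    ok = sens > 0
    out[ok] = theta[ok] / sens[ok] * bp[ok]
    return out


def depierro_denoise(
    theta_em: np.ndarray,
    theta_prev: np.ndarray,
    beta: float,
    ctx: PenaltyContext,
) -> np.ndarray:
    """Apply the noise-compensation operator F_beta to an EM update.

    Evaluated in the numerically stable branch of the quadratic-root
    formula (the textbook 2 theta_em / (xi + sqrt(...)) form suffers
    cancellation when xi < 0).
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    theta_em = np.asarray(theta_em, dtype=float)
    if beta == 0:
        return theta_em.copy()
    theta_reg = smoothed_image(np.asarray(theta_prev, dtype=float), ctx.weights)
    return _denoise_core(theta_em, beta, ctx.nu, theta_reg)


def _denoise_core(
    theta_em: np.ndarray, beta: float, nu: np.ndarray, theta_reg: np.ndarray
) -> np.ndarray:
    """Positive root of beta nu x^2 + xi x - theta_em = 0, elementwise."""
    a = beta * nu
    xi = 1.0 - a * theta_reg
    disc = xi**2 + 4.0 * a * theta_em
    if np.any(np.isnan(disc)):
        raise FloatingPointError("NaN in the De Pierro discriminant")
    root = np.sqrt(disc)
    out = np.empty_like(theta_em)
    pos = xi >= 0
    denom = xi + root
    # xi >= 0: stable rationalised form; xi < 0 (only possible when a > 0):
    # direct quadratic root avoids catastrophic cancellation
    np.divide(2.0 * theta_em, denom, out=out, where=pos & (denom > 0))
    out[pos & (denom <= 0)] = 0.0
    neg = ~pos
    if np.any(neg):
        out[neg] = (root[neg] - xi[neg]) / (2.0 * a[neg])
    np.clip(out, 0.0, None, out=out)
    return out


def mapem_fixed_beta(
    m: np.ndarray,
    b: np.ndarray,
    geom: Geometry,
    ctx: PenaltyContext,
    beta: float,
    n_iter: int,
    theta0: np.ndarray | None = None,
    track_objective: bool = True,
) -> ReconResult:
    """Fixed-penalty-strength MAPEM: theta <- F_beta(MLEM(theta)).

    ``beta = 0`` reduces to plain MLEM iterate-for-iterate.
    """
    sens = sensitivity_image(geom)
    if theta0 is None:
        theta = np.where(sens > 0, 1.0, 0.0)
    else:
        theta = np.asarray(theta0, dtype=float).copy()
    obj = []
    for _ in range(n_iter):
        theta_em = mlem_update(theta, m, b, geom, sens=sens)
        theta = depierro_denoise(theta_em, theta, beta, ctx)
        if track_objective:
            obj.append(map_objective(theta, m, b, geom, beta, ctx))
    return ReconResult(image=theta, objective=np.array(obj))
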