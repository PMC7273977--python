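"""Bootstrap-optimised selection of the penalty strength beta.

The idea: at each iteration, the unregularised EM update of the measured
data is a model of the mean of an ensemble of noisy updates, while the EM
update of a bootstrap replicate of the data models one noisy member of
that ensemble.  Fitting the regularised bootstrap update to the measured
update — minimising the masked squared distance

    C(beta) = sum_{j in Omega} ( theta_meas_j - F_beta(theta_boot)_j )^2

over beta (the ensemble-mean objective function, EMOF) — estimates how
much regularisation maps a noisy update onto the ensemble mean.  The
running maximum of the fitted values, beta_use, is retained, and an
exponentially cooled over-regularisation term lambda^(k) beta_opt^(k) is
added on top early on so that low spatial frequencies are fitted before
the noise-dominated high frequencies enter the comparison:

    lambda^(k) = lambda0 exp(-k / N),
    beta_cool^(k) = beta_use^(k) + lambda^(k) beta_opt^(k).

Each iteration then applies theta^(k+1) = F_{beta_cool}(theta_meas).  With
several bootstrap replicates, beta_opt is the maximum of the per-replicate
fits, which guards against a single replicate fitting beta = 0 on
high-count data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .bootstrap import bootstrap_replicates
from .penalties import PenaltyContext, smoothed_image
from .projector import Geometry, fbp, sensitivity_image
from .recon import ReconResult, _denoise_core, depierro_denoise, mlem_update

__all__ = [
    "BetaState",
    "DriverConfig",
    "emof",
    "emof_gradient",
    "optimise_beta",
    "update_beta_use",
    "cooling",
    "multi_bootstrap_beta",
    "reconstruct_bootstrap_optimised",
    "default_emof_mask",
]

logger = logging.getLogger(__name__)


@dataclass
class BetaState:
    """Per-iteration trace of the fitted and applied penalty strengths."""

    beta_opt: list[float] = field(default_factory=list)
    beta_use: list[float] = field(default_factory=list)
    beta_cool: list[float] = field(default_factory=list)
    lambda_k: list[float] = field(default_factory=list)
    emof_value: list[float] = field(default_factory=list)

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v, dtype=float) for k, v in self.__dict__.items()}


@dataclass
class DriverConfig:
    """Settings of the bootstrap-optimised reconstruction driver.

    ``lambda0`` and ``N`` only need to be "large enough"; the selected
    beta plateaus in both.  ``max_iter`` should be at least 3-4 N so the
    over-regularisation has decayed away by the end.
    """

    lambda0: float = 1000.0
    N: int = 100
    max_iter: int = 400
    n_bootstrap: int = 1
    seed: int = 0
    beta_bracket_growth: float = 10.0
    emof_mask: np.ndarray | None = None  # Omega; derived from FBP if absent

    def __post_init__(self) -> None:
        if self.lambda0 <= 0 or self.N < 1 or self.n_bootstrap < 1:
            raise ValueError("lambda0 > 0, N >= 1 and n_bootstrap >= 1 required")
        if self.max_iter < 3 * self.N:
            logger.warning(
                "max_iter=%d is below 3*N=%d; beta may not have settled by the end",
                self.max_iter,
                3 * self.N,
            )


# ---------------------------------------------------------------------------
# EMOF and its 1D optimisation


class _EmofProblem:
    """Caches the beta-independent pieces of C(beta) on the mask."""

    def __init__(
        self,
        theta_meas: np.ndarray,
        theta_boot_em: np.ndarray,
        theta_prev: np.ndarray,
        ctx: PenaltyContext,
        mask: np.ndarray,
    ) -> None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("EMOF mask is empty")
        theta_reg = smoothed_image(np.asarray(theta_prev, dtype=float), ctx.weights)
        self.meas = np.asarray(theta_meas, dtype=float)[mask]
        self.boot = np.asarray(theta_boot_em, dtype=float)[mask]
        self.nu = ctx.nu[mask]
        self.reg = theta_reg[mask]

    def _f(self, beta: float) -> np.ndarray:
        if beta == 0:
            return self.boot
        return _denoise_core(self.boot, beta, self.nu, self.reg)

    def value(self, beta: float) -> float:
        return float(np.sum((self.meas - self._f(beta)) ** 2))

    def gradient(self, beta: float) -> float:
        f = self._f(beta)
        a = beta * self.nu
        xi = 1.0 - a * self.reg
        root = np.sqrt(xi**2 + 4.0 * a * self.boot)
        # implicit differentiation of a f^2 + xi f - theta_boot = 0:
        # df/dbeta = -nu f (f - theta_reg) / sqrt(disc)
        df = np.zeros_like(f)
        ok = root > 0
        df[ok] = -self.nu[ok] * f[ok] * (f[ok] - self.reg[ok]) / root[ok]
        return float(np.sum(-2.0 * (self.meas - f) * df))


def emof(
    beta: float,
    theta_meas: np.ndarray,
    theta_boot_em: np.ndarray,
    theta_prev: np.ndarray,
    ctx: PenaltyContext,
    mask: np.ndarray,
) -> float:
    """Ensemble-mean objective: masked squared distance between the
    measured-data EM update and the regularised bootstrap EM update."""
    return _EmofProblem(theta_meas, theta_boot_em, theta_prev, ctx, mask).value(beta)


def emof_gradient(
    beta: float,
    theta_meas: np.ndarray,
    theta_boot_em: np.ndarray,
    theta_prev: np.ndarray,
    ctx: PenaltyContext,
    mask: np.ndarray,
) -> float:
    """Analytic dC/dbeta via the implicit derivative of the quadratic root."""
    return _EmofProblem(theta_meas, theta_boot_em, theta_prev, ctx, mask).gradient(beta)


def _bracket_upper(problem: _EmofProblem, growth: float, max_expand: int = 12) -> float:
    """Grow beta_hi geometrically until the objective is rising again."""
    hi = 1.0
    prev = problem.value(hi / growth)
    for _ in range(max_expand):
        cur = problem.value(hi)
        if cur > prev:
            return hi
        prev = cur
        hi *= growth
    return hi / growth


def _refine(problem: _EmofProblem, lo: float, hi: float) -> tuple[float, float]:
    if hi <= lo:
        return lo, problem.value(lo)
    res = minimize_scalar(
        problem.value,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": max(1e-3 * hi, 1e-12)},
    )
    return float(res.x), float(res.fun)


def optimise_beta(
    theta_meas: np.ndarray,
    theta_boot_em: np.ndarray,
    theta_prev: np.ndarray,
    ctx: PenaltyContext,
    mask: np.ndarray,
    bracket_growth: float = 10.0,
    beta_warm: float | None = None,
) -> tuple[float, float]:
    """argmin_beta of the EMOF on [0, beta_hi]; returns (beta_opt, C(beta_opt)).

    beta_hi is found by geometric bracket expansion; a coarse log-spaced
    scan then seeds a bounded 1D minimisation (plus a second start warm-
    started at the previous iteration's fit), and the boundary beta = 0 is
    always admitted.  beta_opt = 0 is a legal outcome.
    """
    problem = _EmofProblem(theta_meas, theta_boot_em, theta_prev, ctx, mask)
    hi = _bracket_upper(problem, bracket_growth)

    candidates: list[tuple[float, float]] = [(0.0, problem.value(0.0))]
    grid = np.geomspace(hi * 1e-9, hi, 80)
    vals = [problem.value(b) for b in grid]
    i_best = int(np.argmin(vals))
    lo_g = grid[max(i_best - 1, 0)]
    hi_g = grid[min(i_best + 1, len(grid) - 1)]
    candidates.append(_refine(problem, lo_g, hi_g))
    candidates.append((float(grid[i_best]), float(vals[i_best])))
    if beta_warm is not None and beta_warm > 0:
        candidates.append(
            _refine(problem, beta_warm / bracket_growth, min(beta_warm * bracket_growth, hi))
        )
    beta, val = min(candidates, key=lambda c: c[1])
    if beta > 0:  # polish to fine relative precision around the winner
        res = minimize_scalar(
            problem.value,
            bounds=(beta / 2, beta * 2),
            method="bounded",
            options={"xatol": 1e-5 * beta},
        )
        if res.fun <= val:
            beta, val = float(res.x), float(res.fun)
    return beta, val


def update_beta_use(beta_opt_history: list[float] | np.ndarray) -> float:
    """Running maximum of the fitted values so far."""
    history = np.asarray(beta_opt_history, dtype=float)
    if history.size == 0:
        raise ValueError("beta_opt history is empty")
    return float(history.max())


def cooling(
    k: int, lambda0: float, N: int, beta_use: float, beta_opt: float
) -> tuple[float, float]:
    """Over-regularisation factor and applied beta at iteration k:
    lambda = lambda0 exp(-k/N), beta_cool = beta_use + lambda * beta_opt."""
    lam = lambda0 * math.exp(-k / N)
    return lam, beta_use + lam * beta_opt


def multi_bootstrap_beta(per_replicate: list[float] | np.ndarray) -> float:
    """Combine per-replicate fits: take the maximum (guards against a
    single replicate yielding beta = 0 on high-count data)."""
    vals = np.asarray(per_replicate, dtype=float)
    if vals.size == 0:
        raise ValueError("no per-replicate beta values")
    return float(vals.max())


def default_emof_mask(
    m: np.ndarray, b: np.ndarray, geom: Geometry, threshold_frac: float = 0.10
) -> np.ndarray:
    """Object mask from an FBP reconstruction of the background-corrected
    data: threshold at a fraction of the 99th percentile, fill holes, keep
    the largest connected component."""
    from .evaluate import make_mask  # local import to avoid a cycle

    recon = fbp(np.clip(np.asarray(m, dtype=float) - b, 0, None), geom, clip_negative=True)
    return make_mask(recon, threshold_frac=threshold_frac)


def reconstruct_bootstrap_optimised(
    m: np.ndarray,
    b: np.ndarray,
    geom: Geometry,
    ctx: PenaltyContext,
    cfg: DriverConfig,
) -> ReconResult:
    """Full bootstrap-optimised regularised reconstruction.

    Bootstrap replicates are generated once, before iterating, and held
    fixed.  Each iteration computes the unregularised EM updates of the
    measured data and of every replicate, fits beta on the EMOF mask,
    updates the running maximum and the cooling term, and applies
    F_{beta_cool} to the measured-data update.
    """
    m = np.asarray(m)
    sens = sensitivity_image(geom)
    theta = np.where(sens > 0, 1.0, 0.0)
    mask = cfg.emof_mask
    if mask is None:
        mask = default_emof_mask(m, b, geom)
    replicates = bootstrap_replicates(m, cfg.n_bootstrap, seed=cfg.seed)

    state = BetaState()
    beta_warm: float | None = None
    for k in range(1, cfg.max_iter + 1):
        theta_meas = mlem_update(theta, m, b, geom, sens=sens)
        fits = [
            optimise_beta(
                theta_meas,
                mlem_update(theta, rep, b, geom, sens=sens),
                theta,
                ctx,
                mask,
                bracket_growth=cfg.beta_bracket_growth,
                beta_warm=beta_warm,
            )
            for rep in replicates
        ]
        beta_opt = multi_bootstrap_beta([f[0] for f in fits])
        emof_val = min(f[1] for f in fits)
        beta_warm = beta_opt if beta_opt > 0 else beta_warm
        state.beta_opt.append(beta_opt)
        beta_use = update_beta_use(state.beta_opt)
        state.beta_use.append(beta_use)
        lam, beta_cool = cooling(k, cfg.lambda0, cfg.N, beta_use, beta_opt)
        state.lambda_k.append(lam)
        state.beta_cool.append(beta_cool)
        state.emof_value.append(emof_val)
        theta = depierro_denoise(theta_meas, theta, beta_cool, ctx)

    if state.beta_use[-1] == 0:
        logger.warning(
            "final beta_use is 0: no regularisation was selected; consider "
            "n_bootstrap > 1 (single replicates can fit beta = 0 on "
            "high-count data)"
        )
    return ReconResult(
        image=theta,
        objective=np.array([]),
        beta_trace=state,
        diagnostics={"mask": mask, "final_beta": state.beta_cool[-1]},
    )
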