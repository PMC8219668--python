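"""Michaelis–Menten parameter estimation on insoluble-substrate rate data.

The forward model is the conventional hyperbola applied to mass loads,

    v_ss = E0 · k_cat · S0 / (S0 + K_M),

with S0 and the apparent K_M expressed in g/L because the substrate is an
insoluble solid. Parameters are estimated by unweighted nonlinear least
squares over all replicate points (pooled fit); internally the optimizer
works in (ln k_cat, ln K_M) so positivity is enforced without active
bounds. Standard deviations come from the Gauss–Newton covariance at the
optimum, mapped back from log space by first-order error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .datamodel import KineticParams, MMDataset
from .errors import ConvergenceError, NoSignalError, ValidationError

#: Fitted K_M beyond this multiple of the largest load marks a
#: non-saturating design in which k_cat and K_M are strongly correlated.
NON_SATURATING_FACTOR = 10.0


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_michaelis_menten`."""

    max_iterations: int = 1000
    relative_tolerance: float = 1e-10
    pool_replicates: bool = True

    def __post_init__(self) -> None:
        if self.relative_tolerance <= 0:
            raise ValidationError("relative_tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


def mm_rate(S0, E0: float, k_cat: float, K_M: float):
    """Quasi-steady-state rate v_ss (µM·s⁻¹) of the hyperbolic model."""
    S0 = np.asarray(S0, dtype=float)
    return E0 * k_cat * S0 / (S0 + K_M)


def _flatten(dataset: MMDataset, pool: bool) -> tuple[np.ndarray, np.ndarray]:
    if pool:
        loads = np.concatenate(
            [np.full(len(r), s) for s, r in zip(dataset.loads, dataset.rates)]
        )
        rates = np.concatenate([np.asarray(r, dtype=float) for r in dataset.rates])
    else:
        loads = np.asarray(dataset.loads, dtype=float)
        rates = np.array([np.mean(r) for r in dataset.rates])
    return loads, rates


def _initial_guess(dataset: MMDataset, E0: float) -> tuple[float, float]:
    means = np.array([np.mean(r) for r in dataset.rates])
    loads = np.asarray(dataset.loads)
    vmax = means.max()
    k_cat0 = 1.2 * vmax / E0
    above_half = loads[means > 0.5 * vmax]
    K_M0 = float(above_half.min()) if above_half.size else float(loads[len(loads) // 2])
    return max(k_cat0, 1e-12), max(K_M0, 1e-12)


def fit_michaelis_menten(dataset: MMDataset, config: FitConfig | None = None) -> KineticParams:
    """Fit (k_cat, K_M) to one enzyme's rate-vs-load data.

    Minimizes the unweighted sum of squared residuals over all replicate
    points (or replicate means when ``pool_replicates`` is off). The fit
    is deterministic given the data and configuration. Output flags:
    ``non_saturating`` when K_M exceeds ten times the largest load.

    Raises
    ------
    NoSignalError
        If every measured rate is zero.
    ConvergenceError
        If the optimizer does not converge within ``max_iterations``;
        the exception carries the last iterate.
    """
    config = config or FitConfig()
    loads, rates = _flatten(dataset, config.pool_replicates)
    if np.all(rates == 0):
        raise NoSignalError(f"{dataset.enzyme_id}: all rates are zero")
    E0 = dataset.enzyme_conc

    def residuals(theta):
        k_cat, K_M = np.exp(theta)
        return mm_rate(loads, E0, k_cat, K_M) - rates

    theta0 = np.log(_initial_guess(dataset, E0))
    result = least_squares(
        residuals,
        theta0,
        method="lm",
        xtol=config.relative_tolerance,
        ftol=config.relative_tolerance,
        gtol=config.relative_tolerance,
        max_nfev=config.max_iterations * 10,
    )
    if not result.success:
        raise ConvergenceError(
            f"{dataset.enzyme_id}: MM fit did not converge ({result.message})",
            last_iterate=np.exp(result.x),
        )
    k_cat, K_M = np.exp(result.x)

    # Heteroscedasticity-consistent (HC3) covariance in log space, then
    # var(p) = p^2 var(ln p). The classical s^2 (J'J)^-1 formula assumes
    # constant error variance; rate noise is closer to multiplicative,
    # and the sandwich form keeps the confidence intervals honest either
    # way while leaving the unweighted point estimate untouched.
    J, r = result.jac, result.fun
    try:
        bread = np.linalg.inv(J.T @ J)
        leverage = np.clip(np.einsum("ij,jk,ik->i", J, bread, J), 0.0, 1.0 - 1e-8)
        weights = r**2 / (1.0 - leverage) ** 2
        cov_log = bread @ (J.T @ (weights[:, None] * J)) @ bread
        sd_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
    except np.linalg.LinAlgError:
        sd_log = np.full(2, np.nan)
    sd_kcat = k_cat * sd_log[0] if math.isfinite(sd_log[0]) else 0.0
    sd_km = K_M * sd_log[1] if math.isfinite(sd_log[1]) else 0.0

    flags = []
    if K_M > NON_SATURATING_FACTOR * max(dataset.loads):
        flags.append("non_saturating")
    return KineticParams(
        enzyme_id=dataset.enzyme_id,
        k_cat=float(k_cat),
        K_M=float(K_M),
        sd_kcat=float(sd_kcat),
        sd_km=float(sd_km),
        source="fitted",
        flags=tuple(flags),
    )


def specificity_constant(params: KineticParams) -> tuple[float, float]:
    """k_cat/K_M (s⁻¹·(g/L)⁻¹) with first-order propagated uncertainty.

    The relative variance of the ratio is the sum of the relative
    variances of k_cat and K_M, assuming independent errors.
    """
    ratio = params.k_cat / params.K_M
    rel = math.hypot(params.sd_kcat / params.k_cat, params.sd_km / params.K_M)
    return ratio, ratio * rel
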