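"""Calibration of computed binding energies and LFER-based prediction.

Binding free energies computed by physics-based methods systematically
overestimate the experimental scale for carbohydrate binding, so a
linear transformation is fitted by regressing experimental ΔΔG°_B
values (from K_M ratios) on the computed ones. The fitted line maps new
computed energies onto the experimental scale; combined with the LFER
(ΔΔG‡ = Φ·ΔΔG°_B) and a reference enzyme it predicts both kinetic
parameters of an uncharacterized enzyme from its computed binding
energy alone:

    K_M    = K_M,ref · exp(ΔΔG°_B / RT)
    k_cat  = k_cat,ref · exp(−Φ·ΔΔG°_B / RT)

Computed inputs must be normalized to the same reference enzyme as the
experimental set (the reference's computed value must be zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .datamodel import Constants, KineticParams
from .errors import DegenerateDesignError, DomainError, InsufficientDataError
from .lfer import ScalingFit


@dataclass(frozen=True)
class CalibrationFit:
    """Linear map from computed to experimental binding energies.

    ``rmse_raw`` is the root-mean-square error of the uncalibrated
    computed values against experiment; ``rmse_calibrated`` the training
    RMSE after applying the fitted line (never larger, by least
    squares). ``rmse_loo`` is the leave-one-out cross-validated RMSE —
    an honest estimate for unseen enzymes.
    """

    slope: float
    intercept: float
    r_squared: float
    rmse_raw: float
    rmse_calibrated: float
    n: int
    rmse_loo: float = float("nan")

    def apply(self, ddg_computed) -> np.ndarray | float:
        """Map computed ΔΔG°_B (kJ/mol) onto the experimental scale."""
        return self.slope * np.asarray(ddg_computed, dtype=float) + self.intercept


def fit_calibration(computed: Sequence[float], experimental: Sequence[float],
                    loo: bool = True) -> CalibrationFit:
    """OLS of experimental ΔΔG°_B on computed ΔΔG°_B (both kJ/mol).

    Raises :class:`InsufficientDataError` for n < 3 and
    :class:`DegenerateDesignError` when the computed values have zero
    variance.
    """
    x = np.asarray(computed, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if x.shape != y.shape:
        raise DomainError("computed and experimental lists must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("energies must be finite")
    if x.size < 3:
        raise InsufficientDataError(f"calibration needs >= 3 enzymes, have {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in computed energies")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    fitted = intercept + slope * x
    rmse_raw = float(np.sqrt(np.mean((y - x) ** 2)))
    rmse_cal = float(np.sqrt(np.mean((y - fitted) ** 2)))

    rmse_loo = float("nan")
    if loo and x.size > 3:
        errs = []
        for i in range(x.size):
            mask = np.arange(x.size) != i
            r = sm.OLS(y[mask], sm.add_constant(x[mask])).fit()
            errs.append(y[i] - (r.params[0] + r.params[1] * x[i]))
        rmse_loo = float(np.sqrt(np.mean(np.square(errs))))

    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(res.rsquared),
        rmse_raw=rmse_raw,
        rmse_calibrated=rmse_cal,
        n=int(x.size),
        rmse_loo=rmse_loo,
    )


def check_reference_normalization(ddg_computed_ref: float, tol: float = 1e-9) -> None:
    """Assert the reference enzyme's computed energy is zero (within tol)."""
    if abs(ddg_computed_ref) > tol:
        raise DomainError(
            "computed energies must be normalized to the reference enzyme "
            f"(its value is {ddg_computed_ref:g}, expected 0)"
        )


def predict_kinetics_from_binding(
    ddg_b_computed: float,
    calib: CalibrationFit,
    scaling: ScalingFit,
    reference: KineticParams,
    constants: Constants | None = None,
) -> tuple[float, float]:
    """Predict (K_M in g/L, k_cat in s⁻¹) from a computed binding energy.

    The computed ΔΔG°_B is first put on the experimental scale via the
    calibration line, then inverted through the binding relation for
    K_M and pushed through the LFER for k_cat. The prediction lies
    exactly on the fitted scaling line in (ln K_M, ln k_cat) space,
    anchored at the reference enzyme.
    """
    if not math.isfinite(ddg_b_computed):
        raise DomainError("computed binding energy must be finite")
    constants = constants or Constants()
    rt = constants.rt
    ddg_b = float(calib.apply(ddg_b_computed))
    ddg_act = scaling.phi * ddg_b
    K_M = reference.K_M * math.exp(ddg_b / rt)
    k_cat = reference.k_cat * math.exp(-ddg_act / rt)
    return K_M, k_cat
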