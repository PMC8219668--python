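"""Linear free energy relationship (LFER) between binding and activation.

Kinetic parameters map to free-energy changes relative to a reference
enzyme:

    ΔΔG°_B = R·T·ln(K_M / K_M,ref)          (binding)
    ΔΔG‡  = −R·T·ln(k_cat / k_cat,ref)      (activation)

so the reference enzyme sits at (0, 0) by construction. An LFER is a
proportionality ΔΔG‡ = Φ·ΔΔG°_B; because both energies are R·T times a
log-ratio, Φ is exactly the negative of the slope of the regression of
ln k_cat on ln K_M, independent of temperature and of the reference
choice. The scaling line is fitted by ordinary least squares with
iterated outlier rejection on externally studentized residuals
(leave-one-out variance), and 95% confidence/prediction bands are
evaluated on a grid spanning the retained points.

The Φ value classifies the energetic origin of kinetic diversity:
Φ = 0 means uniform binding (ground state and transition state shift
together), Φ = −1 pure ground-state stabilization (fixed transition
state), and |Φ| → ∞ pure transition-state stabilization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .datamodel import AnalysisConfig, Constants, KineticParams
from .errors import DegenerateDesignError, DomainError, InsufficientDataError

N_BAND_POINTS = 200


def ddg_binding(K_M: float, K_M_ref: float, T: float | None = None,
                constants: Constants | None = None) -> float:
    """Binding free-energy change ΔΔG°_B (kJ/mol) relative to the reference.

    Positive for weaker binding (larger K_M) than the reference.
    """
    constants = _constants(T, constants)
    if K_M <= 0 or K_M_ref <= 0:
        raise DomainError("K_M values must be > 0")
    return constants.rt * math.log(K_M / K_M_ref)


def ddg_activation(k_cat: float, k_cat_ref: float, T: float | None = None,
                   constants: Constants | None = None) -> float:
    """Activation free-energy change ΔΔG‡ (kJ/mol) relative to the reference.

    Negative for faster turnover (larger k_cat) than the reference.
    """
    constants = _constants(T, constants)
    if k_cat <= 0 or k_cat_ref <= 0:
        raise DomainError("k_cat values must be > 0")
    return -constants.rt * math.log(k_cat / k_cat_ref)


def _constants(T: float | None, constants: Constants | None) -> Constants:
    if constants is not None and T is not None and T != constants.temperature:
        raise DomainError("give either T or constants, not conflicting both")
    if constants is not None:
        return constants
    if T is not None:
        return Constants(temperature=T)
    return Constants()


@dataclass(frozen=True)
class EnergyDelta:
    """Relative free energies (kJ/mol) of one enzyme: (ΔΔG°_B, ΔΔG‡)."""

    enzyme_id: str
    ddg_binding: float
    ddg_activation: float
    sd_ddg_binding: float = 0.0
    sd_ddg_activation: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.ddg_binding, self.ddg_activation,
                self.sd_ddg_binding, self.sd_ddg_activation)
        if not all(math.isfinite(v) for v in vals):
            raise DomainError(f"{self.enzyme_id}: free energies must be finite")


def energy_deltas(points: Sequence[KineticParams], reference: KineticParams,
                  constants: Constants | None = None) -> list[EnergyDelta]:
    """Map kinetic parameters to (ΔΔG°_B, ΔΔG‡) pairs against ``reference``.

    Parameter SDs propagate as sd(ΔΔG) = R·T·sd(p)/p to first order.
    """
    constants = constants or Constants()
    rt = constants.rt
    out = []
    for p in points:
        out.append(
            EnergyDelta(
                enzyme_id=p.enzyme_id,
                ddg_binding=ddg_binding(p.K_M, reference.K_M, constants=constants),
                ddg_activation=ddg_activation(p.k_cat, reference.k_cat, constants=constants),
                sd_ddg_binding=rt * p.sd_km / p.K_M,
                sd_ddg_activation=rt * p.sd_kcat / p.k_cat,
            )
        )
    return out


@dataclass(frozen=True)
class Bands:
    """Confidence and prediction intervals sampled on an x-grid."""

    x: tuple[float, ...]
    fit: tuple[float, ...]
    conf_lo: tuple[float, ...]
    conf_hi: tuple[float, ...]
    pred_lo: tuple[float, ...]
    pred_hi: tuple[float, ...]
    level: float = 0.95


@dataclass(frozen=True)
class ScalingFit:
    """Fitted scaling line ln k_cat = ln A + a·ln K_M, with Φ = −a."""

    slope_a: float
    intercept_lnA: float
    se_slope: float
    se_intercept: float
    r_squared: float
    n_used: int
    n_outliers: int
    outlier_ids: tuple[str, ...]
    bands: Bands
    point_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def phi(self) -> float:
        """LFER proportionality constant; identical magnitude, opposite
        sign to the log-log slope."""
        return -self.slope_a

    @property
    def se_phi(self) -> float:
        return self.se_slope


def _ols(x: np.ndarray, y: np.ndarray):
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 points for the scaling fit, have {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in x: scaling line undefined")
    return sm.OLS(y, sm.add_constant(x)).fit()


def fit_scaling(points: Sequence[KineticParams],
                config: AnalysisConfig | None = None) -> ScalingFit:
    """Fit the scaling line to (ln K_M, ln k_cat) with outlier rejection.

    Externally studentized residuals are computed for the current fit;
    while any exceeds ``config.outlier_cutoff`` in magnitude, the single
    worst point is removed and the line refitted (ties broken by input
    order; single-pass removal available via ``outlier_iterate=False``).
    The returned fit, r², and bands refer to the retained points only;
    ``outlier_ids`` lists removals in removal order.
    """
    config = config or AnalysisConfig()
    ids = [p.enzyme_id for p in points]
    x = np.log([p.K_M for p in points])
    y = np.log([p.k_cat for p in points])

    retained = list(range(len(points)))
    removed: list[int] = []
    while True:
        res = _ols(x[retained], y[retained])
        # An (all but) exact fit leaves only floating-point noise in the
        # residuals; studentizing that noise would flag arbitrary points.
        if res.ssr <= 1e-24 * max(1.0, float(np.sum(np.square(y[retained])))):
            break
        student = OLSInfluence(res).resid_studentized_external
        worst = int(np.argmax(np.abs(student)))
        if abs(student[worst]) <= config.outlier_cutoff:
            break
        if config.outlier_iterate:
            removed.append(retained.pop(worst))
        else:
            over = [i for i, t in enumerate(student) if abs(t) > config.outlier_cutoff]
            removed.extend(retained[i] for i in over)
            retained = [i for k, i in enumerate(retained) if k not in set(over)]
            res = _ols(x[retained], y[retained])
            break

    intercept, slope = res.params
    se_intercept, se_slope = res.bse
    with np.errstate(divide="ignore", invalid="ignore"):
        r_squared = float(res.rsquared)  # -inf/nan when y has zero variance
    if res.ssr <= 1e-300 and not math.isfinite(r_squared):
        r_squared = 1.0
    bands = _bands(res, x[retained], config.band_level)
    return ScalingFit(
        slope_a=float(slope),
        intercept_lnA=float(intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        r_squared=r_squared,
        n_used=len(retained),
        n_outliers=len(removed),
        outlier_ids=tuple(ids[i] for i in removed),
        bands=bands,
        point_ids=tuple(ids[i] for i in retained),
    )


def _bands(res, x_used: np.ndarray, level: float) -> Bands:
    grid = np.linspace(x_used.min(), x_used.max(), N_BAND_POINTS)
    pred = res.get_prediction(sm.add_constant(grid))
    conf = pred.conf_int(alpha=1 - level)
    obs = pred.conf_int(obs=True, alpha=1 - level)
    return Bands(
        x=tuple(grid),
        fit=tuple(pred.predicted_mean),
        conf_lo=tuple(conf[:, 0]),
        conf_hi=tuple(conf[:, 1]),
        pred_lo=tuple(obs[:, 0]),
        pred_hi=tuple(obs[:, 1]),
        level=level,
    )


def fit_scaling_energies(deltas: Sequence[EnergyDelta],
                         config: AnalysisConfig | None = None):
    """OLS of ΔΔG‡ on ΔΔG°_B; the slope is Φ directly.

    Algebraically the dual of :func:`fit_scaling`: R·T cancels from both
    axes, so this slope equals −(log-space slope) to machine precision.
    Returns the statsmodels results object.
    """
    x = np.array([d.ddg_binding for d in deltas])
    y = np.array([d.ddg_activation for d in deltas])
    return _ols(x, y)


def phi_from_scaling(fit: ScalingFit) -> tuple[float, float]:
    """Extract (Φ, SE(Φ)) from a fitted scaling line; Φ = −slope."""
    return fit.phi, fit.se_phi


@dataclass(frozen=True)
class RegimeThresholds:
    """Decision bounds for :func:`classify_regime` (dimensionless Φ)."""

    uniform_abs: float = 0.15
    ts_abs: float = 3.0
    gs_cutoff: float = -0.85
    gs_dominated_cutoff: float = -0.5


def classify_regime(phi: float,
                    thresholds: RegimeThresholds | None = None) -> tuple[str, str | None]:
    """Classify the energetic regime implied by a Φ value.

    Returns ``(label, annotation)`` where label is one of
    ``uniform_binding`` (|Φ| small: ground and transition state move
    together), ``ts_stabilization`` (|Φ| large: activation energy varies
    independently of binding), ``gs_stabilization`` (Φ near −1: fixed
    transition state) or ``intermediate``. An intermediate Φ between the
    GS cutoff and −0.5 carries the ``gs_dominated`` annotation.
    """
    if not math.isfinite(phi):
        raise DomainError("phi must be finite")
    t = thresholds or RegimeThresholds()
    if abs(phi) <= t.uniform_abs:
        return "uniform_binding", None
    if abs(phi) >= t.ts_abs:
        return "ts_stabilization", None
    if phi <= t.gs_cutoff:
        return "gs_stabilization", None
    annotation = "gs_dominated" if t.gs_cutoff < phi <= t.gs_dominated_cutoff else None
    return "intermediate", annotation
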