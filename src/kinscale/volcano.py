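"""Volcano rate model: the scaling line turned into a rate predictor.

Exponentiating the LFER gives a power law k_cat = A·K_M^a with a = −Φ
and A = k_cat,ref / K_M,ref^(−Φ). Substituting it into the
Michaelis–Menten equation expresses the quasi-steady-state rate as a
function of K_M alone,

    v_ss(K_M) = E0 · A · K_M^a · S0 / (S0 + K_M),

which for 0 < a < 1 has a single interior maximum at

    K_M,opt = S0 · a / (1 − a).

This is the Sabatier picture: enzymes binding tighter than the optimum
(K_M < K_M,opt) gain rate from weaker binding, and vice versa. The
curves carry no free parameters beyond the reference pair and the fitted
slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class VolcanoModel:
    """Power-law rate model k_cat = A·K_M^a.

    ``amplitude_A`` has units (s⁻¹)·(g/L)^(−a); ``valid_range`` is the
    K_M interval spanned by the underlying scaling fit — predictions
    outside it are extrapolations and trigger a warning, not an error.
    """

    amplitude_A: float
    exponent_a: float
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.amplitude_A <= 0:
            raise ValidationError("amplitude_A must be > 0")

    @classmethod
    def from_reference(cls, k_cat_ref: float, K_M_ref: float, phi: float,
                       valid_range: tuple[float, float] | None = None) -> "VolcanoModel":
        """Construct from the reference enzyme and the LFER Φ.

        A = k_cat,ref / K_M,ref^(−Φ), so the power law passes exactly
        through the reference point.
        """
        if k_cat_ref <= 0 or K_M_ref <= 0:
            raise DomainError("reference parameters must be > 0")
        a = -phi
        return cls(amplitude_A=k_cat_ref / K_M_ref ** (-phi), exponent_a=a,
                   valid_range=valid_range)


def predict_kcat(K_M, model: VolcanoModel):
    """Predicted turnover A·K_M^a (s⁻¹); warns outside the fitted range."""
    K_M = np.asarray(K_M, dtype=float)
    if np.any(K_M <= 0):
        raise DomainError("K_M must be > 0")
    if model.valid_range is not None:
        lo, hi = model.valid_range
        if np.any((K_M < lo) | (K_M > hi)):
            warnings.warn(
                f"K_M outside the fitted range [{lo:g}, {hi:g}] g/L: "
                "prediction is an extrapolation",
                stacklevel=2,
            )
    out = model.amplitude_A * K_M ** model.exponent_a
    return float(out) if out.ndim == 0 else out


def volcano_rate(K_M, S0: float, E0: float, model: VolcanoModel):
    """Rate v_ss = E0·A·K_M^a·S0/(S0+K_M) in µM·s⁻¹."""
    K_M = np.asarray(K_M, dtype=float)
    if np.any(K_M <= 0) or S0 <= 0 or E0 <= 0:
        raise DomainError("K_M, S0 and E0 must all be > 0")
    out = E0 * predict_kcat(K_M, model) * S0 / (S0 + K_M)
    return float(out) if np.ndim(out) == 0 else out


def optimal_km(S0: float, a: float) -> float:
    """Rate-maximizing affinity K_M,opt = S0·a/(1−a) (g/L).

    Only defined for 0 < a < 1; at the boundaries the rate has no
    interior maximum (a→1 favors arbitrarily weak binding, a≤0 favors
    arbitrarily tight binding).
    """
    if S0 <= 0:
        raise DomainError("S0 must be > 0")
    if not 0 < a < 1:
        raise DomainError(f"optimal K_M requires 0 < a < 1, got a={a}")
    return S0 * a / (1.0 - a)


def volcano_curves(S0_list: Sequence[float], K_M_grid: Sequence[float],
                   E0: float, model: VolcanoModel) -> pd.DataFrame:
    """Volcano curves at several loads, with the analytic optimum marked.

    Returns a long-format frame (``S0``, ``K_M``, ``v_ss``,
    ``is_optimum``); for each load the row flagged ``is_optimum`` is the
    analytic maximum appended to the grid.
    """
    grid = np.asarray(K_M_grid, dtype=float)
    if np.any(grid <= 0) or any(s <= 0 for s in S0_list):
        raise DomainError("loads and K_M grid points must be > 0")
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extrapolation warned once per call below
        for s0 in S0_list:
            frames.append(pd.DataFrame({
                "S0": s0,
                "K_M": grid,
                "v_ss": volcano_rate(grid, s0, E0, model),
                "is_optimum": False,
            }))
            km_opt = optimal_km(s0, model.exponent_a)
            frames.append(pd.DataFrame({
                "S0": [s0],
                "K_M": [km_opt],
                "v_ss": [volcano_rate(km_opt, s0, E0, model)],
                "is_optimum": [True],
            }))
    if model.valid_range is not None:
        lo, hi = model.valid_range
        if grid.min() < lo or grid.max() > hi:
            warnings.warn(
                f"curve grid extends beyond the fitted K_M range [{lo:g}, {hi:g}] g/L",
                stacklevel=2,
            )
    return pd.concat(frames, ignore_index=True)
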