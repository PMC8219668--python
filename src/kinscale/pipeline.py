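"""End-to-end orchestration: rates → MM fits → energies → LFER → volcano."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, EnzymeRecord, KineticParams, MMDataset
from .errors import KinscaleError
from .lfer import EnergyDelta, ScalingFit, energy_deltas, fit_scaling
from .mm import FitConfig, fit_michaelis_menten
from .volcano import VolcanoModel, volcano_curves

DEFAULT_DEMO_LOADS = (1.0, 5.0, 10.0, 50.0, 100.0)


@dataclass(frozen=True)
class PipelineResult:
    """Bundle of every stage output of one analysis run."""

    kinetics: tuple[tuple[EnzymeRecord, KineticParams], ...]
    energies: tuple[EnergyDelta, ...]
    scaling: ScalingFit
    volcano_model: VolcanoModel
    curves: pd.DataFrame


def find_reference(params: Sequence[KineticParams], reference_id: str) -> KineticParams:
    """Locate the reference enzyme's parameters; no silent fallback.

    Relative free energies are meaningless without an explicit anchor,
    so a missing reference is a configuration error, not a default.
    """
    for p in params:
        if p.enzyme_id == reference_id:
            return p
    raise KinscaleError(
        f"reference enzyme {reference_id!r} not found in the parameter table; "
        "supply its (K_M, k_cat) explicitly or choose another reference"
    )


def fit_all(datasets: Sequence[MMDataset],
            fit_config: FitConfig | None = None) -> list[KineticParams]:
    """Fit Michaelis–Menten parameters for every dataset."""
    return [fit_michaelis_menten(ds, fit_config) for ds in datasets]


def run_pipeline(
    kinetics: Sequence[tuple[EnzymeRecord, KineticParams]],
    config: AnalysisConfig | None = None,
    demo_loads: Sequence[float] = DEFAULT_DEMO_LOADS,
    E0: float = 0.1,
    n_grid: int = 200,
) -> PipelineResult:
    """Run energy mapping, scaling fit and volcano prediction.

    ``kinetics`` may come from MM fits (:func:`fit_all`), a read table,
    or a synthetic ensemble. The volcano model is anchored at the
    configured reference enzyme with the fitted Φ, and demonstration
    curves are generated at ``demo_loads`` over a log grid spanning the
    observed K_M range.
    """
    config = config or AnalysisConfig()
    params = [p for _, p in kinetics]
    reference = find_reference(params, config.reference_enzyme_id)
    deltas = energy_deltas(params, reference, config.constants)
    scaling = fit_scaling(params, config)

    km_values = [p.K_M for p in params]
    valid_range = (min(km_values), max(km_values))
    model = VolcanoModel.from_reference(
        reference.k_cat, reference.K_M, scaling.phi, valid_range=valid_range
    )
    grid = np.geomspace(valid_range[0], valid_range[1], n_grid)
    curves = volcano_curves(demo_loads, grid, E0, model)
    return PipelineResult(
        kinetics=tuple(kinetics),
        energies=tuple(deltas),
        scaling=scaling,
        volcano_model=model,
        curves=curves,
    )
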