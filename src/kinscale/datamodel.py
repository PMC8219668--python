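"""Domain types and physical constants shared by every pipeline stage.

Units are fixed package-wide and never converted silently:

========================  =============================
quantity                  unit
========================  =============================
substrate load S0, K_M    g/L (mass load; the substrate
                          is insoluble, so molarity is
                          undefined)
enzyme concentration E0   µM
steady-state rate v_ss    µM product · s⁻¹
turnover number k_cat     s⁻¹
free energies             kJ/mol
temperature               K
========================  =============================

All logarithms in the analysis are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ValidationError

#: Molar gas constant in kJ·mol⁻¹·K⁻¹.
GAS_CONSTANT_KJ = 0.0083145

#: Default experimental temperature (25 °C) in kelvin.
DEFAULT_TEMPERATURE_K = 298.15

GH_FAMILIES = frozenset({5, 6, 7, 12, 45})
MODES = frozenset({"CBH", "EG", "unknown"})


@dataclass(frozen=True)
class Constants:
    """Physical constants for free-energy mapping.

    A single instance is threaded through a run so that a temperature
    override propagates to every free-energy operation consistently.
    """

    gas_constant: float = GAS_CONSTANT_KJ
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.gas_constant <= 0:
            raise ValidationError("gas_constant must be strictly positive")
        if self.temperature <= 0:
            raise ValidationError("temperature must be strictly positive")

    @property
    def rt(self) -> float:
        """R·T in kJ/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class EnzymeRecord:
    """Identity and structural/functional annotation of one enzyme.

    ``gh_family`` is the glycoside-hydrolase sequence family (5, 6, 7, 12
    or 45 for fungal cellulases), ``mode`` distinguishes cellobiohydrolases
    (CBH, chain-end attack) from endoglucanases (EG, internal attack), and
    ``has_cbm`` records whether a carbohydrate-binding module is present.
    Unknown annotations are permitted; identity is not.
    """

    enzyme_id: str
    gh_family: int | str = "unknown"
    mode: str = "unknown"
    has_cbm: bool | str = "unknown"
    is_wildtype: bool = True
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.enzyme_id:
            raise ValidationError("enzyme_id must be a non-empty string")
        if self.gh_family != "unknown" and int(self.gh_family) not in GH_FAMILIES:
            raise ValidationError(
                f"gh_family must be one of {sorted(GH_FAMILIES)} or 'unknown', "
                f"got {self.gh_family!r}"
            )
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {sorted(MODES)}, got {self.mode!r}")


@dataclass(frozen=True)
class MMDataset:
    """Rate-vs-load measurements for one enzyme.

    ``loads`` are substrate mass loads S0 (g/L); ``rates[i]`` holds the
    replicate quasi-steady-state rates v_ss (µM·s⁻¹) measured at
    ``loads[i]``. Replicate counts may differ between loads.
    """

    enzyme_id: str
    enzyme_conc: float  # E0, µM
    loads: tuple[float, ...]
    rates: tuple[tuple[float, ...], ...]

    def __init__(
        self,
        enzyme_id: str,
        enzyme_conc: float,
        loads: Sequence[float],
        rates: Sequence[Sequence[float]],
    ) -> None:
        object.__setattr__(self, "enzyme_id", enzyme_id)
        object.__setattr__(self, "enzyme_conc", float(enzyme_conc))
        object.__setattr__(self, "loads", tuple(float(s) for s in loads))
        object.__setattr__(self, "rates", tuple(tuple(float(v) for v in r) for r in rates))
        self._validate()

    def _validate(self) -> None:
        if self.enzyme_conc <= 0:
            raise ValidationError(f"{self.enzyme_id}: enzyme concentration E0 must be > 0")
        if len(self.loads) != len(self.rates):
            raise ValidationError(f"{self.enzyme_id}: loads and rates must align")
        if len(set(self.loads)) < 3:
            raise ValidationError(
                f"{self.enzyme_id}: at least 3 distinct substrate loads are required, "
                f"got {len(set(self.loads))}"
            )
        if any(s <= 0 for s in self.loads):
            raise ValidationError(f"{self.enzyme_id}: all loads must be > 0")
        for s, reps in zip(self.loads, self.rates):
            if len(reps) < 1:
                raise ValidationError(f"{self.enzyme_id}: load {s} has no replicate rates")
            if any(v < 0 for v in reps):
                raise ValidationError(f"{self.enzyme_id}: negative rate at load {s}")

    @property
    def n_points(self) -> int:
        """Total number of replicate measurements."""
        return sum(len(r) for r in self.rates)


@dataclass(frozen=True)
class KineticParams:
    """Fitted (or true) Michaelis–Menten parameters for one enzyme.

    ``k_cat`` in s⁻¹, ``K_M`` as apparent substrate mass load in g/L.
    ``source`` records provenance: ``fitted`` (from rate data), ``table``
    (read from a parameter table) or ``synthetic-truth`` (generator
    ground truth). ``flags`` carries fit diagnostics such as
    ``non_saturating``.
    """

    enzyme_id: str
    k_cat: float
    K_M: float
    sd_kcat: float = 0.0
    sd_km: float = 0.0
    source: str = "table"
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not math.isfinite(self.k_cat) or self.k_cat <= 0:
            raise ValidationError(f"{self.enzyme_id}: k_cat must be finite and > 0, got {self.k_cat}")
        if not math.isfinite(self.K_M) or self.K_M <= 0:
            raise ValidationError(f"{self.enzyme_id}: K_M must be finite and > 0, got {self.K_M}")
        if self.sd_kcat < 0 or self.sd_km < 0:
            raise ValidationError(f"{self.enzyme_id}: standard deviations must be >= 0")
        if self.source not in {"fitted", "table", "synthetic-truth"}:
            raise ValidationError(f"{self.enzyme_id}: unknown source {self.source!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the scaling-line (LFER) analysis.

    ``reference_enzyme_id`` anchors the relative free energies; the
    conventional anchor is the GH6 cellobiohydrolase TrCel6A.
    ``outlier_cutoff`` is the bound on externally studentized residuals
    (±2.5 is a conservative choice), ``outlier_iterate`` selects
    one-worst-point-per-pass iterated removal versus a single pass, and
    ``band_level`` is the level of the confidence/prediction bands.
    """

    reference_enzyme_id: str = "TrCel6A"
    outlier_cutoff: float = 2.5
    outlier_iterate: bool = True
    band_level: float = 0.95
    seed: int = 0
    constants: Constants = field(default_factory=Constants)

    def __post_init__(self) -> None:
        if self.outlier_cutoff <= 0:
            raise ValidationError("outlier_cutoff must be > 0")
        if not 0 < self.band_level < 1:
            raise ValidationError("band_level must lie in (0, 1)")
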