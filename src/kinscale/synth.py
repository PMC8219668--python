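"""Synthetic-data generators mirroring the experimental design.

Three generators close the pipeline under synthesis:

* :func:`generate_lfer_ensemble` draws an enzyme ensemble whose
  (ln K_M, ln k_cat) points scatter around a scaling line, with an
  optional sub-line outlier population (catalytically impaired enzymes
  appear below the line; none above it).
* :func:`generate_mm_dataset` produces triplicate rate-vs-load
  measurements for one enzyme under the hyperbolic forward model with
  multiplicative lognormal noise, on the experimental load grid.
* :func:`simulate_mechanistic_enzyme` realizes a minimal three-step
  interfacial mechanism — association, hydrolysis, dissociation — in
  which turnover is dissociation-limited. Its single coupling parameter
  ``c`` (the fraction of the binding free energy expressed at the
  dissociation transition state) interpolates the LFER regimes: an
  ensemble of such enzymes exhibits Φ = c − 1 exactly, spanning pure
  ground-state stabilization (c=0, Φ=−1) to uniform binding (c=1, Φ=0).

All generators are bit-reproducible given their seed
(``numpy.random.default_rng``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Constants, EnzymeRecord, KineticParams, MMDataset
from .errors import ValidationError

#: Default ln k_cat scatter about the line: the central ~95% band then
#: spans close to a factor 2 in k_cat.
DEFAULT_VERTICAL_SD = math.log(2) / 2


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a synthetic scaling-line enzyme ensemble.

    Defaults emulate the reference experimental design: 83 enzymes, a
    scaling slope of 0.74, vertical scatter of ln(2)/2 (~factor-2 band
    in k_cat), and a 5% sub-line outlier population displaced 3 ln-units
    down (low specificity constant, the "southeastern" region).
    ``lnKm_range`` is in ln(g/L); its default spans ~1–300 g/L.
    """

    n_enzymes: int = 83
    lnKm_range: tuple[float, float] = (0.0, math.log(300.0))
    true_slope_a: float = 0.74
    true_intercept_lnA: float = 0.0
    vertical_sd: float = DEFAULT_VERTICAL_SD
    outlier_fraction: float = 0.05
    outlier_offset: float = -3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enzymes < 3:
            raise ValidationError("n_enzymes must be >= 3")
        if self.vertical_sd < 0:
            raise ValidationError("vertical_sd must be >= 0")
        if not 0 <= self.outlier_fraction < 1:
            raise ValidationError("outlier_fraction must lie in [0, 1)")
        if self.outlier_offset > 0:
            raise ValidationError("outlier_offset must be <= 0 (outliers lie below the line)")
        if self.lnKm_range[1] <= self.lnKm_range[0]:
            raise ValidationError("lnKm_range must be a non-empty interval")


@dataclass(frozen=True)
class MeasurementSpec:
    """Design of one enzyme's rate measurements.

    Defaults match the experimental protocol: loads spanning 1–100 g/L,
    0.1 µM enzyme, triplicates, ~5% multiplicative noise.
    """

    loads: tuple[float, ...] = (1, 2, 5, 10, 20, 35, 50, 75, 100)
    E0: float = 0.1
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.loads)) != len(self.loads) or any(s <= 0 for s in self.loads):
            raise ValidationError("loads must be positive and distinct")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.E0 <= 0:
            raise ValidationError("E0 must be > 0")


@dataclass(frozen=True)
class MechanisticSpec:
    """Three-step interfacial kinetics: association, hydrolysis, dissociation.

    ``k_on`` is the association rate constant ((g/L)⁻¹·s⁻¹), ``k_off0``
    the dissociation prefactor (s⁻¹), ``products_per_visit`` the number
    of catalytic turnovers per substrate visit (processivity, n_p ≥ 1),
    ``dG_b`` the ligand binding free energy in kJ/mol (negative =
    tighter), and ``ts_coupling_c`` ∈ [0, 1] the fraction of the binding
    free energy already expressed at the dissociation transition state:
    c = 1 is uniform binding (barrier independent of ΔG_b), c = 0 a
    fixed transition state (pure ground-state stabilization).
    """

    k_on: float = 1.0
    k_off0: float = 10.0
    products_per_visit: float = 4.0
    ts_coupling_c: float = 0.0
    dG_b: float = -15.0
    T: float = Constants().temperature

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off0 <= 0:
            raise ValidationError("rate constants must be > 0")
        if self.products_per_visit < 1:
            raise ValidationError("products_per_visit must be >= 1")
        if not 0 <= self.ts_coupling_c <= 1:
            raise ValidationError("ts_coupling_c must lie in [0, 1]")
        if self.T <= 0:
            raise ValidationError("temperature must be > 0")


@dataclass(frozen=True)
class SyntheticEnsemble:
    """Generator output: annotated records, true parameters, outlier ids."""

    members: tuple[tuple[EnzymeRecord, KineticParams], ...]
    outlier_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def params(self) -> list[KineticParams]:
        return [p for _, p in self.members]


def generate_lfer_ensemble(spec: EnsembleSpec) -> SyntheticEnsemble:
    """Draw a synthetic enzyme ensemble around a scaling line.

    ln K_M is uniform on ``lnKm_range``; ln k_cat is the line value plus
    Gaussian scatter. ``floor(n·outlier_fraction)`` members, chosen at
    random, are additionally displaced ``outlier_offset`` ln-units down
    and reported in ``outlier_ids``. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_enzymes
    ln_km = rng.uniform(*spec.lnKm_range, size=n)
    ln_kcat = (
        spec.true_intercept_lnA
        + spec.true_slope_a * ln_km
        + rng.normal(0.0, spec.vertical_sd, size=n)
    )
    n_out = int(n * spec.outlier_fraction)
    outlier_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    ln_kcat[outlier_idx] += spec.outlier_offset

    families = np.array(sorted({5, 6, 7, 12, 45}))
    members = []
    width = len(str(n))
    for i in range(n):
        eid = f"SYN{i + 1:0{width}d}"
        rec = EnzymeRecord(
            enzyme_id=eid,
            gh_family=int(rng.choice(families)),
            mode=str(rng.choice(["CBH", "EG"])),
            has_cbm=bool(rng.random() < 0.5),
            is_wildtype=True,
        )
        par = KineticParams(
            enzyme_id=eid,
            k_cat=float(np.exp(ln_kcat[i])),
            K_M=float(np.exp(ln_km[i])),
            source="synthetic-truth",
        )
        members.append((rec, par))
    return SyntheticEnsemble(
        members=tuple(members),
        outlier_ids=tuple(members[i][0].enzyme_id for i in sorted(outlier_idx)),
    )


def generate_mm_dataset(truth: KineticParams, spec: MeasurementSpec) -> MMDataset:
    """Simulate replicate rate measurements for one enzyme.

    Each measurement is the hyperbolic model rate times a mean-one
    lognormal factor with coefficient of variation ``noise_cv``
    (σ² = ln(1+cv²), µ = −σ²/2). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    loads = np.asarray(spec.loads, dtype=float)
    clean = spec.E0 * truth.k_cat * loads / (loads + truth.K_M)
    if spec.noise_cv > 0:
        sigma2 = math.log1p(spec.noise_cv**2)
        factors = rng.lognormal(
            mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=(loads.size, spec.replicates)
        )
    else:
        factors = np.ones((loads.size, spec.replicates))
    rates = clean[:, None] * factors
    return MMDataset(
        enzyme_id=truth.enzyme_id,
        enzyme_conc=spec.E0,
        loads=loads,
        rates=[tuple(row) for row in rates],
    )


def simulate_mechanistic_enzyme(spec: MechanisticSpec,
                                enzyme_id: str = "MECH") -> KineticParams:
    """Kinetic parameters implied by the three-step dissociation-limited scheme.

    The dissociation barrier is the gap between the transition state
    (at fraction ``c`` of the binding energy) and the complex
    (at ``dG_b``), so

        k_off = k_off0 · exp((1 − c)·ΔG_b / RT),
        k_cat = n_p · k_off                       (turnover is off-rate
                                                   limited; n_p products
                                                   are released per visit),
        K_M  ≈ K_D = (k_off0/k_on) · exp(ΔG_b / RT),

    where K_D reflects the full binding free energy — association passes
    over the same transition state, so detailed balance fixes the
    equilibrium independent of ``c``. Across an ensemble varying only in
    ΔG_b, ln k_cat is affine in ln K_M with slope 1 − c, i.e. Φ = c − 1:
    c = 0 gives pure ground-state stabilization (Φ = −1), c = 1 uniform
    binding (Φ = 0).
    """
    rt = Constants(temperature=spec.T).rt
    k_off = spec.k_off0 * math.exp((1.0 - spec.ts_coupling_c) * spec.dG_b / rt)
    k_cat = spec.products_per_visit * k_off
    K_M = (spec.k_off0 / spec.k_on) * math.exp(spec.dG_b / rt)
    return KineticParams(
        enzyme_id=enzyme_id, k_cat=k_cat, K_M=K_M, source="synthetic-truth"
    )


def generate_rate_tables(ensemble: SyntheticEnsemble,
                         spec: MeasurementSpec) -> list[MMDataset]:
    """One simulated rate dataset per ensemble member.

    Per-enzyme seeds are spawned from ``spec.seed`` so datasets are
    independent yet jointly reproducible.
    """
    seeds = np.random.SeedSequence(spec.seed).generate_state(len(ensemble.members))
    out = []
    for (rec, truth), s in zip(ensemble.members, seeds):
        child = MeasurementSpec(
            loads=spec.loads, E0=spec.E0, replicates=spec.replicates,
            noise_cv=spec.noise_cv, seed=int(s % (2**31)),
        )
        out.append(generate_mm_dataset(truth, child))
    return out
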