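"""Seeded synthetic reporter-assay datasets.

Emulates the endpoint flow-cytometry experiments used to characterise
the split-RNAP resource allocator: geometric-mean fluorescence per
sample with white-cell (autofluorescence) background, multiplicative
lognormal replicate noise, triplicate assays, and the IPTG titration
grids of the induction, competition, and regulator experiments.  Each
generator runs the equilibrium allocation model forward, converts
promoter activities to fluorescence, and emits a
:class:`~rnapalloc.assay.MeasurementTable` whose metadata carries the
white-cell/reporter-only references and the inducer-to-expression
calibration series an analyst would measure separately.

Defaults (all overridable) encode the characterised system:

* core pool 1.0 AU with tight SynZIP-fused binding, ``kd_core = 0.01``
  x core (deep saturation); the no-SynZIP variant binds ~100x weaker
  and never saturates over the grid;
* four orthogonal sigma fragments T7 > CGG > K1FR > T3 with a < 4-fold
  activity spread; the T7 efficiency is anchored so that saturated
  P_T7 activity over the reporter-only baseline is ~4,000-fold, and a
  full-length polymerase control sits 4x above the split plateau;
* lognormal replicate noise with CV 0.1, triplicates, 2% leaky
  expression from uninduced inducible promoters;
* a low-allocator variant at 0.36x the high core level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import InductionModel, MeasurementTable
from .errors import ValidationError
from .model import (
    AllocatorSystem,
    CoreSpec,
    PromoterSpec,
    SigmaSpec,
    equilibrate,
    promoter_activities,
)

__all__ = [
    "SATURATION_GRID",
    "COMPETITION_GRID",
    "NULL_GRID",
    "ALPHA_GRID",
    "FULL_LENGTH_ACTIVITY_RATIO",
    "GeneratorConfig",
    "default_system",
    "default_sigma_induction",
    "default_null_induction",
    "default_alpha_induction",
    "generate_titration",
    "generate_competition",
    "generate_regulator_assay",
    "random_system",
]

#: IPTG grids (uM) used in the characterisation assays
SATURATION_GRID = (0.0, 1.0, 2.0, 4.0, 6.3, 10.0, 16.0, 25.0, 40.0, 63.0, 100.0, 1000.0)
COMPETITION_GRID = (0.0, 2.0, 4.0, 6.3, 7.4, 8.6, 10.0, 13.0, 16.0, 20.0, 25.0, 32.0)
NULL_GRID = (0.0, 2.0, 4.0, 10.0, 16.0, 25.0, 40.0, 1000.0)
ALPHA_GRID = (0.0, 2.0, 4.0, 10.0, 16.0, 25.0, 40.0)

#: full-length polymerase control activity relative to the split plateau
FULL_LENGTH_ACTIVITY_RATIO = 4.0

#: leaky expression of uninduced inducible promoters, fraction of vmax
LEAK_FRACTION = 0.02

# efficiencies in fluorescence-AU per complex-AU; T7/T3 spread < 4-fold,
# K1FR ~ T3 so competing raw sums stay near-constant
DEFAULT_EFFICIENCIES = {"T7": 4.0e5, "CGG": 2.4e5, "K1FR": 1.2e5, "T3": 1.15e5}
# constitutive totals (AU) where a fragment is expressed constitutively
DEFAULT_TOTALS = {"T7": 3.0, "T3": 3.0, "K1FR": 1.5, "CGG": 3.0}


def default_system(
    core_total: float = 1.0,
    kd_core: float = 0.01,
    synzip: bool = True,
    requires_alpha: bool = False,
    kd_alpha: float = 0.01,
    alpha_total: float = 0.0,
) -> AllocatorSystem:
    """The characterised four-fragment allocator.

    Without the SynZIP fusion the sigma:core affinity drops ~100-fold
    and the pool is never saturated over the induction grid.
    """
    kd = kd_core if synzip else kd_core * 100.0
    sigmas = tuple(
        SigmaSpec(name, DEFAULT_TOTALS[name], kd, DEFAULT_EFFICIENCIES[name])
        for name in ("T7", "T3", "K1FR", "CGG")
    )
    promoters = tuple(
        PromoterSpec(f"P{name}", name, 0.0) for name in ("T7", "T3", "K1FR", "CGG")
    )
    core = CoreSpec(core_total, requires_alpha, kd_alpha, alpha_total)
    return AllocatorSystem(core, sigmas, promoters)


def default_sigma_induction(vmax: float = 6.0) -> InductionModel:
    """P_Tac-style induction of a sigma fragment (2% leak, K 10 uM)."""
    return InductionModel(basal=LEAK_FRACTION * vmax, vmax=vmax, k_half=10.0, hill_n=2.0)


def default_null_induction(vmax: float = 45.0) -> InductionModel:
    """Null-fragment cassette: strong enough to outcompete constitutive sigma.

    With the constitutive sigma at 3.0 AU and 2% leak, full induction
    shifts the saturated share from 3/(3 + 0.9) to 3/(3 + 45), a
    ~12-fold drop in cognate activity.
    """
    return InductionModel(basal=LEAK_FRACTION * vmax, vmax=vmax, k_half=10.0, hill_n=2.0)


def default_alpha_induction(vmax: float = 2.0, leak: float = LEAK_FRACTION) -> InductionModel:
    return InductionModel(basal=leak * vmax, vmax=vmax, k_half=10.0, hill_n=2.0)


def random_system(
    rng: np.random.Generator,
    n_sigma: int | None = None,
    max_sigma: int = 6,
    kd_range: tuple[float, float] = (1e-4, 1e2),
    total_range: tuple[float, float] = (0.0, 10.0),
    core_total: float = 1.0,
) -> AllocatorSystem:
    """Randomised allocator system for property testing.

    Dissociation constants are drawn log-uniformly over ``kd_range``
    (relative to ``core_total``), sigma totals uniformly over
    ``total_range``; one promoter per fragment, identity crosstalk.
    """
    n = int(n_sigma) if n_sigma is not None else int(rng.integers(1, max_sigma + 1))
    kds = core_total * np.exp(
        rng.uniform(np.log(kd_range[0]), np.log(kd_range[1]), size=n)
    )
    totals = rng.uniform(*total_range, size=n)
    sigmas = tuple(
        SigmaSpec(f"s{i}", float(totals[i]), float(kds[i]), efficiency=1.0)
        for i in range(n)
    )
    promoters = tuple(PromoterSpec(f"p{i}", f"s{i}", 0.0) for i in range(n))
    return AllocatorSystem(CoreSpec(core_total), sigmas, promoters)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic assays."""

    system: AllocatorSystem = field(default_factory=default_system)
    induction: InductionModel | None = None
    iptg_grid: tuple[float, ...] | None = None
    replicates: int = 3
    noise_cv: float = 0.1
    white_cell_mean: float = 40.0
    reporter_only_mean: float = 100.0
    core_ratio: float = 0.36
    batch_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if not (0 < self.core_ratio <= 1):
            raise ValidationError("core_ratio must be in (0, 1]")
        if self.iptg_grid is not None and any(v < 0 for v in self.iptg_grid):
            raise ValidationError("iptg grid values must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def _emit_rows(
    rows: list[dict],
    rng: np.random.Generator,
    config: GeneratorConfig,
    condition: str,
    iptg: float,
    activities: dict[str, float],
    promoters: list[str],
) -> None:
    for promoter in promoters:
        noise = _lognormal_factors(rng, config.noise_cv, config.replicates)
        signal = (activities[promoter] + config.white_cell_mean) * config.batch_factor
        for rep in range(1, config.replicates + 1):
            rows.append(
                {
                    "condition": condition,
                    "iptg_uM": iptg,
                    "promoter": promoter,
                    "replicate": rep,
                    "fluorescence_au": signal * noise[rep - 1],
                }
            )


def _finish(rows: list[dict], config: GeneratorConfig, extra: dict) -> MeasurementTable:
    data = pd.DataFrame(rows)
    reporter_only = {
        p.name: config.reporter_only_mean + config.white_cell_mean
        for p in config.system.promoters
    }
    return MeasurementTable(
        data=data,
        white_cell={"default": config.white_cell_mean},
        reporter_only=reporter_only,
        extra={"seed": config.seed, **extra},
    )


def generate_titration(
    config: GeneratorConfig,
    induced_sigma: str,
    *,
    control: str | None = None,
) -> MeasurementTable:
    """Single-sigma induction series against a constant allocator.

    Only the induced cassette is present; all other sigma totals are
    zero.  ``control="full_length"`` replaces the split polymerase with
    a full-length control whose activity is constant across the grid at
    :data:`FULL_LENGTH_ACTIVITY_RATIO` times the split saturation level
    (a complete polymerase needs no sigma fragment).
    """
    system = config.system
    sigma = system.sigma(induced_sigma)  # raises for unknown names
    induction = config.induction or default_sigma_induction()
    grid = config.iptg_grid or SATURATION_GRID
    rng = np.random.default_rng(config.seed)
    promoters = [p.name for p in system.promoters]
    cognate = next(p for p in system.promoters if p.cognate_sigma == induced_sigma)

    rows: list[dict] = []
    for iptg in grid:
        if control == "full_length":
            plateau = sigma.efficiency * system.core.total * FULL_LENGTH_ACTIVITY_RATIO
            activities = {p.name: p.basal for p in system.promoters}
            activities[cognate.name] = plateau
        else:
            totals = {s.name: 0.0 for s in system.sigmas}
            totals[induced_sigma] = float(induction.expression(iptg))
            sys_i = system.with_sigma_totals(totals)
            activities = promoter_activities(equilibrate(sys_i), sys_i)
        _emit_rows(rows, rng, config, f"titration_{induced_sigma}", iptg, activities, promoters)

    calibration = {
        "iptg_uM": list(grid),
        "expression_au": [float(induction.expression(v)) for v in grid],
    }
    return _finish(
        rows,
        config,
        {"assay": "titration", "induced_sigma": induced_sigma, "calibration": calibration},
    )


def generate_competition(
    config: GeneratorConfig,
    constant_sigma: str = "K1FR",
    induced_sigma: str = "T3",
    allocator_level: str = "high",
) -> MeasurementTable:
    """Two-sigma competition for the core pool plus saturation references.

    The constant fragment stays at its constitutive (leaky) level from
    the system spec while the induced fragment is titrated.  Conditions
    emitted: ``competition`` across the grid, and single-sigma
    ``saturation_<name>`` references (each fragment alone, expressed to
    saturation) required by the fraction-core-utilized normalisation.
    ``allocator_level="low"`` scales the core total by ``core_ratio``.
    """
    if constant_sigma == induced_sigma:
        raise ValidationError("constant and induced sigma must differ")
    if allocator_level not in ("high", "low"):
        raise ValidationError("allocator_level must be 'high' or 'low'")
    system = config.system
    system.sigma(constant_sigma)
    system.sigma(induced_sigma)
    if allocator_level == "low":
        c = system.core
        system = AllocatorSystem(
            CoreSpec(c.total * config.core_ratio, c.requires_alpha, c.kd_alpha, c.alpha_total),
            system.sigmas,
            system.promoters,
            system.crosstalk,
        )
    induction = config.induction or default_sigma_induction()
    grid = config.iptg_grid or COMPETITION_GRID
    rng = np.random.default_rng(config.seed)
    constant_total = system.sigma(constant_sigma).total
    pair_promoters = [
        p.name
        for p in system.promoters
        if p.cognate_sigma in (constant_sigma, induced_sigma)
    ]

    rows: list[dict] = []
    for iptg in grid:
        totals = {s.name: 0.0 for s in system.sigmas}
        totals[constant_sigma] = constant_total
        totals[induced_sigma] = float(induction.expression(iptg))
        sys_i = system.with_sigma_totals(totals)
        activities = promoter_activities(equilibrate(sys_i), sys_i)
        _emit_rows(rows, rng, config, "competition", iptg, activities, pair_promoters)

    # single-sigma saturation references at full induction
    sat_level = float(induction.expression(max(SATURATION_GRID)))
    for name in (constant_sigma, induced_sigma):
        totals = {s.name: 0.0 for s in system.sigmas}
        totals[name] = max(sat_level, constant_total)
        sys_s = system.with_sigma_totals(totals)
        activities = promoter_activities(equilibrate(sys_s), sys_s)
        cognate = next(p.name for p in system.promoters if p.cognate_sigma == name)
        _emit_rows(
            rows, rng, config, f"saturation_{name}", max(SATURATION_GRID), activities, [cognate]
        )

    calibration = {
        "iptg_uM": list(grid),
        "expression_au": [float(induction.expression(v)) for v in grid],
    }
    truth = {
        "constant_sigma": constant_sigma,
        "induced_sigma": induced_sigma,
        "constant_total": constant_total,
        "allocator_level": allocator_level,
        "core_ratio": config.core_ratio,
    }
    return _finish(
        rows,
        config,
        {"assay": "competition", "calibration": calibration, "truth": truth},
    )


def generate_regulator_assay(config: GeneratorConfig, regulator: str) -> MeasurementTable:
    """Titration of a regulator against a constitutive sigma/core pair.

    ``regulator="null"`` adds an inducible catalytically dead fragment
    that sequesters core away from the constitutive T7 sigma fragment
    (activity falls monotonically; >= 10-fold suppression at full
    induction with the defaults).  ``regulator="alpha"`` titrates the
    alpha fragment against a beta core (activity rises from zero).
    A matching no-regulator ``control`` series is emitted alongside.
    """
    system = config.system
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []

    if regulator == "null":
        grid = config.iptg_grid or NULL_GRID
        induction = config.induction or default_null_induction()
        sigma_name = "T7"
        system.sigma(sigma_name)
        null = SigmaSpec(
            "null",
            0.0,
            system.sigma(sigma_name).kd_core,
            efficiency=0.0,
            is_null=True,
        )
        base = AllocatorSystem(
            system.core, system.sigmas + (null,), system.promoters, None
        )
        cognate = next(p.name for p in system.promoters if p.cognate_sigma == sigma_name)
        for iptg in grid:
            totals = {s.name: 0.0 for s in base.sigmas}
            totals[sigma_name] = DEFAULT_TOTALS[sigma_name]
            totals["null"] = float(induction.expression(iptg))
            sys_i = base.with_sigma_totals(totals)
            acts = promoter_activities(equilibrate(sys_i), sys_i)
            _emit_rows(rows, rng, config, "titration", iptg, acts, [cognate])
            # control lacking the inducible null cassette
            totals["null"] = 0.0
            sys_c = base.with_sigma_totals(totals)
            acts_c = promoter_activities(equilibrate(sys_c), sys_c)
            _emit_rows(rows, rng, config, "control", iptg, acts_c, [cognate])
    elif regulator == "alpha":
        if not system.core.requires_alpha:
            raise ValidationError("alpha assay needs a system with requires_alpha core")
        grid = config.iptg_grid or ALPHA_GRID
        induction = config.induction or default_alpha_induction()
        sigma_name = "T7"
        cognate = next(p.name for p in system.promoters if p.cognate_sigma == sigma_name)
        for iptg in grid:
            alpha_total = float(induction.expression(iptg))
            core = CoreSpec(system.core.total, True, system.core.kd_alpha, alpha_total)
            totals = {s.name: 0.0 for s in system.sigmas}
            totals[sigma_name] = DEFAULT_TOTALS[sigma_name]
            sys_i = AllocatorSystem(
                core, system.sigmas, system.promoters, system.crosstalk
            ).with_sigma_totals(totals)
            acts = promoter_activities(equilibrate(sys_i), sys_i)
            _emit_rows(rows, rng, config, "titration", iptg, acts, [cognate])
            # control lacking the alpha cassette entirely
            core0 = CoreSpec(system.core.total, True, system.core.kd_alpha, 0.0)
            sys_c = AllocatorSystem(
                core0, system.sigmas, system.promoters, system.crosstalk
            ).with_sigma_totals(totals)
            acts_c = promoter_activities(equilibrate(sys_c), sys_c)
            _emit_rows(rows, rng, config, "control", iptg, acts_c, [cognate])
    else:
        raise ValidationError("regulator must be 'null' or 'alpha'")

    calibration = {
        "iptg_uM": list(grid),
        "expression_au": [float(induction.expression(v)) for v in grid],
    }
    return _finish(
        rows, config, {"assay": f"regulator_{regulator}", "calibration": calibration}
    )
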