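"""Equilibrium allocation of a shared RNA-polymerase core fragment.

Split T7 RNAP separates promoter recognition from catalysis: a small
"sigma fragment" carries the specificity loop and binds a larger "core
fragment" to form an active polymerase.  When several sigma fragments
(including catalytically dead "null" fragments) are expressed at once,
they compete for a limited core pool by mass action.  The equilibrium
partition of the core among the sigma fragments sets how much
transcription each cognate promoter receives, and the core level sets
the total transcriptional budget.

The core can itself be split once more into a short alpha fragment and
a beta core fragment; the beta core is inactive until alpha binds, so
alpha expression positively regulates the whole budget.  Alpha:beta
association is modelled as an independent prior equilibrium (sequential
assembly: alpha activates the core, the activated core then binds a
sigma fragment).

All concentrations and activities are in arbitrary units (AU); the
model is scale-free and only ratios are identifiable from endpoint
reporter assays.

Binding model
-------------
For active core total ``C`` and sigma fragments with totals ``S_i`` and
dissociation constants ``K_i``, simultaneous bimolecular binding
``core + sigma_i <=> complex_i`` gives, at equilibrium with free core
``F``::

    complex_i = S_i * F / (K_i + F)
    F * (1 + sum_i S_i / (K_i + F)) = C

The left-hand side is strictly increasing in ``F``, so the equilibrium
is unique and found by bracketed root finding on ``F in [0, C]``.

``K_i == 0`` is accepted as the *titration limit*: binding is so tight
that the pool is partitioned stoichiometrically — every fragment fully
bound while core remains, and complexes proportional to totals once the
totals exceed the core budget.  This is the regime the tight SynZIP
fusion operates in, and it is the limit in which bound shares depend
only on relative sigma expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import NumericalError, UndefinedShareError, ValidationError

__all__ = [
    "SigmaSpec",
    "CoreSpec",
    "PromoterSpec",
    "CrosstalkMatrix",
    "AllocatorSystem",
    "BoundState",
    "activate_core",
    "equilibrate",
    "promoter_activities",
    "saturated_shares",
]

#: conservation must hold to this relative tolerance or equilibrate raises
CONSERVATION_RTOL = 1e-9


@dataclass(frozen=True)
class SigmaSpec:
    """One sigma-type fragment competing for the core pool.

    Parameters
    ----------
    name : str
        Unique identifier (e.g. ``"T7"``, ``"T3"``, ``"K1FR"``, ``"CGG"``).
    total : float
        Total concentration, AU.
    kd_core : float
        Dissociation constant versus the (activated) core, AU.  Zero is
        the titration limit (see module docstring).
    efficiency : float
        Transcription rate coefficient per bound complex on the cognate
        promoter, activity-AU per complex-AU.
    is_null : bool
        A null fragment binds the core but supports no transcription;
        it must have ``efficiency == 0``.
    """

    name: str
    total: float
    kd_core: float
    efficiency: float = 1.0
    is_null: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("sigma fragment needs a non-empty name")
        if self.total < 0:
            raise ValidationError(f"sigma {self.name!r}: total must be >= 0")
        if self.kd_core < 0:
            raise ValidationError(f"sigma {self.name!r}: kd_core must be >= 0")
        if self.efficiency < 0:
            raise ValidationError(f"sigma {self.name!r}: efficiency must be >= 0")
        if self.is_null and self.efficiency != 0:
            raise ValidationError(
                f"null fragment {self.name!r} must have efficiency == 0"
            )


@dataclass(frozen=True)
class CoreSpec:
    """The shared core-fragment pool (optionally the alpha-activated beta core).

    ``requires_alpha=True`` models the beta core fragment, inactive
    until the 67-aa alpha fragment binds with dissociation constant
    ``kd_alpha``; only the alpha:beta complex competes for sigma
    fragments.
    """

    total: float
    requires_alpha: bool = False
    kd_alpha: float = 1.0
    alpha_total: float = 0.0

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValidationError("core total must be >= 0")
        if self.kd_alpha <= 0:
            raise ValidationError("kd_alpha must be > 0")
        if self.alpha_total < 0:
            raise ValidationError("alpha_total must be >= 0")


@dataclass(frozen=True)
class PromoterSpec:
    """A reporter promoter driven by one cognate sigma fragment."""

    name: str
    cognate_sigma: str
    basal: float = 0.0

    def __post_init__(self) -> None:
        if self.basal < 0:
            raise ValidationError(f"promoter {self.name!r}: basal must be >= 0")


@dataclass(frozen=True)
class CrosstalkMatrix:
    """Relative efficiency multipliers for non-cognate sigma/promoter pairs.

    Entries are dimensionless in [0, 1]; cognate (diagonal) entries are 1.
    The default, built with :meth:`identity`, encodes full orthogonality.
    """

    sigma_names: tuple[str, ...]
    promoter_names: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]

    @classmethod
    def identity(
        cls, sigmas: list[SigmaSpec], promoters: list[PromoterSpec]
    ) -> "CrosstalkMatrix":
        """Orthogonal default: 1 on cognate pairs, 0 elsewhere."""
        rows = tuple(
            tuple(1.0 if p.cognate_sigma == s.name else 0.0 for p in promoters)
            for s in sigmas
        )
        return cls(
            tuple(s.name for s in sigmas), tuple(p.name for p in promoters), rows
        )

    def __post_init__(self) -> None:
        try:
            vals = np.asarray(self.values, dtype=float).reshape(
                len(self.sigma_names), len(self.promoter_names)
            )
        except ValueError as exc:
            raise ValidationError("crosstalk matrix shape mismatch") from exc
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValidationError("crosstalk entries must lie in [0, 1]")

    def get(self, sigma: str, promoter: str) -> float:
        try:
            i = self.sigma_names.index(sigma)
            j = self.promoter_names.index(promoter)
        except ValueError as exc:
            raise ValidationError(
                f"crosstalk matrix has no entry for ({sigma!r}, {promoter!r})"
            ) from exc
        return self.values[i][j]


@dataclass(frozen=True)
class AllocatorSystem:
    """Full species inventory: core pool, sigma fragments, promoters, crosstalk."""

    core: CoreSpec
    sigmas: tuple[SigmaSpec, ...]
    promoters: tuple[PromoterSpec, ...]
    crosstalk: CrosstalkMatrix | None = None

    def __post_init__(self) -> None:
        sigmas = tuple(self.sigmas)
        promoters = tuple(self.promoters)
        object.__setattr__(self, "sigmas", sigmas)
        object.__setattr__(self, "promoters", promoters)
        names = [s.name for s in sigmas]
        if len(set(names)) != len(names):
            raise ValidationError("sigma fragment names must be unique")
        for p in promoters:
            if p.cognate_sigma not in names:
                raise ValidationError(
                    f"promoter {p.name!r}: cognate sigma {p.cognate_sigma!r} unknown"
                )
        kds = [s.kd_core for s in sigmas]
        if any(k == 0 for k in kds) and any(k > 0 for k in kds):
            raise ValidationError(
                "titration-limit (kd_core == 0) and finite-affinity sigma fragments "
                "cannot be mixed in one system"
            )
        if self.crosstalk is None:
            object.__setattr__(
                self, "crosstalk", CrosstalkMatrix.identity(list(sigmas), list(promoters))
            )

    def sigma(self, name: str) -> SigmaSpec:
        for s in self.sigmas:
            if s.name == name:
                return s
        raise ValidationError(f"unknown sigma fragment {name!r}")

    def with_sigma_totals(self, totals: dict[str, float]) -> "AllocatorSystem":
        """Copy of the system with some sigma totals replaced."""
        unknown = set(totals) - {s.name for s in self.sigmas}
        if unknown:
            raise ValidationError(f"unknown sigma fragment(s): {sorted(unknown)}")
        new = tuple(
            SigmaSpec(s.name, totals.get(s.name, s.total), s.kd_core, s.efficiency, s.is_null)
            for s in self.sigmas
        )
        return AllocatorSystem(self.core, new, self.promoters, self.crosstalk)


@dataclass(frozen=True)
class BoundState:
    """Equilibrium concentrations: free core and per-sigma complexes (AU)."""

    free_core: float
    complexes: dict[str, float]
    active_core_total: float


def activate_core(core: CoreSpec) -> float:
    """Concentration of sigma-competent core, AU.

    For the unsplit core this is just ``core.total``.  For the beta core
    it is the equilibrium alpha:beta complex from two-species binding —
    the smaller root of the association quadratic, evaluated in the
    numerically stable form ``2ab / (a + b + K + sqrt((a+b+K)^2 - 4ab))``.
    """
    if not core.requires_alpha:
        return core.total
    a, b, kd = core.alpha_total, core.total, core.kd_alpha
    if a == 0.0 or b == 0.0:
        return 0.0
    s = a + b + kd
    disc = math.sqrt(max(s * s - 4.0 * a * b, 0.0))
    return 2.0 * a * b / (s + disc)


def _solve_free_core(c_active: float, totals: np.ndarray, kds: np.ndarray) -> float:
    """Free core F solving F * (1 + sum S/(K+F)) = C, by Brent + Newton polish."""

    def g(f: float) -> float:
        return f + float(np.sum(totals * f / (kds + f))) - c_active

    hi = c_active
    if g(hi) < 0:  # can only happen through rounding; widen marginally
        hi = c_active * (1 + 1e-12)
    f = brentq(g, 0.0, hi, xtol=1e-18 * max(c_active, 1.0), rtol=8.9e-16, maxiter=200)
    # one or two Newton steps drive the conservation residual to machine precision
    for _ in range(2):
        resid = g(f)
        dg = 1.0 + float(np.sum(totals * kds / (kds + f) ** 2))
        step = resid / dg
        if f - step >= 0:
            f -= step
    return max(f, 0.0)


def equilibrate(system: AllocatorSystem) -> BoundState:
    """Unique mass-action equilibrium of the sigma-for-core competition.

    Returns a :class:`BoundState`; conservation
    ``free_core + sum(complexes) == active_core_total`` is verified to
    relative tolerance ``CONSERVATION_RTOL`` and a :class:`NumericalError`
    is raised if the solver fails it.

    With no sigma fragments (or all totals zero) the core stays free.
    In the titration limit (all ``kd_core == 0``) the partition is
    stoichiometric: everything binds while core remains; once sigma
    totals exceed the budget the core is split in proportion to totals.
    """
    c_active = activate_core(system.core)
    names = [s.name for s in system.sigmas]
    totals = np.array([s.total for s in system.sigmas], dtype=float)
    kds = np.array([s.kd_core for s in system.sigmas], dtype=float)

    if len(names) == 0 or c_active == 0.0 or float(totals.sum()) == 0.0:
        return BoundState(c_active, {n: 0.0 for n in names}, c_active)

    if np.all(kds == 0.0):
        s_tot = float(totals.sum())
        if s_tot <= c_active:
            complexes = totals.copy()
            free = c_active - s_tot
        else:
            complexes = c_active * totals / s_tot
            free = 0.0
    else:
        free = _solve_free_core(c_active, totals, kds)
        complexes = totals * free / (kds + free)

    resid = abs(free + float(complexes.sum()) - c_active)
    if resid > CONSERVATION_RTOL * c_active:
        raise NumericalError(
            f"core conservation violated: residual {resid:.3e} on active total "
            f"{c_active:.6g} (free={free:.6g}, n_sigma={len(names)})"
        )
    return BoundState(free, dict(zip(names, complexes.tolist())), c_active)


def promoter_activities(state: BoundState, system: AllocatorSystem) -> dict[str, float]:
    """Activity of each promoter, AU: ``basal + sum_i eff_i * xt[i,p] * complex_i``.

    Promoter activity is assumed linearly proportional to the number of
    bound (active) polymerases; null fragments contribute nothing since
    their efficiency is zero.
    """
    acts: dict[str, float] = {}
    for p in system.promoters:
        a = p.basal
        for s in system.sigmas:
            a += s.efficiency * system.crosstalk.get(s.name, p.name) * state.complexes[s.name]
        acts[p.name] = a
    return acts


def saturated_shares(sigma_totals: dict[str, float]) -> dict[str, float]:
    """Bound-core fractions in the saturated regime: ``x_i / sum_j x_j``.

    When the pool is fully titrated, the fraction of core bound by each
    sigma fragment (null fragments included) depends only on relative
    expression.  Raises :class:`UndefinedShareError` if all totals are
    zero.
    """
    for name, x in sigma_totals.items():
        if x < 0:
            raise ValidationError(f"sigma {name!r}: total must be >= 0")
    total = sum(sigma_totals.values())
    if total == 0:
        raise UndefinedShareError("all sigma totals are zero; shares undefined")
    return {name: x / total for name, x in sigma_totals.items()}
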