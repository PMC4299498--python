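"""Reporter-assay processing and model inference.

Implements the measurement chain used to characterise the split-RNAP
resource allocator from endpoint flow-cytometry reporter assays:

* promoter activity = per-sample geometric-mean fluorescence minus the
  white-cell (autofluorescence) background, negatives retained;
* fold induction = white-cell-corrected activity over the reporter-only
  (no polymerase) activity;
* "fraction core utilized" = activity normalised by the promoter's
  single-sigma saturation activity under the same allocator, estimating
  the fraction of the core pool bound by that sigma fragment;
* sum constancy of competing promoters (the core budget is conserved);
* through-origin regression of low- versus high-allocator activities
  (the budget scales all outputs equally);
* a one-parameter saturated-competition fit: with the core pool fully
  titrated, the induced fragment's bound fraction is x/(x+s) where x is
  its expression and s — the only free parameter — is the competitor's
  constant relative expression;
* sigma x promoter orthogonality matrices;
* copy-number compensation via the alpha fragment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import bootstrap, gmean

from .errors import (
    DegenerateFitError,
    InfeasibleTargetError,
    InsufficientDataError,
    UndefinedFoldError,
    ValidationError,
)
from .model import AllocatorSystem, CoreSpec, equilibrate, promoter_activities

__all__ = [
    "REQUIRED_COLUMNS",
    "MeasurementTable",
    "InductionModel",
    "ExpressionCalibration",
    "FitResult",
    "promoter_activity",
    "fold_induction",
    "fraction_core_utilized",
    "sum_constancy",
    "core_ratio_regression",
    "fit_relative_expression",
    "orthogonality_matrix",
    "compensate_alpha_expression",
]

REQUIRED_COLUMNS = ("condition", "iptg_uM", "promoter", "replicate", "fluorescence_au")


@dataclass
class MeasurementTable:
    """Long-format replicate fluorescence records plus batch metadata.

    ``data`` must carry the columns in :data:`REQUIRED_COLUMNS` (an
    optional ``batch`` column selects the white-cell value; a single
    ``"default"`` batch is assumed otherwise).  ``white_cell`` maps batch
    to white-cell fluorescence (AU); ``reporter_only`` maps promoter to
    reporter-only fluorescence (AU).  ``extra`` holds free-form metadata
    (seed, calibration series, generator truth).
    """

    data: pd.DataFrame
    white_cell: dict[str, float]
    reporter_only: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"measurement table missing column(s): {missing}")
        if len(self.data) == 0:
            raise ValidationError("measurement table is empty")
        fl = self.data["fluorescence_au"].to_numpy(dtype=float)
        if not np.all(np.isfinite(fl)):
            raise ValidationError("fluorescence values must be finite")
        batches = (
            self.data["batch"].unique() if "batch" in self.data.columns else ["default"]
        )
        for b in batches:
            if b not in self.white_cell:
                raise ValidationError(f"no white-cell fluorescence for batch {b!r}")

    # -- persistence ---------------------------------------------------
    def write(self, csv_path: str | Path, metadata_path: str | Path) -> None:
        self.data.to_csv(csv_path, index=False)
        meta = {
            "white_cell": self.white_cell,
            "reporter_only": self.reporter_only,
            **self.extra,
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, csv_path: str | Path, metadata_path: str | Path) -> "MeasurementTable":
        data = pd.read_csv(csv_path)
        meta = json.loads(Path(metadata_path).read_text())
        white = {str(k): float(v) for k, v in meta.pop("white_cell", {}).items()}
        rep = {str(k): float(v) for k, v in meta.pop("reporter_only", {}).items()}
        return cls(data=data, white_cell=white, reporter_only=rep, extra=meta)


@dataclass(frozen=True)
class InductionModel:
    """Hill dose-response mapping inducer concentration to expression.

    ``expression(iptg) = basal + (vmax - basal) * iptg^n / (k_half^n + iptg^n)``.
    ``basal`` captures leaky expression of the uninduced promoter.
    """

    basal: float
    vmax: float
    k_half: float
    hill_n: float

    def __post_init__(self) -> None:
        if not (self.vmax >= self.basal >= 0):
            raise ValidationError("induction model requires vmax >= basal >= 0")
        if self.k_half <= 0 or self.hill_n <= 0:
            raise ValidationError("induction model requires k_half > 0 and hill_n > 0")

    def expression(self, iptg: float) -> float:
        iptg = np.asarray(iptg, dtype=float)
        with np.errstate(divide="ignore"):
            frac = iptg**self.hill_n / (self.k_half**self.hill_n + iptg**self.hill_n)
        return self.basal + (self.vmax - self.basal) * frac


class ExpressionCalibration:
    """Inducer -> expression calibration from a measured series.

    Piecewise-linear interpolation of measured (iptg, expression) points
    — the preferred route when a calibration series exists — with a Hill
    fit available as a smooth fallback.
    """

    def __init__(self, iptg: np.ndarray, expression: np.ndarray):
        iptg = np.asarray(iptg, dtype=float)
        expression = np.asarray(expression, dtype=float)
        if len(iptg) < 2:
            raise ValidationError("calibration needs at least two points")
        order = np.argsort(iptg)
        self.iptg = iptg[order]
        self.expression = expression[order]

    def __call__(self, iptg) -> np.ndarray:
        return np.interp(np.asarray(iptg, dtype=float), self.iptg, self.expression)

    def fit_hill(self) -> InductionModel:
        lo, hi = float(self.expression.min()), float(self.expression.max())
        x0 = np.array([max(lo, 1e-9), max(hi, 1e-9), np.median(self.iptg[self.iptg > 0]), 2.0])

        def resid(p):
            m = InductionModel(min(p[0], p[1]), max(p[0], p[1]), abs(p[2]) + 1e-12, abs(p[3]) + 1e-6)
            return m.expression(self.iptg) - self.expression

        sol = least_squares(resid, x0)
        p = sol.x
        return InductionModel(min(p[0], p[1]), max(p[0], p[1]), abs(p[2]) + 1e-12, abs(p[3]) + 1e-6)


@dataclass
class FitResult:
    """Parameter estimates with residual norm and bootstrap intervals."""

    parameters: dict[str, float]
    residual_norm: float
    bootstrap_ci: dict[str, tuple[float, float]]
    n_boot: int
    seed: int | None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        # percentile intervals are widened, if needed, to contain the estimate
        for name, est in self.parameters.items():
            if name in self.bootstrap_ci:
                lo, hi = self.bootstrap_ci[name]
                self.bootstrap_ci[name] = (min(lo, est), max(hi, est))

    def to_json(self) -> str:
        return json.dumps(
            {
                "parameters": self.parameters,
                "residual_norm": self.residual_norm,
                "bootstrap_ci": {k: list(v) for k, v in self.bootstrap_ci.items()},
                "n_boot": self.n_boot,
                "seed": self.seed,
                "ci_level": self.ci_level,
            },
            indent=2,
            sort_keys=True,
        )


# ----------------------------------------------------------------------
# normalisation chain
# ----------------------------------------------------------------------

def promoter_activity(table: MeasurementTable) -> pd.DataFrame:
    """Background-corrected activities per (condition, iptg, promoter).

    The geometric mean over replicate fluorescences is computed first,
    then the batch white-cell fluorescence is subtracted; negative
    activities are retained.
    """
    df = table.data.copy()
    if "batch" not in df.columns:
        df["batch"] = "default"
    if (df["fluorescence_au"] < 0).any():
        raise ValidationError("geometric mean requires non-negative fluorescence values")

    def _one(group: pd.DataFrame) -> pd.Series:
        batch = group["batch"].iloc[0]
        vals = group["fluorescence_au"].to_numpy(dtype=float)
        g = 0.0 if np.any(vals == 0) else gmean(vals)
        return pd.Series(
            {
                "activity_au": g - table.white_cell[batch],
                "n_replicates": len(group),
            }
        )

    out = (
        df.groupby(["condition", "iptg_uM", "promoter"], sort=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out


def fold_induction(activity_test: float, activity_reporter_only: float) -> float:
    """Ratio of white-cell-corrected test activity to reporter-only activity."""
    if activity_reporter_only <= 0:
        raise UndefinedFoldError(
            f"reporter-only activity must be > 0, got {activity_reporter_only}"
        )
    return activity_test / activity_reporter_only


def fraction_core_utilized(
    activities: pd.DataFrame, saturation: dict[str, float]
) -> pd.DataFrame:
    """Normalise activities by each promoter's single-sigma saturation activity.

    ``saturation`` maps promoter name to the activity measured when its
    cognate sigma fragment alone saturates the same allocator.  The
    result estimates the fraction of the core pool bound by that sigma;
    noisy values may exceed 1 and are not clipped.
    """
    out = activities.copy()
    missing = sorted(set(out["promoter"]) - set(saturation))
    if missing:
        raise ValidationError(f"no saturation reference for promoter(s): {missing}")
    for p, ref in saturation.items():
        if ref <= 0:
            raise ValidationError(f"saturation activity for {p!r} must be > 0")
    out["fraction"] = out.apply(
        lambda r: r["activity_au"] / saturation[r["promoter"]], axis=1
    )
    return out


def sum_constancy(activities: pd.DataFrame) -> tuple[float, float]:
    """Mean and coefficient of variation of per-induction-point activity sums.

    The allocator conserves the core budget, so the summed activity of
    competing promoters should stay flat across the induction series.
    """
    sums = activities.groupby("iptg_uM")["activity_au"].sum()
    if len(sums) < 2:
        raise ValidationError("sum constancy needs at least two induction points")
    mean = float(sums.mean())
    cv = float(sums.std(ddof=1) / mean) if mean != 0 else float("inf")
    return mean, cv


# ----------------------------------------------------------------------
# regression and model fitting
# ----------------------------------------------------------------------

def core_ratio_regression(
    low_activities: np.ndarray,
    high_activities: np.ndarray,
    *,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> FitResult:
    """Through-origin least-squares slope of low- vs high-allocator activities.

    Paired points (same condition/inducer/promoter at two core levels)
    are regressed as ``low = slope * high`` with the intercept fixed to
    zero: ``slope = sum(x*y) / sum(x^2)``.  The slope estimates the
    ratio of the two core budgets.  The CI is a nonparametric percentile
    bootstrap over the paired points.
    """
    y = np.asarray(low_activities, dtype=float)
    x = np.asarray(high_activities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("low/high activity arrays must be 1-D and paired")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise DegenerateFitError("all high-allocator activities are zero")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x

    def _slope(xs, ys, axis=-1):
        denom = np.sum(xs * xs, axis=axis)
        return np.sum(xs * ys, axis=axis) / np.where(denom > 0, denom, np.nan)

    if n_boot > 0:
        with warnings.catch_warnings():
            # exact (noiseless) data give a degenerate bootstrap distribution;
            # the CI then collapses onto the point estimate below
            warnings.simplefilter("ignore")
            boot = bootstrap(
                (x, y),
                _slope,
                paired=True,
                vectorized=True,
                n_resamples=n_boot,
                confidence_level=ci_level,
                method="BCa",
                rng=np.random.default_rng(seed),
            )
        lo, hi = boot.confidence_interval.low, boot.confidence_interval.high
        if not (np.isfinite(lo) and np.isfinite(hi)):
            lo = hi = slope
    else:
        lo = hi = slope
    return FitResult(
        parameters={"slope": slope},
        residual_norm=float(np.sqrt(np.sum(resid**2))),
        bootstrap_ci={"slope": (float(lo), float(hi))},
        n_boot=n_boot,
        seed=seed,
        ci_level=ci_level,
    )


def _shares_residuals(s: float, x: np.ndarray, f_ind: np.ndarray, f_comp: np.ndarray) -> np.ndarray:
    pred_ind = x / (x + s)
    pred_comp = s / (x + s)
    return np.concatenate([f_ind - pred_ind, f_comp - pred_comp])


def fit_relative_expression(
    x: np.ndarray,
    fraction_induced: np.ndarray,
    fraction_competitor: np.ndarray,
    *,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> FitResult:
    """Fit the single parameter of the saturated-competition model.

    With the core pool fully titrated, the bound-core fraction of the
    induced sigma fragment at expression ``x`` is ``x / (x + s)`` and the
    constant competitor's fraction is ``s / (x + s)``, where ``s`` is the
    competitor's (unmeasured) relative expression — the model's only free
    parameter.  Both normalised curves are fitted jointly by least
    squares on the fraction scale.  The bootstrap resamples induction
    points (with their replicate rows) nonparametrically.
    """
    x = np.asarray(x, dtype=float)
    f_ind = np.asarray(fraction_induced, dtype=float)
    f_comp = np.asarray(fraction_competitor, dtype=float)
    if not (x.shape == f_ind.shape == f_comp.shape) or x.ndim != 1:
        raise ValidationError("x and fraction arrays must be 1-D with equal length")
    points = np.unique(x)
    if len(points) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct induction points, got {len(points)}"
        )

    def _fit(xv, fi, fc) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            moment = xv * fc / np.where(fi > 0, fi, np.nan)
        s0 = float(np.nanmedian(moment))
        if not np.isfinite(s0) or s0 <= 0:
            s0 = max(float(np.median(xv[xv > 0])) if np.any(xv > 0) else 1.0, 1e-6)
        sol = least_squares(
            lambda p: _shares_residuals(np.exp(p[0]), xv, fi, fc),
            x0=[np.log(s0)],
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        return float(np.exp(sol.x[0]))

    s_hat = _fit(x, f_ind, f_comp)
    resid = _shares_residuals(s_hat, x, f_ind, f_comp)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        groups = [np.flatnonzero(x == p) for p in points]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            sel = rng.integers(0, len(groups), len(groups))
            idx = np.concatenate([groups[i] for i in sel])
            boots[b] = _fit(x[idx], f_ind[idx], f_comp[idx])
        alpha = (1 - ci_level) / 2
        lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    else:
        lo = hi = s_hat
    return FitResult(
        parameters={"s": s_hat},
        residual_norm=float(np.sqrt(np.sum(resid**2))),
        bootstrap_ci={"s": (float(lo), float(hi))},
        n_boot=n_boot,
        seed=seed,
        ci_level=ci_level,
    )


def orthogonality_matrix(
    activities: pd.DataFrame,
    *,
    normalize: bool = False,
    cognate: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Sigma x promoter activity matrix at saturating induction.

    ``activities`` needs columns ``sigma``, ``promoter``, ``activity_au``
    with one value per cell.  With ``normalize=True`` each promoter
    column is divided by its cognate sigma's activity (``cognate`` maps
    promoter -> sigma), so cognate cells read 1 and off-diagonals give
    relative cross-reactivity.
    """
    for col in ("sigma", "promoter", "activity_au"):
        if col not in activities.columns:
            raise ValidationError(f"orthogonality input missing column {col!r}")
    mat = activities.pivot_table(
        index="sigma", columns="promoter", values="activity_au", aggfunc="mean"
    )
    if mat.isna().any().any():
        missing = [
            (s, p) for s in mat.index for p in mat.columns if pd.isna(mat.loc[s, p])
        ]
        raise ValidationError(f"missing sigma x promoter cell(s): {missing}")
    if normalize:
        if cognate is None:
            raise ValidationError("normalize=True requires a promoter->sigma cognate map")
        for p in mat.columns:
            ref = mat.loc[cognate[p], p]
            if ref <= 0:
                raise ValidationError(f"cognate activity for promoter {p!r} must be > 0")
            mat[p] = mat[p] / ref
    return mat


def compensate_alpha_expression(
    copy_numbers: dict[str, float],
    target_activity: float,
    system: AllocatorSystem,
    promoter: str | None = None,
) -> dict[str, float]:
    """Per-copy alpha cassette strength compensating plasmid copy number.

    For each backbone the alpha dose is ``strength * copy_number``.  The
    reporter cassette scales with copy number as well, but with the
    polymerase limiting, promoter activity tracks bound polymerase, not
    promoter dosage, so the reporter scaling drops out of the readout.
    The per-copy strength is solved (1-D root finding) so every backbone
    reaches ``target_activity`` on ``promoter`` despite different copy
    numbers; strengths come out inversely related to copy number.  The
    full-length core (``requires_alpha=False``) offers no such knob and
    raises :class:`InfeasibleTargetError`.
    """
    if not system.core.requires_alpha:
        raise InfeasibleTargetError(
            "core does not require alpha: activities scale with copy number and "
            "cannot be compensated"
        )
    for name, n in copy_numbers.items():
        if n <= 0:
            raise ValidationError(f"copy number for {name!r} must be > 0")
    if promoter is None:
        promoter = system.promoters[0].name

    def activity(alpha_total: float) -> float:
        core = CoreSpec(system.core.total, True, system.core.kd_alpha, alpha_total)
        sys_a = AllocatorSystem(core, system.sigmas, system.promoters, system.crosstalk)
        return promoter_activities(equilibrate(sys_a), sys_a)[promoter]

    ceiling = activity(1e9 * system.core.total)
    if target_activity > ceiling * (1 - 1e-9):
        raise InfeasibleTargetError(
            f"target {target_activity:.4g} exceeds beta-core ceiling {ceiling:.4g}"
        )
    f = lambda a: activity(a) - target_activity
    hi = system.core.total
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12 * system.core.total:
            raise InfeasibleTargetError(f"target {target_activity:.4g} unreachable")
    alpha_needed = brentq(f, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
    return {name: alpha_needed / copy for name, copy in copy_numbers.items()}
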