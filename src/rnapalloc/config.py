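"""YAML/JSON configuration round-tripping for systems, generators, dynamics."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .assay import InductionModel
from .dynamics import DynamicsConfig, Schedule
from .errors import ValidationError
from .model import AllocatorSystem, CoreSpec, CrosstalkMatrix, PromoterSpec, SigmaSpec
from .synthetic import GeneratorConfig, default_system

__all__ = [
    "load_config",
    "system_from_dict",
    "system_to_dict",
    "generator_config_from_dict",
    "dynamics_from_dict",
    "schedule_from_dict",
]

SCHEMA_VERSION = 1


def load_config(path: str | Path) -> dict:
    """Parse a YAML or JSON config file into a dict."""
    text = Path(path).read_text()
    try:
        if str(path).endswith(".json"):
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ValidationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"config {path} must be a mapping at top level")
    return doc


def system_from_dict(doc: dict) -> AllocatorSystem:
    try:
        core_doc = doc["core"]
        core = CoreSpec(
            total=float(core_doc["total"]),
            requires_alpha=bool(core_doc.get("requires_alpha", False)),
            kd_alpha=float(core_doc.get("kd_alpha", 1.0)),
            alpha_total=float(core_doc.get("alpha_total", 0.0)),
        )
        sigmas = tuple(
            SigmaSpec(
                name=s["name"],
                total=float(s.get("total", 0.0)),
                kd_core=float(s["kd_core"]),
                efficiency=float(s.get("efficiency", 1.0)),
                is_null=bool(s.get("is_null", False)),
            )
            for s in doc["sigmas"]
        )
        promoters = tuple(
            PromoterSpec(
                name=p["name"],
                cognate_sigma=p["cognate_sigma"],
                basal=float(p.get("basal", 0.0)),
            )
            for p in doc["promoters"]
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"system config missing or malformed field: {exc}") from exc
    crosstalk = None
    if "crosstalk" in doc and doc["crosstalk"] is not None:
        x = doc["crosstalk"]
        try:
            crosstalk = CrosstalkMatrix(
                tuple(x["sigmas"]),
                tuple(x["promoters"]),
                tuple(tuple(float(v) for v in row) for row in x["values"]),
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"crosstalk config malformed: {exc}") from exc
    return AllocatorSystem(core, sigmas, promoters, crosstalk)


def system_to_dict(system: AllocatorSystem) -> dict:
    return {
        "core": {
            "total": system.core.total,
            "requires_alpha": system.core.requires_alpha,
            "kd_alpha": system.core.kd_alpha,
            "alpha_total": system.core.alpha_total,
        },
        "sigmas": [
            {
                "name": s.name,
                "total": s.total,
                "kd_core": s.kd_core,
                "efficiency": s.efficiency,
                "is_null": s.is_null,
            }
            for s in system.sigmas
        ],
        "promoters": [
            {"name": p.name, "cognate_sigma": p.cognate_sigma, "basal": p.basal}
            for p in system.promoters
        ],
        "crosstalk": {
            "sigmas": list(system.crosstalk.sigma_names),
            "promoters": list(system.crosstalk.promoter_names),
            "values": [list(r) for r in system.crosstalk.values],
        },
        "schema_version": SCHEMA_VERSION,
    }


def _induction_from_dict(doc: dict | None) -> InductionModel | None:
    if doc is None:
        return None
    try:
        return InductionModel(
            basal=float(doc.get("basal", 0.0)),
            vmax=float(doc["vmax"]),
            k_half=float(doc["k_half"]),
            hill_n=float(doc.get("hill_n", 2.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"induction config malformed: {exc}") from exc


def generator_config_from_dict(doc: dict, seed: int | None = None) -> GeneratorConfig:
    system = system_from_dict(doc["system"]) if "system" in doc else default_system(
        **doc.get("default_system", {})
    )
    gen = doc.get("generator", {})
    kwargs = {
        k: gen[k]
        for k in (
            "replicates",
            "noise_cv",
            "white_cell_mean",
            "reporter_only_mean",
            "core_ratio",
            "batch_factor",
            "seed",
        )
        if k in gen
    }
    if "iptg_grid" in gen:
        kwargs["iptg_grid"] = tuple(float(v) for v in gen["iptg_grid"])
    if seed is not None:
        kwargs["seed"] = int(seed)
    return GeneratorConfig(
        system=system, induction=_induction_from_dict(doc.get("induction")), **kwargs
    )


def dynamics_from_dict(doc: dict) -> DynamicsConfig:
    dyn = doc.get("dynamics", {})
    allowed = {
        "dilution_rate",
        "core_production",
        "toxicity_threshold",
        "mode",
        "time_step",
        "quasi_equilibrium",
        "binding_on_rate",
    }
    unknown = set(dyn) - allowed
    if unknown:
        raise ValidationError(f"unknown dynamics config key(s): {sorted(unknown)}")
    return DynamicsConfig(**dyn)


def schedule_from_dict(doc: dict) -> Schedule:
    sched = doc.get("schedule")
    if sched is None:
        raise ValidationError("config is missing a 'schedule' section")
    try:
        events = tuple(
            (float(e[0]), str(e[1]), float(e[2])) for e in sched.get("events", [])
        )
        return Schedule(events=events, horizon=float(sched["horizon"]))
    except (KeyError, TypeError, IndexError) as exc:
        raise ValidationError(f"schedule config malformed: {exc}") from exc
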