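"""Clinic configuration I/O, result serialization, and the pipeline driver.

A clinic configuration is a YAML (or JSON) document with sections
``resources``, ``activities``, ``pathways`` and either ``clinic`` (a single
profile) or ``clinics`` (several profiles sharing one process map, with a
selector choosing which to load).  The bundled fixture describing the two
published physiotherapy clinics ships in this format under
``tdabc/data/clinics.yaml`` and is loaded through the same code path as
user configurations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .costing import CURRENCY
from .model import (
    Activity,
    ClinicModel,
    ClinicProfile,
    ElicitedQuantity,
    Pathways,
    StaffResource,
    validate_process_map,
    ProcessMap,
)
from .scenarios import projection_table, scenario_cost_table
from .uncertainty import DEFAULT_ITERATIONS, DEFAULT_SEED, activity_cost_table, child_seed

logger = logging.getLogger(__name__)

FIXTURE_RESOURCE = "data/clinics.yaml"

#: Money columns rounded to cents when tables are serialized.
_MONEY_COLUMNS = ("mean", "sd", "ci_low", "ci_high", "mean_cost_per_event", "annual_cost")


class ConfigError(ValueError):
    """A clinic configuration file is missing, malformed, or invalid."""


class ReportedStats(BaseModel):
    """Published Monte Carlo summary carried alongside a fixture activity."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    mean: float
    sd: float
    ci_low: float
    ci_high: float


class ActivityEntry(BaseModel):
    """Raw activity record as it appears in a configuration file."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    id: int
    label: str
    process: Literal["referral", "booking", "reminder", "attendance"]
    performer: str
    duration: ElicitedQuantity
    pathway_tags: list[str] = []
    clinics: Optional[list[str]] = None
    reported: Optional[ReportedStats] = None

    def to_activity(self) -> Activity:
        tags = set(self.pathway_tags) | set(self.clinics or [])
        return Activity(
            id=self.id,
            label=self.label,
            process=self.process,
            performer=self.performer,
            duration=self.duration,
            pathway_tags=frozenset(tags),
        )


class ConfigFile(BaseModel):
    """Schema of a clinic configuration document."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    currency: str = CURRENCY
    resources: list[StaffResource]
    clinic: Optional[ClinicProfile] = None
    clinics: dict[str, ClinicProfile] = {}
    activities: list[ActivityEntry]
    pathways: Pathways


def _load_raw(path: Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: cannot parse: {exc}") from exc
    if raw is None:
        raise ConfigError(f"{path}: configuration file is empty")
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(raw).__name__}")
    return raw


def _format_validation_error(source: str, exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return f"{source}: invalid configuration:\n  " + "\n  ".join(lines)


def _select_profile(cfg: ConfigFile, source: str, clinic: Optional[str]) -> ClinicProfile:
    if cfg.clinics:
        if clinic is None:
            if len(cfg.clinics) == 1:
                return next(iter(cfg.clinics.values()))
            raise ConfigError(
                f"{source}: declares several clinics "
                f"({', '.join(cfg.clinics)}); a selector is required"
            )
        if clinic not in cfg.clinics:
            raise ConfigError(
                f"{source}: unknown clinic {clinic!r}; available: {', '.join(cfg.clinics)}"
            )
        return cfg.clinics[clinic]
    if cfg.clinic is None:
        raise ConfigError(f"{source}: neither 'clinic' nor 'clinics' section present")
    if clinic is not None and clinic != cfg.clinic.name:
        raise ConfigError(f"{source}: file declares clinic {cfg.clinic.name!r}, not {clinic!r}")
    return cfg.clinic


def parse_config(raw: dict, source: str = "<config>", clinic: Optional[str] = None) -> ClinicModel:
    """Validate a raw configuration mapping into a per-clinic model.

    Activities restricted to other clinics are dropped, as are attendance
    response segments referencing them; the resulting process map is then
    structurally validated (hard failure on any issue).
    """
    try:
        cfg = ConfigFile.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(source, exc)) from exc

    profile = _select_profile(cfg, source, clinic)

    kept = [
        e for e in cfg.activities if e.clinics is None or profile.name in e.clinics
    ]
    kept_ids = {e.id for e in kept}
    pathways = cfg.pathways.model_copy(
        update={
            "response": {
                name: seg
                for name, seg in cfg.pathways.response.items()
                if set(seg.activities) <= kept_ids
            }
        }
    )

    model = ClinicModel(
        process_map=ProcessMap(
            activities=[e.to_activity() for e in kept], pathways=pathways
        ),
        profile=profile,
        resources={r.id: r for r in cfg.resources},
    )
    validate_process_map(model.process_map, model.resources).raise_if_invalid()
    return model


def read_clinic_config(path: Path, clinic: Optional[str] = None) -> ClinicModel:
    """Load and validate a clinic configuration file (YAML or JSON)."""
    path = Path(path)
    return parse_config(_load_raw(path), source=str(path), clinic=clinic)


def _fixture_raw() -> dict:
    text = resources.files("tdabc").joinpath(FIXTURE_RESOURCE).read_text()
    return yaml.safe_load(text)


def load_paper_fixture(clinic: str) -> ClinicModel:
    """Load one of the two bundled clinics (``clinic1`` or ``clinic2``).

    clinic1 is the musculoskeletal clinic (2997 referrals/year, 8%
    non-attendance, 4% cancellation); clinic2 the women's, men's and
    pelvic health clinic (3347 referrals/year, 10% non-attendance, 8%
    cancellation).
    """
    return parse_config(_fixture_raw(), source=FIXTURE_RESOURCE, clinic=clinic)


def paper_reference(clinic: Optional[str] = None) -> pd.DataFrame:
    """Published per-activity Monte Carlo summaries from the bundled fixture.

    One row per activity: elicited duration triple, performer, and the
    published simulated mean/SD/95% CI.  Used as a cross-check reference
    by tests and reproduction scripts, never as a costing input.
    """
    raw = _fixture_raw()
    cfg = ConfigFile.model_validate(raw)
    rows = []
    for e in cfg.activities:
        if clinic is not None and e.clinics is not None and clinic not in e.clinics:
            continue
        rows.append(
            {
                "activity_id": e.id,
                "label": e.label,
                "performer": e.performer,
                "time_mean": e.duration.mean,
                "time_low": e.duration.low,
                "time_high": e.duration.high,
                "reported_mean": e.reported.mean if e.reported else None,
                "reported_sd": e.reported.sd if e.reported else None,
                "reported_ci_low": e.reported.ci_low if e.reported else None,
                "reported_ci_high": e.reported.ci_high if e.reported else None,
            }
        )
    return pd.DataFrame(rows)


def write_clinic_config(model: ClinicModel, path: Path) -> None:
    """Serialize a single-clinic model back to a YAML configuration file.

    ``read_clinic_config`` on the written file reproduces the model
    field-for-field.
    """
    doc = {
        "currency": CURRENCY,
        "resources": [
            r.model_dump(exclude_none=True) for r in model.resources.values()
        ],
        "clinic": model.profile.model_dump(),
        "activities": [
            {
                "id": a.id,
                "label": a.label,
                "process": a.process,
                "performer": a.performer,
                "pathway_tags": sorted(a.pathway_tags),
                "duration": a.duration.model_dump(),
            }
            for a in model.process_map.activities
        ],
        "pathways": model.process_map.pathways.model_dump(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


class RunConfig(BaseModel):
    """Parameters of one end-to-end pipeline run."""

    model_config = ConfigDict(frozen=True)

    input_path: Optional[Path] = None  # None -> bundled fixture
    clinic: Optional[str] = None
    iterations: int = Field(default=DEFAULT_ITERATIONS, ge=1)
    seed: int = DEFAULT_SEED
    output_dir: Optional[Path] = None
    format: Literal["csv", "json"] = "csv"


@dataclass
class PipelineResult:
    """Tables produced by one pipeline run."""

    model: ClinicModel
    activity_costs: pd.DataFrame
    scenario_costs: pd.DataFrame
    projections: pd.DataFrame


def _round_money(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _MONEY_COLUMNS:
        if col in out.columns:
            out[col] = out[col].round(2)
    return out


def write_table(df: pd.DataFrame, path: Path, fmt: str = "csv") -> None:
    """Write a result table, rounding monetary columns to cents."""
    out = _round_money(df)
    if fmt == "csv":
        out.to_csv(path, index=False)
    elif fmt == "json":
        out.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full costing pipeline for one clinic.

    Loads and validates the model, simulates per-activity costs, costs
    every enumerated scenario, and projects annual costs at the clinic's
    non-attendance / cancellation rates.  Stage seeds are derived from the
    run seed, so a rerun with the same configuration is bit-identical.
    """
    if cfg.input_path is None:
        if cfg.clinic is None:
            raise ConfigError("a clinic selector is required with the bundled fixture")
        model = load_paper_fixture(cfg.clinic)
        source = FIXTURE_RESOURCE
    else:
        model = read_clinic_config(cfg.input_path, clinic=cfg.clinic)
        source = str(cfg.input_path)
    logger.info(
        "pipeline: clinic=%s source=%s iterations=%d seed=%d",
        model.profile.name, source, cfg.iterations, cfg.seed,
    )

    activity_costs = activity_cost_table(
        model, n=cfg.iterations, seed=child_seed(cfg.seed, "activities")
    )
    scenario_costs = scenario_cost_table(
        model, n=cfg.iterations, seed=child_seed(cfg.seed, "scenarios")
    )
    projections = projection_table(model, scenario_costs)

    if cfg.output_dir is not None:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = cfg.format
        write_table(activity_costs, outdir / f"activity_costs.{ext}", ext)
        write_table(scenario_costs, outdir / f"scenario_costs.{ext}", ext)
        write_table(projections, outdir / f"projections.{ext}", ext)
        logger.info("pipeline: wrote tables to %s", outdir)

    return PipelineResult(
        model=model,
        activity_costs=activity_costs,
        scenario_costs=scenario_costs,
        projections=projections,
    )
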