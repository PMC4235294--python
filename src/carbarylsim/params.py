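"""Model parameters, configuration loading and body-weight scaling.

All parameters of the carbaryl PBPK/PD model live in one validated,
immutable :class:`ModelParams` tree (physiology / chemical / pharmacodynamic
/ Monte Carlo sections).  Configuration files are YAML with a strict schema:
unknown keys are rejected and every invariant violation raises an error that
names the offending parameter.

Units convention (documented per field below): amounts nmol, volumes L,
times h for rate constants, urine output L/min (the unit urine flow is
reported in by biomonitoring surveys).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterator, Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

#: perfused, diffusion-limited tissue compartments (exchange with plasma)
TISSUES = ("liver", "fat", "brain", "rest")
#: compartments in which carbaryl hydrolysis to 1-naphthol occurs
HYDROLYSIS_COMPARTMENTS = ("gi", "liver", "fat", "brain", "rest", "plasma", "rbc")
#: tissues / blood cells with a partition coefficient against plasma
PARTITIONED = ("liver", "fat", "brain", "rest", "rbc")
#: sites carrying an acetylcholinesterase pharmacodynamic sub-model
PD_SITES = ("brain", "rbc")


class ConfigError(ValueError):
    """Raised when a configuration file is missing, malformed or invalid."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


def _require_keys(mapping: dict, keys: tuple[str, ...], field: str) -> None:
    got = set(mapping)
    want = set(keys)
    if got != want:
        missing = sorted(want - got)
        extra = sorted(got - want)
        raise ValueError(
            f"{field}: expected keys {sorted(want)}; missing {missing}, unknown {extra}"
        )


class PhysiologyParams(_Strict):
    """Anatomy and physiology of one (reference or scaled) individual.

    body_weight kg; cardiac_output L/h; tissue_volume_fraction — fraction of
    body weight per compartment (blood included, density 1 kg/L assumed);
    blood_flow_fraction — fraction of cardiac output per perfused tissue;
    hematocrit — RBC volume fraction of blood; urine_output L/min (bladder
    filling rate: void volume over inter-void time).
    """

    body_weight: float
    cardiac_output: float
    tissue_volume_fraction: dict[str, float]
    blood_flow_fraction: dict[str, float]
    hematocrit: float
    urine_output: float

    @model_validator(mode="after")
    def _check(self) -> "PhysiologyParams":
        _require_keys(
            self.tissue_volume_fraction,
            TISSUES + ("blood",),
            "tissue_volume_fraction",
        )
        _require_keys(self.blood_flow_fraction, TISSUES, "blood_flow_fraction")
        for name in ("body_weight", "cardiac_output", "urine_output"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for key, v in self.tissue_volume_fraction.items():
            if v <= 0:
                raise ValueError(f"tissue_volume_fraction.{key} must be positive")
        for key, v in self.blood_flow_fraction.items():
            if v <= 0:
                raise ValueError(f"blood_flow_fraction.{key} must be positive")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError(f"hematocrit must lie in (0, 1), got {self.hematocrit}")
        vsum = sum(self.tissue_volume_fraction.values())
        if vsum > 1.0 + 1e-12:
            raise ValueError(f"tissue volume fractions sum to {vsum:.4f} > 1")
        qsum = sum(self.blood_flow_fraction.values())
        if qsum > 1.0 + 1e-12:
            raise ValueError(f"blood flow fractions sum to {qsum:.4f} > 1")
        return self


class ChemicalParams(_Strict):
    """Carbaryl and 1-naphthol disposition constants.

    ka 1/h oral absorption; partition_coefficient (tissue:plasma,
    dimensionless); permeability_area L/h membrane conductance per tissue;
    hydrolysis_rate 1/h carbaryl -> 1-naphthol per compartment;
    naphthol_metabolism_rate 1/h (1-N -> unspecified further metabolites);
    naphthol_urinary_clearance L/h; naphthol_volume L (single well-mixed
    1-N disposition pool).  The optional Michaelis–Menten branch replaces
    first-order hepatic hydrolysis when enabled (mm_vmax nmol/h, mm_km nM);
    exposure-range doses sit far below saturation so it ships disabled.
    """

    ka: float
    partition_coefficient: dict[str, float]
    permeability_area: dict[str, float]
    hydrolysis_rate: dict[str, float]
    naphthol_metabolism_rate: float
    naphthol_urinary_clearance: float
    naphthol_volume: float
    mm_enabled: bool = False
    mm_vmax: float = 0.0
    mm_km: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "ChemicalParams":
        _require_keys(self.partition_coefficient, PARTITIONED, "partition_coefficient")
        _require_keys(self.permeability_area, PARTITIONED, "permeability_area")
        _require_keys(self.hydrolysis_rate, HYDROLYSIS_COMPARTMENTS, "hydrolysis_rate")
        for key, v in self.partition_coefficient.items():
            if v <= 0:
                raise ValueError(f"partition_coefficient.{key} must be positive")
        for field in ("permeability_area", "hydrolysis_rate"):
            for key, v in getattr(self, field).items():
                if v < 0:
                    raise ValueError(f"{field}.{key} must be non-negative")
        for name in ("ka", "naphthol_metabolism_rate", "naphthol_urinary_clearance", "mm_vmax"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.naphthol_volume <= 0:
            raise ValueError("naphthol_volume must be positive")
        if self.mm_km <= 0:
            raise ValueError("mm_km must be positive")
        return self


class PDSiteParams(_Strict):
    """AChE turnover and carbamylation kinetics at one site.

    k_syn nmol/h zero-order synthesis; k_deg 1/h degradation of active
    enzyme; k_i 1/(uM·h) bimolecular carbamylation by carbaryl; k_r 1/h
    spontaneous decarbamylation (releases the 1-naphthol moiety).
    """

    k_syn: float
    k_deg: float
    k_i: float
    k_r: float

    @model_validator(mode="after")
    def _check(self) -> "PDSiteParams":
        for name in ("k_syn", "k_i", "k_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_deg <= 0:
            raise ValueError("k_deg must be positive (baseline E0 = k_syn/k_deg)")
        return self

    @property
    def e0(self) -> float:
        """Baseline active enzyme amount (nmol) at synthesis/degradation balance."""
        return self.k_syn / self.k_deg


class PDParams(_Strict):
    brain: PDSiteParams
    rbc: PDSiteParams


class McDistribution(_Strict):
    """Monte Carlo sampling distribution for one model parameter.

    ``parameter`` is a dotted path into ModelParams (e.g. ``chemical.ka``).
    ``central`` defaults to the parameter's configured value when omitted.
    For lognormal, ``spread`` is a geometric SD (>= 1); for normal it is a
    coefficient of variation as an SD fraction of the central value (>= 0).
    Only distributions with ``sensitive: true`` are varied.
    """

    parameter: str
    shape: Literal["normal", "lognormal"]
    spread: float
    central: float | None = None
    sensitive: bool = True

    @model_validator(mode="after")
    def _check(self) -> "McDistribution":
        if self.shape == "lognormal" and self.spread < 1.0:
            raise ValueError(f"{self.parameter}: lognormal spread (GSD) must be >= 1")
        if self.shape == "normal" and self.spread < 0.0:
            raise ValueError(f"{self.parameter}: normal spread must be >= 0")
        return self


class ModelParams(_Strict):
    physiology: PhysiologyParams
    chemical: ChemicalParams
    pd: PDParams
    monte_carlo: tuple[McDistribution, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "ModelParams":
        for dist in self.monte_carlo:
            try:
                get_param(self, dist.parameter)
            except KeyError as exc:
                raise ValueError(f"monte_carlo: unknown parameter {dist.parameter!r}") from exc
        return self


# ---------------------------------------------------------------------------
# configuration I/O


def load_config(path: str | Path) -> ModelParams:
    """Load and validate a YAML parameter file; raise :class:`ConfigError` naming
    the offending key on any schema or invariant violation."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    return params_from_dict(raw)


def params_from_dict(raw: dict) -> ModelParams:
    try:
        return ModelParams.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(params: ModelParams, path: str | Path) -> None:
    """Serialize a parameter set back to YAML (round-trips exactly)."""
    Path(path).write_text(
        yaml.safe_dump(params.model_dump(mode="python"), sort_keys=False)
    )


def default_params() -> ModelParams:
    """The shipped default parameterization.

    The values reproduce the qualitative kinetic behaviour of carbaryl —
    a terminal plasma half-life near 9 h after an oral bolus and urinary
    elimination of 1-naphthol slower than carbaryl clearance — and are
    defaults for reproduction of that behaviour, not a published
    physiological compilation.
    """
    with resources.files("carbarylsim.data").joinpath("default_params.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return params_from_dict(raw)


# ---------------------------------------------------------------------------
# body-weight scaling


def scale_physiology(base: PhysiologyParams, body_weight: float) -> PhysiologyParams:
    """Scale a reference physiology to a subject's body weight.

    Compartment volumes scale linearly with body weight (they are stored as
    fractions, so only ``body_weight`` changes); cardiac output follows the
    standard allometric exponent, QC ∝ BW^0.75.  Fractions, hematocrit and
    urine output are untouched — urine output is an independently assigned
    per-subject measurement, not an allometric quantity.
    """
    if body_weight <= 0:
        raise ValueError(f"body_weight must be positive, got {body_weight}")
    factor = (body_weight / base.body_weight) ** 0.75
    return base.model_copy(
        update={
            "body_weight": body_weight,
            "cardiac_output": base.cardiac_output * factor,
        }
    )


# ---------------------------------------------------------------------------
# dotted-path access (used by the sensitivity screen and Monte Carlo engine)


def _walk(prefix: str, node) -> Iterator[tuple[str, float]]:
    if isinstance(node, BaseModel):
        for name in type(node).model_fields:
            if name in ("mm_enabled", "monte_carlo"):
                continue
            yield from _walk(f"{prefix}.{name}" if prefix else name, getattr(node, name))
    elif isinstance(node, dict):
        for key, val in node.items():
            yield from _walk(f"{prefix}.{key}", val)
    elif isinstance(node, bool):
        return
    elif isinstance(node, (int, float)):
        yield prefix, float(node)


def flatten_params(params: ModelParams) -> dict[str, float]:
    """All scalar model parameters as a {dotted path: value} mapping."""
    return dict(_walk("", params))


def get_param(params: ModelParams, path: str) -> float:
    node = params
    for part in path.split("."):
        if isinstance(node, BaseModel):
            if part not in type(node).model_fields:
                raise KeyError(path)
            node = getattr(node, part)
        elif isinstance(node, dict):
            if part not in node:
                raise KeyError(path)
            node = node[part]
        else:
            raise KeyError(path)
    if not isinstance(node, (int, float)) or isinstance(node, bool):
        raise KeyError(f"{path} is not a scalar parameter")
    return float(node)


def set_params(params: ModelParams, updates: dict[str, float]) -> ModelParams:
    """Return a new, re-validated parameter set with dotted-path updates applied."""
    raw = params.model_dump(mode="python")
    for path, value in updates.items():
        node = raw
        parts = path.split(".")
        for part in parts[:-1]:
            if part not in node:
                raise KeyError(path)
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(path)
        node[parts[-1]] = float(value)
    return params_from_dict(raw)
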