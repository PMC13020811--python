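"""Simulation configuration: YAML-backed, validated, with artifact defaults.

A configuration mirrors the model structure: a ``genome`` block (trait
architecture), a ``reproduction`` block, a ``hazards`` block (a mortality
process is active when its sub-block is present *and* its token appears in
``process_order``), an ``init`` block (de-novo population or a snapshot
path), and a ``recording`` block. Unknown keys are rejected with the
offending key named.
"""

from __future__ import annotations

from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .genome import ConfigurationError, GenomeArchitecture, TraitSpec, build_architecture
from .hazards import AbioticWaveSpec, InfectionParams, PredationParams, StarvationParams
from .reproduction import ReproductionParams

__all__ = ["SimulationConfig", "load_config", "config_from_dict", "DEFAULT_PROCESS_ORDER"]

#: Default per-step process schedule.
DEFAULT_PROCESS_ORDER = (
    "intrinsic",
    "abiotic",
    "infection",
    "predation",
    "starvation",
    "reproduction",
    "aging",
    "drift",
)

_VALID_PROCESSES = set(DEFAULT_PROCESS_ORDER)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TraitConfig(_Strict):
    age_dependent: bool = True
    bits_per_block: int = 8
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    evolvable: bool = True
    initial_value: float = 0.0


def _default_survival() -> TraitConfig:
    return TraitConfig()


def _default_reproduction() -> TraitConfig:
    # maximum attainable reproduction probability is 50% per step
    return TraitConfig(upper_bound=0.5)


def _default_mutation_rate() -> TraitConfig:
    return TraitConfig(age_dependent=False, evolvable=False, upper_bound=0.01, initial_value=0.001)


class GenomeConfig(_Strict):
    n_age_classes: int = 50
    survival: TraitConfig = None  # type: ignore[assignment]
    reproduction: TraitConfig = None  # type: ignore[assignment]
    mutation_rate: TraitConfig = None  # type: ignore[assignment]

    @model_validator(mode="before")
    @classmethod
    def _fill_traits(cls, data):
        if isinstance(data, dict):
            data = dict(data)  # never mutate the caller's mapping
            data.setdefault("survival", _default_survival())
            data.setdefault("reproduction", _default_reproduction())
            data.setdefault("mutation_rate", _default_mutation_rate())
        return data


class AbioticConfig(_Strict):
    shape: Literal["flat", "sinusoid", "square", "triangle", "sawtooth"] = "flat"
    amplitude: float = 0.0
    period: int = 1
    phase: int = 0
    baseline: float = 0.0


class InfectionConfig(_Strict):
    transmissibility: float = 0.0
    fatality_rate: float = 0.0
    recovery_rate: float = 0.0
    background_infection: float = 0.0


class PredationConfig(_Strict):
    predator_growth_rate: float = 0.0
    vulnerability: float = 0.0
    initial_predators: float = 0.0


class StarvationConfig(_Strict):
    model: Literal["instantaneous", "gradual"] = "gradual"
    susceptibility: float = 0.1
    age_weighting: Optional[list[float]] = None


class HazardsConfig(_Strict):
    abiotic: Optional[AbioticConfig] = None
    infection: Optional[InfectionConfig] = None
    predation: Optional[PredationConfig] = None
    starvation: Optional[StarvationConfig] = StarvationConfig()


class ReproductionConfig(_Strict):
    mode: Literal["sexual", "asexual"] = "sexual"
    maturity_age: int = 10
    menopause_age: Optional[int] = None
    oviparous: bool = False
    incubation: int = 0
    hatching_policy: Literal["fixed_incubation", "when_adults_extinct"] = "fixed_incubation"
    recombination_rate: float = 1.0
    mutation_rate: Union[float, Literal["evolvable"]] = 0.001


class InitConfig(_Strict):
    n: int = 1000
    ones_fraction: dict[str, float] = None  # type: ignore[assignment]
    snapshot: Optional[str] = None

    @model_validator(mode="before")
    @classmethod
    def _fill_fractions(cls, data):
        if isinstance(data, dict):
            data = dict(data)  # never mutate the caller's mapping
            frac = dict(data.get("ones_fraction") or {})
            frac.setdefault("survival", 0.95)
            frac.setdefault("reproduction", 0.5)
            frac.setdefault("mutation_rate", 0.5)
            data["ones_fraction"] = frac
        return data


class RecordingConfig(_Strict):
    window: int = 100
    genotype_dump_every: int = 0  # 0 disables periodic genotype dumps
    intrinsic_every: int = 0  # cadence of intrinsic-curve records (0: window)


class SimulationConfig(_Strict):
    """Top-level simulation parameters (artifact defaults)."""

    steps: int = 1_000_000
    seed: int = 1
    carrying_capacity: int = 1000
    process_order: list[str] = list(DEFAULT_PROCESS_ORDER)
    drift_rate: float = 0.0
    genome: GenomeConfig = GenomeConfig()
    hazards: HazardsConfig = HazardsConfig()
    reproduction: ReproductionConfig = ReproductionConfig()
    init: InitConfig = InitConfig()
    recording: RecordingConfig = RecordingConfig()

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        unknown = [p for p in self.process_order if p not in _VALID_PROCESSES]
        if unknown:
            raise ValueError(f"unknown process tokens {unknown}")
        if len(set(self.process_order)) != len(self.process_order):
            raise ValueError("process_order contains duplicates")
        if self.process_order.count("aging") != 1:
            raise ValueError("process_order must contain 'aging' exactly once")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be >= 1")
        if self.drift_rate < 0:
            raise ValueError("drift_rate must be >= 0")
        g = self.genome
        r = self.reproduction
        if r.maturity_age >= g.n_age_classes:
            raise ValueError("maturity_age must be below n_age_classes")
        if r.menopause_age is not None and r.menopause_age > g.n_age_classes:
            raise ValueError("menopause_age must not exceed n_age_classes")
        if r.mutation_rate == "evolvable" and not g.mutation_rate.evolvable:
            raise ValueError(
                "reproduction.mutation_rate is 'evolvable' but the mutation_rate "
                "trait is not evolvable in the genome block"
            )
        return self

    # -- conversion to runtime objects ------------------------------------
    def architecture(self) -> GenomeArchitecture:
        specs = []
        for name in ("survival", "reproduction", "mutation_rate"):
            tc: TraitConfig = getattr(self.genome, name)
            specs.append(
                TraitSpec(
                    name=name,
                    age_dependent=tc.age_dependent,
                    bits_per_block=tc.bits_per_block,
                    lower_bound=tc.lower_bound,
                    upper_bound=tc.upper_bound,
                    evolvable=tc.evolvable,
                    initial_value=tc.initial_value,
                )
            )
        return build_architecture(specs, self.genome.n_age_classes)

    def reproduction_params(self) -> ReproductionParams:
        r = self.reproduction
        return ReproductionParams(
            mode=r.mode,
            maturity_age=r.maturity_age,
            menopause_age=r.menopause_age,
            oviparous=r.oviparous,
            incubation=r.incubation,
            hatching_policy=r.hatching_policy,
            recombination_rate=r.recombination_rate,
            mutation_rate=r.mutation_rate,
        )

    def abiotic_params(self) -> AbioticWaveSpec | None:
        a = self.hazards.abiotic
        return None if a is None else AbioticWaveSpec(**a.model_dump())

    def infection_params(self) -> InfectionParams | None:
        i = self.hazards.infection
        return None if i is None else InfectionParams(**i.model_dump())

    def predation_params(self) -> PredationParams | None:
        p = self.hazards.predation
        return None if p is None else PredationParams(**p.model_dump())

    def starvation_params(self) -> StarvationParams | None:
        s = self.hazards.starvation
        if s is None:
            return None
        return StarvationParams(
            model=s.model,
            susceptibility=s.susceptibility,
            age_weighting=None if s.age_weighting is None else tuple(s.age_weighting),
        )


def config_from_dict(data: dict) -> SimulationConfig:
    """Validate a plain dict into a :class:`SimulationConfig`.

    Raises :class:`~senesim.genome.ConfigurationError` naming the offending
    key on unknown or invalid entries.
    """
    try:
        return SimulationConfig.model_validate(data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigurationError("invalid configuration — " + "; ".join(lines)) from exc


def load_config(path: str) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)
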