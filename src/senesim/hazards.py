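"""The five mortality processes.

Each operator turns the current population state into a boolean death mask
over the living pool (eggs never enter the living pool and are therefore
exempt by construction). Hazards are applied in a configurable order;
deaths from one process are committed before the next process reads state,
while within a process all individuals are evaluated simultaneously against
the state at the process start.

Causes of death
---------------
``intrinsic``   genetic, age-specific (1 - survival(age))
``abiotic``     periodic environmental hazard, age-independent
``infection``   SIS epidemic with fatality
``predation``   saturating functional response with logistic predator growth
``starvation``  density dependence above carrying capacity K
``age_limit``   reaching the last age class (applied by the engine's aging step)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import ConfigurationError, PhenotypeTable
from .population import PopulationState

__all__ = [
    "CAUSES",
    "AbioticWaveSpec",
    "InfectionParams",
    "PredationParams",
    "StarvationParams",
    "intrinsic_deaths",
    "abiotic_hazard",
    "abiotic_deaths",
    "infection_step",
    "predation_step",
    "starvation_step",
    "expected_sequential_mortality",
]

#: Stable cause taxonomy used in death ledgers.
CAUSES = ("intrinsic", "abiotic", "infection", "predation", "starvation", "age_limit")

_WAVE_SHAPES = ("flat", "sinusoid", "square", "triangle", "sawtooth")


@dataclass(frozen=True)
class AbioticWaveSpec:
    """Periodic abiotic hazard: ``baseline + amplitude * waveform(t)``.

    The waveform has range [0, 1]; ``baseline + amplitude`` must not exceed 1
    so the hazard is a valid probability at every step.
    """

    shape: str = "flat"
    amplitude: float = 0.0
    period: int = 1
    phase: int = 0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in _WAVE_SHAPES:
            raise ConfigurationError(f"unknown wave shape {self.shape!r}")
        if self.period < 1:
            raise ConfigurationError("wave period must be >= 1")
        if self.baseline < 0 or self.amplitude < 0 or self.baseline + self.amplitude > 1:
            raise ConfigurationError(
                "abiotic hazard requires baseline >= 0, amplitude >= 0 and "
                "baseline + amplitude <= 1"
            )


@dataclass(frozen=True)
class InfectionParams:
    """SIS epidemic: infection scales with the infected fraction.

    A healthy individual becomes infected with probability
    ``background_infection + transmissibility * infected / living``; an
    infected individual dies with ``fatality_rate``, otherwise recovers (back
    to susceptible) with ``recovery_rate``, otherwise stays infected.
    """

    transmissibility: float = 0.0
    fatality_rate: float = 0.0
    recovery_rate: float = 0.0
    background_infection: float = 0.0

    def __post_init__(self) -> None:
        for name in ("transmissibility", "fatality_rate", "recovery_rate", "background_infection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.fatality_rate + self.recovery_rate > 1.0:
            raise ConfigurationError("fatality_rate + recovery_rate must be <= 1")


@dataclass(frozen=True)
class PredationParams:
    """Predator pool with logistic growth capped by prey abundance.

    Per-prey kill probability is ``vulnerability * (1 - exp(-P/N))`` with
    ``P`` predators and ``N`` living prey at the process start; predators then
    update as ``P' = P + growth * P * (1 - P/N)``, floored at zero.
    """

    predator_growth_rate: float = 0.0
    vulnerability: float = 0.0
    initial_predators: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vulnerability <= 1.0:
            raise ConfigurationError("vulnerability must be in [0, 1]")
        if self.initial_predators < 0:
            raise ConfigurationError("initial_predators must be >= 0")


@dataclass(frozen=True)
class StarvationParams:
    """Density dependence above carrying capacity K.

    ``instantaneous``: the ``N - K`` individuals beyond capacity, chosen
    uniformly, die immediately. ``gradual``: everyone shares the shortage;
    per-step survival decays as ``(1 - m)^t`` with ``t`` the number of
    consecutive steps the population has exceeded K. An optional age weighting
    (normalised to mean 1 over the living) skews gradual starvation by age.
    """

    model: str = "gradual"
    susceptibility: float = 0.1
    age_weighting: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.model not in ("instantaneous", "gradual"):
            raise ConfigurationError(f"unknown starvation model {self.model!r}")
        if self.model == "gradual" and not 0.0 < self.susceptibility <= 1.0:
            raise ConfigurationError("gradual starvation requires susceptibility in (0, 1]")
        if self.age_weighting is not None and any(w < 0 for w in self.age_weighting):
            raise ConfigurationError("age_weighting entries must be non-negative")


def intrinsic_deaths(
    pop: PopulationState,
    phen: PhenotypeTable,
    rng: np.random.Generator,
) -> np.ndarray:
    """Each living individual of age a dies with probability 1 - survival(a)."""
    if phen.n != pop.n_living:
        raise ValueError("phenotype table does not match population size")
    survival = phen.value_at("survival", pop.ages)
    return rng.random(pop.n_living) >= survival


def abiotic_hazard(wave: AbioticWaveSpec, step: int) -> float:
    """Hazard probability at a given step for a periodic wave spec."""
    frac = ((step - wave.phase) % wave.period) / wave.period
    if wave.shape == "flat":
        w = 0.0
    elif wave.shape == "sinusoid":
        w = 0.5 * (1.0 + np.sin(2.0 * np.pi * frac))
    elif wave.shape == "square":
        w = 1.0 if frac < 0.5 else 0.0
    elif wave.shape == "triangle":
        w = 1.0 - abs(2.0 * frac - 1.0)
    else:  # sawtooth
        w = frac
    return float(wave.baseline + wave.amplitude * w)


def abiotic_deaths(
    pop: PopulationState,
    wave: AbioticWaveSpec,
    step: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Age- and genotype-independent periodic mortality."""
    h = abiotic_hazard(wave, step)
    return rng.random(pop.n_living) < h


def infection_step(
    pop: PopulationState,
    params: InfectionParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the SIS epidemic; updates ``pop.infected`` in place.

    All transitions use the infected/living counts at the process start.
    Returns the death mask (cause ``infection``).
    """
    n = pop.n_living
    if n == 0:
        return np.zeros(0, dtype=bool)
    infected = pop.infected
    n_inf = int(infected.sum())
    force = params.background_infection + params.transmissibility * (n_inf / n)
    force = min(max(force, 0.0), 1.0)
    u = rng.random(n)
    new_infections = ~infected & (u < force)
    deaths = infected & (u < params.fatality_rate)
    recoveries = infected & ~deaths & (u < params.fatality_rate + params.recovery_rate)
    pop.infected = (infected | new_infections) & ~recoveries
    return deaths


def predation_step(
    pop: PopulationState,
    predators: float,
    params: PredationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Predation deaths plus the updated predator count."""
    n = pop.n_living
    if n == 0:
        return np.zeros(0, dtype=bool), max(predators, 0.0)
    p_kill = params.vulnerability * (1.0 - np.exp(-predators / n))
    deaths = rng.random(n) < p_kill
    new_predators = predators + params.predator_growth_rate * predators * (1.0 - predators / n)
    return deaths, max(new_predators, 0.0)


def starvation_step(
    pop: PopulationState,
    streak: int,
    carrying_capacity: int,
    params: StarvationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Starvation deaths plus the updated consecutive-starvation counter."""
    n = pop.n_living
    if n <= carrying_capacity:
        return np.zeros(n, dtype=bool), 0
    streak += 1
    if params.model == "instantaneous":
        excess = n - carrying_capacity
        idx = rng.choice(n, size=excess, replace=False)
        deaths = np.zeros(n, dtype=bool)
        deaths[idx] = True
        return deaths, streak
    m = params.susceptibility
    if params.age_weighting is None:
        p_death = 1.0 - (1.0 - m) ** streak
        deaths = rng.random(n) < p_death
    else:
        w = np.asarray(params.age_weighting, dtype=np.float64)
        wa = w[np.clip(pop.ages, 0, w.shape[0] - 1)]
        wa = wa / wa.mean() if wa.mean() > 0 else wa
        p_death = 1.0 - np.clip(1.0 - m * wa, 0.0, 1.0) ** streak
        deaths = rng.random(n) < p_death
    return deaths, streak


def expected_sequential_mortality(
    n: int,
    hazards: list[float] | tuple[float, ...] | np.ndarray,
) -> dict[str, object]:
    """Expected death structure of hazards applied in sequence.

    Each hazard acts on the survivors of the previous one, so its observed
    population-level rate (deaths over the starting population) is smaller
    than its per-capita rate. The total number of deaths — and the total rate
    ``1 - prod(1 - h_i)`` — is invariant under reordering; only the
    attribution of deaths to sources changes.
    """
    if n < 0:
        raise ValueError("cohort size must be >= 0")
    h = np.asarray(hazards, dtype=np.float64)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("hazards must be probabilities in [0, 1]")
    survivors = float(n)
    deaths = []
    for hi in h:
        d = survivors * hi
        deaths.append(d)
        survivors -= d
    deaths_arr = np.asarray(deaths)
    observed = deaths_arr / n if n > 0 else np.zeros_like(deaths_arr)
    return {
        "deaths": deaths_arr,
        "observed_rates": observed,
        "total_deaths": float(deaths_arr.sum()),
        "total_rate": float(1.0 - np.prod(1.0 - h)),
    }
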