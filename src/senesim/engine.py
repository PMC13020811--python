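"""Step scheduler, environment, RNG streams, snapshots and the run loop.

A simulation runs in three phases: initialization (architecture, genomes,
environment), the stepped simulation phase, and termination (metadata).
Each step executes the configured process order; within a process, every
individual's outcome depends only on the state at the process start
(parallel-update semantics), while deaths are committed between processes.
Offspring and hatchlings are exempt from hazards in their birth step.

Randomness comes from one master seed that spawns a named stream per
process, so enabling or disabling one process does not perturb another
process's draws. Identical configuration + seed gives bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .genome import (
    GenomeArchitecture,
    PhenotypeTable,
    init_genomes,
    interpret_phenotypes,
    new_drift_map,
)
from .hazards import (
    abiotic_deaths,
    infection_step,
    intrinsic_deaths,
    predation_step,
    starvation_step,
)
from .population import PopulationState
from .recording import DemographicLedger, intrinsic_curves
from .reproduction import eligible_parents, generate_offspring, hatch_eggs, pair_mates

__all__ = [
    "EnvironmentState",
    "RunOutputs",
    "Simulation",
    "run_simulation",
    "drift_environment",
    "save_snapshot",
    "load_snapshot",
]

#: Fixed name -> spawn-key mapping for the per-process RNG streams.
STREAM_NAMES = (
    "init",
    "intrinsic",
    "abiotic",
    "infection",
    "predation",
    "starvation",
    "reproduction",
    "drift",
)

SNAPSHOT_VERSION = 1


@dataclass
class EnvironmentState:
    """Shared environment: step counter, starvation streak, predators, drift map."""

    step: int
    starvation_streak: int
    predators: float
    drift_map: np.ndarray


@dataclass
class RunOutputs:
    """Ledgers, final state and metadata produced by one run."""

    config: SimulationConfig
    arch: GenomeArchitecture
    ledger: DemographicLedger
    population: PopulationState
    env: EnvironmentState
    metadata: dict
    intrinsic_history: list = field(default_factory=list)
    genotype_dumps: list = field(default_factory=list)

    def final_phenotypes(self) -> PhenotypeTable:
        r = self.config.reproduction
        return interpret_phenotypes(
            self.population.genomes,
            self.arch,
            self.env.drift_map,
            maturity_age=r.maturity_age,
            menopause_age=r.menopause_age,
        )


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    return {
        name: np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(i,))))
        for i, name in enumerate(STREAM_NAMES)
    }


def config_digest(config: SimulationConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def drift_environment(
    drift_map: np.ndarray,
    drift_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Flip a Poisson(drift_rate) number of uniformly chosen drift-map bits."""
    if drift_rate < 0:
        raise ValueError("drift_rate must be >= 0")
    if drift_rate == 0:
        return drift_map
    k = int(rng.poisson(drift_rate))
    if k == 0:
        return drift_map
    idx = rng.integers(drift_map.shape[0], size=k)
    out = drift_map.copy()
    out[idx] ^= 1
    return out


class Simulation:
    """One configured simulation run."""

    def __init__(
        self,
        config: SimulationConfig,
        seed: int | None = None,
        initial_population: PopulationState | None = None,
    ) -> None:
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.arch = config.architecture()
        self.rparams = config.reproduction_params()
        self.abiotic = config.abiotic_params()
        self.infection = config.infection_params()
        self.predation = config.predation_params()
        self.starvation = config.starvation_params()
        self.order = list(config.process_order)
        self.rng = _spawn_streams(self.seed)
        self.ledger = DemographicLedger(self.arch.n_age_classes, window=config.recording.window)
        self._phen: PhenotypeTable | None = None
        self.intrinsic_history: list = []
        self.genotype_dumps: list = []
        self.hatch_events = 0
        self.extinction_step: int | None = None

        if initial_population is not None:
            if initial_population.genomes.shape[2] != self.arch.total_bits:
                raise SnapshotError(
                    "initial population genome width does not match the architecture"
                )
            self.pop = initial_population
            self.env = EnvironmentState(
                step=0,
                starvation_streak=0,
                predators=self.predation.initial_predators if self.predation else 0.0,
                drift_map=new_drift_map(self.arch),
            )
        elif config.init.snapshot is not None:
            pop, env, rng_states, header = load_snapshot(config.init.snapshot)
            _check_architecture(header, self.arch)
            self.pop = pop
            self.env = env
            if rng_states is not None:
                for name, state in rng_states.items():
                    if name in self.rng:
                        self.rng[name].bit_generator.state = state
        else:
            genomes = init_genomes(
                config.init.n, self.arch, config.init.ones_fraction, self.rng["init"]
            )
            self.pop = PopulationState.from_genomes(genomes, step=-1)
            self.env = EnvironmentState(
                step=0,
                starvation_streak=0,
                predators=self.predation.initial_predators if self.predation else 0.0,
                drift_map=new_drift_map(self.arch),
            )

    # -- phenotypes --------------------------------------------------------
    @property
    def phen(self) -> PhenotypeTable:
        if self._phen is None or self._phen.n != self.pop.n_living:
            self._phen = interpret_phenotypes(
                self.pop.genomes,
                self.arch,
                self.env.drift_map,
                maturity_age=self.rparams.maturity_age,
                menopause_age=self.rparams.menopause_age,
            )
        return self._phen

    def _filter_phen(self, keep: np.ndarray) -> None:
        if self._phen is not None and self._phen.n != keep.shape[0]:
            self._phen = None  # stale (e.g. newborns appended); recompute on demand
        if self._phen is not None:
            self._phen = PhenotypeTable(
                values={k: v[keep] for k, v in self._phen.values.items()},
                n_age_classes=self._phen.n_age_classes,
            )

    def _commit_deaths(self, mask: np.ndarray, cause: str, step: int) -> int:
        mask = mask & (self.pop.birth_step < step)
        n = int(mask.sum())
        if n:
            self.ledger.record_deaths(cause, self.pop.ages[mask])
            self.pop.remove(mask)
            self._filter_phen(~mask)
        return n

    # -- the step ----------------------------------------------------------
    def step_once(self) -> None:
        s = self.env.step
        pop = self.pop
        self._phen = None
        self.ledger.record_step_start(pop.n_living)
        self.ledger.record_exposure(pop.ages)
        deaths = 0
        recruits = 0
        popsize_recorded = False
        for proc in self.order:
            if proc == "intrinsic":
                mask = intrinsic_deaths(pop, self.phen, self.rng["intrinsic"])
                deaths += self._commit_deaths(mask, "intrinsic", s)
            elif proc == "abiotic":
                if self.abiotic is not None:
                    mask = abiotic_deaths(pop, self.abiotic, s, self.rng["abiotic"])
                    deaths += self._commit_deaths(mask, "abiotic", s)
            elif proc == "infection":
                if self.infection is not None:
                    mask = infection_step(pop, self.infection, self.rng["infection"])
                    deaths += self._commit_deaths(mask, "infection", s)
            elif proc == "predation":
                if self.predation is not None:
                    mask, self.env.predators = predation_step(
                        pop, self.env.predators, self.predation, self.rng["predation"]
                    )
                    deaths += self._commit_deaths(mask, "predation", s)
            elif proc == "starvation":
                if self.starvation is not None:
                    mask, self.env.starvation_streak = starvation_step(
                        pop,
                        self.env.starvation_streak,
                        self.config.carrying_capacity,
                        self.starvation,
                        self.rng["starvation"],
                    )
                    deaths += self._commit_deaths(mask, "starvation", s)
            elif proc == "reproduction":
                recruits += self._reproduce(s)
                self.ledger.record_popsize(s, pop.n_living, pop.n_eggs)
                popsize_recorded = True
            elif proc == "aging":
                grown = pop.birth_step < s
                pop.ages[grown] += 1
                mask = pop.ages >= self.arch.n_age_classes
                deaths += self._commit_deaths(mask, "age_limit", s)
            elif proc == "drift":
                new_map = drift_environment(
                    self.env.drift_map, self.config.drift_rate, self.rng["drift"]
                )
                if new_map is not self.env.drift_map:
                    self.env.drift_map = new_map
                    self._phen = None
        if not popsize_recorded:
            self.ledger.record_popsize(s, pop.n_living, pop.n_eggs)
        self.ledger.record_step_totals(deaths, recruits)
        self._record_cadenced(s)
        self.ledger.end_step(s)
        self.env.step = s + 1

    def _reproduce(self, s: int) -> int:
        pop = self.pop
        rng = self.rng["reproduction"]
        recruits = 0
        if pop.n_living > 0:
            attempts = eligible_parents(pop, self.phen, self.rparams, rng)
            ids = np.flatnonzero(attempts)
            if self.rparams.mode == "sexual":
                parents = pair_mates(ids, rng)
            else:
                parents = ids
            genomes, parental_ages = generate_offspring(
                pop, parents, self.phen, self.rparams, self.arch, rng
            )
            if genomes.shape[0]:
                self.ledger.record_births(parental_ages)
                if self.rparams.oviparous:
                    pop.eggs.add(genomes, s, parental_ages)
                else:
                    pop.add_living(genomes, step=s)
                    recruits += genomes.shape[0]
        if self.rparams.oviparous:
            hatched, _ = hatch_eggs(pop, self.rparams, s)
            if hatched:
                self.hatch_events += 1
                recruits += hatched
        return recruits

    def _record_cadenced(self, s: int) -> None:
        rec = self.config.recording
        every = rec.intrinsic_every or rec.window
        if (s + 1) % every == 0 and self.pop.n_living > 0:
            curves = intrinsic_curves(self.phen)
            self.intrinsic_history.append((s, curves.mortality.copy(), curves.fertility.copy()))
        if rec.genotype_dump_every and (s + 1) % rec.genotype_dump_every == 0:
            self.genotype_dumps.append((s, self.pop.genomes.copy()))

    def run(self, steps: int | None = None) -> RunOutputs:
        n_steps = self.config.steps if steps is None else steps
        target = self.env.step + n_steps
        while self.env.step < target:
            if self.pop.extinct:
                self.extinction_step = self.env.step
                break
            self.step_once()
        metadata = {
            "seed": self.seed,
            "config_digest": config_digest(self.config),
            "steps_run": self.env.step,
            "extinction_step": self.extinction_step,
            "hatch_events": self.hatch_events,
            "final_living": self.pop.n_living,
            "final_eggs": self.pop.n_eggs,
        }
        return RunOutputs(
            config=self.config,
            arch=self.arch,
            ledger=self.ledger,
            population=self.pop,
            env=self.env,
            metadata=metadata,
            intrinsic_history=self.intrinsic_history,
            genotype_dumps=self.genotype_dumps,
        )

    def save_snapshot(self, path: str) -> None:
        save_snapshot(path, self.pop, self.env, self.arch, rng_streams=self.rng)


def run_simulation(config: SimulationConfig, seed: int | None = None) -> RunOutputs:
    """Initialize, simulate and terminate one run. Extinction ends the run
    gracefully with the extinction step recorded in the metadata."""
    return Simulation(config, seed=seed).run()


# -- snapshots -------------------------------------------------------------

def _arch_signature(arch: GenomeArchitecture) -> dict:
    return {
        "n_age_classes": arch.n_age_classes,
        "total_bits": arch.total_bits,
        "traits": [
            {
                "name": t.name,
                "age_dependent": t.age_dependent,
                "bits_per_block": t.bits_per_block,
                "lower_bound": t.lower_bound,
                "upper_bound": t.upper_bound,
                "evolvable": t.evolvable,
                "initial_value": t.initial_value,
            }
            for t in arch.traits
        ],
    }


class SnapshotError(ValueError):
    """Raised when a snapshot is incompatible with the target configuration."""


def _check_architecture(header: dict, arch: GenomeArchitecture) -> None:
    sig = _arch_signature(arch)
    if header.get("architecture") != sig:
        raise SnapshotError(
            "snapshot architecture does not match the configured architecture "
            f"(snapshot total_bits={header.get('architecture', {}).get('total_bits')}, "
            f"config total_bits={sig['total_bits']})"
        )


def save_snapshot(
    path: str,
    pop: PopulationState,
    env: EnvironmentState,
    arch: GenomeArchitecture,
    rng_streams: dict[str, np.random.Generator] | None = None,
) -> None:
    """Write a deterministic single-file snapshot (zip of .npy blocks + JSON).

    The snapshot embeds the genome architecture for validation on load and,
    optionally, the per-process RNG stream states so a run can be continued
    exactly where it stopped.
    """
    header = {
        "format_version": SNAPSHOT_VERSION,
        "step": env.step,
        "starvation_streak": env.starvation_streak,
        "predators": env.predators,
        "architecture": _arch_signature(arch),
        "rng_states": None
        if rng_streams is None
        else {name: gen.bit_generator.state for name, gen in rng_streams.items()},
    }
    blocks = {
        "ages": pop.ages,
        "genomes": pop.genomes,
        "infected": pop.infected,
        "birth_step": pop.birth_step,
        "egg_genomes": pop.eggs.genomes,
        "egg_laid_step": pop.eggs.laid_step,
        "egg_parental_age": pop.eggs.parental_age,
        "drift_map": env.drift_map,
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo("header.json", date_time=(1980, 1, 1, 0, 0, 0))
        zf.writestr(info, json.dumps(header, sort_keys=True))
        for name in sorted(blocks):
            buf = io.BytesIO()
            np.save(buf, blocks[name])
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_snapshot(path: str) -> tuple[PopulationState, EnvironmentState, dict | None, dict]:
    """Read a snapshot back; the round trip is lossless.

    Returns (population, environment, rng_states or None, header).
    """
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        if header.get("format_version") != SNAPSHOT_VERSION:
            raise SnapshotError(
                f"unsupported snapshot format version {header.get('format_version')!r}"
            )
        blocks = {
            name[:-4]: np.load(io.BytesIO(zf.read(name)))
            for name in zf.namelist()
            if name.endswith(".npy")
        }
    pop = PopulationState(
        ages=blocks["ages"],
        genomes=blocks["genomes"],
        infected=blocks["infected"],
        birth_step=blocks["birth_step"],
    )
    pop.eggs.genomes = blocks["egg_genomes"]
    pop.eggs.laid_step = blocks["egg_laid_step"]
    pop.eggs.parental_age = blocks["egg_parental_age"]
    env = EnvironmentState(
        step=header["step"],
        starvation_streak=header["starvation_streak"],
        predators=header["predators"],
        drift_map=blocks["drift_map"],
    )
    rng_states = header.get("rng_states")
    if rng_states is not None:
        rng_states = {name: state for name, state in rng_states.items()}
    return pop, env, rng_states, header
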