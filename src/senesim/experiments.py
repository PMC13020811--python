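"""Baseline-vs-comparative experiment harness and the Rose-style preset.

An experiment runs a burn-in once, snapshots the equilibrated population,
then starts every arm (baseline plus named parameter deltas) from that same
snapshot so evolved differences are attributable to the deltas alone. Arms
are paired by replicate: replicate *i* of every arm uses the same derived
seed.

The Rose preset reproduces a classical laboratory-evolution design with two
non-overlapping-generation populations: B propagates each generation from
eggs laid in an early window after maturity, while O lets adults lay up to a
late day and carries the latest-laid eggs preferentially into the next
generation — selecting for late-life survival and fertility. A "wild-like"
extension then re-runs the evolved populations with overlapping generations
and resource limitation.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig, config_from_dict
from .engine import Simulation, save_snapshot
from .genome import (
    ConfigurationError,
    TraitSpec,
    build_architecture,
    init_genomes,
    interpret_phenotypes,
    mutate_genomes,
    new_drift_map,
    recombine_batch,
)
from .population import PopulationState
from .recording import (
    intrinsic_curves,
    life_table_observed,
    median_from_survivorship,
    summary_metrics,
)

__all__ = [
    "ExperimentPlan",
    "ExperimentResult",
    "apply_overrides",
    "run_experiment",
    "RosePlan",
    "preset_emergent_aging",
    "preset_neutral_drift",
    "preset_rose",
    "select_rose_eggs",
    "run_rose_generation",
    "run_rose_experiment",
]


def _replicate_seed(seed: int, replicate: int) -> int:
    """Derived seed for one replicate (identical across paired arms)."""
    ss = np.random.SeedSequence(seed, spawn_key=(replicate,))
    return int(ss.generate_state(1)[0] % (2**31))


def apply_overrides(config: SimulationConfig, overrides: dict[str, object]) -> SimulationConfig:
    """Return a config with dotted-key overrides applied (keys must exist)."""
    data = config.model_dump()
    for key, value in overrides.items():
        parts = key.split(".")
        node = data
        for p in parts[:-1]:
            if not isinstance(node, dict) or p not in node:
                raise ConfigurationError(f"override key {key!r} does not exist")
            node = node[p]
        if not isinstance(node, dict) or parts[-1] not in node:
            raise ConfigurationError(f"override key {key!r} does not exist")
        node[parts[-1]] = value
    return config_from_dict(data)


@dataclass
class ExperimentPlan:
    """Baseline config, named variant deltas, burn-in and replication policy."""

    baseline: SimulationConfig
    variants: dict[str, dict[str, object]] = field(default_factory=dict)
    burn_in_steps: int = 1000
    arm_steps: int = 1000
    replicates: int = 3
    seed: int = 1


@dataclass
class ExperimentResult:
    """Per-arm per-replicate metrics plus shared burn-in provenance."""

    table: pd.DataFrame
    burn_in_digest: str
    burn_in_metadata: dict

    def arm_summary(self) -> pd.DataFrame:
        """Across-replicate mean and dispersion of every metric, per arm."""
        metrics = [c for c in self.table.columns if c not in ("arm", "replicate", "seed")]
        return self.table.groupby("arm")[metrics].agg(["mean", "std"])


def _arm_metrics(outputs) -> dict[str, float]:
    metrics = summary_metrics(outputs.ledger)
    if outputs.population.n_living == 0:  # extinct arm: no final phenotypes
        metrics["intrinsic_median_lifespan"] = np.nan
        metrics["mean_intrinsic_mortality"] = np.nan
        metrics["extinct"] = 1.0
        return metrics
    curves = intrinsic_curves(outputs.final_phenotypes())
    metrics["intrinsic_median_lifespan"] = median_from_survivorship(curves.survivorship)
    metrics["mean_intrinsic_mortality"] = float(np.mean(curves.mortality))
    metrics["extinct"] = 0.0
    return metrics


def run_experiment(plan: ExperimentPlan, output_dir: str | None = None) -> ExperimentResult:
    """Run burn-in once, then every arm x replicate from the shared snapshot."""
    burn_cfg = apply_overrides(plan.baseline, {"steps": plan.burn_in_steps})
    sim = Simulation(burn_cfg, seed=plan.seed)
    burn = sim.run()
    if burn.metadata["extinction_step"] is not None:
        raise RuntimeError(
            f"burn-in went extinct at step {burn.metadata['extinction_step']}; "
            "adjust the baseline parameters"
        )
    own_dir = output_dir is None
    workdir = tempfile.mkdtemp(prefix="senesim-exp-") if own_dir else output_dir
    os.makedirs(workdir, exist_ok=True)
    snap_path = os.path.join(workdir, "burn_in.snapshot")
    # RNG states deliberately omitted: every arm restarts from its own seed.
    save_snapshot(snap_path, burn.population, burn.env, burn.arch, rng_streams=None)
    with open(snap_path, "rb") as fh:
        digest = hashlib.sha256(fh.read()).hexdigest()

    arms = {"baseline": {}, **plan.variants}
    rows = []
    for arm_name, deltas in arms.items():
        cfg = apply_overrides(
            plan.baseline,
            {**deltas, "steps": plan.arm_steps, "init.snapshot": snap_path},
        )
        for rep in range(plan.replicates):
            seed = _replicate_seed(plan.seed, rep)
            out = Simulation(cfg, seed=seed).run()
            row = {"arm": arm_name, "replicate": rep, "seed": seed}
            row.update(_arm_metrics(out))
            rows.append(row)
    table = pd.DataFrame(rows)
    return ExperimentResult(table=table, burn_in_digest=digest, burn_in_metadata=burn.metadata)


# -- study presets ---------------------------------------------------------

def preset_emergent_aging(steps: int = 10_000, carrying_capacity: int = 500) -> SimulationConfig:
    """Scaled-down emergent-aging study conditions.

    An age-flat (non-aging) initial population — survival near its upper
    bound at every age and fertility at its ceiling — evolving under
    resource limitation. The per-bit germline mutation rate of 0.002 gives a
    mutation-pressure relaxation time of 1/(2*mu) = 250 generations, well
    inside the roughly 700 generations such a run spans, so the
    age-graded erosion of unselected late-life trait blocks (mutation
    accumulation) is observable by the end of the run.
    """
    return config_from_dict(
        {
            "steps": steps,
            "carrying_capacity": carrying_capacity,
            "init": {"n": carrying_capacity,
                     "ones_fraction": {"survival": 0.95, "reproduction": 1.0}},
            "genome": {
                "n_age_classes": 25,
                "survival": {"bits_per_block": 4},
                "reproduction": {"bits_per_block": 4, "upper_bound": 0.5},
                "mutation_rate": {"evolvable": False, "age_dependent": False,
                                  "initial_value": 0.002},
            },
            "reproduction": {"maturity_age": 10, "mutation_rate": 0.002},
            "hazards": {"starvation": {"model": "gradual", "susceptibility": 0.1}},
            "recording": {"window": 1000},
        }
    )


def preset_neutral_drift(steps: int = 2000, population_size: int = 200,
                         n_loci: int = 40) -> SimulationConfig:
    """Neutral, Wright-Fisher-like discrete-generation study conditions.

    All loci have zero phenotypic effect (survival bounds collapsed to 1),
    mutation is off, and generations are discrete: adults survive every step
    until the age limit, lay eggs throughout, the whole egg pool hatches
    when the adults die, and instantaneous starvation uniformly trims the
    hatchlings back to the carrying capacity — a Cannings resampling whose
    offspring-number variance is close to Poisson because the egg pool is an
    order of magnitude larger than the carrying capacity.
    """
    return config_from_dict(
        {
            "steps": steps,
            "carrying_capacity": population_size,
            "init": {"n": population_size, "ones_fraction": {"survival": 0.5}},
            "genome": {
                "n_age_classes": 50,
                "survival": {"age_dependent": False, "bits_per_block": n_loci,
                             "lower_bound": 1.0, "upper_bound": 1.0},
                "reproduction": {"evolvable": False, "age_dependent": False,
                                 "initial_value": 0.5},
                "mutation_rate": {"evolvable": False, "age_dependent": False,
                                  "initial_value": 0.0},
            },
            "reproduction": {"mode": "sexual", "maturity_age": 0, "oviparous": True,
                             "hatching_policy": "when_adults_extinct",
                             "recombination_rate": 1.0, "mutation_rate": 0.0},
            "hazards": {"starvation": {"model": "instantaneous"}},
            "recording": {"window": 500},
        }
    )


# -- Rose-style preset -----------------------------------------------------

@dataclass
class RosePlan:
    """Parameters of the Rose-style two-arm selection experiment.

    Arm B collects the next generation from eggs laid in the window
    ``[maturity_age, b_last_day]``; arm O lets adults lay up to
    ``o_last_day`` and ranks eggs by laying day descending, carrying the
    latest-laid over (up to the carrying capacity).
    """

    carrying_capacity: int = 1000
    maturity_age: int = 14
    b_last_day: int = 21
    o_last_day: int = 50
    n_age_classes: int = 51
    bits_per_block: int = 4
    mutation_rate: float = 0.001
    recombination_rate: float = 1.0
    generations: int = 30
    burn_in_generations: int = 200
    init_survival_fraction: float = 0.98
    init_fertility_fraction: float = 1.0
    selection: str = "latest"  # or "weighted": carry-over probability ~ laying day
    # Wild-like extension: overlapping generations with age-weighted
    # resource competition (older individuals starve first); demographic
    # transients from the imported single-age cohort are allowed to settle
    # before the measurement window.
    wild_settle_steps: int = 400
    wild_measure_steps: int = 200
    wild_age_weight_slope: float = 0.3

    def architecture(self):
        return build_architecture(
            [
                TraitSpec("survival", bits_per_block=self.bits_per_block),
                TraitSpec("reproduction", bits_per_block=self.bits_per_block, upper_bound=0.5),
                TraitSpec("mutation_rate", evolvable=False, age_dependent=False,
                          initial_value=self.mutation_rate),
            ],
            self.n_age_classes,
        )


def preset_rose(**kwargs) -> RosePlan:
    """The Rose-style experiment preset with artifact default parameters."""
    return RosePlan(**kwargs)


def select_rose_eggs(
    laid_days: np.ndarray,
    k: int,
    arm: str,
    plan: RosePlan,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of the eggs carried into the next generation.

    B: uniform draw from eggs laid within the early window. O: latest-laid
    first; ties at the marginal day resolved uniformly ("latest" policy), or
    carry-over probability proportional to laying day ("weighted" policy).
    """
    laid_days = np.asarray(laid_days)
    if arm == "B":
        pool = np.flatnonzero(
            (laid_days >= plan.maturity_age) & (laid_days <= plan.b_last_day)
        )
        if pool.size <= k:
            return pool
        return rng.choice(pool, size=k, replace=False)
    if arm != "O":
        raise ValueError(f"unknown arm {arm!r}")
    pool = np.flatnonzero(laid_days <= plan.o_last_day)
    if pool.size <= k:
        return pool
    if plan.selection == "weighted":
        w = laid_days[pool].astype(np.float64)
        w = w / w.sum()
        return rng.choice(pool, size=k, replace=False, p=w)
    days = laid_days[pool]
    chosen: list[np.ndarray] = []
    remaining = k
    for day in np.sort(np.unique(days))[::-1]:
        idx = pool[days == day]
        if idx.size <= remaining:
            chosen.append(idx)
            remaining -= idx.size
        else:
            chosen.append(rng.choice(idx, size=remaining, replace=False))
            remaining = 0
        if remaining == 0:
            break
    return np.concatenate(chosen)


def _block_values(genomes: np.ndarray, arch, trait: str, age: int) -> np.ndarray:
    """Trait value at one age for a same-aged cohort (all-ones drift map)."""
    spec = arch.trait(trait)
    sl = arch.block_slice(trait, age)
    raw = genomes[:, :, sl].sum(axis=(1, 2)) / (2.0 * spec.bits_per_block)
    return spec.lower_bound + raw * (spec.upper_bound - spec.lower_bound)


def run_rose_generation(
    genomes: np.ndarray,
    plan: RosePlan,
    arm: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation: a same-aged cohort lives, lays eggs, and is replaced.

    The cohort experiences intrinsic mortality only (benign laboratory
    conditions); eggs are collected with their laying day and the arm's
    selection rule picks the next generation.
    """
    arch = plan.architecture()
    last_day = plan.b_last_day if arm == "B" else plan.o_last_day
    alive = genomes
    egg_genomes: list[np.ndarray] = []
    egg_days: list[np.ndarray] = []
    for day in range(last_day + 1):
        if alive.shape[0] == 0:
            break
        survival = _block_values(alive, arch, "survival", day)
        alive = alive[rng.random(alive.shape[0]) < survival]
        if alive.shape[0] < 2 or day < plan.maturity_age:
            continue
        fert = _block_values(alive, arch, "reproduction", day)
        ids = np.flatnonzero(rng.random(alive.shape[0]) < fert)
        if ids.size < 2:
            continue
        perm = rng.permutation(ids)
        pairs = perm[: 2 * (perm.size // 2)].reshape(-1, 2)
        rec = recombine_batch(alive[pairs.reshape(-1)], plan.recombination_rate, rng)
        p = pairs.shape[0]
        rec = rec.reshape(p, 2, 2, -1)
        choice = rng.integers(2, size=(p, 2))
        rows = np.arange(p)
        kids = np.stack([rec[rows, 0, choice[:, 0]], rec[rows, 1, choice[:, 1]]], axis=1)
        kids = mutate_genomes(kids.astype(np.uint8), plan.mutation_rate, rng, inplace=True)
        egg_genomes.append(kids)
        egg_days.append(np.full(p, day, dtype=np.int32))
    if not egg_genomes:
        return np.zeros((0, 2, arch.total_bits), dtype=np.uint8)
    eggs = np.concatenate(egg_genomes)
    days = np.concatenate(egg_days)
    keep = select_rose_eggs(days, plan.carrying_capacity, arm, plan, rng)
    return eggs[keep]


def _intrinsic_median(genomes: np.ndarray, plan: RosePlan) -> float:
    arch = plan.architecture()
    phen = interpret_phenotypes(genomes, arch, new_drift_map(arch), plan.maturity_age)
    return median_from_survivorship(intrinsic_curves(phen).survivorship)


def run_rose_experiment(
    plan: RosePlan,
    seed: int = 1,
    replicates: int = 10,
    wild: bool = True,
) -> pd.DataFrame:
    """Burn-in under B conditions, then paired B/O evolution per replicate.

    Returns one row per replicate with median intrinsic lifespans of both
    evolved arms and, if ``wild`` is set, observed median lifespans of both
    arms re-run under wild-like conditions (overlapping generations with
    resource limitation) plus the full wild survivorship curves.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    arch = plan.architecture()
    genomes = init_genomes(
        plan.carrying_capacity,
        arch,
        {
            "survival": plan.init_survival_fraction,
            "reproduction": plan.init_fertility_fraction,
            "mutation_rate": 0.5,
        },
        rng,
    )
    for _ in range(plan.burn_in_generations):
        genomes = run_rose_generation(genomes, plan, "B", rng)
        if genomes.shape[0] == 0:
            raise RuntimeError("Rose burn-in went extinct; adjust the plan parameters")
    burn_in = genomes

    rows = []
    for rep in range(replicates):
        rep_seed = _replicate_seed(seed, rep + 1)
        evolved = {}
        for arm in ("B", "O"):
            arm_rng = np.random.default_rng(np.random.SeedSequence(rep_seed, spawn_key=(0 if arm == "B" else 1,)))
            g = burn_in.copy()
            for _ in range(plan.generations):
                g = run_rose_generation(g, plan, arm, arm_rng)
                if g.shape[0] == 0:
                    break
            evolved[arm] = g
        row = {
            "replicate": rep,
            "seed": rep_seed,
            "intrinsic_median_B": _intrinsic_median(evolved["B"], plan),
            "intrinsic_median_O": _intrinsic_median(evolved["O"], plan),
        }
        if wild:
            for arm in ("B", "O"):
                curves = _wild_survivorship(evolved[arm], plan, rep_seed + (7 if arm == "O" else 3))
                row[f"wild_median_{arm}"] = median_from_survivorship(curves)
                row[f"wild_survivorship_{arm}"] = curves
        rows.append(row)
    return pd.DataFrame(rows)


def _wild_survivorship(genomes: np.ndarray, plan: RosePlan, seed: int) -> np.ndarray:
    """Observed survivorship of an evolved population under wild-like
    conditions: overlapping generations (viviparity) and limited resources,
    with starvation risk increasing with age. The life table is estimated
    after a settling period so the imported single-age cohort's demographic
    waves have dissipated."""
    weights = [1.0 + plan.wild_age_weight_slope * a for a in range(plan.n_age_classes)]
    cfg = config_from_dict(
        {
            "steps": plan.wild_settle_steps + plan.wild_measure_steps,
            "carrying_capacity": plan.carrying_capacity,
            "genome": {
                "n_age_classes": plan.n_age_classes,
                "survival": {"bits_per_block": plan.bits_per_block},
                "reproduction": {"bits_per_block": plan.bits_per_block, "upper_bound": 0.5},
                "mutation_rate": {
                    "evolvable": False,
                    "age_dependent": False,
                    "initial_value": plan.mutation_rate,
                },
            },
            "reproduction": {
                "mode": "sexual",
                "maturity_age": plan.maturity_age,
                "oviparous": False,
                "recombination_rate": plan.recombination_rate,
                "mutation_rate": plan.mutation_rate,
            },
            "hazards": {
                "starvation": {
                    "model": "gradual",
                    "susceptibility": 0.1,
                    "age_weighting": weights,
                }
            },
            "recording": {"window": plan.wild_measure_steps},
        }
    )
    pop = PopulationState.from_genomes(genomes.copy(), step=-1)
    out = Simulation(cfg, seed=seed % (2**31), initial_population=pop).run()
    first_measure_window = plan.wild_settle_steps // plan.wild_measure_steps
    return life_table_observed(out.ledger, slice(first_measure_window, None)).survivorship
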