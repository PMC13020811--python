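"""Reproduction: eligibility, mate pairing, offspring genomes, egg hatching.

Reproduction runs after all mortality within a step, so offspring never face
hazards in their birth step. Sexual offspring are built by recombining each
parent's haplotype pair, assorting one haplotype from each, then applying
germline mutation; asexual offspring are mutated clones. Each reproducing
individual (or pair) produces at most one offspring per step, and each
individual mates at most once per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import (
    ConfigurationError,
    GenomeArchitecture,
    PhenotypeTable,
    assort,
    mutate_genomes,
    recombine_batch,
)
from .population import PopulationState

__all__ = [
    "ReproductionParams",
    "eligible_parents",
    "pair_mates",
    "generate_offspring",
    "hatch_eggs",
]

EVOLVABLE = "evolvable"


@dataclass(frozen=True)
class ReproductionParams:
    """Reproduction mode and life-cycle switches.

    ``mutation_rate`` is either a constant per-bit probability or the string
    ``"evolvable"``, in which case each offspring is mutated at the rate
    encoded in its mother-of-record's genome (the first-listed pair member in
    sexual mode).
    """

    mode: str = "sexual"
    maturity_age: int = 0
    menopause_age: int | None = None
    oviparous: bool = False
    incubation: int = 0
    hatching_policy: str = "fixed_incubation"
    recombination_rate: float = 1.0
    mutation_rate: float | str = 0.001

    def __post_init__(self) -> None:
        if self.mode not in ("sexual", "asexual"):
            raise ConfigurationError(f"unknown reproduction mode {self.mode!r}")
        if self.hatching_policy not in ("fixed_incubation", "when_adults_extinct"):
            raise ConfigurationError(f"unknown hatching policy {self.hatching_policy!r}")
        if self.maturity_age < 0 or self.incubation < 0:
            raise ConfigurationError("maturity_age and incubation must be >= 0")
        if self.menopause_age is not None and self.menopause_age <= self.maturity_age:
            raise ConfigurationError("menopause_age must exceed maturity_age")
        if not isinstance(self.mutation_rate, str):
            if not 0.0 <= self.mutation_rate <= 1.0:
                raise ConfigurationError("mutation_rate must be in [0, 1]")
        elif self.mutation_rate != EVOLVABLE:
            raise ConfigurationError("mutation_rate must be a probability or 'evolvable'")


def eligible_parents(
    pop: PopulationState,
    phen: PhenotypeTable,
    params: ReproductionParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mask of individuals attempting reproduction this step.

    Eligible means alive and within [maturity, menopause); each eligible
    individual then attempts with probability fertility(age).
    """
    eligible = pop.ages >= params.maturity_age
    if params.menopause_age is not None:
        eligible &= pop.ages < params.menopause_age
    fert = phen.value_at("reproduction", pop.ages)
    return eligible & (rng.random(pop.n_living) < fert)


def pair_mates(attempting_ids: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split a uniformly shuffled attempt list into disjoint pairs.

    Returns an array of shape (n_pairs, 2); an odd leftover individual does
    not reproduce this step. Pairing ignores age and genotype (random mating).
    """
    ids = np.asarray(attempting_ids)
    perm = rng.permutation(ids)
    n_pairs = perm.shape[0] // 2
    return perm[: 2 * n_pairs].reshape(n_pairs, 2)


def _offspring_mutation_rates(
    mothers: np.ndarray,
    mother_ages: np.ndarray,
    phen: PhenotypeTable,
    params: ReproductionParams,
) -> np.ndarray | float:
    if params.mutation_rate == EVOLVABLE:
        rates = phen.values["mutation_rate"]
        if rates.ndim == 2:  # age-dependent evolvable rate
            ages = np.clip(mother_ages, 0, phen.n_age_classes - 1)
            return rates[mothers, ages]
        return rates[mothers]
    return float(params.mutation_rate)


def generate_offspring(
    pop: PopulationState,
    parents: np.ndarray,
    phen: PhenotypeTable,
    params: ReproductionParams,
    arch: GenomeArchitecture,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Build offspring genomes from pairs (sexual) or selfers (asexual).

    ``parents`` is (p, 2) pair indices in sexual mode or (p,) indices in
    asexual mode. Returns ``(genomes, parental_ages)`` where parental age is
    the mother-of-record's (first pair member's) age.

    Sexual mode: recombine each parent's haplotypes, then assort one
    haplotype from each; asexual mode: copy both haplotypes. Germline
    mutation is applied last, at the offspring-relevant rate.
    """
    parents = np.asarray(parents)
    if params.mode == "sexual":
        if parents.size == 0:
            empty = np.zeros((0, 2, pop.genomes.shape[2]), dtype=np.uint8)
            return empty, np.zeros(0, dtype=np.int32)
        mothers = parents[:, 0]
        flat = parents.reshape(-1)
        recombined = recombine_batch(pop.genomes[flat], params.recombination_rate, rng)
        p = parents.shape[0]
        choice = rng.integers(2, size=(p, 2))
        rec = recombined.reshape(p, 2, 2, -1)
        rows = np.arange(p)
        offspring = np.stack(
            [rec[rows, 0, choice[:, 0]], rec[rows, 1, choice[:, 1]]], axis=1
        ).astype(np.uint8)
    else:
        mothers = parents
        offspring = pop.genomes[parents].copy()
    rates = _offspring_mutation_rates(mothers, pop.ages[mothers], phen, params)
    offspring = mutate_genomes(offspring, rates, rng, inplace=True)
    return offspring, pop.ages[mothers].astype(np.int32)


def sexual_offspring_single(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    recombination_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One sexual offspring genome from two parental genomes (no mutation)."""
    rec = recombine_batch(np.stack([parent_a, parent_b]), recombination_rate, rng)
    return assort(rec[0], rec[1], rng)


def hatch_eggs(
    pop: PopulationState,
    params: ReproductionParams,
    step: int,
) -> tuple[int, np.ndarray]:
    """Move due eggs into the living pool at age 0.

    ``fixed_incubation``: an egg laid at step s hatches at step
    s + 1 + incubation (incubation 0 means the step after laying).
    ``when_adults_extinct``: the whole egg pool hatches at the first step
    with zero living individuals, producing non-overlapping generations.
    Returns (number hatched, parental ages of the hatched eggs).
    """
    if pop.n_eggs == 0:
        return 0, np.zeros(0, dtype=np.int32)
    if params.hatching_policy == "fixed_incubation":
        due = pop.eggs.laid_step + params.incubation < step
    else:
        if pop.n_living > 0:
            return 0, np.zeros(0, dtype=np.int32)
        due = np.ones(pop.n_eggs, dtype=bool)
    if not due.any():
        return 0, np.zeros(0, dtype=np.int32)
    genomes, _, parental_age = pop.eggs.take(due)
    pop.add_living(genomes, step=step)
    return genomes.shape[0], parental_age
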