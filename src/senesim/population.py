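"""Population state containers.

Living individuals and eggs are held in separate parallel-array pools. Eggs
are developing individuals that are invulnerable to every mortality source;
keeping them out of the living pool makes that exemption structural — hazard
operators simply never see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PopulationState", "EggPool"]


@dataclass
class EggPool:
    """Eggs awaiting hatching: genome, laying step and parental age."""

    genomes: np.ndarray  # (m, 2, L) uint8
    laid_step: np.ndarray  # (m,) int64
    parental_age: np.ndarray  # (m,) int32

    @classmethod
    def empty(cls, total_bits: int) -> "EggPool":
        return cls(
            genomes=np.zeros((0, 2, total_bits), dtype=np.uint8),
            laid_step=np.zeros(0, dtype=np.int64),
            parental_age=np.zeros(0, dtype=np.int32),
        )

    @property
    def n(self) -> int:
        return self.genomes.shape[0]

    def add(self, genomes: np.ndarray, laid_step: int, parental_age: np.ndarray) -> None:
        if genomes.shape[0] == 0:
            return
        self.genomes = np.concatenate([self.genomes, genomes.astype(np.uint8)])
        self.laid_step = np.concatenate(
            [self.laid_step, np.full(genomes.shape[0], laid_step, dtype=np.int64)]
        )
        self.parental_age = np.concatenate(
            [self.parental_age, np.asarray(parental_age, dtype=np.int32)]
        )

    def take(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Remove and return (genomes, laid_step, parental_age) for ``mask``."""
        taken = (self.genomes[mask], self.laid_step[mask], self.parental_age[mask])
        keep = ~mask
        self.genomes = self.genomes[keep]
        self.laid_step = self.laid_step[keep]
        self.parental_age = self.parental_age[keep]
        return taken


@dataclass
class PopulationState:
    """Parallel per-individual records for the living pool, plus the egg pool."""

    ages: np.ndarray  # (n,) int32
    genomes: np.ndarray  # (n, 2, L) uint8
    infected: np.ndarray  # (n,) bool
    birth_step: np.ndarray  # (n,) int64
    eggs: EggPool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.ages.shape[0]
        if not (self.genomes.shape[0] == self.infected.shape[0] == self.birth_step.shape[0] == n):
            raise ValueError("population arrays have inconsistent lengths")
        if self.eggs is None:
            self.eggs = EggPool.empty(self.genomes.shape[2])

    @classmethod
    def from_genomes(cls, genomes: np.ndarray, step: int = 0, ages: np.ndarray | None = None) -> "PopulationState":
        n = genomes.shape[0]
        return cls(
            ages=np.zeros(n, dtype=np.int32) if ages is None else np.asarray(ages, dtype=np.int32),
            genomes=genomes.astype(np.uint8),
            infected=np.zeros(n, dtype=bool),
            birth_step=np.full(n, step, dtype=np.int64),
        )

    @property
    def n_living(self) -> int:
        return self.ages.shape[0]

    @property
    def n_eggs(self) -> int:
        return self.eggs.n

    @property
    def extinct(self) -> bool:
        return self.n_living == 0 and self.n_eggs == 0

    def remove(self, death_mask: np.ndarray) -> None:
        """Drop the masked individuals from the living pool."""
        if not death_mask.any():
            return
        keep = ~death_mask
        self.ages = self.ages[keep]
        self.genomes = self.genomes[keep]
        self.infected = self.infected[keep]
        self.birth_step = self.birth_step[keep]

    def add_living(self, genomes: np.ndarray, step: int, ages: np.ndarray | None = None) -> None:
        """Append newborns / hatchlings (healthy, age 0 unless given)."""
        k = genomes.shape[0]
        if k == 0:
            return
        self.ages = np.concatenate(
            [self.ages, np.zeros(k, dtype=np.int32) if ages is None else np.asarray(ages, dtype=np.int32)]
        )
        self.genomes = np.concatenate([self.genomes, genomes.astype(np.uint8)])
        self.infected = np.concatenate([self.infected, np.zeros(k, dtype=bool)])
        self.birth_step = np.concatenate([self.birth_step, np.full(k, step, dtype=np.int64)])
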