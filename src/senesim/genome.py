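"""Bit-string genomes and their genotype->phenotype interpretation.

Each individual carries two haplotypes of ``total_bits`` bits (two haplotypes
are kept even under asexual reproduction, where both are copied to the
offspring). Bits are organised into *blocks*: an age-dependent trait owns one
block per age class, an age-independent trait owns a single block. Within a
block the bits act additively — the fraction of bits (over both haplotypes)
that match the environmental drift map is scaled linearly between the trait's
lower and upper bound. The per-bit phenotypic effect is therefore
``(upper - lower) / (2 * bits_per_block)``, which yields a spectrum of loci
with age-specific, configurable effect sizes.

A :class:`DriftMap` records, per locus, which bit value is currently
beneficial; with environmental drift disabled it is all-ones, so a 1-bit is
always the trait-increasing allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "GenomeArchitecture",
    "PhenotypeTable",
    "build_architecture",
    "new_drift_map",
    "init_genomes",
    "interpret_phenotypes",
    "mutate_genomes",
    "recombine",
    "recombine_batch",
    "assort",
]

#: Trait names understood by the simulator.
TRAIT_NAMES = ("survival", "reproduction", "mutation_rate")


class ConfigurationError(ValueError):
    """Raised for inconsistent architecture or parameter settings."""


@dataclass(frozen=True)
class TraitSpec:
    """Specification of one heritable (or constant) life-history trait.

    Parameters
    ----------
    name:
        One of ``survival``, ``reproduction``, ``mutation_rate``.
    age_dependent:
        If True the trait owns one block per age class.
    bits_per_block:
        Number of bits per block on each haplotype.
    lower_bound, upper_bound:
        Phenotype range (per-step probabilities).
    evolvable:
        If False no bits are allocated and the trait is the constant
        ``initial_value``.
    initial_value:
        Constant value for non-evolvable traits.
    """

    name: str
    age_dependent: bool = True
    bits_per_block: int = 8
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    evolvable: bool = True
    initial_value: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in TRAIT_NAMES:
            raise ConfigurationError(f"unknown trait name {self.name!r}")
        if not (0.0 <= self.lower_bound <= self.upper_bound <= 1.0):
            raise ConfigurationError(
                f"trait {self.name!r}: bounds must satisfy "
                f"0 <= lower ({self.lower_bound}) <= upper ({self.upper_bound}) <= 1"
            )
        if self.evolvable and self.bits_per_block < 1:
            raise ConfigurationError(f"trait {self.name!r}: bits_per_block must be >= 1")

    @property
    def effect_size(self) -> float:
        """Phenotypic effect of a single bit (diploid block, linear map)."""
        if not self.evolvable:
            return 0.0
        return (self.upper_bound - self.lower_bound) / (2.0 * self.bits_per_block)


@dataclass(frozen=True)
class GenomeArchitecture:
    """Layout mapping bit positions to (trait, age class, offset within block).

    ``slices`` maps each evolvable trait to its half-open bit range; within a
    trait's range, consecutive blocks of ``bits_per_block`` bits correspond to
    age classes 0, 1, ... (a single block for age-independent traits).
    """

    n_age_classes: int
    traits: tuple[TraitSpec, ...]
    total_bits: int
    slices: dict[str, slice] = field(repr=False)

    def trait(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def n_blocks(self, spec: TraitSpec) -> int:
        return self.n_age_classes if spec.age_dependent else 1

    def block_slice(self, name: str, age_class: int) -> slice:
        """Bit range of one trait block (age_class ignored if age-independent)."""
        spec = self.trait(name)
        if name not in self.slices:
            raise KeyError(f"trait {name!r} is not evolvable; no bits allocated")
        base = self.slices[name].start
        block = age_class if spec.age_dependent else 0
        start = base + block * spec.bits_per_block
        return slice(start, start + spec.bits_per_block)

    def locus_table(self, drift_map: np.ndarray | None = None) -> pd.DataFrame:
        """Per-bit annotation: trait, age class, effect size, beneficial bit.

        Used as the layout sidecar for genotype dumps and for annotating
        site-frequency spectra.
        """
        rows = []
        for spec in self.traits:
            if spec.name not in self.slices:
                continue
            sl = self.slices[spec.name]
            for i in range(sl.start, sl.stop):
                offset = i - sl.start
                block = offset // spec.bits_per_block
                rows.append(
                    {
                        "bit": i,
                        "trait": spec.name,
                        "age_class": block if spec.age_dependent else -1,
                        "effect_size": spec.effect_size,
                    }
                )
        table = pd.DataFrame(rows, columns=["bit", "trait", "age_class", "effect_size"])
        if drift_map is not None:
            table["beneficial_bit"] = np.asarray(drift_map, dtype=np.uint8)[
                table["bit"].to_numpy()
            ]
        return table


def build_architecture(
    traits: list[TraitSpec] | tuple[TraitSpec, ...],
    n_age_classes: int,
) -> GenomeArchitecture:
    """Assemble the deterministic bit layout for a set of trait specs.

    Evolvable traits are laid out contiguously in the order given; the bit
    index <-> (trait, age class, offset) relation is a bijection over the
    allocated bits.
    """
    if n_age_classes < 1:
        raise ConfigurationError("n_age_classes must be >= 1")
    names = [t.name for t in traits]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate trait names")
    slices: dict[str, slice] = {}
    cursor = 0
    for spec in traits:
        if not spec.evolvable:
            continue
        n_blocks = n_age_classes if spec.age_dependent else 1
        width = n_blocks * spec.bits_per_block
        slices[spec.name] = slice(cursor, cursor + width)
        cursor += width
    return GenomeArchitecture(
        n_age_classes=n_age_classes,
        traits=tuple(traits),
        total_bits=cursor,
        slices=slices,
    )


def new_drift_map(arch: GenomeArchitecture) -> np.ndarray:
    """All-ones drift map: a set bit is beneficial at every locus."""
    return np.ones(arch.total_bits, dtype=np.uint8)


def init_genomes(
    n: int,
    arch: GenomeArchitecture,
    ones_fraction: dict[str, float] | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` de-novo genomes, shape ``(n, 2, total_bits)``.

    Each bit within a trait's blocks is set independently with that trait's
    fraction. A single float applies to all traits. Identical fractions across
    age classes produce an age-flat (non-aging) expected phenotype.
    """
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    genomes = np.zeros((n, 2, arch.total_bits), dtype=np.uint8)
    for spec in arch.traits:
        if spec.name not in arch.slices:
            continue
        frac = ones_fraction if isinstance(ones_fraction, (int, float)) else ones_fraction[spec.name]
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(
                f"ones_fraction for {spec.name!r} must be in [0, 1], got {frac}"
            )
        sl = arch.slices[spec.name]
        genomes[:, :, sl] = rng.random((n, 2, sl.stop - sl.start)) < frac
    return genomes


@dataclass
class PhenotypeTable:
    """Per-individual interpreted trait values.

    Age-dependent traits are ``(n, n_age_classes)`` arrays; age-independent
    traits are ``(n,)`` arrays.
    """

    values: dict[str, np.ndarray]
    n_age_classes: int

    @property
    def n(self) -> int:
        first = next(iter(self.values.values()))
        return first.shape[0]

    def value_at(self, trait: str, ages: np.ndarray) -> np.ndarray:
        """Trait value of each individual at its own (clipped) age."""
        arr = self.values[trait]
        if arr.ndim == 1:
            return arr
        a = np.clip(ages, 0, self.n_age_classes - 1)
        return arr[np.arange(arr.shape[0]), a]


def interpret_phenotypes(
    genomes: np.ndarray,
    arch: GenomeArchitecture,
    drift_map: np.ndarray,
    maturity_age: int = 0,
    menopause_age: int | None = None,
) -> PhenotypeTable:
    """Map genomes to age-specific trait values.

    Per block the raw score is the fraction of bits, over both haplotypes,
    equal to the drift-map target; the value is
    ``lower + raw * (upper - lower)``, clipped to the bounds. Non-evolvable
    traits are filled with their constant. Reproduction is forced to zero
    below ``maturity_age`` and at or above ``menopause_age``.
    """
    genomes = np.asarray(genomes)
    if genomes.ndim != 3 or genomes.shape[1] != 2 or genomes.shape[2] != arch.total_bits:
        raise ValueError(
            f"genome array shape {genomes.shape} does not match architecture "
            f"(expected (n, 2, {arch.total_bits}))"
        )
    n = genomes.shape[0]
    match = genomes == drift_map[None, None, :]
    values: dict[str, np.ndarray] = {}
    for spec in arch.traits:
        if not spec.evolvable:
            const = np.float64(spec.initial_value)
            if spec.age_dependent:
                values[spec.name] = np.full((n, arch.n_age_classes), const)
            else:
                values[spec.name] = np.full(n, const)
            continue
        sl = arch.slices[spec.name]
        n_blocks = arch.n_blocks(spec)
        block = match[:, :, sl].reshape(n, 2, n_blocks, spec.bits_per_block)
        raw = block.sum(axis=(1, 3), dtype=np.float64) / (2.0 * spec.bits_per_block)
        vals = spec.lower_bound + raw * (spec.upper_bound - spec.lower_bound)
        np.clip(vals, spec.lower_bound, spec.upper_bound, out=vals)
        values[spec.name] = vals if spec.age_dependent else vals[:, 0]
    if "reproduction" in values:
        repro = values["reproduction"]
        if repro.ndim == 2:
            repro[:, :maturity_age] = 0.0
            if menopause_age is not None:
                repro[:, menopause_age:] = 0.0
    return PhenotypeTable(values=values, n_age_classes=arch.n_age_classes)


def mutate_genomes(
    genomes: np.ndarray,
    per_bit_rate: np.ndarray | float,
    rng: np.random.Generator,
    inplace: bool = False,
) -> np.ndarray:
    """Flip each bit independently with its individual's germline rate.

    Mutation is symmetric (0->1 and 1->0 equally likely). This operator is
    applied to offspring genomes only; genomes are stable across life.
    """
    rate = np.asarray(per_bit_rate, dtype=np.float64)
    if np.any(rate < 0) or np.any(rate > 1):
        raise ConfigurationError("mutation rates must be in [0, 1]")
    out = genomes if inplace else genomes.copy()
    if out.size == 0 or np.all(rate == 0):
        return out
    r = rate.reshape(-1, 1, 1) if rate.ndim == 1 else rate
    flips = rng.random(out.shape) < r
    np.bitwise_xor(out, flips.astype(np.uint8), out=out)
    return out


def recombine(
    haplotypes: np.ndarray,
    recombination_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cross over one individual's haplotype pair.

    The crossover count is Poisson with mean ``recombination_rate``; cut
    positions are uniform interior boundaries drawn without replacement.
    Segments between successive cuts alternate haplotypes, so the unordered
    pair of bits at each locus is conserved.
    """
    if recombination_rate < 0:
        raise ConfigurationError("recombination_rate must be >= 0")
    out = haplotypes.copy()
    length = out.shape[1]
    if recombination_rate == 0 or length < 2:
        return out
    k = rng.poisson(recombination_rate)
    k = min(k, length - 1)
    if k == 0:
        return out
    cuts = rng.choice(length - 1, size=k, replace=False) + 1
    swap = _parity_mask(cuts, length)
    out[0, swap], out[1, swap] = haplotypes[1, swap], haplotypes[0, swap]
    return out


def _parity_mask(cuts: np.ndarray, length: int) -> np.ndarray:
    ind = np.zeros(length, dtype=np.int64)
    ind[cuts] = 1
    return np.cumsum(ind) % 2 == 1


def recombine_batch(
    genomes: np.ndarray,
    recombination_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised :func:`recombine` over a ``(k, 2, L)`` stack of genomes.

    Same distribution as the scalar version: per genome a Poisson crossover
    count with positions uniform without replacement (the ``counts[i]``
    lowest-ranked of i.i.d. uniforms over the interior boundaries).
    """
    if recombination_rate < 0:
        raise ConfigurationError("recombination_rate must be >= 0")
    out = genomes.copy()
    k, _, length = out.shape
    if recombination_rate == 0 or length < 2 or k == 0:
        return out
    counts = np.minimum(rng.poisson(recombination_rate, size=k), length - 1)
    if not counts.any():
        return out
    u = rng.random((k, length - 1))
    order = np.argsort(u, axis=1)
    ranks = np.empty_like(order)
    ranks[np.arange(k)[:, None], order] = np.arange(length - 1)[None, :]
    ind = np.zeros((k, length), dtype=np.int8)
    ind[:, 1:] = ranks < counts[:, None]
    swap = (np.cumsum(ind, axis=1) & 1).astype(bool)
    out[:, 0, :] = np.where(swap, genomes[:, 1, :], genomes[:, 0, :])
    out[:, 1, :] = np.where(swap, genomes[:, 0, :], genomes[:, 1, :])
    return out


def assort(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one haplotype uniformly from each (recombined) parent."""
    ha = parent_a[rng.integers(2)]
    hb = parent_b[rng.integers(2)]
    return np.stack([ha, hb]).astype(np.uint8, copy=True)
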