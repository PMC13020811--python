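"""Demographic ledgers, life-history curves, and variant-frequency analysis.

Three output families:

* demographic records — deaths by cause and age, births by parental age,
  age structure (person-steps per age class), population size per step;
* life-history traits — *observed* curves estimated from the ledger
  (realised outcomes, shaped by all hazards) and *intrinsic* curves read off
  the genomes (the biological potential if only genetic mortality acted);
* variant frequencies — per-locus allele frequencies and the site frequency
  spectrum, annotated with each locus's trait, age class and effect under
  the current drift map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeArchitecture, PhenotypeTable
from .hazards import CAUSES

__all__ = [
    "DemographicLedger",
    "LifeHistoryCurves",
    "SFSResult",
    "life_table_observed",
    "intrinsic_curves",
    "individual_intrinsic_survivorship",
    "compute_sfs",
    "summary_metrics",
    "median_from_survivorship",
]


class DemographicLedger:
    """Longitudinal per-window demographic bookkeeping.

    Deaths, births and exposure are aggregated over windows of ``window``
    steps; population size is recorded every step (immediately after
    reproduction). Exposure at age a counts individuals alive entering age a
    — since an individual spends exactly one step in each age class this
    equals person-steps at that age. Death ages run 0..n_age_classes where
    the last slot holds age-limit deaths.
    """

    def __init__(self, n_age_classes: int, window: int = 100) -> None:
        self.n_age_classes = n_age_classes
        self.window = window
        self.n_ages = n_age_classes + 1  # +1: the age-limit slot
        self._cause_idx = {c: i for i, c in enumerate(CAUSES)}
        self._deaths: list[np.ndarray] = []
        self._births: list[np.ndarray] = []
        self._exposure: list[np.ndarray] = []
        self._popsize: list[tuple[int, int, int]] = []  # (step, living, eggs)
        self._step_deaths: list[int] = []
        self._step_recruits: list[int] = []  # viviparous births + hatchlings
        self._step_start_living: list[int] = []
        self._new_window()

    def _new_window(self) -> None:
        self._deaths.append(np.zeros((len(CAUSES), self.n_ages), dtype=np.int64))
        self._births.append(np.zeros(self.n_ages, dtype=np.int64))
        self._exposure.append(np.zeros(self.n_ages, dtype=np.int64))

    @property
    def n_windows(self) -> int:
        return len(self._deaths)

    # -- per-step hooks ----------------------------------------------------
    def record_exposure(self, ages: np.ndarray) -> None:
        self._exposure[-1] += np.bincount(
            np.clip(ages, 0, self.n_ages - 1), minlength=self.n_ages
        )

    def record_deaths(self, cause: str, ages: np.ndarray) -> None:
        if ages.size == 0:
            return
        self._deaths[-1][self._cause_idx[cause]] += np.bincount(
            np.clip(ages, 0, self.n_ages - 1), minlength=self.n_ages
        )

    def record_births(self, parental_ages: np.ndarray) -> None:
        if parental_ages.size == 0:
            return
        self._births[-1] += np.bincount(
            np.clip(parental_ages, 0, self.n_ages - 1), minlength=self.n_ages
        )

    def record_popsize(self, step: int, living: int, eggs: int) -> None:
        self._popsize.append((step, living, eggs))

    def record_step_totals(self, deaths: int, recruits: int) -> None:
        self._step_deaths.append(deaths)
        self._step_recruits.append(recruits)

    def record_step_start(self, living: int) -> None:
        self._step_start_living.append(living)

    def end_step(self, step: int) -> None:
        if (step + 1) % self.window == 0:
            self._new_window()

    # -- access ------------------------------------------------------------
    def deaths_array(self, window: int | slice = slice(None)) -> np.ndarray:
        """(n_causes, n_ages) death counts summed over the selected windows."""
        return np.sum(np.stack(self._deaths)[window], axis=0)

    def births_array(self, window: int | slice = slice(None)) -> np.ndarray:
        return np.sum(np.stack(self._births)[window], axis=0)

    def exposure_array(self, window: int | slice = slice(None)) -> np.ndarray:
        return np.sum(np.stack(self._exposure)[window], axis=0)

    @property
    def step_deaths(self) -> np.ndarray:
        return np.asarray(self._step_deaths, dtype=np.int64)

    @property
    def step_recruits(self) -> np.ndarray:
        return np.asarray(self._step_recruits, dtype=np.int64)

    @property
    def step_start_living(self) -> np.ndarray:
        return np.asarray(self._step_start_living, dtype=np.int64)

    def popsize_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._popsize, columns=["step", "living", "eggs"])

    def deaths_frame(self) -> pd.DataFrame:
        """Tidy table: one row per window x cause x age class."""
        rows = []
        for w, block in enumerate(self._deaths):
            for c, cause in enumerate(CAUSES):
                for a in range(self.n_ages):
                    if block[c, a]:
                        rows.append((w, cause, a, int(block[c, a])))
        return pd.DataFrame(rows, columns=["window", "cause", "age_class", "deaths"])

    def births_frame(self) -> pd.DataFrame:
        rows = [
            (w, a, int(block[a]))
            for w, block in enumerate(self._births)
            for a in range(self.n_ages)
            if block[a]
        ]
        return pd.DataFrame(rows, columns=["window", "parental_age", "births"])


@dataclass
class LifeHistoryCurves:
    """Per-age survivorship, mortality hazard and fertility.

    ``survivorship`` has length n_ages + 1 with survivorship[0] = 1.
    ``flavor`` is ``observed`` (ledger-derived) or ``intrinsic``
    (genome-derived). Ages with no exposure carry NaN, not zero.
    """

    survivorship: np.ndarray
    mortality: np.ndarray
    fertility: np.ndarray
    flavor: str


def life_table_observed(ledger: DemographicLedger, window: int | slice = slice(None)) -> LifeHistoryCurves:
    """Period life table from ledger counts.

    q(a) = deaths(a) / exposure(a); l(a) = prod_{x<a} (1 - q(x)) with
    l(0) = 1; f(a) = births to parents aged a / exposure(a).
    """
    deaths = ledger.deaths_array(window).sum(axis=0).astype(np.float64)
    exposure = ledger.exposure_array(window).astype(np.float64)
    births = ledger.births_array(window).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(exposure > 0, deaths / exposure, np.nan)
        f = np.where(exposure > 0, births / exposure, np.nan)
    surv = np.empty(q.shape[0] + 1)
    surv[0] = 1.0
    surv[1:] = np.cumprod(1.0 - np.nan_to_num(q, nan=0.0))
    return LifeHistoryCurves(survivorship=surv, mortality=q, fertility=f, flavor="observed")


def intrinsic_curves(phen: PhenotypeTable) -> LifeHistoryCurves:
    """Population-mean intrinsic curves from the current phenotype table."""
    surv_vals = phen.values["survival"]
    fert_vals = phen.values["reproduction"]
    if surv_vals.ndim == 1:
        surv_vals = np.broadcast_to(surv_vals[:, None], (surv_vals.shape[0], phen.n_age_classes))
    if fert_vals.ndim == 1:
        fert_vals = np.broadcast_to(fert_vals[:, None], (fert_vals.shape[0], phen.n_age_classes))
    mu = 1.0 - surv_vals.mean(axis=0)
    f = fert_vals.mean(axis=0)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - mu)])
    return LifeHistoryCurves(survivorship=surv, mortality=mu, fertility=f, flavor="intrinsic")


def individual_intrinsic_survivorship(phen: PhenotypeTable) -> np.ndarray:
    """(n, n_ages + 1) per-individual intrinsic survivorship curves.

    Row i is the survivorship of a hypothetical cohort of clones of
    individual i dying only from intrinsic causes.
    """
    surv_vals = phen.values["survival"]
    if surv_vals.ndim == 1:
        surv_vals = np.broadcast_to(surv_vals[:, None], (surv_vals.shape[0], phen.n_age_classes))
    out = np.ones((surv_vals.shape[0], phen.n_age_classes + 1))
    out[:, 1:] = np.cumprod(surv_vals, axis=1)
    return out


@dataclass
class SFSResult:
    """Per-locus allele frequencies plus the binned spectrum.

    ``frequencies`` is the fraction of haplotypes carrying a 1 at each locus;
    ``counts`` bins the polymorphic loci (fixed loci excluded unless
    requested); ``annotation`` gives trait / age class / effect size /
    beneficial direction per locus.
    """

    frequencies: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    annotation: pd.DataFrame = field(repr=False)

    @property
    def n_polymorphic(self) -> int:
        return int(((self.frequencies > 0) & (self.frequencies < 1)).sum())


def compute_sfs(
    genomes: np.ndarray,
    arch: GenomeArchitecture,
    drift_map: np.ndarray,
    bins: int = 10,
    include_fixed: bool = False,
) -> SFSResult:
    """Site frequency spectrum over all haplotypes of a genotype dump."""
    genomes = np.asarray(genomes)
    haplotypes = genomes.reshape(-1, genomes.shape[-1])
    if haplotypes.shape[0] < 2:
        raise ValueError("SFS requires at least 2 haplotypes")
    freqs = haplotypes.mean(axis=0)
    annotation = arch.locus_table(drift_map)
    annotation["frequency"] = freqs[annotation["bit"].to_numpy()]
    polymorphic = (freqs > 0) & (freqs < 1)
    selected = freqs if include_fixed else freqs[polymorphic]
    counts, edges = np.histogram(selected, bins=bins, range=(0.0, 1.0))
    return SFSResult(frequencies=freqs, bin_edges=edges, counts=counts, annotation=annotation)


def median_from_survivorship(survivorship: np.ndarray) -> float:
    """Age at which survivorship crosses 0.5, linearly interpolated.

    Returns the last age if the curve never reaches 0.5 (more than half the
    cohort survives the full age range).
    """
    s = np.asarray(survivorship, dtype=np.float64)
    below = np.flatnonzero(s <= 0.5)
    if below.size == 0:
        return float(s.shape[0] - 1)
    i = below[0]
    if i == 0:
        return 0.0
    hi, lo = s[i - 1], s[i]
    if hi == lo:
        return float(i)
    return float(i - 1 + (hi - 0.5) / (hi - lo))


def summary_metrics(ledger: DemographicLedger, window: int | slice = slice(None)) -> dict[str, float]:
    """Median lifespan, life expectancy at birth, and the maximal lifespan.

    Median and maximum come from the age-at-death distribution in the
    window. Life expectancy at birth is the sum of the survivorship curve,
    sum_a l(a): each age class contributes the probability of entering it as
    one age-class unit of expected lifetime (l(0) = 1 counts the age-0 step).
    """
    deaths_by_age = ledger.deaths_array(window).sum(axis=0)
    total = deaths_by_age.sum()
    if total == 0:
        return {"median_lifespan": np.nan, "life_expectancy": np.nan, "max_lifespan": np.nan}
    cum = np.cumsum(deaths_by_age)
    median = float(np.searchsorted(cum, (total + 1) / 2.0))
    max_age = float(np.flatnonzero(deaths_by_age > 0)[-1])
    curves = life_table_observed(ledger, window)
    life_expectancy = float(np.nansum(curves.survivorship))
    return {
        "median_lifespan": median,
        "life_expectancy": life_expectancy,
        "max_lifespan": max_age,
    }
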