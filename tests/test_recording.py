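"""Ledger-derived life tables, intrinsic curves, SFS and summary metrics."""

import numpy as np
import pytest

from senesim.config import config_from_dict
from senesim.engine import Simulation
from senesim.genome import PhenotypeTable, TraitSpec, build_architecture, new_drift_map
from senesim.recording import (
    DemographicLedger,
    compute_sfs,
    individual_intrinsic_survivorship,
    intrinsic_curves,
    life_table_observed,
    median_from_survivorship,
    summary_metrics,
)


def ledger_from_counts(deaths_by_age, exposure_by_age, births_by_age=None):
    n_ages = len(exposure_by_age)
    led = DemographicLedger(n_ages - 1, window=100)
    led._deaths[-1][0, :] = deaths_by_age
    led._exposure[-1][:] = exposure_by_age
    if births_by_age is not None:
        led._births[-1][:] = births_by_age
    return led


class TestObservedLifeTable:
    def test_textbook_example(self):
        led = ledger_from_counts([50, 50], [100, 50])
        curves = life_table_observed(led)
        assert np.allclose(curves.mortality, [0.5, 1.0])
        assert np.allclose(curves.survivorship, [1.0, 0.5, 0.0])

    def test_no_deaths_flat_survivorship(self):
        led = ledger_from_counts([0, 0, 0], [100, 100, 100])
        assert np.allclose(life_table_observed(led).survivorship, 1.0)

    def test_zero_exposure_is_undefined_not_zero(self):
        led = ledger_from_counts([10, 0], [100, 0])
        q = life_table_observed(led).mortality
        assert q[0] == pytest.approx(0.1)
        assert np.isnan(q[1])

    def test_fertility_rates_from_births(self):
        led = ledger_from_counts([0, 0], [100, 50], births_by_age=[20, 25])
        f = life_table_observed(led).fertility
        assert np.allclose(f, [0.2, 0.5])

    def test_recovers_known_hazard_from_cohort(self):
        # non-reproducing cohort at constant survival: q(a) ~ 1 - s everywhere
        cfg = config_from_dict({
            "steps": 12, "carrying_capacity": 100_000,
            "init": {"n": 20_000},
            "genome": {"n_age_classes": 10,
                       "survival": {"evolvable": False, "age_dependent": False,
                                    "initial_value": 0.8},
                       "reproduction": {"evolvable": False, "age_dependent": False,
                                        "initial_value": 0.0},
                       "mutation_rate": {"evolvable": False, "age_dependent": False,
                                         "initial_value": 0.0}},
            "reproduction": {"mode": "asexual", "maturity_age": 0, "mutation_rate": 0.0},
            "hazards": {"starvation": None},
            "recording": {"window": 12},
        })
        out = Simulation(cfg, seed=8).run()
        curves = life_table_observed(out.ledger)
        exposure = out.ledger.exposure_array()
        for age in range(9):
            se = np.sqrt(0.2 * 0.8 / exposure[age])
            assert abs(curves.mortality[age] - 0.2) < 4 * se

    def test_observed_cohort_matches_genome_predicted_survivorship(self):
        # observed survivorship of a genetically variable, non-reproducing
        # cohort equals the mean of the per-individual intrinsic curves
        cfg = config_from_dict({
            "steps": 10, "carrying_capacity": 100_000,
            "init": {"n": 20_000, "ones_fraction": {"survival": 0.85,
                                                    "reproduction": 0.0}},
            "genome": {"n_age_classes": 8,
                       "survival": {"bits_per_block": 8},
                       "reproduction": {"bits_per_block": 4, "upper_bound": 0.5,
                                        "lower_bound": 0.0}},
            "reproduction": {"mode": "asexual", "maturity_age": 2, "mutation_rate": 0.0},
            "hazards": {"starvation": None},
            "recording": {"window": 10},
        })
        diffs = []
        for seed in (3, 4, 5):
            sim = Simulation(cfg, seed=seed)
            predicted = individual_intrinsic_survivorship(sim.phen).mean(axis=0)
            obs = life_table_observed(sim.run().ledger).survivorship
            diffs.append(obs[:9] - predicted)
        assert np.abs(np.mean(diffs, axis=0)).max() < 0.01


class TestIntrinsicCurves:
    def make_phen(self, survival_rows):
        survival = np.asarray(survival_rows, dtype=float)
        return PhenotypeTable(
            values={"survival": survival,
                    "reproduction": np.full_like(survival, 0.2)},
            n_age_classes=survival.shape[1],
        )

    def test_survivorship_is_cumprod_of_mean_survival(self):
        phen = self.make_phen([[0.9, 0.8]])
        curves = intrinsic_curves(phen)
        assert np.allclose(curves.mortality, [0.1, 0.2])
        assert np.allclose(curves.survivorship, [1.0, 0.9, 0.72])

    def test_identical_genomes_zero_variance(self):
        phen = self.make_phen([[0.9, 0.8]] * 50)
        per_ind = individual_intrinsic_survivorship(phen)
        assert np.allclose(per_ind.var(axis=0), 0.0)
        assert np.allclose(per_ind[0], [1.0, 0.9, 0.72])

    def test_mean_curve_matches_monte_carlo_cohort(self, rng):
        # survivorship from mean mortality vs a simulated clone cohort
        phen = self.make_phen([[0.95, 0.9, 0.7]])
        curves = intrinsic_curves(phen)
        n = 200_000
        alive = np.ones(n, dtype=bool)
        observed = [1.0]
        for s in (0.95, 0.9, 0.7):
            alive &= rng.random(n) < s
            observed.append(alive.mean())
        assert np.allclose(curves.survivorship, observed, atol=0.005)


class TestSFS:
    def test_per_locus_frequency(self, small_arch):
        g = np.zeros((5, 2, small_arch.total_bits), dtype=np.uint8)
        g[0, 0, 0] = g[1, 0, 0] = g[2, 1, 0] = 1  # 3 of 10 haplotypes
        res = compute_sfs(g, small_arch, new_drift_map(small_arch))
        assert res.frequencies[0] == pytest.approx(0.3)

    def test_fixed_loci_excluded_from_bins(self, small_arch):
        g = np.zeros((5, 2, small_arch.total_bits), dtype=np.uint8)
        g[:, :, 1] = 1  # fixed
        g[0, 0, 2] = 1  # polymorphic at 0.1
        res = compute_sfs(g, small_arch, new_drift_map(small_arch))
        assert res.counts.sum() == 1
        assert res.n_polymorphic == 1
        res_all = compute_sfs(g, small_arch, new_drift_map(small_arch),
                              include_fixed=True)
        assert res_all.counts.sum() == small_arch.total_bits

    def test_annotation_links_loci_to_traits(self, small_arch):
        g = np.zeros((4, 2, small_arch.total_bits), dtype=np.uint8)
        res = compute_sfs(g, small_arch, new_drift_map(small_arch))
        ann = res.annotation
        sl = small_arch.slices["reproduction"]
        repro = ann[(ann.bit >= sl.start) & (ann.bit < sl.stop)]
        assert (repro.trait == "reproduction").all()
        assert np.allclose(repro.effect_size, 0.5 / 8)

    def test_single_haplotype_rejected(self, small_arch):
        with pytest.raises(ValueError):
            compute_sfs(np.zeros((0, 2, small_arch.total_bits), dtype=np.uint8),
                        small_arch, new_drift_map(small_arch))


class TestSummaries:
    def test_median_and_max_from_death_ages(self):
        led = ledger_from_counts([0, 1, 1, 1], [10, 9, 8, 7])
        m = summary_metrics(led)
        assert m["median_lifespan"] == 2.0
        assert m["max_lifespan"] == 3.0

    def test_life_expectancy_is_survivorship_sum(self):
        led = ledger_from_counts([50, 50], [100, 50])  # l = (1, .5, 0)
        assert summary_metrics(led)["life_expectancy"] == pytest.approx(1.5)

    def test_no_deaths_flagged_undefined(self):
        led = ledger_from_counts([0, 0], [100, 100])
        assert np.isnan(summary_metrics(led)["median_lifespan"])

    def test_median_from_survivorship_interpolates(self):
        assert median_from_survivorship([1.0, 0.5, 0.0]) == pytest.approx(1.0)
        assert median_from_survivorship([1.0, 0.75, 0.25, 0.0]) == pytest.approx(1.5)
        assert median_from_survivorship([1.0, 0.9, 0.8]) == 2.0  # never crosses

    def test_ledger_metrics_match_direct_bookkeeping(self):
        out = Simulation(config_from_dict({
            "steps": 150, "carrying_capacity": 400,
            "init": {"n": 300, "ones_fraction": {"survival": 0.9, "reproduction": 1.0}},
            "genome": {"n_age_classes": 10,
                       "survival": {"bits_per_block": 4},
                       "reproduction": {"bits_per_block": 4, "upper_bound": 0.5}},
            "reproduction": {"maturity_age": 2},
            "recording": {"window": 150},
        }), seed=6).run()
        # recompute the metrics from the tidy deaths frame (dual bookkeeping)
        frame = out.ledger.deaths_frame()
        ages = np.repeat(frame["age_class"].to_numpy(), frame["deaths"].to_numpy())
        metrics = summary_metrics(out.ledger)
        assert metrics["max_lifespan"] == ages.max()
        assert metrics["median_lifespan"] == pytest.approx(np.median(ages), abs=0.5)

    def test_rectangularization_without_extrinsic_hazards(self):
        # same cohort with vs without an extrinsic hazard: removing the
        # hazard concentrates deaths into late life (lower variance in age at
        # death; the survivorship curve rectangularizes)
        def death_age_variance(abiotic, seed):
            hazards = {"starvation": None}
            if abiotic:
                hazards["abiotic"] = {"shape": "flat", "baseline": 0.15}
            cfg = config_from_dict({
                "steps": 18, "carrying_capacity": 100_000,
                "init": {"n": 3000, "ones_fraction": {"survival": 0.99,
                                                      "reproduction": 0.0}},
                "genome": {"n_age_classes": 15,
                           "survival": {"bits_per_block": 4},
                           "reproduction": {"bits_per_block": 4, "upper_bound": 0.5,
                                            "lower_bound": 0.0}},
                "reproduction": {"maturity_age": 3},
                "hazards": hazards,
                "recording": {"window": 18},
            })
            out = Simulation(cfg, seed=seed).run()
            d = out.ledger.deaths_array().sum(axis=0)
            ages = np.arange(d.shape[0])
            mean = (ages * d).sum() / d.sum()
            return ((ages - mean) ** 2 * d).sum() / d.sum()

        for seed in range(10, 15):
            assert death_age_variance(False, seed) < death_age_variance(True, seed)
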