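"""Writing run outputs to a directory tree of stable CSV/JSON files."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .engine import RunOutputs, save_snapshot

__all__ = ["write_outputs"]


def write_outputs(out: RunOutputs, directory: str) -> None:
    """Write ledgers, metadata, genotype dumps and the final snapshot.

    Files: popsize.csv (per-step living/egg counts), deaths.csv /
    births.csv / age_structure.csv (tidy per-window tables),
    intrinsic_history.csv (population-mean intrinsic mortality and fertility
    per recording cadence), genotypes.csv (one row per haplotype of the
    final population) with genotype_layout.csv (bit -> trait / age class /
    effect / beneficial direction), metadata.json and final.snapshot.
    """
    os.makedirs(directory, exist_ok=True)
    ledger = out.ledger
    ledger.popsize_frame().to_csv(os.path.join(directory, "popsize.csv"), index=False)
    ledger.deaths_frame().to_csv(os.path.join(directory, "deaths.csv"), index=False)
    ledger.births_frame().to_csv(os.path.join(directory, "births.csv"), index=False)

    exposure = pd.DataFrame(
        [
            (w, a, int(ledger._exposure[w][a]))
            for w in range(ledger.n_windows)
            for a in range(ledger.n_ages)
            if ledger._exposure[w][a]
        ],
        columns=["window", "age_class", "count"],
    )
    exposure.to_csv(os.path.join(directory, "age_structure.csv"), index=False)

    if out.intrinsic_history:
        rows = []
        for step, mu, fert in out.intrinsic_history:
            for a in range(mu.shape[0]):
                rows.append((step, a, float(mu[a]), float(fert[a])))
        pd.DataFrame(
            rows, columns=["step", "age_class", "intrinsic_mortality", "intrinsic_fertility"]
        ).to_csv(os.path.join(directory, "intrinsic_history.csv"), index=False)

    haplos = out.population.genomes.reshape(-1, out.arch.total_bits)
    geno = pd.DataFrame(haplos, columns=[f"bit{i}" for i in range(out.arch.total_bits)])
    geno.insert(0, "individual", np.repeat(np.arange(out.population.n_living), 2))
    geno.insert(1, "haplotype", np.tile([0, 1], out.population.n_living))
    geno.to_csv(os.path.join(directory, "genotypes.csv"), index=False)
    out.arch.locus_table(out.env.drift_map).to_csv(
        os.path.join(directory, "genotype_layout.csv"), index=False
    )

    with open(os.path.join(directory, "metadata.json"), "w") as fh:
        json.dump(out.metadata, fh, indent=2, sort_keys=True)
    save_snapshot(
        os.path.join(directory, "final.snapshot"), out.population, out.env, out.arch
    )
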