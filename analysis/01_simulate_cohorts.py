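"""Generate the synthetic study inputs: ten tumor/normal expression cohorts
with planted metabolic alterations, an expression-linked survival cohort, and
extracellular-flux stress-test plates.

Writes expression/metadata TSVs, the metabolic gene list, the planted truth,
the survival table and the plate traces under results/analysis/.
"""

import sys
from pathlib import Path

import numpy as np

from hccmet import io as hio
from hccmet.synthetic import (CohortSpec, PlantedTruth, generate_multi_cohort,
                              generate_plate_traces, generate_survival_cohort)

SEED = 20240229
OUT = Path("results/analysis")

N_COHORTS, N_GENES, N_PLANTED, N_METABOLIC = 10, 5200, 200, 2752


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(SEED)
    seeds = [int(s) for s in ss.generate_state(N_COHORTS + 3) % (2 ** 31)]

    rng = np.random.default_rng(seeds[-1])
    genes = [f"G{i:05d}" for i in range(N_GENES)]
    planted_idx = sorted(rng.choice(N_GENES, size=N_PLANTED, replace=False))
    directions = {genes[g]: ("up" if i % 2 == 0 else "down")
                  for i, g in enumerate(planted_idx)}
    rest = [i for i in range(N_GENES) if i not in set(planted_idx)]
    metabolic = {genes[g] for g in planted_idx} | {
        genes[g] for g in rng.choice(rest, size=N_METABOLIC - N_PLANTED, replace=False)}

    truth = PlantedTruth(directions, effect_size=3.0, penetrance=1.0)
    specs = [CohortSpec(f"C{k:02d}", N_GENES, n_tumor=20, n_normal=20,
                        noise_sd=0.5, seed=seeds[k]) for k in range(N_COHORTS)]
    cohorts, record = generate_multi_cohort(specs, truth, metabolic)
    for c in cohorts:
        hio.write_expression(c, OUT / f"expr_{c.cohort_id}.tsv",
                             OUT / f"meta_{c.cohort_id}.tsv")
    hio.write_gene_set(metabolic, OUT / "metabolic_genes.txt")
    hio.write_json(record, OUT / "truth.json")

    surv = generate_survival_cohort(n=200, beta=0.5, censor_rate=0.2, seed=seeds[-2])
    hio.write_survival(surv, OUT / "survival.tsv")

    traces = generate_plate_traces(seeds[-3], noise_sd=2.0, n_wells=8)
    traces.to_csv(OUT / "traces.tsv", sep="\t", index=False)

    print(f"wrote {N_COHORTS} cohorts ({N_GENES} genes, 20/20 samples), "
          f"{N_PLANTED} planted of {len(metabolic)} metabolic genes, "
          f"a 200-patient survival cohort ({int(surv['event'].sum())} events), "
          f"and {traces['well'].nunique()}-well stress-test traces -> {OUT}/",
          file=sys.stderr)


if __name__ == "__main__":
    main()
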