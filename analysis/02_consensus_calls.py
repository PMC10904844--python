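"""Per-cohort differential expression and the cross-cohort consensus vote.

Reads the ten cohorts written by 01_simulate_cohorts.py, applies the Welch
test with the P < 0.001 / |log2FC| > 1.5 gate, derives each cohort's
adaptive fold-change cutoff, votes at >= 8 of 10 with the exclusivity rule,
and scores the calls against the planted truth.
"""

import sys
from pathlib import Path

from hccmet import io as hio
from hccmet.consensus import MetabolicGeneSet, consensus_pipeline
from hccmet.diffexp import apply_de_gate, differential_expression

OUT = Path("results/analysis")


def main() -> None:
    truth = hio.read_json(OUT / "truth.json")
    metabolic = MetabolicGeneSet(hio.read_gene_set(OUT / "metabolic_genes.txt"))
    gated = {}
    for matrix in sorted(OUT.glob("expr_C*.tsv")):
        cid = matrix.stem.replace("expr_", "")
        cohort = hio.read_expression(matrix, OUT / f"meta_{cid}.tsv", cid)
        table = apply_de_gate(differential_expression(cohort))
        hio.write_de_table(table, OUT / f"de_{cid}.tsv")
        gated[cid] = table
        print(f"{cid}: {int(table['passes_gate'].sum())} genes pass the DE gate",
              file=sys.stderr)

    calls = consensus_pipeline(gated, metabolic, n_datasets=10, min_datasets=8)
    calls.to_csv(OUT / "consensus.tsv", sep="\t", index_label="gene")

    planted = truth["directions"]
    hits = sum(calls.loc[g, "status"] == f"consistent_{d}"
               for g, d in planted.items() if g in calls.index)
    false_calls = int((calls.loc[calls.index.difference(list(planted)), "status"]
                       != "not_consistent").sum())
    counts = calls["status"].value_counts().to_dict()
    hio.write_json({"status_counts": counts,
                    "sensitivity": hits / len(planted),
                    "false_consistent_calls": false_calls},
                   OUT / "consensus_summary.json")
    print(f"consensus: {counts}; sensitivity {hits / len(planted):.3f} "
          f"({hits}/{len(planted)} planted recovered), "
          f"{false_calls} false consistent calls", file=sys.stderr)


if __name__ == "__main__":
    main()
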