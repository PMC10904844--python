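"""End-to-end orchestration: synthetic inputs -> DE -> consensus -> survival
-> tracer predictions -> ATP partition, with a reproducibility manifest.

A run is fully determined by its RunConfig (validated up front, unknown keys
rejected); the manifest records the seed, parameters and a SHA-256 digest of
every output file, so identical config + seed gives identical digests.
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import io as hio
from .bioenergetics import atp_partition, glyco_metrics, mito_metrics, summarize_trace, AtpConstants
from .consensus import MetabolicGeneSet, consensus_pipeline
from .diffexp import apply_de_gate, differential_expression
from .survival import km_estimate, logrank_test, stratify_by_expression
from .synthetic import (CohortSpec, PlantedTruth, generate_multi_cohort,
                        generate_plate_traces, generate_survival_cohort)
from .tracer import predict_named_routes

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    seed: int = 0
    outdir: str = "results/run"
    # cohort design
    n_cohorts: int = 10
    n_genes: int = 3000
    n_tumor: int = 20
    n_normal: int = 20
    noise_sd: float = 0.5
    n_planted: int = 100
    effect_size: float = 3.0
    penetrance: float = 1.0
    n_metabolic: int = 1000
    # DE gate / consensus
    p_max: float = 0.001
    lfc_min: float = 1.5
    n_datasets: int = 10
    min_datasets: int = 8
    # survival
    survival_n: int = 200
    survival_beta: float = 0.5
    censor_rate: float = 0.2
    stratification: str = "median"
    # tracing / bioenergetics
    tracer: str = "U-13C6-glucose"
    atp_constants: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.min_datasets > self.n_datasets:
            raise ValueError(f"min_datasets ({self.min_datasets}) > n_datasets ({self.n_datasets})")
        if self.n_cohorts != self.n_datasets:
            raise ValueError("n_cohorts must equal n_datasets")
        if self.stratification not in ("median", "tertile"):
            raise ValueError(f"unknown stratification {self.stratification!r}")
        if self.p_max <= 0 or self.lfc_min <= 0 or self.noise_sd <= 0:
            raise ValueError("p_max, lfc_min and noise_sd must be positive")
        AtpConstants(**self.atp_constants)  # raises on bad constants


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; return (and write) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(3 + config.n_cohorts) % (2 ** 31)]
    cohort_seeds, surv_seed, trace_seed, truth_seed = \
        seeds[: config.n_cohorts], seeds[-3], seeds[-2], seeds[-1]
    paths: list[Path] = []

    # synthetic cohorts with planted truth
    _log("simulate", f"{config.n_cohorts} cohorts, {config.n_genes} genes, seed {config.seed}")
    rng = np.random.default_rng(truth_seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    planted = rng.choice(config.n_genes, size=config.n_planted, replace=False)
    directions = {genes[g]: ("up" if i % 2 == 0 else "down")
                  for i, g in enumerate(sorted(planted))}
    metabolic = set(genes[g] for g in planted)
    extra = rng.choice([i for i in range(config.n_genes) if i not in set(planted)],
                       size=max(0, config.n_metabolic - config.n_planted), replace=False)
    metabolic |= {genes[g] for g in extra}
    truth = PlantedTruth(directions, config.effect_size, config.penetrance)
    specs = [CohortSpec(f"C{k:02d}", config.n_genes, config.n_tumor, config.n_normal,
                        noise_sd=config.noise_sd, seed=cohort_seeds[k])
             for k in range(config.n_cohorts)]
    cohorts, record = generate_multi_cohort(specs, truth, metabolic)
    hio.write_gene_set(metabolic, out / "metabolic_genes.txt")
    hio.write_json(record, out / "truth.json")
    paths += [out / "metabolic_genes.txt", out / "truth.json"]
    for c in cohorts:
        mp, dp = out / f"expr_{c.cohort_id}.tsv", out / f"meta_{c.cohort_id}.tsv"
        hio.write_expression(c, mp, dp)
        paths += [mp, dp]

    # per-cohort DE + gate
    _log("diffexp", f"gate: p < {config.p_max}, |log2FC| > {config.lfc_min}")
    gated = {}
    for c in cohorts:
        table = apply_de_gate(differential_expression(c),
                              p_max=config.p_max, lfc_min=config.lfc_min)
        gated[c.cohort_id] = table
        p = out / f"de_{c.cohort_id}.tsv"
        hio.write_de_table(table, p)
        paths.append(p)

    # consensus
    calls = consensus_pipeline(gated, MetabolicGeneSet(frozenset(metabolic)),
                               n_datasets=config.n_datasets,
                               min_datasets=config.min_datasets)
    counts = calls["status"].value_counts().to_dict()
    _log("consensus", f"status counts: {counts}")
    calls.to_csv(out / "consensus.tsv", sep="\t", index_label="gene")
    hio.write_json({"status_counts": counts,
                    "min_datasets": config.min_datasets,
                    "n_datasets": config.n_datasets}, out / "consensus_summary.json")
    paths += [out / "consensus.tsv", out / "consensus_summary.json"]

    # survival
    surv = generate_survival_cohort(config.survival_n, config.survival_beta,
                                    config.censor_rate, surv_seed)
    strat = stratify_by_expression(surv, mode=config.stratification)
    lo = strat[strat["stratum"] == "low"]
    hi = strat[strat["stratum"] == "high"]
    res = logrank_test(lo["time_months"], lo["event"], hi["time_months"], hi["event"])
    _log("survival", f"log-rank chi2 = {res.statistic:.3f}, p = {res.p_value:.3g}")
    hio.write_survival(strat, out / "survival.tsv")
    km_lo = km_estimate(lo["time_months"], lo["event"])
    km_hi = km_estimate(hi["time_months"], hi["event"])
    km_lo.to_frame().assign(stratum="low").to_csv(out / "km_risk_table.tsv", sep="\t",
                                                  index=False, mode="w")
    km_hi.to_frame().assign(stratum="high").to_csv(out / "km_risk_table.tsv", sep="\t",
                                                   index=False, mode="a", header=False)
    hio.write_json({"statistic": res.statistic, "p_value": res.p_value,
                    "mode": config.stratification}, out / "logrank.json")
    paths += [out / "survival.tsv", out / "km_risk_table.tsv", out / "logrank.json"]

    # tracer predictions
    preds = predict_named_routes(config.tracer)
    _log("trace", f"{len(preds)} route predictions for {config.tracer}")
    import pandas as pd
    pd.DataFrame(preds).to_csv(out / "tracer_predictions.tsv", sep="\t", index=False)
    paths.append(out / "tracer_predictions.tsv")

    # bioenergetics
    traces = generate_plate_traces(trace_seed, noise_sd=2.0)
    traces.to_csv(out / "traces.tsv", sep="\t", index=False)
    mito = mito_metrics(summarize_trace(traces, "mito"))
    glyco = glyco_metrics(summarize_trace(traces, "glyco"))
    glyco_ecar = summarize_trace(traces, "glyco").ecar["post_glucose"]
    part = atp_partition(mito["atp_linked"], glyco_ecar,
                         AtpConstants(**config.atp_constants))
    _log("atp", f"fraction_glyc = {part.fraction_glyc:.3f}")
    hio.write_json({"mito": mito, "glyco": glyco, "partition": part.to_dict()},
                   out / "bioenergetics.json")
    paths += [out / "traces.tsv", out / "bioenergetics.json"]

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {p.name: _sha256(p) for p in paths},
    }
    hio.write_json(manifest, out / "manifest.json")
    return manifest
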