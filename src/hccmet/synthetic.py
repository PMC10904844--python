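"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's input classes:

* multi-cohort tumor/normal log2 expression matrices with planted up/down
  metabolic genes (i.i.d. Gaussian noise on the log2 scale, microarray-like;
  per-cohort penetrance abstracts "altered in 8 of 10 datasets" style
  heterogeneity);
* time-to-event cohorts from an exponential proportional-hazards model with
  a tunable hazard-expression link and administrative censoring at a
  follow-up horizon (default 60 months, i.e. five years);
* extracellular-flux stress-test traces (mito: baseline -> oligomycin ->
  uncoupler -> rotenone+antimycin; glyco: baseline -> glucose -> oligomycin
  -> 2-DG) with three measurement points per phase.

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import ExpressionCohort

__all__ = [
    "CohortSpec",
    "PlantedTruth",
    "MitoProfile",
    "GlycoProfile",
    "generate_multi_cohort",
    "generate_survival_cohort",
    "generate_plate_traces",
    "default_gene_universe",
]

FOLLOW_UP_MONTHS = 60.0
POINTS_PER_PHASE = 3

MITO_PHASES = ("baseline", "post_oligomycin", "post_uncoupler", "post_rotAA")
GLYCO_PHASES = ("baseline", "post_glucose", "post_oligomycin", "post_2DG")


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort."""

    cohort_id: str
    n_genes: int = 6000
    n_tumor: int = 50
    n_normal: int = 30
    baseline_mean: float = 8.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need n_tumor >= 2 and n_normal >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth: which genes are altered, how strongly, how consistently.

    ``directions`` maps gene id -> 'up' | 'down'; unlisted genes are null.
    ``penetrance`` is the per-cohort probability that a planted gene carries
    its effect in that cohort.
    """

    directions: dict
    effect_size: float = 3.0
    penetrance: float = 1.0

    def __post_init__(self):
        if self.directions and self.effect_size <= 0:
            raise ValueError("effect_size must be > 0 for non-null genes")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        bad = set(self.directions.values()) - {"up", "down"}
        if bad:
            raise ValueError(f"unknown directions {bad}")


def default_gene_universe(n_genes: int) -> list:
    return [f"G{i:05d}" for i in range(n_genes)]


def generate_multi_cohort(spec_list, truth: PlantedTruth, metabolic_ids):
    """Generate one ExpressionCohort per spec plus a truth record.

    All specs must share the same gene universe size; ``metabolic_ids`` must
    be a subset of the universe, as must every planted gene.  Planted genes
    shift the tumor-group mean by +/- effect_size in a Bernoulli(penetrance)
    subset of cohorts.  Returns (cohorts, truth_record) where the record
    lists the planted carriers per cohort.
    """
    spec_list = list(spec_list)
    if not spec_list:
        raise ValueError("empty spec list")
    n_genes = spec_list[0].n_genes
    if any(s.n_genes != n_genes for s in spec_list):
        raise ValueError("all cohorts must share the same gene universe")
    genes = default_gene_universe(n_genes)
    universe = set(genes)
    missing = set(truth.directions) - universe
    if missing:
        raise ValueError(f"planted genes absent from the universe: {sorted(missing)[:5]}")
    missing = set(metabolic_ids) - universe
    if missing:
        raise ValueError(f"metabolic ids absent from the universe: {sorted(missing)[:5]}")

    sign = np.zeros(n_genes)
    for i, g in enumerate(genes):
        d = truth.directions.get(g)
        if d is not None:
            sign[i] = 1.0 if d == "up" else -1.0

    cohorts, record = [], {"effect_size": truth.effect_size,
                           "penetrance": truth.penetrance,
                           "directions": dict(truth.directions),
                           "carriers": {}}
    for spec in spec_list:
        rng = np.random.default_rng(spec.seed)
        # per-gene baselines vary around the cohort baseline (platform-like offsets)
        base = rng.normal(spec.baseline_mean, 1.0, size=n_genes)
        carried = rng.random(n_genes) < truth.penetrance
        effect = sign * truth.effect_size * carried
        n = spec.n_tumor + spec.n_normal
        values = base[:, None] + rng.normal(0.0, spec.noise_sd, size=(n_genes, n))
        values[:, : spec.n_tumor] += effect[:, None]
        group = ["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal
        samples = [f"{spec.cohort_id}_T{i:03d}" for i in range(spec.n_tumor)] + \
                  [f"{spec.cohort_id}_N{i:03d}" for i in range(spec.n_normal)]
        cohorts.append(ExpressionCohort(spec.cohort_id, genes, samples, values, group))
        record["carriers"][spec.cohort_id] = sorted(
            g for g, s, c in zip(genes, sign, carried) if s != 0 and c
        )
    return cohorts, record


def generate_survival_cohort(n: int, beta: float, censor_rate: float, seed: int,
                             baseline_rate: float = 0.02,
                             horizon: float = FOLLOW_UP_MONTHS) -> pd.DataFrame:
    """Exponential proportional-hazards survival cohort.

    Each patient gets expression x ~ N(0, 1) and an event time from
    Exp(rate = baseline_rate * exp(beta * x)) (months).  A Bernoulli
    (censor_rate) fraction is additionally censored at a Uniform(0, horizon)
    time; everyone is administratively censored at the follow-up horizon.
    Columns: id, time_months, event, expression.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=n)
    rate = baseline_rate * np.exp(beta * x)
    t_event = rng.exponential(1.0 / rate)
    c_time = np.where(rng.random(n) < censor_rate,
                      rng.uniform(0.0, horizon, size=n), np.inf)
    c_time = np.minimum(c_time, horizon)
    time = np.minimum(t_event, c_time)
    event = (t_event <= c_time).astype(int)
    # product-limit conventions need strictly positive times
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({
        "id": [f"P{i:04d}" for i in range(n)],
        "time_months": time,
        "event": event,
        "expression": x,
    })


@dataclass(frozen=True)
class MitoProfile:
    """Noiseless OCR plateaus (pmol O2/min) of a mitochondrial stress test."""

    basal: float = 100.0
    post_oligomycin: float = 40.0
    post_uncoupler: float = 180.0
    post_rotAA: float = 20.0
    ecar: float = 30.0  # constant ECAR carried alongside (mpH/min)

    def plateaus(self):
        return dict(zip(MITO_PHASES, (self.basal, self.post_oligomycin,
                                      self.post_uncoupler, self.post_rotAA)))

    def __post_init__(self):
        if min(self.basal, self.post_oligomycin, self.post_uncoupler,
               self.post_rotAA, self.ecar) < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class GlycoProfile:
    """Noiseless ECAR plateaus (mpH/min) of a glycolysis stress test."""

    baseline: float = 10.0
    post_glucose: float = 60.0
    post_oligomycin: float = 90.0
    post_2DG: float = 12.0
    ocr: float = 50.0  # constant OCR carried alongside (pmol O2/min)

    def plateaus(self):
        return dict(zip(GLYCO_PHASES, (self.baseline, self.post_glucose,
                                       self.post_oligomycin, self.post_2DG)))

    def __post_init__(self):
        if min(self.baseline, self.post_glucose, self.post_oligomycin,
               self.post_2DG, self.ocr) < 0:
            raise ValueError("rates must be non-negative")


def generate_plate_traces(seed: int, mito: MitoProfile | None = None,
                          glyco: GlycoProfile | None = None,
                          n_wells: int = 5, noise_sd: float = 0.0,
                          points_per_phase: int = POINTS_PER_PHASE) -> pd.DataFrame:
    """Plate-format stress-test traces with phase labels.

    Returns a long table (well, assay, phase, timepoint, OCR, ECAR); with
    noise_sd = 0 the measurements equal the profile plateaus exactly.
    Negative noisy draws are clipped at 0 (rates are physical).
    """
    mito = mito or MitoProfile()
    glyco = glyco or GlycoProfile()
    rng = np.random.default_rng(seed)
    rows = []
    for well in range(n_wells):
        tp = 0
        for phase, ocr in mito.plateaus().items():
            for _ in range(points_per_phase):
                rows.append((f"W{well:02d}", "mito", phase, tp,
                             ocr + rng.normal(0, noise_sd) if noise_sd else ocr,
                             mito.ecar + rng.normal(0, noise_sd) if noise_sd else mito.ecar))
                tp += 1
        tp = 0
        for phase, ecar in glyco.plateaus().items():
            for _ in range(points_per_phase):
                rows.append((f"W{well:02d}", "glyco", phase, tp,
                             glyco.ocr + rng.normal(0, noise_sd) if noise_sd else glyco.ocr,
                             ecar + rng.normal(0, noise_sd) if noise_sd else ecar))
                tp += 1
    df = pd.DataFrame(rows, columns=["well", "assay", "phase", "timepoint", "OCR", "ECAR"])
    df[["OCR", "ECAR"]] = df[["OCR", "ECAR"]].clip(lower=0.0)
    return df
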