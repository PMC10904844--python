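"""Cross-cohort consensus calling of tumor-altered metabolic genes.

The procedure, per cohort: (1) keep DE-gate-passing genes; (2) restrict to a
metabolism-annotated gene list; (3) derive an adaptive cutoff as the mean
absolute log2FC of the cohort's gate-passing genes -- this excludes probes
with very small expression changes; (4) call a gene up-regulated when its
log2FC is at or above +cutoff, down-regulated at or below -cutoff, else ns.
Across cohorts a gene is *consistently altered* when it falls exclusively in
the up- (or exclusively in the down-) regulated category in at least
``min_datasets`` of ``n_datasets`` cohorts (default 8 of 10).

The adaptive cutoff is computed over all gate-passing genes of the cohort
before metabolic restriction by default; ``over_metabolic_only=True``
computes it after restriction instead.  The signed mean would be near zero
and unusable as a two-sided threshold, so "average logFC" is taken on
absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetabolicGeneSet",
    "restrict_to_metabolic",
    "adaptive_cutoff",
    "classify_direction",
    "consensus_vote",
    "consensus_pipeline",
    "false_call_bound",
]


@dataclass(frozen=True)
class MetabolicGeneSet:
    gene_ids: frozenset
    source_label: str = "metabolic"

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError("metabolic gene set is empty")

    @classmethod
    def from_file(cls, path, source_label: str | None = None) -> "MetabolicGeneSet":
        with open(path) as fh:
            ids = frozenset(line.strip() for line in fh if line.strip())
        return cls(ids, source_label or str(path))


def restrict_to_metabolic(table: pd.DataFrame, genes: MetabolicGeneSet) -> pd.DataFrame:
    """Keep only gate-passing rows whose gene id is in the metabolic set (order preserved)."""
    mask = table["passes_gate"] & table.index.isin(genes.gene_ids)
    out = table.loc[mask].copy()
    out.attrs = dict(table.attrs)
    return out


def adaptive_cutoff(table: pd.DataFrame, over: str = "all") -> float:
    """Per-cohort cutoff: mean |log2FC| used as the up/down reference threshold.

    ``over='all'`` (default) averages over every gene of the cohort's DE
    output, giving a small threshold whose role is to exclude probes with
    very small expression changes; ``over='gated'`` averages over the
    DE-gate-passing genes only.  The default follows the reference-mean
    reading: a threshold computed from the gate-passing genes alone would sit
    at the typical DE effect size and discard roughly half of them, which is
    incompatible with its stated small-change-exclusion role.
    """
    if over not in ("all", "gated"):
        raise ValueError(f"unknown cutoff base {over!r}")
    lfc = table.loc[table["passes_gate"], "log2fc"] if over == "gated" else table["log2fc"]
    if lfc.empty:
        cohort = table.attrs.get("cohort_id", "<unknown>")
        raise ValueError(f"no DEGs; cutoff undefined for cohort {cohort}")
    return float(lfc.abs().mean())


def classify_direction(table: pd.DataFrame, cutoff: float) -> pd.Series:
    """Direction per gene: 'up' iff log2FC >= +cutoff, 'down' iff <= -cutoff, else 'ns'."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lfc = table["log2fc"]
    direction = pd.Series("ns", index=table.index, name="direction")
    direction[lfc >= cutoff] = "up"
    direction[lfc <= -cutoff] = "down"
    return direction


def consensus_vote(calls: pd.DataFrame, n_datasets: int = 10,
                   min_datasets: int = 8) -> pd.DataFrame:
    """Vote across cohorts; genes absent from a cohort's calls count as ns.

    ``calls``: genes x cohorts frame of {'up','down','ns'} (NaN treated as ns).
    A gene is consistent_up iff n_up >= min_datasets and n_down == 0
    (exclusivity), symmetrically for consistent_down.
    """
    if min_datasets > n_datasets:
        raise ValueError(f"min_datasets ({min_datasets}) > n_datasets ({n_datasets})")
    if calls.shape[1] > n_datasets:
        raise ValueError(f"{calls.shape[1]} cohorts exceed the design value n_datasets={n_datasets}")
    filled = calls.fillna("ns")
    n_up = (filled == "up").sum(axis=1)
    n_down = (filled == "down").sum(axis=1)
    status = pd.Series("not_consistent", index=calls.index, name="status")
    status[(n_up >= min_datasets) & (n_down == 0)] = "consistent_up"
    status[(n_down >= min_datasets) & (n_up == 0)] = "consistent_down"
    out = filled.copy()
    out["n_up"] = n_up
    out["n_down"] = n_down
    out["status"] = status
    return out


def consensus_pipeline(gated_tables: dict, genes: MetabolicGeneSet,
                       n_datasets: int = 10, min_datasets: int = 8,
                       cutoff_over: str = "all",
                       cutoff_over_metabolic_only: bool = False) -> pd.DataFrame:
    """Full cross-cohort procedure from gated DE tables to consensus calls.

    ``gated_tables`` maps cohort id -> gated DE table (apply_de_gate output;
    full table with the passes_gate flag).  The adaptive cutoff is computed
    per cohort before metabolic restriction by default;
    ``cutoff_over_metabolic_only=True`` computes it after restriction, and
    ``cutoff_over`` selects the averaging base (see :func:`adaptive_cutoff`).
    """
    directions = {}
    for cid, table in gated_tables.items():
        restricted = restrict_to_metabolic(table, genes)
        cut = adaptive_cutoff(restricted if cutoff_over_metabolic_only else table,
                              over=cutoff_over)
        directions[cid] = classify_direction(restricted, cut)
    all_genes = sorted(set().union(*(d.index for d in directions.values())))
    calls = pd.DataFrame("ns", index=pd.Index(all_genes, name="gene"),
                         columns=list(gated_tables))
    for cid, d in directions.items():
        calls.loc[d.index, cid] = np.asarray(d)
    return consensus_vote(calls, n_datasets=n_datasets, min_datasets=min_datasets)


def false_call_bound(n_null: int, n_datasets: int = 10, min_datasets: int = 8,
                     p_call_per_direction: float = 0.5) -> float:
    """Brute-force binomial bound on the expected number of false consistent calls.

    A null gene is falsely consistent only if it is called in one fixed
    direction in >= min_datasets independent cohorts.  With per-cohort,
    per-direction call probability q the per-gene probability is bounded by
    2 * P[Binom(n_datasets, q) >= min_datasets], evaluated by enumeration.
    Under the raw-P DE gate, q <= p_max / 2 for a null gene (each direction
    is equally likely), so q = 0.0005 is the bound matching the default gate;
    q = 0.5 is the assumption-free worst case.
    """
    from math import comb

    q = p_call_per_direction
    tail = sum(comb(n_datasets, k) * q ** k * (1 - q) ** (n_datasets - k)
               for k in range(min_datasets, n_datasets + 1))
    return 2.0 * tail * n_null
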