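"""Per-cohort two-group differential expression on log2 expression matrices.

The primary filter used downstream is the raw-P gate: a gene is a DE
candidate when P < 0.001 and |log2FC| > 1.5.  log2FC is the difference of
group means on already-log2 data (tumor minus normal); P comes from a
two-sided unequal-variance (Welch) t test.  No cross-gene shrinkage and no
multiple-testing correction are applied at this step; the downstream
cross-cohort consensus is threshold-based, not rank-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ExpressionCohort", "differential_expression", "apply_de_gate"]

P_MAX_DEFAULT = 0.001
LFC_MIN_DEFAULT = 1.5


@dataclass
class ExpressionCohort:
    """One cohort's log2 expression matrix with tumor/normal sample labels.

    ``values`` is genes x samples; ``group`` holds one label per sample,
    either "tumor" or "normal".
    """

    cohort_id: str
    gene_ids: list = field(repr=False)
    sample_ids: list = field(repr=False)
    values: np.ndarray = field(repr=False)
    group: list = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"{self.cohort_id}: matrix shape {self.values.shape} != "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(self.group) != len(self.sample_ids):
            raise ValueError(f"{self.cohort_id}: one group label per sample required")
        bad = set(self.group) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"{self.cohort_id}: unknown group labels {bad}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.cohort_id}: non-finite expression values")
        self._tumor = np.array([g == "tumor" for g in self.group])
        if self._tumor.sum() < 2 or (~self._tumor).sum() < 2:
            raise ValueError(f"{self.cohort_id}: need >= 2 samples per group")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self._tumor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def differential_expression(cohort: ExpressionCohort) -> pd.DataFrame:
    """Welch-t differential expression for every gene of one cohort.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (tumor mean
    minus normal mean), ``p_value`` and ``passes_gate`` (filled by
    :func:`apply_de_gate`; ``False`` here).

    Degenerate genes follow a documented convention: zero variance in both
    groups with equal means gives p = 1; zero variance with unequal means
    gives p = 0.
    """
    t_mask = cohort.tumor_mask
    tumor = cohort.values[:, t_mask]
    normal = cohort.values[:, ~t_mask]
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    import warnings
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance genes trip scipy's catastrophic-cancellation warning;
        # they are handled by the documented convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    p[degenerate & (log2fc == 0.0)] = 1.0
    p[degenerate & (log2fc != 0.0)] = 0.0
    table = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "passes_gate": False},
        index=pd.Index(cohort.gene_ids, name="gene"),
    )
    table.attrs["cohort_id"] = cohort.cohort_id
    return table


def apply_de_gate(table: pd.DataFrame, p_max: float = P_MAX_DEFAULT,
                  lfc_min: float = LFC_MIN_DEFAULT, absolute: bool = True) -> pd.DataFrame:
    """Mark genes passing the DE gate: p < p_max and |log2FC| > lfc_min.

    With ``absolute=False`` only up-regulation (log2FC > lfc_min) passes,
    preserving the literal one-sided reading of the threshold.
    """
    if p_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    lfc = out["log2fc"].abs() if absolute else out["log2fc"]
    out["passes_gate"] = (out["p_value"] < p_max) & (lfc > lfc_min)
    out.attrs = dict(table.attrs)
    return out
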