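"""Extracellular-flux stress-test metrics and ATP-rate partitioning.

Mito stress test (OCR, pmol O2/min): basal = baseline - post_rotAA;
ATP-linked = baseline - post_oligomycin; proton leak = post_oligomycin -
post_rotAA; maximal = post_uncoupler - post_rotAA; spare = maximal - basal.
Glycolysis stress test (ECAR, mpH/min): glycolysis = post_glucose -
baseline; capacity = post_oligomycin - baseline; reserve = capacity -
glycolysis.  Negative differences are clipped to 0 with a warning.

ATP partitioning follows the extracellular-flux accounting of Mookerjee &
Brand: glycolytic ATP comes from the lactate-linked proton efflux (ECAR
scaled by the medium buffering factor, corrected for respiratory CO2
acidification), oxidative ATP from the ATP-linked OCR via the P/O ratio
(2 oxygen atoms per O2).  The stoichiometric constants are configuration
values; the defaults are taken from that methodology but every check on
this module is algebraic/property-based, not tied to them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .synthetic import MITO_PHASES, GLYCO_PHASES

__all__ = ["StressTrace", "AtpConstants", "AtpPartition",
           "mito_metrics", "glyco_metrics", "atp_partition",
           "summarize_trace"]


@dataclass
class StressTrace:
    """Per-phase OCR/ECAR summaries of one assay."""

    assay: str                      # 'mito' | 'glyco'
    ocr: dict                       # phase -> summary OCR
    ecar: dict                      # phase -> summary ECAR

    def __post_init__(self):
        phases = {"mito": MITO_PHASES, "glyco": GLYCO_PHASES}.get(self.assay)
        if phases is None:
            raise ValueError(f"unknown assay {self.assay!r}")
        for d in (self.ocr, self.ecar):
            missing = set(phases) - set(d)
            if missing:
                raise ValueError(f"{self.assay} trace missing phase(s): {sorted(missing)}")
            if any(v < 0 for v in d.values()):
                raise ValueError("rates must be non-negative")


def summarize_trace(traces: pd.DataFrame, assay: str) -> StressTrace:
    """Collapse a long trace table to per-phase means (over wells and points)."""
    sub = traces[traces["assay"] == assay]
    if sub.empty:
        raise ValueError(f"no rows for assay {assay!r}")
    g = sub.groupby("phase")
    return StressTrace(assay, g["OCR"].mean().to_dict(), g["ECAR"].mean().to_dict())


def _clip(name: str, value: float) -> float:
    if value < 0:
        warnings.warn(f"{name} was negative ({value:.3g}); clipped to 0", stacklevel=3)
        return 0.0
    return value


def mito_metrics(trace: StressTrace) -> dict:
    """Basal, ATP-linked, proton-leak, maximal and spare respiration.

    Non-mitochondrial OCR (the post rotenone+antimycin plateau) is
    subtracted where the definitions require it; basal = ATP-linked +
    proton leak by construction.
    """
    if trace.assay != "mito":
        raise ValueError("mito_metrics needs a mito-assay trace")
    o = trace.ocr
    m = {
        "basal": o["baseline"] - o["post_rotAA"],
        "atp_linked": o["baseline"] - o["post_oligomycin"],
        "proton_leak": o["post_oligomycin"] - o["post_rotAA"],
        "maximal": o["post_uncoupler"] - o["post_rotAA"],
    }
    m = {k: _clip(k, v) for k, v in m.items()}
    m["spare"] = _clip("spare", m["maximal"] - m["basal"])
    return m


def glyco_metrics(trace: StressTrace) -> dict:
    """Glycolysis, glycolytic capacity and glycolytic reserve from ECAR."""
    if trace.assay != "glyco":
        raise ValueError("glyco_metrics needs a glyco-assay trace")
    e = trace.ecar
    m = {
        "glycolysis": e["post_glucose"] - e["baseline"],
        "glycolytic_capacity": e["post_oligomycin"] - e["baseline"],
    }
    m = {k: _clip(k, v) for k, v in m.items()}
    m["glycolytic_reserve"] = _clip("glycolytic_reserve",
                                    m["glycolytic_capacity"] - m["glycolysis"])
    return m


@dataclass(frozen=True)
class AtpConstants:
    """Stoichiometric constants of the ECAR/OCR -> ATP conversion.

    atp_per_lactate: ATP per lactate-linked proton (glycolytic yield), ~1.
    p_o_ratio: ATP per oxygen atom at the ATP-linked OCR (max P/O ~ 2.486).
    buffering_factor: pmol H+ per mpH per min; instrument/medium dependent.
    co2_acidification_correction: H+ per ATP-linked O2 consumed, accounting
    for respiratory CO2 hydration acidifying the medium.
    """

    atp_per_lactate: float = 1.0
    p_o_ratio: float = 2.486
    buffering_factor: float = 1.0
    co2_acidification_correction: float = 0.0

    def __post_init__(self):
        if min(self.atp_per_lactate, self.p_o_ratio, self.buffering_factor) <= 0:
            raise ValueError("stoichiometric constants must be positive")
        if self.co2_acidification_correction < 0:
            raise ValueError("co2_acidification_correction must be >= 0")


@dataclass
class AtpPartition:
    J_glyc: float
    J_ox: float

    def __post_init__(self):
        if self.J_glyc < 0 or self.J_ox < 0:
            raise ValueError("ATP rates must be non-negative")

    @property
    def total(self) -> float:
        return self.J_glyc + self.J_ox

    @property
    def fraction_glyc(self) -> float:
        return self.J_glyc / self.total if self.total > 0 else 0.0

    def to_dict(self) -> dict:
        return {"J_glyc": self.J_glyc, "J_ox": self.J_ox,
                "J_total": self.total, "fraction_glyc": self.fraction_glyc}


def atp_partition(atp_linked_ocr: float, glyco_ecar: float,
                  constants: AtpConstants | None = None) -> AtpPartition:
    """Partition ATP production into glycolytic and oxidative rates.

    J_glyc = max(0, ECAR * buffering_factor
                    - co2_correction * ATP-linked OCR) * atp_per_lactate
    J_ox   = 2 * p_o_ratio * ATP-linked OCR     (two O atoms per O2)

    A negative CO2-corrected proton flux floors J_glyc at 0 with a warning.
    """
    c = constants or AtpConstants()
    if atp_linked_ocr < 0 or glyco_ecar < 0:
        raise ValueError("rates must be non-negative")
    h_flux = glyco_ecar * c.buffering_factor \
        - c.co2_acidification_correction * atp_linked_ocr
    if h_flux < 0:
        warnings.warn(f"CO2-corrected proton flux negative ({h_flux:.3g}); "
                      "glycolytic ATP rate floored at 0", stacklevel=2)
        h_flux = 0.0
    return AtpPartition(J_glyc=h_flux * c.atp_per_lactate,
                        J_ox=2.0 * c.p_o_ratio * atp_linked_ocr)
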