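"""Atom-mapped 13C label-propagation engine for central carbon metabolism.

The engine tracks the full positional labeling state of one molecule at a
time: a *pattern distribution* maps tuples of per-carbon label flags
(0 = 12C, 1 = 13C) to probabilities.  Reactions are carbon-level bijections
from substrate slots to product slots, so applying one is a deterministic
permutation of the joint substrate pattern; condensations (citrate synthase,
pyruvate carboxylase, reverse IDH) combine independent substrate
distributions, which on the mass level is a convolution of their
isotopologue distributions.

Semantics are single-pass ("first turn"): a route applies each reaction once
to the tracer, with every co-substrate drawn either from an explicitly
unlabeled pool or from a previously computed intermediate.  This matches how
labeling predictions such as "m+2 citrate via PDH" or "m+5 citrate via
reductive carboxylation" are customarily read off a tracer diagram; it is
not a steady-state flux model.

Succinate and fumarate are 2-fold symmetric: the molecular orientation is
scrambled 50/50 when they are produced.  Scrambling changes positional
patterns only -- the mass-shift distribution is permutation-invariant.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "AtomMappedReaction",
    "ReactionNetwork",
    "IsotopologueDistribution",
    "Route",
    "RouteStep",
    "build_default_network",
    "load_default_routes",
    "tracer_pattern",
    "propagate",
    "convolve",
    "mix",
    "unmix",
    "predict_named_routes",
]

NORM_TOL = 1e-9

#: Named tracers -> (metabolite, fully-labeled carbon count)
TRACERS = {
    "U-13C6-glucose": "glucose",
    "U-13C5-glutamine": "glutamine",
}

# A pattern distribution is a dict: tuple[int, ...] -> float.
PatternDist = dict


@dataclass(frozen=True)
class Metabolite:
    """A metabolite with a fixed carbon skeleton size (CO2 has 1)."""

    name: str
    n_carbons: int

    def __post_init__(self):
        if self.n_carbons < 1:
            raise ValueError(f"{self.name}: n_carbons must be >= 1")


@dataclass(frozen=True)
class AtomMappedReaction:
    """A reaction with a carbon-level bijection between substrates and products.

    Slots are 1-based and flattened over the substrate (resp. product) list
    in declared order.  ``mapping`` holds (substrate_slot, product_slot)
    pairs; carbon conservation (total substrate carbons == total product
    carbons, mapping a bijection over all slots) is checked at construction.
    """

    id: str
    substrates: tuple  # tuple[tuple[str, int], ...]
    products: tuple
    mapping: tuple  # tuple[tuple[int, int], ...]

    def __post_init__(self):
        n_sub = sum(n for _, n in self.substrates)
        n_prod = sum(n for _, n in self.products)
        if n_sub != n_prod:
            raise ValueError(
                f"reaction {self.id}: carbon conservation violated "
                f"({n_sub} substrate vs {n_prod} product carbons)"
            )
        src = sorted(s for s, _ in self.mapping)
        dst = sorted(d for _, d in self.mapping)
        if src != list(range(1, n_sub + 1)) or dst != list(range(1, n_prod + 1)):
            raise ValueError(f"reaction {self.id}: mapping is not a bijection over all carbon slots")

    @property
    def n_carbons(self) -> int:
        return sum(n for _, n in self.substrates)

    def product_slices(self):
        """Yield (name, start, stop) 0-based slot ranges for each product."""
        off = 0
        for name, n in self.products:
            yield name, off, off + n
            off += n


class ReactionNetwork:
    """A validated library of atom-mapped reactions."""

    def __init__(self, reactions: Iterable[AtomMappedReaction],
                 metabolites: Mapping[str, int],
                 symmetric: Iterable[str] = ()):
        self.reactions = {r.id: r for r in reactions}
        self.metabolites = {n: Metabolite(n, c) for n, c in metabolites.items()}
        self.symmetric = frozenset(symmetric)
        for rxn in self.reactions.values():
            for name, n in list(rxn.substrates) + list(rxn.products):
                met = self.metabolites.get(name)
                if met is None or met.n_carbons != n:
                    raise ValueError(
                        f"reaction {rxn.id}: {name} carbon count {n} disagrees "
                        f"with metabolite table"
                    )

    def __getitem__(self, rid: str) -> AtomMappedReaction:
        return self.reactions[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.reactions

    def apply(self, rxn_id: str, substrate_dists: Sequence[PatternDist],
              scramble: bool = True) -> list[PatternDist]:
        """Apply a reaction to independent substrate pattern distributions.

        Returns one pattern distribution per product.  Asserts label-count
        conservation on every joint assignment.
        """
        rxn = self[rxn_id]
        if len(substrate_dists) != len(rxn.substrates):
            raise ValueError(f"reaction {rxn_id}: expected {len(rxn.substrates)} substrate distributions")
        for (name, n), dist in zip(rxn.substrates, substrate_dists):
            for pat in dist:
                if len(pat) != n:
                    raise ValueError(f"reaction {rxn_id}: pattern of length {len(pat)} for {name} ({n} carbons)")
        perm = {s - 1: d - 1 for s, d in rxn.mapping}
        n_total = rxn.n_carbons
        out: list[PatternDist] = [dict() for _ in rxn.products]
        for joint in itertools.product(*(d.items() for d in substrate_dists)):
            flat = tuple(itertools.chain.from_iterable(pat for pat, _ in joint))
            p = 1.0
            for _, w in joint:
                p *= w
            if p == 0.0:
                continue
            prod_flat = [0] * n_total
            for s_idx, d_idx in perm.items():
                prod_flat[d_idx] = flat[s_idx]
            assert sum(prod_flat) == sum(flat), "label count not conserved"
            for i, (name, start, stop) in enumerate(rxn.product_slices()):
                pat = tuple(prod_flat[start:stop])
                if scramble and name in self.symmetric:
                    for half in (pat, pat[::-1]):
                        out[i][half] = out[i].get(half, 0.0) + p / 2.0
                else:
                    out[i][pat] = out[i].get(pat, 0.0) + p
        for dist in out:
            total = sum(dist.values())
            assert abs(total - 1.0) < NORM_TOL, "pattern distribution not normalized"
        return out


def _network_from_dict(doc: Mapping) -> ReactionNetwork:
    reactions = [
        AtomMappedReaction(
            id=r["id"],
            substrates=tuple((m, int(n)) for m, n in r["substrates"]),
            products=tuple((m, int(n)) for m, n in r["products"]),
            mapping=tuple((int(s), int(d)) for s, d in r["map"]),
        )
        for r in doc["reactions"]
    ]
    return ReactionNetwork(reactions, doc["metabolites"],
                           doc.get("symmetric_metabolites", ()))


def load_network(path) -> ReactionNetwork:
    """Load and validate an atom-mapped reaction network from JSON."""
    with open(path) as fh:
        return _network_from_dict(json.load(fh))


def build_default_network() -> ReactionNetwork:
    """The shipped central-carbon library: glycolysis, PDH/PC entry, first-turn
    oxidative TCA, reductive carboxylation, both PPP arms, glutaminolysis."""
    text = resources.files("hccmet.data").joinpath("network.json").read_text()
    return _network_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Isotopologue distributions

@dataclass
class IsotopologueDistribution:
    """Mass-shift fractions f(m+0) .. f(m+C) for one metabolite."""

    metabolite: str
    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1 or len(self.fractions) < 1:
            raise ValueError("fractions must be a 1-D vector")
        if np.any(self.fractions < -NORM_TOL):
            raise ValueError("negative isotopologue fraction")
        if abs(self.fractions.sum() - 1.0) > NORM_TOL:
            raise ValueError(f"{self.metabolite}: fractions sum to {self.fractions.sum()}, not 1")

    @classmethod
    def from_pattern_dist(cls, metabolite: str, dist: PatternDist,
                          n_carbons: int) -> "IsotopologueDistribution":
        frac = np.zeros(n_carbons + 1)
        for pat, p in dist.items():
            frac[sum(pat)] += p
        return cls(metabolite, frac)

    @property
    def mass_shift(self) -> int:
        """Mass shift of the most abundant isotopologue."""
        return int(np.argmax(self.fractions))

    def fraction(self, k: int) -> float:
        return float(self.fractions[k]) if 0 <= k < len(self.fractions) else 0.0

    def __eq__(self, other):
        return (isinstance(other, IsotopologueDistribution)
                and self.metabolite == other.metabolite
                and len(self.fractions) == len(other.fractions)
                and np.allclose(self.fractions, other.fractions, atol=NORM_TOL))


def convolve(d1: IsotopologueDistribution, d2: IsotopologueDistribution,
             metabolite: str | None = None) -> IsotopologueDistribution:
    """MID of a condensation product: f_out(m+k) = sum_j f1(m+j) f2(m+(k-j))."""
    out = np.convolve(d1.fractions, d2.fractions)
    name = metabolite or f"{d1.metabolite}+{d2.metabolite}"
    return IsotopologueDistribution(name, out / out.sum())


def mix(distributions: Sequence[IsotopologueDistribution],
        weights: Sequence[float]) -> IsotopologueDistribution:
    """Weighted mixture of MIDs over the same metabolite (weights sum to 1)."""
    if len(distributions) != len(weights):
        raise ValueError("length mismatch between distributions and weights")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > NORM_TOL:
        raise ValueError("mixture weights must sum to 1")
    size = max(len(d.fractions) for d in distributions)
    out = np.zeros(size)
    for d, wi in zip(distributions, w):
        out[: len(d.fractions)] += wi * d.fractions
    return IsotopologueDistribution(distributions[0].metabolite, out / out.sum())


def unmix(mixed: IsotopologueDistribution,
          basis: Sequence[IsotopologueDistribution]) -> np.ndarray:
    """Least-squares mixture weights of ``mixed`` over basis MIDs."""
    size = max(len(mixed.fractions), max(len(b.fractions) for b in basis))

    def pad(f):
        out = np.zeros(size)
        out[: len(f)] = f
        return out

    A = np.column_stack([pad(b.fractions) for b in basis])
    w, *_ = np.linalg.lstsq(A, pad(mixed.fractions), rcond=None)
    return w


# ---------------------------------------------------------------------------
# Routes

@dataclass
class RouteStep:
    reaction: str
    inputs: dict = field(default_factory=dict)   # substrate name -> carry|pool|saved:<name>
    product: str | None = None
    product_index: int = 0
    save_as: str | None = None


@dataclass
class Route:
    """Ordered reaction steps from a tracer entry to a terminal metabolite."""

    name: str
    tracer: object            # tracer name from TRACERS, or {"metabolite", "pattern"}
    steps: list
    label: str = ""

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Route":
        steps = [
            RouteStep(
                reaction=s["reaction"],
                inputs=dict(s.get("inputs", {})),
                product=s.get("product"),
                product_index=int(s.get("product_index", 0)),
                save_as=s.get("save_as"),
            )
            for s in doc["steps"]
        ]
        return cls(name=doc["name"], tracer=doc["tracer"], steps=steps,
                   label=doc.get("label", ""))


def load_routes(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    return {r["name"]: Route.from_dict(r) for r in doc["routes"]}


def load_default_routes() -> dict:
    """The shipped canonical routes (glycolysis, PDH/PC, TCA, PPP, glutaminolysis)."""
    text = resources.files("hccmet.data").joinpath("routes.json").read_text()
    doc = json.loads(text)
    return {r["name"]: Route.from_dict(r) for r in doc["routes"]}


def tracer_pattern(network: ReactionNetwork, tracer) -> tuple[str, PatternDist]:
    """Resolve a tracer declaration to (entry metabolite, pattern distribution).

    Accepts a named tracer (uniformly labeled) or an explicit
    ``{"metabolite": ..., "pattern": [0/1, ...]}`` declaration.
    """
    if isinstance(tracer, str):
        if tracer not in TRACERS:
            raise ValueError(f"unknown tracer {tracer!r}; known: {sorted(TRACERS)}")
        met = TRACERS[tracer]
        n = network.metabolites[met].n_carbons
        return met, {tuple([1] * n): 1.0}
    met = tracer["metabolite"]
    pat = tuple(int(x) for x in tracer["pattern"])
    n = network.metabolites[met].n_carbons
    if len(pat) != n:
        raise ValueError(f"tracer pattern length {len(pat)} != {met} carbons ({n})")
    return met, {pat: 1.0}


def _unlabeled(network: ReactionNetwork, met: str) -> PatternDist:
    n = network.metabolites[met].n_carbons
    return {tuple([0] * n): 1.0}


def propagate(network: ReactionNetwork, route: Route,
              scramble: bool = True) -> IsotopologueDistribution:
    """Propagate a tracer along a route; return the terminal metabolite's MID.

    Deterministic; every reaction application asserts carbon conservation and
    normalization.  Co-substrates default to unlabeled pools.
    """
    entry_met, carry = tracer_pattern(network, route.tracer)
    carry_met = entry_met
    saved: dict[str, tuple[str, PatternDist]] = {}
    for step in route.steps:
        if step.reaction not in network:
            raise ValueError(f"route {route.name}: unknown reaction {step.reaction!r}")
        rxn = network[step.reaction]
        dists = []
        carry_used = False
        for sub_name, n in rxn.substrates:
            src = step.inputs.get(sub_name)
            if src is None:
                # single-substrate steps implicitly consume the carried molecule
                src = "carry" if len(rxn.substrates) == 1 else "pool"
            if src == "carry":
                if carry_met != sub_name:
                    raise ValueError(
                        f"route {route.name}, step {step.reaction}: carried metabolite "
                        f"is {carry_met}, but substrate {sub_name} requests it"
                    )
                dists.append(carry)
                carry_used = True
            elif src == "pool":
                dists.append(_unlabeled(network, sub_name))
            elif isinstance(src, str) and src.startswith("saved:"):
                key = src.split(":", 1)[1]
                if key not in saved:
                    raise ValueError(f"route {route.name}, step {step.reaction}: no saved intermediate {key!r}")
                smet, sdist = saved[key]
                if smet != sub_name:
                    raise ValueError(f"route {route.name}: saved {key!r} is {smet}, not {sub_name}")
                dists.append(sdist)
            else:
                raise ValueError(f"route {route.name}: bad input source {src!r}")
        del carry_used
        products = network.apply(step.reaction, dists, scramble=scramble)
        target = step.product or rxn.products[0][0]
        idx = [i for i, (name, _) in enumerate(rxn.products) if name == target]
        if not idx:
            raise ValueError(f"route {route.name}, step {step.reaction}: no product {target!r}")
        carry = products[idx[step.product_index]]
        carry_met = target
        if step.save_as:
            saved[step.save_as] = (carry_met, carry)
    n = network.metabolites[carry_met].n_carbons
    return IsotopologueDistribution.from_pattern_dist(carry_met, carry, n)


# ---------------------------------------------------------------------------
# Named predictions

#: route name -> biological interpretation used in reports
_ROUTE_TRACER_GROUP = {
    "U-13C6-glucose": [
        "glucose_to_lactate", "glucose_to_alanine", "glucose_pdh_citrate",
        "glucose_pc_oaa", "glucose_pdh_pc_citrate", "glucose_oxidative_tca_succinate",
        "glucose_oxppp_6pg", "glucose_oxppp_r5p", "g3p_nonoxppp_r5p",
    ],
    "U-13C5-glutamine": [
        "gln_to_glutamate", "gln_oxidative_succinate", "gln_oxidative_malate",
        "gln_oxidative_aspartate", "gln_oxidative_citrate",
        "gln_reductive_citrate", "gln_reductive_aspartate",
    ],
}


def predict_named_routes(tracer: str, network: ReactionNetwork | None = None):
    """Expected m+k for every canonical route of a tracer.

    Returns a list of dicts (metabolite, route, label, mass_shift, fraction)
    obtained by running :func:`propagate` on each shipped route.  The
    non-oxidative PPP route is grouped under the glucose tracer because its
    m+3 G3P entry derives from labeled glucose.
    """
    if tracer not in _ROUTE_TRACER_GROUP:
        raise ValueError(f"unknown tracer {tracer!r}; known: {sorted(_ROUTE_TRACER_GROUP)}")
    network = network or build_default_network()
    routes = load_default_routes()
    rows = []
    for rname in _ROUTE_TRACER_GROUP[tracer]:
        route = routes[rname]
        mid = propagate(network, route)
        rows.append({
            "metabolite": mid.metabolite,
            "route": rname,
            "label": route.label,
            "mass_shift": mid.mass_shift,
            "fraction": mid.fraction(mid.mass_shift),
        })
    return rows
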