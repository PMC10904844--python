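"""Atom-mapped label propagation: conservation, convolution, route predictions.

The independent oracle is a seeded single-molecule simulator: it pushes one
molecule at a time through a route, choosing symmetric orientations and
co-substrate molecules at random, and tallies terminal label counts.  It
shares no code with the exact enumeration engine.
"""

import zlib

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hccmet.tracer import (AtomMappedReaction, IsotopologueDistribution, Route,
                           build_default_network, convolve, load_default_routes,
                           mix, predict_named_routes, propagate, tracer_pattern,
                           unmix)

# Expected terminal mass shifts of every shipped route (the study's stated
# labeling outcomes: glycolysis m+3, PDH m+2 / PC m+3 / combined m+5 citrate,
# oxidative glutamine m+4 species, reductive m+5 citrate and m+3 aspartate,
# oxidative PPP m+6/m+5, non-oxidative PPP m+3).
EXPECTED_MASS_SHIFTS = {
    "glucose_to_lactate": ("lactate", 3),
    "glucose_to_alanine": ("alanine", 3),
    "glucose_pdh_citrate": ("citrate", 2),
    "glucose_pc_oaa": ("OAA", 3),
    "glucose_pdh_pc_citrate": ("citrate", 5),
    "glucose_oxidative_tca_succinate": ("succinate", 2),
    "glucose_oxppp_6pg": ("6PG", 6),
    "glucose_oxppp_r5p": ("R5P", 5),
    "g3p_nonoxppp_r5p": ("R5P", 3),
    "gln_to_glutamate": ("glutamate", 5),
    "gln_oxidative_succinate": ("succinate", 4),
    "gln_oxidative_malate": ("malate", 4),
    "gln_oxidative_aspartate": ("aspartate", 4),
    "gln_oxidative_citrate": ("citrate", 4),
    "gln_reductive_citrate": ("citrate", 5),
    "gln_reductive_aspartate": ("aspartate", 3),
}


class TestNetwork:
    def test_all_reactions_conserve_carbon_and_are_bijections(self, network):
        # construction already validates; re-assert the invariant explicitly
        for rxn in network.reactions.values():
            n_sub = sum(n for _, n in rxn.substrates)
            n_prod = sum(n for _, n in rxn.products)
            assert n_sub == n_prod
            assert sorted(s for s, _ in rxn.mapping) == list(range(1, n_sub + 1))
            assert sorted(d for _, d in rxn.mapping) == list(range(1, n_prod + 1))

    def test_conservation_violation_rejected_at_load(self):
        with pytest.raises(ValueError, match="carbon conservation"):
            AtomMappedReaction("bad", (("pyruvate", 3),), (("CO2", 1),), ((1, 1),))
        with pytest.raises(ValueError, match="bijection"):
            AtomMappedReaction("bad2", (("pyruvate", 3),), (("lactate", 3),),
                               ((1, 1), (2, 1), (3, 3)))

    def test_pdh_releases_c1(self, network):
        accoa, co2 = network.apply("PDH", [{(1, 1, 1): 1.0}])
        assert accoa == {(1, 1): 1.0} and co2 == {(1,): 1.0}
        # positionally: labeled C1 only -> unlabeled AcCoA, labeled CO2
        accoa, co2 = network.apply("PDH", [{(1, 0, 0): 1.0}])
        assert accoa == {(0, 0): 1.0} and co2 == {(1,): 1.0}

    def test_pc_adds_unlabeled_co2(self, network):
        oaa, = network.apply("PC", [{(1, 1, 1): 1.0}, {(0,): 1.0}])
        assert oaa == {(1, 1, 1, 0): 1.0}


class TestPropagate:
    @pytest.mark.parametrize("route_name", sorted(EXPECTED_MASS_SHIFTS))
    def test_route_terminal_mass_shift(self, network, routes, route_name):
        met, k = EXPECTED_MASS_SHIFTS[route_name]
        mid = propagate(network, routes[route_name])
        assert mid.metabolite == met
        assert mid.mass_shift == k
        assert mid.fraction(k) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("route_name", sorted(EXPECTED_MASS_SHIFTS))
    def test_unlabeled_tracer_stays_m0(self, network, routes, route_name):
        route = routes[route_name]
        met, pat = tracer_pattern(network, route.tracer)
        unlabeled = Route(route.name, {"metabolite": met,
                                       "pattern": [0] * len(next(iter(pat)))},
                          route.steps)
        mid = propagate(network, unlabeled)
        assert mid.mass_shift == 0 and mid.fraction(0) == pytest.approx(1.0)

    @pytest.mark.parametrize("route_name", sorted(EXPECTED_MASS_SHIFTS))
    def test_normalization_invariant(self, network, routes, route_name):
        mid = propagate(network, routes[route_name])
        assert abs(mid.fractions.sum() - 1.0) < 1e-9
        assert (mid.fractions >= -1e-12).all()

    def test_unknown_reaction_named_in_error(self, network):
        route = Route("r", "U-13C6-glucose", [type("S", (), {
            "reaction": "NOPE", "inputs": {}, "product": None,
            "product_index": 0, "save_as": None})()])
        with pytest.raises(ValueError, match="NOPE"):
            propagate(network, route)

    def test_carry_mismatch_names_step(self, network, routes):
        steps = routes["gln_to_glutamate"].steps
        route = Route("bad", "U-13C6-glucose", steps)
        with pytest.raises(ValueError, match="GLS"):
            propagate(network, route)

    def test_scrambling_changes_positions_not_mass(self, network):
        """Succinate 2-fold symmetry permutes positional patterns but leaves
        the mass-shift distribution unchanged."""
        pat = {(1, 1, 0, 0, 0): 1.0}  # aKG labeled at C1,C2
        on, _ = network.apply("OGDH", [pat], scramble=True)
        off, _ = network.apply("OGDH", [pat], scramble=False)
        assert on != off  # positional patterns differ
        mid_on = IsotopologueDistribution.from_pattern_dist("succinate", on, 4)
        mid_off = IsotopologueDistribution.from_pattern_dist("succinate", off, 4)
        np.testing.assert_allclose(mid_on.fractions, mid_off.fractions, atol=1e-12)


def _simulate_route(network, route, rng, n_molecules=2000):
    """Single-molecule Monte-Carlo oracle for a route's terminal MID."""
    entry_met, entry = tracer_pattern(network, route.tracer)
    entry_pats = list(entry)
    entry_p = np.array([entry[p] for p in entry_pats])
    counts = np.zeros(network.metabolites[route.steps[-1].product or
                                          network[route.steps[-1].reaction].products[0][0]].n_carbons + 1)
    for _ in range(n_molecules):
        carry = entry_pats[rng.choice(len(entry_pats), p=entry_p)]
        carry_met = entry_met
        saved = {}
        for step in route.steps:
            rxn = network[step.reaction]
            flat = []
            for name, n in rxn.substrates:
                src = step.inputs.get(name) or ("carry" if len(rxn.substrates) == 1 else "pool")
                if src == "carry":
                    mol = carry
                elif src == "pool":
                    mol = (0,) * n
                else:
                    mol = saved[src.split(":", 1)[1]]
                flat.extend(mol)
            prod = [0] * len(flat)
            for s, d in rxn.mapping:
                prod[d - 1] = flat[s - 1]
            off, chosen = 0, None
            target = step.product or rxn.products[0][0]
            seen = 0
            for name, n in rxn.products:
                piece = tuple(prod[off: off + n])
                if name in network.symmetric and rng.random() < 0.5:
                    piece = piece[::-1]
                if name == target:
                    if seen == step.product_index:
                        chosen = piece
                    seen += 1
                off += n
            carry, carry_met = chosen, target
            if step.save_as:
                saved[step.save_as] = carry
        counts[sum(carry)] += 1
    return counts / n_molecules


@pytest.mark.parametrize("route_name", sorted(EXPECTED_MASS_SHIFTS))
def test_engine_matches_single_molecule_oracle(network, routes, route_name):
    rng = np.random.default_rng(zlib.crc32(route_name.encode()) % 2 ** 31)
    mid = propagate(network, routes[route_name])
    sim = _simulate_route(network, routes[route_name], rng)
    # 5 sigma Monte-Carlo band at n=2000 per isotopologue
    np.testing.assert_allclose(mid.fractions, sim[: len(mid.fractions)],
                               atol=5 * np.sqrt(0.25 / 2000) + 1e-9)


class TestConvolveMix:
    def test_convolution_examples(self):
        ac = IsotopologueDistribution("AcCoA", [0, 0, 1])
        oaa0 = IsotopologueDistribution("OAA", [1, 0, 0, 0, 0])
        oaa3 = IsotopologueDistribution("OAA", [0, 0, 0, 1, 0])
        assert convolve(ac, oaa0, "citrate").mass_shift == 2
        assert convolve(ac, oaa3, "citrate").mass_shift == 5

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=7))
    def test_m0_is_convolution_identity(self, raw):
        f = np.array(raw) / np.sum(raw)
        d = IsotopologueDistribution("x", f)
        ident = IsotopologueDistribution("e", [1.0])
        np.testing.assert_allclose(convolve(d, ident).fractions[: len(f)], f, atol=1e-12)

    def test_mix_weighted_sum_and_identity(self):
        m4 = IsotopologueDistribution("citrate", [0, 0, 0, 0, 1, 0, 0])
        m5 = IsotopologueDistribution("citrate", [0, 0, 0, 0, 0, 1, 0])
        half = mix([m4, m5], [0.5, 0.5])
        assert half.fraction(4) == pytest.approx(0.5) and half.fraction(5) == pytest.approx(0.5)
        same = mix([m4, m5], [1.0, 0.0])
        np.testing.assert_allclose(same.fractions, m4.fractions)
        with pytest.raises(ValueError, match="length mismatch"):
            mix([m4], [0.5, 0.5])

    @pytest.mark.parametrize("w", [0.0, 0.17, 0.5, 0.83, 1.0])
    def test_mixture_weight_recovery_to_1e9(self, network, routes, w):
        """Oxidative vs reductive citrate contributions recovered by
        least-squares inversion over the two route basis MIDs."""
        ox = propagate(network, routes["gln_oxidative_citrate"])
        red = propagate(network, routes["gln_reductive_citrate"])
        mixed = mix([ox, red], [w, 1 - w])
        w_hat = unmix(mixed, [ox, red])
        assert abs(w_hat[0] - w) < 1e-9 and abs(w_hat[1] - (1 - w)) < 1e-9


class TestNamedPredictions:
    def test_glucose_predictions_cover_stated_isotopologues(self):
        rows = {(r["metabolite"], r["mass_shift"]) for r in predict_named_routes("U-13C6-glucose")}
        assert {("lactate", 3), ("alanine", 3), ("citrate", 2), ("OAA", 3),
                ("citrate", 5), ("6PG", 6), ("R5P", 5), ("R5P", 3)} <= rows

    def test_glutamine_predictions_cover_stated_isotopologues(self):
        rows = {(r["metabolite"], r["mass_shift"]) for r in predict_named_routes("U-13C5-glutamine")}
        assert {("glutamate", 5), ("succinate", 4), ("malate", 4), ("aspartate", 4),
                ("citrate", 4), ("citrate", 5), ("aspartate", 3)} <= rows

    def test_unknown_tracer_rejected(self):
        with pytest.raises(ValueError, match="unknown tracer"):
            predict_named_routes("U-13C3-lactate")
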