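"""Generic reaction-network machinery: rate laws, RHS assembly, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stromasim.reaction_network import (
    NetworkDefinitionError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    assemble_rhs,
    check_network,
    evaluate_rate,
    load_network,
    save_network,
    simulate_network,
)


def binding_network():
    """Reversible 2:1 receptor-ligand binding: 2 x1 + xu3 <-> x2."""
    return ReactionNetwork(
        species=[
            SpeciesSpec("x1", "internal", 3.0),
            SpeciesSpec("x2", "internal", 0.0),
            SpeciesSpec("xu3", "internal", 2.0),
        ],
        reactions=[
            Reaction("v3", RateLaw("mass_action", "k2p", {"xu3": 1, "x1": 2}),
                     {"x1": -2, "xu3": -1, "x2": +1}),
            Reaction("v4", RateLaw("mass_action", "k2m", {"x2": 1}),
                     {"x2": -1, "x1": +2, "xu3": +1}),
        ],
        parameters={"k2p": 0.4, "k2m": 0.7},
    )


class TestEvaluateRate:
    def test_mass_action_closed_form(self):
        law = RateLaw("mass_action", "k", {"xu3": 1, "x1": 2})
        assert evaluate_rate(law, {"xu3": 2.0, "x1": 3.0}, {"k": 1.0}) == 18.0

    def test_saturating_half_point(self):
        law = RateLaw("saturating", "k5p", {"x2": 1},
                      saturating_species="x3", half_constant="Ks1")
        flux = evaluate_rate(law, {"x2": 4.0, "x3": 1.5}, {"k5p": 0.3, "Ks1": 1.5})
        assert flux == pytest.approx(0.3 * 4.0 * 0.5)

    def test_zero_concentrations_give_zero_flux(self):
        law = RateLaw("saturating", "k", {"a": 1}, saturating_species="b",
                      half_constant="K")
        assert evaluate_rate(law, {"a": 0.0, "b": 0.0}, {"k": 5.0, "K": 1.0}) == 0.0

    def test_missing_symbols_are_named(self):
        law = RateLaw("mass_action", "kz", {"x99": 1})
        with pytest.raises(NetworkDefinitionError, match="x99"):
            evaluate_rate(law, {}, {"kz": 1.0})
        with pytest.raises(NetworkDefinitionError, match="kz"):
            evaluate_rate(law, {"x99": 1.0}, {})

    def test_negative_concentration_rejected(self):
        law = RateLaw("mass_action", "k", {"x": 1})
        with pytest.raises(ValueError, match="negative"):
            evaluate_rate(law, {"x": -0.1}, {"k": 1.0})

    @given(st.floats(0, 50), st.floats(0, 50), st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_flux_nonnegative(self, a, b, k):
        law = RateLaw("mass_action", "k", {"a": 1, "b": 2})
        assert evaluate_rate(law, {"a": a, "b": b}, {"k": k}) >= 0


class TestAssembleRHS:
    def test_balanced_production_degradation(self):
        net = ReactionNetwork(
            [SpeciesSpec("x1", "internal", 1.0)],
            [Reaction("v1", RateLaw("mass_action", "kp", {"x1": 1}), {"x1": +1}),
             Reaction("v2", RateLaw("mass_action", "km", {"x1": 1}), {"x1": -1})],
            {"kp": 0.37, "km": 0.37},
        )
        rhs = assemble_rhs(net)
        for x in (0.0, 0.5, 10.0):
            assert rhs(0.0, np.array([x])) == pytest.approx(0.0)

    def test_binding_conservation_is_structural(self):
        """d(x1 + 2 x2)/dt == 0 and d(xu3 + x2)/dt == 0 symbolically."""
        rhs = assemble_rhs(binding_network())
        order = rhs.dyn
        i1, i2, iu = order.index("x1"), order.index("x2"), order.index("xu3")
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 5, size=3)
            d = rhs(0.0, x)
            assert d[i1] + 2 * d[i2] == pytest.approx(0.0, abs=1e-12)
            assert d[iu] + d[i2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_state_is_equilibrium_of_both_cell_models(self, cell_spec):
        rhs = assemble_rhs(cell_spec.network)
        d = rhs(0.0, np.zeros(rhs.n_dyn), np.zeros(rhs.n_in))
        assert np.all(d == 0.0)

    def test_shape_mismatch_raises(self):
        rhs = assemble_rhs(binding_network())
        with pytest.raises(ValueError, match="shape"):
            rhs(0.0, np.zeros(5))

    def test_assembly_is_additive_over_reaction_subsets(self, cancer_spec, rng):
        """The RHS of a union of reactions is the sum of the parts' RHS."""
        net = cancer_spec.network
        reactions = net.reactions
        split = len(reactions) // 2
        parts = [reactions[:split], reactions[split:]]
        x = rng.uniform(0.1, 2.0, size=len(net.dynamical_species))
        u = rng.uniform(0.1, 2.0, size=len(net.input_species))
        total = assemble_rhs(net)(0.0, x, u)
        partial = np.zeros_like(total)
        for sub in parts:
            sub_net = ReactionNetwork(net.species, list(sub), net.parameters)
            partial += assemble_rhs(sub_net)(0.0, x, u)
        np.testing.assert_allclose(partial, total, rtol=1e-12)


class TestSimulate:
    def test_analytic_exponential_decay(self):
        net = ReactionNetwork(
            [SpeciesSpec("x", "internal", 2.0)],
            [Reaction("deg", RateLaw("mass_action", "k", {"x": 1}), {"x": -1})],
            {"k": 0.21},
        )
        t = np.linspace(0, 30, 40)
        traj = simulate_network(net, [2.0], times=t, rtol=1e-8)
        exact = 2.0 * np.exp(-0.21 * t)
        assert np.max(np.abs(traj["x"] - exact) / exact) <= 1e-6

    def test_binding_conservation_over_72h(self):
        net = binding_network()
        traj = simulate_network(net, [3.0, 0.0, 2.0], times=np.linspace(0, 72, 20))
        total = traj["x1"] + 2 * traj["x2"]
        assert np.max(np.abs(total - total[0]) / total[0]) <= 1e-6
        lig = traj["xu3"] + traj["x2"]
        assert np.max(np.abs(lig - lig[0]) / lig[0]) <= 1e-6

    def test_deterministic_bitwise(self):
        net = binding_network()
        a = simulate_network(net, [3.0, 0.0, 2.0], times=[0, 10, 20])
        b = simulate_network(net, [3.0, 0.0, 2.0], times=[0, 10, 20])
        assert np.array_equal(a.values, b.values)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate_network(binding_network(), [1, 0, 1], times=[0, 5, 5])

    def test_trajectory_values_finite_nonnegative(self, cell_spec):
        net = cell_spec.network
        traj = simulate_network(net, net.initial_state(),
                                inputs=cell_spec.input_vector(),
                                times=np.linspace(0, 72, 10))
        assert np.all(np.isfinite(traj.values))
        assert np.all(traj.values >= 0)


class TestCheckNetwork:
    def test_well_formed_networks_pass(self, cell_spec):
        report = check_network(cell_spec.network)
        assert report.ok
        assert not report.undefined_species and not report.undefined_parameters

    def test_unknown_species_reported_by_name(self):
        net = binding_network()
        bad = ReactionNetwork(
            net.species,
            net.reactions + [Reaction(
                "vx", RateLaw("mass_action", "k2p", {"x99": 1}), {"x99": -1})],
            net.parameters,
        )
        report = check_network(bad)
        assert "x99" in report.undefined_species
        assert not report.ok

    def test_duplicate_names_warn_but_pass(self, caf_spec):
        report = check_network(caf_spec.network)
        assert report.duplicate_reaction_names == ["w3"]
        assert report.ok


class TestSerialization:
    def test_roundtrip_lossless(self, cell_spec, tmp_path):
        path = tmp_path / "net.yaml"
        save_network(cell_spec.network, path)
        loaded = load_network(path)
        assert loaded.species == cell_spec.network.species
        assert loaded.reactions == cell_spec.network.reactions
        assert loaded.parameters == cell_spec.network.parameters

    def test_bundled_definition_files_match_builders(self, cell_spec):
        from importlib import resources

        ref = resources.files("stromasim") / "data" / f"{cell_spec.name}.yaml"
        loaded = load_network(str(ref))
        assert loaded.reactions == cell_spec.network.reactions
        assert loaded.parameters == cell_spec.network.parameters
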