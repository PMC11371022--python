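"""Reaction-network kinetics: closed-form oracles, the canonical
nine-species network, and the exposure surrogate."""

import numpy as np
import pytest

from flashsr import radiolysis_kinetics as rk
from flashsr.synthetic_data import generate_toy_network


def two_species_chain(p_g=0.5, k=2.0):
    """Production into A (while the beam is on) feeding A -> B."""
    return rk.ReactionNetwork(
        species=(
            rk.Species("A", g_value=p_g),
            rk.Species("B"),
        ),
        reactions=(rk.Reaction.from_equation("A -> B", k),),
        name="chain",
        readout="A",
    )


class TestNetworkDefinition:
    def test_equation_parsing_with_coefficients(self):
        rxn = rk.Reaction.from_equation("2 OH -> H2O2", 5.5e9)
        assert rxn.order == 2
        assert rxn.reactants == (("OH", 2.0),)
        assert rxn.products == (("H2O2", 1.0),)

    def test_fractional_products_and_empty_rhs(self):
        rxn = rk.Reaction.from_equation("O2m -> 0.5 H2O2 + 0.5 O2", 2e4)
        assert rxn.products == (("H2O2", 0.5), ("O2", 0.5))
        sink = rk.Reaction.from_equation("ROO ->", 10.0)
        assert sink.products == ()

    def test_order_three_rejected(self):
        with pytest.raises(rk.NetworkConfigError):
            rk.Reaction.from_equation("A + B + C -> D", 1.0)

    def test_unknown_species_in_reaction_rejected(self):
        with pytest.raises(rk.NetworkConfigError):
            rk.ReactionNetwork(
                species=(rk.Species("A"),),
                reactions=(rk.Reaction.from_equation("A -> Z", 1.0),),
                readout="A",
            )

    def test_yaml_round_trip(self, tmp_path, canonical_network):
        path = tmp_path / "net.yaml"
        canonical_network.to_yaml(path)
        back = rk.load_network(path)
        assert back.species_names == canonical_network.species_names
        assert len(back.reactions) == len(canonical_network.reactions)
        assert back.readout == canonical_network.readout
        for a, b in zip(back.reactions, canonical_network.reactions):
            assert a.equation == b.equation
            assert a.rate_constant == b.rate_constant

    def test_canonical_network_has_the_nine_species(self, canonical_network):
        assert set(canonical_network.species_names) == {
            "e_aq", "O2", "H2O2", "OH", "H", "H2", "O2m", "R", "ROO",
        }


class TestAssembleRhs:
    def test_empty_network_zero_derivative(self):
        net = rk.ReactionNetwork(species=(rk.Species("A"),), reactions=(), readout="A")
        rhs = rk.assemble_rhs(net, rk.IrradiationProtocol(10.0, 1.0))
        assert np.allclose(rhs(0.5, np.array([1e-6])), 0.0)

    def test_production_switches_off_after_delivery(self):
        net = rk.ReactionNetwork(
            species=(rk.Species("A", g_value=0.3),), reactions=(), readout="A"
        )
        protocol = rk.IrradiationProtocol(10.0, 2.0)  # beam on for 5 s
        rhs = rk.assemble_rhs(net, protocol)
        assert rhs(1.0, np.zeros(1))[0] == pytest.approx(0.3e-6 * 2.0, rel=1e-12)
        assert rhs(6.0, np.zeros(1))[0] == 0.0

    def test_pure_production_grows_linearly(self):
        net = rk.ReactionNetwork(
            species=(rk.Species("A", g_value=0.3),), reactions=(), readout="A"
        )
        protocol = rk.IrradiationProtocol(10.0, 2.0, post_irradiation_followup=0.0)
        res = rk.integrate(net, protocol)
        expected = 0.3e-6 * 2.0 * res.time_grid
        assert np.allclose(res.concentrations["A"], expected, rtol=1e-6)


class TestIntegrationOracles:
    def test_first_order_decay_matches_closed_form(self):
        net = rk.ReactionNetwork(
            species=(rk.Species("S", initial_concentration=1e-6),),
            reactions=(rk.Reaction.from_equation("S ->", 2.0),),
            readout="S",
        )
        res = rk.integrate(net, rk.IrradiationProtocol(0.0, 1.0, post_irradiation_followup=5.0))
        expected = 1e-6 * np.exp(-2.0 * res.time_grid)
        assert np.max(np.abs(res.concentrations["S"] - expected)) < 1e-6 * 1e-6

    def test_production_decay_auc_is_pT_over_k(self):
        net, info = generate_toy_network("production-decay")
        dose, rate = 10.0, 2.0
        res = rk.integrate(
            net, rk.IrradiationProtocol(dose, rate, post_irradiation_followup=50.0)
        )
        p = info["g_value"] * 1e-6 * rate
        expected = p * (dose / rate) / info["k"]
        assert res.roo_auc == pytest.approx(expected, rel=1e-4)

    def test_auc_independent_of_rate_for_linear_kinetics(self):
        # with first-order removal the exposure integral depends on the
        # dose only: halving the dose rate doubles the delivery time but
        # halves the production rate
        net, info = generate_toy_network("production-decay")
        auc_fast = rk.integrate(
            net, rk.IrradiationProtocol(10.0, 4.0, post_irradiation_followup=30.0)
        ).roo_auc
        auc_slow = rk.integrate(
            net, rk.IrradiationProtocol(10.0, 2.0, post_irradiation_followup=30.0)
        ).roo_auc
        assert auc_fast == pytest.approx(auc_slow, rel=1e-4)

    def test_linear_chain_closed_form_and_conservation(self):
        net, info = generate_toy_network("linear-chain")
        res = rk.integrate(
            net, rk.IrradiationProtocol(0.0, 1.0, post_irradiation_followup=8.0)
        )
        a0, k1, k2 = info["a0"], info["k1"], info["k2"]
        t = res.time_grid
        expected_b = a0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
        assert np.max(np.abs(res.concentrations["B"] - expected_b)) < 1e-4 * a0
        total = (
            res.concentrations["A"] + res.concentrations["B"] + res.concentrations["C"]
        )
        assert np.allclose(total, a0, rtol=1e-8)

    def test_oxygen_capture_second_order_closed_form(self):
        net, info = generate_toy_network("oxygen-capture")
        res = rk.integrate(
            net, rk.IrradiationProtocol(0.0, 1.0, post_irradiation_followup=1e-3)
        )
        r0, o0, k = info["r0"], info["o2"], info["k"]
        t = res.time_grid
        # exact A + B -> C solution for unequal initial amounts
        expected_r = r0 * (o0 - r0) / (o0 * np.exp((o0 - r0) * k * t) - r0)
        assert np.max(np.abs(res.concentrations["R"] - expected_r)) < 1e-5 * r0

    def test_mass_bookkeeping_oxygen_capture(self):
        net, info = generate_toy_network("oxygen-capture")
        res = rk.integrate(
            net, rk.IrradiationProtocol(0.0, 1.0, post_irradiation_followup=1e-3)
        )
        r_plus_roo = res.concentrations["R"] + res.concentrations["ROO"]
        o2_plus_roo = res.concentrations["O2"] + res.concentrations["ROO"]
        assert np.allclose(r_plus_roo, info["r0"], rtol=1e-8)
        assert np.allclose(o2_plus_roo, info["o2"], rtol=1e-8)

    def test_zero_dose_leaves_initial_state(self, canonical_network):
        res = rk.integrate(
            canonical_network,
            rk.IrradiationProtocol(0.0, 1.0, post_irradiation_followup=1.0),
        )
        assert res.roo_auc == pytest.approx(0.0, abs=1e-18)
        assert res.concentrations["O2"][-1] == pytest.approx(5e-5, rel=1e-6)


class TestCanonicalNetwork:
    def test_concentrations_stay_nonnegative(self, canonical_network):
        for rate in (0.1, 1e3, 1e7):
            res = rk.integrate(
                canonical_network, rk.IrradiationProtocol(10.0, rate)
            )
            worst = min(np.min(c) for c in res.concentrations.values())
            assert worst > -1e-12

    def test_flash_exposure_below_conventional(self, canonical_network):
        conventional = rk.integrate(
            canonical_network, rk.IrradiationProtocol(10.0, 0.1)
        ).roo_auc
        flash = rk.integrate(
            canonical_network, rk.IrradiationProtocol(10.0, 1e6)
        ).roo_auc
        assert flash < conventional

    def test_long_format_export(self, canonical_network):
        res = rk.integrate(canonical_network, rk.IrradiationProtocol(1.0, 1e3))
        frame = res.to_frame()
        assert set(frame.columns) == {"time_s", "species", "concentration_M"}
        assert set(frame["species"].unique()) == set(canonical_network.species_names)


class TestExposureSurface:
    def test_anchor_column_is_one(self, canonical_surface):
        assert np.allclose(canonical_surface.normalized_exposure[:, 0], 1.0)

    def test_normalized_exposure_in_unit_interval(self, canonical_surface):
        n = canonical_surface.normalized_exposure
        assert np.all(n > 0.0) and np.all(n <= 1.0)

    def test_non_increasing_along_dose_rate(self, canonical_surface):
        n = canonical_surface.normalized_exposure
        assert np.all(np.diff(n, axis=1) <= 1e-9)

    def test_raw_auc_roughly_linear_in_dose_at_conventional_rate(
        self, canonical_surface
    ):
        doses = canonical_surface.dose_grid
        raw = canonical_surface.raw_auc[:, 0]
        # 5 -> 10 Gy at 0.01 Gy/s: the response is close to linear
        ratio = raw[1] / raw[0]
        assert ratio == pytest.approx(doses[1] / doses[0], rel=0.15)

    def test_csv_export_shape(self, canonical_surface, tmp_path):
        path = tmp_path / "surface.csv"
        canonical_surface.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path, index_col=0)
        assert back.shape == canonical_surface.normalized_exposure.shape

    def test_invalid_grids_rejected(self, canonical_network):
        with pytest.raises(rk.KineticsDomainError):
            rk.exposure_surface(canonical_network, np.array([-5.0]), np.array([1.0]))
        with pytest.raises(rk.KineticsDomainError):
            rk.exposure_surface(
                canonical_network, np.array([5.0]), np.array([10.0, 1.0])
            )


class TestSurrogate:
    def test_round_trip_parameter_recovery(self):
        a_true = np.array([0.5, 0.012, 1e-4])
        b_true = np.array([1.2, 0.03, -2e-4])
        w_true = 0.6
        doses = np.linspace(5, 30, 8)
        rates = np.geomspace(1e-2, 1e7, 15)
        dd, ll = np.meshgrid(doses, np.log10(rates), indexing="ij")
        n = rk._surrogate_eval(a_true, b_true, w_true, dd, ll)
        surface = rk.ExposureSurface(doses, rates, n.copy(), n)
        fit = rk.fit_surrogate(surface, poly_degree=2)
        assert np.max(np.abs(fit.a_coefficients - a_true)) < 1e-3
        assert np.max(np.abs(fit.b_coefficients - b_true)) < 1e-3
        assert abs(fit.width - w_true) < 1e-3
        assert fit.max_residual < 1e-6

    def test_constant_surface_gives_zero_amplitude(self):
        doses = np.linspace(5, 30, 5)
        rates = np.geomspace(1e-2, 1e7, 9)
        n = np.ones((5, 9))
        surface = rk.ExposureSurface(doses, rates, n.copy(), n)
        fit = rk.fit_surrogate(surface, poly_degree=2)
        assert np.max(np.abs(fit.a(doses))) < 1e-6

    def test_canonical_surface_fit_quality(self, canonical_surrogate):
        assert canonical_surrogate.max_residual < 0.05

    def test_surrogate_matches_ode_at_interior_point(
        self, canonical_network, canonical_surface, canonical_surrogate
    ):
        # direct ODE evaluation at a grid point not used for anchoring
        dose = 10.0
        rate = canonical_surface.dose_rate_grid[5]
        anchor_rate = canonical_surface.dose_rate_grid[0]
        auc = rk.integrate(
            canonical_network, rk.IrradiationProtocol(dose, rate)
        ).roo_auc
        anchor = rk.integrate(
            canonical_network, rk.IrradiationProtocol(dose, anchor_rate)
        ).roo_auc
        direct = min(auc / anchor, 1.0)
        fitted = rk.normalized_exposure(canonical_surrogate, dose, rate)
        assert abs(direct - fitted) <= canonical_surrogate.max_residual + 1e-9

    def test_limits_of_normalized_exposure(self, canonical_surrogate):
        low = rk.normalized_exposure(canonical_surrogate, 10.0, 1e-6)
        assert low == pytest.approx(1.0, abs=0.02)
        high = rk.normalized_exposure(canonical_surrogate, 10.0, 1e12)
        floor = 1.0 - canonical_surrogate.a(10.0)
        assert high == pytest.approx(floor, abs=1e-3)

    def test_nonpositive_dose_rate_rejected(self, canonical_surrogate):
        with pytest.raises(rk.KineticsDomainError):
            rk.normalized_exposure(canonical_surrogate, 10.0, 0.0)

    def test_yaml_round_trip(self, canonical_surrogate, tmp_path):
        path = tmp_path / "surrogate.yaml"
        canonical_surrogate.to_yaml(path)
        back = rk.SurrogateModel.from_yaml(path)
        assert np.allclose(back.a_coefficients, canonical_surrogate.a_coefficients)
        assert np.allclose(back.b_coefficients, canonical_surrogate.b_coefficients)
        assert back.width == pytest.approx(canonical_surrogate.width)
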