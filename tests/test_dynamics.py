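"""Normalized-Hill math, ODE right-hand side, integration.

The Hill-shape reference values were frozen from a 2-D root-finding
oracle (scipy.optimize.fsolve on f(1)=1, f(ec50)=1/2), which this module
also re-runs as a property check against the closed form.
"""

import itertools

import numpy as np
import pytest
from scipy.optimize import fsolve

import hillnet as hn
from hillnet.nets import random_network

S_DEFAULT = hn.hill_shape(1.4, 0.5)


def oracle_shape(n, ec50):
    """Independent (beta, k): numerically solve the normalization anchors."""
    def eqs(p):
        beta, k = p
        f = lambda x: beta * x ** n / (k ** n + x ** n)
        return [f(1.0) - 1.0, f(ec50) - 0.5]

    beta, k = fsolve(eqs, [2.0, 1.0], full_output=False)
    return beta, k


class TestHillShape:
    @pytest.mark.parametrize(
        "n, ec50, beta, k",
        [
            # frozen from oracle_shape
            (1.4, 0.5, 2.5649064800646, 1.3769566816527),
            (2.0, 0.5, 1.5, 2 ** -0.5),
            (3.0, 0.4, 1.0733944954128, 0.4186854123723),
        ],
    )
    def test_closed_form_matches_root_finding_oracle(self, n, ec50, beta, k):
        s = hn.hill_shape(n, ec50)
        assert s.beta == pytest.approx(beta, abs=1e-9)
        assert s.k == pytest.approx(k, abs=1e-9)
        ob, ok = oracle_shape(n, ec50)
        assert s.beta == pytest.approx(ob, abs=1e-8)
        assert s.k == pytest.approx(ok, abs=1e-8)

    @pytest.mark.parametrize(
        "n, ec50",
        list(itertools.product([0.7, 1.4, 2.0, 4.0], [0.1, 0.2, 0.3])) + [(1.4, 0.49)],
    )
    def test_normalization_anchors(self, n, ec50):
        s = hn.hill_shape(n, ec50)
        assert hn.act(0.0, s) == 0.0
        assert hn.act(1.0, s) == pytest.approx(1.0, abs=1e-9)
        assert hn.act(ec50, s) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize(
        "n, ec50", [(1.0, 0.5), (1.4, 0.99), (0.5, 0.3), (-1, 0.5), (2, 0.0), (2, 1.0)]
    )
    def test_invalid_domains_raise(self, n, ec50):
        with pytest.raises(hn.HillParameterizationError):
            hn.hill_shape(n, ec50)


class TestActInhib:
    @pytest.mark.parametrize(
        "n, ec50", list(itertools.product([0.8, 1.4, 3.0], [0.1, 0.2, 0.3]))
    )
    def test_monotone_and_complementary(self, n, ec50):
        s = hn.hill_shape(n, ec50)
        x = np.linspace(0, 1, 501)
        f = hn.act(x, s)
        assert np.all(np.diff(f) >= 0)
        assert np.all((f >= 0) & (f <= 1))
        assert np.allclose(hn.act(x, s) + hn.inhib(x, s), 1.0, atol=1e-12)

    def test_half_max_and_clamp(self):
        assert hn.act(0.5, S_DEFAULT) == pytest.approx(0.5, abs=1e-9)
        assert hn.inhib(0.5, S_DEFAULT) == pytest.approx(0.5, abs=1e-9)
        assert hn.act(2.0, S_DEFAULT) == 1.0  # clamped above saturation
        with pytest.raises(ValueError):
            hn.act(-0.1, S_DEFAULT)


class TestFluxAndDrive:
    def test_input_reaction_flux_is_weight(self, examplenet):
        stim = hn.set_reaction_weight(examplenet, "r1", 1.0)
        y = np.zeros(5)
        assert hn.reaction_flux(stim.get_reaction("r1"), y, stim) == 1.0
        assert hn.reaction_flux(examplenet.get_reaction("r1"), y, examplenet) == 0.0

    def test_and_gate_flux(self, examplenet):
        r5 = examplenet.get_reaction("r5")  # A & !B => E
        y = np.zeros(5)
        y[examplenet.species_index("A")] = 1.0
        assert hn.reaction_flux(r5, y, examplenet) == pytest.approx(1.0, abs=1e-9)
        y[examplenet.species_index("B")] = 1.0
        assert hn.reaction_flux(r5, y, examplenet) == pytest.approx(0.0, abs=1e-9)

    def test_or_fold_value_and_identity(self):
        # two half-strength routes onto one target combine to 0.75
        from hillnet.dynamics import _or_fold

        assert _or_fold([0.5, 0.5]) == pytest.approx(0.75, abs=1e-12)
        for x in [0.0, 0.3, 1.0]:
            assert _or_fold([x, 0.0]) == pytest.approx(x, abs=1e-12)

    def test_or_fold_order_invariance(self):
        from hillnet.dynamics import _or_fold

        rng = np.random.default_rng(7)
        for _ in range(50):
            fluxes = rng.uniform(0, 1, size=rng.integers(2, 6))
            a = _or_fold(fluxes)
            b = _or_fold(fluxes[rng.permutation(len(fluxes))])
            assert abs(a - b) < 1e-12

    def test_node_drive_single_and_none(self, examplenet):
        y = np.zeros(5)
        y[examplenet.species_index("B")] = 0.5
        r4 = examplenet.get_reaction("r4")
        assert hn.node_drive("D", y, examplenet) == pytest.approx(
            hn.reaction_flux(r4, y, examplenet)
        )
        # A has only its (off) input reaction; B itself has no other drive
        assert hn.node_drive("A", y, examplenet) == 0.0


def naive_rhs(y, model):
    """Brute-force oracle: per-node loop over all reactions, every term
    recomputed from scratch; independent of the compiled production path."""
    out = np.zeros(len(model.species))
    for i, sp in enumerate(model.species):
        phi = 0.0
        for r in model.reactions:
            if r.target_id != sp.id:
                continue
            if r.terms:
                flux = r.w
                for t in r.terms:
                    s = hn.hill_shape(r.n, r.ec50)
                    x = max(float(y[[q.id for q in model.species].index(t.species_id)]), 0.0)
                    a = min(max(s.beta * x ** s.n / (s.k ** s.n + x ** s.n), 0.0), 1.0)
                    flux *= a if t.sign > 0 else 1.0 - a
            else:
                flux = r.w
            phi = phi + flux - phi * flux
        phi = min(max(phi, 0.0), 1.0)
        out[i] = (phi * sp.y_max - y[i]) / sp.tau
    return out


class TestRhs:
    def test_null_network_has_zero_flow(self, examplenet):
        assert np.array_equal(hn.rhs(0.0, np.zeros(5), examplenet), np.zeros(5))

    def test_single_species_unit_drive(self):
        m = hn.NetworkModel(
            [hn.Species(id="A")], [hn.reaction_from_rule("r1", "=> A", w=1.0)]
        )
        assert hn.rhs(0.0, np.array([0.0]), m) == pytest.approx([1.0])

    def test_knocked_out_species_is_inert(self, cardiacdevnet):
        ko = hn.apply_knockout(
            hn.set_reaction_weight(cardiacdevnet, "r1", 1.0), "NKX25"
        )
        i = ko.species_index("NKX25")
        dy = hn.rhs(0.0, np.zeros(5), ko)
        assert dy[i] == 0.0

    def test_nonfinite_state_rejected(self, examplenet):
        with pytest.raises(ValueError):
            hn.rhs(0.0, np.array([0, 1, np.nan, 0, 0.0]), examplenet)

    def test_agreement_with_bruteforce_oracle_on_random_models(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            m = random_network(
                n_species=int(rng.integers(2, 7)),
                n_reactions=int(rng.integers(1, 10)),
                p_input=0.3,
                p_inhib=0.4,
                seed=int(rng.integers(2 ** 31)),
            )
            y = rng.uniform(0, 1, len(m.species))
            assert np.allclose(
                hn.rhs(0.0, y, m), naive_rhs(y, m), atol=1e-12, rtol=0
            )


class TestIntegration:
    def test_null_simulation_stays_exactly_zero(self, examplenet):
        tc = hn.simulate_segment(examplenet, duration=10)
        assert np.all(tc.activities == 0.0)

    def test_first_row_is_exactly_y0(self, examplenet):
        y0 = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        tc = hn.simulate_segment(examplenet, y0, duration=3, n_out=7)
        assert np.array_equal(tc.activities[0], y0)
        assert tc.times[0] == 0.0 and tc.times[-1] == pytest.approx(3.0)
        assert len(tc.times) == 7

    def test_single_node_closed_form(self):
        # one constant input: y(t) = y_max * (1 - exp(-t / tau))
        m = hn.NetworkModel(
            [hn.Species(id="A", tau=2.0, y_max=0.8)],
            [hn.reaction_from_rule("r1", "=> A", w=1.0)],
        )
        tc = hn.simulate_segment(m, duration=10, n_out=51)
        expected = 0.8 * (1 - np.exp(-tc.times / 2.0))
        assert np.allclose(tc.activities[:, 0], expected, atol=1e-5)
        assert tc.activities[-1, 0] == pytest.approx(
            0.8 * (1 - np.exp(-5.0)), abs=1e-5
        )

    def test_semigroup_property(self, examplenet):
        stim = hn.set_reaction_weight(examplenet, "r1", 1.0)
        one = hn.simulate_segment(stim, duration=20)
        a = hn.simulate_segment(stim, duration=10)
        b = hn.simulate_segment(stim, a.final_state, duration=10, t0=10)
        assert np.allclose(one.final_state, b.final_state, atol=1e-6)

    def test_trajectories_bounded_for_random_models(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            m = random_network(
                n_species=int(rng.integers(2, 6)),
                n_reactions=int(rng.integers(2, 9)),
                seed=int(rng.integers(2 ** 31)),
            )
            tc = hn.simulate_segment(m, duration=50, n_out=101)
            ymax = np.array([s.y_max for s in m.species])
            assert np.all(tc.activities >= -1e-6)
            assert np.all(tc.activities <= ymax + 1e-6)


class TestSteadyState:
    def test_examplenet_stimulated_fixed_point(self, examplenet):
        stim = hn.set_reaction_weight(examplenet, "r1", 1.0)
        ss, converged = hn.steady_state(stim)
        assert converged
        by_id = dict(zip(stim.species_ids, ss))
        for s in "ACE":
            assert by_id[s] == pytest.approx(1.0, abs=1e-3)
        for s in "BD":
            assert by_id[s] == pytest.approx(0.0, abs=1e-6)

    def test_and_gate_kills_E_when_both_inputs_on(self, examplenet):
        stim = hn.set_reaction_weight(
            hn.set_reaction_weight(examplenet, "r1", 1.0), "r2", 1.0
        )
        ss, converged = hn.steady_state(stim)
        assert converged
        assert ss[stim.species_index("E")] == pytest.approx(0.0, abs=1e-3)

    def test_all_off_converges_immediately(self, examplenet):
        ss, converged = hn.steady_state(examplenet)
        assert converged and np.array_equal(ss, np.zeros(5))
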