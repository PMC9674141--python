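"""Random-parameter ODE ensemble engine."""

import numpy as np
import pytest

import emphybrid as eh
from emphybrid import racipe
from emphybrid.racipe import (
    RepeatBlock,
    SamplingConfig,
    SteadyStateEnsemble,
    integrate_circuit,
)


class TestShiftedHill:
    def test_unity_at_zero(self):
        assert racipe.shifted_hill(0.0, 10.0, 4, 0.2) == pytest.approx(1.0)

    def test_half_effect_at_threshold(self):
        assert racipe.shifted_hill(10.0, 10.0, 3, 0.5) == pytest.approx(0.75)

    def test_activation_limit(self):
        assert racipe.shifted_hill(1e9, 1.0, 2, 3.0) == pytest.approx(3.0, rel=1e-6)

    def test_nonpositive_threshold_raises(self):
        with pytest.raises(ValueError):
            racipe.shifted_hill(1.0, 0.0, 2, 0.5)


class TestSampleParameters:
    def test_fold_change_respects_edge_sign(self, emt_core):
        params = racipe.sample_parameters(emt_core, 500, seed=1)
        for j, (_s, _t, sign) in enumerate(params.edges):
            lam = params.fold_change[:, j]
            assert np.all(lam < 1) if sign < 0 else np.all(lam > 1)

    def test_hill_coefficients_integer_in_range(self, emt_core):
        params = racipe.sample_parameters(emt_core, 300, seed=2)
        assert params.hill.dtype.kind == "i"
        assert params.hill.min() >= 1 and params.hill.max() <= 6

    def test_bit_identical_under_seed(self, toggle):
        a = racipe.sample_parameters(toggle, 100, seed=3)
        b = racipe.sample_parameters(toggle, 100, seed=3)
        assert np.array_equal(a.production, b.production)
        assert np.array_equal(a.threshold, b.threshold)

    def test_invalid_range_raises(self):
        with pytest.raises(ValueError, match="min >= max"):
            SamplingConfig(production=(10.0, 1.0))

    def test_gaussian_option_stays_in_range(self, toggle):
        cfg = SamplingConfig(distribution="gaussian")
        params = racipe.sample_parameters(toggle, 400, config=cfg, seed=4)
        assert params.production.min() >= 1 and params.production.max() <= 100


class TestIntegrateCircuit:
    def test_unregulated_node_settles_at_p_over_d(self):
        net = eh.GRNTopology(name="solo", nodes=("A",), edges=())
        params = racipe.sample_parameters(net, 1, seed=0)
        ok, x = integrate_circuit(net, params, [0.0])
        assert ok
        expected = params.production[0, 0] / params.degradation[0, 0]
        assert x[0] == pytest.approx(expected, rel=1e-6)

    def test_toggle_strong_inhibition_polarizes(self, toggle):
        """With symmetric strong repression the winner settles at P/D and the
        loser at lam * P/D (closed-form nullclines for deep Hill repression)."""
        params = racipe.ParameterEnsemble(
            nodes=toggle.nodes,
            edges=tuple((e.source, e.target, e.sign) for e in toggle.edges),
            production=np.array([[50.0, 50.0]]),
            degradation=np.array([[0.5, 0.5]]),
            fold_change=np.array([[0.01, 0.01]]),
            hill=np.array([[6, 6]]),
            threshold=np.array([[50.0, 50.0]]),
        )
        ok, x = integrate_circuit(toggle, params, [80.0, 1.0])
        assert ok
        # nullcline fixed point: winner at P/D * H(loser), loser at
        # P/D * H(winner); iterate the closed-form map to convergence
        w, l = 100.0, 0.0
        for _ in range(200):
            w = 100.0 * racipe.shifted_hill(l, 50.0, 6, 0.01)
            l = 100.0 * racipe.shifted_hill(w, 50.0, 6, 0.01)
        assert x[0] == pytest.approx(w, rel=0.02)
        assert x[1] == pytest.approx(l, rel=0.02)
        assert x[0] > 90 and x[1] < 5  # polarized: one high, one low

    def test_dt_refinement_stable(self, emt_core):
        """Halving the Euler step changes converged levels by < 1%."""
        params = racipe.sample_parameters(emt_core, 20, seed=5)
        rng = np.random.default_rng(0)
        for k in range(20):
            ic = rng.uniform(0, 1.5 * params.production[k] / params.degradation[k])
            ok1, x1 = integrate_circuit(emt_core, params, ic, param_set=k, dt=0.1)
            ok2, x2 = integrate_circuit(emt_core, params, ic, param_set=k, dt=0.05)
            if ok1 and ok2:
                scale = np.maximum(np.abs(x1), 1.0)
                assert np.max(np.abs(x1 - x2) / scale) < 0.01


class TestRunEnsemble:
    def test_single_unregulated_node_is_monostable(self):
        net = eh.GRNTopology(name="solo", nodes=("A",), edges=())
        ens = racipe.run_ensemble(net, n_sets=50, n_ics=5, repeats=1, seed=1)
        assert all(c == 1 for c in ens.distinct_state_counts()[0])
        assert racipe.multistability_fraction(ens) == 0.0

    def test_record_shape_and_convergence(self, toggle):
        ens = racipe.run_ensemble(toggle, n_sets=100, n_ics=8, repeats=2, seed=2)
        for block in ens.repeats:
            assert block.states.shape == (100, 8, 2)
            assert block.converged.shape == (100, 8)

    def test_toggle_is_bistable_for_some_parameter_sets(self, toggle):
        ens = racipe.run_ensemble(toggle, n_sets=400, n_ics=10, repeats=1, seed=3)
        assert racipe.multistability_fraction(ens) > 0

    def test_levels_bounded_by_production_over_degradation(self, emt_core):
        """Steady levels cannot exceed P/D times the product of activating
        fold changes on the node (regulation only scales production)."""
        ens = racipe.run_ensemble(emt_core, n_sets=150, n_ics=5, repeats=1, seed=4)
        cfg = SamplingConfig()
        pooled = ens.pooled_states()
        for i, node in enumerate(emt_core.nodes):
            n_act = sum(e.target == node and e.sign > 0 for e in emt_core.edges)
            bound = (cfg.production[1] / cfg.degradation[0]) * (
                cfg.lambda_activation[1] ** n_act
            )
            assert pooled[:, i].max() <= bound

    def test_deleting_an_edge_reduces_toggle_bistability(self, toggle):
        """Mutual inhibition is the bistability motif: breaking one arm
        leaves a monotone cascade that is monostable far more often."""
        broken = eh.GRNTopology(name="broken", nodes=toggle.nodes, edges=toggle.edges[:1])
        full = np.mean(
            [
                racipe.multistability_fraction(
                    racipe.run_ensemble(toggle, 200, 8, repeats=1, seed=s)
                )
                for s in (1, 2, 3)
            ]
        )
        cut = np.mean(
            [
                racipe.multistability_fraction(
                    racipe.run_ensemble(broken, 200, 8, repeats=1, seed=s)
                )
                for s in (1, 2, 3)
            ]
        )
        assert full > cut


class TestBinarize:
    def _ensemble_from_states(self, states, nodes=("A", "B")):
        arr = np.asarray(states, dtype=float)[:, None, :]
        block = RepeatBlock(states=arr, converged=np.ones(arr.shape[:2], dtype=bool))
        return SteadyStateEnsemble(nodes=nodes, repeats=(block,))

    def test_symmetric_two_state_ensemble(self):
        ens = self._ensemble_from_states([[10.0, 1.0], [1.0, 10.0]] * 5)
        dist = racipe.binarize(ens)
        assert dist.freqs == {"10": 0.5, "01": 0.5}

    def test_distribution_sums_to_one(self, emt_core):
        ens = racipe.run_ensemble(emt_core, n_sets=100, n_ics=5, repeats=1, seed=6)
        dist = racipe.binarize(ens, signal_nodes=eh.find_signal_nodes(emt_core))
        assert sum(dist.freqs.values()) == pytest.approx(1.0)

    def test_signal_node_trimmed_from_strings(self, emt_core):
        ens = racipe.run_ensemble(emt_core, n_sets=60, n_ics=5, repeats=1, seed=7)
        trimmed = racipe.binarize(ens, signal_nodes={"SNAIL"})
        full = racipe.binarize(ens)
        assert all(len(s) == 3 for s in trimmed.freqs)
        assert all(len(s) == 4 for s in full.freqs)

    def test_zero_variance_node_raises(self):
        ens = self._ensemble_from_states([[5.0, 1.0], [5.0, 10.0]])
        with pytest.raises(ValueError, match="'A'"):
            racipe.binarize(ens)

    def test_invariant_to_parameter_set_order(self, toggle):
        ens = racipe.run_ensemble(toggle, n_sets=80, n_ics=5, repeats=1, seed=8)
        block = ens.repeats[0]
        perm = np.random.default_rng(0).permutation(80)
        shuffled = SteadyStateEnsemble(
            nodes=ens.nodes,
            repeats=(RepeatBlock(states=block.states[perm], converged=block.converged[perm]),),
        )
        assert racipe.binarize(ens).freqs == racipe.binarize(shuffled).freqs

    def test_refinement_same_binarized_states(self, emt_core):
        """dt=0.05 and dt=0.1 binarize to the same states for >= 99% of runs."""
        kw = dict(n_sets=100, n_ics=2, repeats=1, seed=9)
        d1 = racipe.run_ensemble(emt_core, dt=0.1, **kw)
        d2 = racipe.run_ensemble(emt_core, dt=0.05, **kw)
        # identical parameter draws and ICs (same seed), only dt differs
        b1, b2 = d1.repeats[0], d2.repeats[0]
        both = b1.converged & b2.converged
        mismatch = np.abs(b1.states[both] - b2.states[both]).max(axis=1) > 1.0
        assert mismatch.mean() <= 0.01
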