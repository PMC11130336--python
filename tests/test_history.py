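import numpy as np
import pytest

import phylohrm as ph

from oracles import enum_marginal


def make_joint(tree, model, states):
    return ph.Reconstruction(
        mode="joint", tree=tree, model=model, theta=np.ones(model.n_params) * 0.01,
        root_prior=ph.RootPrior(), node_states=np.asarray(states),
    )


class TestCountTransitions:
    def test_uniform_history_has_no_events(self):
        t = ph.parse_newick("((A:1,B:1):1,C:2);")
        m = ph.build_hidden_rates_model(2, 1)
        s = ph.count_transitions(t, make_joint(t, m, [0] * t.n_nodes))
        assert s.gains == 0 and s.losses == 0
        assert s.minimum_change_caveat

    def test_single_gain_on_constructed_tree(self):
        t = ph.parse_newick("((A:1,B:1):1,C:2);")
        m = ph.build_hidden_rates_model(2, 1)
        states = np.zeros(t.n_nodes, dtype=int)
        inner = ph.find_mrca(t, ["A", "B"])
        states[[inner, t.tip_id("A"), t.tip_id("B")]] = 1
        s = ph.count_transitions(t, make_joint(t, m, states))
        assert s.gains == 1 and s.losses == 0
        assert s.gains + s.losses <= t.n_nodes - 1

    def test_marginal_input_rejected(self):
        t = ph.parse_newick("(A:1,B:1);")
        m = ph.build_hidden_rates_model(2, 1)
        recon = ph.marginal_reconstruct(t, ph.TraitMatrix({"A": 0, "B": 1}), m, [0.3, 0.3])
        with pytest.raises(ValueError, match="joint"):
            ph.count_transitions(t, recon)

    @pytest.mark.parametrize("seed", range(10))
    def test_low_rate_histories_counted_exactly(self, seed):
        """In a low-rate regime (few expected events/edge) node-to-node
        counting recovers the true number of gains."""
        tree = ph.simulate_tree(120, seed=seed, scale_height=100)
        model = ph.build_hidden_rates_model(2, 1)
        theta = np.array([0.002, 0.0005])
        traits, hist = ph.simulate_trait_history(tree, model, theta, root_state=0, seed=seed)
        recon = ph.joint_reconstruct(
            tree, traits, model, theta, ph.RootPrior("user", vector=(1.0, 0.0))
        )
        s = ph.count_transitions(tree, recon)
        assert s.gains == hist.true_gains()


class TestCladeEvents:
    def test_events_assigned_to_smallest_clade_and_conserved(self):
        t = ph.parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);")
        m = ph.build_hidden_rates_model(2, 1)
        states = np.zeros(t.n_nodes, dtype=int)
        ab = ph.find_mrca(t, ["A", "B"])
        states[[ab, t.tip_id("A"), t.tip_id("B")]] = 1
        states[t.tip_id("E")] = 1
        s = ph.count_transitions(t, make_joint(t, m, states))
        clades = {"left": ["A", "B", "C", "D"], "ab": ["A", "B"], "right": ["E", "F"]}
        tab = ph.tabulate_clade_events(t, s, clades).set_index("clade")
        # gain on ab's stem edge: parent is inside 'left' but not 'ab'
        assert tab.loc["left", "gains"] == 1
        assert tab.loc["right", "gains"] == 1
        assert tab.gains.sum() == s.gains and tab.losses.sum() == s.losses

    def test_event_outside_named_clades_goes_to_catch_all(self):
        t = ph.parse_newick("((A:1,B:1):1,C:2);")
        m = ph.build_hidden_rates_model(2, 1)
        states = np.zeros(t.n_nodes, dtype=int)
        states[t.tip_id("C")] = 1
        s = ph.count_transitions(t, make_joint(t, m, states))
        tab = ph.tabulate_clade_events(t, s, {"ab": ["A", "B"]}).set_index("clade")
        assert tab.loc["(other)", "gains"] == 1

    def test_unknown_tip_in_clade_definition(self):
        t = ph.parse_newick("((A:1,B:1):1,C:2);")
        m = ph.build_hidden_rates_model(2, 1)
        s = ph.count_transitions(t, make_joint(t, m, [0] * t.n_nodes))
        with pytest.raises(KeyError):
            ph.tabulate_clade_events(t, s, {"bad": ["A", "Z"]})


class TestLabelRateClasses:
    def _fit_with_theta(self, theta):
        model = ph.build_hidden_rates_model(2, 3, no_gain_class="R1")
        return ph.FitResult(
            model=model, theta=np.asarray(theta), lnl=0.0, n_params=model.n_params,
            restarts=[], seed=0, root_prior=ph.RootPrior(),
        )

    def test_constructed_rates_get_expected_roles(self):
        from phylohrm.simulate import nfc_like_model_and_theta

        model, theta = nfc_like_model_and_theta()
        fit = ph.FitResult(
            model=model, theta=theta, lnl=0.0, n_params=model.n_params,
            restarts=[], seed=0, root_prior=ph.RootPrior(),
        )
        labels = ph.label_rate_classes(fit, negligible=1e-6)
        assert labels == {"R1": "non-precursor", "R2": "precursor", "R3": "intermediary"}
        # the defining rate ordering: gain from the intermediary is 10x the
        # precursor->intermediary transition
        sp = model.space
        Q = model.assemble_Q(theta)
        assert Q[sp.index(0, 2), sp.index(1, 2)] == pytest.approx(
            10 * Q[sp.index(0, 1), sp.index(0, 2)]
        )

    def test_symmetric_classes_not_assignable(self):
        model = ph.build_hidden_rates_model(2, 3)
        fit = ph.FitResult(
            model=model, theta=np.full(model.n_params, 0.1), lnl=0.0,
            n_params=model.n_params, restarts=[], seed=0, root_prior=ph.RootPrior(),
        )
        with pytest.raises(ValueError, match="not uniquely"):
            ph.label_rate_classes(fit)

    def test_wrong_model_shape_rejected(self):
        model = ph.build_hidden_rates_model(2, 2)
        fit = ph.FitResult(
            model=model, theta=np.full(model.n_params, 0.1), lnl=0.0,
            n_params=model.n_params, restarts=[], seed=0, root_prior=ph.RootPrior(),
        )
        with pytest.raises(ValueError, match="3-class"):
            ph.label_rate_classes(fit)


@pytest.fixture(scope="module")
def scan_setup():
    tree = ph.simulate_tree(120, seed=21, scale_height=100)
    model = ph.build_hidden_rates_model(2, 1)
    traits, _ = ph.simulate_trait_history(tree, model, [0.01, 0.004], root_state=0, seed=21)
    focal = tree.mrca(tree.tip_labels[:30])
    return tree, traits, focal


class TestRateGridScan:
    def test_default_grid_has_100_records_including_mle(self, scan_setup):
        tree, traits, focal = scan_setup
        grid = ph.rate_grid_scan(tree, traits, focal, seed=0, n_restarts=3)
        assert len(grid.records) == 100
        g, l = grid.anchor_fit.theta
        hit = np.isclose(grid.records.gain, g) & np.isclose(grid.records.loss, l)
        assert hit.sum() == 1
        assert np.allclose(grid.records.p_absent + grid.records.p_present, 1.0)

    def test_mle_record_matches_direct_computation(self, scan_setup):
        tree, traits, focal = scan_setup
        grid = ph.rate_grid_scan(tree, traits, focal, grid_spec={"n": 1}, seed=0, n_restarts=3)
        assert len(grid.records) == 1
        rec = grid.records.iloc[0]
        model = ph.build_hidden_rates_model(2, 1)
        assert rec.lnl == pytest.approx(grid.anchor_fit.lnl, abs=1e-6)
        recon = ph.marginal_reconstruct(tree, traits, model, grid.anchor_fit.theta)
        p = ph.ancestor_probability(recon, focal)
        assert rec.p_present == pytest.approx(p[1], abs=1e-12)

    def test_present_probability_non_increasing_in_loss_gain_ratio(self):
        # all-absent outgroup, mixed ingroup: the more loss dominates gain,
        # the less plausible an ancestrally present focal node becomes
        tree = ph.parse_newick(
            "(((I1:10,I2:10):10,(I3:10,I4:10):10):30,(O1:25,O2:25):25);"
        )
        traits = ph.TraitMatrix({"I1": 1, "I2": 0, "I3": 1, "I4": 0, "O1": 0, "O2": 0})
        focal = tree.mrca(["I1", "I4"])
        grid = ph.rate_grid_scan(tree, traits, focal, grid_spec={"n": 21}, seed=0, n_restarts=3)
        rec = grid.records.assign(ratio=lambda d: d.loss / d.gain).sort_values("ratio")
        assert np.all(np.diff(rec.p_present.values) <= 1e-9)

    def test_empty_grid_spec_rejected(self, scan_setup):
        tree, traits, focal = scan_setup
        with pytest.raises(ValueError):
            ph.rate_grid_scan(tree, traits, focal, grid_spec={"n": 0}, seed=0)


class TestAncestorProbability:
    def test_matches_enumeration_posterior_and_sums_to_one(self):
        tree = ph.parse_newick("((A:1,B:2):1,(C:1.5,D:0.5):2);")
        model = ph.build_hidden_rates_model(2, 1)
        traits = ph.TraitMatrix({"A": 1, "B": 0, "C": 1, "D": None})
        recon = ph.marginal_reconstruct(tree, traits, model, [0.3, 0.2])
        node = tree.mrca(["A", "B"])
        p = ph.ancestor_probability(recon, node)
        assert p.sum() == pytest.approx(1.0)
        exp = enum_marginal(tree, traits, model, [0.3, 0.2])
        assert p[1] == pytest.approx(exp[node, 1], abs=1e-8)

    def test_constrained_node_has_unit_mass(self):
        tree = ph.parse_newick("((A:1,B:2):1,C:2);")
        model = ph.build_hidden_rates_model(2, 1)
        traits = ph.TraitMatrix({"A": 1, "B": 0, "C": 0})
        node = tree.mrca(["A", "B"])
        recon = ph.marginal_reconstruct(
            tree, traits, model, [0.3, 0.2],
            constraints=[ph.NodeConstraint.observed(node, 1, model.space)],
        )
        assert ph.ancestor_probability(recon, node)[1] == pytest.approx(1.0)

    def test_joint_mode_rejected(self):
        tree = ph.parse_newick("(A:1,B:1);")
        model = ph.build_hidden_rates_model(2, 1)
        recon = ph.joint_reconstruct(tree, ph.TraitMatrix({"A": 0, "B": 1}), model, [0.3, 0.2])
        with pytest.raises(ValueError):
            ph.ancestor_probability(recon, 0)
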