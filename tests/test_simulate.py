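import numpy as np
import pytest

import phylohrm as ph
from phylohrm.simulate import nfc_like_model_and_theta

from oracles import expected_event_count


class TestSimulateTree:
    def test_exact_tip_count_and_labels_unique(self):
        t = ph.simulate_tree(50, seed=0)
        assert t.n_tips == 50
        assert len(set(t.tip_labels)) == 50

    def test_ultrametric(self):
        t = ph.simulate_tree(40, seed=1)
        depths = t.node_depths()[t.tip_ids]
        assert np.ptp(depths) < 1e-9

    def test_seed_determinism(self):
        a = ph.write_newick(ph.simulate_tree(30, seed=5))
        b = ph.write_newick(ph.simulate_tree(30, seed=5))
        assert a == b
        c = ph.write_newick(ph.simulate_tree(30, seed=6))
        assert a != c

    def test_height_scaling(self):
        t = ph.simulate_tree(30, seed=2, scale_height=100.0)
        assert t.node_depths()[t.tip_ids[0]] == pytest.approx(100.0)

    def test_death_rate_supported(self):
        t = ph.simulate_tree(30, seed=3, birth=1.0, death=0.4)
        assert t.n_tips == 30
        assert np.ptp(t.node_depths()[t.tip_ids]) < 1e-9

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            ph.simulate_tree(10, birth=0.5, death=0.5)


class TestSimulateTraitHistory:
    def test_zero_rates_inherit_root_state(self):
        t = ph.simulate_tree(20, seed=0, scale_height=100)
        m = ph.build_hidden_rates_model(2, 1)
        traits, hist = ph.simulate_trait_history(t, m, [0.0, 0.0], root_state=1, seed=0)
        assert all(s == 1 for s in traits.states.values())
        assert not hist.events

    def test_tip_states_consistent_with_event_chains(self):
        t = ph.simulate_tree(100, seed=4, scale_height=100)
        m = ph.build_hidden_rates_model(2, 2)
        theta = np.full(m.n_params, 0.01)
        traits, hist = ph.simulate_trait_history(t, m, theta, root_state=0, seed=4)
        for v in t.tip_ids:
            state = hist.node_states[t.parent[v]]
            for _, a, b in hist.events.get(int(v), []):
                assert a == state
                state = b
            assert state == hist.node_states[v]
            assert traits.states[t.labels[v]] == m.space.obs_part(int(state))

    def test_truth_counts_dominate_endpoint_differences(self):
        t = ph.simulate_tree(150, seed=9, scale_height=100)
        m = ph.build_hidden_rates_model(2, 1)
        traits, hist = ph.simulate_trait_history(t, m, [0.02, 0.01], root_state=0, seed=9)
        k = m.space.n_classes
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            diff = int(
                m.space.obs_part(int(hist.node_states[v]))
                != m.space.obs_part(int(hist.node_states[t.parent[v]]))
            )
            assert hist.obs_changes[v] >= diff

    def test_mean_event_count_matches_markov_expectation(self):
        """Single edge: mean number of jumps vs the matrix-method value
        E[N] = ∫ occupancy(t)·exit_rates dt, within 3 standard errors."""
        tree = ph.parse_newick("(A:80,B:0);")
        m = ph.build_hidden_rates_model(2, 1)
        theta = np.array([0.02, 0.01])
        Q = m.assemble_Q(theta)
        expected = expected_event_count(Q, start=0, T=80.0)
        n_rep = 4000
        counts = []
        for s in range(n_rep):
            _, hist = ph.simulate_trait_history(tree, m, theta, root_state=0, seed=s)
            counts.append(sum(len(e) for e in hist.events.values()))
        counts = np.array(counts)
        se = counts.std(ddof=1) / np.sqrt(n_rep)
        assert abs(counts.mean() - expected) < 3 * se

    def test_seed_determinism(self):
        t = ph.simulate_tree(50, seed=0, scale_height=100)
        m = ph.build_hidden_rates_model(2, 1)
        a, _ = ph.simulate_trait_history(t, m, [0.01, 0.01], root_state=0, seed=3)
        b, _ = ph.simulate_trait_history(t, m, [0.01, 0.01], root_state=0, seed=3)
        assert a.states == b.states


class TestMaskStates:
    def test_zero_fraction_is_identity(self):
        tm = ph.TraitMatrix({f"t{i}": i % 2 for i in range(10)})
        assert ph.mask_states(tm, 0.0, seed=0).states == tm.states

    def test_exact_count_and_determinism(self):
        tm = ph.TraitMatrix({f"t{i}": i % 2 for i in range(100)})
        a = ph.mask_states(tm, 0.5, seed=1)
        assert len(a.unknown_labels()) == 50
        b = ph.mask_states(tm, 0.5, seed=1)
        assert a.states == b.states

    def test_invalid_fraction(self):
        tm = ph.TraitMatrix({"A": 0})
        with pytest.raises(ValueError):
            ph.mask_states(tm, 1.0)


class TestNfcLikeFixture:
    def test_default_profile_has_multiple_gains(self, small_fixture):
        assert small_fixture.history.true_gains() >= 2

    def test_rate_profile_ordering(self):
        model, theta = nfc_like_model_and_theta()
        sp = model.space
        Q = model.assemble_Q(theta)
        gain_inter = Q[sp.index(0, 2), sp.index(1, 2)]
        prec_to_inter = Q[sp.index(0, 1), sp.index(0, 2)]
        loss = Q[sp.index(1, 2), sp.index(0, 2)]
        assert gain_inter == pytest.approx(10 * prec_to_inter)
        assert gain_inter == pytest.approx(150 * loss)
        # non-precursor absent state is absorbing (negligible exit)
        assert -Q[sp.index(0, 0), sp.index(0, 0)] < 1e-6

    def test_outgroup_tips_all_absent(self, small_fixture):
        fx = small_fixture
        for lab in fx.clades["outgroup"]:
            assert fx.full_traits.states[lab] == 0

    def test_unknown_fraction_masks_tips(self):
        fx = ph.make_nfc_like_fixture(n_tips=120, unknown_fraction=0.1, seed=3)
        assert len(fx.traits.unknown_labels()) == 12
        assert not fx.full_traits.unknown_labels()

    def test_save_round_trips(self, tmp_path, small_fixture):
        small_fixture.save(tmp_path / "fx")
        t = ph.parse_newick(str(tmp_path / "fx" / "tree.nwk"))
        assert sorted(t.tip_labels) == sorted(small_fixture.tree.tip_labels)
        tm = ph.read_trait_table(tmp_path / "fx" / "traits.csv")
        assert tm.states == small_fixture.traits.states
        from phylohrm.models import RateModel

        m = RateModel.from_json(tmp_path / "fx" / "model.json")
        assert m.name == small_fixture.model.name
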