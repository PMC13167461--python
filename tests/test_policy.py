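"""Exit-criterion semantics: normalized entropy, patience dynamics, the
hybrid decision rule, and its degeneracy/composition invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import earlyexit as ee
from earlyexit.exceptions import (
    ConfigurationError,
    InvalidClassSpaceError,
    InvalidDistributionError,
    InvalidLayerError,
    InvalidTrajectoryError,
)
from earlyexit.policy import PatienceState

from conftest import make_trajectory, random_trajectories


class TestNormalizedEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 1.0),  # uniform: maximal
            ([0.0, 1.0, 0.0], 0.0),  # one-hot: fully confident
            ([1.0, 0.0], 0.0),
            ([0.5, 0.5, 0.0, 0.0], 0.5),  # log 2 / log 4
        ],
    )
    def test_closed_form_values(self, p, expected):
        assert ee.normalized_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidClassSpaceError):
            ee.normalized_entropy([1.0])
        with pytest.raises(InvalidDistributionError):
            ee.normalized_entropy([0.3, 0.3])
        with pytest.raises(InvalidDistributionError):
            ee.normalized_entropy([1.2, -0.2])

    @given(
        logits=arrays(
            float,
            st.integers(2, 9),
            elements=st.floats(-8, 8, allow_nan=False),
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_range_and_extremes(self, logits):
        p = np.exp(logits - logits.max())
        p /= p.sum()
        h = ee.normalized_entropy(p)
        assert 0.0 <= h <= 1.0 + 1e-12
        # equals 1 only for uniform, 0 only for one-hot
        if h > 1.0 - 1e-9:
            assert np.allclose(p, 1.0 / p.size, atol=1e-4)
        if h < 1e-9:
            assert np.isclose(p.max(), 1.0, atol=1e-4)

    def test_base_invariance(self):
        # log base cancels in the ratio: compare against a base-2 computation
        p = np.array([0.6, 0.25, 0.1, 0.05])
        h2 = -np.sum(p * np.log2(p)) / np.log2(p.size)
        assert ee.normalized_entropy(p) == pytest.approx(h2, abs=1e-12)


class TestArgmaxAndPatience:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.1, 0.7, 0.2], 1),
            ([0.4, 0.4, 0.2], 0),  # tie -> lowest index
            ([0.25, 0.25, 0.25, 0.25], 0),
        ],
    )
    def test_argmax_ties_to_lowest_index(self, p, expected):
        assert ee.argmax_class(p) == expected

    def test_argmax_empty_vector(self):
        with pytest.raises(InvalidDistributionError):
            ee.argmax_class([])

    def test_patience_increments_on_agreement(self):
        s = ee.update_patience(PatienceState(count=1, last_class=2), 2)
        assert (s.count, s.last_class) == (2, 2)

    def test_patience_resets_to_one_on_disagreement(self):
        s = ee.update_patience(PatienceState(count=3, last_class=0), 1)
        assert (s.count, s.last_class) == (1, 1)

    def test_first_observation_is_run_of_one(self):
        s = ee.update_patience(PatienceState(), 5)
        assert (s.count, s.last_class) == (1, 5)

    def test_counter_matches_run_length_counting(self):
        # brute-force run lengths of a class sequence
        rng = np.random.default_rng(0)
        classes = rng.integers(0, 3, size=50)
        state = PatienceState()
        for i, c in enumerate(classes):
            state = ee.update_patience(state, int(c))
            run = 1
            j = i
            while j >= 1 and classes[j] == classes[j - 1]:
                run += 1
                j -= 1
            assert state.count == run


class TestDecide:
    M = 12
    cfg = ee.PolicyConfig(mode="epee", tau=0.2, patience_threshold=3)

    def test_entropy_criterion_fires(self):
        assert ee.decide(0.05, 1, 2, self.cfg, self.M) is True

    def test_patience_criterion_fires(self):
        assert ee.decide(0.9, 3, 5, self.cfg, self.M) is True

    def test_neither_criterion_continues(self):
        assert ee.decide(0.9, 2, 5, self.cfg, self.M) is False

    def test_final_layer_always_exits(self):
        assert ee.decide(1.0, 1, self.M, self.cfg, self.M) is True

    def test_layer_out_of_range(self):
        with pytest.raises(InvalidLayerError):
            ee.decide(0.5, 1, 0, self.cfg, self.M)
        with pytest.raises(InvalidLayerError):
            ee.decide(0.5, 1, 13, self.cfg, self.M)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            ee.PolicyConfig(mode="epee", tau=1.5)
        with pytest.raises(ConfigurationError):
            ee.PolicyConfig(mode="epee", patience_threshold=0)
        with pytest.raises(ConfigurationError):
            ee.PolicyConfig(mode="magic")


class TestRunPolicy:
    def test_constant_argmax_exits_at_patience_threshold(self):
        # identical distributions at every layer: patience grows 1,2,...
        traj = np.tile([0.5, 0.3, 0.2], (6, 1))
        trace = ee.run_policy(traj, ee.PolicyConfig("epee", tau=0.0, patience_threshold=2))
        assert trace.exit_layer == 2
        assert trace.trigger == "patience"
        assert trace.patience_counts == [1, 2]

    def test_hand_simulated_mixed_criteria(self):
        # entropies fall below tau exactly when the patience run completes
        traj = make_trajectory([0.8, 0.7, 0.6, 0.3, 0.2], [2, 2, 1, 1, 1])
        trace = ee.run_policy(traj, ee.PolicyConfig("epee", tau=0.25, patience_threshold=3))
        assert trace.exit_layer == 5
        assert trace.predicted_class == 1
        assert trace.trigger == "both"
        assert trace.patience_counts == [1, 2, 1, 2, 3]

    def test_tau_one_exits_immediately_on_nonuniform(self):
        traj = make_trajectory([0.9, 0.5], [0, 1])
        trace = ee.run_policy(traj, ee.PolicyConfig("epee", tau=1.0, patience_threshold=2))
        assert trace.exit_layer == 1
        assert trace.trigger == "entropy"

    def test_patience_one_forces_first_layer_exit(self):
        traj = make_trajectory([0.99, 0.2, 0.1], [0, 1, 2])
        trace = ee.run_policy(traj, ee.PolicyConfig("epee", tau=0.0, patience_threshold=1))
        assert trace.exit_layer == 1

    def test_trace_lengths_match_exit_layer(self):
        traj = make_trajectory([0.9, 0.9, 0.05], [0, 1, 2])
        trace = ee.run_policy(traj, ee.PolicyConfig("epee", tau=0.1, patience_threshold=3))
        assert len(trace.entropies) == len(trace.patience_counts) == trace.exit_layer

    def test_empty_trajectory_rejected(self):
        with pytest.raises(InvalidTrajectoryError):
            ee.run_policy(np.empty((0, 3)), ee.PolicyConfig())


class TestOracleAndInvariants:
    def _policies(self, rng, M):
        tau = float(rng.choice([0.0, 0.05, 0.2, 0.5, 0.9, 1.0]))
        pt = int(rng.integers(1, M + 1))
        return ee.PolicyConfig("epee", tau=tau, patience_threshold=pt)

    def test_run_policy_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for traj in random_trajectories(rng, 400):
            cfg = self._policies(rng, traj.shape[0])
            assert ee.run_policy(traj, cfg).exit_layer == ee.exit_layer_oracle(traj, cfg)

    def test_min_composition(self):
        # hybrid exit layer = min(entropy-only, patience-only) on any input
        rng = np.random.default_rng(43)
        for traj in random_trajectories(rng, 300):
            M = traj.shape[0]
            tau = float(rng.choice([0.05, 0.2, 0.5, 0.9]))
            pt = int(rng.integers(1, M + 1))
            hybrid = ee.run_policy(
                traj, ee.PolicyConfig("epee", tau=tau, patience_threshold=pt)
            ).exit_layer
            ent = ee.run_policy(traj, ee.PolicyConfig("entropy", tau=tau)).exit_layer
            pat = ee.run_policy(
                traj, ee.PolicyConfig("patience", patience_threshold=pt)
            ).exit_layer
            assert hybrid == min(ent, pat)

    def test_exit_layer_monotone_in_tau_and_patience(self):
        rng = np.random.default_rng(44)
        taus = [0.0, 0.1, 0.3, 0.6, 1.0]
        for traj in random_trajectories(rng, 120):
            M = traj.shape[0]
            pt = int(rng.integers(1, M + 1))
            exits = [
                ee.run_policy(traj, ee.PolicyConfig("epee", tau=t, patience_threshold=pt)).exit_layer
                for t in taus
            ]
            assert all(a >= b for a, b in zip(exits, exits[1:]))  # non-increasing in tau
            tau = float(rng.choice(taus))
            exits_p = [
                ee.run_policy(traj, ee.PolicyConfig("epee", tau=tau, patience_threshold=p)).exit_layer
                for p in range(1, M + 1)
            ]
            assert all(a <= b for a, b in zip(exits_p, exits_p[1:]))  # non-decreasing in P_t

    def test_degeneracy_to_single_criterion_policies(self):
        # tau=0 silences the strict entropy test; P_t=M silences patience
        rng = np.random.default_rng(45)
        for traj in random_trajectories(rng, 200):
            M = traj.shape[0]
            pt = int(rng.integers(1, M + 1))
            a = ee.run_policy(traj, ee.PolicyConfig("epee", tau=0.0, patience_threshold=pt))
            b = ee.run_policy(traj, ee.PolicyConfig("patience", patience_threshold=pt))
            assert a.to_dict() == b.to_dict()
            tau = float(rng.uniform(0, 1))
            c = ee.run_policy(traj, ee.PolicyConfig("epee", tau=tau, patience_threshold=M))
            d = ee.run_policy(traj, ee.PolicyConfig("entropy", tau=tau))
            assert c.to_dict() == d.to_dict()

    def test_degeneracy_with_one_hot_predictions_and_zero_tau(self):
        # strict inequality: H=0 does not satisfy H < 0
        traj = np.zeros((4, 3))
        traj[0, 0] = traj[1, 1] = traj[2, 2] = traj[3, 0] = 1.0
        trace = ee.run_policy(traj, ee.PolicyConfig("epee", tau=0.0, patience_threshold=4))
        assert trace.exit_layer == 4
        assert trace.trigger == "final_layer"

    def test_oracle_special_cases(self):
        rng = np.random.default_rng(46)
        for traj in random_trajectories(rng, 100):
            M = traj.shape[0]
            # tau=0: first layer whose terminal run length reaches P_t
            pt = int(rng.integers(1, M + 1))
            cfg = ee.PolicyConfig("epee", tau=0.0, patience_threshold=pt)
            argmaxes = traj.argmax(axis=1)
            expected = M
            for m in range(M):
                run = 1
                j = m
                while j >= 1 and argmaxes[j] == argmaxes[j - 1]:
                    run += 1
                    j -= 1
                if run >= pt:
                    expected = m + 1
                    break
            assert ee.exit_layer_oracle(traj, cfg) == expected
            # P_t=M: first layer with entropy < tau, else M
            tau = float(rng.uniform(0, 1))
            cfg2 = ee.PolicyConfig("epee", tau=tau, patience_threshold=M)
            ents = [ee.normalized_entropy(p) for p in traj]
            below = [i + 1 for i, h in enumerate(ents) if h < tau]
            assert ee.exit_layer_oracle(traj, cfg2) == (below[0] if below else M)
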