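import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adherclust import (
    Cohort,
    StateSpace,
    Trajectory,
    build_feature_vector,
    devectorize,
    estimate_joint_transition_matrix,
    estimate_order2_joint,
    estimate_state_proportions,
    feature_matrix,
    row_normalize,
    vectorize,
)

state_seq = st.lists(st.sampled_from([0, 1, 2]), min_size=3, max_size=20)


def traj_of(codes, space):
    return Trajectory("s", space.decode(codes))


class TestProportions:
    def test_hand_counted_proportions_of_printed_sequence(self, space, worked_example):
        p = estimate_state_proportions(worked_example[0], space)
        assert np.allclose(p.values, [5 / 12, 4 / 12, 3 / 12])

    def test_all_three_printed_individuals_coincide(self, space, worked_example):
        vecs = [estimate_state_proportions(t, space).values for t in worked_example]
        assert np.allclose(vecs[0], vecs[1]) and np.allclose(vecs[1], vecs[2])

    def test_constant_sequence_is_degenerate(self, space):
        p = estimate_state_proportions(Trajectory("c", tuple("11111")), space)
        assert np.allclose(p.values, [0, 1, 0])


class TestJointTransitionMatrix:
    def test_enumerated_pairs_of_printed_sequence(self, space, worked_example):
        q = estimate_joint_transition_matrix(worked_example[0], space)
        i0, i1, i9 = (space.index(s) for s in "019")
        expected = np.zeros((3, 3))
        expected[i9, i9] = 2 / 11
        expected[i9, i0] = 1 / 11
        expected[i0, i0] = 4 / 11
        expected[i0, i1] = 1 / 11
        expected[i1, i1] = 3 / 11
        assert np.allclose(q.values, expected)
        assert q.n_transitions == 11

    def test_second_and_third_individuals_share_q(self, space, worked_example):
        q2 = estimate_joint_transition_matrix(worked_example[1], space)
        q3 = estimate_joint_transition_matrix(worked_example[2], space)
        assert np.allclose(q2.values, q3.values)

    def test_constant_sequence_single_cell(self, space):
        q = estimate_joint_transition_matrix(Trajectory("c", tuple("1111")), space)
        i1 = space.index("1")
        assert q.values[i1, i1] == 1.0 and q.values.sum() == 1.0

    def test_span_shorter_than_one_transition_rejected(self, space, worked_example):
        with pytest.raises(ValueError):
            estimate_joint_transition_matrix(worked_example[0], space, 5, 5)


class TestRowNormalize:
    def test_printed_sequence_conditional_row(self, space, worked_example):
        q = estimate_joint_transition_matrix(worked_example[0], space)
        p = row_normalize(q)
        i0 = space.index("0")
        assert np.allclose(p.values[i0], [4 / 5, 1 / 5, 0])

    def test_zero_rows_flagged_not_raised(self, space):
        q = estimate_joint_transition_matrix(Trajectory("c", tuple("1111")), space)
        p = row_normalize(q)
        assert p.defined_rows.tolist() == [False, True, False]
        assert np.allclose(p.values[space.index("1")], [0, 1, 0])
        assert np.isnan(p.values[space.index("0")]).all()


class TestVectorize:
    def test_column_major_stacking(self):
        space = StateSpace(("a", "b"))
        from adherclust.markov_features import JointTransitionMatrix

        q = JointTransitionMatrix(np.array([[0.1, 0.2], [0.3, 0.4]]), 10, space)
        z = vectorize(q)
        assert np.allclose(z.values, [0.1, 0.3, 0.2, 0.4])

    def test_devectorize_inverts(self, space, worked_example):
        q = estimate_joint_transition_matrix(worked_example[0], space)
        assert np.allclose(devectorize(vectorize(q), space), q.values)


class TestFeatureVector:
    def test_m3_distinguishes_what_m2_cannot(self, space, worked_example):
        m2 = [build_feature_vector(t, space, "M2").values for t in worked_example]
        assert np.allclose(m2[1], m2[2]) and not np.allclose(m2[0], m2[1])
        m3 = [build_feature_vector(t, space, "M3", t1=6).values for t in worked_example]
        for a in range(3):
            for b in range(a + 1, 3):
                assert not np.allclose(m3[a], m3[b])

    def test_m3_halves_each_normalized(self, space, worked_example):
        z = build_feature_vector(worked_example[1], space, "M3", t1=6)
        S2 = space.n_states ** 2
        assert z.values[:S2].sum() == pytest.approx(1.0, abs=1e-12)
        assert z.values[S2:].sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("t1", [1, 12, 0])
    def test_invalid_change_point_rejected(self, space, worked_example, t1):
        with pytest.raises(ValueError):
            build_feature_vector(worked_example[0], space, "M3", t1=t1)

    def test_m3_requires_change_point(self, space, worked_example):
        with pytest.raises(ValueError):
            build_feature_vector(worked_example[0], space, "M3")

    def test_cohort_feature_matrix_matches_per_subject_path(self, space, rng):
        codes = rng.integers(0, 3, size=(20, 12))
        co = Cohort.from_codes(space, codes)
        for model, t1 in (("M1", None), ("M2", None), ("M3", 6)):
            X = feature_matrix(co, model, t1=t1)
            for row, tr in zip(X, co.trajectories):
                z = build_feature_vector(tr, space, model, t1=t1)
                assert np.allclose(row, z.values)


class TestOrder2:
    def test_enumerated_triples_of_printed_sequence(self, space, worked_example):
        o2 = estimate_order2_joint(worked_example[0], space)
        i0, i9 = space.index("0"), space.index("9")
        assert o2.values[i9, i9, i9] == pytest.approx(1 / 10)
        assert o2.values[i0, i0, i0] == pytest.approx(3 / 10)
        assert o2.n_triples == 10

    def test_constant_sequence_single_cell(self, space):
        o2 = estimate_order2_joint(Trajectory("c", tuple("111")), space)
        i1 = space.index("1")
        assert o2.values[i1, i1, i1] == 1.0

    def test_too_short_rejected(self, space):
        with pytest.raises(ValueError):
            estimate_order2_joint(Trajectory("s", tuple("01")), space)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(codes=st.lists(st.sampled_from([0, 1, 2]), min_size=3, max_size=15))
    def test_marginalizing_first_index_gives_late_span_q(self, codes):
        """Summing the triple array over X_{t-2} reproduces Q of visits 2..T."""
        space = StateSpace(("0", "1", "9"), missing_label="9")
        tr = traj_of(codes, space)
        o2 = estimate_order2_joint(tr, space)
        q_late = estimate_joint_transition_matrix(tr, space, 2, len(codes))
        assert np.allclose(o2.values.sum(axis=0), q_late.values)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(codes=state_seq)
def test_q_margins_are_visit_proportions(codes):
    """Row sums of Q are occupancy over visits 1..T-1; columns over 2..T."""
    space = StateSpace(("0", "1", "9"), missing_label="9")
    tr = traj_of(codes, space)
    q = estimate_joint_transition_matrix(tr, space)
    T = len(codes)
    first = np.bincount(codes[:-1], minlength=3) / (T - 1)
    last = np.bincount(codes[1:], minlength=3) / (T - 1)
    assert np.allclose(q.values.sum(axis=1), first)
    assert np.allclose(q.values.sum(axis=0), last)
    assert q.values.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(codes=state_seq)
def test_proportions_recoverable_from_q_and_endpoints(codes):
    """T*P_s = (T-1)*rowsum_s(Q) + I(X_T = s)."""
    space = StateSpace(("0", "1", "9"), missing_label="9")
    tr = traj_of(codes, space)
    T = len(codes)
    p = estimate_state_proportions(tr, space).values
    q = estimate_joint_transition_matrix(tr, space)
    rebuilt = ((T - 1) * q.values.sum(axis=1) + np.eye(3)[codes[-1]]) / T
    assert np.allclose(p, rebuilt)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(codes=state_seq, perm=st.permutations([0, 1, 2]))
def test_state_relabelling_permutes_q_consistently(codes, perm):
    """Permuting state labels permutes Q's rows and columns the same way."""
    space = StateSpace(("0", "1", "9"), missing_label="9")
    q = estimate_joint_transition_matrix(traj_of(codes, space), space).values
    permuted_codes = [perm[c] for c in codes]
    qp = estimate_joint_transition_matrix(traj_of(permuted_codes, space), space).values
    perm = list(perm)
    assert np.allclose(qp[np.ix_(perm, perm)], q)
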