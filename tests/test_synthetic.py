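import numpy as np
import pytest

from dfcstates import (CohortSpec, StateSpec, make_state_covariances,
                       simulate_cohort, simulate_state_sequence,
                       simulate_subject)
from dfcstates.io import BehaviorTable
from dfcstates.synthetic import (ParameterError, default_base_occupancy,
                                 shifted_occupancy, transition_matrix)


class TestStateCovariances:
    def test_k5_structure(self, parcellation, state_spec):
        assert state_spec.K == 5
        sm = parcellation.rois_in("SM")
        seg = state_spec.covariances[0]
        within_sm = seg[np.ix_(sm, sm)][np.triu_indices(len(sm), 1)]
        assert within_sm.mean() > 0.4
        sparse = state_spec.covariances[-1]
        off = sparse[np.triu_indices(53, 1)]
        assert np.abs(off).mean() < 0.05

    def test_all_unit_diagonal_positive_definite(self, state_spec):
        for C in state_spec.covariances:
            np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
            assert np.linalg.eigvalsh(C).min() > 1e-6
            np.testing.assert_allclose(C, C.T, atol=1e-12)

    def test_k2_gives_distinct_states(self, parcellation):
        spec = make_state_covariances(parcellation, K=2, seed=0)
        d = np.linalg.norm(spec.covariances[0] - spec.covariances[1])
        assert d > 0

    def test_same_seed_reproducible(self, parcellation):
        a = make_state_covariances(parcellation, K=4, seed=9)
        b = make_state_covariances(parcellation, K=4, seed=9)
        for Ca, Cb in zip(a.covariances, b.covariances):
            np.testing.assert_array_equal(Ca, Cb)

    def test_k_below_two_rejected(self, parcellation):
        with pytest.raises(ParameterError):
            make_state_covariances(parcellation, K=1, seed=0)


class TestStateSequence:
    def test_degenerate_occupancy_constant_sequence(self, state_spec):
        spec = StateSpec(covariances=state_spec.covariances,
                         base_occupancy=[1.0, 0.0, 0.0, 0.0, 0.0])
        seq = simulate_state_sequence(spec, 500, seed=0)
        assert (seq == 0).all()

    def test_stationary_distribution_matches_base(self, state_spec):
        seq = simulate_state_sequence(state_spec, 100_000, seed=3)
        emp = np.bincount(seq, minlength=5) / len(seq)
        assert np.abs(emp - state_spec.base_occupancy).max() < 0.01

    def test_mean_dwell_matches_request(self, parcellation):
        # Monte-Carlo oracle: with equal occupancy the run-length
        # distribution is geometric with the requested mean
        dwell = 20.0
        spec = StateSpec(covariances=make_state_covariances(
            parcellation, K=4, seed=1).covariances,
            dwell_mean_windows=dwell, base_occupancy=[0.25] * 4)
        seq = simulate_state_sequence(spec, 200_000, seed=5)
        change = np.flatnonzero(np.r_[True, np.diff(seq) != 0, True])
        runs = np.diff(change)
        n = len(runs)
        sem = dwell / np.sqrt(n)    # geometric sd ~ mean
        assert abs(runs.mean() - dwell) < 1.96 * sem * 1.5

    def test_infeasible_dwell_raises(self):
        with pytest.raises(ParameterError):
            transition_matrix(np.array([0.97, 0.03]), 2.0)

    def test_transition_matrix_exactly_stationary(self):
        pi = np.array([0.12, 0.1467, 0.1467, 0.1466, 0.44])
        P = transition_matrix(pi, 4.0)
        np.testing.assert_allclose(pi @ P, pi, atol=1e-12)
        np.testing.assert_allclose(P.sum(1), 1.0, atol=1e-12)
        assert (P >= 0).all()


class TestShiftedOccupancy:
    def test_zero_effect_identity(self):
        base = default_base_occupancy(5)
        np.testing.assert_array_equal(shifted_occupancy(base, 0.0, 2.0), base)

    def test_shift_moves_mass_between_endpoints_only(self):
        base = default_base_occupancy(5)
        shifted = shifted_occupancy(base, 0.5, 2.0)
        assert shifted[0] > base[0]
        assert shifted[-1] < base[-1]
        np.testing.assert_allclose(shifted[1:-1], base[1:-1], atol=1e-15)
        np.testing.assert_allclose(shifted.sum(), 1.0, atol=1e-12)


class TestSimulateSubject:
    def test_positive_trait_raises_first_state_occupancy(self, state_spec):
        cohort = CohortSpec(n_subjects=1, T=2000, seed=0, occupancy_effect=1.0)
        _, occ_hi, _ = simulate_subject(state_spec, cohort, 3.0, seed=11)
        _, occ_lo, _ = simulate_subject(state_spec, cohort, 0.0, seed=11)
        assert occ_hi[0] > occ_lo[0]

    def test_single_state_segment_covariance_recovered(self, state_spec):
        # sampling-error oracle: 2000 samples from one state's MVN
        spec = StateSpec(covariances=state_spec.covariances,
                         base_occupancy=[1.0, 0, 0, 0, 0])
        cohort = CohortSpec(n_subjects=1, T=2000, noise_sd=0.0, seed=0)
        scans, _, _ = simulate_subject(spec, cohort, 0.0, seed=4)[0], None, None
        X = scans[0].data
        sample_corr = np.corrcoef(X.T)
        assert np.abs(sample_corr - state_spec.covariances[0]).max() < 0.1

    def test_occupancy_sums_to_one(self, state_spec):
        cohort = CohortSpec(n_subjects=1, scans_per_subject=2, seed=0)
        _, occ, seqs = simulate_subject(state_spec, cohort, 0.5, seed=2)
        np.testing.assert_allclose(occ.sum(), 1.0, atol=1e-12)
        assert len(seqs) == 2


class TestSimulateCohort:
    def test_cohort_shapes_and_validation(self, small_cohort):
        scans, behavior, truth = small_cohort
        assert len(scans) == 12
        assert isinstance(behavior, BehaviorTable)
        assert behavior.n_subjects == 12
        assert truth.realized_occupancy.shape == (12, 5)
        np.testing.assert_allclose(truth.realized_occupancy.sum(1), 1.0,
                                   atol=1e-9)

    def test_determinism_same_seed(self, state_spec):
        cohort = CohortSpec(n_subjects=3, seed=77)
        s1, b1, t1 = simulate_cohort(state_spec, cohort)
        s2, b2, t2 = simulate_cohort(state_spec, cohort)
        for sid in s1:
            np.testing.assert_array_equal(s1[sid][0].data, s2[sid][0].data)
        np.testing.assert_array_equal(t1.traits, t2.traits)
        assert b1.table.equals(b2.table)

    def test_null_occupancy_effect_recovers_base(self, state_spec):
        cohort = CohortSpec(n_subjects=200, T=80, occupancy_effect=0.0,
                            seed=5)
        _, _, truth = simulate_cohort(state_spec, cohort)
        mae = np.abs(truth.expected_occupancy
                     - state_spec.base_occupancy).mean()
        assert mae < 0.02

    def test_mediation_truth_bookkeeping(self, state_spec):
        cohort = CohortSpec(n_subjects=3, T=80, seed=1,
                            mediation={"a": 0.0, "b": 0.5, "c_prime": 0.2})
        _, _, truth = simulate_cohort(state_spec, cohort)
        assert truth.true_ab == 0.0
        cohort = CohortSpec(n_subjects=3, T=80, seed=1,
                            mediation={"a": 0.5, "b": 0.5, "c_prime": 0.0})
        _, _, truth = simulate_cohort(state_spec, cohort)
        assert truth.true_proportion_mediated == pytest.approx(1.0)

    def test_ols_path_identity_in_expectation(self, state_spec):
        # linear-model identity: total effect c = c' + a*b on generated data
        cohort = CohortSpec(n_subjects=2000, T=80, seed=3,
                            site_sd=0.0, family_sd=0.0)
        _, behavior, truth = simulate_cohort(state_spec, cohort)
        x = (truth.realized_occupancy[:, 0]
             - truth.realized_occupancy[:, 0].mean())
        x /= x.std()
        m = behavior.table["cbcl_attention"].to_numpy()
        y = behavior.table["nihtbx_fluid"].to_numpy()
        X1 = np.column_stack([np.ones_like(x), x])
        a_hat = np.linalg.lstsq(X1, m, rcond=None)[0][1]
        c_hat = np.linalg.lstsq(X1, y, rcond=None)[0][1]
        X2 = np.column_stack([np.ones_like(x), x, m])
        cb = np.linalg.lstsq(X2, y, rcond=None)[0]
        np.testing.assert_allclose(c_hat, cb[1] + a_hat * cb[2], atol=1e-10)

    def test_family_nested_within_site(self, small_cohort):
        _, behavior, _ = small_cohort
        per_family = behavior.table.groupby("family_id", observed=True)[
            "site_id"].nunique()
        assert (per_family == 1).all()
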