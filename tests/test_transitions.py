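from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from mbtemporal import transitions as tr


def series(labels_by_participant):
    """Build (labels, participants, days) series from {pid: [states]}."""
    sids, labs, parts, days = [], [], [], []
    for pid, seq in labels_by_participant.items():
        for d, s in enumerate(seq):
            sids.append(f"{pid}_{d}")
            labs.append(s)
            parts.append(pid)
            days.append(d)
    idx = pd.Index(sids, name="sample_id")
    return (pd.Series(labs, index=idx), pd.Series(parts, index=idx),
            pd.Series(days, index=idx))


class TestTransitionNull:
    def test_hand_example(self):
        """Labels A,A,B: expected probs {AA: 1/3, AB: 2/3}; observed 1 each."""
        labels, parts, days = series({"p": ["A", "A", "B"]})
        res = tr.transition_null(labels, parts, days)
        t = res.table.set_index(["state_a", "state_b"])
        assert t.loc[("A", "A"), "expected_prob"] == pytest.approx(1 / 3)
        assert t.loc[("A", "B"), "expected_prob"] == pytest.approx(2 / 3)
        assert t.loc[("A", "A"), "observed"] == 1
        assert t.loc[("A", "B"), "observed"] == 1
        assert t.loc[("A", "A"), "expected"] == pytest.approx(2 / 3)
        assert t.loc[("A", "B"), "expected"] == pytest.approx(4 / 3)

    def test_single_state(self):
        labels, parts, days = series({"p": ["A"] * 5, "q": ["A"] * 4})
        res = tr.transition_null(labels, parts, days)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_probs_sum_to_one_and_match_enumeration(self, rng):
        """Expected probabilities equal exhaustive unordered-pair counting on
        instances with <= 12 samples."""
        for _ in range(300):
            n_parts = int(rng.integers(1, 4))
            labels_by = {}
            total = 0
            for p in range(n_parts):
                k = int(rng.integers(2, 6))
                if total + k > 12:
                    k = max(2, 12 - total)
                total += k
                labels_by[f"p{p}"] = list(rng.choice(list("ABCD"), size=k))
            labels, parts, days = series(labels_by)
            res = tr.transition_null(labels, parts, days)
            assert res.table["expected_prob"].sum() == pytest.approx(1.0)
            # oracle: enumerate all unordered pairs of pooled samples
            pool = list(labels)
            pairs = list(combinations(range(len(pool)), 2))
            for _, row in res.table.iterrows():
                a, b = row["state_a"], row["state_b"]
                cnt = sum(1 for i, j in pairs
                          if {pool[i], pool[j]} == ({a, b} if a != b else {a}))
                assert row["expected_prob"] == pytest.approx(cnt / len(pairs))
            assert res.table["observed"].sum() == res.n_transitions

    def test_residual_formula(self):
        labels, parts, days = series({"p": ["A", "A", "A", "B", "B"]})
        res = tr.transition_null(labels, parts, days)
        t = res.table.set_index(["state_a", "state_b"])
        for key in [("A", "A"), ("A", "B"), ("B", "B")]:
            o, e, pr = t.loc[key, ["observed", "expected", "expected_prob"]]
            assert t.loc[key, "std_residual"] == pytest.approx(
                (o - e) / np.sqrt(e * (1 - pr)))


class TestConstellation:
    def test_hand_matrix_medians(self):
        ids = ["a", "b", "c", "d"]
        d = pd.DataFrame(
            [[0.0, 0.1, 0.5, 0.6],
             [0.1, 0.0, 0.7, 0.8],
             [0.5, 0.7, 0.0, 0.2],
             [0.6, 0.8, 0.2, 0.0]], index=ids, columns=ids)
        labels = pd.Series(["X", "X", "Y", "Y"], index=ids)
        res = tr.constellation_dissimilarity(d, labels)
        med = res["pair_medians"]
        assert med[("X", "X")] == pytest.approx(0.1)
        assert med[("Y", "Y")] == pytest.approx(0.2)
        assert med[("X", "Y")] == pytest.approx(np.median([0.5, 0.6, 0.7, 0.8]))

    def test_identical_states_equal_medians(self):
        ids = list("abcd")
        d = pd.DataFrame(0.3 * (1 - np.eye(4)), index=ids, columns=ids)
        labels = pd.Series(["X", "Y", "X", "Y"], index=ids)
        med = tr.constellation_dissimilarity(d, labels)["pair_medians"]
        assert med[("X", "X")] == med[("X", "Y")] == med[("Y", "Y")]

    def test_within_subject_majority_grouping(self):
        ids = [f"s{i}" for i in range(6)]
        d = pd.DataFrame(0.4 * (1 - np.eye(6)), index=ids, columns=ids)
        labels = pd.Series(["X", "X", "Y", "Y", "Y", "Y"], index=ids)
        parts = pd.Series(["p1", "p1", "p1", "p2", "p2", "p2"], index=ids)
        res = tr.constellation_dissimilarity(d, labels, participants=parts)
        ws = res["within_subject"].set_index("participant_id")
        assert ws.loc["p1", "majority_state"] in {"X", "Y"}
        assert ws.loc["p2", "majority_state"] == "Y"


class TestConsecutiveShift:
    def test_null_uniform_rejection_rate(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 300
        for r in range(reps):
            n = 40
            ids = [f"s{i}" for i in range(n)]
            vals = rng.uniform(0.2, 0.8, size=(n, n))
            d = pd.DataFrame((vals + vals.T) / 2, index=ids, columns=ids)
            np.fill_diagonal(d.values, 0)
            labels = pd.Series(rng.choice(["A", "B"], size=n), index=ids)
            parts = pd.Series(["p"] * n, index=ids)
            res = tr.consecutive_shift_test(d, labels, parts, seed=r)
            if res["p"] is not None:
                hits += res["p"] < 0.05
        assert abs(hits / reps - 0.05) <= 0.04

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 60
        for r in range(reps):
            n = 122
            ids = [f"s{i}" for i in range(n)]
            labels = pd.Series(rng.choice(["A", "B"], size=n), index=ids)
            vals = rng.uniform(0.3, 0.5, size=(n, n))
            d = (vals + vals.T) / 2
            for i in range(n - 1):
                if labels.iloc[i] != labels.iloc[i + 1]:
                    d[i, i + 1] += 0.2
                    d[i + 1, i] += 0.2
            dd = pd.DataFrame(d, index=ids, columns=ids)
            parts = pd.Series(["p"] * n, index=ids)
            res = tr.consecutive_shift_test(dd, labels, parts, seed=r)
            hits += res["p"] < 0.05
        assert hits / reps >= 0.9


class TestCTMC:
    def test_generator_and_transition_matrix_invariants(self, rng):
        for _ in range(20):
            K = int(rng.integers(2, 5))
            q = rng.uniform(0.01, 0.5, size=(K, K))
            np.fill_diagonal(q, 0)
            np.fill_diagonal(q, -q.sum(axis=1))
            assert np.allclose(q.sum(axis=1), 0)
            t = float(rng.uniform(0.1, 10))
            P = tr._batched_expm(np.array([q * t]))[0]
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert (P >= 0).all()
            assert np.allclose(P, expm(q * t), atol=1e-10)

    def test_zero_beta_risk_ratios_are_one(self):
        model = tr.CTMCModel(states=[0, 1], q_matrix=np.array([[-0.1, 0.1], [0.2, -0.2]]),
                             betas=np.zeros((2, 1)), covariates=["z"],
                             transitions=[(0, 1), (1, 0)], log_likelihood=0.0,
                             n_params=4, n_obs=10, theta=np.zeros(4),
                             cov_theta=np.eye(4) * 0.01, converged=True)
        rr = model.risk_ratios()
        assert (rr["risk_ratio"] == 1.0).all()

    def test_intensity_recovery_two_state(self):
        q0 = np.array([[-0.1, 0.1], [0.2, -0.2]])
        df = tr.simulate_ctmc(q0, None, np.zeros(150), 30, seed=2)
        m = tr.ctmc_fit(df, 2, compute_cov=False)
        assert m.q_matrix[0, 1] == pytest.approx(0.1, abs=0.03)
        assert m.q_matrix[1, 0] == pytest.approx(0.2, abs=0.05)

    def test_covariate_recovery_and_lr(self):
        q0 = np.array([[-0.1, 0.1], [0.2, -0.2]])
        z = np.random.default_rng(3).choice([-1.0, 0.0, 1.0], size=150)
        df = tr.simulate_ctmc(q0, np.array([0.7, 0.7]), z, 30, seed=4)
        with_cov = tr.ctmc_fit(df, 2, covariates=["z"])
        without = tr.ctmc_fit(df, 2, compute_cov=False)
        rr = with_cov.risk_ratios()
        assert rr["risk_ratio"].between(1.5, 2.7).all()  # truth e^0.7 ~ 2.01
        res = tr.ctmc_covariate_test(with_cov, without)
        assert res["p"] < 0.001
        assert res["df"] == 2

    def test_identical_models_lr_zero(self):
        q0 = np.array([[-0.1, 0.1], [0.2, -0.2]])
        df = tr.simulate_ctmc(q0, None, np.zeros(30), 15, seed=5)
        m1 = tr.ctmc_fit(df, 2, compute_cov=False)
        res = tr.ctmc_covariate_test(m1, m1)
        assert res["statistic"] == 0.0
        assert res["p"] == 1.0

    def test_non_nested_rejected(self):
        q0 = np.array([[-0.1, 0.1], [0.2, -0.2]])
        df = tr.simulate_ctmc(q0, None, np.zeros(20), 10, seed=6)
        m1 = tr.ctmc_fit(df, 2, compute_cov=False)
        df2 = tr.simulate_ctmc(q0, None, np.zeros(25), 10, seed=7)
        m2 = tr.ctmc_fit(df2, 2, compute_cov=False)
        with pytest.raises(ValueError):
            tr.ctmc_covariate_test(m1, m2)
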