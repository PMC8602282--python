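"""Enterotype stability: transition null model, constellation dissimilarity,
consecutive-shift testing, and a continuous-time Markov model (CTMC) with
covariate-modulated transition intensities.

The transition null compares observed consecutive-sample enterotype switches
with expectations from enterotype prevalence: the expected probability of an
unordered {A,B} pair is ``n_A n_B / C(N,2)`` (A != B) or ``C(n_A,2)/C(N,2)``
(A == B), with ``n_A`` the pooled number of samples labeled A. The CTMC is
observed as snapshots at collection times; intensities are
``q_rs(z) = q0_rs exp(beta_rs . z)`` and the likelihood multiplies matrix
exponentials ``P(t; z) = expm(Q(z) t)`` over successive observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.tools.numdiff import approx_hess1


# ---------------------------------------------------------------------------
# transition null model

@dataclass
class TransitionSummary:
    table: pd.DataFrame  # per unordered state pair
    chi2: float
    p: float
    n_transitions: int

    def to_json_dict(self):
        return {"chi2": self.chi2, "p": self.p, "n_transitions": self.n_transitions,
                "table": self.table.to_dict(orient="records")}


def _pair_key(a, b):
    return tuple(sorted((a, b)))


def transition_null(
    labels: pd.Series,
    participants: pd.Series,
    days: pd.Series | None = None,
    dist: pd.DataFrame | None = None,
    states: list | None = None,
    residual_mode: str = "gof",
) -> TransitionSummary:
    """Observed vs. expected enterotype transition counts.

    Transitions are counted between consecutive collected samples within a
    participant, direction-collapsed to unordered pairs. Expected pair
    probabilities come from pooled enterotype prevalence. Standardized
    residuals are ``(O - E)/sqrt(E (1 - p_i))`` (``residual_mode='pearson'``
    drops the ``1 - p_i`` factor). Median Bray-Curtis dissimilarity per
    constellation is attached when ``dist`` is given.
    """
    participants = participants.loc[labels.index]
    if days is None:
        days = pd.Series(np.arange(len(labels)), index=labels.index)
    observed: dict[tuple, int] = {}
    for pid in participants.unique():
        sids = labels.index[participants == pid]
        sids = sids[np.argsort(days.loc[sids].to_numpy())]
        seq = labels.loc[sids].to_numpy()
        for a, b in zip(seq[:-1], seq[1:]):
            key = _pair_key(a, b)
            observed[key] = observed.get(key, 0) + 1

    counts = labels.value_counts()
    if states is None:
        states = sorted(counts.index)
    N = int(counts.sum())
    total_pairs = N * (N - 1) / 2
    rows = []
    n_trans = sum(observed.values())
    for a, b in combinations_with_replacement(states, 2):
        n_a = int(counts.get(a, 0))
        n_b = int(counts.get(b, 0))
        if a == b:
            prob = n_a * (n_a - 1) / 2 / total_pairs
        else:
            prob = n_a * n_b / total_pairs
        obs = observed.get(_pair_key(a, b), 0)
        if prob == 0 and obs > 0:
            raise ValueError(f"observed transition {a}-{b} has expected probability 0")
        rows.append({"state_a": a, "state_b": b, "observed": obs, "expected_prob": prob})
    df = pd.DataFrame(rows)
    df["expected"] = df["expected_prob"] * n_trans
    if residual_mode == "gof":
        denom = np.sqrt(df["expected"] * (1 - df["expected_prob"]))
    else:
        denom = np.sqrt(df["expected"])
    with np.errstate(divide="ignore", invalid="ignore"):
        df["std_residual"] = (df["observed"] - df["expected"]) / denom
    nonzero = df["expected"] > 0
    chi2 = float((((df["observed"] - df["expected"]) ** 2 / df["expected"])[nonzero]).sum())
    dof = int(nonzero.sum()) - 1
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    if dist is not None:
        med = constellation_dissimilarity(dist, labels)["pair_medians"]
        df["median_bc"] = [med.get(_pair_key(a, b), np.nan)
                           for a, b in zip(df["state_a"], df["state_b"])]
    return TransitionSummary(table=df, chi2=chi2, p=p, n_transitions=n_trans)


def constellation_dissimilarity(
    dist: pd.DataFrame,
    labels: pd.Series,
    participants: pd.Series | None = None,
    exclude_participants: list | None = None,
) -> dict:
    """Median Bray-Curtis dissimilarity per state constellation.

    ``pair_medians`` considers all sample pairs of the respective states.
    When ``participants`` is given, per-participant within-subject medians
    are also returned, grouped by the participant's majority enterotype.
    """
    labels = labels.loc[dist.index]
    d = dist.to_numpy()
    states = sorted(labels.unique())
    idx = {s: np.flatnonzero((labels == s).to_numpy()) for s in states}
    pair_medians = {}
    for a, b in combinations_with_replacement(states, 2):
        ia, ib = idx[a], idx[b]
        if a == b:
            if ia.size < 2:
                pair_medians[(a, b)] = np.nan
                continue
            sub = d[np.ix_(ia, ia)]
            vals = sub[np.triu_indices(ia.size, k=1)]
        else:
            vals = d[np.ix_(ia, ib)].ravel()
        pair_medians[_pair_key(a, b)] = float(np.median(vals)) if vals.size else np.nan
    out = {"pair_medians": pair_medians}
    if participants is not None:
        participants = participants.loc[dist.index]
        excl = set(exclude_participants or [])
        rows = []
        for pid in participants.unique():
            if pid in excl:
                continue
            ii = np.flatnonzero((participants == pid).to_numpy())
            if ii.size < 2:
                continue
            sub = d[np.ix_(ii, ii)]
            med = float(np.median(sub[np.triu_indices(ii.size, k=1)]))
            majority = labels.iloc[ii].mode().iloc[0]
            rows.append({"participant_id": pid, "majority_state": majority,
                         "within_median_bc": med})
        out["within_subject"] = pd.DataFrame(rows)
    return out


def consecutive_shift_test(
    dist: pd.DataFrame,
    labels: pd.Series,
    participants: pd.Series,
    days: pd.Series | None = None,
    seed: int = 0,
) -> dict:
    """Compare BC dissimilarity of same- vs. different-enterotyped
    consecutive sample pairs (two-sided rank-sum test, larger group
    subsampled to the smaller's size)."""
    rng = np.random.default_rng(seed)
    participants = participants.loc[labels.index]
    if days is None:
        days = pd.Series(np.arange(len(labels)), index=labels.index)
    same, diff = [], []
    for pid in participants.unique():
        sids = labels.index[participants == pid]
        sids = sids[np.argsort(days.loc[sids].to_numpy())]
        for s1, s2 in zip(sids[:-1], sids[1:]):
            bc = dist.loc[s1, s2]
            (same if labels.loc[s1] == labels.loc[s2] else diff).append(bc)
    if not same or not diff:
        return {"p": None, "n": 0, "same": same, "diff": diff}
    n = min(len(same), len(diff))
    same_a = rng.choice(np.asarray(same), size=n, replace=False)
    diff_a = rng.choice(np.asarray(diff), size=n, replace=False)
    _, p = stats.mannwhitneyu(same_a, diff_a, alternative="two-sided")
    return {"p": float(p), "n": n, "same": same, "diff": diff}


# ---------------------------------------------------------------------------
# continuous-time Markov model with covariates

@dataclass
class CTMCModel:
    states: list
    q_matrix: np.ndarray  # baseline generator (diagonal = -rowsum)
    betas: np.ndarray  # n_transitions x n_covariates
    covariates: list[str]
    transitions: list[tuple[int, int]]  # directed (from, to) index pairs
    log_likelihood: float
    n_params: int
    n_obs: int
    theta: np.ndarray
    cov_theta: np.ndarray | None
    converged: bool

    def risk_ratios(self, z: float = 1.0) -> pd.DataFrame:
        """exp(beta) per transition and covariate with 95% CI (per ``z``-unit
        increase); significant when the CI excludes 1."""
        rows = []
        nt = len(self.transitions)
        for ci, cov in enumerate(self.covariates):
            for ti, (r, s) in enumerate(self.transitions):
                b = self.betas[ti, ci]
                pidx = nt + ci * nt + ti
                se = (np.sqrt(self.cov_theta[pidx, pidx])
                      if self.cov_theta is not None else np.nan)
                lo, hi = np.exp(z * (b - 1.96 * se)), np.exp(z * (b + 1.96 * se))
                rows.append({"from": self.states[r], "to": self.states[s],
                             "covariate": cov, "risk_ratio": float(np.exp(z * b)),
                             "ci_low": float(lo), "ci_high": float(hi),
                             "significant": bool(lo > 1 or hi < 1)})
        return pd.DataFrame(rows)

    def to_json_dict(self):
        return {"states": list(map(str, self.states)),
                "q_matrix": self.q_matrix.tolist(),
                "betas": self.betas.tolist(), "covariates": self.covariates,
                "log_likelihood": self.log_likelihood}


def _batched_expm(Qt: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of small generators via batched
    eigendecomposition, with a scaling-and-squaring fallback on failure."""
    try:
        w, V = np.linalg.eig(Qt)
        expw = np.exp(w)
        M = V * expw[:, None, :]
        P = np.linalg.solve(V.transpose(0, 2, 1), M.transpose(0, 2, 1)).transpose(0, 2, 1)
        P = P.real
        err = np.abs(P.sum(axis=2) - 1.0).max()
        if not np.isfinite(err) or err > 1e-8:
            raise np.linalg.LinAlgError
        return np.clip(P, 0.0, None)
    except np.linalg.LinAlgError:
        return np.stack([np.clip(linalg.expm(q).real, 0.0, None) for q in Qt])


def _prepare_intervals(df: pd.DataFrame, covariates: list[str]):
    """Consecutive-observation intervals: (from, to, dt, z at interval start)."""
    frm, to, dts, zs = [], [], [], []
    for pid, sub in df.groupby("participant_id", sort=True):
        sub = sub.sort_values("day")
        s = sub["state"].to_numpy()
        d = sub["day"].to_numpy(dtype=float)
        z = sub[covariates].to_numpy(dtype=float) if covariates else np.zeros((len(sub), 0))
        frm.extend(s[:-1])
        to.extend(s[1:])
        dts.extend(np.diff(d))
        zs.extend(z[:-1])
    return (np.asarray(frm, dtype=int), np.asarray(to, dtype=int),
            np.asarray(dts, dtype=float), np.asarray(zs, dtype=float))


def ctmc_fit(
    data: pd.DataFrame,
    n_states: int,
    covariates: list[str] | None = None,
    max_iter: int = 500,
    compute_cov: bool = True,
    states: list | None = None,
) -> CTMCModel:
    """Maximum-likelihood CTMC fit from snapshot observations.

    ``data`` needs columns ``participant_id``, ``day``, ``state`` (integer
    codes 0..n_states-1) and any covariate columns (standardize them before
    fitting for comparable effect sizes). All directed transitions are
    allowed; intensities are log-parameterized. Standard errors come from
    the numerical Hessian at the optimum.
    """
    covariates = covariates or []
    K = n_states
    trans_idx = [(r, s) for r in range(K) for s in range(K) if r != s]
    nt = len(trans_idx)
    nc = len(covariates)
    frm, to, dts, zs = _prepare_intervals(data, covariates)
    n_obs = frm.size
    if n_obs == 0:
        raise ValueError("no observation intervals")
    counts = data["state"].value_counts()
    if (counts < 1).any() or len(counts) < K:
        warnings.warn("some states unobserved; intensities involving them are weakly identified")

    # crude initial rates: observed one-step transition fractions per day
    crude = np.full((K, K), 0.01)
    tot_time = np.zeros(K)
    for f, t, dt in zip(frm, to, dts):
        tot_time[f] += dt
        if f != t:
            crude[f, t] += 1.0
    for r in range(K):
        crude[r] /= max(tot_time[r], 1.0)
    x0 = np.concatenate([
        np.log(np.clip([crude[r, s] for r, s in trans_idx], 1e-4, None)),
        np.zeros(nt * nc),
    ])

    def unpack(theta):
        logq = theta[:nt]
        betas = theta[nt:].reshape(nc, nt).T if nc else np.zeros((nt, 0))
        return logq, betas

    def neg_loglik(theta):
        logq, betas = unpack(theta)
        # per-interval generator
        rates = np.exp(np.clip(logq[None, :] + (zs @ betas.T if nc else 0.0), -30, 8))
        Q = np.zeros((n_obs, K, K))
        for ti, (r, s) in enumerate(trans_idx):
            Q[:, r, s] = rates[:, ti]
        Q[:, np.arange(K), np.arange(K)] = -Q.sum(axis=2)
        P = _batched_expm(Q * dts[:, None, None])
        p = P[np.arange(n_obs), frm, to]
        return -float(np.log(np.clip(p, 1e-300, None)).sum())

    res = optimize.minimize(neg_loglik, x0, method="L-BFGS-B",
                            options={"maxiter": max_iter, "maxfun": 20000})
    if not res.success:
        warnings.warn(f"CTMC optimization did not converge: {res.message}")
    theta = res.x
    logq, betas = unpack(theta)
    q0 = np.zeros((K, K))
    for ti, (r, s) in enumerate(trans_idx):
        q0[r, s] = np.exp(logq[ti])
    q0[np.arange(K), np.arange(K)] = -q0.sum(axis=1)

    cov_theta = None
    if compute_cov:
        try:
            H = approx_hess1(theta, neg_loglik)
            cov_theta = np.linalg.pinv(H)
        except Exception:  # pragma: no cover - degenerate Hessian
            cov_theta = None
    return CTMCModel(
        states=list(states) if states is not None else list(range(K)),
        q_matrix=q0, betas=betas, covariates=covariates, transitions=trans_idx,
        log_likelihood=-float(res.fun), n_params=theta.size, n_obs=n_obs,
        theta=theta, cov_theta=cov_theta, converged=bool(res.success),
    )


def ctmc_covariate_test(model_with: CTMCModel, model_without: CTMCModel) -> dict:
    """Likelihood-ratio test of nested CTMC models (2 dLogL ~ chi2_df)."""
    if model_with.n_obs != model_without.n_obs:
        raise ValueError("models were fitted on different data")
    df = model_with.n_params - model_without.n_params
    if df < 0 or not set(model_without.covariates) <= set(model_with.covariates):
        raise ValueError("models are not nested")
    lr = 2.0 * (model_with.log_likelihood - model_without.log_likelihood)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return {"statistic": float(lr), "df": int(df), "p": p}


def simulate_ctmc(
    q0: np.ndarray,
    betas: np.ndarray | None,
    z_values: np.ndarray,
    n_days: int,
    seed: int = 0,
    initial_states: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate snapshot observations of a covariate-modulated CTMC.

    One series per entry of ``z_values`` (the covariate is constant within a
    series); states are recorded at integer days 0..n_days. Used by
    recovery and coverage tests.
    """
    rng = np.random.default_rng(seed)
    q0 = np.asarray(q0, dtype=float)
    K = q0.shape[0]
    rows = []
    z_values = np.atleast_1d(np.asarray(z_values, dtype=float))
    for i, z in enumerate(z_values):
        Q = q0.copy()
        if betas is not None:
            b = np.asarray(betas, dtype=float)
            idx = 0
            for r in range(K):
                for s in range(K):
                    if r != s:
                        Q[r, s] = q0[r, s] * np.exp(b.ravel()[idx] * z)
                        idx += 1
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        state = (int(initial_states[i]) if initial_states is not None
                 else int(rng.integers(0, K)))
        t = 0.0
        jumps = [(0.0, state)]
        while t < n_days:
            rate = -Q[state, state]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= n_days:
                break
            probs = np.clip(Q[state], 0.0, None)
            probs[state] = 0.0
            probs /= probs.sum()
            state = int(rng.choice(K, p=probs))
            jumps.append((t, state))
        times = np.array([j[0] for j in jumps])
        sts = np.array([j[1] for j in jumps])
        for day in range(n_days + 1):
            s_at = sts[np.searchsorted(times, day, side="right") - 1]
            rows.append({"participant_id": f"s{i:04d}", "day": day,
                         "state": int(s_at), "z": float(z)})
    return pd.DataFrame(rows)
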