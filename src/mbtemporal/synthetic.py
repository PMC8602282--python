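"""Synthetic longitudinal cohort generator.

Emulates the structure of a dense quantitative gut-microbiome time series:
20 participants sampled near-daily for ~36 days, genus abundances (cells/g)
fluctuating log-normally around per-person equilibria with an AR(1) memory,
Taylor-law mean-variance scaling across hosts, four Dirichlet community
templates with occasional Markovian state switching, microbial loads in the
6-22 x 10^10 cells/g range, stool moisture negatively coupled to load and
driven by the protein/carbohydrate diet ratio at a configurable lag, and read
counts drawn multinomially from copy-number-distorted relative cell
abundances. Ground truth (equilibria, CVs, state labels, lags, swap manifest)
is emitted alongside the cohort for recovery tests.

The generative model, per participant ``p``, genus ``g`` and day ``t``::

    log10 cells_pgt = log10(L_p * m_g) + a_pg + e_pgt      (latent)
    e_pgt = phi * e_pg,t-1 + eta_t,   sd(e) = sigma_w(pg)  (stationary AR(1))
    cells -> cells * F[state_pt, g]                        (community state)

``sigma_w`` is set from a per-genus temporal coefficient of variation so that
across participants ``var ~ mean^b`` (Taylor's law; ``b = 2`` is constant CV).
``a_pg ~ N(0, sigma_b^2)`` is an independent per-genus participant effect, so
the latent-scale intraclass correlation is ``sigma_b^2 / (sigma_b^2 +
sigma_w^2)`` per genus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_cohort import Cohort, CohortTable

LN10 = np.log(10.0)


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; defaults emulate the study cohort."""

    n_participants: int = 20
    n_days: int = 36
    n_genera: int = 150
    taylor_slope_target: float = 2.0  # b: var ~ mean^b across hosts
    genus_cv_range: tuple[float, float] = (0.5, 2.0)  # temporal CV, log-uniform
    load_range: tuple[float, float] = (6e10, 22e10)  # cells/g
    moisture_range: tuple[float, float] = (52.0, 93.0)  # percent
    n_states: int = 4
    state_switch_prob: float = 0.05  # per day, away from the home state
    state_return_prob: float = 0.6  # per day, back to the home state
    diet_lag_days: int = 1
    ar_coef: float = 0.3
    between_subject_sd: float = 0.25  # sigma_b on the log10 scale
    read_depth: int = 30000
    miss_prob: float = 0.035  # daily probability of a missed sample
    detect_frac: float = 2e-5  # cells below detect_frac * load truncated to 0
    mean_copy_number: float = 3.88
    state_boost: float = 4.0  # driver-genus multiplier inside its state
    state_damp: float = 0.4  # driver-genus multiplier outside its state
    drivers_per_state: int = 3
    template_concentration: float = 80.0  # Dirichlet precision of templates
    moisture_load_coef: float = -4.0  # % per SD of log10 load
    moisture_diet_coef: float = 2.5  # % per SD of P/C
    moisture_noise_sd: float = 2.5
    swap_pairs: Sequence[tuple[str, str]] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants >= 2 required")
        if self.n_days < 3:
            raise ValueError("n_days >= 3 required")
        if self.taylor_slope_target <= 0:
            raise ValueError("infeasible Taylor target: b must be > 0")
        for rng_ in (self.genus_cv_range, self.load_range, self.moisture_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"range not ordered: {rng_}")
        if not 0.0 <= self.state_switch_prob <= 1.0:
            raise ValueError("state_switch_prob must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Generator-side truth used by recovery tests."""

    equilibrium: pd.DataFrame  # participants x genera, cells/g (median scale)
    cv: pd.DataFrame  # participants x genera temporal CV of the latent series
    icc: pd.Series  # per-genus latent-scale intraclass correlation
    true_cells: pd.DataFrame  # samples x genera cells/g before read sampling
    state_labels: pd.Series  # per-sample community state index
    templates: np.ndarray  # n_states x n_genera Dirichlet alphas
    transition_matrix: pd.DataFrame  # per-day state transition probabilities
    diet_lag: pd.Series  # per-participant lag in days
    swap_manifest: list[tuple[str, str]]


def _cn_sigma(x: float) -> float:
    return x


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, GroundTruth]:
    """Generate a longitudinal cohort plus its ground truth.

    Returns a :class:`~mbtemporal.io_cohort.Cohort` whose table holds read
    counts and whose metadata carries loads (cells/g), moisture, Bristol
    scores, sampling times and a medication flag, plus the generator truth.
    """
    rng = np.random.default_rng(spec.seed)
    P, T, G, K = spec.n_participants, spec.n_days, spec.n_genera, spec.n_states

    genus_ids = np.array(
        [f"g__Genus{i:03d}" if i % 7 else f"uc_f_Fam{i:03d}" for i in range(G)]
    )
    participants = [f"p{800 + i}" for i in range(P)]

    # cohort-level genus profile: heavy-tailed relative means
    m = rng.lognormal(mean=0.0, sigma=1.5, size=G)
    m = np.sort(m)[::-1]
    m /= m.sum()

    # 16S copy numbers, rrnDB-like: lognormal with the requested mean, >= 1
    sigma_cn = 0.45
    cn = rng.lognormal(np.log(spec.mean_copy_number) - sigma_cn**2 / 2, sigma_cn, size=G)
    cn = np.clip(cn, 1.0, None)

    # community-state factor matrix: drivers_per_state genera per state taken
    # from the most abundant genera, boosted in their state and damped outside
    F = np.ones((K, G))
    d = spec.drivers_per_state
    offset = 2  # keep the two most abundant genera state-neutral
    for s in range(K):
        drv = offset + np.arange(s * d, (s + 1) * d)
        F[:, drv] = spec.state_damp
        F[s, drv] = spec.state_boost
    templates = np.array([m * F[s] for s in range(K)])
    templates /= templates.sum(axis=1, keepdims=True)
    template_alphas = templates * spec.template_concentration

    # per-genus temporal CV -> latent log10 SD
    lo, hi = spec.genus_cv_range
    if hi <= 0:
        cv_g = np.zeros(G)
    else:
        lo = max(lo, 1e-6)
        cv_g = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
        # abundant genera fluctuate least: rank-match CVs to descending
        # abundance so the summed load stays in a realistic band
        cv_g = np.sort(cv_g)

    sigma_b = spec.between_subject_sd
    a = rng.normal(0.0, sigma_b, size=(P, G))  # participant effects, log10

    loads_base = np.exp(
        rng.uniform(np.log(spec.load_range[0] * 1.2), np.log(spec.load_range[1] / 1.2), size=P)
    )
    mu = np.log10(loads_base[:, None] * m[None, :]) + a  # P x G equilibria
    # center the expected load on the drawn baseline: a deterministic
    # correction for E[10^a] (a realized-sum correction would leak a shared
    # participant effect into every genus and distort the ICC truth)
    mu -= sigma_b**2 * LN10 / 2.0

    # Taylor scaling: CV_pg = CV_g * (mean_pg / geo-mean_g)^((b-2)/2)
    b = spec.taylor_slope_target
    ref = mu.mean(axis=0)  # log10 geometric-mean abundance per genus
    with np.errstate(over="ignore"):
        cv_pg = cv_g[None, :] * np.power(10.0, (mu - ref[None, :]) * (b - 2.0) / 2.0)
    cv_pg = np.clip(cv_pg, 0.0, 20.0)
    sigma_w = np.sqrt(np.log1p(cv_pg**2)) / LN10  # log10 stationary SD

    # stationary AR(1) innovations on the log10 scale
    phi = spec.ar_coef
    e = np.empty((P, G, T))
    e[:, :, 0] = rng.normal(0.0, 1.0, size=(P, G)) * sigma_w
    innov_sd = sigma_w * np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        e[:, :, t] = phi * e[:, :, t - 1] + rng.normal(0.0, 1.0, size=(P, G)) * innov_sd

    # community state chains: orbit a home state with transitory excursions
    home = rng.integers(0, K, size=P)
    trans = np.empty((K, K))
    states = np.empty((P, T), dtype=int)
    for p in range(P):
        s = home[p]
        for t in range(T):
            states[p, t] = s
            if s == home[p]:
                if K > 1 and rng.random() < spec.state_switch_prob:
                    others = [k for k in range(K) if k != s]
                    s = others[rng.integers(0, K - 1)]
            else:
                if rng.random() < spec.state_return_prob:
                    s = home[p]
                elif K > 1 and rng.random() < spec.state_switch_prob:
                    others = [k for k in range(K) if k != s]
                    s = others[rng.integers(0, K - 1)]
    # nominal (population-averaged) per-day transition matrix, for reference
    pswitch = spec.state_switch_prob
    trans = np.full((K, K), pswitch / max(K - 1, 1))
    np.fill_diagonal(trans, 1.0 - pswitch)

    # latent cells/g, modulated by the per-day community state
    cells = np.power(10.0, mu[:, :, None] + e)  # P x G x T
    for p in range(P):
        cells[p] *= F[states[p]].T  # G x T

    loads = cells.sum(axis=1)  # P x T

    # detection limit: very rare genera fall below the observable fraction
    if spec.detect_frac > 0:
        limit = spec.detect_frac * loads[:, None, :]
        cells = np.where(cells < limit, 0.0, cells)
        loads = cells.sum(axis=1)

    # diet: Western-style macronutrient intake, iid around typical values
    carb = np.clip(rng.normal(250.0, 40.0, size=(P, T)), 30.0, None)
    protein = np.clip(rng.normal(75.0, 15.0, size=(P, T)), 10.0, None)
    fat = np.clip(rng.normal(80.0, 15.0, size=(P, T)), 10.0, None)
    fiber = np.clip(rng.normal(13.0, 4.0, size=(P, T)), 1.0, None)
    sodium = np.clip(rng.normal(2.5, 0.6, size=(P, T)), 0.2, None)
    pc = (4.0 * protein) / (4.0 * carb)

    # moisture: negative load coupling + lagged P/C response + noise
    lag = spec.diet_lag_days
    zload = (np.log10(loads) - np.log10(loads).mean()) / (np.log10(loads).std() + 1e-12)
    zpc = (pc - pc.mean()) / (pc.std() + 1e-12)
    zpc_lag = np.empty_like(zpc)
    for t in range(T):
        zpc_lag[:, t] = zpc[:, max(t - lag, 0)]
    mid = 0.5 * (spec.moisture_range[0] + spec.moisture_range[1])
    moisture = (
        mid
        + spec.moisture_load_coef * zload
        + spec.moisture_diet_coef * zpc_lag
        + rng.normal(0.0, spec.moisture_noise_sd, size=(P, T))
    )
    moisture = np.clip(moisture, spec.moisture_range[0] + 0.5, spec.moisture_range[1] - 0.5)
    bss = np.clip(np.round(1.0 + 6.0 * (moisture - 52.0) / 41.0 + rng.normal(0, 0.7, (P, T))), 1, 7)

    # missed defecations: drop days at random, keeping >= 3 per participant
    keep = rng.random((P, T)) >= spec.miss_prob
    for p in range(P):
        if keep[p].sum() < 3:
            keep[p, rng.choice(T, size=3, replace=False)] = True

    # read counts: multinomial from copy-number-distorted composition
    rows, meta_rows, diet_rows, truth_rows, state_rows = [], [], [], [], []
    times = np.array(["morning", "noon", "afternoon_evening", "night"])
    tprobs = np.array([0.5, 0.2, 0.25, 0.05])
    for p, pid in enumerate(participants):
        for t in range(T):
            diet_rows.append(
                dict(participant_id=pid, day=t, carb_g=carb[p, t], protein_g=protein[p, t],
                     fat_g=fat[p, t], fiber_g=fiber[p, t], sodium_g=sodium[p, t],
                     pc_ratio=pc[p, t])
            )
            if not keep[p, t]:
                continue
            sid = f"{pid}_d{t:02d}"
            depth = int(np.round(rng.lognormal(np.log(spec.read_depth), 0.25)))
            w = cells[p, :, t] * cn
            total = w.sum()
            counts = rng.multinomial(depth, w / total) if total > 0 else np.zeros(G, dtype=int)
            rows.append(pd.Series(counts, index=genus_ids, name=sid))
            meta_rows.append(
                dict(sample_id=sid, participant_id=pid, day=t, load=loads[p, t],
                     moisture=moisture[p, t], bss=bss[p, t],
                     sampling_time=times[rng.choice(4, p=tprobs)],
                     medication=bool(rng.random() < 0.05))
            )
            truth_rows.append(pd.Series(cells[p, :, t], index=genus_ids, name=sid))
            state_rows.append((sid, int(states[p, t])))

    abundance = pd.DataFrame(rows).astype(np.int64)
    abundance.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    diet = pd.DataFrame(diet_rows)
    table = CohortTable(abundance=abundance, unit="reads",
                        samples=meta[["participant_id", "day"]])

    cn_series = pd.Series(cn, index=pd.Index(genus_ids, name="genus_id"), name="copy_number")

    # latent-scale ICC truth: the participant effect on a genus combines the
    # independent per-genus effect with the shared baseline-load offset
    sb2_eff = sigma_b**2 + float(np.var(np.log10(loads_base), ddof=1))
    icc_truth = pd.Series(
        sb2_eff / (sb2_eff + (np.sqrt(np.log1p(cv_g**2)) / LN10) ** 2 + 1e-300),
        index=genus_ids, name="icc",
    )
    truth = GroundTruth(
        equilibrium=pd.DataFrame(np.power(10.0, mu), index=participants, columns=genus_ids),
        cv=pd.DataFrame(cv_pg, index=participants, columns=genus_ids),
        icc=icc_truth,
        true_cells=pd.DataFrame(truth_rows),
        state_labels=pd.Series(dict(state_rows), name="state"),
        templates=template_alphas,
        transition_matrix=pd.DataFrame(trans),
        diet_lag=pd.Series(spec.diet_lag_days, index=participants, name="lag_days"),
        swap_manifest=list(spec.swap_pairs),
    )

    cohort = Cohort(table=table, meta=meta, diet=diet, copy_numbers=cn_series)
    if spec.swap_pairs:
        swapped = inject_swaps(table, spec.swap_pairs)
        cohort = Cohort(table=swapped, meta=meta, diet=diet, copy_numbers=cn_series)
    return cohort, truth


def generate_background(
    n_samples: int,
    templates: np.ndarray,
    seed: int,
    depth: int = 10000,
    weights: Sequence[float] | None = None,
) -> tuple[CohortTable, pd.Series, pd.DataFrame]:
    """Cross-sectional background population from Dirichlet templates.

    One sample per pseudo-participant. Returns the relative-abundance table,
    the true state label per sample, and the integer count matrix drawn at
    ``depth`` reads (the matrix enterotyping consumes).
    """
    templates = np.asarray(templates, dtype=float)
    K, G = templates.shape
    if n_samples < K:
        raise ValueError("n_samples must be >= number of templates")
    rng = np.random.default_rng(seed)
    w = np.full(K, 1.0 / K) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    labels = rng.choice(K, size=n_samples, p=w)
    genus_ids = [f"g__Genus{i:03d}" if i % 7 else f"uc_f_Fam{i:03d}" for i in range(G)]
    counts = np.empty((n_samples, G), dtype=np.int64)
    for i in range(n_samples):
        pvec = rng.dirichlet(templates[labels[i]])
        counts[i] = rng.multinomial(depth, pvec)
    sids = pd.Index([f"bg{i:04d}" for i in range(n_samples)], name="sample_id")
    count_df = pd.DataFrame(counts, index=sids, columns=genus_ids)
    rel = count_df.div(count_df.sum(axis=1), axis=0)
    samples = pd.DataFrame(
        {"participant_id": [f"bgp{i:04d}" for i in range(n_samples)],
         "day": np.zeros(n_samples, dtype=int)},
        index=sids,
    )
    table = CohortTable(abundance=rel, unit="relative", samples=samples)
    return table, pd.Series(labels, index=sids, name="state"), count_df


def inject_swaps(
    table: CohortTable, swap_pairs: Sequence[tuple[str, str]]
) -> CohortTable:
    """Exchange abundance rows of the listed sample pairs (labels unchanged)."""
    abundance = table.abundance.copy()
    for s1, s2 in swap_pairs:
        for s in (s1, s2):
            if s not in abundance.index:
                raise KeyError(f"unknown sample_id: {s}")
        r1 = abundance.loc[s1].copy()
        abundance.loc[s1] = abundance.loc[s2]
        abundance.loc[s2] = r1
    return CohortTable(abundance=abundance, unit=table.unit, samples=table.samples.copy())
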