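"""Community-level dissimilarity analyses.

Bray-Curtis dissimilarity, principal coordinates analysis retaining
negative eigenvalues, homogeneity-of-dispersion testing (betadisper
semantics: distances to group centroids combine real and imaginary axes as
sqrt(max(0, d_real^2 - d_imag^2))), and similarity-decay regression of
log(1 - BC) on elapsed days with per-day balanced subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io_cohort import CohortTable


def bray_curtis(table: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, sum|x-y| / sum(x+y).

    Pairs of all-zero rows get a null entry (the dissimilarity is
    undefined); the diagonal is zero.
    """
    ab = table.abundance if isinstance(table, CohortTable) else table
    x = ab.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    zero = x.sum(axis=1) == 0
    if zero.any():
        d[np.ix_(zero, zero)] = np.nan
        np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ab.index, columns=ab.index)


@dataclass
class PCoAResult:
    coords: pd.DataFrame  # real axes (positive eigenvalues)
    neg_coords: pd.DataFrame  # imaginary axes (negative eigenvalues)
    eigenvalues: np.ndarray  # all eigenvalues, descending


def pcoa(dist: pd.DataFrame, eps: float = 1e-10) -> PCoAResult:
    """Classical scaling (Gower double-centering + eigendecomposition).

    Negative eigenvalues are retained and reported; their axes (scaled by
    sqrt(-lambda)) are returned separately as the imaginary part of the
    embedding.
    """
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > eps
    neg = evals < -eps
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    neg_coords = evecs[:, neg] * np.sqrt(-evals[neg])
    return PCoAResult(
        coords=pd.DataFrame(coords, index=dist.index,
                            columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]),
        neg_coords=pd.DataFrame(neg_coords, index=dist.index,
                                columns=[f"iPCo{i + 1}" for i in range(neg_coords.shape[1])]),
        eigenvalues=evals,
    )


@dataclass
class DispersionResult:
    dispersions: pd.Series  # per-sample distance to its group centroid
    group_means: pd.Series
    f_stat: float
    p: float


def dispersion_test(dist: pd.DataFrame, groups: pd.Series) -> DispersionResult:
    """ANOVA on multivariate homogeneity of group dispersions.

    Embeds the dissimilarity matrix by PCoA, computes each sample's distance
    to its group centroid with the imaginary-axis correction, and runs a
    one-way ANOVA on those distances across groups. Singleton groups are
    excluded with a warning (their dispersion is identically zero).
    """
    groups = groups.loc[dist.index]
    sizes = groups.value_counts()
    keep = groups.isin(sizes[sizes >= 2].index)
    if keep.sum() < dist.shape[0]:
        import warnings

        warnings.warn("singleton groups excluded from dispersion test")
        dist = dist.loc[keep[keep].index, keep[keep].index]
        groups = groups[keep]
    res = pcoa(dist)
    real = res.coords.to_numpy()
    imag = res.neg_coords.to_numpy()
    d2 = np.empty(len(groups))
    for g in groups.unique():
        idx = np.flatnonzero((groups == g).to_numpy())
        cr = real[idx].mean(axis=0)
        ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        dr2 = ((real[idx] - cr) ** 2).sum(axis=1)
        di2 = ((imag[idx] - ci) ** 2).sum(axis=1) if imag.size else 0.0
        d2[idx] = np.maximum(0.0, dr2 - di2)
    disp = pd.Series(np.sqrt(d2), index=dist.index, name="dispersion")
    samples_by_group = [disp[groups == g].to_numpy() for g in groups.unique()]
    if len(samples_by_group) < 2:
        raise ValueError("dispersion test needs >= 2 groups")
    f, p = stats.f_oneway(*samples_by_group)
    return DispersionResult(
        dispersions=disp,
        group_means=disp.groupby(groups).mean(),
        f_stat=float(f), p=float(p),
    )


def within_vs_between_dispersion(
    dist: pd.DataFrame,
    table: CohortTable,
    reference_day: int = 0,
) -> pd.DataFrame:
    """Per-participant test of within-series vs. between-individual
    dispersion.

    The between-individual group is one sample per participant (by default
    the earliest study day, standing in for the sample closest to the first
    day of menses). For each participant, a two-group dispersion ANOVA
    compares the participant's full series against that reference set;
    p-values are Benjamini-Hochberg adjusted across participants.
    """
    first = [
        table.participant_samples(pid)[0] for pid in table.participants
    ]
    rows = []
    for pid in table.participants:
        own = list(table.participant_samples(pid))
        between = [s for s in first if table.samples.loc[s, "participant_id"] != pid]
        ids = own + between
        sub = dist.loc[ids, ids]
        labels = pd.Series(["within"] * len(own) + ["between"] * len(between), index=ids)
        res = dispersion_test(sub, labels)
        rows.append({"participant_id": pid,
                     "within_dispersion": res.group_means.get("within", np.nan),
                     "between_dispersion": res.group_means.get("between", np.nan),
                     "F": res.f_stat, "p": res.p})
    out = pd.DataFrame(rows).set_index("participant_id")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# similarity decay

@dataclass
class DecayFit:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p: float
    n_pairs: int
    max_days: int
    pairs_per_day: int


def interpolate_daily(table: CohortTable, participant_id: str, max_gap: int = 3) -> pd.DataFrame:
    """Linear interpolation of a participant's abundance series to daily
    resolution; gaps longer than ``max_gap`` days stay missing."""
    sids = table.participant_samples(participant_id)
    days = table.samples.loc[sids, "day"].to_numpy()
    sub = table.abundance.loc[sids].copy()
    sub.index = pd.Index(days, name="day")
    full = sub.reindex(range(int(days.min()), int(days.max()) + 1))
    filled = full.interpolate(method="index", limit=max_gap - 1, limit_area="inside")
    return filled


def similarity_decay(
    table: CohortTable,
    max_days: int = 36,
    seed: int = 0,
    max_gap: int = 3,
    exclude_participants: list[str] | None = None,
) -> tuple[DecayFit, pd.DataFrame]:
    """Regression of log(1 - Bray-Curtis) on elapsed days.

    Per participant the series is linearly interpolated to daily resolution
    (gaps <= ``max_gap`` days), all within-participant day pairs with
    elapsed time 1..``max_days`` are formed, each elapsed-day bin is
    subsampled to the size of the smallest bin (seeded), and a linear model
    of log similarity on elapsed days is fitted.
    """
    rng = np.random.default_rng(seed)
    excl = set(exclude_participants or [])
    pairs: dict[int, list[float]] = {k: [] for k in range(1, max_days + 1)}
    span_ok = False
    for pid in table.participants:
        if pid in excl:
            continue
        daily = interpolate_daily(table, pid, max_gap=max_gap)
        days = daily.index.to_numpy()
        vals = daily.to_numpy(dtype=float)
        ok = ~np.isnan(vals).any(axis=1)
        days, vals = days[ok], vals[ok]
        if days.size >= 2 and days.max() - days.min() >= max_days:
            span_ok = True
        for i in range(days.size):
            for j in range(i + 1, days.size):
                dt = int(days[j] - days[i])
                if 1 <= dt <= max_days:
                    x, y = vals[i], vals[j]
                    denom = (x + y).sum()
                    if denom > 0:
                        bc = np.abs(x - y).sum() / denom
                        pairs[dt].append(bc)
    if not span_ok:
        raise ValueError("max_days exceeds every participant's span")
    counts = {k: len(v) for k, v in pairs.items() if len(v) > 0}
    if not counts:
        raise ValueError("no within-window sample pairs")
    n_per_day = min(counts.values())
    rows = []
    for dt in sorted(counts):
        vals = np.asarray(pairs[dt])
        take = rng.choice(vals.size, size=n_per_day, replace=False)
        for bc in vals[take]:
            rows.append((dt, bc))
    df = pd.DataFrame(rows, columns=["elapsed_days", "bc"])
    sim = 1.0 - df["bc"].clip(upper=1 - 1e-12)
    df["log_similarity"] = np.log(sim)
    res = stats.linregress(df["elapsed_days"], df["log_similarity"])
    n = len(df)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    fit = DecayFit(slope=float(res.slope), intercept=float(res.intercept),
                   r2=float(r2), adj_r2=float(adj), p=float(res.pvalue),
                   n_pairs=n, max_days=max_days, pairs_per_day=n_per_day)
    return fit, df
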