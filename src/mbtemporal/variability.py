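"""Within- versus between-subject variation statistics.

Covers the intraclass correlation coefficient (one-way ANOVA variance
components with the unbalanced-design correction), per-genus temporal
coefficients of variation, maximum fold changes and rank coverage,
augmented Dickey-Fuller stationarity screening, Taylor's law mean-variance
fits, and the error-on-the-median subsampling curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .io_cohort import CohortTable


# ---------------------------------------------------------------------------
# intraclass correlation

@dataclass
class ICCResult:
    var_among: float | None
    var_within: float | None
    icc: float | None


def icc(values, groups) -> ICCResult:
    """One-way ANOVA intraclass correlation coefficient.

    ``var_within = MSW``; ``var_among = (MSB - MSW) / k0`` with
    ``k0 = (N - sum(n_i^2) / N) / (k - 1)`` the average group size of the
    (possibly unbalanced) design; ``icc = var_among / (var_among +
    var_within)``. Negative estimates (MSB < MSW) are reported raw, not
    truncated. Returns nulls when the total variance is zero.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    ok = s.notna()
    s, g = s[ok], g[ok]
    sizes = g.value_counts()
    sizes = sizes[sizes >= 2]
    keep = g.isin(sizes.index)
    s, g = s[keep], g[keep]
    k = sizes.size
    N = int(sizes.sum())
    if k < 2:
        raise ValueError("icc needs >= 2 groups with >= 2 observations")
    grand = s.mean()
    if np.allclose(s, grand):
        return ICCResult(None, None, None)
    means = s.groupby(g.to_numpy()).mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((s - means.loc[g].to_numpy()) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    k0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    var_among = (msb - msw) / k0
    return ICCResult(var_among, msw, var_among / (var_among + msw))


def icc_per_genus(table: CohortTable, genera: list[str] | None = None,
                  log_transform: bool = False) -> pd.DataFrame:
    """ICC of each genus abundance series, participants as groups."""
    genera = list(table.genus_ids) if genera is None else genera
    groups = table.samples["participant_id"]
    out = {}
    for gname in genera:
        vals = table.abundance[gname].to_numpy(dtype=float)
        if log_transform:
            pos = vals[vals > 0]
            floor = pos.min() / 2 if pos.size else 1.0
            vals = np.log10(np.maximum(vals, floor))
        r = icc(vals, groups)
        out[gname] = {"var_among": r.var_among, "var_within": r.var_within, "icc": r.icc}
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "genus_id"
    return df


# ---------------------------------------------------------------------------
# coefficients of variation

def cv_per_genus(table: CohortTable, genera: list[str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Temporal CV (sd/mean over a participant's detected samples) per
    (genus, participant), plus the cohort summary over per-genus medians:
    mean +- sd and min:max."""
    genera = list(table.genus_ids) if genera is None else genera
    rows = []
    for pid in table.participants:
        sids = table.participant_samples(pid)
        sub = table.abundance.loc[sids, genera]
        for gname in genera:
            series = sub[gname].to_numpy(dtype=float)
            series = series[series > 0]
            if series.size < 2 or series.mean() == 0:
                cv = np.nan
            else:
                cv = series.std(ddof=1) / series.mean()
            rows.append({"genus_id": gname, "participant_id": pid, "cv": cv})
    df = pd.DataFrame(rows, columns=["genus_id", "participant_id", "cv"])
    med = df.groupby("genus_id")["cv"].median().dropna()
    summary = {
        "mean": float(med.mean()), "sd": float(med.std(ddof=1)),
        "min": float(med.min()), "max": float(med.max()),
        "per_genus_median": med,
    }
    return df, summary


# ---------------------------------------------------------------------------
# fold changes and rank coverage

@dataclass
class FoldChangeResult:
    genus_id: str
    participant_id: str
    max_overall: float | None
    max_consecutive: float | None
    rank_span: int | None


def _fold_stats(series: np.ndarray) -> tuple[float | None, float | None]:
    pos = series > 0
    vals = series[pos]
    if vals.size < 2:
        return None, None
    max_overall = float(vals.max() / vals.min())
    idx = np.flatnonzero(pos)
    consec = [
        max(series[i], series[j]) / min(series[i], series[j])
        for i, j in zip(idx[:-1], idx[1:])
        if j == i + 1
    ]
    max_consecutive = float(max(consec)) if consec else None
    return max_overall, max_consecutive


def fold_changes(
    table: CohortTable,
    genera: list[str] | None = None,
    pseudocount: bool = False,
    rank_mode: str = "span",
) -> pd.DataFrame:
    """Per (genus, participant): maximum overall and consecutive-sample fold
    change among positive observations, and the dense-rank span of the genus
    across the participant's samples (genera ranked within each sample by
    descending abundance).

    "Consecutive" means adjacent collected samples; zeros are skipped for
    ratios and break consecutive adjacency. ``pseudocount=True`` instead
    replaces zeros with half the smallest positive value in the table
    (sensitivity mode). ``rank_mode='distinct'`` counts distinct attained
    ranks instead of the span max - min + 1.
    """
    genera = list(table.genus_ids) if genera is None else genera
    records = []
    abundance = table.abundance
    if pseudocount:
        vals = abundance.to_numpy(dtype=float)
        floor = vals[vals > 0].min() / 2 if (vals > 0).any() else 1.0
        abundance = abundance.where(abundance > 0, floor)
    ranks = abundance.rank(axis=1, method="dense", ascending=False)
    for pid in table.participants:
        sids = table.participant_samples(pid)
        sub = abundance.loc[sids, genera]
        rsub = ranks.loc[sids, genera]
        present = sub > 0
        for gname in genera:
            series = sub[gname].to_numpy(dtype=float)
            max_overall, max_consecutive = _fold_stats(series)
            pr = rsub[gname][present[gname]]
            if not pr.size:
                span = None
            elif rank_mode == "distinct":
                span = int(pr.nunique())
            else:
                span = int(pr.max() - pr.min() + 1)
            records.append(FoldChangeResult(gname, pid, max_overall, max_consecutive, span))
    cols = ["genus_id", "participant_id", "max_overall", "max_consecutive", "rank_span"]
    return pd.DataFrame([vars(r) for r in records], columns=cols)


def fold_changes_series(series: np.ndarray) -> tuple[float | None, float | None]:
    """Fold-change statistics of a single ordered abundance series."""
    return _fold_stats(np.asarray(series, dtype=float))


# ---------------------------------------------------------------------------
# stationarity

@dataclass
class ADFResult:
    statistic: float
    p: float
    n_lags: int
    stationary: bool


def adf_stationarity(series, alpha: float = 0.05) -> ADFResult:
    """Augmented Dickey-Fuller test with drift (no trend).

    The augmentation order is AIC-selected up to ``floor((n - 1)^(1/3))``
    lags (a fixed maximal order wastes most of the test's power at the
    series lengths of a daily six-week design); p-value from the
    interpolated Dickey-Fuller distribution. ``stationary`` is True when
    the unit root is rejected at ``alpha`` — i.e. the series fluctuates
    around an equilibrium.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("ADF needs a series of length >= 10")
    maxlag = int(np.floor((x.size - 1) ** (1.0 / 3.0)))
    stat, p, usedlag, *_ = adfuller(x, maxlag=maxlag, regression="c", autolag="AIC")
    return ADFResult(float(stat), float(p), int(usedlag), bool(p < alpha))


def adf_per_genus(
    table: CohortTable, genera: list[str] | None = None,
    presence_threshold: float = 0.6, alpha: float = 0.05,
) -> pd.DataFrame:
    """ADF screen of every (participant, genus) series present in more than
    ``presence_threshold`` of the participant's samples; others are skipped
    and recorded."""
    genera = list(table.genus_ids) if genera is None else genera
    rows = []
    for pid in table.participants:
        sids = table.participant_samples(pid)
        sub = table.abundance.loc[sids, genera]
        for gname in genera:
            series = sub[gname].to_numpy(dtype=float)
            frac = float((series > 0).mean())
            if frac <= presence_threshold or series.size < 10:
                rows.append({"participant_id": pid, "genus_id": gname,
                             "presence": frac, "statistic": np.nan, "p": np.nan,
                             "stationary": pd.NA, "skipped": True})
                continue
            r = adf_stationarity(series, alpha=alpha)
            rows.append({"participant_id": pid, "genus_id": gname, "presence": frac,
                         "statistic": r.statistic, "p": r.p,
                         "stationary": r.stationary, "skipped": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Taylor's law

@dataclass
class TaylorFit:
    genus_id: str
    slope: float | None
    intercept: float | None
    adj_r2: float | None
    p: float | None
    n_points: int


def taylor_fit(means, variances, genus_id: str = "") -> TaylorFit:
    """OLS of log10(variance) on log10(mean) with intercept.

    Requires >= 5 (mean, variance) points with positive entries; degenerate
    x-variance yields nulls. Log base 10 (any base gives the same slope).
    """
    m = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    ok = (m > 0) & (v > 0)
    m, v = m[ok], v[ok]
    n = m.size
    if n < 5:
        return TaylorFit(genus_id, None, None, None, None, n)
    x, y = np.log10(m), np.log10(v)
    if np.allclose(x, x.mean()):
        return TaylorFit(genus_id, None, None, None, None, n)
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return TaylorFit(genus_id, float(res.slope), float(res.intercept),
                     float(adj), float(res.pvalue), n)


def taylor_per_genus(
    table: CohortTable, genera: list[str] | None = None, min_detections: int = 3,
    min_points: int = 5,
) -> pd.DataFrame:
    """Taylor-law fit per genus over per-participant temporal (mean, variance)
    pairs; series with fewer than ``min_detections`` detections are dropped,
    genera with fewer than ``min_points`` contributing participants are
    skipped (nulls)."""
    genera = list(table.genus_ids) if genera is None else genera
    fits = []
    for gname in genera:
        ms, vs = [], []
        for pid in table.participants:
            sids = table.participant_samples(pid)
            series = table.abundance.loc[sids, gname].to_numpy(dtype=float)
            det = series[series > 0]
            if det.size < min_detections:
                continue
            ms.append(det.mean())
            vs.append(det.var(ddof=1))
        if len(ms) < min_points:
            fits.append(TaylorFit(gname, None, None, None, None, len(ms)))
        else:
            fits.append(taylor_fit(ms, vs, genus_id=gname))
    cols = ["genus_id", "slope", "intercept", "adj_r2", "p", "n_points"]
    df = pd.DataFrame([vars(f) for f in fits], columns=cols).set_index("genus_id")
    return df


def taylor_rank_contrast(slopes: pd.Series, mean_ranks: pd.Series, top_n: int) -> tuple[float, float]:
    """Welch two-sample t of Taylor slopes, top-``top_n``-ranked genera vs. the
    rest (ranks = cohort-wide mean abundance ranks, 1 = most abundant)."""
    slopes = slopes.dropna()
    ranks = mean_ranks.loc[slopes.index]
    if top_n >= slopes.size:
        raise ValueError("top_n must be smaller than the number of genera")
    top = slopes[ranks <= top_n]
    rest = slopes[ranks > top_n]
    if top.nunique() <= 1 and rest.nunique() <= 1 and top.iloc[0] == rest.iloc[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(top, rest, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# error on the median with increasing timepoints

def median_error_curve(
    table: CohortTable,
    n_points: range | list[int] = range(1, 22),
    reps: int = 10000,
    n_top_genera: int = 100,
    seed: int = 0,
) -> tuple[pd.Series, int]:
    """Standard error on the median genus abundance versus number of
    timepoints.

    For each participant and each of their ``n_top_genera`` most abundant
    genera, draw ``n`` distinct timepoints at random, take the genus median,
    and report the standard deviation of those subsample medians over
    ``reps`` repetitions, averaged over genera and participants. Also returns
    the elbow of the curve (maximum distance to the chord).
    """
    rng = np.random.default_rng(seed)
    ns = list(n_points)
    errors = {n: [] for n in ns}
    for pid in table.participants:
        sids = table.participant_samples(pid)
        sub = table.abundance.loc[sids]
        top = sub.mean(axis=0).nlargest(min(n_top_genera, sub.shape[1])).index
        vals = sub[top].to_numpy(dtype=float)  # T x G
        T = vals.shape[0]
        for n in ns:
            if n > T:
                continue
            if n == T:
                for g in range(vals.shape[1]):
                    errors[n].append(0.0)
                continue
            # reps draws of n distinct timepoints, vectorized
            idx = np.argsort(rng.random((reps, T)), axis=1)[:, :n]
            meds = np.median(vals[idx, :], axis=1)  # reps x G
            errors[n].extend(meds.std(axis=0, ddof=0).tolist())
    curve = pd.Series({n: float(np.mean(v)) for n, v in errors.items() if v},
                      name="median_error")
    curve.index.name = "n_timepoints"
    return curve, curve_elbow(curve)


def curve_elbow(curve: pd.Series) -> int:
    """Index of maximum perpendicular distance to the chord of the curve."""
    x = np.asarray(curve.index, dtype=float)
    y = curve.to_numpy(dtype=float)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    if norm == 0:
        return int(x[0])
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / norm
    return int(x[int(np.argmax(dist))])
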