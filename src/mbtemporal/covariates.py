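"""Host covariates: energy intake, per-participant dietary lag, hormones.

Energy intake uses the Atwater factors 9/4/4 kcal per gram of fat, protein
and carbohydrate. The dietary lag links each day's microbiome sample to the
diet record ``lag`` days earlier: starting from the 1-day average transit
time, the lag is adjusted per participant from the cross-correlation of the
protein/carbohydrate energy ratio (P/C) with stool moisture. Ovarian
hormone levels are inferred by aligning a 28-day standard cycle profile to
each participant's reported cycle length, modifying only the variable
follicular phase at the start of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KCAL_PER_G = {"fat": 9.0, "protein": 4.0, "carb": 4.0}


def energy_intake(diet: pd.DataFrame) -> pd.DataFrame:
    """Total energy intake and %EI per macronutrient for each diet record.

    EI = 9*fat + 4*protein + 4*carb (kcal); the P/C ratio is protein %EI
    over carbohydrate %EI. Zero-EI days yield nulls.
    """
    out = diet.copy()
    ei = (KCAL_PER_G["fat"] * diet["fat_g"]
          + KCAL_PER_G["protein"] * diet["protein_g"]
          + KCAL_PER_G["carb"] * diet["carb_g"])
    out["energy_kcal"] = ei
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = ei.where(ei > 0, np.nan)
        out["carb_pct"] = 100.0 * 4.0 * diet["carb_g"] / denom
        out["protein_pct"] = 100.0 * 4.0 * diet["protein_g"] / denom
        out["fat_pct"] = 100.0 * 9.0 * diet["fat_g"] / denom
        carb_e = (4.0 * diet["carb_g"]).where(diet["carb_g"] > 0, np.nan)
        out["pc_ratio"] = (4.0 * diet["protein_g"]) / carb_e
    return out


@dataclass
class LagAssignment:
    participant_id: str
    lag_days: int
    best_ccf_lag: int | None
    ccf_values: dict[int, float] = field(default_factory=dict)
    significant: bool = False
    rationale: str = "default"


def _lagged_correlation(pc: pd.Series, mc: pd.Series, lag: int) -> tuple[float, int]:
    """Pearson r of P/C at day t-lag with moisture at day t, pairwise
    complete; returns (r, n_pairs)."""
    days = mc.index.intersection(pc.index + lag)
    x = pc.reindex(days - lag).to_numpy(dtype=float)
    y = mc.reindex(days).to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan, int(ok.sum())
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan, int(ok.sum())
    return float(np.corrcoef(x, y)[0, 1]), int(ok.sum())


def dietary_lag(
    pc_by_day: pd.Series,
    moisture_by_day: pd.Series,
    participant_id: str = "",
    sampling_times: pd.Series | None = None,
    lags: range = range(1, 6),
    min_overlap: int = 10,
) -> LagAssignment:
    """Assign a dietary lag to one participant.

    Searches Pearson correlations of P/C against moisture at lags 1..5 days
    (diet leading) plus lag 0; significance threshold ``|r| > 1.96/sqrt(n)``.
    Rules: default lag 1; a significant, stronger correlation at lags 2-5
    moves the lag there; a stronger same-day correlation moves the lag to 0
    only when the majority of samples were taken in the late afternoon or
    evening.
    """
    pc_by_day = pc_by_day.dropna()
    moisture_by_day = moisture_by_day.dropna()
    searched = [0] + list(lags)
    ccf: dict[int, float] = {}
    ns: dict[int, int] = {}
    for lag in searched:
        r, n = _lagged_correlation(pc_by_day, moisture_by_day, lag)
        ccf[lag], ns[lag] = r, n
    if max(ns.values(), default=0) < min_overlap:
        return LagAssignment(participant_id, 1, None, ccf, False, "default")

    finite = {k: v for k, v in ccf.items() if np.isfinite(v)}
    if not finite:
        return LagAssignment(participant_id, 1, None, ccf, False, "default")
    best = max(finite, key=lambda k: abs(finite[k]))
    thresh = {k: 1.96 / np.sqrt(ns[k]) for k in finite}
    sig = {k: abs(finite[k]) > thresh[k] for k in finite}
    r1 = abs(finite.get(1, 0.0))

    lag_days, rationale, significant = 1, "default", bool(sig.get(1, False))
    if best in range(2, 6) and sig[best] and abs(finite[best]) > r1:
        lag_days, rationale, significant = best, "ccf_adjusted", True
    elif best == 0 and sig[best] and abs(finite[best]) > r1:
        if sampling_times is not None:
            evening = (sampling_times == "afternoon_evening").mean()
            if evening > 0.5:
                lag_days, rationale, significant = 0, "evening_sampling", True
    return LagAssignment(participant_id, lag_days, best, ccf, significant, rationale)


def dietary_lag_cohort(
    diet: pd.DataFrame,
    meta: pd.DataFrame,
    samples: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Per-participant lag assignment over a cohort."""
    rows = []
    diet_e = energy_intake(diet)
    for pid in sorted(samples["participant_id"].unique()):
        dsub = diet_e[diet_e["participant_id"] == pid].set_index("day")
        msub = samples[samples["participant_id"] == pid]
        mc = pd.Series(meta.loc[msub.index, "moisture"].to_numpy(),
                       index=msub["day"].to_numpy())
        st = (pd.Series(meta.loc[msub.index, "sampling_time"].to_numpy(),
                        index=msub["day"].to_numpy())
              if "sampling_time" in meta.columns else None)
        la = dietary_lag(dsub["pc_ratio"], mc, participant_id=pid,
                         sampling_times=st, **kwargs)
        rows.append({"participant_id": pid, "lag_days": la.lag_days,
                     "best_ccf_lag": la.best_ccf_lag, "significant": la.significant,
                     "rationale": la.rationale,
                     **{f"r_lag{k}": v for k, v in la.ccf_values.items()}})
    return pd.DataFrame(rows).set_index("participant_id")


# ---------------------------------------------------------------------------
# hormone profiles

def synthetic_standard_curve(seed: int = 0) -> pd.DataFrame:
    """Synthetic 28-day standard ovarian-hormone profile.

    A parameterized stand-in for a luteinizing-hormone-peak-aligned
    reference curve (the published reference data are not redistributable):
    estrogen peaks just before the day-14 LH reference and again mid-luteal;
    progesterone shows the single broad luteal peak. Arbitrary units.
    """
    days = np.arange(1, 29)
    est = (100.0 * np.exp(-0.5 * ((days - 13) / 2.0) ** 2)
           + 55.0 * np.exp(-0.5 * ((days - 21) / 3.5) ** 2) + 35.0)
    prog = 14.0 * np.exp(-0.5 * ((days - 21) / 3.0) ** 2) + 0.8
    return pd.DataFrame({"day": days, "estrogen": est, "progesterone": prog}).set_index("day")


def infer_hormones(
    cycle_length: int,
    standard_curve: pd.DataFrame | pd.Series,
) -> pd.DataFrame | pd.Series:
    """Personal daily hormone profile for a given cycle length.

    The 14-day luteal tail of the 28-day standard curve is preserved; only
    the start of the cycle is modified. Shorter cycles drop days from the
    start; longer cycles insert extrapolated days at the start with
    ``level(28 + x) = level(day1) + (level(day1) - level(day28)) * exp(-x)``
    for each additional day ``x = 1, 2, ...`` (converging to the day-1
    level). Cycle lengths outside 21..45 are clamped with a warning.
    """
    import warnings

    squeeze = isinstance(standard_curve, pd.Series)
    curve = standard_curve.to_frame() if squeeze else standard_curve
    if len(curve) != 28:
        raise ValueError("standard curve must have 28 daily values")
    if not 21 <= cycle_length <= 45:
        warnings.warn(f"cycle length {cycle_length} outside 21..45; clamped")
        cycle_length = int(np.clip(cycle_length, 21, 45))
    vals = curve.to_numpy(dtype=float)
    if cycle_length == 28:
        out = vals
    elif cycle_length < 28:
        out = vals[28 - cycle_length:]
    else:
        x = np.arange(1, cycle_length - 28 + 1, dtype=float)
        extra = vals[0][None, :] + (vals[0] - vals[27])[None, :] * np.exp(-x)[:, None]
        out = np.vstack([extra, vals])
    res = pd.DataFrame(out, index=pd.RangeIndex(1, cycle_length + 1, name="day"),
                       columns=curve.columns)
    return res.iloc[:, 0] if squeeze else res


def hormone_series(
    cycle_day: pd.Series, cycle_length: pd.Series, standard_curve: pd.DataFrame
) -> pd.DataFrame:
    """Daily hormone estimates for samples given cycle day and length."""
    rows = {}
    profiles: dict[int, pd.DataFrame] = {}
    for sid in cycle_day.index:
        L = int(cycle_length.loc[sid])
        if L not in profiles:
            profiles[L] = infer_hormones(L, standard_curve)
        prof = profiles[L]
        d = int(cycle_day.loc[sid])
        d = ((d - 1) % len(prof)) + 1
        rows[sid] = prof.loc[d]
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = cycle_day.index.name
    return out
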