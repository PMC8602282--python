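"""RMP and QMP construction, alpha diversity, and abundance filters.

Relative microbiome profiles (RMP) rarefy every sample's reads to a fixed
depth (default 10,000). Quantitative microbiome profiles (QMP) instead
rarefy to even *sampling depth*, defined per sample as the 16S copy-number
corrected read total divided by the microbial load (cells/g), then scale the
resulting composition by the load to obtain cells/g. The target sampling
depth is optimized to exclude as few samples as possible while guaranteeing
at least ``min_reads`` (default 500) corrected reads per retained sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_cohort import CohortTable


def rarefy_reads(counts_row: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray | None:
    """Subsample a count vector without replacement to ``depth`` reads.

    Multivariate hypergeometric draw; returns ``None`` when the row total is
    below ``depth`` (the sample is to be marked excluded, not an exception).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    counts = np.asarray(counts_row, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        return None
    if total == depth:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def build_rmp(table: CohortTable, depth: int = 10000, seed: int = 0) -> tuple[CohortTable, list[str]]:
    """Rarefy every sample to ``depth`` reads; returns (RMP table, excluded ids)."""
    rng = np.random.default_rng(seed)
    rows, kept, excluded = [], [], []
    for sid in table.sample_ids:
        row = rarefy_reads(table.abundance.loc[sid].to_numpy(), depth, rng)
        if row is None:
            excluded.append(sid)
        else:
            rows.append(row)
            kept.append(sid)
    abundance = pd.DataFrame(rows, index=pd.Index(kept, name="sample_id"),
                             columns=table.genus_ids)
    rmp = CohortTable(abundance=abundance, unit="reads", samples=table.samples.loc[kept])
    return rmp, excluded


def corrected_depth(counts_row: pd.Series | np.ndarray, cn_map: pd.Series | np.ndarray) -> float:
    """Copy-number corrected sequencing depth: sum over genera of count/cn."""
    counts = np.asarray(counts_row, dtype=float)
    cn = np.asarray(cn_map, dtype=float)
    return float((counts / cn).sum())


@dataclass
class QMPBuild:
    """Result of QMP construction."""

    target_depth: float  # D: corrected reads per cell
    corrected_depths: pd.Series  # per-sample corrected read totals
    sampling_depths: pd.Series  # d_s = corrected_depth_s / load_s
    retained: list[str]
    excluded: pd.DataFrame  # sample_id, reason in {no_load, low_reads, below_min_after_rarefaction}
    qmp: CohortTable  # cells/g

    def to_json_dict(self):
        return {
            "target_depth": self.target_depth,
            "n_retained": len(self.retained),
            "excluded": self.excluded.to_dict(orient="records"),
        }


def _candidate_retention(d_s: np.ndarray, loads: np.ndarray, min_reads: int, D: float) -> np.ndarray:
    """Retention mask for candidate target depth D."""
    return (d_s >= D) & (np.round(D * loads) >= min_reads)


def choose_target_depth(
    d_s: np.ndarray, loads: np.ndarray, min_reads: int
) -> tuple[float, np.ndarray]:
    """Pick the sampling depth retaining the most samples (ties: larger D).

    Candidates are the observed per-sample sampling depths; any other depth
    is dominated by one of them.
    """
    best_D, best_mask, best_n = None, None, -1
    for D in np.unique(d_s):
        mask = _candidate_retention(d_s, loads, min_reads, D)
        n = int(mask.sum())
        if n > best_n or (n == best_n and D > best_D):
            best_D, best_mask, best_n = float(D), mask, n
    if best_n < 1:
        raise ValueError("no candidate sampling depth retains any sample")
    return best_D, best_mask


def build_qmp(
    table: CohortTable,
    cn_map: pd.Series,
    loads: pd.Series,
    min_reads: int = 500,
    seed: int = 0,
) -> QMPBuild:
    """Build quantitative microbiome profiles (cells/g).

    Rarefaction happens on the copy-number-corrected scale: for a retained
    sample the corrected read total is subsampled to ``round(D * load)``
    reads by a multinomial draw with probabilities proportional to
    ``count_g / cn_g`` (corrected reads are fractional, so a probability
    model replaces the without-replacement draw). The rarefied composition
    is then scaled by the microbial load.
    """
    rng = np.random.default_rng(seed)
    cn = cn_map.loc[table.genus_ids].to_numpy(dtype=float)
    counts = table.abundance.to_numpy(dtype=float)
    corrected = (counts / cn).sum(axis=1)
    load_vec = loads.reindex(table.sample_ids).to_numpy(dtype=float)

    excluded_rows = []
    usable = np.isfinite(load_vec) & (load_vec > 0)
    for sid in table.sample_ids[~usable]:
        excluded_rows.append({"sample_id": sid, "reason": "no_load"})

    # upfront exclusion: can never reach min_reads corrected reads
    low = usable & (corrected < min_reads)
    for sid in table.sample_ids[low]:
        excluded_rows.append({"sample_id": sid, "reason": "low_reads"})
    cand = usable & ~low

    if not cand.any():
        raise ValueError("no sample is usable for QMP construction")
    d_s_all = np.full(len(table.sample_ids), np.nan)
    d_s_all[usable] = corrected[usable] / load_vec[usable]

    D, mask_cand = choose_target_depth(d_s_all[cand], load_vec[cand], min_reads)
    retained_mask = np.zeros(len(table.sample_ids), dtype=bool)
    retained_mask[np.flatnonzero(cand)[mask_cand]] = True
    for sid in table.sample_ids[cand & ~retained_mask]:
        excluded_rows.append({"sample_id": sid, "reason": "below_min_after_rarefaction"})

    rows, kept = [], []
    for i in np.flatnonzero(retained_mask):
        sid = table.sample_ids[i]
        n_target = int(np.round(D * load_vec[i]))
        probs = counts[i] / cn
        probs = probs / probs.sum()
        rare = rng.multinomial(n_target, probs)
        rel = rare / rare.sum()
        rows.append(rel * load_vec[i])
        kept.append(sid)

    abundance = pd.DataFrame(rows, index=pd.Index(kept, name="sample_id"),
                             columns=table.genus_ids)
    qmp = CohortTable(abundance=abundance, unit="cells_per_gram",
                      samples=table.samples.loc[kept])
    excluded = pd.DataFrame(excluded_rows, columns=["sample_id", "reason"])
    return QMPBuild(
        target_depth=D,
        corrected_depths=pd.Series(corrected, index=table.sample_ids, name="corrected_depth"),
        sampling_depths=pd.Series(d_s_all, index=table.sample_ids, name="sampling_depth"),
        retained=kept,
        excluded=excluded,
        qmp=qmp,
    )


@dataclass
class AlphaDiversity:
    richness: int | None
    shannon: float | None
    pielou: float | None


def alpha_diversity(abundance_row: np.ndarray | pd.Series) -> AlphaDiversity:
    """Observed richness S, Shannon H (natural log), Pielou J = H / ln S.

    J is undefined (None) for S <= 1; an all-zero row yields an all-null
    record.
    """
    x = np.asarray(abundance_row, dtype=float)
    total = x.sum()
    if total <= 0:
        return AlphaDiversity(None, None, None)
    p = x[x > 0] / total
    S = int(p.size)
    H = float(-(p * np.log(p)).sum())
    J = float(H / np.log(S)) if S >= 2 else None
    return AlphaDiversity(S, H, J)


def alpha_diversity_table(table: CohortTable) -> pd.DataFrame:
    """Per-sample alpha diversity (richness, shannon, pielou)."""
    recs = {}
    for sid in table.sample_ids:
        a = alpha_diversity(table.abundance.loc[sid].to_numpy())
        recs[sid] = {"richness": a.richness, "shannon": a.shannon, "pielou": a.pielou}
    df = pd.DataFrame.from_dict(recs, orient="index")
    df.index.name = "sample_id"
    return df


def filter_genera(
    table: CohortTable,
    min_rel_abundance: float = 0.005,
    min_participants: int | None = None,
    min_samples: int | None = None,
) -> list[str]:
    """Genera whose maximum within-cohort relative abundance exceeds the
    threshold, optionally also detected in more than ``min_participants``
    participants with more than ``min_samples`` positive samples each.

    Inequalities are strict, following the ">0.5%", ">5 individuals",
    ">3 samples" convention.
    """
    rel = table.relative()
    keep = rel.max(axis=0) > min_rel_abundance
    genera = rel.columns[keep]
    if min_participants is not None:
        present = (table.abundance[genera] > 0).groupby(
            table.samples["participant_id"]
        ).sum()
        need = 0 if min_samples is None else min_samples
        n_part = (present > need).sum(axis=0)
        genera = genera[(n_part > min_participants).to_numpy()]
    return list(genera)


def filtered_view(table: CohortTable, genera: list[str]) -> CohortTable:
    """Restrict a cohort table to the given genera (presence/membership work).

    Relative tables are renormalized over the kept genera so the unit
    invariant still holds.
    """
    sub = table.abundance[genera]
    if table.unit == "relative":
        totals = sub.sum(axis=1)
        sub = sub.div(totals.where(totals > 0, np.nan), axis=0).fillna(0.0)
    return CohortTable(abundance=sub, unit=table.unit, samples=table.samples)
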