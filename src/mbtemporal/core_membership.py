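"""Core / persistent / transient / person-specific genus classification.

Definitions operate on presence masks from the 0.5%-filtered QMP matrix
(presence = abundance > 0 in a retained genus; "consecutive" refers to
adjacency in collection order):

* temporal core — present in more than 95% of one person's samples;
* persistent — present in more than 20% of the samples with at least 90% of
  those observations consecutive;
* transient — present in more than 60% of the samples while fewer than 75%
  of those observations are consecutive;
* cross-sectional core — present in at least one sample of every individual;
* person-specific — present in at least one sample of exactly one individual
  (genera seen in negative controls excluded).

Classes are not forced to be exclusive: a record is emitted for every
satisfied predicate and overlaps are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_cohort import CohortTable

TEMPORAL_CORE_PRESENCE = 0.95
PERSISTENT_PRESENCE = 0.20
PERSISTENT_CONSECUTIVE = 0.90
TRANSIENT_PRESENCE = 0.60
TRANSIENT_CONSECUTIVE = 0.75


def consecutive_fraction(mask: np.ndarray) -> float:
    """Fraction of presence observations whose previous or next collected
    sample is also a presence. 0 when no presences; a single isolated
    presence has fraction 0."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        return 0.0
    prev_ = np.concatenate([[False], mask[:-1]])
    next_ = np.concatenate([mask[1:], [False]])
    good = mask & (prev_ | next_)
    return float(good.sum() / n)


def classify_mask(mask: np.ndarray) -> tuple[float, float, list[str]]:
    """Per-participant classes from one presence mask."""
    mask = np.asarray(mask, dtype=bool)
    pf = float(mask.mean())
    cf = consecutive_fraction(mask)
    classes = []
    if pf > TEMPORAL_CORE_PRESENCE:
        classes.append("temporal_core")
    if pf > PERSISTENT_PRESENCE and cf >= PERSISTENT_CONSECUTIVE:
        classes.append("persistent")
    if pf > TRANSIENT_PRESENCE and cf < TRANSIENT_CONSECUTIVE:
        classes.append("transient")
    return pf, cf, classes


def classify_membership(
    table: CohortTable,
    negative_control_genera: list[str] | None = None,
) -> pd.DataFrame:
    """Membership records for every genus.

    Returns one row per (genus, participant, class) for the per-participant
    classes and one row per genus (participant null) for the cohort-level
    classes, with presence and consecutive fractions and an ``overlap`` flag
    when a genus satisfies several per-participant predicates at once.
    """
    neg = set(negative_control_genera or [])
    records = []
    presence_by_participant = {}
    for pid in table.participants:
        sids = table.participant_samples(pid)
        sub = table.abundance.loc[sids] > 0
        presence_by_participant[pid] = sub.any(axis=0)
        for gname in table.genus_ids:
            pf, cf, classes = classify_mask(sub[gname].to_numpy())
            for cls in classes:
                records.append({
                    "genus_id": gname, "participant_id": pid, "class": cls,
                    "presence_fraction": pf, "consecutive_fraction": cf,
                    "overlap": len(classes) > 1,
                })
    anyp = pd.DataFrame(presence_by_participant)  # genus x participant
    cross = anyp.all(axis=1)
    specific = anyp.sum(axis=1) == 1
    for gname in table.genus_ids:
        overall_pf = float((table.abundance[gname] > 0).mean())
        if cross.loc[gname]:
            records.append({"genus_id": gname, "participant_id": None,
                            "class": "cross_sectional_core",
                            "presence_fraction": overall_pf,
                            "consecutive_fraction": np.nan, "overlap": False})
        if specific.loc[gname] and gname not in neg:
            pid = anyp.columns[anyp.loc[gname]].tolist()[0]
            records.append({"genus_id": gname, "participant_id": pid,
                            "class": "person_specific",
                            "presence_fraction": overall_pf,
                            "consecutive_fraction": np.nan, "overlap": False})
    return pd.DataFrame(records)


def temporal_core_size(presence: np.ndarray) -> int:
    """Number of genera present in > 95% of the rows of a samples x genera
    presence matrix."""
    presence = np.asarray(presence, dtype=bool)
    return int((presence.mean(axis=0) > TEMPORAL_CORE_PRESENCE).sum())


def core_size_accumulation(
    table: CohortTable,
    participant_id: str,
    n_samples: list[int] | range | None = None,
    reps: int = 200,
    seed: int = 0,
    band: float = 0.10,
) -> tuple[pd.Series, int | None]:
    """Expected temporal-core size as a function of sampling effort.

    For each ``n``, the mean over ``reps`` random draws of ``n`` distinct
    samples of the temporal-core size computed on those samples. Also
    returns the smallest ``n`` from which the mean stays within ``band``
    (default 10%) of the full-series core size.
    """
    rng = np.random.default_rng(seed)
    sids = table.participant_samples(participant_id)
    presence = (table.abundance.loc[sids] > 0).to_numpy()
    T = presence.shape[0]
    ns = list(n_samples) if n_samples is not None else list(range(1, T + 1))
    full = temporal_core_size(presence)
    means = {}
    for n in ns:
        if n > T:
            continue
        if n == T:
            means[n] = float(full)
            continue
        sizes = []
        for _ in range(reps):
            idx = rng.choice(T, size=n, replace=False)
            sizes.append(temporal_core_size(presence[idx]))
        means[n] = float(np.mean(sizes))
    curve = pd.Series(means, name="core_size")
    curve.index.name = "n_samples"
    threshold_n = None
    if full > 0:
        within = (curve - full).abs() <= band * full
        for n in sorted(within.index):
            if within.loc[n:].all():
                threshold_n = int(n)
                break
    return curve, threshold_n
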