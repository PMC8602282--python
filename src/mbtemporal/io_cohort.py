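"""Reading, writing and validation of cohort artifacts.

The central in-memory containers are thin wrappers around pandas objects:

* :class:`CohortTable` — a samples x genera abundance matrix (read counts,
  relative abundances, or cells per gram) annotated with participant and
  study-day labels.
* ``SampleMeta`` / ``DietDay`` — plain DataFrames with documented schemas.
* ``CopyNumberMap`` — a pandas Series mapping genus identifiers to 16S rRNA
  gene copy numbers (rrnDB-style values, >= 1).

All tabular artifacts are TSV on disk; nested results are JSON. A minimal
BIOM 1.0 (JSON) reader is provided for count tables exported by other tools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mbtemporal")

VALID_UNITS = ("reads", "relative", "cells_per_gram")

#: default column names of the on-disk schemas; a user-supplied mapping can
#: rename any of them (published cohort tables do not
#: share a single schema).
DEFAULT_COLUMNS = {
    "sample_id": "sample_id",
    "participant_id": "participant_id",
    "day": "day",
    "load": "load",
    "moisture": "moisture",
    "bss": "bss",
    "sampling_time": "sampling_time",
}

SAMPLING_TIMES = ("morning", "noon", "afternoon_evening", "night")


@dataclass
class CohortTable:
    """Samples x genera abundance matrix with sample annotations.

    Parameters
    ----------
    abundance
        DataFrame indexed by ``sample_id`` with genus identifiers as columns;
        entries are non-negative.
    unit
        One of ``reads`` (integer counts), ``relative`` (rows sum to 1) or
        ``cells_per_gram`` (absolute abundances).
    samples
        DataFrame indexed by ``sample_id`` with at least ``participant_id``
        (str) and ``day`` (int, 0-based within participant).
    """

    abundance: pd.DataFrame
    unit: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.abundance.index.has_duplicates:
            dups = self.abundance.index[self.abundance.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_id: {dups}")
        vals = self.abundance.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("negative abundance values")
        if not self.abundance.index.equals(self.samples.index):
            missing = self.abundance.index.difference(self.samples.index)
            if len(missing):
                raise ValueError(f"samples missing annotations: {list(missing)[:5]}")
            self.samples = self.samples.loc[self.abundance.index]
        pd_dupes = self.samples.duplicated(subset=["participant_id", "day"])
        if pd_dupes.any():
            raise ValueError(
                "duplicate (participant_id, day) pairs: "
                f"{self.samples.index[pd_dupes].tolist()}"
            )
        if self.unit == "reads":
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("unit='reads' requires integer entries")
        if self.unit == "relative":
            totals = vals.sum(axis=1)
            nz = totals > 0
            if not np.allclose(totals[nz], 1.0, atol=1e-9):
                raise ValueError("unit='relative' rows must sum to 1 +- 1e-9")

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def genus_ids(self) -> pd.Index:
        return self.abundance.columns

    @property
    def participants(self) -> list[str]:
        return sorted(self.samples["participant_id"].unique())

    def participant_samples(self, participant_id: str) -> pd.Index:
        """Sample ids of one participant, ordered by study day."""
        sub = self.samples[self.samples["participant_id"] == participant_id]
        return sub.sort_values("day").index

    def relative(self) -> pd.DataFrame:
        """Row-normalized abundance (all-zero rows stay zero)."""
        totals = self.abundance.sum(axis=1)
        rel = self.abundance.div(totals.where(totals > 0, np.nan), axis=0)
        return rel.fillna(0.0)

    def sorted(self) -> "CohortTable":
        """Deterministic ordering: by (participant, day); genera alphabetical."""
        order = self.samples.sort_values(["participant_id", "day"]).index
        return CohortTable(
            abundance=self.abundance.loc[order, sorted(self.abundance.columns)],
            unit=self.unit,
            samples=self.samples.loc[order],
        )

    def copy(self) -> "CohortTable":
        return CohortTable(self.abundance.copy(), self.unit, self.samples.copy())


class Cohort(NamedTuple):
    """Bundle returned by :func:`load_cohort`."""

    table: CohortTable
    meta: pd.DataFrame
    diet: pd.DataFrame
    copy_numbers: pd.Series


def _rename(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if not column_map:
        return df
    inv = {v: k for k, v in column_map.items()}
    return df.rename(columns=inv)


def read_counts_tsv(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a samples-as-rows count table; first column is the sample id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = _rename(df, column_map)
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    return df


def read_biom_json(path: str | Path) -> pd.DataFrame:
    """Read a BIOM 1.0 (JSON) table into a samples x genera DataFrame."""
    with open(path) as fh:
        doc = json.load(fh)
    obs_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    # BIOM stores observations (genera) as rows; we use samples as rows
    return pd.DataFrame(mat.T, index=pd.Index(sample_ids, name="sample_id"), columns=obs_ids)


def load_cohort(
    counts_path: str | Path,
    meta_path: str | Path,
    diet_path: str | Path | None = None,
    cn_path: str | Path | None = None,
    unit: str = "reads",
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Load and join all cohort inputs into a validated :class:`Cohort`.

    Samples missing a microbial load are retained (flagged by a NaN load; QMP
    construction excludes them). Genera absent from the copy-number map are
    assigned the map's mean, with a log message.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".biom":
        counts = read_biom_json(counts_path)
    else:
        counts = read_counts_tsv(counts_path, column_map)
    # annotated tables (as written by write_cohort_table) carry these columns
    counts = counts.drop(columns=[c for c in ("participant_id", "day") if c in counts])

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "participant_id": str})
    meta = _rename(meta, column_map)
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    meta = meta.set_index("sample_id")

    missing = counts.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples without metadata: {list(missing)[:5]}")
    meta = meta.loc[counts.index]

    # 0-based day within participant (calendar offsets converted on load)
    day = meta["day"].astype(int)
    day = day - day.groupby(meta["participant_id"]).transform("min")
    meta = meta.assign(day=day)

    samples = meta[["participant_id", "day"]]
    table = CohortTable(abundance=counts, unit=unit, samples=samples).sorted()
    meta = meta.loc[table.sample_ids]

    if "load" in meta.columns and meta["load"].notna().any():
        bad = meta["load"].dropna() <= 0
        if bad.any():
            raise ValueError(f"non-positive loads: {meta.index[meta['load'] <= 0].tolist()}")
        n_missing = int(meta["load"].isna().sum())
        if n_missing:
            logger.info("%d samples lack a microbial load; unusable for QMP", n_missing)
    if "moisture" in meta.columns:
        m = meta["moisture"].dropna()
        if ((m <= 0) | (m >= 100)).any():
            raise ValueError("moisture must lie strictly between 0 and 100")

    if diet_path is not None:
        diet = pd.read_csv(diet_path, sep="\t", dtype={"participant_id": str})
        diet = _rename(diet, column_map)
        mass_cols = [c for c in ("carb_g", "protein_g", "fat_g", "fiber_g", "sodium_g") if c in diet]
        if (diet[mass_cols] < 0).any().any():
            raise ValueError("negative dietary masses")
    else:
        diet = pd.DataFrame(columns=["participant_id", "day", "carb_g", "protein_g", "fat_g"])

    if cn_path is not None:
        cn_df = pd.read_csv(cn_path, sep="\t")
        cn = pd.Series(cn_df.iloc[:, 1].to_numpy(dtype=float), index=cn_df.iloc[:, 0].astype(str))
        if (cn < 1).any() or not np.isfinite(cn).all():
            raise ValueError("copy numbers must be finite and >= 1")
        absent = table.genus_ids.difference(cn.index)
        if len(absent):
            logger.info(
                "%d genera absent from the copy-number map; mean-imputed (%.3f)",
                len(absent), cn.mean(),
            )
            cn = pd.concat([cn, pd.Series(cn.mean(), index=absent)])
        cn = cn.loc[table.genus_ids]
    else:
        cn = pd.Series(1.0, index=table.genus_ids)
    cn.index.name = "genus_id"
    cn.name = "copy_number"

    return Cohort(table=table, meta=meta, diet=diet, copy_numbers=cn)


# ---------------------------------------------------------------------------
# writing

FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    """Write abundance + annotations to ``path`` (TSV, deterministic order)."""
    out = table.sorted()
    joined = pd.concat([out.samples, out.abundance], axis=1)
    write_table(joined, path)


def read_cohort_table(path: str | Path, unit: str) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "participant_id": str})
    df = df.set_index("sample_id")
    samples = df[["participant_id", "day"]].assign(day=df["day"].astype(int))
    abundance = df.drop(columns=["participant_id", "day"])
    if unit == "reads":
        abundance = abundance.round().astype(np.int64)
    return CohortTable(abundance=abundance, unit=unit, samples=samples)


def _jsonable(obj):
    if obj is None or isinstance(obj, (str, bool, int, float)):
        return obj
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if hasattr(obj, "to_json_dict"):
        return obj.to_json_dict()
    if hasattr(obj, "__dict__"):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_results(obj, path: str | Path, format: str = "tsv") -> None:
    """Write any pipeline result.

    DataFrames go to TSV with 12 significant digits; any other object (model
    dataclasses, nested dicts) goes to JSON via a generic encoder.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        if isinstance(obj, pd.Series):
            obj = obj.to_frame()
        if not isinstance(obj, pd.DataFrame):
            raise TypeError("TSV output requires a DataFrame; use format='json'")
        write_table(obj, path)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(obj, fh, default=_jsonable, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
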