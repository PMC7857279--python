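"""Read, validate, filter, and aggregate mating-group observations.

Data layout (long format, one file per measurement episode):

* ``groups``      -- one row per focal x mating group: mating counts.
* ``recipients``  -- one row per sperm recipient (4 per group): sperm and
  offspring counts, with ``total_sperm`` left empty when an egg in the
  antrum prevented counting (``egg_in_antrum`` must then be true).
* ``penetrance``  -- one row per focal: marker-penetrance screen counts.

All operations take and return a :class:`Dataset` of three DataFrames so
the pipeline stages compose without re-reading files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    GROUP_LABELS,
    GroupObservation,
    PenetranceRecord,
    RecipientObservation,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

GROUP_COLUMNS = ["replicate_id", "batch", "group_label", "total_matings", "focal_matings"]
RECIPIENT_COLUMNS = [
    "replicate_id",
    "group_label",
    "recipient_index",
    "total_sperm",
    "focal_sperm",
    "egg_in_antrum",
    "total_offspring",
    "focal_offspring",
]
PENETRANCE_COLUMNS = ["replicate_id", "offspring_screened", "gfp_positive"]

_TABLE_COLUMNS = {
    "groups": GROUP_COLUMNS,
    "recipients": RECIPIENT_COLUMNS,
    "penetrance": PENETRANCE_COLUMNS,
}


@dataclass
class Dataset:
    """The three observation tables of one experiment."""

    groups: pd.DataFrame
    recipients: pd.DataFrame
    penetrance: pd.DataFrame

    def copy(self) -> "Dataset":
        return Dataset(
            self.groups.copy(), self.recipients.copy(), self.penetrance.copy()
        )

    @property
    def replicate_ids(self) -> list:
        return sorted(self.groups["replicate_id"].unique())

    def subset(self, replicate_ids) -> "Dataset":
        """Restrict all tables to the given focals (order-preserving, no dedup)."""
        ids = set(replicate_ids)
        return Dataset(
            self.groups[self.groups["replicate_id"].isin(ids)].reset_index(drop=True),
            self.recipients[self.recipients["replicate_id"].isin(ids)].reset_index(drop=True),
            self.penetrance[self.penetrance["replicate_id"].isin(ids)].reset_index(drop=True),
        )


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].unique()[:5]
        raise SchemaError(f"cannot interpret boolean values {list(bad)}")
    return out.astype(bool)


def _apply_schema(df: pd.DataFrame, table: str, schema: Optional[Mapping]) -> pd.DataFrame:
    """Rename file columns to canonical names and check presence."""
    if schema and table in schema:
        df = df.rename(columns={v: k for k, v in schema[table].items()})
    missing = [c for c in _TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {', '.join(missing)}")
    return df[_TABLE_COLUMNS[table]].copy()


def read_observations(
    path,
    schema: Optional[Mapping] = None,
    *,
    groups_file: str = "groups.csv",
    recipients_file: str = "recipients.csv",
    penetrance_file: str = "penetrance.csv",
    validate: bool = True,
):
    """Read a dataset directory into a validated :class:`Dataset`.

    Parameters
    ----------
    path:
        Directory containing the three CSV/TSV tables.
    schema:
        Optional nested mapping ``{table: {canonical: file_column}}``
        renaming file columns to the canonical schema.
    validate:
        When true (default), invariant violations raise
        :class:`~repsel.types.ValidationError` with row-level diagnostics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames = {}
    for table, fname in (
        ("groups", groups_file),
        ("recipients", recipients_file),
        ("penetrance", penetrance_file),
    ):
        fpath = path / fname
        if not fpath.exists():
            raise FileNotFoundError(fpath)
        sep = "\t" if fpath.suffix.lower() in {".tsv", ".tab"} else ","
        frames[table] = _apply_schema(pd.read_csv(fpath, sep=sep), table, schema)

    groups = frames["groups"]
    recipients = frames["recipients"]
    penetrance = frames["penetrance"]

    groups["replicate_id"] = groups["replicate_id"].astype(str)
    recipients["replicate_id"] = recipients["replicate_id"].astype(str)
    penetrance["replicate_id"] = penetrance["replicate_id"].astype(str)
    recipients["egg_in_antrum"] = _coerce_bool(recipients["egg_in_antrum"])
    recipients["total_sperm"] = pd.to_numeric(recipients["total_sperm"], errors="coerce")

    ds = Dataset(groups, recipients, penetrance)
    if validate:
        validate_dataset(ds)
    logger.info(
        "read %d group rows, %d recipient rows, %d penetrance rows from %s",
        len(groups), len(recipients), len(penetrance), path,
    )
    return ds


def validate_dataset(ds: Dataset) -> None:
    """Check every row against the type invariants.

    Raises :class:`ValidationError` whose ``rows`` attribute lists
    ``(table, row_index, message)`` for each offending row.
    """
    bad = []

    g = ds.groups
    for idx in g.index[g["focal_matings"] > g["total_matings"]]:
        bad.append(("groups", idx, "focal_matings > total_matings"))
    for idx in g.index[(g[["total_matings", "focal_matings"]] < 0).any(axis=1)]:
        bad.append(("groups", idx, "negative mating count"))
    for idx in g.index[~g["group_label"].isin(GROUP_LABELS)]:
        bad.append(("groups", idx, f"group_label not in {GROUP_LABELS}"))
    dup = g.duplicated(subset=["replicate_id", "group_label"], keep=False)
    for idx in g.index[dup]:
        bad.append(("groups", idx, "duplicate replicate_id x group_label"))

    r = ds.recipients
    observed = r["total_sperm"].notna()
    for idx in r.index[observed & (r["focal_sperm"] > r["total_sperm"])]:
        bad.append(("recipients", idx, "focal_sperm > total_sperm"))
    for idx in r.index[~observed & ~r["egg_in_antrum"]]:
        bad.append(("recipients", idx, "total_sperm missing without egg_in_antrum"))
    for idx in r.index[r["focal_offspring"] > r["total_offspring"]]:
        bad.append(("recipients", idx, "focal_offspring > total_offspring"))
    counts = r[["focal_sperm", "total_offspring", "focal_offspring"]]
    for idx in r.index[(counts < 0).any(axis=1) | (r["total_sperm"] < 0)]:
        bad.append(("recipients", idx, "negative count"))
    for idx in r.index[~r["recipient_index"].between(1, 4)]:
        bad.append(("recipients", idx, "recipient_index outside 1-4"))
    # recipients must belong to a known group row
    keys = set(map(tuple, g[["replicate_id", "group_label"]].itertuples(index=False)))
    rkeys = list(map(tuple, r[["replicate_id", "group_label"]].itertuples(index=False)))
    for idx, key in zip(r.index, rkeys):
        if key not in keys:
            bad.append(("recipients", idx, f"no matching group row for {key}"))

    p = ds.penetrance
    for idx in p.index[p["gfp_positive"] > p["offspring_screened"]]:
        bad.append(("penetrance", idx, "gfp_positive > offspring_screened"))
    for idx in p.index[(p[["offspring_screened", "gfp_positive"]] < 0).any(axis=1)]:
        bad.append(("penetrance", idx, "negative count"))

    if bad:
        lines = "; ".join(f"{t}[row {i}]: {m}" for t, i, m in bad[:20])
        raise ValidationError(
            f"{len(bad)} invariant violation(s): {lines}", rows=bad
        )


def to_observations(ds: Dataset):
    """Convert a validated dataset into record objects.

    Returns (list of :class:`GroupObservation`, list of :class:`PenetranceRecord`).
    """
    rec_by_key = {}
    for row in ds.recipients.itertuples(index=False):
        total = None if pd.isna(row.total_sperm) else int(row.total_sperm)
        rec = RecipientObservation(
            replicate_id=str(row.replicate_id),
            group_label=row.group_label,
            recipient_index=int(row.recipient_index),
            total_sperm=total,
            focal_sperm=int(row.focal_sperm),
            egg_in_antrum=bool(row.egg_in_antrum),
            total_offspring=int(row.total_offspring),
            focal_offspring=int(row.focal_offspring),
        )
        rec_by_key.setdefault((rec.replicate_id, rec.group_label), []).append(rec)
    groups = []
    for row in ds.groups.itertuples(index=False):
        recs = sorted(
            rec_by_key.get((str(row.replicate_id), row.group_label), []),
            key=lambda r: r.recipient_index,
        )
        groups.append(
            GroupObservation(
                replicate_id=str(row.replicate_id),
                batch=int(row.batch),
                group_label=row.group_label,
                total_matings=int(row.total_matings),
                focal_matings=int(row.focal_matings),
                recipients=tuple(recs),
            )
        )
    pens = [
        PenetranceRecord(str(r.replicate_id), int(r.offspring_screened), int(r.gfp_positive))
        for r in ds.penetrance.itertuples(index=False)
    ]
    return groups, pens


def write_dataset(ds: Dataset, path) -> None:
    """Write the three tables as CSV (missing total_sperm as empty field)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ds.groups.to_csv(path / "groups.csv", index=False)
    rec = ds.recipients.copy()
    # keep integer rendering for observed totals despite the NaN column
    rec["total_sperm"] = rec["total_sperm"].astype("Int64")
    rec.to_csv(path / "recipients.csv", index=False)
    ds.penetrance.to_csv(path / "penetrance.csv", index=False)


def apply_penetrance_filter(
    ds: Dataset,
    min_fraction: float = 0.90,
    require_offspring: bool = True,
):
    """Drop all observations of focals failing the marker-penetrance screen.

    A focal is excluded when its screened-offspring marker fraction falls
    below ``min_fraction``, or when it produced no screened offspring at all
    and ``require_offspring`` is set. Focals without a penetrance record are
    flagged in the report but retained. No per-offspring correction is ever
    applied to retained focals.

    Returns (filtered Dataset, report DataFrame with columns
    ``replicate_id``, ``action``, ``reason``).
    """
    pen = ds.penetrance.set_index("replicate_id")
    report_rows = []
    excluded = set()
    for rid in ds.replicate_ids:
        if rid not in pen.index:
            report_rows.append((rid, "flagged", "no penetrance record"))
            continue
        screened = int(pen.loc[rid, "offspring_screened"])
        positive = int(pen.loc[rid, "gfp_positive"])
        if screened == 0:
            if require_offspring:
                excluded.add(rid)
                report_rows.append((rid, "excluded", "no offspring in penetrance screen"))
            else:
                report_rows.append((rid, "flagged", "no offspring in penetrance screen"))
            continue
        frac = positive / screened
        if frac < min_fraction:
            excluded.add(rid)
            report_rows.append(
                (rid, "excluded", f"penetrance {frac:.2f} < {min_fraction:.2f}")
            )
    report = pd.DataFrame(report_rows, columns=["replicate_id", "action", "reason"])
    kept = [rid for rid in ds.replicate_ids if rid not in excluded]
    filtered = ds.subset(kept)
    logger.info(
        "penetrance filter: %d focals excluded, %d retained",
        len(excluded), len(kept),
    )
    return filtered, report


def group_counts(ds: Dataset) -> pd.DataFrame:
    """Per focal x group summed counts (the per-group analysis unit).

    Requires imputed sperm totals if any egg-bearing recipient lacks one
    (see :func:`repsel.fitness.impute_total_sperm`).
    """
    if ds.recipients["total_sperm"].isna().any():
        raise ValidationError(
            "recipients with missing total_sperm present; run sperm imputation first"
        )
    rec = (
        ds.recipients.groupby(["replicate_id", "group_label"])
        .agg(
            s_t=("total_sperm", "sum"),
            s_f=("focal_sperm", "sum"),
            o_t=("total_offspring", "sum"),
            o_f=("focal_offspring", "sum"),
        )
        .reset_index()
    )
    out = ds.groups.merge(rec, on=["replicate_id", "group_label"], how="left")
    sums = out[["s_t", "s_f", "o_t", "o_f"]]
    if sums.isna().any().any():
        missing = out.loc[sums.isna().any(axis=1), ["replicate_id", "group_label"]]
        raise ValidationError(
            "group rows without recipient rows: "
            + ", ".join(f"{r.replicate_id}/{r.group_label}" for r in missing.itertuples())
        )
    out = out.rename(columns={"total_matings": "m_t", "focal_matings": "m_f"})
    return out[["replicate_id", "batch", "group_label", "m_t", "m_f", "s_t", "s_f", "o_t", "o_f"]]


def aggregate_replicates(ds: Dataset) -> pd.DataFrame:
    """Sum counts across a focal's mating groups.

    Focals observed in fewer than three groups are retained (sums run over
    the available groups); ``groups_present`` records which contributed.

    Returns a DataFrame with one row per replicate_id and columns
    ``batch, m_t, m_f, s_t, s_f, o_t, o_f, groups_present``.
    """
    per_group = group_counts(ds)
    if per_group.empty:
        raise ValidationError("no groups to aggregate")
    agg = (
        per_group.groupby("replicate_id")
        .agg(
            batch=("batch", "first"),
            m_t=("m_t", "sum"),
            m_f=("m_f", "sum"),
            s_t=("s_t", "sum"),
            s_f=("s_f", "sum"),
            o_t=("o_t", "sum"),
            o_f=("o_f", "sum"),
            groups_present=("group_label", lambda s: "".join(sorted(s))),
        )
        .reset_index()
    )
    return agg
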