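"""Domain types for the mating-group fitness pipeline.

The tabular layer (``repsel.io_data``) works on pandas DataFrames; the
dataclasses here are the validated record-level view of the same data and
define the invariants every table must satisfy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

GROUP_LABELS = ("B", "C", "D")
#: Component labels in canonical order (F, MS, STE, SFE) plus reproductive success.
COMPONENTS = ("F", "MS", "STE", "SFE")
ALL_MEASURES = ("mRS",) + COMPONENTS


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """One or more rows violate a type invariant.

    Attributes
    ----------
    rows : list of (row index, message)
    """

    def __init__(self, message: str, rows: Optional[Sequence[tuple]] = None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


@dataclass(frozen=True)
class RecipientObservation:
    """Sperm and offspring counts for one sperm recipient.

    ``total_sperm`` is None when an egg in the antrum prevented counting;
    such recipients are the unit of sperm imputation.
    """

    replicate_id: str
    group_label: str
    recipient_index: int
    total_sperm: Optional[int]
    focal_sperm: int
    egg_in_antrum: bool
    total_offspring: int
    focal_offspring: int

    def __post_init__(self):
        errs = []
        if self.group_label not in GROUP_LABELS:
            errs.append(f"group_label {self.group_label!r} not in {GROUP_LABELS}")
        if not 1 <= self.recipient_index <= 4:
            errs.append(f"recipient_index {self.recipient_index} outside 1-4")
        for name in ("focal_sperm", "total_offspring", "focal_offspring"):
            if getattr(self, name) < 0:
                errs.append(f"{name} negative")
        if self.total_sperm is None:
            if not self.egg_in_antrum:
                errs.append("total_sperm missing without egg_in_antrum flag")
        else:
            if self.total_sperm < 0:
                errs.append("total_sperm negative")
            if self.focal_sperm > self.total_sperm:
                errs.append(
                    f"focal_sperm {self.focal_sperm} > total_sperm {self.total_sperm}"
                )
        if self.focal_offspring > self.total_offspring:
            errs.append(
                f"focal_offspring {self.focal_offspring} > total_offspring "
                f"{self.total_offspring}"
            )
        if errs:
            raise ValidationError(
                f"recipient {self.replicate_id}/{self.group_label}/"
                f"{self.recipient_index}: " + "; ".join(errs)
            )


@dataclass(frozen=True)
class GroupObservation:
    """One focal x one mating group: mating counts plus its four recipients."""

    replicate_id: str
    batch: int
    group_label: str
    total_matings: int
    focal_matings: int
    recipients: tuple = field(default_factory=tuple)

    def __post_init__(self):
        errs = []
        if self.group_label not in GROUP_LABELS:
            errs.append(f"group_label {self.group_label!r} not in {GROUP_LABELS}")
        if self.total_matings < 0 or self.focal_matings < 0:
            errs.append("negative mating count")
        if self.focal_matings > self.total_matings:
            errs.append(
                f"focal_matings {self.focal_matings} > total_matings "
                f"{self.total_matings}"
            )
        if self.recipients and len(self.recipients) != 4:
            errs.append(f"expected 4 recipients, got {len(self.recipients)}")
        for r in self.recipients:
            if r.replicate_id != self.replicate_id or r.group_label != self.group_label:
                errs.append("recipient keys do not match group keys")
        if errs:
            raise ValidationError(
                f"group {self.replicate_id}/{self.group_label}: " + "; ".join(errs)
            )


@dataclass(frozen=True)
class PenetranceRecord:
    """Marker-penetrance screen for one focal."""

    replicate_id: str
    offspring_screened: int
    gfp_positive: int

    def __post_init__(self):
        if self.offspring_screened < 0 or self.gfp_positive < 0:
            raise ValidationError(f"penetrance {self.replicate_id}: negative count")
        if self.gfp_positive > self.offspring_screened:
            raise ValidationError(
                f"penetrance {self.replicate_id}: gfp_positive "
                f"{self.gfp_positive} > offspring_screened {self.offspring_screened}"
            )

    @property
    def fraction(self) -> float:
        if self.offspring_screened == 0:
            return math.nan
        return self.gfp_positive / self.offspring_screened


@dataclass(frozen=True)
class ReplicateAggregate:
    """Counts summed over a focal's mating groups (after sperm imputation)."""

    replicate_id: str
    batch: int
    m_t: int
    m_f: int
    s_t: float
    s_f: int
    o_t: int
    o_f: int
    groups_present: frozenset = frozenset()

    def __post_init__(self):
        errs = []
        if self.m_f > self.m_t:
            errs.append("m_f > m_t")
        if self.s_f > self.s_t:
            errs.append("s_f > s_t")
        if self.o_f > self.o_t:
            errs.append("o_f > o_t")
        if min(self.m_t, self.m_f, self.s_t, self.s_f, self.o_t, self.o_f) < 0:
            errs.append("negative count")
        if errs:
            raise ValidationError(
                f"aggregate {self.replicate_id}: " + "; ".join(errs)
            )


@dataclass(frozen=True)
class FitnessVector:
    """The five fitness quantities of one focal; STE/SFE may be undefined."""

    replicate_id: str
    F: float
    MS: Optional[float]
    STE: Optional[float]
    SFE: Optional[float]
    mRS: float

    def product_defined(self) -> bool:
        return all(
            v is not None and not (isinstance(v, float) and math.isnan(v))
            for v in (self.F, self.MS, self.STE, self.SFE)
        )
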