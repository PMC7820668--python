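"""Sample/project metadata, database curation, and browsing filters.

Every database sample carries a unified metadata record: habitat fields
(domain, type, details), sampling context, sequencing technology, and the
NSTI reliability score for 16S-inferred functional profiles.  Curation
excludes samples lacking habitat information and amplicon samples with
fewer than 500 total reads or more than 20% unannotatable reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .profiles import Profile

__all__ = [
    "HABITAT_DOMAINS",
    "DEFAULT_HABITAT_TYPES",
    "HABITAT_TYPE_DOMAIN",
    "SampleRecord",
    "ProjectRecord",
    "MetadataStore",
    "CurationReport",
    "MIN_AMPLICON_READS",
    "MAX_UNANNOTATED_FRACTION",
    "curate_sample",
    "curate_store",
    "filter_samples",
    "load_metadata",
    "save_metadata",
]

#: The three unified habitat domains.
HABITAT_DOMAINS = ("human associated", "animal associated", "environment")

#: Configurable 22-category habitat-type vocabulary (users may supply their
#: own); each type maps to its habitat domain.
HABITAT_TYPE_DOMAIN: dict[str, str] = {
    "gut": "human associated",
    "oral": "human associated",
    "skin": "human associated",
    "airways": "human associated",
    "urogenital": "human associated",
    "milk": "human associated",
    "blood": "human associated",
    "human other": "human associated",
    "animal gut": "animal associated",
    "animal oral": "animal associated",
    "animal skin": "animal associated",
    "animal surface": "animal associated",
    "insect": "animal associated",
    "animal other": "animal associated",
    "soil": "environment",
    "marine": "environment",
    "freshwater": "environment",
    "sediment": "environment",
    "plant": "environment",
    "indoor": "environment",
    "wastewater": "environment",
    "environment other": "environment",
}
DEFAULT_HABITAT_TYPES = tuple(HABITAT_TYPE_DOMAIN)

# Curation thresholds for amplicon samples, strict as printed: a sample with
# 499 reads is excluded and 500 is kept; unannotated 0.201 is excluded and
# 0.200 is kept.
MIN_AMPLICON_READS = 500
MAX_UNANNOTATED_FRACTION = 0.20


@dataclass
class SampleRecord:
    """Unified per-sample metadata."""

    project_id: str
    sample_id: str
    habitat_domain: str | None = None
    habitat_type: str | None = None
    habitat_details: str | None = None
    sampling_site: str | None = None
    sampling_product: str | None = None
    date: str | None = None
    country_region: str | None = None
    gender: str | None = None
    age: str | None = None
    description: str | None = None
    amplicon_sequence_type: str | None = None
    amplicon_platform: str | None = None
    has_wgs: bool = False
    wgs_platform: str | None = None
    has_function: bool = False
    nsti: float | None = None
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id.startswith(self.project_id):
            raise ValidationError(
                f"sample id {self.sample_id!r} must begin with its project id "
                f"{self.project_id!r}"
            )
        if self.habitat_domain is not None and self.habitat_domain not in HABITAT_DOMAINS:
            raise ValidationError(
                f"habitat_domain {self.habitat_domain!r} is not one of {HABITAT_DOMAINS}"
            )
        if self.nsti is not None and self.nsti < 0:
            raise ValidationError(f"nsti must be >= 0, got {self.nsti}")

    @property
    def is_amplicon(self) -> bool:
        return (
            self.amplicon_sequence_type is not None
            or self.amplicon_platform is not None
        )


@dataclass
class ProjectRecord:
    """Unified per-project metadata."""

    project_id: str
    title: str | None = None
    institute: str | None = None
    principal_investigator: str | None = None
    publication_title: str | None = None
    publication_journal: str | None = None
    source_link: str | None = None
    sequence_type: str | None = None
    date: str | None = None


_SAMPLE_FIELDS = [
    f.name for f in dc_fields(SampleRecord) if f.name != "extras"
]
_BOOL_FIELDS = {"has_wgs", "has_function"}


class MetadataStore:
    """An ordered collection of sample records, keyed by sample id."""

    def __init__(self, records: Iterable[SampleRecord] = ()) -> None:
        self._records: dict[str, SampleRecord] = {}
        self.extra_columns: list[str] = []
        for record in records:
            self.add(record)

    def add(self, record: SampleRecord) -> None:
        if record.sample_id in self._records:
            raise ValidationError(f"duplicate sample id {record.sample_id!r}")
        self._records[record.sample_id] = record
        for col in record.extras:
            if col not in self.extra_columns:
                self.extra_columns.append(col)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._records

    def __iter__(self):
        return iter(self.sample_ids())

    def get(self, sample_id: str) -> SampleRecord | None:
        return self._records.get(sample_id)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._records[sample_id]

    def sample_ids(self) -> list[str]:
        return sorted(self._records)

    def records(self) -> list[SampleRecord]:
        return [self._records[sid] for sid in self.sample_ids()]

    def subset(self, sample_ids: Iterable[str]) -> "MetadataStore":
        return MetadataStore(self._records[sid] for sid in sorted(sample_ids))


@dataclass(frozen=True)
class CurationReport:
    """Partition of a store into retained samples and excluded samples with
    their (single, first-triggered) exclusion reason."""

    retained: list[str]
    excluded: list[tuple[str, str]]


def curate_sample(
    record: SampleRecord, profile: Profile
) -> tuple[bool, str | None]:
    """Apply the curation rules to one sample.

    Rules, checked in fixed order for determinism:

    1. ``missing_habitat`` — habitat domain, type and details all absent;
    2. ``low_reads`` — amplicon sample with total reads < 500;
    3. ``high_unannotated`` — amplicon sample with > 20% unannotatable reads.
    """
    if (
        record.habitat_domain is None
        and record.habitat_type is None
        and record.habitat_details is None
    ):
        return False, "missing_habitat"
    if record.is_amplicon:
        if profile.total_reads is None:
            raise ValidationError(
                f"amplicon sample {record.sample_id!r} lacks total_reads"
            )
        if profile.unannotated_fraction is None:
            raise ValidationError(
                f"amplicon sample {record.sample_id!r} lacks unannotated_fraction"
            )
        if profile.total_reads < MIN_AMPLICON_READS:
            return False, "low_reads"
        if profile.unannotated_fraction > MAX_UNANNOTATED_FRACTION:
            return False, "high_unannotated"
    return True, None


def curate_store(
    store: MetadataStore, profiles: Mapping[str, Profile]
) -> CurationReport:
    """Curate every sample in *store*; retained/excluded partition the input."""
    retained: list[str] = []
    excluded: list[tuple[str, str]] = []
    for sid in store.sample_ids():
        profile = profiles.get(sid)
        if profile is None:
            raise ValidationError(f"no profile for sample {sid!r}")
        keep, reason = curate_sample(store[sid], profile)
        if keep:
            retained.append(sid)
        else:
            excluded.append((sid, reason))
    return CurationReport(retained=retained, excluded=excluded)


def filter_samples(
    store: MetadataStore, criteria: Mapping[str, object]
) -> list[SampleRecord]:
    """Conjunctive metadata filter for browsing.

    Each criterion maps a schema field (or preserved extra column) to a
    value or a set of acceptable values.  Records matching all criteria are
    returned ordered by sample id; an unknown field is an error.
    """
    known = set(_SAMPLE_FIELDS) | set(store.extra_columns)
    for key in criteria:
        if key not in known:
            raise ValidationError(f"unknown metadata field {key!r}")
    out: list[SampleRecord] = []
    for record in store.records():
        ok = True
        for key, wanted in criteria.items():
            actual = (
                record.extras.get(key)
                if key in store.extra_columns and key not in _SAMPLE_FIELDS
                else getattr(record, key)
            )
            accepted = (
                wanted
                if isinstance(wanted, (set, frozenset, list, tuple))
                else (wanted,)
            )
            if actual not in accepted:
                ok = False
                break
        if ok:
            out.append(record)
    return out


# ---------------------------------------------------------------------------
# TSV serialization (one column per unified field; extra columns preserved)
# ---------------------------------------------------------------------------


def _to_cell(name: str, value: object) -> str:
    if value is None:
        return ""
    if name in _BOOL_FIELDS:
        return "true" if value else "false"
    return str(value)


def _from_cell(name: str, raw: str) -> object:
    if raw == "":
        return False if name in _BOOL_FIELDS else None
    if name in _BOOL_FIELDS:
        return raw.strip().lower() in {"true", "yes", "1"}
    if name == "nsti":
        return float(raw)
    return raw


def save_metadata(store: MetadataStore, path: str | Path) -> None:
    columns = _SAMPLE_FIELDS + store.extra_columns
    rows = []
    for record in store.records():
        row = {name: _to_cell(name, getattr(record, name)) for name in _SAMPLE_FIELDS}
        for col in store.extra_columns:
            row[col] = record.extras.get(col, "")
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)


def load_metadata(path: str | Path) -> MetadataStore:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("project_id", "sample_id") if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in frame.columns if c not in _SAMPLE_FIELDS]
    store = MetadataStore()
    for _, row in frame.iterrows():
        kwargs = {
            name: _from_cell(name, row[name])
            for name in _SAMPLE_FIELDS
            if name in frame.columns
        }
        extras = {col: row[col] for col in extra_cols}
        store.add(SampleRecord(extras=extras, **kwargs))
    # preserve original extra-column order even for all-empty columns
    store.extra_columns = extra_cols
    return store
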