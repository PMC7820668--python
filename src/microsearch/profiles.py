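"""Compositional profiles and taxonomy lineages.

A microbiome sample is represented as a compositional profile: a mapping from
feature identifiers (OTUs, species, or KEGG Orthology IDs) to non-negative
relative abundances.  Profiles are the common currency of the whole package:
the similarity metrics, the index keys and the search all operate on
normalized profiles.

This module also parses Greengenes-style taxonomy lineage strings
(``k__Bacteria;p__Firmicutes;...``) into fixed seven-rank lineages, and
applies 16S amplicon copy-number correction to OTU profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "FeatureSpace",
    "Profile",
    "TaxonomyLineage",
    "UNCLASSIFIED",
    "RANK_NAMES",
    "RANK_PREFIXES",
    "normalize",
    "copy_number_correct",
    "parse_lineage",
    "lineage_to_string",
    "read_profile",
    "write_profile",
    "read_database_matrix",
    "write_database_matrix",
    "read_copy_numbers",
    "write_copy_numbers",
    "read_lineages",
    "write_lineages",
    "read_ko_map",
    "write_ko_map",
]


class FeatureSpace(str, Enum):
    """The three feature spaces a profile can live in."""

    OTU = "otu"
    SPECIES = "species"
    KO = "ko"


#: Sentinel label for a taxonomic rank without an assigned name.
UNCLASSIFIED = "UNCLASSIFIED"

RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_TO_RANK = {p: i for i, p in enumerate(RANK_PREFIXES)}


@dataclass(frozen=True)
class Profile:
    """A sample's compositional vector in one feature space.

    Parameters
    ----------
    feature_space
        Which feature space the identifiers belong to.
    abundances
        Mapping feature_id -> non-negative abundance.  Not necessarily
        normalized; :func:`normalize` returns the relative-abundance form.
    total_reads
        Sequencing depth of the sample, when known.  Used by database
        curation (amplicon samples below 500 reads are excluded).
    unannotated_fraction
        Fraction of reads that could not be annotated, in [0, 1].  Amplicon
        samples above 0.20 are excluded by curation.
    """

    feature_space: FeatureSpace
    abundances: dict[str, float]
    total_reads: int | None = None
    unannotated_fraction: float | None = None

    def __post_init__(self) -> None:
        for fid, value in self.abundances.items():
            if not math.isfinite(value):
                raise ValidationError(f"non-finite abundance for feature {fid!r}")
            if value < 0:
                raise ValidationError(f"negative abundance for feature {fid!r}: {value}")
        if self.unannotated_fraction is not None and not (
            0.0 <= self.unannotated_fraction <= 1.0
        ):
            raise ValidationError(
                f"unannotated_fraction must lie in [0, 1], got {self.unannotated_fraction}"
            )
        if self.total_reads is not None and self.total_reads < 0:
            raise ValidationError(f"total_reads must be >= 0, got {self.total_reads}")

    @property
    def total(self) -> float:
        return math.fsum(self.abundances.values())

    def is_normalized(self, tol: float = 1e-9) -> bool:
        return abs(self.total - 1.0) <= tol


def normalize(profile: Profile) -> Profile:
    """Return the relative-abundance form of *profile* (values sum to 1).

    Proportions are preserved exactly; an all-zero profile is an error.
    The division is iterated until the compensated sum equals 1.0 exactly,
    which makes the operation idempotent bit-for-bit.
    """
    values = dict(profile.abundances)
    total = math.fsum(values.values())
    if total <= 0.0:
        raise ValidationError("cannot normalize an all-zero profile")
    for _ in range(10):
        if total == 1.0:
            break
        values = {k: v / total for k, v in values.items()}
        total = math.fsum(values.values())
    return Profile(
        feature_space=profile.feature_space,
        abundances=values,
        total_reads=profile.total_reads,
        unannotated_fraction=profile.unannotated_fraction,
    )


def copy_number_correct(profile: Profile, table: Mapping[str, float]) -> Profile:
    """Correct an OTU profile for 16S amplicon copy numbers.

    Each abundance is divided by its marker-gene copy number and the profile
    is renormalized, so organisms carrying many 16S copies are no longer
    over-represented.  Features missing from *table* default to copy number 1
    with a warning.
    """
    if profile.feature_space is not FeatureSpace.OTU:
        raise ValidationError(
            f"copy-number correction applies to OTU profiles, got {profile.feature_space.value!r}"
        )
    for fid, cn in table.items():
        if cn < 1.0:
            raise ValidationError(f"copy number for {fid!r} is {cn}, must be >= 1")
    missing = [fid for fid in profile.abundances if fid not in table]
    if missing:
        warnings.warn(
            f"{len(missing)} feature(s) missing from copy-number table; "
            f"defaulting to copy number 1 (e.g. {missing[0]!r})",
            stacklevel=2,
        )
    corrected = {fid: v / table.get(fid, 1.0) for fid, v in profile.abundances.items()}
    return normalize(
        Profile(
            feature_space=profile.feature_space,
            abundances=corrected,
            total_reads=profile.total_reads,
            unannotated_fraction=profile.unannotated_fraction,
        )
    )


# ---------------------------------------------------------------------------
# Taxonomy lineages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonomyLineage:
    """A fixed seven-rank lineage (kingdom .. species).

    Each slot holds either a rank label (without its ``k__``-style prefix) or
    the :data:`UNCLASSIFIED` sentinel.
    """

    ranks: tuple[str, str, str, str, str, str, str] = field(
        default=(UNCLASSIFIED,) * 7
    )

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValidationError(f"a lineage has 7 ranks, got {len(self.ranks)}")

    @property
    def kingdom(self) -> str:
        return self.ranks[0]

    @property
    def family(self) -> str:
        return self.ranks[4]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def species(self) -> str:
        return self.ranks[6]

    def deepest_classified(self) -> int:
        """Index of the deepest classified rank, or -1 if fully unclassified."""
        deepest = -1
        for i, label in enumerate(self.ranks):
            if label != UNCLASSIFIED:
                deepest = i
        return deepest

    def classified_prefix(self) -> tuple[str, ...]:
        """Prefixed labels down to the deepest classified rank.

        Internally-unclassified ranks (above the deepest classified one) are
        kept as placeholder tokens so the prefix length always equals
        ``deepest_classified() + 1``.
        """
        deepest = self.deepest_classified()
        return tuple(
            RANK_PREFIXES[i] + self.ranks[i] for i in range(deepest + 1)
        )


def parse_lineage(s: str) -> TaxonomyLineage:
    """Parse a Greengenes-style lineage string, leniently.

    Semicolon-separated tokens, each optionally carrying a rank prefix
    (``k__`` .. ``s__``).  Empty labels and missing trailing ranks map to
    :data:`UNCLASSIFIED`; a token with an unknown prefix is treated as a bare
    label at the next expected rank.
    """
    ranks = [UNCLASSIFIED] * 7
    if not s or not s.strip():
        return TaxonomyLineage(tuple(ranks))
    pointer = 0
    for raw in s.split(";"):
        token = raw.strip()
        if pointer >= 7:
            break
        if not token:
            pointer += 1
            continue
        prefix = token[:3]
        if prefix in _PREFIX_TO_RANK and _PREFIX_TO_RANK[prefix] >= pointer:
            idx = _PREFIX_TO_RANK[prefix]
            label = token[3:].strip()
        else:
            idx = pointer
            label = token
        ranks[idx] = label if label else UNCLASSIFIED
        pointer = idx + 1
    return TaxonomyLineage(tuple(ranks))


def lineage_to_string(lineage: TaxonomyLineage) -> str:
    """Serialize a lineage back to ``k__...;p__...;...`` form."""
    parts = []
    for prefix, label in zip(RANK_PREFIXES, lineage.ranks):
        parts.append(prefix + ("" if label == UNCLASSIFIED else label))
    return ";".join(parts)


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------


def read_profile(path: str | Path, feature_space: FeatureSpace | str) -> Profile:
    """Read a two-column ``feature_id<TAB>abundance`` TSV into a Profile.

    A ``#``-prefixed header line is skipped.  The returned profile is
    un-normalized; duplicate feature ids and negative abundances are errors.
    """
    feature_space = FeatureSpace(feature_space)
    abundances: dict[str, float] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"{path}: line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        fid, raw_value = fields[0].strip(), fields[1].strip()
        if not fid:
            raise ParseError(f"{path}: line {lineno}: empty feature id")
        try:
            value = float(raw_value)
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {lineno}: abundance {raw_value!r} is not a number"
            ) from exc
        if value < 0:
            raise ValidationError(
                f"{path}: line {lineno}: negative abundance {value} for {fid!r}"
            )
        if fid in abundances:
            raise ValidationError(f"{path}: line {lineno}: duplicate feature id {fid!r}")
        abundances[fid] = value
    return Profile(feature_space=feature_space, abundances=abundances)


def write_profile(profile: Profile, path: str | Path) -> None:
    """Write a profile as a two-column TSV (round-trips with read_profile)."""
    lines = ["#feature_id\tabundance"]
    for fid, value in profile.abundances.items():
        lines.append(f"{fid}\t{value!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_database_matrix(
    path: str | Path, feature_space: FeatureSpace | str
) -> dict[str, Profile]:
    """Read a samples-by-features abundance matrix TSV.

    First column is ``sample_id``, remaining columns are feature ids.
    Profiles are normalized on load, so the database always stores relative
    abundances regardless of the scale of the input counts.
    """
    feature_space = FeatureSpace(feature_space)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse matrix TSV: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate feature id {dup!r}")
    profiles: dict[str, Profile] = {}
    for sample_id, row in frame.iterrows():
        values = {fid: float(v) for fid, v in row.items() if float(v) != 0.0}
        profiles[str(sample_id)] = normalize(
            Profile(feature_space=feature_space, abundances=values)
        )
    return profiles


def write_database_matrix(profiles: Mapping[str, Profile], path: str | Path) -> None:
    """Write profiles as a samples-by-features matrix TSV (union of features)."""
    feature_ids = sorted({fid for p in profiles.values() for fid in p.abundances})
    lines = ["sample_id\t" + "\t".join(feature_ids)]
    for sample_id in sorted(profiles):
        abund = profiles[sample_id].abundances
        row = "\t".join(repr(abund.get(fid, 0.0)) for fid in feature_ids)
        lines.append(f"{sample_id}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_copy_numbers(path: str | Path) -> dict[str, float]:
    """Read a ``feature_id<TAB>copy_number`` TSV; all values must be >= 1."""
    table: dict[str, float] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields")
        fid, raw = fields[0].strip(), fields[1].strip()
        try:
            cn = float(raw)
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: bad copy number {raw!r}") from exc
        if cn < 1.0:
            raise ValidationError(f"{path}: line {lineno}: copy number {cn} < 1")
        table[fid] = cn
    return table


def write_copy_numbers(table: Mapping[str, float], path: str | Path) -> None:
    lines = ["#feature_id\tcopy_number"]
    for fid in sorted(table):
        lines.append(f"{fid}\t{table[fid]!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_lineages(path: str | Path) -> dict[str, TaxonomyLineage]:
    """Read a ``feature_id<TAB>lineage_string`` TSV."""
    lineages: dict[str, TaxonomyLineage] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields")
        fid = fields[0].strip()
        if fid in lineages:
            raise ValidationError(f"{path}: line {lineno}: duplicate feature id {fid!r}")
        lineages[fid] = parse_lineage(fields[1])
    return lineages


def write_lineages(lineages: Mapping[str, TaxonomyLineage], path: str | Path) -> None:
    lines = ["#feature_id\tlineage"]
    for fid in sorted(lineages):
        lines.append(f"{fid}\t{lineage_to_string(lineages[fid])}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ko_map(path: str | Path) -> dict[str, list[str]]:
    """Read a KO -> BRITE level-2 pathway map.

    Format: ``ko_id<TAB>pathway[;pathway...]``.  A KO may map to several
    level-2 pathways.
    """
    ko_map: dict[str, list[str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields")
        ko = fields[0].strip()
        if ko in ko_map:
            raise ValidationError(f"{path}: line {lineno}: duplicate KO id {ko!r}")
        pathways = [p.strip() for p in fields[1].split(";") if p.strip()]
        ko_map[ko] = pathways
    return ko_map


def write_ko_map(ko_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = ["#ko_id\tlevel2_pathways"]
    for ko in sorted(ko_map):
        lines.append(f"{ko}\t{';'.join(ko_map[ko])}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
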