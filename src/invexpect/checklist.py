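"""Nonindigenous-species (NIS) checklists and their summary statistics.

A checklist is one recipient system's curated list of established NIS. Each
record carries a scientific name, a kingdom/phylum/class assignment, the set
of native (donor) regions, and per-subregion presence flags (e.g. North Sea
vs Baltic Sea within the pooled North-Baltic system).

The summaries implemented here are the standard descriptive layer of an
origin analysis:

* fractional origin attribution -- a species native to k regions contributes
  1/k to each of them, so the region tallies sum exactly to the number of
  species (conservation);
* taxonomic composition at a chosen rank, optionally excluding phyla (vascular
  plants are commonly excluded as a sensitivity view);
* subregion overlap partitions (only-A / only-B / both);
* shared species between two recipient systems;
* a donor-by-recipient flow matrix, in the conservative fractional convention
  or the flow-count convention that books one unit flow per native region.

Fractional tallies use exact rational arithmetic (:class:`fractions.Fraction`)
so conservation holds to equality, not merely to tolerance.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError
from .regions import REGION_CODES, validate_region

logger = logging.getLogger(__name__)

#: logical column names understood by :func:`load_checklist`
CORE_COLUMNS = ("name", "kingdom", "phylum", "class", "native_regions")

_SYNONYM_RE = re.compile(r"\s*\(\s*=[^)]*\)\s*")
_WS_RE = re.compile(r"\s+")


def normalize_name(name: str, *, casefold: bool = True) -> str:
    """Normalize a scientific name for comparison.

    Strips inline bracketed synonyms of the form ``Genus (=Synonym) species``,
    collapses whitespace, and (by default) casefolds. The synonym convention
    appears verbatim in curated checklists, e.g.
    ``Chelicorophium (=Corophium) curvispinum``.
    """
    out = _SYNONYM_RE.sub(" ", name)
    out = _WS_RE.sub(" ", out).strip()
    return out.casefold() if casefold else out


@dataclass
class SpeciesRecord:
    """One NIS: name, taxonomy, native-range set, subregion presence flags."""

    name: str
    kingdom: str
    phylum: str
    klass: str  # class is reserved; may be empty at this rank only
    native_regions: frozenset[str]
    presence: dict[str, bool]

    def __post_init__(self) -> None:
        if not normalize_name(self.name):
            raise ValidationError("species name empty after normalization")
        if not self.native_regions:
            raise ValidationError(f"{self.name}: native_regions must be non-empty")
        for region in self.native_regions:
            validate_region(region, context=self.name)
        if not any(self.presence.values()):
            raise ValidationError(f"{self.name}: at least one presence flag must be true")

    @property
    def primary_name(self) -> str:
        """Synonym-stripped display form (original case)."""
        return normalize_name(self.name, casefold=False)

    @property
    def match_key(self) -> str:
        """Casefolded primary name used for identity and dedup."""
        return normalize_name(self.name)


@dataclass
class Checklist:
    """A recipient system's NIS list.

    ``recipient_region`` may be ``None`` for tables that span more than one
    recipient system (a cross-system compilation keeps subregions of both).
    """

    recipient_region: str | None
    subregion_ids: list[str]
    records: list[SpeciesRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.recipient_region is not None:
            validate_region(self.recipient_region, context="recipient_region")
        seen: set[str] = set()
        for rec in self.records:
            key = rec.match_key
            if key in seen:
                raise ValidationError(f"duplicate species name {rec.name!r}")
            seen.add(key)
            unknown = set(rec.presence) - set(self.subregion_ids)
            if unknown:
                raise ValidationError(
                    f"{rec.name}: presence keys {sorted(unknown)} not in subregions"
                )

    def __len__(self) -> int:
        return len(self.records)

    def names(self) -> set[str]:
        return {rec.primary_name for rec in self.records}

    def retained(self, exclude_phyla: Iterable[str] = ()) -> list[SpeciesRecord]:
        """Records after removing the given phyla (case-insensitive)."""
        excluded = {p.casefold() for p in exclude_phyla}
        return [r for r in self.records if r.phylum.casefold() not in excluded]


class PartitionCounts(NamedTuple):
    only_a: int
    only_b: int
    both: int
    total: int


def _resolve_schema(columns: Sequence[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    mapping = {name: name for name in CORE_COLUMNS}
    if schema:
        mapping.update(schema)
    missing = [col for col in mapping.values() if col not in columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return mapping


def load_checklist(
    path: str | Path,
    *,
    recipient_region: str | None = None,
    schema: Mapping[str, str] | None = None,
) -> Checklist:
    """Load a delimited-text checklist (comma or tab separated, UTF-8).

    Expected columns: ``name, kingdom, phylum, class, native_regions`` plus one
    0/1 presence column per subregion; ``native_regions`` is a
    semicolon-separated list of region codes. ``schema`` maps logical to actual
    column names for files with different headers.

    Rows duplicating a (normalized) species name are collapsed into a single
    record with unioned presence flags and native ranges; a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"checklist file not found: {path}")
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    colmap = _resolve_schema(list(frame.columns), schema)
    subregion_cols = [c for c in frame.columns if c not in set(colmap.values())]
    if not subregion_cols:
        raise SchemaError(f"{path}: no subregion presence columns found")

    merged: dict[str, SpeciesRecord] = {}
    for idx, row in frame.iterrows():
        raw_regions = [tok.strip() for tok in str(row[colmap["native_regions"]]).split(";")]
        regions = frozenset(tok for tok in raw_regions if tok)
        for region in regions:
            if region not in REGION_CODES:
                raise ValidationError(f"{path} row {idx + 2}: unknown region code {region!r}")
        presence = {}
        for sub in subregion_cols:
            val = str(row[sub]).strip().lower()
            presence[sub] = val in {"1", "x", "true", "yes"}
        rec = SpeciesRecord(
            name=str(row[colmap["name"]]).strip(),
            kingdom=str(row[colmap["kingdom"]]).strip(),
            phylum=str(row[colmap["phylum"]]).strip(),
            klass=str(row[colmap["class"]]).strip(),
            native_regions=regions,
            presence=presence,
        )
        key = rec.match_key
        if key in merged:
            logger.warning("%s: duplicate species %r merged (presence unioned)", path, rec.name)
            old = merged[key]
            merged[key] = SpeciesRecord(
                name=old.name,
                kingdom=old.kingdom or rec.kingdom,
                phylum=old.phylum or rec.phylum,
                klass=old.klass or rec.klass,
                native_regions=old.native_regions | rec.native_regions,
                presence={s: old.presence[s] or rec.presence[s] for s in subregion_cols},
            )
        else:
            merged[key] = rec
    return Checklist(
        recipient_region=recipient_region,
        subregion_ids=list(subregion_cols),
        records=list(merged.values()),
    )


def tally_origins(
    checklist: Checklist, exclude_phyla: Iterable[str] = ()
) -> dict[str, Fraction]:
    """Fractional donor-region tallies under the 1/k attribution rule.

    A species native to k regions adds ``Fraction(1, k)`` to each of them, so
    the tallies sum exactly to the number of retained species. Species with
    native range {unknown} count toward the ``unknown`` donor group.
    """
    tally: dict[str, Fraction] = {}
    for rec in checklist.retained(exclude_phyla):
        share = Fraction(1, len(rec.native_regions))
        for region in sorted(rec.native_regions):
            tally[region] = tally.get(region, Fraction(0)) + share
    return tally


def origin_percentages(
    checklist: Checklist, exclude_phyla: Iterable[str] = ()
) -> dict[str, float]:
    """Donor-region percentages of the retained species count (full precision).

    Rounding to the integer percents seen in published summaries is a display
    concern; see :func:`display_percent`.
    """
    retained = checklist.retained(exclude_phyla)
    if not retained:
        raise ValidationError("origin_percentages: no species retained after exclusion")
    n = len(retained)
    return {
        region: float(frac) * 100.0 / n
        for region, frac in tally_origins(checklist, exclude_phyla).items()
    }


_RANK_ATTR = {"kingdom": "kingdom", "phylum": "phylum", "class": "klass"}


def taxonomic_composition(
    checklist: Checklist,
    rank: str,
    exclude_phyla: Iterable[str] = (),
) -> dict[str, tuple[int, float]]:
    """Counts and percents per taxon label at ``rank`` (kingdom/phylum/class).

    Ordered by descending count with alphabetical tie-break. Percents are over
    the retained species count.
    """
    if rank not in _RANK_ATTR:
        raise ValidationError(f"invalid rank {rank!r}; expected kingdom, phylum or class")
    retained = checklist.retained(exclude_phyla)
    counts = Counter(getattr(rec, _RANK_ATTR[rank]) for rec in retained)
    n = len(retained)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {label: (count, 100.0 * count / n) for label, count in ordered}


def presence_partition(
    checklist: Checklist,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> PartitionCounts:
    """Overlap partition between two groups of subregions.

    A species is "in" a group if it is present in any of its subregions.
    Species absent from both groups are excluded from ``total``, so
    ``only_a + only_b + both == total`` always holds.
    """
    for sub in list(group_a) + list(group_b):
        if sub not in checklist.subregion_ids:
            raise ValidationError(f"unknown subregion id {sub!r}")
    only_a = only_b = both = 0
    for rec in checklist.records:
        in_a = any(rec.presence.get(s, False) for s in group_a)
        in_b = any(rec.presence.get(s, False) for s in group_b)
        if in_a and in_b:
            both += 1
        elif in_a:
            only_a += 1
        elif in_b:
            only_b += 1
    return PartitionCounts(only_a, only_b, both, only_a + only_b + both)


def subregion_partition(checklist: Checklist, a: str, b: str) -> PartitionCounts:
    """Overlap partition between two single subregions (only-a, only-b, both, total)."""
    if a == b:
        raise ValidationError("subregion_partition requires two distinct subregions")
    return presence_partition(checklist, [a], [b])


def shared_species(x: Checklist, y: Checklist) -> set[str]:
    """Species recorded in both checklists, as synonym-stripped primary names.

    Matching is on normalized names (casefolded, whitespace collapsed,
    bracketed synonyms removed); returned names keep their original case as
    spelled in ``x``.
    """
    by_key = {rec.match_key: rec.primary_name for rec in x.records}
    return {by_key[rec.match_key] for rec in y.records if rec.match_key in by_key}


def observed_count(checklist: Checklist, donor: str) -> int:
    """Integer number of species in the checklist native to ``donor``.

    This is the convention used when comparing observed with expected NIS:
    a multi-origin species counts fully toward each of its native regions
    (unlike the fractional tallies used for composition summaries).
    """
    validate_region(donor, context="observed_count")
    return sum(1 for rec in checklist.records if donor in rec.native_regions)


def flow_matrix(
    checklists: Sequence[Checklist],
    exclude_phyla: Iterable[str] = (),
    *,
    mode: str = "fractional",
) -> pd.DataFrame:
    """Donor-region x recipient-region flow matrix.

    ``mode='fractional'`` uses the conservative 1/k attribution, so each
    column sums to that recipient's retained species count. ``mode='count'``
    books one integer unit flow per (species, native region) pair, the
    convention of chord-diagram style flow plots, which double-counts
    multi-origin species.
    """
    if not checklists:
        raise ValidationError("flow_matrix requires at least one checklist")
    if mode not in {"fractional", "count"}:
        raise ValidationError(f"unknown flow matrix mode {mode!r}")
    columns: dict[str, dict[str, float]] = {}
    for cl in checklists:
        recipient = cl.recipient_region or "combined"
        col: dict[str, float] = {}
        if mode == "fractional":
            for region, frac in tally_origins(cl, exclude_phyla).items():
                col[region] = col.get(region, 0.0) + float(frac)
        else:
            for rec in cl.retained(exclude_phyla):
                for region in sorted(rec.native_regions):
                    col[region] = col.get(region, 0.0) + 1
        columns[recipient] = col
    frame = pd.DataFrame(columns).fillna(0.0)
    return frame.sort_index()


def display_percent(value: float) -> int:
    """Round a percentage half-up to the integer used in report output."""
    from .comparison import round_half_up

    return int(round_half_up(value, 0))
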