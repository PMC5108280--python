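"""Closed vocabulary of biogeographic donor/recipient region codes.

The groups follow the convention used in checklist curation for ballast-water
invasion studies: ocean quadrants, a handful of named seas and lake systems,
large inland freshwater groupings, and an explicit ``unknown`` category for
species whose native range could not be resolved. ``unknown`` is a first-class
donor group, never a missing value.

``north_baltic`` is the pooled North Sea + Baltic Sea recipient system; it is
also a valid donor code because the pooled system acts as a donor toward the
Great Lakes-St. Lawrence River and vice versa.
"""

from __future__ import annotations

from .errors import ValidationError

REGION_CODES: frozenset[str] = frozenset(
    {
        "northeast_atlantic",
        "northwest_atlantic",
        "southeast_atlantic",
        "southwest_atlantic",
        "northeast_pacific",
        "northwest_pacific",
        "southeast_pacific",
        "southwest_pacific",
        "north_sea",
        "baltic_sea",
        "north_baltic",
        "great_lakes_st_lawrence",
        "mediterranean",
        "eurasia",
        "mississippi",
        "yangtze",
        "arctic",
        "australia",
        "new_zealand",
        "indo_pacific",
        "africa",
        "north_america",
        "south_america",
        "ponto_caspian",
        "unknown",
    }
)


def validate_region(code: str, *, context: str = "") -> str:
    """Return ``code`` if it belongs to the closed vocabulary, else raise.

    ``context`` is prepended to the error message so loaders can name the
    offending row.
    """
    if code not in REGION_CODES:
        where = f"{context}: " if context else ""
        raise ValidationError(f"{where}unknown region code {code!r}")
    return code
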