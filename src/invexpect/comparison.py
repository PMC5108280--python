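"""Expected-versus-observed NIS comparison (the null-model layer).

The expected number of NIS from donor region A in recipient region B is
``E = average donor richness x P_AB(Inv)``: the null model of exchanges that
ignores species traits entirely. Observed integer counts from the checklists
are compared with E by one-cell goodness-of-fit chi-square statistics,
``chi2 = (O - E)**2 / E`` with df = 1 per pair, and by a per-recipient (or
pooled) sum over donors with df = k - 1.

Display conventions follow the tabulated style this analysis reproduces:

* expected values >= 1 round half-up to integers; values < 1 are shown to one
  significant figure;
* chi-square statistics < 100 are shown to two decimals, larger ones as
  integers;
* p-values below .001 display as ``<.001``.

Chi-square statistics (and their p-values) are computed from the *displayed*
expected value, i.e. from the numbers a reader of the report can see, and the
p-value from the displayed chi-square. The full-precision expected value is
kept alongside on every result row. Very small expected values (E < 0.005 or
so) make the chi-square approximation unreliable; they are permitted with a
logged caveat and no continuity correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .checklist import Checklist, observed_count
from .errors import SchemaError, ValidationError
from .richness import RegionRichness

logger = logging.getLogger(__name__)

#: below this expected count the one-cell chi-square approximation is dubious
SMALL_EXPECTED = 0.005


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up (0.5 rounds away from zero), unlike banker's rounding."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def display_expected(expected: float) -> float:
    """Report-style rounding of an expected count.

    Values >= 1 round half-up to an integer; positive values < 1 round
    half-up to one significant figure (0.0342 -> 0.03, 0.0045 -> 0.005).
    """
    if expected < 0:
        raise ValidationError("expected count must be >= 0")
    if expected == 0:
        return 0.0
    if expected >= 1:
        return round_half_up(expected, 0)
    ndigits = -int(math.floor(math.log10(expected)))
    return round_half_up(expected, ndigits)


def display_chi_square(chi2: float) -> float:
    """Two decimals below 100, integer above."""
    return round_half_up(chi2, 2 if chi2 < 100 else 0)


def display_p_value(p: float) -> str:
    """``<.001`` below the reporting threshold, else three decimals (1 stays 1)."""
    if p < 0.001:
        return "<.001"
    if p == 1:
        return "1"
    return f"{p:.3f}".lstrip("0")


@dataclass
class DonorRecipientResult:
    """One donor -> recipient comparison row.

    ``expected`` is full precision; ``expected_display`` is the reported
    value; ``chi_square`` and ``p_value`` are computed from the displayed
    expected value (see module docstring) and themselves display-rounded.
    """

    donor: str
    recipient: str
    average_richness: float
    p_invasion: float
    expected: float
    expected_display: float
    observed: int
    chi_square: float
    p_value: float
    df: int = 1

    @property
    def p_display(self) -> str:
        return display_p_value(self.p_value)


def expected_nis(richness: RegionRichness | float, p_inv: float) -> float:
    """Expected NIS count: donor average richness times region-pair P(Inv)."""
    value = richness.average_richness if isinstance(richness, RegionRichness) else float(richness)
    if not value > 0:
        raise ValidationError("richness must be positive")
    if not 0.0 <= p_inv <= 1.0:
        raise ValidationError("invasion probability must be in [0, 1]")
    return value * p_inv


def pair_chi_square(observed: int, expected: float) -> tuple[float, float]:
    """One-cell goodness-of-fit statistic ``(O - E)**2 / E`` with its df=1 upper-tail p."""
    if observed < 0:
        raise ValidationError("observed count must be >= 0")
    if not expected > 0:
        raise ValidationError(
            "expected count must be positive; zero-expected pairs have no defined "
            "chi-square (see the degenerate-expected policy in the module docs)"
        )
    if expected < SMALL_EXPECTED:
        logger.warning(
            "expected count %.4g is below %.3g; chi-square approximation unreliable",
            expected,
            SMALL_EXPECTED,
        )
    chi2 = (observed - expected) ** 2 / expected
    return chi2, float(stats.chi2.sf(chi2, df=1))


def overall_chi_square(
    results: Sequence[DonorRecipientResult],
    recipient: str | None = None,
) -> tuple[float, int, float]:
    """Sum of per-pair statistics over donors, df = number of donors - 1.

    ``recipient=None`` pools every row (both recipients in a two-recipient
    analysis); otherwise only that recipient's donors enter.
    """
    rows = [r for r in results if recipient is None or r.recipient == recipient]
    if len(rows) < 2:
        raise ValidationError("overall chi-square needs at least two donor rows")
    for r in rows:
        if not r.expected > 0:
            raise ValidationError(f"{r.donor} -> {r.recipient}: non-positive expected count")
    chi2 = sum(r.chi_square for r in rows)
    df = len(rows) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df=df))


def _make_result(
    donor: str,
    recipient: str,
    richness_value: float,
    p_inv: float,
    observed: int,
) -> DonorRecipientResult:
    e_full = expected_nis(richness_value, p_inv)
    e_disp = display_expected(e_full)
    if e_disp > 0:
        chi2_raw, _ = pair_chi_square(observed, e_disp)
        chi2 = display_chi_square(chi2_raw)
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = float("nan"), float("nan")
        logger.warning("%s -> %s: displayed expected is 0; chi-square undefined", donor, recipient)
    return DonorRecipientResult(
        donor=donor,
        recipient=recipient,
        average_richness=richness_value,
        p_invasion=p_inv,
        expected=e_full,
        expected_display=e_disp,
        observed=int(observed),
        chi_square=chi2,
        p_value=p,
    )


def comparison_table(
    richness: Sequence[RegionRichness],
    probs: Mapping[tuple[str, str], float],
    observed: Mapping[tuple[str, str], int] | Sequence[Checklist],
) -> list[DonorRecipientResult]:
    """Assemble one result row per (donor, recipient) probability entry.

    ``observed`` is either an explicit ``(donor, recipient) -> count`` map or
    a sequence of checklists, in which case each checklist's
    ``recipient_region`` keys the recipient and integer donor counts are
    taken from its records. Rows are sorted by recipient, then by descending
    expected count. Pairs lacking a donor richness or an observed count are
    reported together in one error.
    """
    rich_by_region = {r.region: r.average_richness for r in richness}
    if not isinstance(observed, Mapping):
        obs_map: dict[tuple[str, str], int] = {}
        for cl in observed:
            if cl.recipient_region is None:
                raise ValidationError("checklist without recipient_region in comparison")
            for (donor, recipient) in probs:
                if recipient == cl.recipient_region:
                    obs_map[(donor, recipient)] = observed_count(cl, donor)
        observed = obs_map
    missing = [
        pair
        for pair in probs
        if pair[0] not in rich_by_region or pair not in observed
    ]
    if missing:
        raise ValidationError(f"missing richness or observed count for pairs: {sorted(missing)}")
    rows = [
        _make_result(donor, recipient, rich_by_region[donor], p_inv, observed[(donor, recipient)])
        for (donor, recipient), p_inv in probs.items()
    ]
    rows.sort(key=lambda r: (r.recipient, -r.expected, r.donor))
    return rows


def table_from_fixture(path_or_frame: str | Path | pd.DataFrame) -> list[DonorRecipientResult]:
    """Build comparison rows from a delimited table of published inputs.

    Required columns: donor, recipient, richness, p_inv, observed. This is
    the entry point for re-running the comparison on tabulated richness and
    invasion probabilities rather than on model output.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        frame = path_or_frame
    else:
        frame = pd.read_csv(path_or_frame, sep=None, engine="python")
    required = {"donor", "recipient", "richness", "p_inv", "observed"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"fixture table missing column(s): {sorted(missing)}")
    richness = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        if row["donor"] not in seen:
            richness.append(
                RegionRichness(region=row["donor"], average_richness=float(row["richness"]))
            )
            seen.add(row["donor"])
    probs = {
        (row["donor"], row["recipient"]): float(row["p_inv"]) for _, row in frame.iterrows()
    }
    observed = {
        (row["donor"], row["recipient"]): int(row["observed"]) for _, row in frame.iterrows()
    }
    return comparison_table(richness, probs, observed)


def results_frame(results: Sequence[DonorRecipientResult]) -> pd.DataFrame:
    """Report table mirroring the comparison columns."""
    return pd.DataFrame(
        {
            "donor": [r.donor for r in results],
            "recipient": [r.recipient for r in results],
            "average_richness": [r.average_richness for r in results],
            "p_invasion": [r.p_invasion for r in results],
            "expected": [r.expected for r in results],
            "expected_display": [r.expected_display for r in results],
            "observed": [r.observed for r in results],
            "chi_square": [r.chi_square for r in results],
            "p_value": [r.p_value for r in results],
            "p_display": [r.p_display for r in results],
        }
    )


def scatter_frame(results: Sequence[DonorRecipientResult]) -> pd.DataFrame:
    """Expected/observed scatter export (one labelled point per pair)."""
    return pd.DataFrame(
        {
            "expected": [r.expected_display for r in results],
            "observed": [r.observed for r in results],
            "donor": [r.donor for r in results],
            "recipient": [r.recipient for r in results],
        }
    )
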