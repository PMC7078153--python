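"""Display formatting: half-up percent rounding and published-style tables.

All internal quantities are exact fractions; rounding happens only here.
Table cells use integer percents ("347 (17%)"); in-text style rates and
simulation results use one decimal ("16.9%", "3.7%").  Machine-readable
outputs always carry the unrounded fractions.
"""

from __future__ import annotations

import decimal

import pandas as pd

from .montecarlo import DecreaseEstimate
from .survey import OILED_CATEGORIES, State, SurveyTally

__all__ = [
    "format_percent",
    "format_count_pct",
    "render_tally_table",
    "render_mcs_line",
]


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Render a fraction as a percent string, rounding half-up."""
    q = decimal.Decimal(1).scaleb(-decimals) if decimals else decimal.Decimal(1)
    value = decimal.Decimal(str(fraction * 100)).quantize(
        q, rounding=decimal.ROUND_HALF_UP
    )
    return f"{value}%"


def format_count_pct(count: int, denom: int, decimals: int = 0) -> str:
    """A published-style cell: count with its percent of ``denom``."""
    if denom == 0:
        return str(count)
    return f"{count} ({format_percent(count / denom, decimals)})"


def _tally_row(label_state: str, t: SurveyTally, show_assessed_pct: bool) -> dict:
    row: dict = {"species": t.species.value, "state": label_state}
    row["n_observed"] = t.n_observed
    row["n_assessed"] = (
        format_count_pct(t.n_assessed, t.n_observed) if show_assessed_pct else t.n_assessed
    )
    row["n_oiled"] = format_count_pct(t.n_oiled, t.n_assessed)
    for cat in OILED_CATEGORIES:
        row[cat.name.lower()] = format_count_pct(t.n_by_category[cat], t.n_oiled)
    return row


def render_tally_table(t: SurveyTally) -> pd.DataFrame:
    """Published-style exposure table: one row per state plus a total row.

    Oiled cells show the percent of assessed birds; per-category cells show
    the percent of oiled birds; the total row also shows the assessed
    percent of observed.
    """
    rows = []
    for state in State:
        st = (t.by_state or {}).get(state)
        if st is not None:
            rows.append(_tally_row(state.value, st, show_assessed_pct=False))
    rows.append(_tally_row("Total", t, show_assessed_pct=True))
    return pd.DataFrame(rows)


def render_mcs_line(est: DecreaseEstimate) -> str:
    """One-line result, e.g. ``decrease median 10.7% (95% CI 6.0-15.8%)``."""
    return (
        f"decrease median {format_percent(est.median)} "
        f"(95% CI {format_percent(est.ci_low).rstrip('%')}"
        f"-{format_percent(est.ci_high)})"
    )
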