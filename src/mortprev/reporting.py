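"""Human-readable report rendering for posterior summaries.

Display conventions: prevalence as percentages to 2 decimal places, counts
rounded to the nearest hundred (with thin-space thousands grouping); the
full-precision CSV is always written alongside the rendered text.
"""

from __future__ import annotations

import logging

import pandas as pd

__all__ = ["format_percent", "format_count", "render_report"]

logger = logging.getLogger(__name__)


def format_percent(proportion: float, dp: int = 2) -> str:
    """0.0082 -> '0.82%'."""
    return f"{100.0 * proportion:.{dp}f}%"


def format_count(value: float) -> str:
    """283140 -> '283 100' (nearest hundred, space-grouped)."""
    rounded = int(round(value / 100.0)) * 100
    return f"{rounded:,}".replace(",", " ")


def _interval(row: pd.Series, fmt) -> str:
    return f"{fmt(row['median'])} ({fmt(row['lower95'])}-{fmt(row['upper95'])})"


def render_report(
    summary: pd.DataFrame,
    treatment_count: int | None = None,
    percent_dp: int = 2,
) -> str:
    """Render per-group and national prevalence estimates as text.

    ``summary`` is a posterior summary table indexed by quantity (as
    produced by :func:`mortprev.inference.summarize`). Quantities absent
    from the table are omitted with a logged warning. When a treatment
    headcount is provided, the proportion of the estimated population in
    treatment is reported as headcount / posterior N.
    """
    lines = ["Prevalence estimates (median, 95% CrI)", "=" * 42]

    pct = lambda p: format_percent(p, percent_dp)  # noqa: E731
    group_rows = [q for q in summary.index if q.startswith("pi[")]
    for q in group_rows:
        label = q[3:-1].replace(",", " / ")
        lines.append(f"  {label:<40s} {_interval(summary.loc[q], pct)}")
    for q, label, fmt in (
        ("national_prevalence", "National prevalence", pct),
        ("n_total", "Total population size N", format_count),
        ("n_miss_total", "Unobserved population", format_count),
    ):
        if q in summary.index:
            lines.append(f"  {label:<40s} {_interval(summary.loc[q], fmt)}")
        else:
            logger.warning("quantity %r missing from summary; omitted", q)
    if treatment_count is not None:
        if "n_total" in summary.index:
            row = summary.loc["n_total"]
            lines.append(
                "  {:<40s} {} ({}-{})".format(
                    "Proportion in treatment",
                    format_percent(treatment_count / row["median"], 0),
                    format_percent(treatment_count / row["upper95"], 0),
                    format_percent(treatment_count / row["lower95"], 0),
                )
            )
        else:
            logger.warning("treatment headcount given but N unavailable")
    return "\n".join(lines) + "\n"
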