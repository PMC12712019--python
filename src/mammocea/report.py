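"""Base-case reporting: the deterministic results table.

Rows follow the conventional presentation of a screening
cost-effectiveness base case per 1000 screened: resource-use counts
(undiscounted), discounted costs by category, screening-related and
cancer-related subtotals, total cost, QALYs, and the ICER. Counts are
rounded to whole events, costs to whole EUR, QALYs to one decimal; full
precision is available from ``table3_frame``.
"""

from __future__ import annotations

import pandas as pd

from .engine import CEAResult, IncrementalResult
from .params import ParameterError

__all__ = ["table3_frame", "render_table3"]

_COUNT_ROWS = [
    ("No. of mammographs", "mammograms"),
    ("No. of AI screen readings", "ai_readings"),
    ("No. of human screen readings", "human_readings"),
    ("No. of conferences", "conferences"),
    ("No. of recalls", "recalls"),
]
_COST_ROWS = [
    ("Cost invitations", "invitation"),
    ("Cost mammographs", "mammography"),
    ("Cost human screen readings", "human_reading"),
    ("Cost AI", "ai"),
    ("Cost conferences", "conference"),
    ("Recall: cost invitation", "recall_invitation"),
    ("Recall: cost of other diagnostics", "recall_diagnostics"),
    ("Cost stage 0", "stage_0"),
    ("Cost stage I", "stage_I"),
    ("Cost stage II", "stage_II"),
    ("Cost stage III", "stage_III"),
    ("Cost stage IV", "stage_IV"),
]


def table3_frame(
    a: CEAResult, b: CEAResult, inc: IncrementalResult
) -> pd.DataFrame:
    """Base-case results as a DataFrame (full precision)."""
    if inc.a is not a or inc.b is not b:
        raise ParameterError("incremental result does not match the arm results")
    rows = []
    for label, key in _COUNT_ROWS:
        va, vb = a.counts[key], b.counts[key]
        rows.append((label, va, vb, va - vb))
    for label, key in _COST_ROWS:
        va, vb = a.cost_by_category[key], b.cost_by_category[key]
        rows.append((label, va, vb, va - vb))
    rows.append(
        ("Screening-related costs", a.screening_cost, b.screening_cost,
         a.screening_cost - b.screening_cost)
    )
    rows.append(
        ("Breast cancer-related costs", a.cancer_cost, b.cancer_cost,
         a.cancer_cost - b.cancer_cost)
    )
    rows.append(
        ("Total cost (screening and breast cancer)", a.total_cost, b.total_cost,
         inc.incremental_cost)
    )
    rows.append(("QALYs", a.total_qaly, b.total_qaly, inc.incremental_qaly))
    return pd.DataFrame(rows, columns=["row", a.name, b.name, "incremental"])


def render_table3(a: CEAResult, b: CEAResult, inc: IncrementalResult) -> str:
    """Plain-text base-case table with conventional rounding."""
    df = table3_frame(a, b, inc)
    width = max(len(r) for r in df["row"]) + 2
    lines = [f"{'':{width}}{a.name:>14}{b.name:>14}{'Incremental':>14}"]

    def fmt(label, va, vb, vi, nd):
        return (
            f"{label:{width}}{va:>14,.{nd}f}{vb:>14,.{nd}f}{vi:>14,.{nd}f}"
        )

    n_counts = len(_COUNT_ROWS)
    for i, (_, r) in enumerate(df.iterrows()):
        nd = 0 if i < len(df) - 1 else 1  # QALYs to one decimal
        lines.append(fmt(r["row"], r.iloc[1], r.iloc[2], r.iloc[3], nd))
        if i == n_counts - 1:
            lines.append("-" * (width + 42))
    if inc.icer is None:
        lines.append(f"{'ICER':{width}}{'undefined':>42}")
    else:
        lines.append(f"{'ICER':{width}}{inc.icer:>40,.0f} ({inc.label})")
    if inc.break_even_age is not None:
        lines.append(f"{'Break-even age':{width}}{inc.break_even_age:>42}")
    return "\n".join(lines)
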