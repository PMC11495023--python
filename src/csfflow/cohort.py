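"""Cohort-level aggregation of per-subject flow metrics.

Descriptive reproduction of the usual report shapes only: direction
counts with exact-rational proportions, per-group mean ± SD (or median
with range), and Pearson correlation of net flow against a covariate
(e.g. ventricular volume).  Inferential statistics (ANOVA, chi-square,
t-tests) are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flow import FlowMetrics

__all__ = [
    "SubjectRecord",
    "direction_counts",
    "group_summary",
    "flow_volume_correlation",
    "format_percent",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's metrics at one site, with a group label and covariates."""

    id: str
    group: str
    site: str
    metrics: FlowMetrics
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group must be non-empty")


def format_percent(p: Fraction) -> str:
    """One-decimal percent, round half away from zero (0.625 → '62.5%')."""
    pct = Decimal(p.numerator * 100) / Decimal(p.denominator)
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


def _check_unique(records: Sequence[SubjectRecord]) -> None:
    keys = [(r.id, r.site) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (id, site) records")


def direction_counts(records: Sequence[SubjectRecord], site: str) -> pd.DataFrame:
    """Counts and exact proportions of each direction label, per group.

    Proportions are exact :class:`fractions.Fraction` values (they sum to
    1 per group in rational arithmetic); ``percent`` is the one-decimal
    formatted copy.  Rows are ordered (group, direction) with an
    ``overall`` block last.
    """
    if not records:
        raise ValueError("records must be non-empty")
    _check_unique(records)
    sites = {r.site for r in records}
    if sites != {site}:
        raise ValueError(f"mixed or wrong sites {sorted(sites)}; expected {site!r}")
    rows = []
    groups = sorted({r.group for r in records})
    for group in groups + ["overall"]:
        members = [r for r in records if group == "overall" or r.group == group]
        total = len(members)
        for direction in sorted({r.metrics.direction for r in members}):
            n = sum(1 for r in members if r.metrics.direction == direction)
            prop = Fraction(n, total)
            rows.append(
                {
                    "group": group,
                    "direction": direction,
                    "n": n,
                    "total": total,
                    "proportion": prop,
                    "percent": format_percent(prop),
                }
            )
    return pd.DataFrame(rows)


def _select(record: SubjectRecord, selector: str | Callable) -> float | None:
    if callable(selector):
        return selector(record)
    if hasattr(record.metrics, selector):
        return getattr(record.metrics, selector)
    return record.covariates.get(selector)


def group_summary(
    records: Sequence[SubjectRecord],
    selector: str | Callable[[SubjectRecord], float],
    stat: str = "mean_sd",
) -> pd.DataFrame:
    """Per-group mean ± sample SD (n−1) or median with min–max range.

    ``selector`` names a numeric :class:`FlowMetrics` field or covariate
    key (or is a callable on the record).  Missing values are dropped
    listwise; a group left empty is an error.
    """
    if stat not in ("mean_sd", "median_range"):
        raise ValueError(f"stat must be 'mean_sd' or 'median_range', got {stat!r}")
    if not records:
        raise ValueError("records must be non-empty")
    rows = []
    for group in sorted({r.group for r in records}):
        values = [
            v
            for r in records
            if r.group == group
            for v in [_select(r, selector)]
            if v is not None
        ]
        if not values:
            raise ValueError(f"group {group!r} has no values for selector")
        arr = np.sort(np.asarray(values, dtype=float))  # permutation-invariant sums
        row = {"group": group, "n": arr.size}
        if stat == "mean_sd":
            row["mean"] = float(arr.mean())
            row["sd"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        else:
            row["median"] = float(np.median(arr))
            row["min"] = float(arr.min())
            row["max"] = float(arr.max())
        rows.append(row)
    return pd.DataFrame(rows)


def flow_volume_correlation(
    records: Sequence[SubjectRecord],
    covariate: str,
    flow_selector: str = "net_per_min",
) -> tuple[float, int]:
    """Pearson r between net flow and a covariate, with the n used.

    Records missing the covariate are dropped listwise; at least 3
    complete pairs are required and both variables must vary.
    """
    pairs = [
        (_select(r, flow_selector), r.covariates.get(covariate))
        for r in records
        if r.covariates.get(covariate) is not None
        and _select(r, flow_selector) is not None
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 records with covariate {covariate!r}, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in flow or covariate; correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r), len(pairs)
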