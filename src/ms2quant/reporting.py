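"""Group comparisons and summary statistics.

Per-embryo window-level values (active-nucleus count, dot size, domain width)
are compared between constructs with a two-sample Student's t test (two-
tailed, equal variance by default, matching the small-scale replicate
analysis this pipeline is built for; Welch's correction is available by
flag). No multiple-testing correction is applied; output tables carry a
footnote saying so.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComparisonResult", "compare", "comparison_table"]

MEASURES = ("active_count", "dot_size", "width")

FOOTNOTE = "p values are from two-tailed two-sample t tests; no multiple-testing correction applied"


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison of one measure in one window."""

    measure: str
    window: str
    group_a: str
    group_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _sem(values: np.ndarray) -> float:
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    measure: str = "active_count",
    window: str = "",
    group_a: str = "A",
    group_b: str = "B",
    welch: bool = False,
) -> ComparisonResult:
    """Student's two-sample two-tailed t test between per-embryo values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group for a t test")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult(
        measure=measure,
        window=window,
        group_a=group_a,
        group_b=group_b,
        values_a=tuple(a),
        values_b=tuple(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=_sem(a),
        sem_b=_sem(b),
        t_statistic=float(t),
        p_value=float(p),
    )


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy table of comparison results; attaches the no-correction footnote."""
    df = pd.DataFrame(
        {
            "measure": [r.measure for r in results],
            "window": [r.window for r in results],
            "group_a": [r.group_a for r in results],
            "group_b": [r.group_b for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "sem_a": [r.sem_a for r in results],
            "sem_b": [r.sem_b for r in results],
            "t": [r.t_statistic for r in results],
            "p": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
    df.attrs["footnote"] = FOOTNOTE
    return df
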