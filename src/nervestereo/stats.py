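"""Paired comparisons between matched groups of nerves.

Each animal contributes one value per condition (its control nerve is the
contralateral transected nerve, so conditions are matched within animal);
groups are compared with a two-tailed paired Student t-test and the usual
significance tiers: * P <= 0.05, ** P <= 0.01, *** P <= 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

__all__ = ["PairedComparison", "paired_t_test", "significance_tier", "summarize_groups"]


def significance_tier(p_value: float) -> str:
    if p_value <= 0.001:
        return "***"
    if p_value <= 0.01:
        return "**"
    if p_value <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class PairedComparison:
    """Result of one paired two-tailed t-test."""

    label_a: str
    label_b: str
    n: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    significance_tier: str
    degenerate_variance: bool = False


def paired_t_test(
    values_a,
    values_b,
    label_a: str = "a",
    label_b: str = "b",
) -> PairedComparison:
    """Two-tailed paired t-test on matched value lists.

    t = mean(a - b) / (sd(a - b) / sqrt(n)) with the sample SD (n - 1
    denominator); p from the Student t distribution with n - 1 degrees of
    freedom.  Degenerate difference variance is handled explicitly: if all
    differences are identical and nonzero the test reports p = 0 with a
    flag; if all differences are zero, t = 0 and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError(
            f"paired samples must be equal-length vectors, got {a.shape} and {b.shape}"
        )
    n = a.size
    if n < 2:
        raise StatsError("paired t-test needs n >= 2 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    df = n - 1
    degenerate = False
    if sd_diff == 0.0:
        if mean_diff == 0.0:
            t, p = 0.0, 1.0
        else:
            t = math.inf if mean_diff > 0 else -math.inf
            p = 0.0
            degenerate = True
    else:
        t = mean_diff / (sd_diff / math.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedComparison(
        label_a=label_a,
        label_b=label_b,
        n=n,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        significance_tier=significance_tier(p),
        degenerate_variance=degenerate,
    )


def summarize_groups(per_section_values, group_labels) -> pd.DataFrame:
    """Per-group n, mean and sample SD, formatted as ``mean ± SD``.

    A group with a single value reports SD = 0 with ``sd_undefined`` set.
    """
    values = np.asarray(per_section_values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise StatsError("values and group labels must be equal-length vectors")
    if values.size == 0:
        raise StatsError("no values to summarize")
    rows = []
    for g in pd.unique(labels):
        v = values[labels == g]
        if v.size == 0:
            raise StatsError(f"empty group {g!r}")
        sd_undefined = v.size < 2
        sd = 0.0 if sd_undefined else float(v.std(ddof=1))
        rows.append(
            {
                "group": g,
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": sd,
                "sd_undefined": sd_undefined,
                "formatted": f"{v.mean():.4g} ± {sd:.4g}",
            }
        )
    return pd.DataFrame(rows)
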