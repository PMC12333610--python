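"""Paired group comparison tables: difference, percentage difference, p value.

Given two paired lists of per-plan metric dictionaries (group A, e.g.
automated plans, and group B, e.g. manual controls), each requested
variable is summarized as mean ± SD per group, difference of means
(A − B), percentage difference 100·(A − B)/B (relative to the control
group), a Shapiro-Wilk normality p value per group, and a two-tailed
paired Wilcoxon signed-rank p value.  The statistical routines are the
established library implementations; they are not re-derived here.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["compare_plans", "load_metrics_dir"]


def compare_plans(
    metrics_a: list[dict],
    metrics_b: list[dict],
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable paired comparison of two equal-length metric lists.

    Plans must be paired by subject (index i of A with index i of B).
    For identical paired samples the Wilcoxon statistic is undefined (all
    differences zero); the p value is reported as NaN.
    """
    if len(metrics_a) != len(metrics_b):
        raise ValueError(
            f"paired groups must have equal length, got {len(metrics_a)} and {len(metrics_b)}"
        )
    if len(metrics_a) == 0:
        raise ValueError("empty metric lists")
    if variables is None:
        variables = [k for k in metrics_a[0] if k in metrics_b[0]]

    rows = []
    for var in variables:
        a = np.array([m[var] for m in metrics_a], dtype=float)
        b = np.array([m[var] for m in metrics_b], dtype=float)
        diff_means = a.mean() - b.mean()
        pct = 100.0 * diff_means / b.mean() if b.mean() != 0 else np.nan
        sw_a = stats.shapiro(a).pvalue if len(a) >= 3 and np.ptp(a) > 0 else np.nan
        sw_b = stats.shapiro(b).pvalue if len(b) >= 3 and np.ptp(b) > 0 else np.nan
        d = a - b
        if np.all(d == 0):
            p = np.nan
        else:
            p = stats.wilcoxon(a, b, alternative="two-sided").pvalue
        rows.append(
            {
                "variable": var,
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1) if len(a) > 1 else 0.0,
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1) if len(b) > 1 else 0.0,
                "difference": diff_means,
                "percentage_difference": pct,
                "shapiro_p_a": sw_a,
                "shapiro_p_b": sw_b,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def load_metrics_dir(directory) -> list[dict]:
    """Read one metric dict per ``*.json`` file, sorted by file name."""
    directory = pathlib.Path(directory)
    out = []
    for path in sorted(directory.glob("*.json")):
        with open(path) as fh:
            out.append(json.load(fh))
    if not out:
        raise FileNotFoundError(f"no metric JSON files in {directory}")
    return out
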