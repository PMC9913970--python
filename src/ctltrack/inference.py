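"""Group comparisons: pooled distribution tests and per-experiment mean tests.

Two complementary pathways are used in this field:

* **pooled** — every track is one observation; groups are compared with the
  two-sample Kolmogorov–Smirnov test (nonparametric, distribution-level);
* **per-experiment** — tracks are first averaged within each independent
  experiment (imaging session / biological replicate), and the small samples
  of experiment means are compared with an unpaired two-tailed Welch t-test.

Significance is flagged at alpha = 0.05 per comparison; no multiple-testing
correction is applied by default (an optional Holm adjustment is available
in the CLI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "ALPHA",
    "ks_compare",
    "t_compare",
    "pooled_vs_per_experiment",
    "compare_metric",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group comparison."""

    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value out of [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        """True iff p < 0.05 (the per-comparison criterion marked * in plots)."""
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "significant": self.significant,
        }


def ks_compare(sample_a, sample_b, exact: bool | None = None) -> ComparisonResult:
    """Two-sample Kolmogorov–Smirnov test on per-track metric values.

    ``D = sup |F_a - F_b|`` with the asymptotic two-sided p value by default;
    ``exact=True`` uses the exact null distribution (sensible when
    ``n * m <= 1e4``), ``exact=None`` lets sample size decide.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if exact is None:
        exact = len(a) * len(b) <= 10_000
    res = stats.ks_2samp(a, b, method="exact" if exact else "asymp")
    return ComparisonResult(
        test="ks_2samp_exact" if exact else "ks_2samp_asymp",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=len(a),
        n_b=len(b),
    )


def t_compare(means_a, means_b) -> ComparisonResult:
    """Unpaired two-tailed Welch t-test on per-experiment means.

    Welch's unequal-variance form is used (the safer default when group
    variances are not known to be equal); the test name in the result records
    this choice.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 per-experiment means per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        test="welch_t_two_tailed",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


def pooled_vs_per_experiment(
    summary: pd.DataFrame,
    metric: str = "mean_track_speed",
    group_col: str = "group",
    experiment_col: str = "experiment_id",
) -> dict[str, pd.DataFrame]:
    """Emit both analysis tables from a per-track summary.

    Returns ``{"pooled": ..., "per_experiment": ...}``:

    * ``pooled`` — one row per track (track-level values feeding the KS
      pathway), columns [group, experiment, value];
    * ``per_experiment`` — one row per (group, experiment) with the mean of
      the metric over its tracks (feeding the t-test pathway).

    With unbalanced experiments the pooled mean and the mean of experiment
    means differ (track-weighted vs experiment-weighted); both tables are
    returned so the weighting is always explicit. A single experiment leaves
    the per-experiment pathway degenerate; a warning is raised.
    """
    for col in (metric, group_col, experiment_col):
        if col not in summary.columns:
            raise ValueError(f"summary table lacks column {col!r}")
    pooled = summary[[group_col, experiment_col, metric]].rename(
        columns={group_col: "group", experiment_col: "experiment_id", metric: "value"}
    )
    per_exp = (
        summary.groupby([group_col, experiment_col])[metric]
        .agg(["mean", "count"])
        .reset_index()
        .rename(
            columns={
                group_col: "group",
                experiment_col: "experiment_id",
                "mean": "value",
                "count": "n_tracks",
            }
        )
    )
    if summary[experiment_col].nunique() < 2:
        warnings.warn(
            "single experiment: per-experiment pathway has no replication",
            stacklevel=2,
        )
    return {"pooled": pooled, "per_experiment": per_exp}


def compare_metric(
    summary: pd.DataFrame,
    group_a: str,
    group_b: str,
    metric: str = "mean_track_speed",
    mode: str = "pooled",
    **kwargs,
) -> ComparisonResult:
    """Compare one metric between two groups via the chosen pathway.

    ``mode="pooled"`` runs the KS test on track-level values,
    ``mode="per-experiment"`` runs the Welch t-test on experiment means.
    """
    tables = pooled_vs_per_experiment(summary, metric=metric, **kwargs)
    if mode == "pooled":
        tab = tables["pooled"]
        a = tab.loc[tab["group"] == group_a, "value"]
        b = tab.loc[tab["group"] == group_b, "value"]
        return ks_compare(a, b)
    if mode == "per-experiment":
        tab = tables["per_experiment"]
        a = tab.loc[tab["group"] == group_a, "value"]
        b = tab.loc[tab["group"] == group_b, "value"]
        return t_compare(a, b)
    raise ValueError("mode must be 'pooled' or 'per-experiment'")
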