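"""Expression-stratified survival analysis.

Patients are dichotomised at the median of a gene's expression (values
strictly above the median are "high"), or cross-classified into four groups
by two genes.  Relapse groups are compared with Welch's t-test; survival is
summarised by the Kaplan-Meier product-limit estimator and compared with the
log-rank test.  The estimator and test are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "split_by_expression",
    "four_group_stratify",
    "compare_relapse_groups",
    "KaplanMeierEstimate",
    "km_estimate",
    "logrank",
]


def split_by_expression(
    cohort: pd.DataFrame, gene: str, quantile: float = 0.5
) -> pd.Series:
    """High/low labels at the per-gene expression quantile (default median).

    Values strictly above the cutpoint are "high"; values at or below it
    are "low", so with an odd cohort the median patient lands in "low".
    """
    values = cohort[gene].astype(float)
    if values.isna().any():
        raise ValueError(f"missing expression values for {gene}")
    cut = float(np.quantile(values, quantile))
    if (values == values.iloc[0]).all():
        raise ValueError(f"all {gene} values identical; no split possible")
    return pd.Series(
        np.where(values > cut, "high", "low"), index=cohort.index, name=gene
    )


def four_group_stratify(
    cohort: pd.DataFrame, gene_a: str, gene_b: str
) -> pd.Series:
    """Cross of the two median splits: labels ``{low,high}_{low,high}``,
    first component for ``gene_a``."""
    a = split_by_expression(cohort, gene_a)
    b = split_by_expression(cohort, gene_b)
    return pd.Series(
        a.str.cat(b, sep="_"), index=cohort.index, name=f"{gene_a}_{gene_b}"
    )


def compare_relapse_groups(
    cohort: pd.DataFrame, gene: str, relapse_col: str = "relapse"
) -> tuple[float, float]:
    """Welch's unequal-variance t-test of expression between relapsed
    ("yes") and non-relapsed ("no") patients; returns (t, two-sided p)."""
    rel = cohort[cohort[relapse_col] == "yes"][gene].astype(float)
    non = cohort[cohort[relapse_col] == "no"][gene].astype(float)
    if len(rel) < 2 or len(non) < 2:
        raise ValueError("need at least 2 patients per relapse group")
    t, p = stats.ttest_ind(rel, non, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Right-continuous product-limit survival step function.

    ``times`` starts at 0 with survival 1 and is strictly increasing;
    ``survival`` is nonincreasing.
    """

    times: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(
    times: Sequence[float], events: Sequence[int]
) -> KaplanMeierEstimate:
    """Kaplan-Meier estimate with right censoring (event=0 censored)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    sf = fitter.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    if t[0] != 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return KaplanMeierEstimate(t, s)


def logrank(
    times: Sequence[float],
    events: Sequence[int],
    labels: Sequence,
) -> tuple[float, int, float]:
    """Log-rank test across 2+ groups: (chi-square, df, p).

    Uses the standard observed-minus-expected statistic over the shared
    event times, with tied events handled by the aggregated risk set.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    result = multivariate_logrank_test(times, labels, events)
    df = len(groups) - 1
    return float(result.test_statistic), df, float(result.p_value)
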