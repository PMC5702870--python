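"""Model comparison across recording sites.

Given per-site variance explained (R^2) for the numerosity model and each
visual-feature model — configuration-specific and constrained scopes — we
summarize each model's R^2 distribution per configuration (mean, SD, the
bar-and-error-bar layout of the figures) and test, per feature model,
whether numerosity explains more variance with a paired two-sided Wilcoxon
signed-rank test on per-site values. A site's overall value within a scope
is the mean of its per-configuration R^2 over the included configurations,
so subsetting configurations and comparing is consistent with the full
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon

__all__ = ["ComparisonTable", "wilcoxon_paired", "compare", "subset_compare"]

REFERENCE_MODEL = "numerosity"
EXACT_MAX_N = 25  # exact null distribution up to here, normal approximation beyond


@dataclass(frozen=True)
class ComparisonTable:
    """Per-model R^2 summaries and paired tests against the numerosity model."""

    summary: pd.DataFrame   # model, scope, configuration, mean_r2, sd_r2, n_sites
    tests: pd.DataFrame     # model, scope, statistic, p, n_effective, median_diff
    site_values: pd.DataFrame  # site, model, scope, overall r2 (mean over configs)


def wilcoxon_paired(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; if every difference is zero the test is
    undefined and (0, 1) is returned. Exact null distribution for up to
    25 nonzero pairs, normal approximation with continuity correction
    beyond.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    method = "exact" if d.size <= EXACT_MAX_N else "approx"
    res = _scipy_wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                          correction=True, method=method)
    return float(res.statistic), float(res.pvalue)


def _site_overall(r2_table: pd.DataFrame, configurations: list[str]) -> pd.DataFrame:
    sub = r2_table[r2_table["configuration"].isin(configurations)]
    out = (
        sub.groupby(["site", "model", "scope"], as_index=False)["r2"]
        .mean()
        .rename(columns={"r2": "overall_r2"})
    )
    return out


def compare(
    r2_table: pd.DataFrame,
    reference: str = REFERENCE_MODEL,
    configurations: list[str] | None = None,
) -> ComparisonTable:
    """Build the comparison table from long-form per-site R^2 rows.

    Parameters
    ----------
    r2_table
        Columns ``site, model, scope, configuration, r2`` with one row per
        (site, model, scope, configuration); scopes are ``specific`` and
        ``constrained``.
    reference
        Model against which all others are tested (default numerosity).
    """
    required = {"site", "model", "scope", "configuration", "r2"}
    if not required <= set(r2_table.columns):
        raise ValueError(f"r2 table must have columns {sorted(required)}")
    if configurations is None:
        # 'all' rows carry a constrained fit's pooled R^2, not a configuration
        configurations = sorted(c for c in r2_table["configuration"].unique() if c != "all")
    sub = r2_table[r2_table["configuration"].isin(configurations)]
    if sub.empty:
        raise ValueError("empty configuration subset")

    summary = (
        sub.groupby(["model", "scope", "configuration"])["r2"]
        .agg(mean_r2="mean", sd_r2=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
             n_sites="count")
        .reset_index()
    )

    site_values = _site_overall(sub, configurations)
    tests_rows = []
    for scope, grp in site_values.groupby("scope"):
        wide = grp.pivot(index="site", columns="model", values="overall_r2")
        if reference not in wide.columns:
            raise ValueError(f"reference model {reference!r} missing from r2 table")
        ref = wide[reference].to_numpy()
        for model in wide.columns:
            if model == reference:
                continue
            other = wide[model].to_numpy()
            stat, p = wilcoxon_paired(ref, other)
            d = ref - other
            tests_rows.append(
                {
                    "model": model,
                    "scope": scope,
                    "statistic": stat,
                    "p": p,
                    "n_effective": int(np.sum(d != 0.0)),
                    "median_diff": float(np.median(d)),
                }
            )
    tests = pd.DataFrame(
        tests_rows,
        columns=["model", "scope", "statistic", "p", "n_effective", "median_diff"],
    )
    return ComparisonTable(summary=summary, tests=tests, site_values=site_values)


def subset_compare(
    r2_table: pd.DataFrame,
    include: list[str] | None = None,
    exclude: list[str] | None = None,
    reference: str = REFERENCE_MODEL,
) -> ComparisonTable:
    """Comparison restricted to a configuration subset.

    Either list the configurations to ``include`` or the ones to
    ``exclude`` (e.g. drop the regime where a feature is constant).
    """
    configs = sorted(r2_table["configuration"].unique())
    if include is not None:
        configs = [c for c in configs if c in include]
    if exclude is not None:
        configs = [c for c in configs if c not in exclude]
    if not configs:
        raise ValueError("configuration subset is empty")
    return compare(r2_table, reference=reference, configurations=configs)
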