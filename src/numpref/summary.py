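"""Per-configuration and pooled feature summary statistics.

Each feature track is summarized, on its table axis (log10 or linear), by
its mean, sample standard deviation, SD/mean ratio, and Pearson
correlation with log10 numerosity over the design points — the column
structure of the published feature tables. A zero-variance track (a
regime's controlled feature) gets r = 0 by convention, since Pearson's r
is undefined for a constant regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .design import DesignSequence
from .features import FEATURE_AXES, FeatureTimecourse

__all__ = ["FeatureSummaryRow", "summarize", "pooled_summaries", "summary_table"]

POOLED_ALL = "All configurations"
POOLED_EXCEPT_CONSTANT = "All except constant"


@dataclass(frozen=True)
class FeatureSummaryRow:
    feature: str
    configuration: str
    mean: float
    sd: float
    sd_over_mean: float
    r_with_log_numerosity: float


def _pearson_vs_log_n(values: np.ndarray, log_n: np.ndarray) -> float:
    ok = np.isfinite(values)
    v, x = values[ok], log_n[ok]
    if v.size < 2 or v.std() == 0.0 or x.std() == 0.0:
        return 0.0
    return float(np.corrcoef(v, x)[0, 1])


def _row(feature: str, label: str, values: np.ndarray, log_n: np.ndarray) -> FeatureSummaryRow:
    ok = np.isfinite(values)
    v = values[ok]
    if v.size == 0:
        raise ValueError(f"feature {feature!r} has no defined steps")
    if np.all(v == v[0]):
        # a controlled feature is constant to the last bit; summation
        # round-off must not manufacture variance (and r is undefined -> 0)
        return FeatureSummaryRow(feature, label, float(v[0]), 0.0, 0.0, 0.0)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    ratio = sd / mean if mean != 0.0 else float("nan")
    return FeatureSummaryRow(feature, label, mean, sd, ratio, _pearson_vs_log_n(values, log_n))


def summarize(track: FeatureTimecourse, design: DesignSequence) -> FeatureSummaryRow:
    """Summary statistics of one track over the design points."""
    values = track.model_values()
    log_n = design.log_numerosities()
    if len(values) != len(log_n):
        raise ValueError("track length must equal design length")
    return _row(track.feature, track.configuration, values, log_n)


def pooled_summaries(
    tracks: dict[str, FeatureTimecourse],
    design: DesignSequence,
    exclude_constant: bool = False,
) -> FeatureSummaryRow:
    """Pool one feature's tracks across configurations, then summarize.

    With ``exclude_constant`` the configurations where the feature does not
    vary (its controlled regimes) are dropped before pooling.
    """
    if not tracks:
        raise ValueError("no tracks to pool")
    log_n = design.log_numerosities()
    feature = next(iter(tracks.values())).feature
    kept, label = [], POOLED_ALL
    if exclude_constant:
        label = POOLED_EXCEPT_CONSTANT
        for tr in tracks.values():
            vals = tr.model_values()
            if np.nanstd(vals) > 0.0:
                kept.append(vals)
        if not kept:
            raise ValueError(f"feature {feature!r} is constant in every configuration")
    else:
        kept = [tr.model_values() for tr in tracks.values()]
    values = np.concatenate(kept)
    return _row(feature, label, values, np.tile(log_n, len(kept)))


def summary_table(
    timecourses: dict[str, dict[str, FeatureTimecourse]],
    design: DesignSequence,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Long-form table of summary rows: per configuration plus pooled rows.

    Parameters
    ----------
    timecourses
        Mapping ``configuration -> feature -> FeatureTimecourse`` (e.g.
        from :func:`numpref.features.feature_timecourses` per regime).
    """
    configs = list(timecourses)
    available = set.intersection(*(set(v) for v in timecourses.values()))
    if features is None:
        features = [f for f in FEATURE_AXES if f in available]
    rows: list[FeatureSummaryRow] = []
    for feat in features:
        per_config = {c: timecourses[c][feat] for c in configs}
        if feat == "numerosity":
            rows.append(
                FeatureSummaryRow(
                    **{**asdict(summarize(per_config[configs[0]], design)),
                       "configuration": "Any configuration"}
                )
            )
            continue
        any_constant = False
        for c in configs:
            row = summarize(per_config[c], design)
            any_constant = any_constant or row.sd == 0.0
            rows.append(row)
        rows.append(pooled_summaries(per_config, design))
        if any_constant:
            rows.append(pooled_summaries(per_config, design, exclude_constant=True))
    return pd.DataFrame([asdict(r) for r in rows])
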