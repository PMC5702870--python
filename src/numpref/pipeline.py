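"""End-to-end analysis pipeline and report generation.

``run_pipeline`` chains the stages: build the design, generate stimulus
displays for the five configurations, quantify feature time courses,
summarize them (the published feature tables), simulate a synthetic
numerosity-tuned voxel population, fit the numerosity model and every
feature model in configuration-specific and constrained scopes, and
compare variance explained across models. ``report`` writes the CSV
tables and the figure-style bar charts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSequence, build_default_design
from .features import FEATURE_NAMES, FeatureTimecourse, feature_timecourses
from .prf import (
    CandidatePredictions,
    ConstrainedFit,
    GridSpec,
    HRFModel,
    fit_constrained,
    fit_grid,
)
from .stimuli import ConfigurationSpec, default_configurations
from .summary import summary_table
from .synthetic import SyntheticVoxelSet, make_numerosity_map, simulate_voxels
from .compare import ComparisonTable, compare

__all__ = ["PipelineResult", "build_timecourses", "fit_population", "run_pipeline", "report"]

log = logging.getLogger("numpref")

#: figure-style grouping of features into families
FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "items": (
        "individual_item_area",
        "individual_item_perimeter",
        "total_item_area",
        "total_item_perimeter",
    ),
    "hull": ("convex_hull_area", "convex_hull_perimeter"),
    "densities": ("luminance_density", "edge_density", "numerical_density"),
    "contrast": ("display_rms_contrast", "hull_rms_contrast"),
    "high_sf": ("high_sf_energy",),
}


@dataclass
class PipelineResult:
    design: DesignSequence
    configurations: dict[str, ConfigurationSpec]
    timecourses: dict[str, dict[str, FeatureTimecourse]]
    feature_table: pd.DataFrame
    voxels: SyntheticVoxelSet
    fits: pd.DataFrame
    comparison: ComparisonTable


def build_timecourses(
    design: DesignSequence,
    configurations: dict[str, ConfigurationSpec] | None = None,
    seed: int = 0,
    pixels_per_degree: float = 128.0,
) -> dict[str, dict[str, FeatureTimecourse]]:
    """Feature tracks for every configuration, seeded per configuration."""
    configurations = configurations or default_configurations()
    rng = np.random.default_rng(seed)
    out = {}
    for name, cfg in configurations.items():
        t0 = time.perf_counter()
        out[name] = feature_timecourses(
            design, cfg, seed=int(rng.integers(2**31 - 1)),
            pixels_per_degree=pixels_per_degree,
        )
        log.info("features[%s]: %.1fs", name, time.perf_counter() - t0)
    return out


def fit_population(
    data: dict[str, np.ndarray],
    timecourses: dict[str, dict[str, FeatureTimecourse]],
    design: DesignSequence,
    models: tuple[str, ...] | None = None,
    hrf: HRFModel | None = None,
    mode: str = "cyclic",
) -> pd.DataFrame:
    """Fit every candidate model to every site, both scopes.

    Returns a long table: ``site, model, scope, configuration, preferred,
    width, amplitude, baseline, r2``. Constrained fits contribute one row
    per configuration (shared tuning, per-configuration amplitude/baseline
    and R^2) plus a ``configuration='all'`` row with the pooled R^2. One
    grid per model, spanning the feature's observed range across all
    configurations, is shared by both scopes so the constrained optimum is
    always a feasible candidate of each specific fit.
    """
    hrf = hrf or HRFModel()
    configs = list(data)
    if models is None:
        models = ("numerosity",) + FEATURE_NAMES
    rows = []
    for model_name in models:
        tracks = {c: timecourses[c][model_name] for c in configs}
        grid = GridSpec.from_tracks(list(tracks.values()))
        preds = {c: CandidatePredictions(tracks[c], grid, hrf, design, mode) for c in configs}
        t0 = time.perf_counter()
        n_sites = len(next(iter(data.values())))
        for site in range(n_sites):
            for c in configs:
                fit = fit_grid(
                    data[c][site], tracks[c], design, predictions=preds[c], scope="specific"
                )
                rows.append(
                    (site, model_name, "specific", c, fit.tuning.preferred,
                     fit.tuning.width, fit.amplitude, fit.baseline, fit.r2)
                )
            cfit = fit_constrained(
                {c: data[c][site] for c in configs}, tracks, design,
                predictions_by_config=preds,
            )
            for c in configs:
                amp, base, r2c = cfit.per_configuration[c]
                rows.append(
                    (site, model_name, "constrained", c, cfit.tuning.preferred,
                     cfit.tuning.width, amp, base, r2c)
                )
            rows.append(
                (site, model_name, "constrained", "all", cfit.tuning.preferred,
                 cfit.tuning.width, float("nan"), float("nan"), cfit.r2)
            )
        log.info("fit[%s]: %d sites, %.1fs", model_name, n_sites, time.perf_counter() - t0)
    return pd.DataFrame(
        rows,
        columns=["site", "model", "scope", "configuration", "preferred",
                 "width", "amplitude", "baseline", "r2"],
    )


def run_pipeline(
    seed: int = 0,
    n_voxels: int = 100,
    cycles: int = 20,
    noise_sd: float = 0.5,
    configurations: dict[str, ConfigurationSpec] | None = None,
    models: tuple[str, ...] | None = None,
    pixels_per_degree: float = 128.0,
    hrf: HRFModel | None = None,
) -> PipelineResult:
    """Run stimuli -> features -> tables -> synthetic voxels -> fits -> comparison."""
    configurations = configurations or default_configurations()
    design = build_default_design(cycles=cycles)
    table_design = build_default_design(cycles=1)

    tcs = build_timecourses(design, configurations, seed=seed,
                            pixels_per_degree=pixels_per_degree)
    table_tcs = build_timecourses(table_design, configurations, seed=seed + 1,
                                  pixels_per_degree=pixels_per_degree)
    table = summary_table(table_tcs, table_design)

    truth = make_numerosity_map(n_voxels, seed=seed)
    numerosity_track = tcs[next(iter(configurations))]["numerosity"]
    voxels = simulate_voxels(
        truth, design, numerosity_track, tuple(configurations),
        hrf=hrf, noise_sd=noise_sd, seed=seed,
    )
    fits = fit_population(voxels.data, tcs, design, models=models, hrf=hrf)
    comparison = compare(fits[["site", "model", "scope", "configuration", "r2"]])
    return PipelineResult(design, configurations, tcs, table, voxels, fits, comparison)


def report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write CSV tables and per-family bar-chart figures; returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    paths = {
        "feature_summary.csv": result.feature_table,
        "fits.csv": result.fits,
        "comparison_summary.csv": result.comparison.summary,
        "comparison_tests.csv": result.comparison.tests,
    }
    for name, df in paths.items():
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    summary = result.comparison.summary
    configs = [c for c in result.configurations]
    ref = summary[summary["model"] == "numerosity"].set_index(["scope", "configuration"])
    for family, feats in FEATURE_FAMILIES.items():
        feats = [f for f in feats if f in set(summary["model"])]
        if not feats:
            continue
        fig, axes = plt.subplots(
            len(feats), 2, figsize=(9, 2.6 * len(feats)), squeeze=False
        )
        for i, feat in enumerate(feats):
            for j, scope in enumerate(("specific", "constrained")):
                ax = axes[i][j]
                sub = summary[(summary["model"] == feat) & (summary["scope"] == scope)]
                sub = sub.set_index("configuration").reindex(configs)
                xs = np.arange(len(configs))
                ax.bar(xs, sub["mean_r2"], yerr=sub["sd_r2"], color="#4477aa",
                       capsize=3)
                for x, cfg in zip(xs, configs):
                    if (scope, cfg) in ref.index:
                        m = ref.loc[(scope, cfg), "mean_r2"]
                        s = ref.loc[(scope, cfg), "sd_r2"]
                        ax.axhspan(m - s, m + s, x / len(configs), (x + 1) / len(configs),
                                   color="0.8", zorder=0)
                        ax.hlines(m, x - 0.5, x + 0.5, color="k", lw=1)
                ax.set_xticks(xs)
                ax.set_xticklabels([c.replace("_", "\n") for c in configs], fontsize=6)
                ax.set_ylim(0, 1)
                ax.set_title(f"{feat} ({scope})", fontsize=8)
                if j == 0:
                    ax.set_ylabel("variance explained (R$^2$)")
        fig.tight_layout()
        p = out / f"comparison_{family}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
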