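"""Synthetic numerosity-tuned voxel populations.

Generates ground-truth recording sites whose responses follow the same
generative model the fitting stage assumes: a Gaussian tuned response to
log10 numerosity, convolved with the HRF, scaled and offset per voxel,
plus additive noise (white or AR(1)). Every downstream stage — grid
fitting, constrained fits, model comparison — can then be exercised and
scored against known truth without access to the original recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSequence
from .features import FeatureTimecourse
from .prf import HRFModel, TuningModel, hrf_kernel, convolve_design, neural_prediction

__all__ = ["SyntheticVoxelSet", "make_numerosity_map", "simulate_voxels"]


@dataclass(frozen=True)
class SyntheticVoxelSet:
    """Simulated voxel series per configuration, with generating truth."""

    truth: pd.DataFrame                    # preferred, width, amplitude, baseline
    data: dict[str, np.ndarray]            # configuration -> (n_voxels, n_samples)
    design: DesignSequence
    noise_sd: float
    ar1_rho: float
    seed: int

    @property
    def n_voxels(self) -> int:
        return len(self.truth)

    @property
    def configurations(self) -> tuple[str, ...]:
        return tuple(self.data)


def make_numerosity_map(
    n_voxels: int,
    preferred_range: tuple[float, float] = (0.0, math.log10(7.0)),
    width_range: tuple[float, float] = (0.2, 1.0),
    width_rule: str = "increasing",
    amplitude: float = 1.0,
    baseline: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth tuning table emulating a topographic numerosity map.

    Preferred log10 numerosities are drawn uniformly over
    ``preferred_range``; tuning widths either increase linearly with the
    preferred value (as along a numerosity map) or are drawn uniformly.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    lo, hi = preferred_range
    if hi < lo:
        raise ValueError("preferred_range must be increasing")
    rng = np.random.default_rng(seed)
    preferred = rng.uniform(lo, hi, size=n_voxels)
    wlo, whi = width_range
    if width_rule == "increasing":
        frac = (preferred - lo) / (hi - lo) if hi > lo else np.zeros(n_voxels)
        width = wlo + frac * (whi - wlo)
    elif width_rule == "uniform":
        width = rng.uniform(wlo, whi, size=n_voxels)
    else:
        raise ValueError("width_rule must be 'increasing' or 'uniform'")
    return pd.DataFrame(
        {
            "voxel": np.arange(n_voxels),
            "preferred": preferred,
            "width": width,
            "amplitude": amplitude,
            "baseline": baseline,
        }
    )


def _noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """White or AR(1) noise with stationary marginal SD ``sd``.

    With rho = 0 this is exactly white Gaussian noise (the innovation
    scaling ``sd * sqrt(1 - rho^2)`` reduces to ``sd``).
    """
    eps = rng.standard_normal(n)
    if rho == 0.0:
        return sd * eps
    if not -1.0 < rho < 1.0:
        raise ValueError("AR(1) coefficient must lie in (-1, 1)")
    out = np.empty(n)
    out[0] = sd * eps[0]
    scale = sd * math.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + scale * eps[t]
    return out


def simulate_voxels(
    truth: pd.DataFrame,
    design: DesignSequence,
    numerosity_track: FeatureTimecourse,
    configurations: tuple[str, ...] | list[str],
    hrf: HRFModel | None = None,
    noise_sd: float = 0.5,
    ar1_rho: float = 0.0,
    seed: int = 0,
    mode: str = "cyclic",
) -> SyntheticVoxelSet:
    """Simulate voxel responses per configuration from ground-truth tuning.

    Every configuration shares the identical numerosity progression (as in
    the experiment), so the noiseless signal is the same across
    configurations; noise is drawn independently per (voxel,
    configuration), seeded per voxel for reproducibility.
    """
    hrf = hrf or HRFModel()
    if len(numerosity_track.values) != design.n_samples:
        raise ValueError("numerosity track length must equal design length")
    kernel = hrf_kernel(hrf, design.sampling_interval)
    data = {c: np.empty((len(truth), design.n_samples)) for c in configurations}
    for i, row in enumerate(truth.itertuples(index=False)):
        model = TuningModel(row.preferred, row.width, numerosity_track.axis)
        signal = row.amplitude * convolve_design(
            neural_prediction(model, numerosity_track), kernel, mode
        ) + row.baseline
        rng = np.random.default_rng(np.random.SeedSequence([seed, int(row.voxel)]))
        for c in configurations:
            data[c][i] = signal + _noise(rng, design.n_samples, noise_sd, ar1_rho)
    return SyntheticVoxelSet(
        truth=truth.reset_index(drop=True),
        data=data,
        design=design,
        noise_sd=noise_sd,
        ar1_rho=ar1_rho,
        seed=seed,
    )
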