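"""Gaussian-tuned population receptive field forward model and grid fit.

The neural model is a 1-D Gaussian over a feature axis: a recording site
prefers a feature quantity ``preferred`` with tuning width ``width`` (the
Gaussian SD), responding with
``exp(-(x(t) - preferred)^2 / (2 width^2))`` to the feature value ``x(t)``
displayed at step ``t`` (on the log10 axis for log-scaled features).
Convolving this neural time course with a hemodynamic response function
(HRF) predicts the BOLD signal. Fitting evaluates predictions for a grid
of (preferred, width) candidates, solves amplitude (non-negative) and
baseline by least squares for each, and keeps the candidate minimizing the
sum of squared errors, i.e. maximizing variance explained
``R^2 = 1 - SSE / SStot``.

Because the stimulus sequence repeats in cycles, prediction uses cyclic
(steady-state) convolution by default: the response to a feature that
never changes is then exactly flat, and such a model explains exactly zero
variance. Linear convolution (with its onset transient) is available via
``mode='linear'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .design import DesignSequence
from .features import FeatureTimecourse

__all__ = [
    "TuningModel",
    "HRFModel",
    "PRFFit",
    "ConstrainedFit",
    "GridSpec",
    "neural_prediction",
    "hrf_kernel",
    "predict_bold",
    "fit_grid",
    "fit_constrained",
]

_EPS_VAR = 1e-24  # prediction variance below this counts as flat


@dataclass(frozen=True)
class TuningModel:
    """Gaussian tuning: preferred feature quantity and tuning width (SD)."""

    preferred: float
    width: float
    axis: str = "log10"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("tuning width must be positive")
        if self.axis not in ("log10", "linear"):
            raise ValueError("axis must be 'log10' or 'linear'")

    def response(self, x: np.ndarray) -> np.ndarray:
        return np.exp(-((x - self.preferred) ** 2) / (2.0 * self.width ** 2))


@dataclass(frozen=True)
class HRFModel:
    """Canonical two-gamma hemodynamic response function parameters.

    Defaults: peak at 6 s, undershoot at 16 s, unit dispersions,
    peak:undershoot amplitude ratio 6, 32 s kernel.
    """

    peak_delay: float = 6.0        # s
    undershoot_delay: float = 16.0  # s
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    duration: float = 32.0         # s

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.ratio <= 0:
            raise ValueError("peak:undershoot ratio must be positive")
        if self.duration < 24.0:
            raise ValueError("kernel duration must be at least 24 s")


def hrf_kernel(hrf: HRFModel, dt: float) -> np.ndarray:
    """Sample the two-gamma kernel at interval ``dt``, peak normalized to 1."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, hrf.duration + dt / 2.0, dt)
    peak = gamma_dist.pdf(t, hrf.peak_delay / hrf.peak_dispersion, scale=hrf.peak_dispersion)
    under = gamma_dist.pdf(
        t, hrf.undershoot_delay / hrf.undershoot_dispersion, scale=hrf.undershoot_dispersion
    )
    kernel = peak - under / hrf.ratio
    return kernel / kernel.max()


def neural_prediction(model: TuningModel, track: FeatureTimecourse) -> np.ndarray:
    """Tuned neural response to a feature track, one value per design step.

    Steps flagged undefined (NaN after the axis transform) evoke no
    response. A nonpositive value on a log axis is an error.
    """
    if model.axis != track.axis:
        raise ValueError(
            f"model axis {model.axis!r} does not match track axis {track.axis!r}"
        )
    if track.axis == "log10" and np.any(np.isfinite(track.values) & (track.values <= 0)):
        raise ValueError("nonpositive value on a log10 feature axis")
    x = track.model_values()
    resp = np.zeros_like(x)
    ok = np.isfinite(x)
    resp[ok] = model.response(x[ok])
    return resp


def _fold_kernel(kernel: np.ndarray, period: int) -> np.ndarray:
    """Wrap a kernel modulo the signal length for cyclic convolution."""
    folded = np.zeros(period)
    for i, k in enumerate(kernel):
        folded[i % period] += k
    return folded


def convolve_design(neural: np.ndarray, kernel: np.ndarray, mode: str = "cyclic") -> np.ndarray:
    """Convolve neural step responses with an HRF kernel.

    ``cyclic`` treats the sequence as periodic (steady state of a repeating
    run); ``linear`` keeps the onset transient and truncates to length.
    """
    T = len(neural)
    if mode == "cyclic":
        folded = _fold_kernel(kernel, T)
        return np.real(np.fft.ifft(np.fft.fft(neural) * np.fft.fft(folded)))
    if mode == "linear":
        return np.convolve(neural, kernel)[:T]
    raise ValueError("mode must be 'cyclic' or 'linear'")


def predict_bold(
    model: TuningModel,
    track: FeatureTimecourse,
    hrf: HRFModel,
    design: DesignSequence,
    mode: str = "cyclic",
) -> np.ndarray:
    """Predicted BOLD time course (unit amplitude, zero baseline)."""
    if len(track.values) != design.n_samples:
        raise ValueError("track length must equal design length")
    kernel = hrf_kernel(hrf, design.sampling_interval)
    return convolve_design(neural_prediction(model, track), kernel, mode)


# ----------------------------------------------------------------------
# grid fitting


@dataclass(frozen=True)
class GridSpec:
    """Candidate (preferred, width) grid on the model axis.

    Defaults: preferred spans the observed feature range extended by 20%
    on each side, 40 steps; width log-spaced 0.05-3 axis units, 30 steps.
    """

    preferred: np.ndarray
    widths: np.ndarray

    @classmethod
    def from_tracks(
        cls,
        tracks: FeatureTimecourse | list[FeatureTimecourse],
        n_preferred: int = 40,
        n_widths: int = 30,
        width_bounds: tuple[float, float] = (0.05, 3.0),
        extend: float = 0.2,
    ) -> "GridSpec":
        if isinstance(tracks, FeatureTimecourse):
            tracks = [tracks]
        vals = np.concatenate([t.model_values() for t in tracks])
        vals = vals[np.isfinite(vals)]
        lo, hi = float(vals.min()), float(vals.max())
        span = hi - lo
        if span == 0.0:
            preferred = np.array([lo])
        else:
            preferred = np.linspace(lo - extend * span, hi + extend * span, n_preferred)
        widths = np.geomspace(width_bounds[0], width_bounds[1], n_widths)
        return cls(preferred=preferred, widths=widths)

    def candidates(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (preferred, width) pairs ordered by width then preferred.

        This ordering makes 'first argmax' implement the tie-break rule:
        smallest width, then smallest preferred.
        """
        W, P = np.meshgrid(self.widths, self.preferred, indexing="ij")
        return P.ravel(), W.ravel()


@dataclass(frozen=True)
class PRFFit:
    """Best-fitting tuned model for one recording site."""

    tuning: TuningModel
    amplitude: float
    baseline: float
    r2: float
    scope: str  # configuration name, or 'all' for constrained fits


@dataclass(frozen=True)
class ConstrainedFit:
    """One (preferred, width) shared across configurations.

    ``r2`` pools the squared errors over all configurations (per-
    configuration amplitude and baseline); ``per_configuration`` maps each
    configuration to its own (amplitude, baseline, r2) under the shared
    tuning.
    """

    tuning: TuningModel
    r2: float
    per_configuration: dict[str, tuple[float, float, float]]


class CandidatePredictions:
    """Precomputed prediction matrix for a (track, grid, hrf) triple.

    Rows are grid candidates in tie-break order; reusable across voxels.
    """

    def __init__(
        self,
        track: FeatureTimecourse,
        grid: GridSpec,
        hrf: HRFModel,
        design: DesignSequence,
        mode: str = "cyclic",
    ) -> None:
        self.grid = grid
        self.preferred, self.widths = grid.candidates()
        x = FeatureTimecourse(track.feature, track.configuration, track.values, track.axis)
        xv = x.model_values()
        ok = np.isfinite(xv)
        neural = np.zeros((len(self.preferred), len(xv)))
        diff = xv[ok][None, :] - self.preferred[:, None]
        neural[:, ok] = np.exp(-(diff ** 2) / (2.0 * self.widths[:, None] ** 2))
        kernel = hrf_kernel(hrf, design.sampling_interval)
        if mode == "cyclic":
            folded = _fold_kernel(kernel, neural.shape[1])
            pred = np.real(
                np.fft.ifft(np.fft.fft(neural, axis=1) * np.fft.fft(folded)[None, :], axis=1)
            )
        else:
            full = np.apply_along_axis(lambda r: np.convolve(r, kernel), 1, neural)
            pred = full[:, : neural.shape[1]]
        self.pred = pred
        self.pred_mean = pred.mean(axis=1)
        self.centered = pred - self.pred_mean[:, None]
        self.s2 = np.einsum("ij,ij->i", self.centered, self.centered)

    def sse(self, observed: np.ndarray, nonneg: bool = True):
        """Residual SSE, amplitude and baseline per candidate (least squares)."""
        y = np.asarray(observed, dtype=float)
        ybar = y.mean()
        yc = y - ybar
        sstot = float(yc @ yc)
        num = self.centered @ yc
        with np.errstate(divide="ignore", invalid="ignore"):
            amp = np.where(self.s2 > _EPS_VAR, num / np.where(self.s2 > 0, self.s2, 1.0), 0.0)
        if nonneg:
            amp = np.maximum(amp, 0.0)
        sse = sstot - 2.0 * amp * num + amp ** 2 * self.s2
        baseline = ybar - amp * self.pred_mean
        return sse, sstot, amp, baseline


def _check_observed(observed: np.ndarray) -> np.ndarray:
    y = np.asarray(observed, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("observed time course contains non-finite values")
    if y.std() == 0.0:
        raise ValueError("observed time course has zero variance")
    return y


def fit_grid(
    observed: np.ndarray,
    track: FeatureTimecourse,
    design: DesignSequence,
    grid: GridSpec | None = None,
    hrf: HRFModel | None = None,
    nonneg_amplitude: bool = True,
    mode: str = "cyclic",
    predictions: CandidatePredictions | None = None,
    scope: str | None = None,
) -> PRFFit:
    """Exhaustive grid search for the best-fitting tuned model.

    Ties in R^2 resolve to the smallest width, then smallest preferred.
    """
    y = _check_observed(observed)
    hrf = hrf or HRFModel()
    if predictions is None:
        grid = grid or GridSpec.from_tracks(track)
        predictions = CandidatePredictions(track, grid, hrf, design, mode)
    sse, sstot, amp, base = predictions.sse(y, nonneg_amplitude)
    best = int(np.argmin(sse))
    r2 = max(0.0, 1.0 - sse[best] / sstot)
    tuning = TuningModel(
        float(predictions.preferred[best]), float(predictions.widths[best]), track.axis
    )
    return PRFFit(tuning, float(amp[best]), float(base[best]),
                  float(min(1.0, r2)), scope or track.configuration)


def fit_constrained(
    observed_by_config: dict[str, np.ndarray],
    tracks_by_config: dict[str, FeatureTimecourse],
    design: DesignSequence,
    grid: GridSpec | None = None,
    hrf: HRFModel | None = None,
    nonneg_amplitude: bool = True,
    mode: str = "cyclic",
    predictions_by_config: dict[str, CandidatePredictions] | None = None,
) -> ConstrainedFit:
    """Fit one (preferred, width) shared across all configurations.

    Amplitude and baseline stay configuration-specific. The winning
    candidate minimizes total SSE over the concatenated configurations;
    overall R^2 pools SSE and SStot across configurations.
    """
    configs = list(observed_by_config)
    if len(configs) < 2:
        raise ValueError("constrained fit needs at least two configurations")
    if set(tracks_by_config) < set(configs):
        raise ValueError("missing feature track for some configuration")
    hrf = hrf or HRFModel()
    if predictions_by_config is None:
        grid = grid or GridSpec.from_tracks([tracks_by_config[c] for c in configs])
        predictions_by_config = {
            c: CandidatePredictions(tracks_by_config[c], grid, hrf, design, mode)
            for c in configs
        }
    total_sse = None
    total_sstot = 0.0
    parts = {}
    for c in configs:
        sse, sstot, amp, base = predictions_by_config[c].sse(
            _check_observed(observed_by_config[c]), nonneg_amplitude
        )
        parts[c] = (sse, sstot, amp, base)
        total_sse = sse if total_sse is None else total_sse + sse
        total_sstot += sstot
    best = int(np.argmin(total_sse))
    any_pred = predictions_by_config[configs[0]]
    axis = tracks_by_config[configs[0]].axis
    tuning = TuningModel(float(any_pred.preferred[best]), float(any_pred.widths[best]), axis)
    per_config = {}
    for c in configs:
        sse, sstot, amp, base = parts[c]
        r2_c = min(1.0, max(0.0, 1.0 - sse[best] / sstot))
        per_config[c] = (float(amp[best]), float(base[best]), float(r2_c))
    r2 = min(1.0, max(0.0, 1.0 - total_sse[best] / total_sstot))
    return ConstrainedFit(tuning, float(r2), per_config)
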