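"""Numerosity presentation design.

The experiment presents dot displays whose numerosity follows a fixed
progression, repeated in cycles. One cycle steps through numerosities 1-7
once each and then holds a 20-dot baseline for three steps, giving ten
design points per cycle. Every stimulus configuration shares this
progression; it is the time axis of all downstream feature tracks, model
predictions and simulated voxel series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DesignSequence", "build_default_design", "DEFAULT_CYCLE"]

#: one cycle: numerosities 1..7 once each, then the 20-dot baseline held 3 steps
DEFAULT_CYCLE: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 20, 20, 20)


@dataclass(frozen=True)
class DesignSequence:
    """Ordered numerosity presentation sequence.

    Parameters
    ----------
    steps
        One cycle as ``(numerosity, duration_s)`` pairs. Durations must be
        positive integer multiples of ``sampling_interval``.
    sampling_interval
        Volume acquisition interval (TR) in seconds.
    cycles
        Number of times the cycle repeats.
    """

    steps: tuple[tuple[int, float], ...]
    sampling_interval: float = 2.0
    cycles: int = 1

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not self.steps:
            raise ValueError("design needs at least one step")
        for n, dur in self.steps:
            if n < 1 or int(n) != n:
                raise ValueError(f"numerosity must be a positive integer, got {n}")
            if dur <= 0:
                raise ValueError(f"step duration must be positive, got {dur}")
            ratio = dur / self.sampling_interval
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    "step durations must be integer multiples of sampling_interval"
                )

    @property
    def cycle_duration(self) -> float:
        return float(sum(dur for _, dur in self.steps))

    @property
    def total_duration(self) -> float:
        return self.cycles * self.cycle_duration

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.cycle_duration / self.sampling_interval))

    @property
    def n_samples(self) -> int:
        return self.cycles * self.samples_per_cycle

    def cycle_numerosities(self) -> np.ndarray:
        """Numerosity at each sampling point of one cycle."""
        reps = [int(round(dur / self.sampling_interval)) for _, dur in self.steps]
        return np.repeat([n for n, _ in self.steps], reps)

    def numerosities(self) -> np.ndarray:
        """Numerosity at each sampling point of the full run (all cycles)."""
        return np.tile(self.cycle_numerosities(), self.cycles)

    def log_numerosities(self) -> np.ndarray:
        """log10 numerosity at each sampling point (the model/statistics axis)."""
        return np.log10(self.numerosities().astype(float))

    @property
    def distinct_numerosities(self) -> tuple[int, ...]:
        return tuple(sorted({n for n, _ in self.steps}))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval


def build_default_design(
    cycles: int = 1,
    step_duration: float = 2.0,
    sampling_interval: float = 2.0,
) -> DesignSequence:
    """Build the default design: [1,2,3,4,5,6,7,20,20,20] per cycle.

    Over one cycle the log10 numerosities have mean 0.761 and sample SD
    0.445, the summary statistics the feature tables are computed against.
    """
    steps = tuple((n, step_duration) for n in DEFAULT_CYCLE)
    return DesignSequence(steps=steps, sampling_interval=sampling_interval, cycles=cycles)
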