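"""Core data containers shared by every stage of the pipeline.

Conventions
-----------
* Times are seconds (floats); frames are 0-based integer indices.
  Conversion always goes through a recording's ``frame_rate``.
* Traces are stored as positive fluorescence on a ``1 + dF/F`` scale
  (a quiescent, noiseless cell sits at 1.0), so the per-trial ratio
  ``F_s / F_b - 1`` is well defined.  Raw-fluorescence inputs can be
  brought onto this scale by dividing by their session mean (see
  :func:`followerkit.io.read_recording`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

#: Condition labels used in the study design.
CONDITION_LABELS = ("L2/3-anesthetized", "L2/3-awake", "L4-awake", "sham")

#: Minimum inter-trial gap (s) required for calcium transients of potential
#: followers to return to baseline before the next trial.
MIN_TRIAL_GAP_S = 2.5


def measure_fwhm(kernel: np.ndarray, frame_rate: float) -> float:
    """Full width at half maximum of a sampled kernel, in seconds.

    Crossing times of the half-maximum level are located by linear
    interpolation between frames, so the result is not quantized to
    whole frame periods.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise InvalidParameterError("empty kernel")
    half = kernel.max() / 2.0
    above = kernel >= half
    if not above.any():
        raise InvalidParameterError("kernel never reaches half maximum")
    idx = np.nonzero(above)[0]
    first, last = idx[0], idx[-1]
    dt = 1.0 / frame_rate

    # rising crossing (before the first above-half sample)
    if first == 0:
        t_rise = 0.0
    else:
        y0, y1 = kernel[first - 1], kernel[first]
        t_rise = (first - 1 + (half - y0) / (y1 - y0)) * dt
    # falling crossing (after the last above-half sample)
    if last == kernel.size - 1:
        t_fall = last * dt
    else:
        y0, y1 = kernel[last], kernel[last + 1]
        t_fall = (last + (y0 - half) / (y0 - y1)) * dt
    return t_fall - t_rise


@dataclass(frozen=True)
class TransientTemplate:
    """Single action-potential calcium transient sampled at the frame rate.

    Attributes
    ----------
    kernel : ndarray
        Nonnegative dF/F fraction per sample; ``kernel.max()`` equals
        ``peak_amplitude``.
    peak_amplitude : float
        Peak dF/F fraction of a 1-AP transient.
    fwhm : float
        Full width at half maximum, seconds (~0.4 s for OGB-1).
    rise_time : float
        Rise time constant, seconds.  The indicator rise is faster than
        one frame period at typical rates, so the default is 0
        (instantaneous at frame resolution).
    frame_rate : float
        Sampling rate of ``kernel``, Hz.
    """

    kernel: np.ndarray
    peak_amplitude: float
    fwhm: float
    rise_time: float
    frame_rate: float

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", k)
        if (k < 0).any():
            raise InvalidParameterError("template kernel must be nonnegative")
        if abs(k.max() - self.peak_amplitude) > 1e-6 * max(self.peak_amplitude, 1.0):
            raise InvalidParameterError(
                "kernel maximum does not equal peak_amplitude"
            )

    @property
    def n_frames(self) -> int:
        return int(self.kernel.size)

    def windowed_mean(self, window_s: float) -> float:
        """Mean of the kernel over the first ``window_s`` seconds.

        This is the expected dF/F response of a single inserted AP when the
        response window starts at the insertion frame (zero-padded if the
        window outruns the kernel).
        """
        n = max(1, int(round(window_s * self.frame_rate)))
        padded = np.zeros(n)
        m = min(n, self.kernel.size)
        padded[:m] = self.kernel[:m]
        return float(padded.mean())


@dataclass(frozen=True)
class StimSchedule:
    """Stimulation trial schedule: pulse onset/offset times in seconds."""

    onsets: np.ndarray
    offsets: np.ndarray

    def __post_init__(self):
        on = np.asarray(self.onsets, dtype=float)
        off = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "onsets", on)
        object.__setattr__(self, "offsets", off)
        if on.shape != off.shape or on.ndim != 1:
            raise InvalidParameterError("onsets/offsets must be matching 1-d arrays")
        if on.size == 0:
            raise InvalidParameterError("schedule must contain at least one trial")
        if not (off > on).all():
            raise InvalidParameterError("every offset must lie strictly after its onset")
        if (np.diff(on) <= 0).any():
            raise InvalidParameterError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return int(self.onsets.size)

    @property
    def end(self) -> float:
        return float(self.offsets[-1])

    def min_gap(self) -> float:
        """Smallest gap between consecutive trials (next onset - prev offset)."""
        if self.n_trials < 2:
            return np.inf
        return float(np.min(self.onsets[1:] - self.offsets[:-1]))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings for synthetic OGB-like recordings.

    The defaults define the reference signal regime of the package: sparse
    Poisson-timed spontaneous transients with small geometric burst sizes,
    i.i.d. Gaussian frame noise, and a ~400 ms FWHM single-AP transient.
    They are calibrated (see docs/methods.md) so that the sham mean-z
    distribution over >=1,000 cells spans approximately [-2.3, 2.1].
    """

    n_cells: int = 56
    frame_rate: float = 10.0
    duration: float | None = None  # seconds; None -> derived from the schedule
    spont_event_rate: float = 0.1  # events / s / cell
    spont_spike_mean: float = 1.5  # mean spikes per event (geometric, support >= 1)
    noise_sd: float = 0.11  # dF/F fraction per frame
    peak_amplitude: float = 0.06  # 1-AP peak dF/F fraction
    fwhm: float = 0.4  # 1-AP transient FWHM, seconds
    drift_amplitude: float = 0.0  # optional slow sinusoidal drift, dF/F fraction
    drift_period: float = 60.0  # seconds
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if not (0 < self.frame_rate):
            raise InvalidParameterError("frame_rate must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.spont_event_rate < 0:
            raise InvalidParameterError("spont_event_rate must be >= 0")
        if self.spont_spike_mean < 1:
            raise InvalidParameterError("spont_spike_mean must be >= 1")


@dataclass
class FovRecording:
    """One imaging session: ROI traces, schedule, and metadata.

    ``traces`` is a cells x frames matrix on the ``1 + dF/F`` scale.
    ``ground_truth`` is set by the synthetic generator only and records the
    per-cell insertion efficacy ``p``, spikes-per-trial ``k``, and which
    trials received insertions.
    """

    traces: np.ndarray
    frame_rate: float
    schedule: StimSchedule
    patched_cell: int | None = None
    cell_positions: np.ndarray | None = None  # (n_cells, 2) in micrometers
    interneuron_flags: np.ndarray | None = None
    condition_label: str = "sham"
    ground_truth: dict | None = None

    def __post_init__(self):
        t = np.asarray(self.traces, dtype=float)
        if t.ndim != 2:
            raise InvalidParameterError("traces must be a cells x frames matrix")
        if not np.isfinite(t).all():
            raise InvalidParameterError("traces contain missing/non-finite frames")
        self.traces = t

    @property
    def n_cells(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.traces.shape[1])

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def replace(self, **changes) -> "FovRecording":
        return dataclasses.replace(self, **changes)
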