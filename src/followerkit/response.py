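"""Per-trial dF/F response extraction.

For every trial the response is the ratio

    r(t) = F_s / F_b - 1

with ``F_s`` the mean fluorescence over the 400 ms starting right at the
stimulus offset and ``F_b`` the mean over the 600 ms immediately preceding the
stimulus onset (a per-trial local baseline).  The responses of all trials of
one cell form its response distribution **R**, the raw material of the
follower statistic.

Window-to-frame conversion: a window of ``w`` seconds covers
``max(1, round(w * frame_rate))`` whole frames; onset/offset times map to the
nearest frame index at or after the stated time.  Both windows are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FovRecording
from .exceptions import DegenerateBaselineError, InvalidParameterError, WindowError

__all__ = [
    "TrialResponseSet",
    "trial_response",
    "extract_responses",
    "spike_amplitude_curve",
    "SpikeAmplitudeCurve",
]

DEFAULT_WINDOW_RESPONSE = 0.4  # seconds after stimulus offset
DEFAULT_WINDOW_BASELINE = 0.6  # seconds before stimulus onset


def window_frames(window_s: float, frame_rate: float) -> int:
    """Number of whole frames covered by a window (>= 1)."""
    if window_s <= 0 or frame_rate <= 0:
        raise InvalidParameterError("window and frame_rate must be positive")
    return max(1, int(round(window_s * frame_rate)))


def frame_at_or_after(t: float, frame_rate: float) -> int:
    """Nearest frame index at or after time ``t`` (seconds)."""
    return int(np.ceil(t * frame_rate - 1e-9))


@dataclass
class TrialResponseSet:
    """Per-trial responses r(t) for every cell of a recording.

    Attributes
    ----------
    responses : ndarray, shape (n_cells, n_trials)
        The distributions **R**, one row per cell.
    f_response, f_baseline : ndarray, shape (n_cells, n_trials)
        Raw window means ``F_s`` and ``F_b`` (kept for the comparator
        criteria, which operate on epoch fluorescence rather than the ratio).
    f0 : ndarray, shape (n_cells,)
        Per-cell session baseline (median of the full trace); reference level
        for epoch dF/F values.
    resp_starts, base_starts : ndarray, shape (n_trials,)
        First frame index of each response / baseline window.
    """

    responses: np.ndarray
    f_response: np.ndarray
    f_baseline: np.ndarray
    f0: np.ndarray
    resp_starts: np.ndarray
    base_starts: np.ndarray
    n_frames_response: int
    n_frames_baseline: int
    frame_rate: float
    window_response: float = DEFAULT_WINDOW_RESPONSE
    window_baseline: float = DEFAULT_WINDOW_BASELINE

    @property
    def n_cells(self) -> int:
        return int(self.responses.shape[0])

    @property
    def n_trials(self) -> int:
        return int(self.responses.shape[1])


def _window_indices(
    onsets: np.ndarray,
    offsets: np.ndarray,
    frame_rate: float,
    n_frames: int,
    window_response: float,
    window_baseline: float,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Frame indices of baseline/response windows; errors name the offending
    trial instead of silently dropping it."""
    nr = window_frames(window_response, frame_rate)
    nb = window_frames(window_baseline, frame_rate)
    resp_starts = np.array([frame_at_or_after(t, frame_rate) for t in offsets])
    onset_idx = np.array([frame_at_or_after(t, frame_rate) for t in onsets])
    base_starts = onset_idx - nb
    for t_idx in range(onsets.size):
        if base_starts[t_idx] < 0:
            raise WindowError(
                f"trial {t_idx} (onset {onsets[t_idx]:g} s): baseline window "
                f"starts before the trace"
            )
        if resp_starts[t_idx] + nr > n_frames:
            raise WindowError(
                f"trial {t_idx} (offset {offsets[t_idx]:g} s): response window "
                f"ends after the trace"
            )
    return resp_starts, base_starts, nr, nb


def trial_response(
    trace: np.ndarray,
    frame_rate: float,
    onset: float,
    offset: float,
    window_response: float = DEFAULT_WINDOW_RESPONSE,
    window_baseline: float = DEFAULT_WINDOW_BASELINE,
) -> float:
    """Single-trial dF/F response ``mean(F_s) / mean(F_b) - 1``.

    The result is invariant under multiplication of the whole trace by any
    positive constant (ratio form).

    Raises
    ------
    WindowError
        If either window falls outside the trace.
    DegenerateBaselineError
        If the baseline mean is <= 0.
    """
    trace = np.asarray(trace, dtype=float)
    resp_starts, base_starts, nr, nb = _window_indices(
        np.array([onset]), np.array([offset]), frame_rate, trace.size,
        window_response, window_baseline,
    )
    fb = trace[base_starts[0] : base_starts[0] + nb].mean()
    if fb <= 0:
        raise DegenerateBaselineError(
            f"baseline mean {fb:g} <= 0 for trial at onset {onset:g} s"
        )
    fs = trace[resp_starts[0] : resp_starts[0] + nr].mean()
    return float(fs / fb - 1.0)


def extract_responses(
    rec: FovRecording,
    window_response: float = DEFAULT_WINDOW_RESPONSE,
    window_baseline: float = DEFAULT_WINDOW_BASELINE,
) -> TrialResponseSet:
    """Compute r(t) for every cell x trial of a recording."""
    sched = rec.schedule
    resp_starts, base_starts, nr, nb = _window_indices(
        sched.onsets, sched.offsets, rec.frame_rate, rec.n_frames,
        window_response, window_baseline,
    )
    # windowed means via cumulative sums, vectorized over cells and trials
    cs = np.concatenate(
        [np.zeros((rec.n_cells, 1)), np.cumsum(rec.traces, axis=1)], axis=1
    )
    f_resp = (cs[:, resp_starts + nr] - cs[:, resp_starts]) / nr
    f_base = (cs[:, base_starts + nb] - cs[:, base_starts]) / nb
    if (f_base <= 0).any():
        cell, trial = np.argwhere(f_base <= 0)[0]
        raise DegenerateBaselineError(
            f"cell {cell}, trial {trial}: baseline mean <= 0"
        )
    return TrialResponseSet(
        responses=f_resp / f_base - 1.0,
        f_response=f_resp,
        f_baseline=f_base,
        f0=np.median(rec.traces, axis=1),
        resp_starts=resp_starts,
        base_starts=base_starts,
        n_frames_response=nr,
        n_frames_baseline=nb,
        frame_rate=rec.frame_rate,
        window_response=window_response,
        window_baseline=window_baseline,
    )


@dataclass
class SpikeAmplitudeCurve:
    """Event-aligned dF/F response binned by spike count, plus a linear fit."""

    per_count: pd.DataFrame  # index: spike count; columns: mean, sd, sem, n
    slope: float
    intercept: float

    @property
    def counts(self) -> np.ndarray:
        return self.per_count.index.to_numpy()


def spike_amplitude_curve(
    trace: np.ndarray,
    frame_rate: float,
    event_times: np.ndarray,
    spike_counts: np.ndarray,
    window_response: float = DEFAULT_WINDOW_RESPONSE,
    window_baseline: float = DEFAULT_WINDOW_BASELINE,
) -> SpikeAmplitudeCurve:
    """Relate windowed dF/F amplitude to the number of spikes per event.

    Each event is treated like a trial with onset = offset = event time, so
    the response window starts at the event and the baseline window ends just
    before it.  Responses are binned by spike count (mean, sd, sem, n per
    bin) and a least-squares line is fitted through all event responses; for
    a linearly summing indicator the slope estimates the windowed 1-AP
    response amplitude.
    """
    event_times = np.asarray(event_times, dtype=float)
    spike_counts = np.asarray(spike_counts)
    if event_times.size == 0:
        raise InvalidParameterError("need at least one event")
    if event_times.shape != spike_counts.shape:
        raise InvalidParameterError("event_times and spike_counts must match")
    r = np.array(
        [
            trial_response(trace, frame_rate, t, t, window_response, window_baseline)
            for t in event_times
        ]
    )
    df = pd.DataFrame({"count": spike_counts, "response": r})
    g = df.groupby("count")["response"]
    per_count = pd.DataFrame(
        {"mean": g.mean(), "sd": g.std(ddof=1), "sem": g.sem(), "n": g.size()}
    )
    if np.unique(spike_counts).size > 1:
        slope, intercept = np.polyfit(spike_counts.astype(float), r, 1)
    else:
        slope, intercept = np.nan, np.nan
    return SpikeAmplitudeCurve(per_count=per_count, slope=float(slope),
                               intercept=float(intercept))
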