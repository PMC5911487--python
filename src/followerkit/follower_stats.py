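"""Circular-shuffle rank-sum mean-z follower detection.

The statistic works in three steps, per cell:

1. extract the real per-trial responses **R** (module :mod:`~followerkit.response`);
2. circularly shift the cell's own trace ``n_iter`` times (default 5,000) by a
   random admissible number of frames and recompute all trial responses on
   each shifted trace at the original stimulus times, yielding null response
   distributions **R**_N that preserve the trace's autocorrelation, noise and
   spontaneous-event statistics;
3. compute a Wilcoxon rank-sum z-value between **R** and each **R**_N and
   average them.  The mean z is compared against thresholds derived from sham
   sessions (no evoked spikes): a cell is an *excited follower* above the
   upper threshold and an *inhibited follower* below the lower one.

Shift admissibility: a shift is admissible when its circular magnitude is at
least one exclusion zone (default 1 s, the duration of a 1-AP transient) away
from both 0 and the trace length, so null response windows never overlap the
true post-stimulus transient of the same trial.  This reading of the
exclusion rule is a documented interpretation (docs/methods.md); the zone
width is a parameter.

The rank-sum z uses the normal approximation with tie-corrected variance and
no continuity correction (sample sizes of ~190 trials make the approximation
excellent).  Sign convention: real responses stochastically larger than the
null give positive z.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import FovRecording
from .exceptions import (
    DegenerateBaselineError,
    InvalidParameterError,
    NoAdmissibleShiftError,
)
from .response import (
    DEFAULT_WINDOW_BASELINE,
    DEFAULT_WINDOW_RESPONSE,
    TrialResponseSet,
    extract_responses,
)

__all__ = [
    "Thresholds",
    "REFERENCE_THRESHOLDS",
    "NullEnsemble",
    "MeanZResult",
    "ranksum_z",
    "circular_null",
    "mean_z_statistic",
    "analyze_fov",
    "calibrate_thresholds",
    "apply_thresholds",
    "kwan_dan_followers",
    "ttest_comparator",
]

LABEL_EXCITED = "excited"
LABEL_INHIBITED = "inhibited"
LABEL_NEUTRAL = "neutral"

DEFAULT_N_ITER = 5000
DEFAULT_EXCLUSION_S = 1.0


@dataclass(frozen=True)
class Thresholds:
    """Mean-z classification thresholds (excited above, inhibited below)."""

    upper: float
    lower: float
    provenance: str = "reference-default"

    def __post_init__(self):
        if not (self.upper > 0 > self.lower):
            raise InvalidParameterError("thresholds must satisfy upper > 0 > lower")


#: Reference thresholds derived from 1,069 sham-stimulated cells in the
#: original study: sham mean-z values never exceeded 2.1 or fell below -2.3.
REFERENCE_THRESHOLDS = Thresholds(upper=2.1, lower=-2.3, provenance="reference-default")


@dataclass
class NullEnsemble:
    """Circular-shuffle null: one set of trial responses per random shift."""

    n_iter: int
    shift_values: np.ndarray  # frames, one per iteration
    null_responses: np.ndarray  # (n_iter, n_trials)
    exclusion: float  # seconds
    seed: int | None


@dataclass
class MeanZResult:
    """Per-cell outcome of the mean-z statistic."""

    cell: int
    z_values: np.ndarray
    mean_z: float
    label: str
    thresholds: Thresholds
    null_median: float  # median of the pooled null responses
    n_trials: int


def classify_mean_z(mean_z: float, thresholds: Thresholds) -> str:
    if mean_z > thresholds.upper:
        return LABEL_EXCITED
    if mean_z < thresholds.lower:
        return LABEL_INHIBITED
    return LABEL_NEUTRAL


def apply_thresholds(
    results: list[MeanZResult], thresholds: Thresholds
) -> list[MeanZResult]:
    """Relabel existing results under different thresholds (no recompute)."""
    return [
        dataclasses.replace(
            r, label=classify_mean_z(r.mean_z, thresholds), thresholds=thresholds
        )
        for r in results
    ]


# ---------------------------------------------------------------------------
# rank-sum z
# ---------------------------------------------------------------------------

def _tie_term(sorted_row: np.ndarray) -> float:
    _, counts = np.unique(sorted_row, return_counts=True)
    c = counts.astype(float)
    return float(np.sum(c**3 - c))


def _z_from_u(u1: np.ndarray, tie: np.ndarray, n1: int, n2: int) -> np.ndarray:
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = np.zeros(np.shape(u1))
    ok = var > 0
    z[ok] = (u1[ok] - n1 * n2 / 2.0) / np.sqrt(var[ok])
    return z


def _ranksum_z_rows(real: np.ndarray, null_rows: np.ndarray) -> np.ndarray:
    """Rank-sum z of ``real`` against every row of ``null_rows``.

    U is accumulated by binary search of each null value in the sorted real
    sample, which avoids ranking the combined sample per iteration.  Rows
    containing ties fall back to an exact average-rank computation with the
    tie-corrected variance; tie-free rows use the closed-form variance
    n1*n2*(n+1)/12.
    """
    real = np.asarray(real, dtype=float)
    null_rows = np.asarray(null_rows, dtype=float)
    n1 = real.size
    m, n2 = null_rows.shape
    real_sorted = np.sort(real)

    flat = null_rows.ravel()
    right = np.searchsorted(real_sorted, flat, side="right").reshape(m, n2)
    left = np.searchsorted(real_sorted, flat, side="left").reshape(m, n2)
    # pairs with real > null count 1, exact ties count 1/2
    u1 = (n1 - right).sum(axis=1) + 0.5 * (right - left).sum(axis=1)

    null_sorted = np.sort(null_rows, axis=1)
    has_tie = (
        (right != left).any(axis=1)
        | (null_sorted[:, 1:] == null_sorted[:, :-1]).any(axis=1)
    )
    real_tie = _tie_term(real_sorted)
    tie = np.full(m, real_tie)
    if has_tie.any():
        for i in np.nonzero(has_tie)[0]:
            tie[i] = _tie_term(np.concatenate([real_sorted, null_sorted[i]]))
    return _z_from_u(u1, tie, n1, n2)


def ranksum_z(real: np.ndarray, null: np.ndarray) -> float:
    """Two-sample Wilcoxon rank-sum z via the normal approximation.

    Tie-corrected variance, no continuity correction.  Positive when ``real``
    is stochastically larger than ``null``; 0 when all values across both
    samples are tied (zero variance).
    """
    real = np.asarray(real, dtype=float).ravel()
    null = np.asarray(null, dtype=float).ravel()
    if real.size == 0 or null.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    return float(_ranksum_z_rows(real, null.reshape(1, -1))[0])


# ---------------------------------------------------------------------------
# circular-shuffle null
# ---------------------------------------------------------------------------

def _admissible_shift_bounds(
    n_frames: int, exclusion_s: float, frame_rate: float
) -> tuple[int, int]:
    excl = max(1, int(round(exclusion_s * frame_rate)))
    lo, hi = excl, n_frames - excl
    if lo > hi:
        raise NoAdmissibleShiftError(
            f"exclusion zone of {exclusion_s:g} s ({excl} frames) on both ends "
            f"leaves no admissible shift for a {n_frames}-frame trace"
        )
    return lo, hi


def _circular_window_means(trace: np.ndarray, width: int) -> np.ndarray:
    """W[j] = mean of ``width`` frames starting at j, wrapping circularly."""
    n = trace.size
    ext = np.concatenate([trace, trace[: width - 1]]) if width > 1 else trace
    cs = np.concatenate([[0.0], np.cumsum(ext)])
    return (cs[width : width + n] - cs[:n]) / width


def _null_response_matrix(
    trace: np.ndarray, rs: TrialResponseSet, shifts: np.ndarray
) -> np.ndarray:
    """Trial responses recomputed on circularly shifted copies of ``trace``.

    A rotation of the trace by ``s`` frames places original frame ``j - s``
    under window start ``j``, so window means on the rotated trace are
    circular window means of the original trace at shifted start indices —
    no per-iteration rolling required.
    """
    n = trace.size
    wr = _circular_window_means(trace, rs.n_frames_response)
    wb = _circular_window_means(trace, rs.n_frames_baseline)
    if (wb <= 0).any():
        raise DegenerateBaselineError(
            "some circularly shifted baseline windows have mean <= 0"
        )
    # start - shift lies in (-n, n); indexing a doubled table at
    # start - shift + n avoids a modulo over the full index matrix
    wr2 = np.concatenate([wr, wr])
    wb2 = np.concatenate([wb, wb])
    offs = (n - np.asarray(shifts))[:, None]
    return wr2[rs.resp_starts[None, :] + offs] / wb2[rs.base_starts[None, :] + offs] - 1.0


def circular_null(
    rec: FovRecording,
    cell: int,
    n_iter: int = DEFAULT_N_ITER,
    exclusion: float = DEFAULT_EXCLUSION_S,
    seed: int | None = None,
    window_response: float = DEFAULT_WINDOW_RESPONSE,
    window_baseline: float = DEFAULT_WINDOW_BASELINE,
    responses: TrialResponseSet | None = None,
) -> NullEnsemble:
    """Build the circular-shuffle null ensemble for one cell.

    Each iteration rotates the cell's trace by a uniformly drawn admissible
    frame shift and recomputes all trial responses at the original stimulus
    times.
    """
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    rs = responses if responses is not None else extract_responses(
        rec, window_response, window_baseline
    )
    lo, hi = _admissible_shift_bounds(rec.n_frames, exclusion, rec.frame_rate)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(lo, hi + 1, size=n_iter)
    null = _null_response_matrix(rec.traces[cell], rs, shifts)
    return NullEnsemble(
        n_iter=n_iter,
        shift_values=shifts,
        null_responses=null,
        exclusion=exclusion,
        seed=seed,
    )


def mean_z_statistic(
    rec: FovRecording,
    cell: int,
    n_iter: int = DEFAULT_N_ITER,
    exclusion: float = DEFAULT_EXCLUSION_S,
    seed: int | None = None,
    thresholds: Thresholds = REFERENCE_THRESHOLDS,
    window_response: float = DEFAULT_WINDOW_RESPONSE,
    window_baseline: float = DEFAULT_WINDOW_BASELINE,
    responses: TrialResponseSet | None = None,
) -> MeanZResult:
    """Mean of ``n_iter`` rank-sum z-values of **R** against shuffled nulls,
    plus the excited/inhibited/neutral label under ``thresholds``."""
    rs = responses if responses is not None else extract_responses(
        rec, window_response, window_baseline
    )
    ens = circular_null(
        rec, cell, n_iter=n_iter, exclusion=exclusion, seed=seed,
        window_response=window_response, window_baseline=window_baseline,
        responses=rs,
    )
    z = _ranksum_z_rows(rs.responses[cell], ens.null_responses)
    mean_z = float(z.mean())
    return MeanZResult(
        cell=cell,
        z_values=z,
        mean_z=mean_z,
        label=classify_mean_z(mean_z, thresholds),
        thresholds=thresholds,
        null_median=float(np.median(ens.null_responses)),
        n_trials=rs.n_trials,
    )


def analyze_fov(
    rec: FovRecording,
    n_iter: int = DEFAULT_N_ITER,
    exclusion: float = DEFAULT_EXCLUSION_S,
    seed: int | None = None,
    thresholds: Thresholds = REFERENCE_THRESHOLDS,
    window_response: float = DEFAULT_WINDOW_RESPONSE,
    window_baseline: float = DEFAULT_WINDOW_BASELINE,
) -> list[MeanZResult]:
    """Run the mean-z statistic on every cell of a recording.

    Cells use independent random substreams spawned from ``seed``, so results
    are reproducible and independent of analysis order.
    """
    rs = extract_responses(rec, window_response, window_baseline)
    children = np.random.SeedSequence(seed).spawn(rec.n_cells)
    out = []
    for cell in range(rec.n_cells):
        cell_seed = int(children[cell].generate_state(1)[0] % (2**31))
        out.append(
            mean_z_statistic(
                rec, cell, n_iter=n_iter, exclusion=exclusion, seed=cell_seed,
                thresholds=thresholds, responses=rs,
            )
        )
    return out


def calibrate_thresholds(sham_results: list[MeanZResult]) -> Thresholds:
    """Thresholds from sham sessions: upper = max sham mean-z, lower = min.

    By construction, re-classifying the calibration set with these thresholds
    yields exactly zero followers (labels use strict inequalities).
    """
    if len(sham_results) == 0:
        raise InvalidParameterError("need at least one sham cell to calibrate")
    mz = np.array([r.mean_z for r in sham_results])
    return Thresholds(
        upper=float(mz.max()), lower=float(mz.min()), provenance="recalibrated"
    )


# ---------------------------------------------------------------------------
# comparator criteria
# ---------------------------------------------------------------------------

def kwan_dan_followers(
    responses: TrialResponseSet, n_sem: float = 3.0
) -> np.ndarray:
    """Amplitude-threshold comparator criterion.

    A cell is deemed a follower when its mean post-stimulus epoch dF/F
    exceeds the mean of the pre-stimulus epoch dF/F by more than ``n_sem``
    standard errors of the pre-epoch values.  Epochs follow the package
    windows: pre = the 600 ms baseline window, post = the 400 ms response
    window, both expressed as dF/F relative to the cell's session baseline
    (trace median).  This is a documented interpretation of the one-line
    criterion reported for the comparator method (see docs/methods.md).
    """
    if responses.n_trials < 2:
        raise InvalidParameterError("need >= 2 trials")
    f0 = responses.f0[:, None]
    pre = responses.f_baseline / f0 - 1.0
    post = responses.f_response / f0 - 1.0
    sem_pre = pre.std(axis=1, ddof=1) / np.sqrt(responses.n_trials)
    return post.mean(axis=1) > pre.mean(axis=1) + n_sem * sem_pre


def ttest_comparator(
    responses: TrialResponseSet | np.ndarray,
    null_responses: list[np.ndarray] | np.ndarray,
) -> np.ndarray:
    """Welch two-sample t-test of real responses against pooled null responses.

    Provided for comparison only: p-value per cell, two-sided.  Degenerate
    zero-variance inputs return p = 1 by convention.
    """
    real = responses.responses if isinstance(responses, TrialResponseSet) else \
        np.atleast_2d(np.asarray(responses, dtype=float))
    p_out = np.ones(real.shape[0])
    for cell in range(real.shape[0]):
        null = np.asarray(
            null_responses[cell]
            if isinstance(null_responses, (list, tuple))
            else null_responses
        ).ravel()
        res = stats.ttest_ind(real[cell], null, equal_var=False)
        p = res.pvalue
        p_out[cell] = 1.0 if not np.isfinite(p) else float(p)
    return p_out
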