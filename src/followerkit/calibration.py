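"""Sensitivity calibration by spike insertion into mock trials.

To measure how reliably the detector finds followers of a given stimulation
efficacy, single-AP calcium transients are inserted into a chosen percentage
``p`` of mock trials on spontaneous (sham) traces, the detector is run on the
augmented data, and the fraction of cells labeled excited followers is
reported per efficacy level, together with the mean z and the mean dF/F of
"relevant" trials.  An observed mean z can then be inverted through the curve
to estimate the efficacy of a real follower.

"Relevant" trials of an excited follower are the trials whose response
exceeds the median of the pooled null responses (mirror image for inhibited
followers).  This is a documented interpretation — see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FovRecording, StimSchedule, TransientTemplate
from .exceptions import InvalidParameterError
from .follower_stats import (
    DEFAULT_EXCLUSION_S,
    DEFAULT_N_ITER,
    LABEL_EXCITED,
    LABEL_INHIBITED,
    MeanZResult,
    Thresholds,
    REFERENCE_THRESHOLDS,
    analyze_fov,
    kwan_dan_followers,
    ttest_comparator,
    circular_null,
)
from .response import TrialResponseSet, extract_responses
from .synthgen import insert_transients, make_template

__all__ = [
    "CalibrationCurve",
    "insert_mock_responses",
    "sensitivity_curve",
    "meanz_vs_efficacy",
    "efficacy_estimate",
    "dff_vs_efficacy",
    "relevant_trials",
    "DEFAULT_EFFICACY_LEVELS",
]

#: Default efficacy grid (fractions of trials receiving one extra AP).
DEFAULT_EFFICACY_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0)


@dataclass
class CalibrationCurve:
    """Detector performance as a function of stimulation efficacy ``p``."""

    efficacy_levels: np.ndarray  # fractions, ascending
    detection_fraction: np.ndarray  # fraction of cells labeled excited, per p
    mean_z_mean: np.ndarray
    mean_z_sem: np.ndarray
    dff_relevant_mean: np.ndarray  # nan where no follower was detected
    dff_relevant_sem: np.ndarray
    n_cells: int
    n_trials: int
    seed: int | None
    spikes_per_trial: int = 1
    comparators: dict = field(default_factory=dict)  # name -> detection fraction per p

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "efficacy": self.efficacy_levels,
                "detection_fraction": self.detection_fraction,
                "mean_z": self.mean_z_mean,
                "mean_z_sem": self.mean_z_sem,
                "dff_relevant": self.dff_relevant_mean,
                "dff_relevant_sem": self.dff_relevant_sem,
            }
        )
        for name, det in self.comparators.items():
            df[f"detection_{name}"] = det
        return df


def insert_mock_responses(
    trace: np.ndarray,
    mock_schedule: StimSchedule,
    template: TransientTemplate,
    p: float,
    k: int = 1,
    seed: int | np.random.Generator | None = None,
    frame_rate: float | None = None,
) -> np.ndarray:
    """Insert ``k`` stacked 1-AP kernels at the offsets of ``round(p * n)``
    randomly chosen mock trials (without replacement).  Pure function: the
    input trace is never modified."""
    trace = np.asarray(trace, dtype=float)
    rate = frame_rate if frame_rate is not None else template.frame_rate
    n_resp = int(np.ceil(mock_schedule.end * rate))
    if n_resp >= trace.size:
        raise InvalidParameterError("mock schedule does not fit the trace")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out, _ = insert_transients(trace, mock_schedule, template, rate, p, k, rng)
    return out


def relevant_trials(responses: np.ndarray, null_median: float, label: str) -> np.ndarray:
    """Boolean mask of trials that contribute to significance.

    Excited follower: responses above the pooled null median; inhibited:
    below (mirror image)."""
    if label == LABEL_INHIBITED:
        return responses < null_median
    return responses > null_median


def sensitivity_curve(
    spont_rec: FovRecording,
    efficacy_levels=DEFAULT_EFFICACY_LEVELS,
    thresholds: Thresholds = REFERENCE_THRESHOLDS,
    template: TransientTemplate | None = None,
    k: int = 1,
    n_iter: int = DEFAULT_N_ITER,
    exclusion: float = DEFAULT_EXCLUSION_S,
    seed: int | None = 0,
    comparators: tuple[str, ...] = (),
    ttest_alpha: float = 0.05,
) -> CalibrationCurve:
    """Run the detector on spike-augmented copies of spontaneous recordings.

    Parameters
    ----------
    spont_rec : FovRecording
        Spontaneous-activity (sham) recording supplying the traces; its
        schedule defines the mock trials.
    efficacy_levels : sequence of float
        Fractions of trials receiving ``k`` extra APs, ascending.
    thresholds : Thresholds
        Classification thresholds (sham-calibrated for the reference curve).
    comparators : subset of {"kwandan", "ttest"}
        Also run the comparator criteria on the same augmented data; their
        detection fractions land in ``CalibrationCurve.comparators``.
    """
    levels = np.asarray(sorted(efficacy_levels), dtype=float)
    if ((levels < 0) | (levels > 1)).any():
        raise InvalidParameterError("efficacy levels must lie in [0, 1]")
    if template is None:
        template = make_template(0.06, 0.4, spont_rec.frame_rate)
    root = np.random.SeedSequence(seed)
    level_seeds = root.spawn(levels.size)

    det = np.zeros(levels.size)
    mz_mean = np.zeros(levels.size)
    mz_sem = np.zeros(levels.size)
    dff_mean = np.full(levels.size, np.nan)
    dff_sem = np.full(levels.size, np.nan)
    comp = {name: np.zeros(levels.size) for name in comparators}

    for i, p in enumerate(levels):
        ss = level_seeds[i]
        rng = np.random.default_rng(ss)
        aug = np.empty_like(spont_rec.traces)
        for cell in range(spont_rec.n_cells):
            aug[cell] = insert_mock_responses(
                spont_rec.traces[cell], spont_rec.schedule, template, p, k,
                seed=rng, frame_rate=spont_rec.frame_rate,
            )
        rec = spont_rec.replace(traces=aug, ground_truth=None)
        fov_seed = int(ss.generate_state(1)[0] % (2**31))
        results = analyze_fov(
            rec, n_iter=n_iter, exclusion=exclusion, seed=fov_seed,
            thresholds=thresholds,
        )
        mz = np.array([r.mean_z for r in results])
        excited = np.array([r.label == LABEL_EXCITED for r in results])
        det[i] = excited.mean()
        mz_mean[i] = mz.mean()
        mz_sem[i] = mz.std(ddof=1) / np.sqrt(mz.size) if mz.size > 1 else 0.0
        d = dff_vs_efficacy(extract_responses(rec), results)
        dff_mean[i], dff_sem[i] = d

        if comparators:
            rs = extract_responses(rec)
            if "kwandan" in comp:
                comp["kwandan"][i] = kwan_dan_followers(rs).mean()
            if "ttest" in comp:
                pvals = np.empty(rec.n_cells)
                for cell in range(rec.n_cells):
                    ens = circular_null(
                        rec, cell, n_iter=n_iter, exclusion=exclusion,
                        seed=int(ss.generate_state(2)[1] % (2**31)) + cell,
                        responses=rs,
                    )
                    pvals[cell] = ttest_comparator(
                        rs.responses[cell][None, :], [ens.null_responses]
                    )[0]
                mean_shift = rs.responses.mean(axis=1)
                comp["ttest"][i] = ((pvals < ttest_alpha) & (mean_shift > 0)).mean()

    return CalibrationCurve(
        efficacy_levels=levels,
        detection_fraction=det,
        mean_z_mean=mz_mean,
        mean_z_sem=mz_sem,
        dff_relevant_mean=dff_mean,
        dff_relevant_sem=dff_sem,
        n_cells=spont_rec.n_cells,
        n_trials=spont_rec.schedule.n_trials,
        seed=seed,
        spikes_per_trial=k,
        comparators=comp,
    )


def dff_vs_efficacy(
    rs: TrialResponseSet, results: list[MeanZResult]
) -> tuple[float, float]:
    """Mean (and sem over cells) dF/F of relevant trials across detected
    followers.  Returns (nan, nan) when no follower was detected."""
    per_cell = []
    for r in results:
        if r.label not in (LABEL_EXCITED, LABEL_INHIBITED):
            continue
        mask = relevant_trials(rs.responses[r.cell], r.null_median, r.label)
        if mask.any():
            per_cell.append(rs.responses[r.cell][mask].mean())
    if not per_cell:
        return (np.nan, np.nan)
    arr = np.asarray(per_cell)
    sem = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
    return (float(arr.mean()), float(sem))


def meanz_vs_efficacy(curve: CalibrationCurve) -> pd.DataFrame:
    """Mean z (mean +/- sem) as a function of efficacy, as a tidy frame."""
    return pd.DataFrame(
        {
            "efficacy": curve.efficacy_levels,
            "mean_z": curve.mean_z_mean,
            "mean_z_sem": curve.mean_z_sem,
        }
    )


def efficacy_estimate(observed_mean_z: float, curve: CalibrationCurve) -> float:
    """Estimate a follower's stimulation efficacy by inverse interpolation of
    the mean-z-vs-efficacy curve.

    Values outside the simulated range are clamped to the nearest end of the
    curve, with a warning.  A mean z of ~0 maps to efficacy ~0 because the
    curve is anchored at (0, 0) (no insertions shift no responses).
    """
    levels = np.concatenate([[0.0], curve.efficacy_levels]) \
        if curve.efficacy_levels[0] > 0 else curve.efficacy_levels
    mz = np.concatenate([[0.0], curve.mean_z_mean]) \
        if curve.efficacy_levels[0] > 0 else curve.mean_z_mean
    order = np.argsort(mz)
    mz_sorted, lv_sorted = mz[order], levels[order]
    if observed_mean_z < mz_sorted[0] or observed_mean_z > mz_sorted[-1]:
        warnings.warn(
            f"observed mean z {observed_mean_z:g} lies outside the simulated "
            f"range [{mz_sorted[0]:g}, {mz_sorted[-1]:g}]; clamping",
            stacklevel=2,
        )
    return float(np.interp(observed_mean_z, mz_sorted, lv_sorted))
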