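"""FOV- and study-level population analyses.

Beyond single-cell follower calls, single-neuron stimulation can shift the
aggregate activity of the imaged population.  The per-FOV *z-median* — the
median of all cells' mean-z values — captures this distributed effect: it is
insensitive to the few strong followers but reflects a weak shift spread over
many cells.  Study-level helpers tally effective stimulators (patched cells
with at least one follower), percent followers, polarity breakdowns, group
contrasts (chi-square on effective-stimulator counts, rank-sum on z-medians)
and covariate correlation checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import FovRecording
from .exceptions import InvalidParameterError
from .follower_stats import LABEL_EXCITED, LABEL_INHIBITED, MeanZResult

__all__ = [
    "PopulationSummary",
    "fov_zmedian",
    "summarize_fov",
    "compare_zmedians",
    "chi2_2x2",
    "tally_study",
    "radius_filter",
    "covariate_correlation",
    "display_percent",
]


@dataclass
class PopulationSummary:
    """Per-FOV population summary."""

    z_median: float
    group: str  # condition label, e.g. "sham" or a stimulation condition
    n_cells: int
    n_excited: int
    n_inhibited: int

    @property
    def n_followers(self) -> int:
        return self.n_excited + self.n_inhibited

    @property
    def percent_followers(self) -> float:
        return 100.0 * self.n_followers / self.n_cells

    @property
    def effective_stimulator(self) -> bool:
        return self.n_followers > 0


def fov_zmedian(
    results: list[MeanZResult], statistic: str = "median"
) -> float:
    """Population z-median of one FOV: median of all cells' mean-z values.

    ``statistic="mean"`` is available as an option; the median is primary
    because it is robust to the few strong followers in a FOV.
    """
    if len(results) == 0:
        raise InvalidParameterError("need at least one cell")
    mz = np.array([r.mean_z for r in results])
    if statistic == "median":
        return float(np.median(mz))
    if statistic == "mean":
        return float(mz.mean())
    raise InvalidParameterError(f"unknown statistic {statistic!r}")


def summarize_fov(results: list[MeanZResult], group: str) -> PopulationSummary:
    labels = [r.label for r in results]
    return PopulationSummary(
        z_median=fov_zmedian(results),
        group=group,
        n_cells=len(results),
        n_excited=sum(l == LABEL_EXCITED for l in labels),
        n_inhibited=sum(l == LABEL_INHIBITED for l in labels),
    )


def compare_zmedians(
    sham_medians: np.ndarray, stim_medians: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between FOV-level z-medians.

    Returns ``(statistic, p)``.
    """
    sham = np.asarray(sham_medians, dtype=float)
    stim = np.asarray(stim_medians, dtype=float)
    if sham.size == 0 or stim.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    res = stats.ranksums(stim, sham)
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(
    successes_1: int, n_1: int, successes_2: int, n_2: int
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    The uncorrected form is used throughout (e.g. comparing 4/19 vs 5/14
    effective stimulators gives p ~ 0.35; the Yates-corrected value would be
    ~0.59).  Raises on a zero margin (all successes or all failures).
    """
    for s, n in ((successes_1, n_1), (successes_2, n_2)):
        if not (0 <= s <= n):
            raise InvalidParameterError("need n >= successes >= 0")
    table = np.array(
        [[successes_1, n_1 - successes_1], [successes_2, n_2 - successes_2]],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InvalidParameterError("chi-square undefined: zero margin in the table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def display_percent(count: int, total: int) -> str:
    """Percentage formatted at the display precision used for follower
    tallies: two significant figures below 1%, one decimal otherwise
    (4/796 -> "0.5", 8/832 -> "0.96", 4/19 -> "21.1")."""
    pct = 100.0 * count / total
    if pct == 0:
        return "0"
    if pct < 1.0:
        return f"{pct:.2g}"
    return f"{pct:.1f}"


def tally_study(summaries: list[PopulationSummary]) -> pd.DataFrame:
    """Pooled per-condition study table.

    One row per condition group: FOV count, cell count, follower counts and
    polarity, pooled percent followers (full precision plus the display
    string), and effective-stimulator tallies.
    """
    if len(summaries) == 0:
        raise InvalidParameterError("need at least one FOV summary")
    rows = {}
    for s in summaries:
        r = rows.setdefault(
            s.group,
            {"n_fovs": 0, "n_cells": 0, "n_excited": 0, "n_inhibited": 0,
             "n_effective_stimulators": 0},
        )
        r["n_fovs"] += 1
        r["n_cells"] += s.n_cells
        r["n_excited"] += s.n_excited
        r["n_inhibited"] += s.n_inhibited
        r["n_effective_stimulators"] += int(s.effective_stimulator)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "group"
    df["n_followers"] = df["n_excited"] + df["n_inhibited"]
    df["percent_followers"] = 100.0 * df["n_followers"] / df["n_cells"]
    df["percent_followers_display"] = [
        display_percent(f, c) for f, c in zip(df["n_followers"], df["n_cells"])
    ]
    df["fraction_effective_stimulators"] = (
        df["n_effective_stimulators"] / df["n_fovs"]
    )
    return df


def radius_filter(
    rec: FovRecording, max_distance: float = 150.0
) -> tuple[FovRecording, bool]:
    """Standardize FOV size: drop cells farther than ``max_distance`` (um)
    from the patched cell.

    Returns ``(filtered recording, radius_ok)`` where ``radius_ok`` is False
    for FOVs whose radius (largest cell distance from the patched cell) is
    below ``max_distance`` — such FOVs should be excluded from standardized
    comparisons.
    """
    if rec.cell_positions is None or rec.patched_cell is None:
        raise InvalidParameterError(
            "radius_filter needs cell_positions and patched_cell"
        )
    pos = np.asarray(rec.cell_positions, dtype=float)
    d = np.linalg.norm(pos - pos[rec.patched_cell], axis=1)
    keep = d <= max_distance
    radius_ok = bool(d.max() >= max_distance) if np.isfinite(max_distance) else True
    kept_idx = np.nonzero(keep)[0]
    gt = None
    if rec.ground_truth is not None:
        gt = {
            "efficacy": rec.ground_truth["efficacy"][keep],
            "spikes": rec.ground_truth["spikes"][keep],
            "inserted_trials": [
                rec.ground_truth["inserted_trials"][i] for i in kept_idx
            ],
        }
    new_patched = None
    if rec.patched_cell is not None and keep[rec.patched_cell]:
        new_patched = int(np.searchsorted(kept_idx, rec.patched_cell))
    return (
        rec.replace(
            traces=rec.traces[keep],
            cell_positions=pos[keep],
            interneuron_flags=(
                rec.interneuron_flags[keep]
                if rec.interneuron_flags is not None
                else None
            ),
            patched_cell=new_patched,
            ground_truth=gt,
        ),
        radius_ok,
    )


def covariate_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p between a covariate and responses.

    Used for membrane-potential-vs-response, baseline-vs-response and
    distance-vs-response checks.  Raises on zero variance in either input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidParameterError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidParameterError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
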