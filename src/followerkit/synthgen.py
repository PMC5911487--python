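"""Synthetic OGB-like recording generator.

Produces spontaneous-activity traces, stimulation schedules, ground-truth
follower cells at a chosen efficacy, and sham sessions, so that every
downstream stage of the pipeline can be exercised without real data.

The generative model (see docs/methods.md for rationale and calibration):

* spontaneous activity: Poisson-timed firing events per cell, each carrying a
  geometric number of spikes (support >= 1), summed linearly as scaled copies
  of the single-AP transient template;
* measurement noise: i.i.d. Gaussian per frame, optional slow sinusoidal
  drift (off by default);
* evoked activity: for a "follower" cell with efficacy ``p`` and spike count
  ``k``, a randomly chosen ``round(p * n_trials)`` subset of trials (sampled
  without replacement) receives ``k`` stacked template kernels starting at
  the first frame at or after the trial's stimulus offset.
"""

from __future__ import annotations

import numpy as np

from .data import FovRecording, StimSchedule, SynthConfig, TransientTemplate
from .exceptions import InvalidParameterError

__all__ = [
    "make_template",
    "make_schedule",
    "simulate_spont_trace",
    "simulate_fov",
    "simulate_study",
]


def make_template(
    peak_amplitude: float,
    fwhm: float,
    frame_rate: float,
    rise_time: float = 0.0,
    cutoff: float = 1e-10,
) -> TransientTemplate:
    """Build a fast-rise / exponential-decay single-AP calcium kernel.

    Parameters
    ----------
    peak_amplitude : float
        Peak dF/F fraction of the transient (> 0).
    fwhm : float
        Target full width at half maximum in seconds (> 0).  For an
        instantaneous rise, a decay constant ``tau = fwhm / ln 2`` yields a
        measured FWHM equal to ``fwhm``.
    frame_rate : float
        Sampling rate in Hz (> 0).
    rise_time : float, optional
        Exponential rise time constant in seconds.  The OGB rise is faster
        than one frame period at 5-15 Hz, so the default is an instantaneous
        rise.
    cutoff : float, optional
        Relative amplitude at which the decaying tail is truncated.

    Returns
    -------
    TransientTemplate
        Kernel sampled at ``frame_rate``, rescaled so its maximum sample
        equals ``peak_amplitude`` exactly.
    """
    if peak_amplitude <= 0 or fwhm <= 0 or frame_rate <= 0:
        raise InvalidParameterError(
            "peak_amplitude, fwhm and frame_rate must all be positive"
        )
    if rise_time < 0:
        raise InvalidParameterError("rise_time must be >= 0")
    tau_d = fwhm / np.log(2.0)
    dt = 1.0 / frame_rate
    t_end = tau_d * np.log(1.0 / cutoff) + 2.0 * rise_time
    t = np.arange(0.0, t_end, dt)
    shape = np.exp(-t / tau_d)
    if rise_time > 0:
        shape = shape * (1.0 - np.exp(-(t + dt) / rise_time))
    kernel = peak_amplitude * shape / shape.max()
    return TransientTemplate(
        kernel=kernel,
        peak_amplitude=peak_amplitude,
        fwhm=fwhm,
        rise_time=rise_time,
        frame_rate=frame_rate,
    )


def make_schedule(
    n_trials: int = 190,
    pulse_s: float = 0.5,
    gap_s: float = 2.5,
    start_s: float = 2.0,
) -> StimSchedule:
    """Regular stimulation schedule: ``n_trials`` pulses of ``pulse_s`` seconds
    separated by ``gap_s`` (>= 2.5 s so transients can return to baseline)."""
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    if pulse_s <= 0 or gap_s < 0 or start_s < 0:
        raise InvalidParameterError("pulse_s must be > 0 and gap_s/start_s >= 0")
    onsets = start_s + np.arange(n_trials) * (pulse_s + gap_s)
    return StimSchedule(onsets=onsets, offsets=onsets + pulse_s)


def _nearest_frame(t: float, frame_rate: float) -> int:
    return int(round(t * frame_rate))


def _frame_at_or_after(t: float, frame_rate: float) -> int:
    return int(np.ceil(t * frame_rate - 1e-9))


def _add_kernel(trace: np.ndarray, start: int, kernel: np.ndarray, scale: float = 1.0):
    """Add ``scale * kernel`` to ``trace`` in place, clipped at the trace end."""
    if start >= trace.size:
        return
    start = max(start, 0)
    m = min(kernel.size, trace.size - start)
    trace[start : start + m] += scale * kernel[:m]


def simulate_spont_trace(
    config: SynthConfig,
    rng: np.random.Generator | int | None = None,
    n_frames: int | None = None,
) -> np.ndarray:
    """Simulate one cell's spontaneous dF/F trace (zero baseline).

    Events occur at Poisson-distributed times with rate
    ``config.spont_event_rate``; each carries a geometric number of spikes
    with mean ``config.spont_spike_mean`` and adds that multiple of the
    single-AP kernel at the nearest frame (linear spike-to-fluorescence
    summation).  I.i.d. Gaussian noise of sd ``config.noise_sd`` is added
    per frame.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    if n_frames is None:
        if config.duration is None:
            raise InvalidParameterError(
                "provide n_frames or set config.duration to simulate a bare trace"
            )
        n_frames = int(round(config.duration * config.frame_rate))
    duration = n_frames / config.frame_rate
    template = make_template(config.peak_amplitude, config.fwhm, config.frame_rate)
    trace = np.zeros(n_frames)

    n_events = rng.poisson(config.spont_event_rate * duration)
    if n_events > 0:
        times = np.sort(rng.uniform(0.0, duration, size=n_events))
        if config.spont_spike_mean > 1.0:
            counts = rng.geometric(1.0 / config.spont_spike_mean, size=n_events)
        else:
            counts = np.ones(n_events, dtype=int)
        for t, c in zip(times, counts):
            _add_kernel(trace, _nearest_frame(t, config.frame_rate), template.kernel, c)
    if config.drift_amplitude > 0:
        t = np.arange(n_frames) / config.frame_rate
        phase = rng.uniform(0, 2 * np.pi)
        trace += config.drift_amplitude * np.sin(
            2 * np.pi * t / config.drift_period + phase
        )
    if config.noise_sd > 0:
        trace += rng.normal(0.0, config.noise_sd, size=n_frames)
    return trace


def _insertion_count(p: float, n_trials: int) -> int:
    # round half up, so p = 0.5 with an odd trial count is deterministic
    return int(np.floor(p * n_trials + 0.5))


def insert_transients(
    trace: np.ndarray,
    schedule: StimSchedule,
    template: TransientTemplate,
    frame_rate: float,
    p: float,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Insert ``k`` stacked 1-AP kernels at the offsets of a random fraction
    ``p`` of trials (without replacement).  Pure: returns a new trace plus the
    sorted indices of the chosen trials."""
    if not (0.0 <= p <= 1.0):
        raise InvalidParameterError("efficacy p must lie in [0, 1]")
    if p > 0 and k < 1:
        raise InvalidParameterError("spike count k must be >= 1 when p > 0")
    out = trace.copy()
    n = schedule.n_trials
    m = _insertion_count(p, n)
    chosen = np.sort(rng.choice(n, size=m, replace=False)) if m > 0 else np.empty(0, int)
    for t_idx in chosen:
        start = _frame_at_or_after(schedule.offsets[t_idx], frame_rate)
        _add_kernel(out, start, template.kernel, float(k))
    return out, chosen


def simulate_fov(
    config: SynthConfig,
    schedule: StimSchedule,
    follower_spec: np.ndarray | dict | None = None,
    seed: int | None = None,
    condition_label: str | None = None,
    patched_cell: int | None = None,
    with_positions: bool = False,
) -> FovRecording:
    """Simulate one field of view.

    Parameters
    ----------
    follower_spec : array-like, dict, or None
        Per-cell ``(efficacy p, spikes k)``: either an ``(n_cells, 2)``
        array, a mapping ``{cell_index: (p, k)}`` (unlisted cells get
        ``p = 0``), or ``None`` for a sham session (all ``p = 0``).
    seed : int, optional
        Overrides ``config.seed``.  Cells use independent substreams spawned
        from this seed, so per-cell traces are reproducible.
    with_positions : bool
        Also draw cell positions uniformly in a 300 um square around a
        centrally patched cell (for radius-filter analyses).

    The recording's ``ground_truth`` holds ``efficacy``, ``spikes`` and the
    per-cell inserted trial indices.
    """
    spec = np.zeros((config.n_cells, 2))
    spec[:, 1] = 1.0
    if follower_spec is not None:
        if isinstance(follower_spec, dict):
            for cell, (p, k) in follower_spec.items():
                spec[cell] = (p, k)
        else:
            spec = np.asarray(follower_spec, dtype=float)
            if spec.shape != (config.n_cells, 2):
                raise InvalidParameterError(
                    "follower_spec must provide (p, k) for every cell"
                )
    if (spec[:, 0] < 0).any() or (spec[:, 0] > 1).any():
        raise InvalidParameterError("efficacies must lie in [0, 1]")
    if ((spec[:, 0] > 0) & (spec[:, 1] < 1)).any():
        raise InvalidParameterError("cells with p > 0 need spike count k >= 1")

    duration = config.duration
    if duration is None:
        duration = schedule.end + 1.0
    n_frames = int(round(duration * config.frame_rate))
    last_resp_frame = _frame_at_or_after(schedule.end, config.frame_rate) + max(
        1, int(round(0.4 * config.frame_rate))
    )
    if last_resp_frame > n_frames or schedule.onsets[0] < 0.6:
        raise InvalidParameterError(
            "schedule does not fit the trace with full baseline/response windows"
        )

    template = make_template(config.peak_amplitude, config.fwhm, config.frame_rate)
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    children = root.spawn(config.n_cells + 1)
    traces = np.empty((config.n_cells, n_frames))
    inserted: list[np.ndarray] = []
    for cell in range(config.n_cells):
        rng = np.random.default_rng(children[cell])
        dff = simulate_spont_trace(config, rng=rng, n_frames=n_frames)
        p, k = spec[cell]
        dff, chosen = insert_transients(
            dff, schedule, template, config.frame_rate, float(p), int(k), rng
        )
        traces[cell] = 1.0 + dff
        inserted.append(chosen)

    positions = None
    if with_positions:
        rng = np.random.default_rng(children[-1])
        positions = rng.uniform(-150.0, 150.0, size=(config.n_cells, 2))
        if patched_cell is None:
            patched_cell = 0
        positions[patched_cell] = 0.0

    if condition_label is None:
        condition_label = "sham" if not (spec[:, 0] > 0).any() else "L2/3-anesthetized"
    return FovRecording(
        traces=traces,
        frame_rate=config.frame_rate,
        schedule=schedule,
        patched_cell=patched_cell,
        cell_positions=positions,
        condition_label=condition_label,
        ground_truth={
            "efficacy": spec[:, 0].copy(),
            "spikes": spec[:, 1].copy(),
            "inserted_trials": inserted,
        },
    )


def simulate_study(
    n_sham_fovs: int,
    n_stim_fovs: int,
    config: SynthConfig | None = None,
    seed: int = 0,
    schedule: StimSchedule | None = None,
    stim_efficacy: float = 0.2,
    stim_spikes: int = 1,
    stim_cell_fraction: float = 0.5,
    stim_label: str = "L2/3-anesthetized",
) -> tuple[list[FovRecording], list[FovRecording]]:
    """Simulate a full study: sham FOVs plus stimulation FOVs carrying a
    distributed effect (a fraction of cells receives 1-AP insertions at the
    given efficacy).

    With the defaults (56 cells per FOV), 19 sham FOVs yield 1,064 sham
    cells, mirroring the scale used to calibrate detection thresholds.
    Deterministic given ``seed``: FOVs use spawned independent substreams.
    """
    if n_sham_fovs < 0 or n_stim_fovs < 0 or n_sham_fovs + n_stim_fovs < 1:
        raise InvalidParameterError("need at least one FOV")
    config = config or SynthConfig()
    schedule = schedule or make_schedule()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sham_fovs + n_stim_fovs)
    sham, stim = [], []
    for i in range(n_sham_fovs):
        fov_seed = int(children[i].generate_state(1)[0] % (2**31))
        sham.append(
            simulate_fov(config, schedule, None, seed=fov_seed, condition_label="sham")
        )
    for i in range(n_stim_fovs):
        ss = children[n_sham_fovs + i]
        fov_seed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(ss)
        n_affected = int(round(stim_cell_fraction * config.n_cells))
        affected = rng.choice(config.n_cells, size=n_affected, replace=False)
        spec = {int(c): (stim_efficacy, stim_spikes) for c in affected}
        stim.append(
            simulate_fov(
                config, schedule, spec, seed=fov_seed, condition_label=stim_label
            )
        )
    return sham, stim
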