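"""Synthetic photon traces: Gillespie trajectories + stochastic detection.

The generator matrix fully specifies the jump process: holding times are
exponential with the superstate's escape rate and the embedded jump chain is
categorical with probabilities rate / escape-rate.  Every realized radiative
transition emits a photon with an intended channel; the measurement layer
then routes each emission through the crosstalk/efficiency matrix (or drops
it), jitters its timestamp by an IRF draw, discards photons falling in their
own channel's dead window, and quantizes times to the acquisition grid.

Draw order per event is fixed (jump target, holding time; then per emission:
routing, IRF delay) so tests can replay sub-sequences from a seeded RNG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import DetectorModel
from .likelihood import PhotonTrace, PulsedTrace
from .statespace import BackgroundSpec, CompositeGenerator, steady_state

__all__ = [
    "TrajectorySample",
    "gillespie_trajectory",
    "apply_detectors",
    "simulate_background",
    "simulate_trace",
]


@dataclass
class TrajectorySample:
    """One realized superstate trajectory with its emission record."""

    states: np.ndarray  # visited superstates b_1..b_N
    holding_times: np.ndarray  # time spent in each, > 0
    emission_times: np.ndarray  # absolute times of radiative transitions
    emission_channels: np.ndarray  # intended channel per emission
    t_start: float
    t_end: float
    truncated: bool = False  # absorbing state reached before the stop rule


def gillespie_trajectory(
    gen: CompositeGenerator,
    rho_start: np.ndarray | None = None,
    t_max: float | None = None,
    max_emissions: int | None = None,
    rng: np.random.Generator | None = None,
    t_start: float = 0.0,
) -> TrajectorySample:
    """Simulate the superstate jump process until a stop rule fires.

    Exactly one of ``t_max`` (total simulated time) or ``max_emissions``
    (number of radiative transitions) must be given.  ``rho_start`` defaults
    to the steady state of ``gen``.
    """
    if (t_max is None) == (max_emissions is None):
        raise ValueError("specify exactly one stop rule: t_max or max_emissions")
    rng = np.random.default_rng() if rng is None else rng
    g = gen.matrix
    m = g.shape[0]
    off = np.where(np.eye(m, dtype=bool), 0.0, g)
    escape = off.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_probs = np.where(escape[:, None] > 0, off / escape[:, None], 0.0)
    jump_cdf = np.cumsum(jump_probs, axis=1)
    # intended channel per (from, to) transition, -1 = nonradiative
    channel_of = np.full((m, m), -1, dtype=np.int64)
    for c in range(gen.n_channels):
        channel_of[gen.radiative_masks[c]] = c

    if rho_start is None:
        rho_start = steady_state(gen)
    state = int(rng.choice(m, p=np.asarray(rho_start) / np.sum(rho_start)))

    states, holds, em_t, em_c = [], [], [], []
    t = t_start
    truncated = False
    while True:
        if t_max is not None and t - t_start >= t_max:
            break
        if max_emissions is not None and len(em_t) >= max_emissions:
            break
        if escape[state] <= 0:
            truncated = True
            break
        nxt = int(np.searchsorted(jump_cdf[state], rng.random()))
        hold = rng.exponential(1.0 / escape[state])
        states.append(state)
        holds.append(hold)
        t += hold
        if t_max is not None and t - t_start > t_max:
            t = t_start + t_max
            break
        c = channel_of[state, nxt]
        if c >= 0:
            em_t.append(t)
            em_c.append(c)
        state = nxt
    return TrajectorySample(
        states=np.asarray(states, dtype=np.int64),
        holding_times=np.asarray(holds, dtype=float),
        emission_times=np.asarray(em_t, dtype=float),
        emission_channels=np.asarray(em_c, dtype=np.int64),
        t_start=t_start,
        t_end=t,
        truncated=truncated,
    )


def simulate_background(
    bg: BackgroundSpec,
    duration: float,
    rng: np.random.Generator | None = None,
    t_start: float = 0.0,
):
    """Poisson background photons per channel over ``duration``.

    Returns (times, channels), merged and time-sorted.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng() if rng is None else rng
    times, chans = [], []
    for c, rate in enumerate(bg.rates):
        if rate <= 0:
            continue
        n = rng.poisson(rate * duration)
        times.append(t_start + rng.random(n) * duration)
        chans.append(np.full(n, c, dtype=np.int64))
    if not times:
        return np.empty(0), np.empty(0, dtype=np.int64)
    t = np.concatenate(times)
    c = np.concatenate(chans)
    order = np.argsort(t, kind="stable")
    return t[order], c[order]


def apply_detectors(
    emission_times: np.ndarray,
    emission_channels: np.ndarray,
    det: DetectorModel,
    rng: np.random.Generator | None = None,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> PhotonTrace:
    """Push emissions through routing, IRF jitter, dead time and quantization.

    Each emission intended for channel j is registered in channel i with
    probability phi[j, i] (undetected otherwise), its timestamp shifted by an
    IRF draw, then photons arriving during their own registration channel's
    dead window are discarded.  Lost-to-inefficiency photons do not trigger
    dead time; registered photons do.  Ties after quantization to the
    acquisition grid are broken by one-grid-quantum offsets.
    """
    rng = np.random.default_rng() if rng is None else rng
    emission_times = np.asarray(emission_times, dtype=float)
    emission_channels = np.asarray(emission_channels, dtype=np.int64)
    reg_t, reg_c = [], []
    for t, j in zip(emission_times, emission_channels):
        r = rng.random()
        cdf = np.cumsum(det.routing[j])
        i = int(np.searchsorted(cdf, r))
        if i >= det.n_channels:
            continue  # undetected
        delay = (
            det.irf_delays[rng.choice(det.irf_delays.size, p=det.irf_weights)]
            if not det.is_delta_irf
            else 0.0
        )
        reg_t.append(t + delay)
        reg_c.append(i)
    t = np.asarray(reg_t)
    c = np.asarray(reg_c, dtype=np.int64)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    # dead-time filtering per registration channel
    keep = np.ones(t.size, dtype=bool)
    last_seen = np.full(det.n_channels, -np.inf)
    for k in range(t.size):
        ch = c[k]
        if t[k] - last_seen[ch] < det.dead_times[ch]:
            keep[k] = False
        else:
            last_seen[ch] = t[k]
    t, c = t[keep], c[keep]
    if det.resolution > 0:
        t = np.round(t / det.resolution) * det.resolution
    # enforce strict monotonicity with grid-quantum (or tiny) offsets
    quantum = det.resolution if det.resolution > 0 else 1e-12
    for k in range(1, t.size):
        if t[k] <= t[k - 1]:
            t[k] = t[k - 1] + quantum
    if t_end is None:
        t_end = float(t[-1]) if t.size else t_start
    inside = (t > t_start) & (t <= t_end)
    return PhotonTrace(times=t[inside], channels=c[inside], t_start=t_start, t_end=t_end)


def simulate_trace(
    gen: CompositeGenerator,
    det: DetectorModel | None = None,
    background: BackgroundSpec | None = None,
    n_photons: int | None = None,
    duration: float | None = None,
    rho_start: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> PhotonTrace:
    """End-to-end synthetic trace: Gillespie + background + detector layer.

    Stop rule is either ``duration`` (experiment length) or ``n_photons``
    (registered, post-detector photons — the photon-budget convention).
    """
    if (n_photons is None) == (duration is None):
        raise ValueError("specify exactly one stop rule: n_photons or duration")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    det = DetectorModel.ideal(gen.n_channels) if det is None else det
    if rho_start is None:
        rho_start = steady_state(gen)

    if duration is not None:
        traj = gillespie_trajectory(gen, rho_start, t_max=duration, rng=rng)
        em_t, em_c = traj.emission_times, traj.emission_channels
        if background is not None:
            bt, bc = simulate_background(background, duration, rng)
            em_t = np.concatenate([em_t, bt])
            em_c = np.concatenate([em_c, bc])
            order = np.argsort(em_t, kind="stable")
            em_t, em_c = em_t[order], em_c[order]
        return apply_detectors(em_t, em_c, det, rng, t_start=0.0, t_end=duration)

    # photon-count stop rule: simulate in growing chunks until K registered
    detected_fraction = max(det.routing.sum(axis=1).min(), 1e-3)
    target = n_photons
    chunk = int(np.ceil(1.5 * target / detected_fraction)) + 16
    traj = gillespie_trajectory(gen, rho_start, max_emissions=chunk, rng=rng)
    em_t, em_c = traj.emission_times, traj.emission_channels
    horizon = traj.t_end
    if background is not None and horizon > 0:
        bt, bc = simulate_background(background, horizon, rng)
        em_t = np.concatenate([em_t, bt])
        em_c = np.concatenate([em_c, bc])
        order = np.argsort(em_t, kind="stable")
        em_t, em_c = em_t[order], em_c[order]
    trace = apply_detectors(em_t, em_c, det, rng, t_start=0.0, t_end=None)
    while trace.n_photons < target and not traj.truncated:
        more = gillespie_trajectory(
            gen, rho_start, max_emissions=chunk, rng=rng, t_start=horizon
        )
        em_t = more.emission_times
        em_c = more.emission_channels
        if background is not None and more.t_end > horizon:
            bt, bc = simulate_background(background, more.t_end - horizon, rng, t_start=horizon)
            em_t = np.concatenate([em_t, bt])
            em_c = np.concatenate([em_c, bc])
            order = np.argsort(em_t, kind="stable")
            em_t, em_c = em_t[order], em_c[order]
        extra = apply_detectors(em_t, em_c, det, rng, t_start=horizon, t_end=None)
        horizon = more.t_end
        traj = more
        trace = PhotonTrace(
            times=np.concatenate([trace.times, extra.times]),
            channels=np.concatenate([trace.channels, extra.channels]),
            t_start=0.0,
            t_end=max(trace.t_end, extra.t_end),
        )
    if trace.n_photons > target:
        t = trace.times[:target]
        c = trace.channels[:target]
        trace = PhotonTrace(times=t, channels=c, t_start=0.0, t_end=float(t[-1]))
    return trace


def simulate_pulsed_trace(
    gen: CompositeGenerator,
    period: float,
    pulse_width: float,
    n_pulses: int,
    det: DetectorModel | None = None,
    rho_start: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> PulsedTrace:
    """Pulsed-illumination trace via piecewise Gillespie simulation.

    Within each pulse the full generator applies; during the dark stretch the
    laser-driven rates are off.  At most the first registered photon per
    interpulse period is kept (single-photon-per-pulse electronics).
    """
    from .statespace import dark_generator

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    det = DetectorModel.ideal(gen.n_channels) if det is None else det
    gd = dark_generator(gen)
    if rho_start is None:
        rho_start = steady_state(gen)
    m = gen.matrix.shape[0]

    def step(gmat, masks, state, t, t_stop):
        """Advance to t_stop under gmat; emit (new_state, time, emissions)."""
        out = []
        while True:
            esc = -gmat[state, state]
            if esc <= 0:
                return state, t_stop, out
            dt = rng.exponential(1.0 / esc)
            if t + dt > t_stop:
                return state, t_stop, out
            t += dt
            probs = np.where(np.eye(m, dtype=bool)[state], 0.0, gmat[state]) / esc
            nxt = int(rng.choice(m, p=probs))
            for c in range(masks.shape[0]):
                if masks[c, state, nxt]:
                    out.append((t, c))
            state = nxt

    state = int(rng.choice(m, p=np.asarray(rho_start) / np.sum(rho_start)))
    idx, mus, chans = [], [], []
    for n in range(n_pulses):
        t0 = n * period
        emissions = []
        state, _, em = step(gen.matrix, gen.radiative_masks, state, t0, t0 + pulse_width)
        emissions += em
        state, _, em = step(gd.matrix, gd.radiative_masks, state, t0 + pulse_width, t0 + period)
        emissions += em
        for t, j in emissions:
            r = rng.random()
            cdf = np.cumsum(det.routing[j])
            i = int(np.searchsorted(cdf, r))
            if i >= det.n_channels:
                continue
            delay = (
                det.irf_delays[rng.choice(det.irf_delays.size, p=det.irf_weights)]
                if not det.is_delta_irf
                else 0.0
            )
            mu = min(t + delay - t0, np.nextafter(period, 0))
            idx.append(n)
            mus.append(mu)
            chans.append(i)
            break  # one photon per pulse
    return PulsedTrace(
        period=period,
        pulse_width=pulse_width,
        n_pulses=n_pulses,
        pulse_indices=np.asarray(idx, dtype=np.int64),
        microtimes=np.asarray(mus, dtype=float),
        channels=np.asarray(chans, dtype=np.int64),
    )
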