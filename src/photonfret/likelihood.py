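"""Photon-trace log-likelihoods under continuous and pulsed illumination.

The likelihood of a photon-arrival record alternates interphoton propagators
exp(dt * G_non) — where G_non is the generator masked by the no-detection
matrix — with radiative jump matrices G_rad for each photon's registration
channel, starting from rho_start and closing with the summation vector.  The
epsilon^K prefactor carried by the K radiative factors is always dropped;
reported values are log(L / epsilon^K).  Everything runs through a
normalize-and-accumulate-log recursion so underflow cannot occur.

The fast path diagonalizes G_non once per evaluation and runs the recursion
in its eigenbasis (a numba kernel); a dense scaling-and-squaring path backs
it up when the eigendecomposition is unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import gammaln

from ._filter import scan_dense, scan_eigenbasis
from .detection import (
    DetectorModel,
    nonradiative_detection_matrix,
    radiative_detection_matrix,
)
from .statespace import CompositeGenerator, SystemKinetics, steady_state

__all__ = [
    "PhotonTrace",
    "PulsedTrace",
    "BinnedTrace",
    "PoissonBinModel",
    "log_likelihood_continuous",
    "log_likelihood_dead_time",
    "log_likelihood_irf",
    "log_likelihood_binned",
    "log_likelihood_pulsed",
    "photon_budget_index",
    "PHOTON_BUDGET_ADEQUATE",
]

#: Rule-of-thumb photon-budget index above which rate estimates are
#: typically resolvable to better than ~15%.
PHOTON_BUDGET_ADEQUATE = 1e6


@dataclass
class PhotonTrace:
    """Photon arrival record under continuous illumination.

    ``times`` are strictly increasing arrival times in (t_start, t_end);
    ``channels`` are 0-based registration channel indices.
    """

    times: np.ndarray
    channels: np.ndarray
    t_start: float = 0.0
    t_end: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.channels, dtype=np.int64)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and channels must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"arrival times must be strictly increasing (photon {bad})")
        if self.t_end is None:
            self.t_end = float(t[-1]) if t.size else self.t_start
        if t.size and (t[0] <= self.t_start or t[-1] > self.t_end):
            raise ValueError("photon times must lie in (t_start, t_end]")
        self.times = t
        self.channels = c

    @property
    def n_photons(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def gaps(self) -> np.ndarray:
        """Waiting times: first photon from t_start, then interphoton gaps."""
        return np.diff(self.times, prepend=self.t_start)


@dataclass
class PulsedTrace:
    """Photon record under pulsed illumination.

    At most one photon per pulse; photon ``k`` arrived in pulse
    ``pulse_indices[k]`` at microtime ``microtimes[k]`` (time since that
    pulse's start, < period) in channel ``channels[k]``.
    """

    period: float
    pulse_width: float
    n_pulses: int
    pulse_indices: np.ndarray
    microtimes: np.ndarray
    channels: np.ndarray

    def __post_init__(self):
        if not 0 < self.pulse_width < self.period:
            raise ValueError("need 0 < pulse_width < period")
        idx = np.asarray(self.pulse_indices, dtype=np.int64)
        mu = np.asarray(self.microtimes, dtype=float)
        ch = np.asarray(self.channels, dtype=np.int64)
        if not (idx.shape == mu.shape == ch.shape):
            raise ValueError("pulse_indices, microtimes, channels must align")
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0 or idx[-1] >= self.n_pulses):
            raise ValueError("pulse indices must be strictly increasing within range")
        if np.any(mu < 0) or np.any(mu >= self.period):
            raise ValueError("microtimes must satisfy 0 <= mu < period")
        self.pulse_indices, self.microtimes, self.channels = idx, mu, ch

    @property
    def n_photons(self) -> int:
        return self.pulse_indices.size

    def absolute_times(self) -> np.ndarray:
        return self.pulse_indices * self.period + self.microtimes


@dataclass
class BinnedTrace:
    """Per-bin photon counts: shape (n_bins, n_channels)."""

    bin_size: float
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or np.any(c < 0):
            raise ValueError("counts must be a nonnegative (n_bins, n_channels) array")
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        self.counts = c.astype(np.int64)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_size


# ---------------------------------------------------------------------------
# reduced generators and the eigenbasis engine


def reduced_generators(gen: CompositeGenerator, det: DetectorModel | None = None):
    """(G_non, [G_rad per channel]) masked by the detector's detection matrices."""
    d_non = nonradiative_detection_matrix(gen, det)
    g_non = gen.matrix * d_non
    g_rads = np.stack(
        [
            gen.matrix * radiative_detection_matrix(gen, c, det)
            for c in range(gen.n_channels)
        ]
    )
    return g_non, g_rads


class _Eigen:
    """Eigendecomposition of a generator, validated for filter use."""

    __slots__ = ("ok", "eigs", "v", "w")

    def __init__(self, g: np.ndarray):
        scale = max(1.0, np.abs(g).max())
        try:
            eigs, v = np.linalg.eig(g)
            w = np.linalg.inv(v)
        except np.linalg.LinAlgError:
            self.ok = False
            return
        residual = np.abs(v @ np.diag(eigs) @ w - g).max()
        self.ok = bool(np.isfinite(residual) and residual <= 1e-7 * scale)
        self.eigs, self.v, self.w = eigs, v, w

    def propagate(self, rho: np.ndarray, dt: float) -> np.ndarray:
        u = (rho.astype(complex) @ self.v) * np.exp(dt * self.eigs)
        return (u @ self.w).real


def _default_rho_start(gen: CompositeGenerator) -> np.ndarray:
    return steady_state(gen)


def _scan(gen, g_non, g_rads, dts, channels, rho_start, end_gap):
    """Run the scaled recursion; returns summed log normalizers.

    ``end_gap`` is the trailing nonradiative stretch (None to terminate at
    the last photon).
    """
    eig = _Eigen(g_non)
    if eig.ok:
        u0 = rho_start.astype(complex) @ eig.v
        w_ones = eig.w @ np.ones(g_non.shape[0])
        jumps = np.einsum("ij,cjk,kl->cil", eig.w, g_rads.astype(complex), eig.v)
        loglik, u = scan_eigenbasis(
            u0, eig.eigs, w_ones, np.ascontiguousarray(jumps), dts, channels
        )
        if not np.isfinite(loglik):
            return -np.inf
        if end_gap is not None:
            p = float(((u * np.exp(end_gap * eig.eigs)) @ w_ones).real)
            if not np.isfinite(p) or p <= 0:
                return -np.inf
            loglik += np.log(p)
        return loglik
    # dense fallback (rare: near-defective G_non)
    props = np.stack([expm(dt * g_non) for dt in dts]) if dts.size else np.zeros((0, *g_non.shape))
    loglik, rho = scan_dense(rho_start.copy(), props, g_rads, channels)
    if not np.isfinite(loglik):
        return -np.inf
    if end_gap is not None:
        p = float((rho @ expm(end_gap * g_non)).sum())
        if not np.isfinite(p) or p <= 0:
            return -np.inf
        loglik += np.log(p)
    return loglik


def log_likelihood_continuous(
    gen: CompositeGenerator,
    trace: PhotonTrace,
    det: DetectorModel | None = None,
    rho_start: np.ndarray | None = None,
    include_end: bool = True,
) -> float:
    """Photon-by-photon log-likelihood under continuous illumination.

    Alternates exp(dt * G_non) over interphoton gaps with the radiative jump
    G_rad of each photon's channel; ``include_end`` appends the final
    nonradiative stretch from the last photon to t_end (set False to
    terminate the product at the last photon's radiative factor).
    ``rho_start`` defaults to the steady state of ``gen``.
    """
    if trace.n_photons == 0 and trace.duration == 0:
        total = 1.0 if rho_start is None else float(np.sum(rho_start))
        return np.log(total) if total > 0 else -np.inf
    if rho_start is None:
        rho_start = _default_rho_start(gen)
    g_non, g_rads = reduced_generators(gen, det)
    if np.any(trace.channels >= gen.n_channels) or np.any(trace.channels < 0):
        raise ValueError("trace contains channel indices outside the detector model")
    end_gap = (trace.t_end - trace.times[-1]) if (include_end and trace.n_photons) else (
        trace.duration if include_end else None
    )
    if trace.n_photons == 0:
        if not include_end:
            return 0.0
        scale = max(1.0, np.abs(g_non).max())
        if np.abs(g_non.sum(axis=1)).max() <= 1e-12 * scale:
            # G_non conserves mass exactly (nothing is ever detected):
            # propagation cannot change the total probability
            total = float(np.sum(rho_start))
        else:
            rho = _Eigen(g_non)
            final = (
                rho.propagate(rho_start, trace.duration)
                if rho.ok
                else rho_start @ expm(trace.duration * g_non)
            )
            total = float(final.sum())
        return np.log(total) if total > 0 else -np.inf
    return _scan(gen, g_non, g_rads, trace.gaps(), trace.channels, rho_start, end_gap)


# ---------------------------------------------------------------------------
# dead time and IRF (dense matrix-product paths; used at calibration scale)


def _dead_window_generator(
    gen: CompositeGenerator, det: DetectorModel | None, dead_channel: int
) -> np.ndarray:
    """Generator during the dead window of one registration channel.

    While channel i is dead, its own intended transitions go unobserved and
    are therefore unconstrained; transitions intended for other channels were
    *not* seen by those (active) channels, so they carry the no-registration
    probability 1 - sum_{i' != i} phi[j, i'].  With a single ideal channel
    this is the full generator: a dead detector blocks nothing observable.
    """
    if det is None:
        det = DetectorModel.ideal(gen.n_channels)
    d = np.ones_like(gen.matrix)
    for j in range(gen.n_channels):
        miss = 1.0 - (det.routing[j].sum() - det.routing[j, dead_channel])
        d[gen.radiative_masks[j]] = miss
    return gen.matrix * d


def _dead_adjusted_gaps(trace: PhotonTrace, dead_times: np.ndarray) -> np.ndarray:
    gaps = trace.gaps()
    if trace.n_photons > 1:
        consumed = dead_times[trace.channels[:-1]]
        gaps[1:] -= consumed
        same = trace.channels[1:] == trace.channels[:-1]
        if np.any(gaps[1:][same] < 0):
            raise ValueError(
                "photon registered during its own channel's dead window: "
                "trace inconsistent with the stated dead times"
            )
        # overlapping windows across different channels: clip (each channel
        # masks only its own window; the residual overlap is negligible at
        # calibrated dead times)
        gaps[1:] = np.maximum(gaps[1:], 0.0)
    return gaps


def log_likelihood_dead_time(
    gen: CompositeGenerator,
    trace: PhotonTrace,
    det: DetectorModel,
    rho_start: np.ndarray | None = None,
    include_end: bool = True,
) -> float:
    """Log-likelihood with per-channel detector dead times.

    After each photon's radiative jump the filter evolves for the channel's
    dead time under the dead-window generator, and the following nonradiative
    stretch is shortened accordingly.
    """
    if not np.any(det.dead_times > 0):
        return log_likelihood_continuous(gen, trace, det, rho_start, include_end)
    if rho_start is None:
        rho_start = _default_rho_start(gen)
    g_non, g_rads = reduced_generators(gen, det)
    dead_props = [
        expm(det.dead_times[c] * _dead_window_generator(gen, det, c))
        for c in range(gen.n_channels)
    ]
    gaps = _dead_adjusted_gaps(trace, det.dead_times)
    rho = rho_start.copy()
    loglik = 0.0
    for k in range(trace.n_photons):
        rho = rho @ expm(gaps[k] * g_non) @ g_rads[trace.channels[k]]
        rho = rho @ dead_props[trace.channels[k]]
        p = rho.sum()
        if not np.isfinite(p) or p <= 0:
            return -np.inf
        loglik += np.log(p)
        rho /= p
    if include_end and trace.n_photons:
        end = max(trace.t_end - trace.times[-1] - det.dead_times[trace.channels[-1]], 0.0)
        p = (rho @ expm(end * g_non)).sum()
        loglik += np.log(p) if p > 0 else -np.inf
    return loglik


def log_likelihood_irf(
    gen: CompositeGenerator,
    trace: PhotonTrace,
    det: DetectorModel,
    rho_start: np.ndarray | None = None,
    include_end: bool = True,
) -> float:
    """Log-likelihood with timestamp jitter (detection IRF) and dead time.

    Each photon's factor becomes the discrete convolution over IRF bins
    sum_b f(tau_b) * Pi_non(dt_k - tau_b) @ G_rad @ Pi_dead(tau_b + delta_c):
    the radiative transition occurred tau_b before the timestamp and the
    channel stays dead through the delay plus its nominal dead time.
    """
    if det.is_delta_irf:
        return log_likelihood_dead_time(gen, trace, det, rho_start, include_end)
    if rho_start is None:
        rho_start = _default_rho_start(gen)
    g_non, g_rads = reduced_generators(gen, det)
    gaps = _dead_adjusted_gaps(trace, det.dead_times)
    if trace.n_photons and det.irf_delays.max() >= gaps.min():
        warnings.warn(
            "IRF support is not small compared to the shortest interphoton gap; "
            "the per-photon convolution may be inaccurate",
            stacklevel=2,
        )
    dead_gens = [_dead_window_generator(gen, det, c) for c in range(gen.n_channels)]
    # per (channel, IRF bin): radiative jump followed by the dead stretch
    jump_dead = [
        [
            g_rads[c] @ expm((tau + det.dead_times[c]) * dead_gens[c])
            for tau in det.irf_delays
        ]
        for c in range(gen.n_channels)
    ]
    eig = _Eigen(g_non)
    prop = (
        eig.propagate if eig.ok else (lambda rho, dt: rho @ expm(dt * g_non))
    )
    rho = rho_start.copy()
    loglik = 0.0
    for k in range(trace.n_photons):
        c = trace.channels[k]
        acc = np.zeros_like(rho)
        for b, (tau, f) in enumerate(zip(det.irf_delays, det.irf_weights)):
            dt = gaps[k] - tau
            if dt < 0:
                continue  # delay longer than the gap: zero-probability branch
            acc += f * (prop(rho, dt) @ jump_dead[c][b])
        p = acc.sum()
        if not np.isfinite(p) or p <= 0:
            return -np.inf
        loglik += np.log(p)
        rho = acc / p
    if include_end and trace.n_photons:
        end = max(trace.t_end - trace.times[-1] - det.dead_times[trace.channels[-1]], 0.0)
        p = (rho @ expm(end * g_non)).sum()
        loglik += np.log(p) if p > 0 else -np.inf
    return loglik


# ---------------------------------------------------------------------------
# binned likelihood


class PoissonBinModel:
    """Default per-bin observation model: independent Poisson counts.

    In system state sigma_i, channel counts over a bin of size eps are
    Poisson with mean eps * lambda_ex split by the state's FRET efficiency
    (acceptor fraction eff_i, donor fraction 1 - eff_i), optionally pushed
    through the detector routing matrix and augmented with background rates.
    Valid in the slow-kinetics, slow-excitation regime where interphoton
    times are dominated by the ground state.
    """

    def __init__(
        self,
        excitation_rate: float,
        efficiencies,
        bin_size: float,
        routing: np.ndarray | None = None,
        background_rates=None,
        channel_names=("acceptor", "donor"),
    ):
        eff = np.asarray(efficiencies, dtype=float)
        a = channel_names.index("acceptor")
        d = channel_names.index("donor")
        intended = np.zeros((eff.size, len(channel_names)))
        intended[:, a] = excitation_rate * eff
        intended[:, d] = excitation_rate * (1.0 - eff)
        registered = intended if routing is None else intended @ np.asarray(routing, float)
        if background_rates is not None:
            registered = registered + np.asarray(background_rates, dtype=float)
        self.means = bin_size * registered  # (Ms, C)
        self.bin_size = bin_size

    def log_prob(self, counts: np.ndarray) -> np.ndarray:
        """(N, C) counts -> (N, Ms) log observation probabilities."""
        counts = np.asarray(counts, dtype=float)
        mu = self.means  # (Ms, C)
        ll = (
            counts[:, None, :] * np.log(np.where(mu > 0, mu, 1.0))[None]
            - mu[None]
            - gammaln(counts + 1.0)[:, None, :]
        )
        impossible = (mu[None] == 0) & (counts[:, None, :] > 0)
        ll = np.where(impossible, -np.inf, ll)
        return ll.sum(axis=2)


def log_likelihood_binned(
    system: SystemKinetics,
    obs_model,
    binned: BinnedTrace,
    rho_start: np.ndarray | None = None,
) -> float:
    """Binned (intensity-trace) log-likelihood over system states only.

    A first-order filter over the Ms system states with per-bin propagator
    Pi_sigma = exp(eps * G_sigma) weighted by the observation model's
    p(counts | sigma_i).  Accurate when eps * system rates << 1 (system
    state effectively constant within a bin).
    """
    g_sys = system.generator
    eps = binned.bin_size
    if eps * np.abs(g_sys[~np.eye(g_sys.shape[0], dtype=bool)]).max(initial=0.0) > 0.1:
        warnings.warn(
            "bin size times the fastest system rate exceeds 0.1; the binned "
            "approximation assumes the system state is constant within a bin",
            stacklevel=2,
        )
    pi = expm(eps * g_sys)
    logw = obs_model.log_prob(binned.counts)  # (N, Ms)
    rho = steady_state(g_sys) if rho_start is None else np.asarray(rho_start, float)
    loglik = 0.0
    for n in range(binned.n_bins):
        shift = logw[n].max()
        if not np.isfinite(shift):
            return -np.inf
        weighted = rho * np.exp(logw[n] - shift)
        rho = weighted @ pi
        p = rho.sum()
        if not np.isfinite(p) or p <= 0:
            return -np.inf
        loglik += np.log(p) + shift
        rho /= p
    return loglik


# ---------------------------------------------------------------------------
# pulsed illumination


def log_likelihood_pulsed(
    gen: CompositeGenerator,
    ptrace: PulsedTrace,
    det: DetectorModel | None = None,
    rho_start: np.ndarray | None = None,
) -> float:
    """Log-likelihood under pulsed illumination (constant intensity pulses).

    Each interpulse period contributes a propagator Q_n: pulse evolution
    exp(delta_pulse * G_non) followed by dark evolution under G_dark (the
    excitation rate switched off), with the photon's radiative jump inserted
    at its microtime — inside the pulse or in the dark stretch — and the IRF
    convolution applied for dark-period photons when the detector has one.
    """
    from .statespace import dark_generator

    if rho_start is None:
        rho_start = _default_rho_start(gen)
    g_non, g_rads = reduced_generators(gen, det)
    gd = dark_generator(gen)
    g_dark = gd.matrix * nonradiative_detection_matrix(gd, det)
    dp, tau = ptrace.pulse_width, ptrace.period
    p_pulse = expm(dp * g_non)
    p_dark = expm((tau - dp) * g_dark)
    q_empty = p_pulse @ p_dark
    eig = _Eigen(q_empty)

    def run_empty(rho, m):
        if m <= 0:
            return rho, 0.0
        if eig.ok:
            u = (rho.astype(complex) @ eig.v) * eig.eigs**m
            out = (u @ eig.w).real
        else:
            out = rho @ np.linalg.matrix_power(q_empty, m)
        p = out.sum()
        if not np.isfinite(p) or p <= 0:
            return out, -np.inf
        return out / p, np.log(p)

    irf = det is not None and not det.is_delta_irf
    rho = rho_start.copy()
    loglik = 0.0
    prev = 0
    for k in range(ptrace.n_photons):
        n, mu, c = ptrace.pulse_indices[k], ptrace.microtimes[k], ptrace.channels[k]
        rho, lp = run_empty(rho, n - prev)
        if not np.isfinite(lp):
            return -np.inf
        loglik += lp
        if mu >= dp:  # photon in the dark stretch
            if irf:
                q = np.zeros_like(q_empty)
                for delay, f in zip(det.irf_delays, det.irf_weights):
                    t_before = mu - dp - delay
                    if t_before < 0:
                        continue
                    q += f * (
                        expm(t_before * g_dark)
                        @ g_rads[c]
                        @ expm((tau - mu + delay) * g_dark)
                    )
                q = p_pulse @ q
            else:
                q = (
                    p_pulse
                    @ expm((mu - dp) * g_dark)
                    @ g_rads[c]
                    @ expm((tau - mu) * g_dark)
                )
        else:  # photon inside the pulse
            q = (
                expm(mu * g_non)
                @ g_rads[c]
                @ expm((dp - mu) * g_non)
                @ p_dark
            )
        rho = rho @ q
        p = rho.sum()
        if not np.isfinite(p) or p <= 0:
            return -np.inf
        loglik += np.log(p)
        rho /= p
        prev = n + 1
    rho, lp = run_empty(rho, ptrace.n_pulses - prev)
    if not np.isfinite(lp):
        return -np.inf
    return loglik + lp


def photon_budget_index(
    n_photons: float, excitation_rate: float, probe_rate: float, n_states: int
) -> float:
    """Dimensionless adequacy score K * lambda_ex / (lambda_probe * M_sigma).

    ``probe_rate`` is the fastest escape rate one wants to resolve; values
    above ~1e6 (:data:`PHOTON_BUDGET_ADEQUATE`) indicate the trace carries
    enough photons to estimate it to roughly 15% or better.
    """
    if excitation_rate <= 0 or probe_rate <= 0 or n_states <= 0 or n_photons <= 0:
        raise ValueError("all photon-budget factors must be positive")
    return n_photons * excitation_rate / (probe_rate * n_states)
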