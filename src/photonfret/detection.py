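"""Detection matrices: what an observation implies about allowed transitions.

A single-photon detector reports, for every instant, either "photon in
channel i" or "no photon".  Each report multiplies the propagator elementwise
by a detection matrix D: radiative matrices carry the routing probability
phi[j, i] (photon intended for channel j registered in channel i) on channel
j's radiative transitions, the nonradiative matrix carries 1 - sum_i phi[j, i]
there and 1 elsewhere, and dead-time matrices zero out transitions intended
for a temporarily dead channel.  With ideal detectors (phi = identity) these
reduce to hard 0/1 masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .statespace import CompositeGenerator

__all__ = [
    "DetectorModel",
    "RoutingFactors",
    "radiative_detection_matrix",
    "nonradiative_detection_matrix",
    "dead_time_matrix",
    "calibrate_from_rcm",
    "routing_from_factors",
]


class RoutingFactors(NamedTuple):
    """Crosstalk/efficiency factors for a two-channel (acceptor, donor) setup."""

    phi_a1: float
    phi_a2: float
    phi_d1: float
    phi_d2: float


@dataclass
class DetectorModel:
    """Effective emission routing, dead times and IRF of a detector bank.

    Parameters
    ----------
    routing : (C, C) matrix, routing[j, i] = P(photon intended for channel j
        is registered in channel i).  Row sums may be below 1; the deficit is
        the probability of the photon going undetected.
    dead_times : per registration channel, the interval after a detection
        during which that channel cannot register photons.
    irf_delays, irf_weights : discretized instrument-response density on the
        acquisition grid (delay between photon arrival and timestamp).
        Weights are nonnegative and sum to one; a single zero-delay bin is a
        delta IRF (no jitter).
    resolution : acquisition grid step (also the IRF grid step).
    """

    routing: np.ndarray
    dead_times: np.ndarray | None = None
    irf_delays: np.ndarray | None = None
    irf_weights: np.ndarray | None = None
    resolution: float = 0.0

    def __post_init__(self):
        phi = np.atleast_2d(np.asarray(self.routing, dtype=float))
        if np.any(phi < 0) or np.any(phi.sum(axis=1) > 1 + 1e-9):
            raise ValueError("routing rows must be nonnegative with sums <= 1")
        self.routing = phi
        c = phi.shape[1]
        if self.dead_times is None:
            self.dead_times = np.zeros(c)
        else:
            self.dead_times = np.asarray(self.dead_times, dtype=float)
            if np.any(self.dead_times < 0) or self.dead_times.shape != (c,):
                raise ValueError("dead_times must be nonnegative, one per channel")
        if self.irf_delays is None:
            self.irf_delays = np.zeros(1)
            self.irf_weights = np.ones(1)
        else:
            self.irf_delays = np.asarray(self.irf_delays, dtype=float)
            self.irf_weights = np.asarray(self.irf_weights, dtype=float)
            if self.irf_delays.shape != self.irf_weights.shape:
                raise ValueError("IRF delays and weights must have equal length")
            if np.any(self.irf_weights < 0) or abs(self.irf_weights.sum() - 1) > 1e-9:
                raise ValueError("IRF weights must be nonnegative and sum to 1")

    @property
    def n_channels(self) -> int:
        return self.routing.shape[1]

    @property
    def is_delta_irf(self) -> bool:
        return self.irf_delays.size == 1 and self.irf_delays[0] == 0.0

    @classmethod
    def ideal(cls, n_channels: int = 2) -> "DetectorModel":
        """Lossless, crosstalk-free, instantaneous detectors."""
        return cls(routing=np.eye(n_channels))

    @classmethod
    def with_truncated_gaussian_irf(
        cls,
        routing: np.ndarray,
        mean: float,
        width: float,
        support: float,
        resolution: float,
        dead_times=None,
    ) -> "DetectorModel":
        """Discretize a truncated-Gaussian IRF by midpoint mass on the grid.

        ``width`` is the Gaussian standard deviation; the density is truncated
        to [0, support], binned at ``resolution`` and renormalized.
        """
        n_bins = max(1, int(round(support / resolution)))
        centers = (np.arange(n_bins) + 0.5) * resolution
        w = np.exp(-0.5 * ((centers - mean) / width) ** 2)
        w = w / w.sum()
        return cls(
            routing=routing,
            dead_times=dead_times,
            irf_delays=centers,
            irf_weights=w,
            resolution=resolution,
        )


def radiative_detection_matrix(
    gen: CompositeGenerator, channel: int, det: DetectorModel | None = None
) -> np.ndarray:
    """Detection matrix for "photon registered in ``channel``".

    Entry = phi[j, channel] on transitions radiative for intended channel j,
    zero elsewhere (including the diagonal).
    """
    if not 0 <= channel < gen.n_channels:
        raise ValueError(f"channel {channel} out of range")
    if det is None:
        det = DetectorModel.ideal(gen.n_channels)
    d = np.zeros_like(gen.matrix)
    for j in range(gen.n_channels):
        d[gen.radiative_masks[j]] = det.routing[j, channel]
    return d


def nonradiative_detection_matrix(
    gen: CompositeGenerator, det: DetectorModel | None = None
) -> np.ndarray:
    """Detection matrix for "no photon registered in any channel".

    Entry 1 on nonradiative transitions; on transitions radiative for
    intended channel j the entry is 1 - sum_i phi[j, i], the probability
    the emitted photon goes undetected.
    """
    if det is None:
        det = DetectorModel.ideal(gen.n_channels)
    d = np.ones_like(gen.matrix)
    miss = 1.0 - det.routing.sum(axis=1)
    for j in range(gen.n_channels):
        d[gen.radiative_masks[j]] = miss[j]
    return d


def dead_time_matrix(gen: CompositeGenerator, channel: int) -> np.ndarray:
    """Detection matrix while ``channel`` is dead: its intended transitions
    are unobservable (entry 0); all other transitions pass (entry 1)."""
    if not 0 <= channel < gen.n_channels:
        raise ValueError(f"channel {channel} out of range")
    d = np.ones_like(gen.matrix)
    d[gen.radiative_masks[channel]] = 0.0
    return d


def calibrate_from_rcm(rcm: np.ndarray) -> RoutingFactors:
    """Crosstalk/efficiency factors from a 2x2 route correction matrix.

    The RCM is proportional to [[phi_d2, -phi_d1], [-phi_a2, phi_a1]]; it is
    normalized by the sum of absolute values of its first row, which fixes
    phi_d1 + phi_d2 = 1 (donor photons fully accounted for between the two
    channels) while the acceptor row absorbs any detection inefficiency.
    """
    rcm = np.asarray(rcm, dtype=float)
    if rcm.shape != (2, 2):
        raise ValueError("route correction matrix must be 2x2")
    if rcm[0, 0] <= 0 or rcm[1, 1] <= 0:
        raise ValueError("route correction matrix must have positive diagonal")
    if rcm[0, 1] > 0 or rcm[1, 0] > 0:
        raise ValueError("route correction matrix off-diagonals must be <= 0")
    scale = np.abs(rcm[0]).sum()
    if scale == 0:
        raise ValueError("route correction matrix first row sums to zero")
    m = rcm / scale
    return RoutingFactors(
        phi_a1=m[1, 1], phi_a2=-m[1, 0] + 0.0, phi_d1=-m[0, 1] + 0.0, phi_d2=m[0, 0]
    )


def routing_from_factors(
    factors: RoutingFactors, channel_names=("acceptor", "donor")
) -> np.ndarray:
    """Assemble the (C, C) routing matrix in a generator's channel order.

    Rows are intended channels, columns registration channels; channel 1 is
    the acceptor channel and channel 2 the donor channel, matching the
    calibration convention.
    """
    value = {
        ("acceptor", "acceptor"): factors.phi_a1,
        ("acceptor", "donor"): factors.phi_a2,
        ("donor", "acceptor"): factors.phi_d1,
        ("donor", "donor"): factors.phi_d2,
    }
    c = len(channel_names)
    phi = np.zeros((c, c))
    for j, intended in enumerate(channel_names):
        for i, registered in enumerate(channel_names):
            phi[j, i] = value[(intended, registered)]
    return phi
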