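"""Composite superstate spaces and their generator matrices.

A labeled molecule ("system") hops among a discrete set of conformational
states sigma_1..sigma_Ms while its FRET dye pair cycles through photophysical
states psi_1..psi_Mp (ground, donor-excited, acceptor-excited, and optionally
a dark/bleached state).  The joint process is a continuous-time Markov jump
process over superstates phi = (sigma_j, psi_k), flattened with index
i = (j-1)*Mp + k (0-based internally), whose generator matrix G has
nonnegative off-diagonal rates and zero row sums.  Donor and acceptor photon
emissions correspond to particular radiative transitions of G, recorded here
as boolean masks per detection channel.

All rates and times are unit-agnostic: the caller supplies one consistent
base unit (the bundled presets and CLI use milliseconds and ms^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ACCEPTOR",
    "DONOR",
    "SystemKinetics",
    "PhotophysicsSpec",
    "BackgroundSpec",
    "CompositeGenerator",
    "build_composite_generator",
    "add_background",
    "dark_generator",
    "fret_efficiency",
    "steady_state",
    "propagate",
]

#: Default channel order.  Channel 1 (index 0) collects acceptor emission,
#: channel 2 (index 1) collects donor emission.
ACCEPTOR = "acceptor"
DONOR = "donor"
DEFAULT_CHANNELS = (ACCEPTOR, DONOR)

_ROW_SUM_TOL = 1e-9


def _check_nonnegative(value, name):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite and nonnegative, got {value!r}")
    return arr


@dataclass(frozen=True)
class SystemKinetics:
    """Conformational (system) kinetics: an Ms x Ms rate matrix.

    Off-diagonal entry (i, j) is the rate sigma_i -> sigma_j; the diagonal is
    recomputed as the negative row sum, so callers may leave it arbitrary.
    """

    rates: np.ndarray

    def __post_init__(self):
        arr = np.array(self.rates, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("system rate matrix must be square")
        off = arr.copy()
        np.fill_diagonal(off, 0.0)
        _check_nonnegative(off, "system rates")
        np.fill_diagonal(off, -off.sum(axis=1))
        object.__setattr__(self, "rates", off)

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    @property
    def generator(self) -> np.ndarray:
        """The system generator matrix (zero row sums)."""
        return self.rates.copy()

    def escape_rates(self) -> np.ndarray:
        return -np.diag(self.rates)


@dataclass(frozen=True)
class PhotophysicsSpec:
    """Photophysics of the FRET pair, shared across system states.

    ``fret_rates`` holds one donor->acceptor transfer rate per system state;
    everything else (excitation, relaxation, bleaching/blinking, direct
    acceptor excitation) is state independent.  A nonzero bleach or blink
    rate adds a fourth, dark photophysical state.
    """

    excitation_rate: float
    donor_relax_rate: float
    acceptor_relax_rate: float
    fret_rates: tuple
    direct_excitation_rate: float = 0.0
    bleach_rate: float = 0.0
    blink_rate: float = 0.0
    unblink_rate: float = 0.0

    def __post_init__(self):
        for name in (
            "excitation_rate",
            "donor_relax_rate",
            "acceptor_relax_rate",
            "direct_excitation_rate",
            "bleach_rate",
            "blink_rate",
            "unblink_rate",
        ):
            _check_nonnegative(getattr(self, name), name)
        fr = tuple(float(x) for x in self.fret_rates)
        _check_nonnegative(fr, "fret_rates")
        object.__setattr__(self, "fret_rates", fr)
        if self.bleach_rate > 0 and self.blink_rate > 0:
            raise ValueError("use either bleach_rate or blink_rate, not both")

    @property
    def n_photo_states(self) -> int:
        return 4 if (self.bleach_rate > 0 or self.blink_rate > 0) else 3

    def block(self, state_index: int) -> np.ndarray:
        """Photophysical generator block for one system state (diag = -rowsum)."""
        lam_f = self.fret_rates[state_index]
        m = self.n_photo_states
        g = np.zeros((m, m))
        g[0, 1] = self.excitation_rate
        g[0, 2] = self.direct_excitation_rate
        g[1, 0] = self.donor_relax_rate
        g[1, 2] = lam_f
        g[2, 0] = self.acceptor_relax_rate
        if m == 4:
            g[1, 3] = self.bleach_rate + self.blink_rate
            if self.unblink_rate > 0:
                g[3, 0] = self.unblink_rate
        np.fill_diagonal(g, 0.0)
        np.fill_diagonal(g, -g.sum(axis=1))
        return g


@dataclass(frozen=True)
class BackgroundSpec:
    """Per-channel constant background emission rates."""

    rates: tuple

    def __post_init__(self):
        r = tuple(float(x) for x in np.atleast_1d(np.asarray(self.rates, dtype=float)))
        _check_nonnegative(r, "background rates")
        object.__setattr__(self, "rates", r)

    @property
    def n_channels(self) -> int:
        return len(self.rates)


@dataclass
class CompositeGenerator:
    """Generator matrix over superstates plus its radiative bookkeeping.

    Attributes
    ----------
    matrix : (M, M) rate matrix, zero row sums.
    radiative_masks : (C, M, M) boolean; mask c marks transitions that emit a
        photon intended for channel c.  Masks are pairwise disjoint with zero
        diagonals.
    excitation_mask : (M, M) boolean marking laser-driven transitions (used to
        build the dark-period generator for pulsed illumination).
    channel_names : names of the C detection channels, in index order.
    labels : human-readable 1-based superstate labels "(sigma_j, psi_k)".
    """

    matrix: np.ndarray
    radiative_masks: np.ndarray
    excitation_mask: np.ndarray
    channel_names: tuple = DEFAULT_CHANNELS
    labels: list = field(default_factory=list)
    n_system_states: int = 0
    n_photo_states: int = 0

    def __post_init__(self):
        g = np.asarray(self.matrix, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("generator matrix must be square")
        off = g - np.diag(np.diag(g))
        if np.any(off < -1e-12):
            raise ValueError("generator off-diagonal rates must be nonnegative")
        if np.max(np.abs(g.sum(axis=1))) > _ROW_SUM_TOL * max(1.0, np.abs(g).max()):
            raise ValueError("generator row sums must be zero")
        masks = np.asarray(self.radiative_masks, dtype=bool)
        if masks.ndim != 3 or masks.shape[1:] != g.shape:
            raise ValueError("radiative_masks must have shape (C, M, M)")
        if any(np.any(np.diag(m)) for m in masks):
            raise ValueError("radiative masks must have zero diagonal")
        if np.any(masks.sum(axis=0) > 1):
            raise ValueError("radiative masks for distinct channels must be disjoint")
        self.matrix = g
        self.radiative_masks = masks
        self.excitation_mask = np.asarray(self.excitation_mask, dtype=bool)

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.radiative_masks.shape[0]

    def radiative_rates(self, channel: int) -> np.ndarray:
        """Rate matrix restricted to channel's radiative transitions (G_rad)."""
        return np.where(self.radiative_masks[channel], self.matrix, 0.0)

    def to_delimited(self, path, delimiter="\t"):
        np.savetxt(path, self.matrix, delimiter=delimiter)


def build_composite_generator(
    system: SystemKinetics,
    photo: PhotophysicsSpec,
    channel_names: tuple = DEFAULT_CHANNELS,
) -> CompositeGenerator:
    """Assemble the superstate generator from system and photophysical parts.

    The resulting matrix has the per-state photophysical blocks on the block
    diagonal and lambda_{sigma_i -> sigma_j} * I off the block diagonal
    (no simultaneous system + photophysical transitions); the diagonal is the
    negative row sum.  Donor emission (psi_2 -> psi_1) and acceptor emission
    (psi_3 -> psi_1) transitions are recorded in the radiative masks for the
    donor- and acceptor-intended channels.
    """
    ms = system.n_states
    if len(photo.fret_rates) != ms:
        raise ValueError(
            f"need one FRET rate per system state: got {len(photo.fret_rates)} "
            f"for {ms} states"
        )
    if DONOR not in channel_names or ACCEPTOR not in channel_names:
        raise ValueError("channel_names must include 'donor' and 'acceptor'")
    mp = photo.n_photo_states
    m = ms * mp
    g = np.zeros((m, m))
    for i in range(ms):
        sl = slice(i * mp, (i + 1) * mp)
        g[sl, sl] = photo.block(i)
        for j in range(ms):
            if i != j:
                g[sl, slice(j * mp, (j + 1) * mp)] = system.rates[i, j] * np.eye(mp)
    np.fill_diagonal(g, 0.0)
    np.fill_diagonal(g, -g.sum(axis=1))

    n_ch = len(channel_names)
    masks = np.zeros((n_ch, m, m), dtype=bool)
    exc = np.zeros((m, m), dtype=bool)
    d_ch = channel_names.index(DONOR)
    a_ch = channel_names.index(ACCEPTOR)
    for i in range(ms):
        base = i * mp
        masks[d_ch, base + 1, base] = True  # donor relaxation emits a donor photon
        masks[a_ch, base + 2, base] = True  # acceptor relaxation emits an acceptor photon
        exc[base, base + 1] = True
        if photo.direct_excitation_rate > 0:
            exc[base, base + 2] = True
    labels = [
        f"(sigma{i + 1},psi{k + 1})" for i in range(ms) for k in range(mp)
    ]
    return CompositeGenerator(
        matrix=g,
        radiative_masks=masks,
        excitation_mask=exc,
        channel_names=tuple(channel_names),
        labels=labels,
        n_system_states=ms,
        n_photo_states=mp,
    )


def add_background(gen: CompositeGenerator, bg: BackgroundSpec) -> CompositeGenerator:
    """Expand a generator with independent two-state background emitters.

    Each detection channel gains a fictitious two-state emitter whose every
    transition (rate lambda_bg) emits a photon into that channel; the joint
    generator is the Kronecker sum G = G_composite (+) G_1 (+) ... (+) G_C,
    and the radiative masks are extended so emitter c's transitions are
    radiative for channel c.
    """
    if bg.n_channels != gen.n_channels:
        raise ValueError(
            f"background spec has {bg.n_channels} channels, generator has {gen.n_channels}"
        )
    g = gen.matrix
    masks = gen.radiative_masks
    exc = gen.excitation_mask
    labels = list(gen.labels)
    for c, rate in enumerate(bg.rates):
        m = g.shape[0]
        emitter = np.array([[-rate, rate], [rate, -rate]])
        g = np.kron(g, np.eye(2)) + np.kron(np.eye(m), emitter)
        emitter_mask = np.array([[False, True], [True, False]])
        new_masks = np.zeros((masks.shape[0], 2 * m, 2 * m), dtype=bool)
        for ch in range(masks.shape[0]):
            new_masks[ch] = np.kron(masks[ch], np.eye(2, dtype=bool))
        new_masks[c] |= np.kron(np.eye(m, dtype=bool), emitter_mask)
        masks = new_masks
        exc = np.kron(exc, np.eye(2, dtype=bool))
        labels = [f"{lab}x(bg{c + 1}:{s})" for lab in labels for s in ("1", "2")]
    return CompositeGenerator(
        matrix=g,
        radiative_masks=masks,
        excitation_mask=exc,
        channel_names=gen.channel_names,
        labels=labels,
        n_system_states=gen.n_system_states,
        n_photo_states=gen.n_photo_states,
    )


def dark_generator(gen: CompositeGenerator) -> CompositeGenerator:
    """Generator with laser-driven (excitation) rates switched off."""
    g = gen.matrix.copy()
    g[gen.excitation_mask] = 0.0
    np.fill_diagonal(g, 0.0)
    np.fill_diagonal(g, -g.sum(axis=1))
    return replace(gen, matrix=g)


def fret_efficiency(fret_rate: float, donor_relax_rate: float) -> float:
    """Fraction of donor de-excitations routed through energy transfer.

    eff = lambda_FRET / (lambda_FRET + lambda_d): the acceptor-photon fraction
    of all emitted photons for a state with transfer rate lambda_FRET.
    """
    if donor_relax_rate <= 0:
        raise ValueError("donor relaxation rate must be positive")
    if fret_rate < 0:
        raise ValueError("FRET rate must be nonnegative")
    return fret_rate / (fret_rate + donor_relax_rate)


def efficiency_to_fret_rate(efficiency: float, donor_relax_rate: float) -> float:
    """Inverse of :func:`fret_efficiency`."""
    if not 0 <= efficiency < 1:
        raise ValueError("efficiency must be in [0, 1)")
    return efficiency / (1.0 - efficiency) * donor_relax_rate


def _stationary_of(matrix: np.ndarray) -> np.ndarray:
    m = matrix.shape[0]
    a = np.vstack([matrix.T, np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    rho, *_ = np.linalg.lstsq(a, b, rcond=None)
    rho = np.clip(rho, 0.0, None)
    total = rho.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("no normalizable stationary vector found")
    rho = rho / total
    if np.max(np.abs(rho @ matrix)) > 1e-8 * max(1.0, np.abs(matrix).max()):
        raise FloatingPointError("stationary solve did not converge")
    return rho


def steady_state(
    gen: CompositeGenerator | np.ndarray,
    start_index: int = 0,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Stationary distribution rho with rho @ G = 0, rho >= 0, sum(rho) = 1.

    For reducible generators (e.g. with photobleached absorbing states) the
    stationary vector of the closed communicating class reachable from
    ``start_index`` (default: the all-ground superstate) is returned, embedded
    in the full state space.  ``support`` optionally restricts the computation
    to a boolean subset of states (used by load-masked generators).
    """
    g = gen.matrix if isinstance(gen, CompositeGenerator) else np.asarray(gen, float)
    if support is not None:
        support = np.asarray(support, dtype=bool)
        idx = np.flatnonzero(support)
        sub = g[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        np.fill_diagonal(sub, -sub.sum(axis=1))
        rho = np.zeros(g.shape[0])
        rho[idx] = steady_state(sub, start_index=0)
        return rho
    adj = (g > 0).astype(np.int8)
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    if n_comp == 1:
        return _stationary_of(g)
    # follow reachability from the start state down to a terminal (closed) class
    current = comp[start_index]
    moved = True
    while moved:
        moved = False
        members = np.flatnonzero(comp == current)
        for i in members:
            targets = comp[np.flatnonzero(adj[i])]
            outside = targets[targets != current]
            if outside.size:
                current = outside[0]
                moved = True
                break
    members = np.flatnonzero(comp == current)
    rho = np.zeros(g.shape[0])
    sub = g[np.ix_(members, members)].copy()
    np.fill_diagonal(sub, 0.0)
    np.fill_diagonal(sub, -sub.sum(axis=1))
    rho[members] = _stationary_of(sub)
    return rho


def propagate(
    gen: CompositeGenerator | np.ndarray, rho: np.ndarray, dt: float
) -> np.ndarray:
    """Propagate a (possibly sub-normalized) state vector: rho @ expm(dt * G)."""
    if dt < 0:
        raise ValueError("propagation duration must be nonnegative")
    g = gen.matrix if isinstance(gen, CompositeGenerator) else np.asarray(gen, float)
    if dt == 0:
        return np.asarray(rho, dtype=float).copy()
    return np.asarray(rho, dtype=float) @ expm(dt * g)
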