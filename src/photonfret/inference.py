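"""Posterior samplers for kinetic rates and the number of system states.

All samplers are Metropolis-within-Gibbs chains over the photon-by-photon
likelihood.  Individual transition rates are updated one at a time with
log-space Gaussian random-walk proposals (whose variable change contributes
a lambda*/lambda Jacobian factor to the acceptance probability) under
independent Gamma priors parameterized by shape ``alpha`` and *mean*
``lambda_ref``.  The nonparametric sampler augments the rate chain with
Bernoulli loads that switch candidate system states on and off; the pulsed
sampler learns system transition probabilities directly under truncated
Dirichlet-process priors.

Estimators follow the scikit-learn protocol: hyperparameters in
``__init__``, ``fit(trace)``, fitted attributes with trailing underscores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .likelihood import (
    PhotonTrace,
    PulsedTrace,
    log_likelihood_continuous,
)
from .statespace import (
    BackgroundSpec,
    CompositeGenerator,
    PhotophysicsSpec,
    SystemKinetics,
    add_background,
    build_composite_generator,
    fret_efficiency,
    steady_state,
)

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorSamples",
    "mh_step_log_rate",
    "load_conditional",
    "ParametricRateSampler",
    "BernoulliLoadSampler",
    "PulsedTransitionSampler",
    "sample_parametric",
    "sample_nonparametric",
    "sample_ihmm_pulsed",
]

#: Proposal variance sets (sigma^2 for excitation, FRET, system-rate blocks),
#: alternated between sweeps so both fine and coarse moves are proposed.
DEFAULT_PROPOSAL_SETS = ((1e-5, 0.01, 0.1), (1e-5, 0.5, 5.0))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters for the rate and load priors.

    Gamma priors use shape ``alpha`` and mean ``*_ref`` (scale = ref/alpha).
    ``expected_states`` (gamma) and ``max_states`` parameterize the Bernoulli
    load prior with success 1 / (1 + (max_states - 1) / gamma);
    ``dp_concentration`` and ``dp_xi`` are the truncated Dirichlet-process
    hyperparameters of the pulsed sampler.
    """

    alpha: float = 1.0
    fret_ref: float = 1e6  # ms^-1 (= 1 ns^-1)
    sys_ref: float = 1.0  # ms^-1 (= 1e-6 ns^-1)
    ex_ref: float | None = None  # default: the supplied excitation rate
    expected_states: float = 1.0
    max_states: int = 10
    dp_concentration: float = 1.0
    dp_xi: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.fret_ref <= 0 or self.sys_ref <= 0:
            raise ValueError("Gamma hyperparameters must be positive")
        if not 1 <= self.expected_states <= self.max_states:
            raise ValueError("need 1 <= expected_states <= max_states")

    @property
    def load_success(self) -> float:
        return 1.0 / (1.0 + (self.max_states - 1) / self.expected_states)

    def log_gamma_prior(self, value: float, ref: float) -> float:
        """log Gamma(value; shape=alpha, mean=ref), up to a constant."""
        if value <= 0:
            return -np.inf
        return (self.alpha - 1.0) * np.log(value) - value * self.alpha / ref

    def draw_gamma(self, ref: float, rng) -> float:
        return rng.gamma(self.alpha, ref / self.alpha)


@dataclass(frozen=True)
class McmcConfig:
    """Chain length, proposal schedule and seed."""

    draws: int = 2000
    proposal_sets: tuple = DEFAULT_PROPOSAL_SETS
    burn_in: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in fraction must be in [0, 1)")
        for s in self.proposal_sets:
            if any(v <= 0 for v in s):
                raise ValueError("proposal variances must be positive")


@dataclass
class PosteriorSamples:
    """Per-draw rate samples, loads, log-posteriors and acceptance counts."""

    rates: pd.DataFrame
    log_posterior: np.ndarray
    acceptance: dict
    loads: np.ndarray | None = None
    burn_in: float = 0.2
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.rates)

    def after_burn_in(self) -> pd.DataFrame:
        return self.rates.iloc[int(self.burn_in * self.n_draws):]


def mh_step_log_rate(value, log_posterior, sigma, rng, current_log_posterior=None):
    """One Metropolis-Hastings update of a positive rate in log space.

    Proposes log(lambda*) ~ Normal(log(lambda), sigma^2) and accepts with
    probability min{1, posterior-ratio * lambda*/lambda}; the rate ratio is
    the Jacobian of the log transform.  Returns
    (new_value, accepted, log_posterior at new value).
    """
    if value <= 0:
        raise ValueError("current rate must be positive")
    if current_log_posterior is None:
        current_log_posterior = log_posterior(value)
    if not np.isfinite(current_log_posterior):
        raise FloatingPointError("log posterior not finite at the current state")
    proposal = value * np.exp(sigma * rng.standard_normal())
    lp = log_posterior(proposal)
    log_alpha = lp - current_log_posterior + np.log(proposal / value)
    if np.log(rng.random()) < log_alpha:
        return proposal, True, lp
    return value, False, current_log_posterior


def load_conditional(loglik_on, loglik_off, prior_success, include_prior=True):
    """Bernoulli success probability for one load's conditional posterior.

    q = p1 * L(b=1) / (p1 * L(b=1) + (1-p1) * L(b=0)) with p1 the prior
    success.  ``include_prior=False`` reproduces the pure likelihood ratio
    (correct only when the prior success is 1/2).
    """
    if not (np.isfinite(loglik_on) or np.isfinite(loglik_off)):
        raise FloatingPointError("both load branches have zero likelihood")
    lp1 = loglik_on + (np.log(prior_success) if include_prior else 0.0)
    lp0 = loglik_off + (np.log1p(-prior_success) if include_prior else 0.0)
    m = max(lp1, lp0)
    e1, e0 = np.exp(lp1 - m), np.exp(lp0 - m)
    return e1 / (e1 + e0)


# ---------------------------------------------------------------------------
# free-parameter bookkeeping shared by the continuous-illumination samplers


class _RateParam:
    __slots__ = ("name", "kind", "ref", "value")

    def __init__(self, name, kind, ref, value):
        self.name = name  # column name
        self.kind = kind  # 'ex' | 'fret' | 'sys' -> proposal-variance slot
        self.ref = ref  # Gamma prior mean
        self.value = value


_KIND_SLOT = {"ex": 0, "fret": 1, "sys": 2}


class _ContinuousModel:
    """Builds composite generators from a free-rate vector and evaluates
    the photon-by-photon log-likelihood with steady-state rho_start."""

    def __init__(
        self,
        n_states,
        donor_relax_rate,
        acceptor_relax_rate,
        detector,
        background,
        direct_excitation_rate=0.0,
    ):
        self.n_states = n_states
        self.donor_relax_rate = donor_relax_rate
        self.acceptor_relax_rate = acceptor_relax_rate
        self.detector = detector
        self.background = background
        self.direct_excitation_rate = direct_excitation_rate

    def build(self, excitation_rate, sys_rates, fret_rates, loads=None) -> CompositeGenerator:
        rates = np.asarray(sys_rates, dtype=float).copy()
        if loads is not None:
            rates = rates * np.outer(loads, loads)
        system = SystemKinetics(rates)
        photo = PhotophysicsSpec(
            excitation_rate=excitation_rate,
            donor_relax_rate=self.donor_relax_rate,
            acceptor_relax_rate=self.acceptor_relax_rate,
            fret_rates=tuple(fret_rates),
            direct_excitation_rate=self.direct_excitation_rate,
        )
        gen = build_composite_generator(system, photo)
        if loads is not None and not np.all(loads):
            # zero out inactive photophysical blocks; system couplings are
            # already masked through the load outer product
            g = gen.matrix.copy()
            mp = gen.n_photo_states
            for i, b in enumerate(loads):
                if not b:
                    sl = slice(i * mp, (i + 1) * mp)
                    g[sl, :] = 0.0
                    g[:, sl] = 0.0
            np.fill_diagonal(g, 0.0)
            np.fill_diagonal(g, -g.sum(axis=1))
            gen.matrix = g
        if self.background is not None:
            gen = add_background(gen, self.background)
        return gen

    def log_likelihood(self, gen, trace, loads=None) -> float:
        if loads is None or np.all(loads):
            rho = steady_state(gen)
        else:
            mp = gen.n_photo_states
            per_state = np.repeat(np.asarray(loads, dtype=bool), mp)
            # background emitters multiply the space; they are always live
            factor = gen.matrix.shape[0] // per_state.size
            support = np.repeat(per_state, factor)
            rho = steady_state(gen, support=support)
        try:
            return log_likelihood_continuous(gen, trace, self.detector, rho_start=rho)
        except FloatingPointError:
            return -np.inf


def _summarize(df, burn_in, donor_relax_rate, quantiles=(0.05, 0.5, 0.95)):
    """Quantile table with derived escape rates and FRET efficiencies."""
    post = df.iloc[int(burn_in * len(df)):]
    out = {}
    for col in post.columns:
        out[col] = [post[col].quantile(q) for q in quantiles]
    fret_cols = [c for c in post.columns if c.startswith("fret_")]
    for c in fret_cols:
        i = c.split("_")[1]
        eff = post[c] / (post[c] + donor_relax_rate)
        out[f"efficiency_{i}"] = [eff.quantile(q) for q in quantiles]
    sys_cols = [c for c in post.columns if c.startswith("sys_")]
    states = sorted({c.split("_")[1].split("->")[0] for c in sys_cols})
    for s in states:
        esc = sum(post[c] for c in sys_cols if c.startswith(f"sys_{s}->"))
        out[f"escape_{s}"] = [esc.quantile(q) for q in quantiles]
    return pd.DataFrame(out, index=[f"q{int(100 * q)}" for q in quantiles]).T


class ParametricRateSampler(BaseEstimator):
    """Gibbs sampler over transition rates for a fixed number of system states.

    Free parameters are the system transition rates and per-state FRET rates
    (and optionally the excitation rate, proposed with a deliberately tiny
    variance since it is precalibrated in practice); donor/acceptor
    relaxation and background rates are fixed.  Each sweep updates every free
    rate by a log-space Metropolis step against the full photon-by-photon
    likelihood, with steady-state rho_start recomputed for every proposal.
    Proposal-variance sets alternate with sweep parity.

    Attributes (after ``fit``)
    --------------------------
    samples_ : DataFrame of per-draw rates (one row per sweep).
    log_posterior_ : per-draw unnormalized log posterior.
    acceptance_ : acceptance fraction per proposal block.
    posterior_ : the same data bundled as :class:`PosteriorSamples`.
    """

    def __init__(
        self,
        n_states=2,
        excitation_rate=10.0,
        donor_relax_rate=277000.0,
        acceptor_relax_rate=285000.0,
        detector=None,
        background=None,
        sample_excitation=True,
        priors=None,
        draws=2000,
        proposal_sets=DEFAULT_PROPOSAL_SETS,
        burn_in=0.2,
        init_rates=None,
        random_state=None,
    ):
        self.n_states = n_states
        self.excitation_rate = excitation_rate
        self.donor_relax_rate = donor_relax_rate
        self.acceptor_relax_rate = acceptor_relax_rate
        self.detector = detector
        self.background = background
        self.sample_excitation = sample_excitation
        self.priors = priors
        self.draws = draws
        self.proposal_sets = proposal_sets
        self.burn_in = burn_in
        self.init_rates = init_rates
        self.random_state = random_state

    def _init_params(self, priors, rng):
        params = []
        init = self.init_rates or {}
        if self.sample_excitation:
            ref = priors.ex_ref or self.excitation_rate
            params.append(
                _RateParam("excitation", "ex", ref,
                           init.get("excitation", self.excitation_rate))
            )
        for i in range(self.n_states):
            for j in range(self.n_states):
                if i != j:
                    name = f"sys_{i + 1}->{j + 1}"
                    params.append(
                        _RateParam(name, "sys", priors.sys_ref,
                                   init.get(name, priors.draw_gamma(priors.sys_ref, rng)))
                    )
        for i in range(self.n_states):
            name = f"fret_{i + 1}"
            params.append(
                _RateParam(name, "fret", priors.fret_ref,
                           init.get(name, priors.draw_gamma(priors.fret_ref, rng)))
            )
        return params

    def _vectors(self, params):
        ex = self.excitation_rate
        sys_rates = np.zeros((self.n_states, self.n_states))
        fret = np.zeros(self.n_states)
        for p in params:
            if p.kind == "ex":
                ex = p.value
            elif p.kind == "sys":
                i, j = p.name[4:].split("->")
                sys_rates[int(i) - 1, int(j) - 1] = p.value
            else:
                fret[int(p.name.split("_")[1]) - 1] = p.value
        return ex, sys_rates, fret

    def fit(self, trace: PhotonTrace, y=None):
        priors = self.priors or PriorSpec()
        rng = np.random.default_rng(self.random_state)
        model = _ContinuousModel(
            self.n_states, self.donor_relax_rate, self.acceptor_relax_rate,
            self.detector, self.background,
        )
        params = self._init_params(priors, rng)

        def loglik(params_list):
            ex, sysr, fret = self._vectors(params_list)
            return model.log_likelihood(model.build(ex, sysr, fret), trace)

        current_ll = loglik(params)
        attempts = 0
        while not np.isfinite(current_ll):
            # a prior draw can land on a zero-likelihood corner; redraw
            params = self._init_params(priors, rng)
            current_ll = loglik(params)
            attempts += 1
            if attempts > 50:
                raise FloatingPointError("could not initialize chain at finite likelihood")

        names = [p.name for p in params]
        chain = np.empty((self.draws, len(params)))
        logpost = np.empty(self.draws)
        accept = {k: 0 for k in ("ex", "fret", "sys")}
        total = {k: 0 for k in ("ex", "fret", "sys")}
        for sweep in range(self.draws):
            variances = self.proposal_sets[sweep % len(self.proposal_sets)]
            for idx, p in enumerate(params):
                sigma = np.sqrt(variances[_KIND_SLOT[p.kind]])
                old = p.value
                proposal = old * np.exp(sigma * rng.standard_normal())
                p.value = proposal
                prop_ll = loglik(params)
                log_alpha = (
                    prop_ll - current_ll
                    + priors.log_gamma_prior(proposal, p.ref)
                    - priors.log_gamma_prior(old, p.ref)
                    + np.log(proposal / old)
                )
                total[p.kind] += 1
                if np.log(rng.random()) < log_alpha:
                    current_ll = prop_ll
                    accept[p.kind] += 1
                else:
                    p.value = old
            chain[sweep] = [p.value for p in params]
            logpost[sweep] = current_ll + sum(
                priors.log_gamma_prior(p.value, p.ref) for p in params
            )
        self.samples_ = pd.DataFrame(chain, columns=names)
        self.log_posterior_ = logpost
        self.acceptance_ = {
            k: (accept[k] / total[k] if total[k] else np.nan) for k in accept
        }
        self.posterior_ = PosteriorSamples(
            rates=self.samples_,
            log_posterior=logpost,
            acceptance=self.acceptance_,
            burn_in=self.burn_in,
            meta={"sampler": "parametric", "n_states": self.n_states},
        )
        return self

    def summary(self) -> pd.DataFrame:
        """Median and 5/95% quantiles per rate, plus derived escape rates and
        FRET efficiencies (post burn-in)."""
        return _summarize(self.samples_, self.burn_in, self.donor_relax_rate)

    def score(self, trace: PhotonTrace, y=None) -> float:
        """Log-likelihood at the posterior-median rates."""
        med = self.samples_.iloc[int(self.burn_in * len(self.samples_)):].median()
        model = _ContinuousModel(
            self.n_states, self.donor_relax_rate, self.acceptor_relax_rate,
            self.detector, self.background,
        )
        ex = med.get("excitation", self.excitation_rate)
        sysr = np.zeros((self.n_states, self.n_states))
        fret = np.zeros(self.n_states)
        for name, v in med.items():
            if name.startswith("sys_"):
                i, j = name[4:].split("->")
                sysr[int(i) - 1, int(j) - 1] = v
            elif name.startswith("fret_"):
                fret[int(name.split("_")[1]) - 1] = v
        return model.log_likelihood(model.build(ex, sysr, fret), trace)


class BernoulliLoadSampler(BaseEstimator):
    """Nonparametric sampler: rates plus Bernoulli loads over candidate states.

    The generator is built at the truncation size ``max_states`` with every
    element tied to the loads of the states it connects; inactive states
    contribute zero rows and columns.  Sweeps update all free rates (rates
    detached from the likelihood by inactive loads are drawn directly from
    their Gamma priors — their conditional *is* the prior) and then each load
    from its exact Bernoulli conditional.  At least one load is always
    active.  The posterior mode of the active-load count estimates the number
    of system states.
    """

    def __init__(
        self,
        max_states=10,
        expected_states=1.0,
        excitation_rate=10.0,
        donor_relax_rate=277000.0,
        acceptor_relax_rate=285000.0,
        detector=None,
        background=None,
        sample_excitation=False,
        priors=None,
        draws=1000,
        proposal_sets=DEFAULT_PROPOSAL_SETS,
        burn_in=0.2,
        include_load_prior=True,
        random_state=None,
    ):
        self.max_states = max_states
        self.expected_states = expected_states
        self.excitation_rate = excitation_rate
        self.donor_relax_rate = donor_relax_rate
        self.acceptor_relax_rate = acceptor_relax_rate
        self.detector = detector
        self.background = background
        self.sample_excitation = sample_excitation
        self.priors = priors
        self.draws = draws
        self.proposal_sets = proposal_sets
        self.burn_in = burn_in
        self.include_load_prior = include_load_prior
        self.random_state = random_state

    def fit(self, trace: PhotonTrace, y=None):
        m = self.max_states
        priors = self.priors or PriorSpec(
            max_states=m, expected_states=self.expected_states
        )
        rng = np.random.default_rng(self.random_state)
        model = _ContinuousModel(
            m, self.donor_relax_rate, self.acceptor_relax_rate,
            self.detector, self.background,
        )
        ex = self.excitation_rate
        sys_rates = np.array(
            [[priors.draw_gamma(priors.sys_ref, rng) if i != j else 0.0
              for j in range(m)] for i in range(m)]
        )
        fret = np.array([priors.draw_gamma(priors.fret_ref, rng) for _ in range(m)])
        loads = (rng.random(m) < priors.load_success).astype(np.int64)
        if loads.sum() == 0:
            loads[rng.integers(m)] = 1

        def loglik(ex_, sysr_, fret_, loads_):
            return model.log_likelihood(
                model.build(ex_, sysr_, fret_, loads_), trace, loads_
            )

        current_ll = loglik(ex, sys_rates, fret, loads)
        while not np.isfinite(current_ll):
            loads = np.zeros(m, dtype=np.int64)
            loads[rng.integers(m)] = 1
            fret = np.array([priors.draw_gamma(priors.fret_ref, rng) for _ in range(m)])
            current_ll = loglik(ex, sys_rates, fret, loads)

        names = (
            (["excitation"] if self.sample_excitation else [])
            + [f"sys_{i + 1}->{j + 1}" for i in range(m) for j in range(m) if i != j]
            + [f"fret_{i + 1}" for i in range(m)]
        )
        chain = np.empty((self.draws, len(names)))
        load_chain = np.empty((self.draws, m), dtype=np.int64)
        logpost = np.empty(self.draws)
        accept = {k: 0 for k in ("ex", "fret", "sys")}
        total = {k: 0 for k in ("ex", "fret", "sys")}

        for sweep in range(self.draws):
            variances = self.proposal_sets[sweep % len(self.proposal_sets)]

            def mh_rate(value, ref, kind, setter):
                nonlocal current_ll
                sigma = np.sqrt(variances[_KIND_SLOT[kind]])
                proposal = value * np.exp(sigma * rng.standard_normal())
                setter(proposal)
                prop_ll = loglik(ex, sys_rates, fret, loads)
                log_alpha = (
                    prop_ll - current_ll
                    + priors.log_gamma_prior(proposal, ref)
                    - priors.log_gamma_prior(value, ref)
                    + np.log(proposal / value)
                )
                total[kind] += 1
                if np.log(rng.random()) < log_alpha:
                    current_ll = prop_ll
                    accept[kind] += 1
                    return proposal
                setter(value)
                return value

            if self.sample_excitation:
                def set_ex(v):
                    nonlocal ex
                    ex = v
                ex = mh_rate(ex, priors.ex_ref or self.excitation_rate, "ex", set_ex)
            for i in range(m):
                for j in range(m):
                    if i == j:
                        continue
                    if loads[i] and loads[j]:
                        def set_sys(v, i=i, j=j):
                            sys_rates[i, j] = v
                        sys_rates[i, j] = mh_rate(
                            sys_rates[i, j], priors.sys_ref, "sys", set_sys
                        )
                    else:
                        # conditional reduces to the prior: direct draw
                        sys_rates[i, j] = priors.draw_gamma(priors.sys_ref, rng)
            for i in range(m):
                if loads[i]:
                    def set_fret(v, i=i):
                        fret[i] = v
                    fret[i] = mh_rate(fret[i], priors.fret_ref, "fret", set_fret)
                else:
                    fret[i] = priors.draw_gamma(priors.fret_ref, rng)

            # direct Bernoulli draws for the loads, one at a time
            for i in range(m):
                others = loads.sum() - loads[i]
                if others == 0:
                    loads[i] = 1  # at least one active state
                    continue
                loads_on = loads.copy(); loads_on[i] = 1
                loads_off = loads.copy(); loads_off[i] = 0
                ll_on = (current_ll if loads[i] == 1
                         else loglik(ex, sys_rates, fret, loads_on))
                ll_off = (current_ll if loads[i] == 0
                          else loglik(ex, sys_rates, fret, loads_off))
                q = load_conditional(
                    ll_on, ll_off, priors.load_success, self.include_load_prior
                )
                new = int(rng.random() < q)
                if new != loads[i]:
                    current_ll = ll_on if new else ll_off
                    loads[i] = new

            row = ([ex] if self.sample_excitation else []) + [
                sys_rates[i, j] for i in range(m) for j in range(m) if i != j
            ] + list(fret)
            chain[sweep] = row
            load_chain[sweep] = loads
            logpost[sweep] = current_ll

        self.samples_ = pd.DataFrame(chain, columns=names)
        self.loads_ = load_chain
        self.log_posterior_ = logpost
        self.acceptance_ = {
            k: (accept[k] / total[k] if total[k] else np.nan) for k in accept
        }
        post = load_chain[int(self.burn_in * self.draws):]
        counts = post.sum(axis=1)
        self.active_counts_ = counts
        self.n_states_ = int(np.bincount(counts).argmax())
        self.posterior_ = PosteriorSamples(
            rates=self.samples_,
            log_posterior=logpost,
            acceptance=self.acceptance_,
            loads=load_chain,
            burn_in=self.burn_in,
            meta={"sampler": "bernoulli-loads", "max_states": m},
        )
        return self

    def state_count_posterior(self) -> np.ndarray:
        """Posterior pmf over the number of active system states."""
        pmf = np.bincount(self.active_counts_, minlength=self.max_states + 1)
        return pmf / pmf.sum()


# ---------------------------------------------------------------------------
# pulsed illumination: truncated-iHMM sampler over transition probabilities


def _log_dirichlet(x, alpha):
    if np.any(x <= 0):
        return -np.inf
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * np.log(x)).sum()
    )


class _PulsedObservationModel:
    """Per-pulse observation probabilities given the system state.

    A pulse excites the dye pair with probability ``detection_probability``
    (folding excitation and detection efficiency together).  Given emission
    in state i, the photon is an acceptor photon with probability
    eff_i = fret_i / (fret_i + lambda_d); the donor microtime is exponential
    with the donor's total de-excitation rate lambda_d + fret_i and the
    acceptor microtime is the two-stage (hypoexponential) delay through the
    acceptor relaxation.  Truncation of the microtime densities to the pulse
    period is negligible when lifetimes << period.
    """

    def __init__(self, detection_probability, donor_relax_rate, acceptor_relax_rate,
                 channel_names=("acceptor", "donor")):
        self.p_det = detection_probability
        self.ld = donor_relax_rate
        self.la = acceptor_relax_rate
        self.acceptor_channel = channel_names.index("acceptor")

    def log_obs(self, fret_rates, ptrace: PulsedTrace) -> np.ndarray:
        """(K, Ms) log p(photon_k | state) for the recorded photons."""
        fret = np.asarray(fret_rates, dtype=float)
        r = self.ld + fret  # (Ms,) donor de-excitation rate per state
        eff = fret / r
        mu = ptrace.microtimes[:, None]  # (K, 1)
        donor_ll = np.log1p(-eff)[None] + np.log(r)[None] - r[None] * mu
        with np.errstate(divide="ignore", invalid="ignore"):
            gap = self.la - r  # sign cancels between the two factors below
            hypo = (
                np.log(eff * r * self.la / np.abs(gap))[None]
                + np.log(np.abs(np.exp(-r[None] * mu) - np.exp(-self.la * mu)))
            )
        acc_ll = np.where(np.isfinite(hypo), hypo, -np.inf)
        is_acc = (ptrace.channels == self.acceptor_channel)[:, None]
        return np.log(self.p_det) + np.where(is_acc, acc_ll, donor_ll)


class PulsedTransitionSampler(BaseEstimator):
    """Truncated-iHMM sampler for pulsed data: system transition probabilities
    and photophysical rates.

    Rows of the system propagator Pi_sigma carry truncated Dirichlet-process
    priors pi_m ~ Dirichlet(alpha * beta) with a shared base measure
    beta ~ Dirichlet(xi * gamma_vec); rows and base are updated by
    Dirichlet-random-walk Metropolis steps against the per-pulse filter
    likelihood, and the per-state FRET rates (and optionally lambda_d) by
    log-space Metropolis steps.  The effective state count is the number of
    states whose stationary weight under a draw of Pi_sigma exceeds
    ``visitation_threshold``.
    """

    def __init__(
        self,
        max_states=5,
        detection_probability=0.005,
        donor_relax_rate=277000.0,
        acceptor_relax_rate=285000.0,
        dp_concentration=1.0,
        dp_xi=1.0,
        priors=None,
        draws=1000,
        proposal_concentration=100.0,
        fret_proposal_sigma=0.3,
        visitation_threshold=0.05,
        burn_in=0.2,
        random_state=None,
    ):
        self.max_states = max_states
        self.detection_probability = detection_probability
        self.donor_relax_rate = donor_relax_rate
        self.acceptor_relax_rate = acceptor_relax_rate
        self.dp_concentration = dp_concentration
        self.dp_xi = dp_xi
        self.priors = priors
        self.draws = draws
        self.proposal_concentration = proposal_concentration
        self.fret_proposal_sigma = fret_proposal_sigma
        self.visitation_threshold = visitation_threshold
        self.burn_in = burn_in
        self.random_state = random_state

    def _loglik(self, pi, fret, obs_model, ptrace):
        """Filter over pulses: runs of empty pulses contribute
        m * log(1 - p_det) and a Pi^m propagation (mass preserved)."""
        ms = self.max_states
        logw = obs_model.log_obs(fret, ptrace)  # (K, Ms)
        n_empty_total = ptrace.n_pulses - ptrace.n_photons
        loglik = n_empty_total * np.log1p(-obs_model.p_det)
        rho = steady_state(pi - np.eye(ms), start_index=0)  # stationary of the chain
        prev = 0
        for k in range(ptrace.n_photons):
            n = ptrace.pulse_indices[k]
            gap = n - prev
            if gap > 0:
                rho = rho @ np.linalg.matrix_power(pi, gap)
            shift = logw[k].max()
            if not np.isfinite(shift):
                return -np.inf
            rho = rho * np.exp(logw[k] - shift)
            p = rho.sum()
            if not np.isfinite(p) or p <= 0:
                return -np.inf
            loglik += np.log(p) + shift
            rho = (rho / p) @ pi
            prev = n + 1
        return loglik

    def fit(self, ptrace: PulsedTrace, y=None):
        ms = self.max_states
        priors = self.priors or PriorSpec(max_states=ms)
        rng = np.random.default_rng(self.random_state)
        obs = _PulsedObservationModel(
            self.detection_probability, self.donor_relax_rate, self.acceptor_relax_rate
        )
        gamma_vec = np.full(ms, 1.0 / ms)
        beta = rng.dirichlet(np.maximum(self.dp_xi * gamma_vec, 1e-2))
        pi = np.vstack([
            rng.dirichlet(np.maximum(self.dp_concentration * beta, 1e-2))
            for _ in range(ms)
        ])
        fret = np.array([priors.draw_gamma(priors.fret_ref, rng) for _ in range(ms)])
        current_ll = self._loglik(pi, fret, obs, ptrace)
        tries = 0
        while not np.isfinite(current_ll):
            fret = np.array([priors.draw_gamma(priors.fret_ref, rng) for _ in range(ms)])
            pi = np.vstack([rng.dirichlet(np.ones(ms)) for _ in range(ms)])
            current_ll = self._loglik(pi, fret, obs, ptrace)
            tries += 1
            if tries > 50:
                raise FloatingPointError("could not initialize pulsed chain")

        pi_chain = np.empty((self.draws, ms, ms))
        fret_chain = np.empty((self.draws, ms))
        logpost = np.empty(self.draws)
        counts = np.empty(self.draws, dtype=np.int64)
        c0 = self.proposal_concentration
        floor = 1e-6

        for sweep in range(self.draws):
            # rows of Pi_sigma
            for mrow in range(ms):
                cur = np.maximum(pi[mrow], floor)
                prop = rng.dirichlet(c0 * cur)
                prop = np.maximum(prop, floor)
                prop = prop / prop.sum()
                pi_new = pi.copy()
                pi_new[mrow] = prop
                ll = self._loglik(pi_new, fret, obs, ptrace)
                log_alpha = (
                    ll - current_ll
                    + _log_dirichlet(prop, self.dp_concentration * beta)
                    - _log_dirichlet(cur, self.dp_concentration * beta)
                    + _log_dirichlet(cur, c0 * prop)
                    - _log_dirichlet(prop, c0 * cur)
                )
                if np.log(rng.random()) < log_alpha:
                    pi = pi_new
                    current_ll = ll
            # shared base measure (no likelihood term; prior + row-prior terms)
            cur_b = np.maximum(beta, floor)
            prop_b = np.maximum(rng.dirichlet(c0 * cur_b), floor)
            prop_b = prop_b / prop_b.sum()
            log_alpha = (
                _log_dirichlet(prop_b, self.dp_xi * gamma_vec)
                - _log_dirichlet(cur_b, self.dp_xi * gamma_vec)
                + sum(
                    _log_dirichlet(np.maximum(pi[r], floor), self.dp_concentration * prop_b)
                    - _log_dirichlet(np.maximum(pi[r], floor), self.dp_concentration * cur_b)
                    for r in range(ms)
                )
                + _log_dirichlet(cur_b, c0 * prop_b)
                - _log_dirichlet(prop_b, c0 * cur_b)
            )
            if np.log(rng.random()) < log_alpha:
                beta = prop_b
            # photophysical rates
            for i in range(ms):
                def lp(v, i=i):
                    f = fret.copy()
                    f[i] = v
                    return (
                        self._loglik(pi, f, obs, ptrace)
                        + priors.log_gamma_prior(v, priors.fret_ref)
                    )
                fret[i], _, _ = mh_step_log_rate(
                    fret[i], lp, self.fret_proposal_sigma, rng,
                    current_log_posterior=current_ll
                    + priors.log_gamma_prior(fret[i], priors.fret_ref),
                )
                current_ll = self._loglik(pi, fret, obs, ptrace)

            pi_chain[sweep] = pi
            fret_chain[sweep] = fret
            logpost[sweep] = current_ll
            stat = steady_state(pi - np.eye(ms))
            counts[sweep] = int((stat > self.visitation_threshold).sum())

        self.pi_samples_ = pi_chain
        self.fret_samples_ = fret_chain
        self.log_posterior_ = logpost
        self.occupancy_counts_ = counts
        post = counts[int(self.burn_in * self.draws):]
        self.n_states_ = int(np.bincount(post).argmax())
        self.samples_ = pd.DataFrame(
            np.concatenate(
                [pi_chain.reshape(self.draws, -1), fret_chain], axis=1
            ),
            columns=[f"pi_{i + 1}->{j + 1}" for i in range(ms) for j in range(ms)]
            + [f"fret_{i + 1}" for i in range(ms)],
        )
        self.posterior_ = PosteriorSamples(
            rates=self.samples_,
            log_posterior=logpost,
            acceptance={},
            burn_in=self.burn_in,
            meta={"sampler": "ihmm-pulsed", "max_states": ms},
        )
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers


def sample_parametric(trace, priors=None, config=None, **model_kwargs) -> PosteriorSamples:
    config = config or McmcConfig()
    est = ParametricRateSampler(
        priors=priors, draws=config.draws, proposal_sets=config.proposal_sets,
        burn_in=config.burn_in, random_state=config.seed, **model_kwargs,
    )
    return est.fit(trace).posterior_


def sample_nonparametric(trace, priors=None, config=None, **model_kwargs) -> PosteriorSamples:
    config = config or McmcConfig(draws=1000)
    est = BernoulliLoadSampler(
        priors=priors, draws=config.draws, proposal_sets=config.proposal_sets,
        burn_in=config.burn_in, random_state=config.seed, **model_kwargs,
    )
    est.fit(trace)
    post = est.posterior_
    post.meta["n_states_mode"] = est.n_states_
    return post


def sample_ihmm_pulsed(ptrace, priors=None, config=None, **model_kwargs) -> PosteriorSamples:
    config = config or McmcConfig(draws=1000)
    est = PulsedTransitionSampler(
        priors=priors, draws=config.draws, burn_in=config.burn_in,
        random_state=config.seed, **model_kwargs,
    )
    est.fit(ptrace)
    post = est.posterior_
    post.meta["n_states_mode"] = est.n_states_
    return post
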