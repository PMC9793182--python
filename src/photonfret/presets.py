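"""Named experiment scenarios: benchmark settings for the samplers.

Each preset encodes the generating conditions of a synthetic experiment —
excitation rate, system escape rates, FRET efficiencies, detector artifacts
and photon budget — in milliseconds / ms^-1.  ``full`` photon budgets match
headline benchmark runs (hundreds of thousands of photons, hours of MCMC);
``scaled`` budgets give desk-scale runs with the same physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import DetectorModel
from .statespace import (
    BackgroundSpec,
    PhotophysicsSpec,
    SystemKinetics,
    build_composite_generator,
    efficiency_to_fret_rate,
)

__all__ = ["SCENARIOS", "Scenario", "get_scenario", "run_scenario"]

# calibration constants shared by the two-channel scenarios
LD = 277000.0  # donor relaxation, ms^-1 (3.6 ns lifetime)
LA = 285000.0  # acceptor relaxation, ms^-1 (3.5 ns lifetime)


@dataclass
class Scenario:
    name: str
    excitation_rate: float
    system_rates: np.ndarray
    efficiencies: tuple
    full_photons: int
    scaled_photons: int
    donor_relax_rate: float = LD
    acceptor_relax_rate: float = LA
    detector: DetectorModel | None = None
    background: BackgroundSpec | None = None
    sampler: str = "parametric"  # or "loads" / "pulsed"
    draws_scaled: int = 1200
    draws_full: int = 9000
    pulsed: dict | None = None
    notes: str = ""

    def fret_rates(self):
        return tuple(
            efficiency_to_fret_rate(e, self.donor_relax_rate) for e in self.efficiencies
        )

    def generator(self):
        system = SystemKinetics(self.system_rates)
        photo = PhotophysicsSpec(
            excitation_rate=self.excitation_rate,
            donor_relax_rate=self.donor_relax_rate,
            acceptor_relax_rate=self.acceptor_relax_rate,
            fret_rates=self.fret_rates(),
        )
        return build_composite_generator(system, photo)


def _two_state_rates(esc1=1.0, esc2=2.0):
    return np.array([[0.0, esc1], [esc2, 0.0]])


def _crosstalk_detector(donor_to_acceptor=0.05):
    # channel order (acceptor, donor): acceptor photons stay put, a fraction
    # of donor photons bleeds into the acceptor channel
    return DetectorModel(
        routing=np.array([[1.0, 0.0], [donor_to_acceptor, 1.0 - donor_to_acceptor]])
    )


SCENARIOS = {
    # two system states, escape rates 1 and 2 ms^-1, efficiencies 0.09 / 0.29
    "two-state-base": Scenario(
        name="two-state-base",
        excitation_rate=10.0,
        system_rates=_two_state_rates(),
        efficiencies=(0.09, 0.29),
        full_photons=430_000,
        scaled_photons=50_000,
        notes="baseline parametric benchmark",
    ),
    "fast-kinetics-slow": Scenario(
        name="fast-kinetics-slow",
        excitation_rate=10.0,
        system_rates=np.array([[0.0, 0.1], [0.1, 0.0]]),
        efficiencies=(0.09, 0.29),
        full_photons=670_000,
        scaled_photons=30_000,
    ),
    "fast-kinetics-mid": Scenario(
        name="fast-kinetics-mid",
        excitation_rate=10.0,
        system_rates=np.array([[0.0, 10.0], [10.0, 0.0]]),
        efficiencies=(0.09, 0.29),
        full_photons=670_000,
        scaled_photons=30_000,
    ),
    "fast-kinetics-fast": Scenario(
        name="fast-kinetics-fast",
        excitation_rate=10.0,
        system_rates=np.array([[0.0, 1000.0], [1000.0, 0.0]]),
        efficiencies=(0.09, 0.29),
        full_photons=670_000,
        scaled_photons=30_000,
        notes="kinetics far above the excitation rate: efficiencies merge toward "
        "their midpoint (~0.185)",
    ),
    "crosstalk": Scenario(
        name="crosstalk",
        excitation_rate=10.0,
        system_rates=_two_state_rates(),
        efficiencies=(0.09, 0.29),
        full_photons=430_000,
        scaled_photons=25_000,
        detector=_crosstalk_detector(0.05),
        notes="5% of donor photons detected by the acceptor channel",
    ),
    "background": Scenario(
        name="background",
        excitation_rate=10.0,
        system_rates=_two_state_rates(),
        efficiencies=(0.09, 0.29),
        full_photons=430_000,
        scaled_photons=12_000,
        background=BackgroundSpec((1.0, 1.0)),  # lambda_ex / 10 per channel
    ),
    "irf-single-dye": Scenario(
        name="irf-single-dye",
        excitation_rate=1e4,  # 0.01 ns^-1
        system_rates=np.array([[0.0]]),
        efficiencies=(0.0,),
        donor_relax_rate=2e6,  # 2 ns^-1
        acceptor_relax_rate=LA,
        full_photons=200_000,
        scaled_photons=20_000,
        detector=DetectorModel.with_truncated_gaussian_irf(
            routing=np.eye(2),
            mean=4.8e-8,  # 48 ps
            width=2.4e-8,
            support=9.6e-8,  # ~96 ps wide
            resolution=1.6e-8,  # 16 ps acquisition grid
        ),
        notes="single fluorophore, no FRET; timestamp jitter comparable to the "
        "excited-state lifetime",
    ),
    "pulsed-three-state": Scenario(
        name="pulsed-three-state",
        excitation_rate=0.0,  # pulsed: excitation enters via per-pulse probability
        system_rates=np.array(
            [[0.0, 0.6, 0.6], [0.6, 0.0, 0.6], [1.2, 1.2, 0.0]]
        ),  # escape rates 1.2, 1.2, 2.4 ms^-1
        efficiencies=(0.1, 0.55, 0.72),
        full_photons=120_000,
        scaled_photons=4_000,
        sampler="pulsed",
        pulsed={"period": 2.5e-5, "pulse_width": 2.5e-6, "excitation_probability": 0.005},
        notes="three system states under 25 ns pulsing; the two high-efficiency "
        "states merge under a forced two-state fit",
    ),
}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


def run_scenario(name, seed, outdir, scaled=True, draws=None, photons=None):
    """Simulate a scenario, fit the matching sampler, write trace + summary.

    Returns the fitted estimator.  Identical seeds give identical outputs.
    """
    from pathlib import Path

    from .inference import (
        BernoulliLoadSampler,
        ParametricRateSampler,
        PulsedTransitionSampler,
    )
    from .io import summarize_posterior, write_photon_trace, write_posterior
    from .simulate import simulate_trace

    sc = get_scenario(name)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_photons = photons or (sc.scaled_photons if scaled else sc.full_photons)
    n_draws = draws or (sc.draws_scaled if scaled else sc.draws_full)

    if sc.sampler == "pulsed":
        from .simulate import simulate_pulsed_trace

        # per-pulse excitation probability -> excitation rate over the pulse
        p = sc.pulsed
        lex = -np.log1p(-p["excitation_probability"]) / p["pulse_width"]
        system = SystemKinetics(sc.system_rates)
        photo = PhotophysicsSpec(
            excitation_rate=lex,
            donor_relax_rate=sc.donor_relax_rate,
            acceptor_relax_rate=sc.acceptor_relax_rate,
            fret_rates=sc.fret_rates(),
        )
        gen = build_composite_generator(system, photo)
        n_pulses = int(np.ceil(n_photons / p["excitation_probability"]))
        ptrace = simulate_pulsed_trace(
            gen, p["period"], p["pulse_width"], n_pulses, rng=rng
        )
        write_photon_trace(ptrace, outdir / f"{name}_trace.tsv")
        est = PulsedTransitionSampler(
            max_states=5,
            detection_probability=p["excitation_probability"],
            donor_relax_rate=sc.donor_relax_rate,
            acceptor_relax_rate=sc.acceptor_relax_rate,
            draws=n_draws,
            random_state=seed,
        ).fit(ptrace)
    else:
        trace = simulate_trace(
            sc.generator(),
            det=sc.detector,
            background=sc.background,
            n_photons=n_photons,
            rng=rng,
        )
        write_photon_trace(trace, outdir / f"{name}_trace.tsv")
        est = ParametricRateSampler(
            n_states=sc.system_rates.shape[0],
            excitation_rate=sc.excitation_rate,
            donor_relax_rate=sc.donor_relax_rate,
            acceptor_relax_rate=sc.acceptor_relax_rate,
            detector=sc.detector,
            background=sc.background,
            draws=n_draws,
            random_state=seed,
        ).fit(trace)
    write_posterior(est.posterior_, outdir / f"{name}_posterior")
    summary = summarize_posterior(est.posterior_, donor_relax_rate=sc.donor_relax_rate)
    summary.to_csv(outdir / f"{name}_summary.tsv", sep="\t")
    return est
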