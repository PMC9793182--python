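# photonfret

Photon-by-photon analysis of single-molecule FRET (smFRET) experiments:
a forward model for single-photon arrival data with realistic detector
physics, and Bayesian samplers that learn conformational kinetics — and the
number of conformational states — directly from the raw photon record.

**Who it is for.** Single-molecule biophysicists with smFRET traces from
immobilized molecules (continuous or pulsed illumination) who want full
posterior distributions over transition rates without binning away
sub-bin kinetics, and methods developers who need a clean, tested
implementation of the photon-level likelihood to build on.

## The model in brief

A labeled molecule hops among discrete conformational states σ while its
dye pair cycles through photophysical states ψ; the composite evolves as a
Markov jump process over superstates φ = (σ, ψ) with generator matrix G
(zero row sums, photophysical blocks on the diagonal, conformational rates
λ_{σi→σj}·I off it). Photon detections constrain the allowed transitions,
giving the likelihood of a trace with photons at T₁ < ... < T_K in
channels c₁...c_K:

```
L ∝ ρ_start · e^{ΔT₁ G_non} G_rad,c₁ · e^{ΔT₂ G_non} G_rad,c₂ ··· e^{ΔT_end G_non} · 1ᵀ
```

where G_non masks out detectable radiative transitions and G_rad,c keeps
only those routed to channel c. Crosstalk and finite detection efficiency
enter through the routing matrix φ_{ji}; dead time and the instrument
response function (timestamp jitter) insert extra propagators; background
enters by Kronecker-summing fictitious two-state emitters onto G. Everything
is computed by a normalized filter recursion (no underflow), with the hot
path running in the eigenbasis of G_non under numba.

Inference is Metropolis-within-Gibbs with log-space random-walk proposals
and Gamma priors on rates. The number of states is learned by Bernoulli
"loads" that switch candidate states on and off (posterior mode of the
active count = state count), or, for pulsed data, by a truncated
infinite-HMM over the per-pulse transition matrix.

## Worked example

The two-state pedagogical composite: excitation 10 ms⁻¹, conformational
rates 2 and 1 ms⁻¹, donor/acceptor lifetimes 3.6/3.5 ns, FRET rates
7·10⁴ and 2.5·10⁶ ms⁻¹ (efficiencies ≈ 0.2 and 0.9). Two photons are
recorded: channel 1 (acceptor) at 0.05 ms, channel 2 (donor) at 0.15 ms.

```python
import numpy as np
from photonfret import (SystemKinetics, PhotophysicsSpec, PhotonTrace,
                        build_composite_generator, log_likelihood_continuous)

gen = build_composite_generator(
    SystemKinetics([[0.0, 2.0], [1.0, 0.0]]),
    PhotophysicsSpec(excitation_rate=10.0,
                     donor_relax_rate=1e6 / 3.6,
                     acceptor_relax_rate=1e6 / 3.5,
                     fret_rates=(70000.0, 2500000.0)))
trace = PhotonTrace(times=[0.05, 0.15], channels=[0, 1], t_end=0.15)
ll = log_likelihood_continuous(gen, trace,
                               rho_start=np.array([1.0, 0, 0, 0, 0, 0]),
                               include_end=False)
print(round(np.exp(ll), 2))   # prints: 3.06
```

The printed number is the likelihood with the ε^K prefactor dropped: the
probability density (per ms²) of exactly this two-photon record starting
from the all-ground superstate.

Fitting rates from a simulated 50 000-photon trace:

```python
from photonfret import ParametricRateSampler, simulate_trace, efficiency_to_fret_rate

ld = 277000.0
gen = build_composite_generator(
    SystemKinetics([[0.0, 1.0], [2.0, 0.0]]),
    PhotophysicsSpec(10.0, ld, 285000.0,
                     tuple(efficiency_to_fret_rate(e, ld) for e in (0.09, 0.29))))
trace = simulate_trace(gen, n_photons=50000, rng=101)
est = ParametricRateSampler(n_states=2, donor_relax_rate=ld,
                            acceptor_relax_rate=285000.0,
                            draws=2000, random_state=11).fit(trace)
print(est.summary().round(3))
```

which prints (2000 sweeps, ~2.5 min on one core; state labels may swap):

```
                      q5         q50          q95
excitation         9.894       9.960       10.028
sys_1->2           1.435       1.823        2.221
sys_2->1           0.566       0.746        1.098
fret_1        108284.764  119851.937   135283.092
fret_2         27276.872   31384.520    34938.456
efficiency_1       0.281       0.302        0.328
efficiency_2       0.090       0.102        0.112
escape_1           1.435       1.823        2.221
escape_2           0.566       0.746        1.098
```

— the 90% credible intervals cover the generating values (escape rates
2 and 1 ms⁻¹, efficiencies 0.29 and 0.09) at this reduced photon budget.

A CLI wraps the same functionality
(`photonfret simulate | likelihood | fit | fit-bnp | fit-pulsed |
calibrate-rcm | scenario`); every run writes a JSON metadata file
sufficient to replay it. `photonfret scenario --name two-state-base --seed 0
--out runs/` reproduces a named benchmark end to end; see
`photonfret.presets.SCENARIOS` for the list.

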