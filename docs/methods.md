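# Methods

## Model

`photonfret` treats a surface-immobilized molecule labeled with a FRET dye
pair as a continuous-time Markov jump process over *superstates*
φ = (σ, ψ): the molecule's conformational ("system") state σ among a
discrete set of M_σ states, paired with the photophysical state ψ of the dye
pair (both dyes ground; donor excited; acceptor excited; optionally a
dark/bleached state). The process is generated by an
M_φ × M_φ rate matrix G (M_φ = M_σ·M_ψ) with photophysical blocks on the
block diagonal and system rates λ_{σi→σj}·I off it; simultaneous system and
photophysical transitions are excluded (rate zero), and diagonals are
negative row sums. Within a system state the photophysical block carries the
excitation rate λ_ex, donor and acceptor relaxation rates λ_d and λ_a,
the state-specific transfer rate λ_FRET(σ), and optionally direct acceptor
excitation, photobleaching or blinking. The FRET efficiency of a state is
λ_FRET/(λ_FRET+λ_d), the acceptor fraction of its emitted photons.

Two transition families are radiative: donor relaxation ψ₂→ψ₁ (a
donor-colored photon) and acceptor relaxation ψ₃→ψ₁ (an acceptor-colored
photon). We keep these as boolean masks per detection channel. Channel
**1 is the acceptor channel and channel 2 the donor channel** (this matches
the convention used by the worked two-photon example below; internal indices
are 0-based, file formats 1-based).

Background photons are modeled as independent fictitious two-state emitters,
one per channel, each of whose transitions (at rate λ_bg) emits into its
channel; the joint generator is the Kronecker sum of the composite generator
with the 2×2 emitter generators, and the radiative masks extend accordingly.

## Likelihood

Observations partially collapse the superstate: a photon in channel i at
time T_k admits only the radiative transitions routed to i at that instant,
while a photon-free stretch admits only undetected evolution. Each
observation multiplies the propagator elementwise by a *detection matrix*:

- nonradiative: 1 on nonradiative transitions, 1 − Σ_i φ_{ji} on transitions
  radiative for intended channel j (φ_{ji} = probability a photon intended
  for j registers in i; rows of φ may sum to < 1, the deficit being
  undetected photons);
- radiative for registration channel i: φ_{ji} on channel-j radiative
  transitions, 0 elsewhere.

With G_non = G ⊙ D_non and G_rad,i = G ⊙ D_rad,i, the photon-by-photon
likelihood is the alternating product

L / ε^K = ρ_start · exp(ΔT₁ G_non) G_rad,c₁ · exp(ΔT₂ G_non) G_rad,c₂ ···
exp(ΔT_end G_non) · 1ᵀ,

where ρ_start defaults to the stationary distribution of G (solved from
ρG = 0; for reducible generators, the stationary law of the closed class
reachable from the all-ground superstate) and the constant ε^K prefactor is
always dropped. The trailing factor to the experiment end is included by
default; the worked-example value 3.06 terminates at the last photon
(`include_end=False`), and both modes are exposed.

**Numerics.** All products run through a normalize-and-accumulate-log
recursion, so underflow is impossible by construction. The hot path
diagonalizes G_non once per evaluation and performs the whole recursion in
its eigenbasis (complex scalar exponentials plus small mat-vecs, compiled
with numba); the decomposition is accepted only if the reconstruction
residual is below 1e−7 relative, otherwise a dense scaling-and-squaring
(`scipy.linalg.expm`) path is used. Rates span six orders of magnitude
(~1 ms⁻¹ system rates vs ~3·10⁵ ms⁻¹ relaxation), which the eigen/expm
paths handle; naive series expansion is never used. When G_non conserves
mass exactly (no detection at all), the recursion shortcuts to the exact
answer L = 1 rather than accumulating matrix-exponential rounding.

**Dead time.** After a registration in channel i the channel is blind for a
calibrated interval δ_i. The likelihood inserts, after each photon's
radiative jump, a dead-window propagator and shortens the following
nonradiative stretch by δ. During the window, transitions intended for the
dead channel are *unconstrained* (they go unobserved), while transitions
intended for still-active channels carry their no-registration probability —
for a single ideal channel the dead-window propagator is exp(δG) with the
full generator, and detection blindness only widens posteriors rather than
biasing them. A photon recorded inside its own channel's dead window is a
data inconsistency and is rejected. Overlapping windows of different
channels are treated independently (each channel masks only its own
window); the residual overlap correction is quadratic in δ/gap and ignored.

**IRF.** Timestamp jitter is a stochastic delay τ between photon arrival
and its record, with density f discretized on the acquisition grid
(midpoint mass, renormalized; the bundled truncated-Gaussian constructor
covers the common calibration form). Each photon factor becomes the
discrete convolution Σ_b f(τ_b) · Π_non(ΔT_k − τ_b) · G_rad · Π_dead(τ_b + δ),
reflecting that the radiative transition happened τ_b before the timestamp
and the channel stays blind through the delay plus its nominal dead time.
The convolution assumes IRF support well below interphoton gaps (a warning
fires otherwise); delay branches longer than the gap carry zero probability.

**Binned traces.** When only per-bin channel counts are available, the
filter runs over system states alone: Π_σ = exp(ε G_σ) weighted per bin by
p(counts | σ_i). This requires ε·λ_sys ≪ 1 (state constant within a bin;
warned at ε·λ > 0.1) and slow excitation. The default observation model is
independent Poisson counts with means ε·λ_ex split by the state's
efficiency, pushed through the routing matrix and augmented by background
rates; it is pluggable — any object with `log_prob(counts) -> (N, Mσ)`
works.

**Pulsed illumination.** With pulses of width δ_pulse every τ, each
interpulse period contributes Q_n = Π_pulse·Π_dark, with
Π_pulse = exp(δ_pulse·G_non) (constant intensity during the pulse — the
closed form; a time-varying profile would need quadrature) and Π_dark built
from G with the laser-driven rates zeroed. A photon's radiative jump is
inserted at its microtime, inside the pulse or in the dark stretch, with the
IRF convolution applied to dark-period photons. Runs of photon-free pulses
are advanced by eigen-powers of the fixed empty-pulse propagator.

The photon budget index s = K·λ_ex/(λ_probe·M_σ) summarizes whether K
photons can resolve an escape rate λ_probe; s ≳ 10⁶ is the rule-of-thumb
adequacy threshold (~15% error).

## Simulation

The Gillespie algorithm samples the jump chain exactly: holding times are
exponential with the occupied superstate's escape rate, jump targets
categorical with probability rate/escape-rate, and every realized radiative
transition records an emission with its intended channel. The measurement
layer then routes each emission through φ (or drops it), adds an IRF delay
draw, discards photons landing in their own channel's dead window
(registered photons — including background — trigger dead time; photons
lost to inefficiency do not), quantizes to the acquisition grid and breaks
ties with one-grid-quantum offsets. Background photons are per-channel
Poisson processes merged into the emission stream before the detector
layer. One RNG stream with a fixed draw order (jump, holding; routing, IRF
delay per emission) makes traces bit-reproducible from a seed; the
photon-count stop rule counts registered photons.

What the generator does *not* emulate: diffusion through a confocal volume,
spatially varying excitation, afterpulsing and detector dark current beyond
the constant background term. Passing tests therefore demonstrate
correctness of the inference machinery under the stated generative model,
not robustness to these additional real-data effects.

## Inference

All samplers are Metropolis-within-Gibbs over the exact photon-by-photon
likelihood, with ρ_start recomputed as the steady state at every proposal.
Individual rates get independent Gamma(α, mean λ_ref) priors — we read the
Gamma's second hyperparameter as the prior *mean* (α=1 with mean 10⁶ ms⁻¹ =
1 ns⁻¹ for FRET rates and 1 ms⁻¹ = 10⁻⁶ ns⁻¹ for system rates by default,
i.e. essentially flat in the decades of interest). Updates propose
log λ* ~ Normal(log λ, σ²) and accept with min{1, posterior-ratio · λ*/λ}
(the λ*/λ factor is the Jacobian of the log transform). Two proposal
variance sets, {σ²_ex, σ²_FRET, σ²_sys} = {10⁻⁵, 0.01, 0.1} and
{10⁻⁵, 0.5, 5.0}, alternate with sweep parity so both local refinement and
decade-scale jumps are proposed. Donor/acceptor relaxation and background
rates are treated as precalibrated constants. The excitation rate may be
sampled (with the deliberately tiny σ²_ex); because that variance cannot
traverse decades, λ_ex initializes at its supplied calibrated value, while
all other free rates initialize from their priors. Chains are reported raw —
label switching is not post-processed; recovery checks compare states
sorted by posterior-median efficiency. Default burn-in for summaries is the
first 20% of draws.

**Bernoulli loads (unknown state count).** The generator is built at a
truncation M_σ^max with every element tied to binary loads b_i: rates
between states i and j carry b_i·b_j, and an inactive state's photophysical
block is zeroed, leaving its superstates unreachable; ρ_start is the steady
state restricted to active blocks. Loads carry Bernoulli priors with
success γ/(γ + M_σ^max − 1), which fixes the a-priori expected state count
to γ as the truncation grows. Each sweep updates all rates (a rate detached
from the likelihood by inactive loads has its prior as exact conditional
and is drawn from it directly) and then each load from its exact Bernoulli
conditional q_i ∝ p₁·L(b_i=1) (computed with log-sum-exp; a configuration
switch drops the prior weights to reproduce the pure likelihood-ratio
form, which is only correct at prior success ½). At least one load is
always active. The posterior mode of Σb_i estimates the number of system
states.

**Pulsed (truncated iHMM).** For pulsed data the sampler learns the
M_σ × M_σ per-pulse transition matrix Π_σ directly: rows carry truncated
Dirichlet-process priors π_m ~ Dirichlet(α·β) with a shared base
β ~ Dirichlet(ξ·γ_vec), γ_vec = 1/M_σ^max. Rows and base are updated by
Dirichlet random-walk Metropolis (proposal concentration 100, floor 10⁻⁶
for numerical support) against a per-pulse filter; per-state FRET rates are
updated by the same log-space Metropolis step. The per-pulse observation
model folds excitation and detection into a constant per-pulse detection
probability; given emission in state i a photon is acceptor-colored with
probability eff_i, donor microtimes are exponential with rate λ_d+λ_FRET,i
and acceptor microtimes hypoexponential through λ_a (truncation of these
densities to the pulse period is neglected since lifetimes ≪ period). The
effective state count is the number of states whose stationary weight under
a draw of Π_σ exceeds a visitation threshold (default 0.05). This
observation model is deliberately structural — it ignores the within-pulse
excitation spread — and is the package's simplification for pulsed data.

## Benchmarks and problem sizes

The bundled scenario presets encode the synthetic benchmark conditions in
ms/ms⁻¹: a two-state system with escape rates 1 and 2 ms⁻¹, efficiencies
0.09/0.29, λ_ex = 10 ms⁻¹, λ_d = 277000 ms⁻¹, λ_a = 285000 ms⁻¹; crosstalk
(5% of donor photons into the acceptor channel); background (1 ms⁻¹ =
λ_ex/10 per channel); a fast-kinetics series (0.1/10/1000 ms⁻¹); an
IRF-dominated single dye (λ_d = 2 ns⁻¹, truncated-Gaussian IRF, 48 ps mean,
~96 ps support, 16 ps grid); and a three-state pulsed scenario (escape
rates 1.2/1.2/2.4 ms⁻¹, 25 ns period, excitation probability 0.005 per
pulse). Full-size photon budgets (430k–670k photons, 9000 sweeps) are what
the headline benchmark figures use and take hours; the test suite and the
`--scaled` presets run the same physics at desk scale — 50 000 photons /
2000 sweeps for the recovery benchmark, 20 000 / 1200 for crosstalk,
10 000 / 800 for background, 10 000 photons / 400 sweeps for the
nonparametric state count — sizes chosen so the posterior is still
informative while a full run completes in minutes. At these scales credible
intervals are several times wider than at full budget; the recovery test
asserts 95% coverage, and the artifact tests assert bias *directions*, not
the full-budget point estimates.

## Known limitations

- The dead-time and IRF likelihood paths use dense matrix products; they are
  meant for calibration-scale traces, not 10⁵-photon fits.
- The binned likelihood implements only the standard slow-kinetics,
  slow-excitation approximation; the exact binned sum is out of scope.
- The pulsed observation model marginalizes photophysics per pulse with the
  simplifications above; within-pulse photon IRF convolution is applied only
  to dark-period photons.
- Nonparametric chains can transiently over-activate states before
  consolidating; state-count summaries should discard burn-in generously.
- No convergence diagnostics beyond acceptance counters and raw chains are
  provided; inspect trace plots for long runs.
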