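# kinetoswitch

Analysis of **sister-kinetochore directional switching** in metaphase
cells: a Markov-switching autoregressive model of paired kinetochore
motion, Bayesian MCMC inference of its parameters and hidden
polymerisation states, detection and classification of directional
switching events, and the event-aligned mechanical signatures
(inter-sister distance, stretch, twist) used to study how the two sisters
coordinate their reversals.

It is written for people who track kinetochores at high frame rate
(~2 s/frame) and want to turn paired 3D trajectories into switching-event
statistics — and for anyone who wants to study the switching model itself
through simulation.

## The model

Each sister kinetochore `k = 1, 2` sits at a signed distance `X^k` from
the metaphase plate along its normal (nm; sister 1 on the positive side,
so typically `X¹ > X²`).  Its K-fibre is either polymerising (`σ^k = +`)
or depolymerising (`σ^k = −`), and frame-to-frame displacements follow

```
ΔX¹ =  c₀ + c(σ¹) − a·X¹ + b·X² + N(0, s²)
ΔX² = −c₀ − c(σ²) − a·X² + b·X¹ + N(0, s²)
```

with `c(+) = c₊ > 0`, `c(−) = c₋ < 0`.  `a` relaxes each sister towards
the plate, `b` couples the sisters through the centromeric spring, and
with the switching drives off the pair relaxes to an inter-sister
separation of `2c₀/(b+a)`.  The pair state `(σ¹, σ²) ∈ {++, +−, −+, −−}`
is a hidden Markov chain: per frame one sister flips with probability
`p_coh` out of a coherent state (`+−`, `−+`) and `p_inc` out of an
incoherent one, the flipping sister chosen at random.  When `a > b` and
`p_inc > p_coh` this produces the stochastic saw-tooth oscillations seen
in live cells.

A Gibbs/Metropolis–Hastings sampler draws from the joint posterior
`π(a, b, c₀, c₊, c₋, s², p, σ | X)` per trajectory.  Only the summed
drives `c₀+c₊` and `c₀+c₋` are visible in the data; `c₀` itself is
identified by a prior on the relaxed separation `2c₀/(b+a)` — the
counterpart of measuring the centromere rest length (788 nm) after
depolymerising all microtubules.

From the inferred states the pipeline extracts **coherent runs** (≥ 5
frames of unchanged co-directional motion) and classifies each reversal
as **LIDS** (lead/depolymerising sister switches first), **TIDS**
(trailing sister first) or **JDS** (both within one frame).

## Worked example

Fit one simulated 150-frame trajectory and inspect the posterior
(`examples/02_fit_trajectory_mcmc.py`):

```
posterior means (truth in brackets):
  a                  0.055 +-    0.001   [0.056]
  b                  0.038 +-    0.001   [0.04]
  c0               646.830 +-   14.926   [667.0]
  c_plus            34.543 +-    9.946   [30.0]
  c_minus          -97.790 +-    9.917   [-100.0]
  s2              1131.236 +-   93.412   [1000.0]
  p_incoherent       0.278 +-    0.155   [0.39]
  p_coherent         0.023 +-    0.013   [0.063]

convergence: R-hat max 1.008 (< 1.1), cross-chain modal-state agreement
100.0% (>= 90%) -> converged
modal state path matches the true hidden states on 99.3% of frames
```

The relaxation/coupling coefficients and drives are recovered within
their posterior spread, the chains agree, and the per-frame hidden
polymerisation states are almost perfectly reconstructed — the state path
is what the downstream event detection consumes.  The other examples
cover simulation (`01`), event detection and statistics (`03`),
event-aligned and run-rescaled signatures (`04`), 3D plate geometry
(`05`) and the end-to-end CSV pipeline (`06`); each prints the numbers it
computes with a line on what they mean.

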