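# Methods

## Model

Paired sister-kinetochore motion along the metaphase-plate normal is
modelled as a linear autoregressive process whose constant drive switches
with the hidden polymerisation state of each sister's K-fibre:

```
ΔX¹_t =  c₀ + c(σ¹_t) − a·X¹_t + b·X²_t + ε¹_t
ΔX²_t = −c₀ − c(σ²_t) − a·X²_t + b·X¹_t + ε²_t ,   ε ~ N(0, s²) i.i.d.
```

Internal units are nanometres and frames (frame interval `dt`, default
2 s).  The drive signs are opposite because the two K-fibres point at
opposite poles; `c(+) = c_plus > 0` (polymerising state), `c(−) = c_minus
< 0` (depolymerising).  Switching is a 4-state Markov chain on
`(σ¹, σ²)`: per frame, exactly one sister may flip — with probability
`p_coherent` when the pair is coherent (`+−` or `−+`) and `p_incoherent`
when incoherent — the flipper chosen uniformly.  Exponential waiting
times are thus realised as geometric waiting times at frame resolution.
A *forced* simulation variant additionally forbids the sister who
switched last from flipping while incoherent, so every excursion out of
coherence completes a directional switch.

Assumptions worth keeping in mind: noise is Gaussian, homoscedastic and
shared between sisters; switching carries no memory, position or tension
dependence (this neutrality is what lets biases in data be attributed to
biology rather than to the detector); and the same `a`, `b` apply to both
sisters.

### Reference parameter set

`SIMULATION_PARAMS` — the regime used throughout the simulation study
because it produces qualitatively realistic saw-tooth oscillations:

| parameter | value | units | role |
|---|---|---|---|
| a | 0.056 | /frame | relaxation towards the plate |
| b | 0.040 | /frame | sister–sister coupling |
| c0 | 667 | nm/frame | baseline (tension-maintaining) drive |
| c_plus | +30 | nm/frame | polymerising drive component |
| c_minus | −100 | nm/frame | depolymerising drive component |
| s2 | 1000 | nm² | displacement noise variance |
| p_incoherent | 0.39 | /frame | switch probability out of `++`/`−−` |
| p_coherent | 0.063 | /frame | switch probability out of `+−`/`−+` |
| dt | 2 | s | frame interval |

The noise value reads a variance quoted in µm² (1/1000 µm² = 1000 nm²,
SD ≈ 31.6 nm); a literal nm² reading would make the noise physically
negligible.  The quoted depolymerising drive magnitude (100 nm) is
stored negative.  Note an important quirk: at this parameter set the
relaxed separation `2c₀/(b+a) ≈ 13.9 µm` and the coherent-state
equilibrium separation `(2c₀+c₊+c₋)/(a+b) ≈ 13.2 µm` are an order of
magnitude above the biological ~0.9 µm scale.  The simulator reproduces
the regime literally and does not rescale; consequences are flagged
below.  Defaults for the initial condition (unstated in the source
regime): `x1 = +450`, `x2 = −450` nm, initial state uniform over the two
coherent states.

## Inference

One trajectory at a time (no hierarchical pooling), requiring ≥ 112
consecutive gap-free frames (75 % of a 150-frame movie).  The sampler
cycles four blocks per iteration:

1. **Hidden states.**  Default: an exact forward-filter/backward-sample
   (FFBS) draw of the whole path given parameters, using the 4×4
   transition matrix and per-frame Gaussian observation likelihoods.  A
   single-site Gibbs sweep is available behind `ChainConfig.state_sampler
   = "single_site"`; both target the same posterior (verified against
   brute-force path enumeration on a 6-frame toy), but single-site moves
   between the two coherent states only through multi-sweep excursions
   via `++`/`−−` (the direct transition has probability zero) and mixes
   too slowly for production use.
2. **Switch probabilities.**  Beta(1,1)-conjugate draws from
   switch/no-switch counts, classed by the coherence of the departing
   state.
3. **Linear coefficients.**  Conditional on the path, the model is linear
   — but exactly singular in `(c₀, c₊, c₋)`: the `c₀` regressor equals
   the sum of the two drive indicators, so only `γ₊ = c₀+c₊` and
   `γ₋ = c₀+c₋` are identifiable.  The sampler draws `(γ₊, γ₋, a, b)`
   from the conjugate multivariate normal given `s²` (an independence
   Metropolis–Hastings step: sign-constraint violations reject, and the
   acceptance ratio is the rest-length prior density ratio, since the
   prior on `2c₀/(b+a)` depends on `a+b`).  A drive state never visited
   by the path leaves its coefficient at the current value (logged).
4. **`c₀` and noise.**  `c₀` has an exact conditional: the normal
   rest-length prior on `L = 2c₀/(b+a)` transforms to a normal in `c₀`,
   truncated to `(max(0, γ₋), γ₊)` by the sign constraints
   `c₊ > 0 > c₋`, `c₀ > 0`; sampled by inverse-CDF (kept strictly
   interior by a relative 1e−6 margin).  `s²` is a conjugate
   inverse-gamma draw (prior IG(1, 1), i.e. weakly informative) from the
   residual sum of squares pooled over both sisters.

The rest-length prior (`Priors.rest_length_mean`, default 788 nm;
`rest_length_sd`, default 100 nm) is therefore not a nuisance: it is the
*only* information that splits `c₀` from the drives.  With a prior that
is flat across `(γ₋, γ₊)` the `c₀` posterior is essentially uniform on
that ~130 nm window, which biases the recovered `c₊` by tens of nm.  The
simulation-study protocol (`validation.study_priors`) accordingly centres
the prior on the generative model's own implied equilibrium separation —
the simulation analogue of measuring the rest length experimentally —
with a 200 nm SD (≈ 1.4 % of the implied rest length).

**Initialisation and chains.**  States are initialised from the sign of
3-frame-smoothed residuals of a state-free AR fit (a raw displacement
threshold fails because the relaxation term dominates the displacement
variance); parameters from least squares given that path, jittered
per chain (log-normal, SD 0.15) for dispersion.  Defaults: 3 chains,
2000 burn-in + 4000 draws (the cohort protocol uses 2 chains,
1000 + 2000, which keeps one trajectory under ~1.5 s).

**Convergence and exclusion.**  Split-chain R̂ < 1.1 on all eight
parameters and ≥ 90 % cross-chain agreement of per-frame modal states
(thresholds configurable).  Non-convergence is a verdict, not an error:
the trajectory is flagged excluded and dropped from parameter-level
cohort summaries.  On simulated cohorts at the reference parameters
~15–20 % of fits are flagged, echoing the exclusion rate seen on real
tracks with weak oscillatory signal.

## Event detection and classification

The point state estimate is the per-frame modal state of the pooled
posterior marginals, ties broken towards the previous frame (persistence).
Coherent runs are maximal constant coherent-state intervals of ≥ 5 frames.
Consecutive opposite-direction runs define a directional switching event;
each sister's switch frame is the flip that persists into the following
run.  Same-direction consecutive runs are reverts and yield no event.

The *lead* sister of an event is the depolymerising sister of the
preceding run (state-based, robust to velocity noise).  In this model's
sign convention that is the rear sister of the drift direction — the
labels attached to `+`/`−` matter less than consistency, since truth
bookkeeping and detection share the same rule and the generative rules
are lead/trail symmetric.  LIDS: lead switches ≥ 1 frame before trail;
TIDS: the reverse; JDS: both within one frame.  Fractions are reported
over directional events only (reverts tallied separately).

**Accuracy scoring** (simulation only): detected events are matched
greedily to the nearest unclaimed true event within half the median true
run length; accuracy = correctly-typed matches / (all true events +
unmatched detections), so missed switches, wrong types and spurious
detections all count against the detector.

## Plate geometry

The metaphase plate is fitted per frame (least-squares plane via SVD;
the normal is the direction of minimal cloud variance) with normal
orientation made temporally consistent; a static single-plane fit is
available by flag.  Observables: signed plate-normal positions, 3D
inter-sister distance `d`, percent stretch `100·(d − L₀)/L₀` against the
nocodazole rest length `L₀ = 788 nm` (3D distance, not its projection —
stretch reflects spring length), and twist = `arccos |û·n̂|` ∈ [0°, 90°]
between the undirected sister axis and the normal.  All outputs are
invariant under rigid transforms of the scene (tested to 1e−9).  Tracks
are admitted if their longest gap-free stretch spans ≥ 112 consecutive
frames, and are trimmed to that stretch.

## Profiles and cohort statistics

Event-aligned averaging stacks a per-pair signal in a ±40 s window around
the first switching sister's modal frame (alignment on the second sister
by option); windows truncated by track ends contribute to the lags they
cover, and mean ± SEM is reported per lag with counts.  Run-rescaled
averaging admits runs of 6–20 frames bounded by directional events on
both sides, linearly interpolates each onto a 101-point [0, 1] grid, and
conditions on the preceding/following event type.  The oscillation
half-period is read from the pooled autocorrelation of overlapping
4-frame sister-centre displacements (lag of the global minimum).  Group
comparisons use Mann–Whitney (two groups) or Kruskal–Wallis (≥ 2);
twist–distance association is a pooled Pearson correlation.  The
bimodality criterion reports the median separation of two groups in
units of their pooled *within-group* SD with a ≥ 2 SD verdict (the
separation needed for a two-Gaussian mixture to be bimodal).

## What the synthetic data does and does not emulate

The generator reproduces: saw-tooth quasi-periodic paired oscillations,
geometric switching statistics with coherence restored faster than it is
lost, revert events, per-frame truth states/switches/events, and (in the
forced variant) guaranteed directional resolution.  It does **not**
reproduce: the biological separation scale (see the 13.9 µm note above —
mean simulated separation is ~12.5 µm and the post-event separation keeps
relaxing upward for both event types, so the real-data event signatures
transfer only as a LIDS-above-TIDS differential, which is what the
signature test asserts), measurement noise structure (no point-spread
function or localisation-error model), 3D motion for the AR process
(the switching model is 1D along the plate normal; 3D scenes are
synthesised separately for the geometry module), track gaps, or
anaphase onset.  Passing tests therefore validate the *algorithms* —
state recovery, event calling, averaging — under the model's own
conditions, not biological fidelity of the trajectories.

## Simulation-study protocol (validation module and acceptance script)

Cohorts of 50 trajectories × 150 frames at the reference parameters;
2 chains × (1000 burn + 2000 draws) per trajectory; recovery priors as
above.  Switch-call accuracy and the LIDS:TIDS lead-bias ratio are
computed over *all* simulated trajectories (the accuracy protocol covers
every simulation; exclusion-by-non-convergence applies to parameter
summaries, which pool posterior means over the first 20 converged fits).
`c₀` and `|c₊|` are reported as the median across trajectories of
per-trajectory posterior means; the switch probabilities as pooled
posterior means.  Problem sizes were chosen so the whole study runs in a
few minutes on one core; the corresponding full-scale study would use
500 trajectories.

With ~2.6 directional events per 150-frame trajectory (coherent exits
every ~16 frames, half of incoherent excursions reverting, short runs
pruned by the 5-frame rule), a 50-trajectory cohort yields ~130 events,
so the lead-bias ratio carries a sampling SD of ~0.18 — single-cohort
ratios as far as 0.80 or 1.20 from the symmetric truth are ordinary;
across five independent cohorts the pooled ratio is ~1.0.

## Numerical choices and degenerate inputs

Modal-state ties break to the previous frame; the first frame breaks to
the lowest state code.  Singular designs (e.g. a path that never visits
a drive state, or a 2-frame trajectory) hold the affected coefficients
and are logged; such fits flag non-convergence through the cross-chain
checks rather than erroring.  `s² = 0` likelihood evaluations return −∞
with nonzero residuals (+∞ otherwise) and are logged.  Collinear plate
clouds and coincident sister positions raise errors naming the frame.
Constant centre series make the displacement autocorrelation undefined
and raise.  All cohort randomness descends from a single seed through
`numpy.random.SeedSequence` spawning, making every pipeline output
byte-reproducible.

## Known limitations

`c₀`, `c₊`, `c₋` are identified only through the rest-length prior; with
150-frame trajectories the switch probabilities carry a visible pull
from their Beta(1,1) priors (~+2–4 points pooled at the reference
values, already present when counting on the true path); single-site
state sampling is retained for methodological comparison, not for
production; and no hierarchical sharing across trajectories is
implemented — each track is fitted independently.
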