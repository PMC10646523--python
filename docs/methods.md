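# Methods

## The model

An inter-system recurrence network (IRN) represents two simultaneously
observed systems X and Y as one graph. Each system contributes its
auto-recurrence network: vertices are time points, and two time points are
linked when the state-space distance between their (embedded) states falls
below a threshold ε, i.e. `R_ij = Θ(ε − ‖y_i − y_j‖)`. The two networks
are joined through the cross-recurrence matrix
`CR_ij = Θ(ε_XY − ‖x_i − y_j‖)`, giving the composite adjacency

    A = [[R_X,  CR ],
         [CR',  R_Y]] − I.

Thresholds are calibrated to target recurrence rates rather than chosen in
distance units; following the recommendation that cross-recurrences be no
denser than within-system recurrences, the defaults are RR_X = RR_Y = 5%
and RR_XY = 3% (simulation benchmark) or 4% (dyad pipeline). The auto rate
counts the strict upper triangle (the trivial self-recurrence diagonal is
excluded); the cross rate counts all N_X·N_Y cells. Thresholds are
linear-interpolation quantiles of the eligible distance population, which
puts the realized rate within one cell count of the target. The default
norm is Euclidean; Chebyshev is available.

## Cross-clustering and implied direction

The coupling readout is the pair of global cross-clustering coefficients
(C_XY, C_YX) and their difference ΔC = C_XY − C_YX. Two estimators are
implemented:

**Graph estimator** (`convention="graph"`; the definition used by the
graph operations `local_cross_clustering` / `global_cross_clustering`):
for a vertex v of G_X with cross-neighbour set U ⊆ V_Y, the fraction of
ordered pairs (u_i, u_j), u_i ≠ u_j ∈ U, that are linked inside G_Y;
vertices with cross-degree ≤ 1 score 0, and the global coefficient
averages over *all* vertices of the partition. This is the standard
vertex-neighbourhood definition of interacting-networks analysis; it is
invariant under vertex relabelling and is what the exhaustive
triangle-enumeration oracle in the test suite checks.

**Time-conditioned estimator** (`convention="time"`, the default of
`analyze_pair` and the pipeline): for a state y_u of Y, take the *times* j
at which X visits y_u's ε_XY-neighbourhood and measure how often Y itself
recurs across those pairs of times (closure in R_Y); the same with roles
swapped gives C_YX. It requires equally long trajectories, which windowed
dyadic data and the benchmark scenarios always provide.

The two estimators agree on symmetric inputs (and on the worked toy
example) but differ on transient, amplitude-non-stationary trajectories.
The time-conditioned estimator is the package default for direction
inference because, on the damped-oscillator benchmark, it produces the
expected ordinal pattern — the driven system carries the larger
coefficient toward its driver — consistently with the diagonal
cross-recurrence profiles of the same runs, whereas the graph estimator
inverts that pattern on these transient trajectories (the driven
oscillator's smeared amplitude envelope makes closure inside its own
dense network almost automatic). On the stationary stochastic dyad
fixtures the two estimators carry the same information with opposite
sign conventions; the default keeps the sign semantics uniform across
both regimes.

Direction is read from ΔC with a ±.01 dead band: ΔC < −.01 implies X
leads (X drives Y), ΔC > +.01 implies Y leads, |ΔC| ≤ .01 is reported as
bidirectional-or-uncoupled — the method cannot distinguish strong
symmetric coupling from no coupling.

## Oscillator benchmark

The benchmark integrates two linear damped oscillators,

    d²X/dt² = −η_x X + ζ_x dX/dt + γ_yx Y
    d²Y/dt² = −η_y Y + ζ_y dY/dt + γ_xy X

with η = 0.3, ζ = −0.05 (note the sign convention: ζ enters with a plus
sign, so negative ζ is decay), X₀ = 3, Y₀ = −3, zero initial velocities,
on t = 0, 1, …, 200 (201 samples; the unit step yields ≈ 17 oscillation
periods, and with it the calibrated thresholds of all four scenarios
reproduce the reference values to the third decimal). The four scenarios
set (γ_xy, γ_yx) to (0, 0), (+0.05, 0), (0, −0.05) and (+0.05, −0.05).
States (X, dX) and (Y, dY) are used natively (no embedding), each
coordinate standardized to zero mean and unit sample variance.
Integration uses LSODA at rtol = atol = 1e−10; the system is linear, so
solver choice is immaterial at this tolerance, and halving it changes no
sampled value by more than 1e−6. A state exceeding 1e12 raises a
divergence error naming the failure time; the coupling sweep records such
cells (and cells whose amplitude envelope grows, i.e. coupling
overpowering the damping) as flagged rather than aborting.

The uncoupled scenario is an exact mirror (y ≡ −x), so ΔC = 0 to machine
precision — a structural check, not a statistical one.

## Embedding parameter selection

Delay embedding uses one shared (lag, dimension) pair per analysis run so
that cross-recurrence between any two series lives in a common
reconstructed space; per-series diagnostics are available for choosing
it. The AMI profile is an equal-width 2-D histogram estimator (default 32
bins) in nats; the delay is its first strict local minimum, falling back
with a warning to the global minimum for monotone profiles. The
histogram estimator saturates on noise-free deterministic signals
(mutual information is then formally infinite), which flattens the
profile; a small amount of measurement noise — always present in real
data — regularizes it, and the quarter-period rule of thumb then holds
to ±1 sample. The FNN criterion uses the classic thresholds r_tol = 10,
a_tol = 2 and picks the smallest dimension with under 1% false
neighbours. The dyad pipeline's defaults, lag 100 and dimension 5 at
1 Hz, are the customary settings for 1 Hz analyses of this kind of wearable data.

## Diagonal cross-recurrence profiles

The DCRP reports the recurrence density of each diagonal of a square
cross-recurrence matrix, normalized by diagonal length. Negative lags
collect the upper triangle (states occurring first in X, i.e. X leading);
positive lags the lower triangle. Significance bands come from full
random permutations of the raw Y series — re-embedded and re-thresholded
to the same target rate per surrogate, so the band reflects temporal
structure, not rate differences. With n surrogates, falling outside the
per-lag min/max envelope is a two-sided pointwise rank test at 1/(n+1)
per tail; the customary n = 39 gives p < .05. Block-preserving surrogate
schemes are deliberately not included. Default maximum lag is N/4.

## The dyad pipeline

Recordings are per-person, per-channel timestamped series at native
wearable rates (ACC 32 Hz, BVP 64 Hz, EDA 4 Hz, HR 1 Hz, TEMP 4 Hz —
public consumer-wristband specifications, used for fixture realism). For
each incident the 35 minutes before the incident time are clipped and
resampled to 1 Hz (2,100 samples): rates above 1 Hz by per-second bin
means, 1 Hz and below by linear interpolation onto the second marks.
Holes up to 5 s are bridged by interpolation; at the first longer gap the
series is truncated and flagged, so a sensor put on late yields a short,
flagged series. An incident is excluded when two or more of its ten
series are shorter than 25 minutes; every exclusion carries a
machine-readable reason. Retained incidents are analyzed per variable
(client = X, caregiver = Y; embedding lag 100, dim 5; RR 5%/4%), then
across variables as a multiplex IRN: one vertex per variable, each
unordered variable pair linked with weight |ΔC| and the implied
direction as an edge label, vertex strength = sum of incident weights.
Because the paired streams for a variable-pair edge can be chosen several
ways, the default couples the *client's* stream of one variable with the
*caregiver's* stream of the other (the cross-person reading); both
within-person variants are a configuration switch, and the choice is
recorded in the output metadata.

## The synthetic dyad generator

No real wearable recordings ship with the package; the fixture generator
produces the study conditions synthetically. Each channel of a dyad is
the real part of a noisy Stuart–Landau (limit-cycle) oscillator per
person — stationary unit amplitude, intrinsic periods of 100–150 s per
channel, weak process noise (0.005), amplitude relaxation 0.1 at 1 Hz.
A planted direction couples the follower to the driver's state from 10 s
earlier, in two ways: a diffusive phase pull (κ = 0.012, about a fifth
of the angular frequency — comparable, relative to the restoring
parameter, to the benchmark's γ = 0.05 against η = 0.3) and an
arousal-like modulation of the follower's target amplitude (0.4 × the
driver's delayed signal). The delayed response gives the follower a
persistent phase lag rather than a symmetric zero-lag lock, and the
amplitude response reproduces the driven-envelope variation that makes
the cross-clustering pair asymmetric; both are the kind of
reaction-time-lagged, arousal-mediated coupling the dyadic stress
setting suggests. The latent 1 Hz signal is rendered at each channel's
native rate with white measurement noise (0.03 sd) and a slow drift
(smoothed random walk, 0.02 sd) emulating baseline wander.

The stationary limit cycle is a deliberate choice: free-running damped
oscillators under independent forcing acquire realization-specific
amplitude envelopes whose asymmetry swamps the ±.01 direction band under
the null, whereas the limit cycle keeps uncoupled dyads tightly
symmetric. What the generator does *not* emulate: artifacts and sensor
dropout beyond simple gaps, heavy-tailed movement bursts,
nonstationary regime shifts across a recording, and cross-channel
physiological dependencies within one person. Passing the recovery tests
therefore shows the method's sign conventions and sensitivity are
coherent end to end under clean planted coupling — not that comparable
accuracy holds on real wearable data.

## Numerical choices and degenerate inputs

- Exact symmetry of auto-distance matrices is enforced (floating-point
  `cdist` output is symmetrized and the diagonal zeroed) so that
  transpose laws hold exactly, not approximately.
- Constant series cannot be standardized and raise; all-equal distance
  populations make the recurrence rate uncontrollable and raise.
- The threshold quantile uses linear interpolation between order
  statistics; realized rates are reported alongside the target.
- Clustering closures are computed with sparse matrix products
  (float32), keeping the 1,700-point pipeline matrices affordable; the
  result is compared to exhaustive triangle enumeration in the tests.
- DCRP peak ties resolve toward the smallest |lag|.
- Seeds: every stochastic component (surrogates, fixtures) takes an
  explicit seed and is bit-reproducible under it.

## Problem sizes used in the checks

The benchmark runs at its native 201 samples. The sweep checks use a
9 × 9 subgrid of the 41 × 41 coupling grid (the full grid is available
through the API and CLI). Direction-recovery checks use 50 planted and
50 uncoupled dyads at the pipeline's full 35-minute, 1 Hz scale; the
multiplex and cohort examples use small cohorts. These sizes are the
package's own test-design choices to keep the suite brisk while leaving
every quantity at the scale the methods are specified for.

## Known limitations

- The time-conditioned estimator requires equal-length trajectories and
  a shared time axis; it is undefined for unequal windows.
- Direction inference near the damping/coupling transition of the
  oscillator benchmark can invert relative to the nominal coupling (the
  sweep's flagged region): the method estimates the *implied* direction
  of the realized dynamics, not the generating parameters.
- |ΔC| ≤ .01 conflates bidirectional coupling with no coupling by
  construction.
- Three of the eight reference clustering coefficients reported for
  the unidirectional and bidirectional scenarios could not be
  reproduced by any estimator variant examined, although all six
  thresholds and the remaining coefficients reproduce to the third
  decimal; the regression test pins the package's own computed values
  and the ordinal structure instead of those three numbers.
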