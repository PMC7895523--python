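# Methods

`trapstroke` analyzes three-bead optical-trap ("dumbbell") recordings of
single myosin molecules: an actin filament stretched between two trapped
beads is lowered onto a surface-bound motor, and each attachment of the
motor both stiffens the dumbbell — visible as a drop in the covariance of
the two bead positions — and displaces it by the working stroke.  The
package implements the covariance-threshold event detector, the
time-forward/time-reversed ensemble averaging used to decompose the working
stroke into substeps and rates, and dead-time-truncated exponential-mixture
maximum likelihood for detachment kinetics, together with a synthetic
generator that makes every stage testable by parameter recovery.

## Synthetic dumbbell model

### Phenomenological mode (default)

The two bead positions are decomposed into a common mode `c(t)` and a
differential mode `d(t)`:

    bead_a = c + d/2,    bead_b = c - d/2.

Each mode is an Ornstein–Uhlenbeck (OU) process with relaxation time
`tau_c = gamma/kappa_trap` (Stokes drag `gamma = 6*pi*eta*r` for a 250 nm
bead in water at 20 °C: 4.72e-6 pN·s/nm, so `tau_c ≈ 79 µs` at the default
0.06 pN/nm trap).  The discretization is exact — `c[n+1] = m + (c[n]-m)·a +
sigma·sqrt(1-a²)·xi` with `a = exp(-dt/tau)` — so the stationary variance
and autocovariance carry no step-size bias at any sample rate.

Myosin attachment is represented by two effects:

* the common-mode stationary SD drops from `sigma_c_unbound` to
  `sigma_c_bound` for the bound interval, which lowers the windowed
  covariance (`cov ≈ var(c) - var(d)/4`) — the detection observable;
* the common-mode target mean shifts by the first substep `d1` at
  attachment and by `d2` more at the substep-2 time; the bead response
  rise-time emerges from `tau_c`.

Attachments arrive as a Poisson process (default 1 /s; arrivals during a
bound interval are discarded because the geometry interrogates a single
molecule).  The dwell from attachment to substep 2 is `Exponential(k2)` and
from substep 2 to detachment `Exponential(k3)`; single-step mode (`d2 = 0`)
draws the whole dwell at `k3`.  An optional two-population mixture draws
each event's detachment rate from `{k3, k_slow}` with a configurable slow
fraction.

Default noise amplitudes are taken from equipartition rather than tuned:
`sigma_c_unbound = sqrt(kBT/(2*kappa_trap)) = 5.8 nm`, `sigma_c_bound =
sqrt(kBT/(2*kappa_trap + kappa_m)) = 1.9 nm` for a ~1 pN/nm myosin spring,
and `sigma_d = 4 nm` for the tether-constrained differential mode.  With
the default 30 ms window these levels separate the bound/unbound covariance
peaks by a wide margin, as the analysis requires.  Condition presets carry
the published working-stroke amplitudes and rates (two-substep wild type
3.32 + 1.09 nm at 99.1 /s forward / 4.59 /s reverse; single-step mutant
1.29 nm at 7.56 /s; drug-rescued mutant 1.82 + 0.84 nm and 2.28 + 1.14 nm
at ~40 /s forward).

### Mechanistic mode

Two coupled overdamped Langevin equations with the symmetric stiffness
matrix `K = [[kt+kl, -kl], [-kl, kt+kl]]` (traps plus inter-bead link);
binding adds `kappa_m/4` to every element through a myosin spring anchored
at the bead midpoint.  The system is integrated exactly in its normal modes
(each an OU process with rate `eig(K)/gamma` and variance `kBT/eig(K)`), so
equipartition holds to sampling error.  The spring anchor is shifted by
`d·(1 + 2*kappa_trap/kappa_m)`: after the series-spring attenuation
`kappa_m/(kappa_m + 2*kappa_trap)` the expected bead displacement equals
`d` exactly.

### What the generator does not emulate

No hydrodynamic coupling between beads, no anti-aliasing or detector
filtering, no QPD voltage-to-nanometer calibration, no stage drift, and no
published bound/unbound covariance levels to match (the instrument values
are not public; the generator is designed to reproduce the signal features
the pipeline consumes — covariance drop, mean shift, dwell structure).
Passing parameter-recovery tests therefore demonstrates correctness of the
analysis chain under this signal model, not robustness to every instrument
artifact.

## Event detection

The sliding covariance uses a centered window (default 30 ms; the
instrument dead time is half the window) with truncated windows at the
edges, computed from prefix sums after global demeaning — this keeps the
accumulators small and makes the result exactly invariant to constant
offsets.  The value distribution over a recording is decomposed into two
Gaussians by EM (scikit-learn, k-means++ initialization, 5 restarts, fixed
random state; values subsampled to 100k for speed) with a histogram
least-squares alternative that must agree on fixtures.  A molecule is
analyzable only when `unbound_mean - unbound_sd > bound_mean + bound_sd`;
an optional window search takes the smallest of {20, 25, 30} ms that still
separates.

Raw events are full excursions from the unbound-peak mean down to the
bound-peak mean and back (equality counts as crossed; all event times are
sample-aligned seconds with half-open intervals).  Refinement moves the
start to the crossing below the halfway level that leads into the raw
start, and the end to the first crossing above 80% of the way back to the
unbound peak after the event's last bound-level sample, then shifts start
and end by -/+ 0.75 dead times to compensate the averaging-window lag.
Both searches anchor on contiguous threshold runs and bound-level evidence
rather than taking the extremal crossing inside a fixed search window: on a
clean signal the two formulations coincide (the hand-computable step cases
give identical boundaries), but the run-anchored form is robust to isolated
noise dips and to noise-delayed raw bounds, which otherwise teleport a few
percent of boundaries by tens of milliseconds and contaminate the ensemble
averages.  Events whose refined duration falls below the dead time are
dropped, and overlapping pairs produced by the outward shifts are both
dropped and logged.

Two measured properties of this (published) detection rule are worth
stating.  First, refined durations exceed the true bound time by about
2.1 dead times (the outward display shifts plus the end-crossing lag), so
detachment rates fitted to pipeline durations are compressed accordingly;
kinetic benchmarks therefore use the standalone duration sampler, which is
how the dwell analysis is specified.  Second, an event must pull the
covariance all the way to the bound-peak *mean*, which a bound interval
only achieves reliably once it exceeds the averaging window with a margin;
recall near twice the dead time is therefore threshold-limited (~50% at the
boundary itself) and the ≥95% recall bound is demonstrated at kinetics
where most events comfortably exceed the window (detachment 2 /s), with
false positives essentially absent at the default contrast.

Trap stiffness is estimated per bead from the Welch power spectrum by
fitting the aliased (sampled-OU) Lorentzian — at 25 kHz the ~2 kHz corner
is a sizeable fraction of Nyquist, where the folded tail biases a naive
Lorentzian fit — giving `kappa = 2*pi*gamma*f_c`, cross-checked against
equipartition `kBT/var(x)`; a flat spectrum is flagged instead of fitted.

## Ensemble averaging and step measurement

Events are aligned at refined starts (time-forward) or refined ends
(time-reversed) and averaged point-wise; each molecule's average gets equal
weight in the combined average regardless of its event count.  Beyond each
event's far boundary the trace is replaced by the level the molecule held
just inside that boundary.  The level is measured over a 0.25-dead-time
window placed *inside* the bound interval — 1.0 dead times inward of the
refined start and 1.6 dead times inward of the refined end, offsets that
undo the deliberate ±0.75 dead-time display shift plus the centered-window
crossing lag (0 at the start, ~0.6 dead times at the end) plus a small
guard against crossing jitter — and the extension begins at the same
anchor.  Extending from the refined boundary itself would average several
milliseconds of unbound baseline into every event (the refined bounds are
deliberately outside the bound interval), which both depresses the plateau
and injects a spurious component at the detachment rate into the forward
average.

The total stroke is the forward extension plateau (mean over the outer 20%
of the extension span, default span 0.5 s, extendable to cover ≥4/k of slow
reverse rises) minus the baseline, where the baseline is the minimum of the
8-ms-smoothed *ensemble average* within ±0.2 s of the alignment zero.
Applying the minimum rule to the averaged trace rather than to single noisy
events matters: the expected minimum of smoothed single-event noise is
about -2 nm at these noise levels and would inflate a 4.4 nm stroke by
almost half, while on the average it is a few hundredths of a nanometer.
The second substep is `d2 = d_total - (reverse extension level -
baseline)`; `d1 = d_total - d2`, so `d1 + d2 = d_total` holds by
construction, and a |d2| below the 0.2 nm resolution floor is reported as
not detected.

Rise rates come from single-exponential fits, `a + b(1 - e^(-k·tau))`
forward and `a + b·e^(-k|tau|)` reverse.  The models are linear in the
amplitudes at fixed rate, so the rate is initialized by an exact profile
scan over a log-spaced grid before the final bounded nonlinear fit.  The
fit region starts past the covariance lag around the alignment point (1.0
dead times forward, 1.6 reverse; an exponential restricted to a shifted
window keeps its rate, so the delayed start trades amplitude for freedom
from boundary smearing).  Reverse rises (detachment-limited, ~1–10 /s) are
fitted over the whole extension span with a free asymptote, which the span
covers well.  Forward rises (substep-2 kinetics, tens to hundreds per
second) are fitted over a 0.3 s window with one refinement: a forward
average necessarily carries a small component at the detachment rate —
within the window the still-bound fraction decays at that rate while
extended events hold their boundary levels — so the model includes a
free-amplitude nuisance exponential fixed at the independently fitted
reverse rate, which keeps the slow component out of the fast rise rate.
(An optional pinned-asymptote variant is retained for constructed
noiseless inputs.)  A near-zero amplitude is flagged as unidentifiable
instead of fitted — single-step conditions correctly report no forward
substep-2 rise.

Two systematics are inherent to the method and documented rather than
corrected.  Detected events oversample long substep-2 dwells (an event must
outlast the dead time), compressing the fitted forward rate by ~5% at
99 /s.  And when the first-substep dwell (1/k2 ≈ 10 ms at wild-type
kinetics) is comparable to the dead time, the start-side level window
unavoidably averages over part of the substep-2 rise, so the reported
d1/d2 split is compressed (d2 low, d1 high) even though their sum — the
total stroke — and both rise rates are recovered; at slower substep rates
(k2 ≲ 20 /s) the split itself is recovered without bias, which is how the
substep-recovery property is exercised.

The buffer-exchange comparison runs the full detection → ensemble → step
chain independently on labelled time segments of one molecule's recording
and reports per-condition measurements plus paired differences; segments
with fewer than 10 events are flagged but still reported.

## Dwell-time maximum likelihood

Durations below the instrument dead time are unobservable, so the
likelihood renormalizes the exponential-mixture density over
`[dead_time, ∞)` (rather than shifting the origin):

    f(t) = sum_i A_i k_i e^(-k_i t) / sum_i A_i e^(-k_i·dead_time).

The order-1 MLE is the closed form `1/(mean - dead_time)`; order 2 is
maximized by bounded L-BFGS-B on (log k1, log k2, logit A) from 20 starts
(log-uniform rates in [1e-3, 1e4] /s, A in [0.01, 0.99], plus a
moment-guided start), with components reported dominant-amplitude-first
(ties to the larger rate).  Model order is chosen by the likelihood-ratio
statistic against chi-squared with two degrees of freedom at alpha = 0.05;
confidence intervals are nonparametric bootstrap percentiles (default 1000
resamples, warm-started refits, deterministic given the seed).  Molecules
enter per-molecule statistics only with more than 75 events.  The duty
ratio uses the stated definition `V_max/k_detach` (cycle time `1/V_max`,
attached time `1/k_detach`); with the printed rates this gives 0.094 and
0.082 where 0.095 and 0.078 are reported — the exact inputs behind the
printed values are not stated, so the definition is implemented and the
small discrepancy documented, not reconciled.

## Problem sizes and determinism

Simulations default to 25 kHz sampling (the acquisition-rate field reaches
250 kHz when desired; the exact OU discretization is unbiased at any rate).
The test suite exercises parameter recovery at 5 molecules × 100–150
events per condition and the acceptance script at 5 × 150–200 (≈2–4 minutes
per condition on one core); dwell-rate recovery uses n = 5000 durations
with 1000 bootstrap resamples, and model-selection calibration 200
replicates at n = 1000.  All randomness flows from explicit seeds
(`numpy.random.default_rng`; per-molecule seeds spawned from a root seed),
EM uses a fixed random state, and a pipeline run is byte-reproducible from
its configuration echo.
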