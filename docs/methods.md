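# Methods

## Model

Each of the eight populations (PYR, PV, SST, VIP per layer) is a single
Wilson–Cowan rate unit,

    tau_i dr_i/dt = -r_i + phi(sum_j W_ij r_j + I_ext,i) + eta_i,
    phi(x) = a x / (1 - exp(-x/b)),

integrated by forward Euler at `dt = 0.1 ms`.  The transfer function is
positive, strictly increasing, asymptotically linear, with `phi(0) = a b`
(its removable singularity evaluated by the limit) and is computed in an
overflow-safe piecewise form.  The noise `eta` is drawn i.i.d. Gaussian per
population and step and enters inside the `dt/tau` update — the discrete
scheme is the definition of the stochastic model, not an approximation to an
SDE.  At fixed `dt = 0.1 ms` this is innocuous; users who vary `dt` and want
dt-invariant noise statistics can enable Euler–Maruyama `sqrt(dt)` scaling
(`ModelParams(sqrt_dt_noise=True)`, off by default).  Conduction delays are
not modeled; rates are not clipped at zero by default (with `sigma = 0.01`
negative excursions are O(sigma); a `clip_rates` flag exists).

Initial rates are zero unless warm-started.  `VIP_deep` is anatomically a
superficial cell class but functionally assigned to the deep layer because
its output column only reaches deep targets; the matrix encodes this.

### Matrix orientation

`W[i, j]` is the weight from source `j` onto target `i`, so recurrent input
is `W @ r` and silencing a cell type's output means zeroing its column.  All
CSV I/O carries population labels and round-trips at full float precision
(`%.17g` on write, round-trip float parsing on read).

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| tau (PYR, PV, SST, VIP) | 4, 5, 25, 12 | ms | fast PYR/PV decay, slow SST, intermediate VIP; placeholders for measured population time constants, overridable per population |
| a (transfer slope) | 1 | – | standard operating point |
| b (transfer threshold) | 1 | Hz | standard operating point |
| sigma (noise SD) | 0.01 | Hz | reference noise level for oscillation analysis |
| dt | 0.1 | ms | reference integration step |
| I_ext to PYR | 5 | Hz | keeps the LFP proxy (PYR rate) above zero under strong inhibition |
| G | swept, 0–600 | – | global coupling, proxy for population count |
| inhibitory_scale | 0.2 | – | ~5:1 pyramidal:interneuron head count |

The short PYR/PV time constants are what place the noise-driven PYR–PV
resonance in the gamma band at moderate coupling; they are a modeling choice
documented here, not measured values.

## Connectivity construction

From raw pairwise tables (target x source over eleven morphological types):
element-wise product of mean EPSP/IPSP amplitude and connection probability;
PV subtypes merged (basket+chandelier superficially, basket+shrub+
horizontally-elongated deep) by summing source columns — outputs of merged
cells add — and averaging target rows — a merged population receives the
input of a representative cell; VIP split into a superficially-targeting
(bitufted) and a deep-targeting (bipolar) population; inhibitory columns
scaled by 0.2; each interneuron column multiplied by its prevalence.
Weak-connection display thresholds are never applied to computation.

Manipulations (`LesionSpec`): output silencing (column zeroing), single-entry
removal/overwrite, PV self-weight equalization across layers, PV/SST
self-connection exchange (an involution), and Gaussian jitter.  Jitter
perturbs only nonzero entries — absent connections carry no measurement
variance — and is the one operation exempt from the sign-pattern invariant.

## Synthetic connectivity

`MotifSpec`/`generate_matrix` produce surrogate matrices carrying the motif
structure the analysis relies on (strongest-in-matrix PV self-inhibition,
deep > superficial; zero SST self-inhibition; mutual SST–PV and SST–VIP
inhibition; strong PYR_sup→PYR_deep drive; deep-to-superficial SST
projections, optionally both directions; layer-confined VIP outputs), plus
weak seeded background entries respecting the sign pattern.
`generate_raw` emits probability/amplitude/prevalence tables whose corrected
build reproduces the generated matrix to machine precision, so the whole
construction pipeline is testable without measured tables.

The default magnitudes are a one-off calibration chosen so that, for
G between roughly 50 and 600, the circuit (i) shows a noise-driven
superficial gamma resonance whose peak frequency rises into the ~90–100 Hz
range near G = 100 and collapses to a slow SST-paced rhythm (~12–15 Hz) by
G = 500, (ii) survives PV silencing with a slow (~20–30 Hz) high-power
oscillation and SST silencing with a fast (~90–160 Hz) one, and (iii) carries
a VIP→SST switch whose hysteresis onset (G ≈ 100) precedes the PV→SST
switch's (G ≈ 450).  Three design facts emerged during calibration and are
worth recording: the PYR–PV pair only has a complex (resonant) eigenpair when
the two populations' effective decay rates are comparable, which requires
short PYR time constants and near-zero recurrent PYR self-excitation; the
resonance is visible above the noise floor only when PV sits at strongly
negative input (its transfer slope small) while PYR stays near threshold;
and weak VIP output weights are required so that the disinhibited state
remains PV-dominated rather than VIP-crushed.  The committed fixture
(`data/fixture_matrix.csv`) is exactly `generate_matrix(MotifSpec())`.

What the surrogate does *not* emulate: empirical weight magnitudes and their
distribution, cell-type-specific time constants measured in vivo, layers 4/6
and layer-1 cell types, and the empirical deep-vs-superficial frequency
ordering (on the fixture the deep layer oscillates *faster* than the
superficial one at large G).  Tests passing on the fixture therefore
establish that the pipeline reproduces the motif-driven phenomenology, not
that it reproduces any particular measured frequency.

## LFP proxy and spectra

The LFP proxy of a layer is its PYR rate.  Spectra are multitaper estimates
on DPSS tapers (time–bandwidth 3, 5 tapers by default), restricted to
1–250 Hz, smoothed with a 5-bin moving average and normalized to unit sum
over the band; the first 500 ms of each trial are discarded as transient.
Multi-trial input is averaged before peak extraction.  A reported peak is the
largest local maximum at >= 10 Hz whose normalized power is at least 1.5x the
band median — an operational definition of a "visible" peak; all of these
settings are configurable and none is a measured fact.  Traces for spectra
are recorded at 1 kHz (`record_stride=10`), ample for the band and cheap.

## Steady states, sweeps and switch metrics

Response curves use noise-free 2 s relaxations; non-convergence (e.g. a limit
cycle) is flagged in the return value, not raised.  Warm-started sweeps
initialize each grid point from the previous one — this is the protocol that
exposes hysteresis.  The Hill fit is least-squares (lmfit) with multi-start
over the exponent (0.5, 1, 2, 4, 8, 16), signed amplitude `d` (decreasing SST
curves are fitted directly), bounds `|d| <= 10x` data range, `k` within
0.01–100x the swept range, `n in (0, 50]`; flat or strongly non-monotone
curves return a quality warning instead of raising.  Fits are applied to raw
(unnormalized) rates.  Hysteresis is reported per layer and summed; it is the
grid sum of |up - down| of the SST curves, zero exactly when the branches
coincide.

`linearized_frequency` provides an analytic oracle for the noise-driven
rhythm: the imaginary part (over 2 pi) of the least-damped complex eigenpair
of `J = diag(1/tau) (-I + diag(phi') W)` at the polished fixed point.  The
spectral peak of a noisy simulation tracks it to within ~15% when a single
lightly damped pair dominates (damping quality `|Im|/2|Re| > ~0.55`); broader
resonances sit on a declining noise background that biases the measured peak
downward, so no claim is made for them.

## Experiments

Seven registered protocols (G sweeps, lesion battery, switch sweeps,
time-constant sweep, translaminar propagation, weighted external drive,
inverted self-connectivity) emit tidy tables with a config hash and per-trial
seed policy, so every row is traceable and bit-reproducible.  Background
states follow the conventions: "SST-enhanced" = +5 Hz to both SST
populations, "VIP state"/"PV state" = +40 Hz to the respective class in both
layers.  Feedforward/feedback input-weight vectors are user data; the
shipped `ILLUSTRATIVE_INPUT_WEIGHTS` only mimic the qualitative pattern
(feedforward recruits PV, feedback recruits VIP) and are flagged as such.

Reference spectral conditions are 50 trials x 20 s; the test suite and the
acceptance script run scaled-down versions (6–10 trials of 5–10 s), which
widens peak-frequency estimator variance (a few Hz to ~20 Hz at weak peaks)
but preserves every ordering asserted.

## Numerical choices and degenerate inputs

Fixed points are polished with a hybrid-Powell root solve before
linearization; steady-state convergence tolerance is 1e-7 Hz/ms on the
terminal derivative.  Divergent simulations (non-finite or |r| > 1e9,
possible under strong recurrent excitation, e.g. the purely excitatory
subcircuit at large G) raise a structured error carrying the blow-up time.
Empty sweep grids, overlapping stimulus windows, sub-second spectra,
mismatched hysteresis grids, invalid population labels and sign-violating
motif specifications are rejected with explicit errors.

## Known limitations

* The surrogate circuit reproduces motif-level phenomenology; absolute
  frequencies, rates and bifurcation points depend on the calibration and on
  the placeholder time constants.
* The deep layer's spectral estimates are noisier than the superficial
  layer's at small trial counts; band-placement claims in the tests are made
  on the superficial LFP proxy.
* In strongly inhibited states the PYR rate can be pinned near zero, where
  its spectrum reflects filtered noise rather than network rhythm; state
  comparisons are made at parameters where the readout population stays
  responsive.
* Bistability is probed by warm-started sweeps on a finite grid, not by
  numerical continuation; hysteresis onsets are reported at the resolution of
  the G grid.
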