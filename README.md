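# microswitch

A rate model of the two-layer (L2/3 + L5) mouse primary visual cortex
microcircuit, built for studying how its three inhibitory interneuron classes
— parvalbumin- (PV), somatostatin- (SST) and vasoactive-intestinal-peptide-
positive (VIP) cells — toggle the pyramidal (PYR) output between an
*inhibited* (SST-dominated, slow-oscillating) and a *disinhibited*
(PV/VIP-dominated, fast-oscillating) state.  It is aimed at computational
neuroscientists who want a compact, fully scriptable testbed for
disinhibition motifs, ultrasensitive/bistable switches, and layer-specific
cortical oscillations.

## Model

Eight populations (PYR, PV, SST, VIP in a superficial and a deep layer) each
follow a Wilson–Cowan rate equation, in vector form

```
tau dr/dt = -r + phi(C r + I_ext) + eta,        phi(x) = a x / (1 - e^(-x/b))
```

with a signed effective connectivity matrix `C` (rows = targets, columns =
sources; excitatory columns >= 0, inhibitory <= 0), per-population time
constants `tau`, additive Gaussian noise `eta` with SD `sigma = 0.01`, and
forward-Euler integration at `dt = 0.1 ms`.  The whole matrix is scaled by a
global coupling factor `G`, a stand-in for population size.  The pyramidal
rate of each layer serves as that layer's LFP proxy; its multitaper power
spectrum (1–250 Hz, normalized to unit sum) is summarized by the dominant
peak at >= 10 Hz.

Switch behaviour is quantified on warm-started input sweeps: the SST response
curve is fitted with the Hill equation `y = c + d x^n / (k^n + x^n)` — the
exponent `n` (`n_H`) measures ultrasensitivity — and hysteresis `h` is the
summed difference between ascending and descending SST curves.

The package constructs `C` either from raw pairwise tables (connection
probability x EPSP/IPSP amplitude, PV/VIP subtype merging, a 0.2 inhibitory
head-count correction, prevalence weighting) or from a calibrated synthetic
generator (`microswitch.synthetic`) that reproduces the canonical structural
motifs: strongest-in-matrix PV self-inhibition (deep > superficial), zero SST
self-inhibition, mutual SST–PV and SST–VIP inhibition, strong superficial-to-
deep pyramidal excitation, deep-to-superficial SST projections and
layer-confined VIP output.

## Worked example

```python
import numpy as np
from microswitch import (ModelParams, background_drive, fixture_matrix,
                         scale_by_G, simulate, compute_psd, find_peak,
                         sweep_response, fit_hill, hysteresis_area)

C0 = fixture_matrix()                  # calibrated 8x8 surrogate circuit
params = ModelParams()                 # tau, a=b=1, sigma=0.01, dt=0.1 ms
stim = background_drive(5.0)           # 5 Hz external drive to PYR cells

# spontaneous oscillation at moderate vs strong coupling
for G in (100.0, 500.0):
    traces = [simulate(scale_by_G(C0, G), params, stim, 5000.0, seed=s,
                       record_stride=10) for s in range(6)]
    pk = find_peak(compute_psd(traces, "superficial"))
    print(f"G={G:5.0f}  superficial LFP peak {pk.frequency:6.1f} Hz")

# the VIP->SST switch at strong coupling
grid = np.arange(0.0, 101.0, 2.0)
C = scale_by_G(C0, 300.0)
sst_stim = stim.added({"SST": 5.0})
up = sweep_response(C, params.with_(sigma=0), sst_stim,
                    ("VIP_sup", "VIP_deep"), grid)
down = sweep_response(C, params.with_(sigma=0), sst_stim,
                      ("VIP_sup", "VIP_deep"), grid[::-1], "descending")
fit = fit_hill(up.curve("SST_sup"))
h = hysteresis_area(up, down)
print(f"Hill exponent n_H = {fit.n:.1f}, hysteresis h_sup = {h.h_superficial:.1f}")
```

Output:

```
G=  100  superficial LFP peak   85.8 Hz
G=  500  superficial LFP peak   24.0 Hz
Hill exponent n_H = 50.0, hysteresis h_sup = 36.6
```

At `G = 100` the circuit rings in the high-gamma range; by `G = 500` the
SST-dominated slow rhythm has taken over.  At `G = 300` the SST response to
VIP drive is a near-binary ultrasensitive switch (the fit exponent saturates
at its upper bound of 50) with clear hysteresis, i.e. the circuit is bistable.

The in-silico experiment battery is also scriptable from the shell:

```
microswitch list-protocols
microswitch run spontaneous_g_sweep --config cfg.yaml --out results/
```

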