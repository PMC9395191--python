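"""Registered in-silico experiment protocols.

Each protocol is a named function taking an :class:`ExperimentSpec` and
returning an :class:`ExperimentResult` — a bundle of tidy result tables with
full provenance (configuration hash and seed policy), so every row is
traceable to a single simulation or fit.

Spectral protocols default to 50 trials of 20 s with noise SD 0.01; a fast
mode (fewer/shorter trials) trades estimator variance for runtime and is used
by the test suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, LesionSpec, apply_lesion, scale_by_G
from .lfp import compute_psd, find_peak
from .model import ModelParams, StimulusProtocol, background_drive, simulate
from .populations import POPULATIONS, POPULATION_INFO, index_of, pyr_index
from .switch_metrics import fit_hill, hysteresis_area, sweep_response
from .synthetic import fixture_matrix

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "PROTOCOLS",
    "run_experiment",
    "ILLUSTRATIVE_INPUT_WEIGHTS",
]

#: Illustrative per-population external-input weight vectors (normalized to
#: PYR = 1).  These are NOT measured values: they only mimic the qualitative
#: pattern that feedforward drive recruits PV strongly while feedback drive
#: preferentially targets VIP cells.  Supply empirical vectors for real use.
ILLUSTRATIVE_INPUT_WEIGHTS: dict[str, dict[str, float]] = {
    "feedforward": {"PYR": 1.0, "PV": 1.0, "SST": 0.25, "VIP": 0.25},
    "feedback": {"PYR": 1.0, "PV": 0.3, "SST": 0.25, "VIP": 1.5},
}

DEFAULT_G_VALUES = (10.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0)


@dataclass
class ExperimentSpec:
    """Configuration of one protocol run.

    ``n_trials``/``trial_duration_ms`` control the spectral protocols
    (defaults match the reference conditions: 50 trials of 20 s);
    ``input_grid`` is the swept external drive (default 0-100 Hz in 1 Hz
    steps); ``record_stride`` subsamples stored traces (10 -> 1 kHz, ample
    for the 1-250 Hz band).
    """

    name: str = ""
    G_values: tuple[float, ...] = DEFAULT_G_VALUES
    matrix: ConnectivityMatrix | None = None
    params: ModelParams | None = None
    baseline_pyr_hz: float = 5.0
    lesions: list[LesionSpec] = field(default_factory=list)
    n_trials: int = 50
    trial_duration_ms: float = 20000.0
    input_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 101.0, 1.0))
    settle_ms: float = 2000.0
    seed: int = 0
    record_stride: int = 10
    extras: dict = field(default_factory=dict)

    def fast(self, n_trials: int = 10, trial_duration_ms: float = 5000.0,
             **kwargs) -> "ExperimentSpec":
        """Reduced-cost variant for smoke runs and CI."""
        return replace(self, n_trials=n_trials,
                       trial_duration_ms=trial_duration_ms, **kwargs)

    # -- internals -------------------------------------------------------
    def base_matrix(self) -> ConnectivityMatrix:
        C = self.matrix if self.matrix is not None else fixture_matrix()
        for spec in self.lesions:
            C = apply_lesion(C, spec)
        return C

    def model_params(self) -> ModelParams:
        return self.params if self.params is not None else ModelParams()

    def base_stim(self) -> StimulusProtocol:
        return background_drive(self.baseline_pyr_hz)

    def trial_seeds(self, n: int, tag: int = 0) -> list[int]:
        ss = np.random.SeedSequence([self.seed, tag])
        return [int(s) % (2 ** 31) for s in ss.generate_state(n)]

    def config_dict(self) -> dict:
        return {
            "name": self.name,
            "G_values": list(map(float, self.G_values)),
            "baseline_pyr_hz": self.baseline_pyr_hz,
            "lesions": [str(l) for l in self.lesions],
            "n_trials": self.n_trials,
            "trial_duration_ms": self.trial_duration_ms,
            "input_grid": [float(self.input_grid[0]), float(self.input_grid[-1]),
                           len(self.input_grid)],
            "settle_ms": self.settle_ms,
            "seed": self.seed,
            "record_stride": self.record_stride,
            "extras": {k: str(v) for k, v in self.extras.items()},
        }


@dataclass
class ExperimentResult:
    """Tidy result tables plus provenance of one protocol run."""

    name: str
    config: dict
    tables: dict[str, pd.DataFrame]

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for key, df in self.tables.items():
            df.to_csv(out / f"{self.name}__{key}.csv", index=False)
        manifest = {"name": self.name, "config": self.config,
                    "config_hash": self.config_hash,
                    "tables": sorted(self.tables)}
        (out / f"{self.name}__manifest.json").write_text(
            json.dumps(manifest, indent=2))


# ----------------------------------------------------------------------
# Shared measurement helpers
# ----------------------------------------------------------------------

def _spectral_peaks(C, params, stim, spec: ExperimentSpec, tag: int) -> dict:
    """Per-layer spectral peaks averaged over noise trials."""
    seeds = spec.trial_seeds(spec.n_trials, tag=tag)
    traces = [
        simulate(C, params, stim, spec.trial_duration_ms, seed=s,
                 record_stride=spec.record_stride)
        for s in seeds
    ]
    out = {}
    for layer in ("superficial", "deep"):
        psd = compute_psd(traces, layer)
        pk = find_peak(psd)
        out[layer] = pk
    return out


def _mean_rates(C, params, stim, spec: ExperimentSpec, tag: int) -> np.ndarray:
    trace = simulate(C, params, stim, spec.trial_duration_ms,
                     seed=spec.trial_seeds(1, tag=tag)[0],
                     record_stride=spec.record_stride)
    return trace.mean_rates()


def _updown_sweeps(C, params, stim, targets, grid, settle_ms):
    up = sweep_response(C, params, stim, targets, grid,
                        direction="ascending", warm_start=True,
                        settle_ms=settle_ms)
    down = sweep_response(C, params, stim, targets, grid[::-1],
                          direction="descending", warm_start=True,
                          settle_ms=settle_ms)
    return up, down


def _translaminar_entries(C: ConnectivityMatrix) -> list[tuple[str, str]]:
    """(source, target) label pairs of nonzero cross-layer connections."""
    pairs = []
    for i, tgt in enumerate(POPULATIONS):
        for j, src in enumerate(POPULATIONS):
            if C.W[i, j] == 0.0:
                continue
            if POPULATION_INFO[src].layer != POPULATION_INFO[tgt].layer:
                pairs.append((src, tgt))
    return pairs


def _remove_entries(C, pairs) -> ConnectivityMatrix:
    for src, tgt in pairs:
        C = apply_lesion(C, LesionSpec("remove_connection", source=src, target=tgt))
    return C


# ----------------------------------------------------------------------
# Protocols
# ----------------------------------------------------------------------

def spontaneous_g_sweep(spec: ExperimentSpec) -> ExperimentResult:
    """Mean spontaneous rates and layer-wise spectral peaks across G.

    Baseline drive is 5 Hz to PYR cells only.  Rates are the average of one
    full-length noisy simulation; peaks come from trial-averaged multitaper
    spectra of each layer's LFP proxy.
    """
    C0, params, stim = spec.base_matrix(), spec.model_params(), spec.base_stim()
    rate_rows, peak_rows = [], []
    for gi, G in enumerate(spec.G_values):
        C = scale_by_G(C0, G)
        rates = _mean_rates(C, params, stim, spec, tag=1000 + gi)
        for k, lbl in enumerate(POPULATIONS):
            rate_rows.append({"G": G, "population": lbl, "rate": rates[k]})
        peaks = _spectral_peaks(C, params, stim, spec, tag=2000 + gi)
        for layer, pk in peaks.items():
            peak_rows.append({"G": G, "layer": layer, "peak_frequency": pk.frequency,
                              "peak_power": pk.power, "found": pk.found})
    return ExperimentResult("spontaneous_g_sweep", spec.config_dict(),
                            {"rates": pd.DataFrame(rate_rows),
                             "peaks": pd.DataFrame(peak_rows)})


def _lesion_conditions(C0: ConnectivityMatrix) -> dict[str, ConnectivityMatrix]:
    """The connectivity-modification battery."""
    trans_sst = [(s, t) for s, t in _translaminar_entries(C0)
                 if s.startswith("SST")]
    conds = {
        "intact": C0,
        "no_pyr_sup_to_pyr_deep": apply_lesion(
            C0, LesionSpec("remove_connection", source="PYR_sup",
                           target="PYR_deep")),
        "no_translaminar_sst": _remove_entries(C0, trans_sst),
        "equalized_pv_self": apply_lesion(C0, LesionSpec("equalize_pv_self")),
    }
    combined = apply_lesion(C0, LesionSpec("remove_connection",
                                           source="PYR_sup", target="PYR_deep"))
    combined = _remove_entries(combined, trans_sst)
    conds["combined_three"] = apply_lesion(combined,
                                           LesionSpec("equalize_pv_self"))
    for cls in ("PV", "SST", "VIP"):
        C = apply_lesion(C0, LesionSpec("silence_cell", source=f"{cls}_sup"))
        C = apply_lesion(C, LesionSpec("silence_cell", source=f"{cls}_deep"))
        conds[f"silence_{cls}"] = C
    return conds


def lesion_battery(spec: ExperimentSpec) -> ExperimentResult:
    """Connection removals and cell-type silencing across the G sweep.

    Covers removal of the superficial-to-deep pyramidal projection, of
    translaminar SST projections, equalized PV self-inhibition, the three
    combined, and full silencing (output columns zeroed) of PV, SST or VIP
    in both layers.
    """
    C0, params, stim = spec.base_matrix(), spec.model_params(), spec.base_stim()
    rate_rows, peak_rows = [], []
    for ci, (cond, Cc) in enumerate(_lesion_conditions(C0).items()):
        for gi, G in enumerate(spec.G_values):
            C = scale_by_G(Cc, G)
            rates = _mean_rates(C, params, stim, spec, tag=ci * 100 + gi)
            for k, lbl in enumerate(POPULATIONS):
                rate_rows.append({"condition": cond, "G": G,
                                  "population": lbl, "rate": rates[k]})
            rate_rows.append({
                "condition": cond, "G": G, "population": "PYR_rate_diff",
                "rate": rates[pyr_index("superficial")] - rates[pyr_index("deep")],
            })
            peaks = _spectral_peaks(C, params, stim, spec,
                                    tag=10000 + ci * 100 + gi)
            for layer, pk in peaks.items():
                peak_rows.append({"condition": cond, "G": G, "layer": layer,
                                  "peak_frequency": pk.frequency,
                                  "peak_power": pk.power, "found": pk.found})
    return ExperimentResult("lesion_battery", spec.config_dict(),
                            {"rates": pd.DataFrame(rate_rows),
                             "peaks": pd.DataFrame(peak_rows)})


#: switch name -> (driven populations, background drives added to baseline)
SWITCH_PROTOCOLS: dict[str, tuple[tuple[str, ...], dict[str, float]]] = {
    "VIP": (("VIP_sup", "VIP_deep"), {"SST": 5.0}),
    "PV": (("PV_sup", "PV_deep"), {"SST": 5.0}),
    "SST": (("SST_sup", "SST_deep"), {}),
    "PYR_plain": (("PYR_sup", "PYR_deep"), {}),
    "PYR_vip40": (("PYR_sup", "PYR_deep"), {"VIP": 40.0}),
    "PYR_pv40": (("PYR_sup", "PYR_deep"), {"PV": 40.0}),
}


def switch_sweeps(spec: ExperimentSpec) -> ExperimentResult:
    """Warm-started up/down input sweeps, Hill fits and hysteresis per G.

    Switch types: VIP or PV drive against an SST-enhanced background (+5 Hz
    to SST in both layers), direct SST drive, and PYR drive under no / VIP
    (40 Hz) / PV (40 Hz) background.  The SST response curve of each layer is
    fitted with the Hill equation and the up/down difference summed into the
    hysteresis areas.
    """
    switches = spec.extras.get("switches", tuple(SWITCH_PROTOCOLS))
    C0, params = spec.base_matrix(), spec.model_params()
    curve_rows, fit_rows = [], []
    for sw in switches:
        targets, bg = SWITCH_PROTOCOLS[sw]
        stim = spec.base_stim().added(bg) if bg else spec.base_stim()
        for G in spec.G_values:
            C = scale_by_G(C0, G)
            up, down = _updown_sweeps(C, params, stim, targets,
                                      spec.input_grid, spec.settle_ms)
            for res in (up, down):
                df = res.to_frame()
                df.insert(0, "switch", sw)
                df.insert(1, "G", G)
                curve_rows.append(df)
            hys = hysteresis_area(up, down)
            for layer, lbl, h in (("superficial", "SST_sup", hys.h_superficial),
                                  ("deep", "SST_deep", hys.h_deep)):
                fit = fit_hill(up.curve(lbl))
                fit_rows.append({"switch": sw, "G": G, "layer": layer,
                                 "c": fit.c, "d": fit.d, "k": fit.k,
                                 "n_H": fit.n, "residual_norm": fit.residual_norm,
                                 "quality_warning": fit.quality_warning or "",
                                 "h": h, "h_total": hys.h_total})
    return ExperimentResult("switch_sweeps", spec.config_dict(),
                            {"curves": pd.concat(curve_rows, ignore_index=True),
                             "fits": pd.DataFrame(fit_rows)})


def time_constant_sweep(spec: ExperimentSpec) -> ExperimentResult:
    """Oscillation frequency of the two switch states under varied tau.

    Time constants are fixed at 10 ms for three cell classes while the
    fourth is varied.  For each setting the VIP switch is probed at a low
    (SST-dominated) and a high (PV/VIP-dominated) VIP input and the
    superficial-layer spectral peak is measured.
    """
    tau_values = spec.extras.get("tau_values", (10.0, 20.0, 40.0))
    classes = spec.extras.get("classes", ("PYR", "PV", "SST", "VIP"))
    low_in, high_in = spec.extras.get("state_inputs", (0.0, 60.0))
    G = spec.extras.get("G", 300.0)
    C = scale_by_G(spec.base_matrix(), G)
    base = spec.base_stim().added({"SST": 5.0})
    rows = []
    for ci, cls in enumerate(classes):
        for ti, tau in enumerate(tau_values):
            params = spec.model_params().with_tau(
                {c: 10.0 for c in ("PYR", "PV", "SST", "VIP")}).with_tau({cls: tau})
            for state, vip_in in (("low", low_in), ("high", high_in)):
                stim = base.added({"VIP": vip_in})
                peaks = _spectral_peaks(C, params, stim, spec,
                                        tag=ci * 1000 + ti * 10 +
                                        (0 if state == "low" else 1))
                pk = peaks["superficial"]
                rows.append({"varied_class": cls, "tau": tau, "state": state,
                             "vip_input": vip_in, "peak_frequency": pk.frequency,
                             "peak_power": pk.power, "found": pk.found})
    return ExperimentResult("time_constant_sweep", spec.config_dict(),
                            {"state_peaks": pd.DataFrame(rows)})


#: panel -> (driven population, background drives)
PROPAGATION_PANELS: dict[str, tuple[str, dict[str, float]]] = {
    "VIP_sup": ("VIP_sup", {"SST": 5.0}),
    "VIP_deep": ("VIP_deep", {"SST": 5.0}),
    "PV_sup": ("PV_sup", {"SST": 5.0}),
    "PV_deep": ("PV_deep", {"SST": 5.0}),
    "SST_sup_vipstate": ("SST_sup", {"VIP": 40.0}),
    "SST_deep_vipstate": ("SST_deep", {"VIP": 40.0}),
    "SST_sup_pvstate": ("SST_sup", {"PV": 40.0}),
    "SST_deep_pvstate": ("SST_deep", {"PV": 40.0}),
}


def translaminar_propagation(spec: ExperimentSpec) -> ExperimentResult:
    """Opposite-layer PYR responses with translaminar connections removed.

    Input goes to one inhibitory population of one layer; the pyramidal
    response of the opposite layer is recorded with the circuit intact, with
    each translaminar source class removed singly, and with all translaminar
    connections severed.
    """
    G = spec.extras.get("G", 300.0)
    panels = spec.extras.get("panels", tuple(PROPAGATION_PANELS))
    C0 = scale_by_G(spec.base_matrix(), G)
    params = spec.model_params()
    trans = _translaminar_entries(C0)
    source_classes = sorted({s.split("_")[0] for s, _ in trans})
    rows = []
    for panel in panels:
        target_pop, bg = PROPAGATION_PANELS[panel]
        stim = spec.base_stim().added(bg)
        in_layer = POPULATION_INFO[target_pop].layer
        out_layer = "deep" if in_layer == "superficial" else "superficial"
        readout = "PYR_deep" if out_layer == "deep" else "PYR_sup"
        conds = {"intact": C0,
                 "all_cut": _remove_entries(C0, trans)}
        for cls in source_classes:
            conds[f"cut_{cls}"] = _remove_entries(
                C0, [(s, t) for s, t in trans if s.startswith(cls)])
        for cond, C in conds.items():
            res = sweep_response(C, params, stim, (target_pop,),
                                 spec.input_grid, warm_start=True,
                                 settle_ms=spec.settle_ms)
            for x, r in zip(res.input_grid, res.rates[:, index_of(readout)]):
                rows.append({"panel": panel, "condition": cond, "input": x,
                             "readout": readout, "pyr_rate": r})
    return ExperimentResult("translaminar_propagation", spec.config_dict(),
                            {"curves": pd.DataFrame(rows)})


def input_weighted_drive(spec: ExperimentSpec) -> ExperimentResult:
    """Rates and spectra under scaled per-population external drive.

    ``spec.extras['input_weights']`` must map vector names (e.g. feedforward,
    feedback) to per-cell-class or per-population weights normalized to PYR.
    """
    weights = spec.extras.get("input_weights")
    if not weights:
        raise ValueError(
            "input_weighted_drive requires extras['input_weights']; "
            "ILLUSTRATIVE_INPUT_WEIGHTS provides flagged example vectors")
    amplitudes = spec.extras.get("amplitudes", tuple(np.arange(0.0, 41.0, 5.0)))
    C0, params = spec.base_matrix(), spec.model_params()
    rate_rows, peak_rows = [], []
    for wi, (name, wdict) in enumerate(sorted(weights.items())):
        wvec = StimulusProtocol.from_dict(dict(wdict)).baseline
        for gi, G in enumerate(spec.G_values):
            C = scale_by_G(C0, G)
            for ai, amp in enumerate(amplitudes):
                stim = StimulusProtocol(baseline=spec.base_stim().baseline,
                                        input_weights=wvec, amplitude=float(amp))
                from .model import steady_state
                ss = steady_state(C, params, stim, duration=spec.settle_ms)
                for k, lbl in enumerate(POPULATIONS):
                    rate_rows.append({"weights": name, "G": G, "amplitude": amp,
                                      "population": lbl, "rate": ss.rates[k]})
                if ai % max(1, len(amplitudes) // 3) == 0:
                    peaks = _spectral_peaks(C, params, stim, spec,
                                            tag=wi * 10000 + gi * 100 + ai)
                    for layer, pk in peaks.items():
                        peak_rows.append({"weights": name, "G": G,
                                          "amplitude": amp, "layer": layer,
                                          "peak_frequency": pk.frequency,
                                          "peak_power": pk.power,
                                          "found": pk.found})
    return ExperimentResult("input_weighted_drive", spec.config_dict(),
                            {"rates": pd.DataFrame(rate_rows),
                             "peaks": pd.DataFrame(peak_rows)})


def inverted_selfconnection_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Sweeps with PV and SST self-connections exchanged.

    Moving the strong PV self-inhibition onto SST cells tests whether the
    asymmetry in self-inhibition explains which interneuron class mediates
    the inhibited versus disinhibited state.
    """
    swapped = apply_lesion(spec.base_matrix(),
                           LesionSpec("swap_self_connections"))
    sub = replace(spec, matrix=swapped, lesions=[],
                  extras={**spec.extras, "switches": ("SST", "VIP", "PV")})
    inner = switch_sweeps(sub)
    return ExperimentResult("inverted_selfconnection_experiment",
                            spec.config_dict(), inner.tables)


PROTOCOLS: dict[str, Callable[[ExperimentSpec], ExperimentResult]] = {
    "spontaneous_g_sweep": spontaneous_g_sweep,
    "lesion_battery": lesion_battery,
    "switch_sweeps": switch_sweeps,
    "time_constant_sweep": time_constant_sweep,
    "translaminar_propagation": translaminar_propagation,
    "input_weighted_drive": input_weighted_drive,
    "inverted_selfconnection_experiment": inverted_selfconnection_experiment,
}


def run_experiment(name: str, spec: ExperimentSpec | None = None) -> ExperimentResult:
    """Run a registered protocol by name."""
    if name not in PROTOCOLS:
        raise KeyError(f"unknown protocol {name!r}; see PROTOCOLS")
    spec = spec or ExperimentSpec(name=name)
    spec = replace(spec, name=name)
    return PROTOCOLS[name](spec)
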