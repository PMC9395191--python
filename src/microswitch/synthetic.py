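"""Surrogate connectivity carrying the canonical microcircuit motifs.

The empirical pairwise-recording tables are licensed data that ship with the
original study; this module generates surrogate matrices reproducing the
structural features the analysis relies on, so every stage of the pipeline is
testable without them:

* PV self-inhibition is the strongest entry of the matrix in each layer, and
  stronger in the deep layer than superficially;
* SST cells have exactly zero self-inhibition;
* mutual inhibition between SST and PV and between SST and VIP in each layer
  (the substrate of the two winner-take-all switches);
* strong superficial-to-deep pyramidal excitation;
* translaminar SST projections (deep-to-superficial by default, optionally
  both directions);
* the VIP_deep output column is confined to deep-layer targets, VIP_sup to
  superficial ones;
* inhibitory weights sit at roughly one fifth of the comparable excitatory
  scale before the PV self-entries.

Default magnitudes are a one-off calibration placing the circuit in the
oscillatory, switch-capable regime for global couplings G between roughly 100
and 500; they are a modeling fixture, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (
    MORPHOLOGICAL_TYPES,
    MORPH_TO_POPULATION,
    ConnectivityError,
    ConnectivityMatrix,
    RawConnectivityData,
    build_corrected_matrix,
)
from .populations import N_POP, POPULATIONS, index_of, layer_indices

__all__ = ["MotifSpec", "generate_matrix", "generate_raw", "fixture_matrix"]


def _default_prevalence() -> dict[str, float]:
    return {
        "PV_sup": 0.5, "SST_sup": 0.3, "VIP_sup": 0.2,
        "PV_deep": 0.55, "SST_deep": 0.35, "VIP_deep": 0.1,
    }


@dataclass
class MotifSpec:
    """Parameters of the surrogate matrix (weights are signed, pre-G).

    Excitatory weights are positive, inhibitory negative.  ``background_scale``
    and ``background_sparsity`` control the weak unstructured entries filling
    connections the motif list leaves open; only these depend on ``seed``.
    """

    # PV self-inhibition: strongest entries, deep > superficial
    pv_self_sup: float = -0.18
    pv_self_deep: float = -0.26
    # mutual-inhibition switch motifs (same in both layers)
    sst_to_pv: float = -0.030
    pv_to_sst: float = -0.015
    sst_to_vip: float = -0.015
    vip_to_sst: float = -0.007
    # within-layer excitation
    pyr_self: float = 0.002
    pyr_to_pv: float = 0.160
    pyr_to_sst: float = 0.035
    pyr_to_vip: float = 0.008
    # within-layer inhibition onto PYR and PV
    pv_to_pyr: float = -0.120
    sst_to_pyr: float = -0.006
    vip_to_pyr_sup: float = -0.0002
    vip_to_pyr_deep: float = -0.0001
    vip_to_pv: float = -0.0005
    # translaminar structure
    pyr_sup_to_pyr_deep: float = 0.030
    pyr_sup_to_pv_deep: float = 0.015
    pyr_deep_to_pyr_sup: float = 0.004
    sst_translaminar: float = -0.010        # onto PYR, PV, VIP of the other layer
    sst_translaminar_directions: tuple[str, ...] = ("deep_to_sup",)
    pv_translaminar_to_pyr: float = -0.008
    # unstructured remainder
    background_scale: float = 0.002
    background_sparsity: float = 0.5
    seed: int = 0
    prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    inhibitory_scale: float = 0.2

    def validate(self) -> None:
        if not abs(self.pv_self_deep) > abs(self.pv_self_sup):
            raise ConnectivityError(
                "deep PV self-inhibition must exceed the superficial one")
        others = [
            self.sst_to_pv, self.pv_to_sst, self.sst_to_vip, self.vip_to_sst,
            self.pyr_self, self.pyr_to_pv, self.pyr_to_sst, self.pyr_to_vip,
            self.pv_to_pyr, self.sst_to_pyr, self.vip_to_pyr_sup,
            self.vip_to_pyr_deep, self.vip_to_pv, self.pyr_sup_to_pyr_deep,
            self.pyr_sup_to_pv_deep, self.pyr_deep_to_pyr_sup,
            self.sst_translaminar, self.pv_translaminar_to_pyr,
        ]
        if abs(self.pv_self_sup) <= max(abs(w) for w in others):
            raise ConnectivityError(
                "PV self-inhibition must be the strongest motif weight")
        for d in self.sst_translaminar_directions:
            if d not in ("deep_to_sup", "sup_to_deep"):
                raise ConnectivityError(f"unknown translaminar direction {d!r}")
        for name in ("pyr_self", "pyr_to_pv", "pyr_to_sst", "pyr_to_vip",
                     "pyr_sup_to_pyr_deep", "pyr_sup_to_pv_deep",
                     "pyr_deep_to_pyr_sup"):
            if getattr(self, name) < 0:
                raise ConnectivityError(f"excitatory weight {name} must be >= 0")
        for name in ("pv_self_sup", "pv_self_deep", "sst_to_pv", "pv_to_sst",
                     "sst_to_vip", "vip_to_sst", "pv_to_pyr", "sst_to_pyr",
                     "vip_to_pyr_sup", "vip_to_pyr_deep", "vip_to_pv",
                     "sst_translaminar", "pv_translaminar_to_pyr"):
            if getattr(self, name) > 0:
                raise ConnectivityError(f"inhibitory weight {name} must be <= 0")
        if self.background_scale < 0 or not 0 <= self.background_sparsity <= 1:
            raise ConnectivityError("invalid background parameters")


def _motif_entries(spec: MotifSpec) -> dict[tuple[int, int], float]:
    """(target, source) -> weight for every structured entry."""
    e: dict[tuple[int, int], float] = {}

    def put(target: str, source: str, w: float) -> None:
        e[(index_of(target), index_of(source))] = w

    for layer in ("sup", "deep"):
        pyr, pv, sst, vip = (f"{c}_{layer}" for c in ("PYR", "PV", "SST", "VIP"))
        put(pyr, pyr, spec.pyr_self)
        put(pv, pyr, spec.pyr_to_pv)
        put(sst, pyr, spec.pyr_to_sst)
        put(vip, pyr, spec.pyr_to_vip)
        put(pyr, pv, spec.pv_to_pyr)
        put(pv, pv, spec.pv_self_sup if layer == "sup" else spec.pv_self_deep)
        put(sst, pv, spec.pv_to_sst)
        put(vip, pv, spec.vip_to_pv * 0.0)  # placeholder, see below
        put(pyr, sst, spec.sst_to_pyr)
        put(pv, sst, spec.sst_to_pv)
        put(vip, sst, spec.sst_to_vip)
        put(sst, sst, 0.0)
        put(sst, vip, spec.vip_to_sst)
        put(pv, vip, spec.vip_to_pv)
        put(vip, vip, 0.0)
    # PV -> VIP is weak/absent; drop the placeholder and keep it background
    del e[(index_of("VIP_sup"), index_of("PV_sup"))]
    del e[(index_of("VIP_deep"), index_of("PV_deep"))]

    put("PYR_sup", "VIP_sup", spec.vip_to_pyr_sup)
    put("PYR_deep", "VIP_deep", spec.vip_to_pyr_deep)
    put("PYR_deep", "PYR_sup", spec.pyr_sup_to_pyr_deep)
    put("PV_deep", "PYR_sup", spec.pyr_sup_to_pv_deep)
    put("PYR_sup", "PYR_deep", spec.pyr_deep_to_pyr_sup)
    put("PYR_deep", "PV_sup", spec.pv_translaminar_to_pyr)
    put("PYR_sup", "PV_deep", spec.pv_translaminar_to_pyr)
    if "deep_to_sup" in spec.sst_translaminar_directions:
        for tgt in ("PYR_sup", "PV_sup", "VIP_sup"):
            put(tgt, "SST_deep", spec.sst_translaminar)
    if "sup_to_deep" in spec.sst_translaminar_directions:
        for tgt in ("PYR_deep", "PV_deep", "VIP_deep"):
            put(tgt, "SST_sup", spec.sst_translaminar)
    return e


def _allowed_background(spec: MotifSpec) -> np.ndarray:
    """Boolean mask of entries the background noise may populate."""
    allowed = np.ones((N_POP, N_POP), dtype=bool)
    # VIP output columns are layer-confined
    sup_rows, deep_rows = layer_indices("superficial"), layer_indices("deep")
    allowed[list(deep_rows), index_of("VIP_sup")] = False
    allowed[list(sup_rows), index_of("VIP_deep")] = False
    # SST self-inhibition is structurally absent
    for lbl in ("SST_sup", "SST_deep"):
        k = index_of(lbl)
        allowed[k, k] = False
    for (i, j) in _motif_entries(spec):
        allowed[i, j] = False
    return allowed


def generate_matrix(spec: MotifSpec | None = None) -> ConnectivityMatrix:
    """Surrogate corrected matrix satisfying every structural invariant.

    Motif entries are deterministic; only the weak background entries depend
    on ``spec.seed``.
    """
    spec = spec or MotifSpec()
    spec.validate()
    W = np.zeros((N_POP, N_POP))
    for (i, j), w in _motif_entries(spec).items():
        W[i, j] = w

    rng = np.random.default_rng(spec.seed)
    mask = _allowed_background(spec)
    present = rng.random((N_POP, N_POP)) >= spec.background_sparsity
    mag = np.abs(rng.standard_normal((N_POP, N_POP))) * spec.background_scale
    sign = np.ones(N_POP)
    for j, lbl in enumerate(POPULATIONS):
        if not lbl.startswith("PYR"):
            sign[j] = -1.0
    W = W + np.where(mask & present, mag * sign[None, :], 0.0)

    C = ConnectivityMatrix(W, G=1.0)
    C.check_motifs()
    return C


def generate_raw(spec: MotifSpec | None = None) -> RawConnectivityData:
    """Raw tables whose corrected build reproduces :func:`generate_matrix`.

    The decomposition routes each merged source population's weight through
    one designated morphological subtype (probability one, remaining subtypes
    silent) and undoes the prevalence and inhibitory scaling, so
    ``build_corrected_matrix(generate_raw(s))`` equals ``generate_matrix(s)``
    to machine precision.
    """
    spec = spec or MotifSpec()
    W = generate_matrix(spec).W
    morphs = list(MORPHOLOGICAL_TYPES)
    amp = pd.DataFrame(0.0, index=morphs, columns=morphs)
    prob = pd.DataFrame(0.0, index=morphs, columns=morphs)
    carrier = {  # designated subtype carrying each merged population's output
        pop: next(m for m in morphs if MORPH_TO_POPULATION[m] == pop)
        for pop in POPULATIONS
    }
    prevalence = pd.Series(spec.prevalence)
    for i, tgt_pop in enumerate(POPULATIONS):
        tgt_morphs = [m for m in morphs if MORPH_TO_POPULATION[m] == tgt_pop]
        for j, src_pop in enumerate(POPULATIONS):
            w = W[i, j]
            if w == 0.0:
                continue
            if src_pop.startswith("PYR"):
                raw_w = w
            else:
                raw_w = w / (spec.inhibitory_scale * prevalence[src_pop])
            src = carrier[src_pop]
            for t in tgt_morphs:  # averaged on merge, so same value per row
                amp.loc[t, src] = raw_w
                prob.loc[t, src] = 1.0
    return RawConnectivityData(
        probability=prob, amplitude=amp, prevalence=prevalence,
        inhibitory_scale=spec.inhibitory_scale,
    )


def fixture_matrix() -> ConnectivityMatrix:
    """The committed default surrogate matrix (``MotifSpec()`` with seed 0).

    Loads the CSV shipped with the package; regenerating it with
    :func:`generate_matrix` under the default :class:`MotifSpec` yields the
    same matrix (asserted in the test suite).
    """
    from importlib import resources

    path = resources.files("microswitch").joinpath("data/fixture_matrix.csv")
    with resources.as_file(path) as f:
        return ConnectivityMatrix.from_csv(f)


def _consistency_check() -> bool:  # pragma: no cover - developer utility
    spec = MotifSpec()
    return bool(np.allclose(build_corrected_matrix(generate_raw(spec)).W,
                            generate_matrix(spec).W, atol=1e-12))
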