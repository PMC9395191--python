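"""Effective connectivity of the eight-population microcircuit.

The corrected connectivity matrix ``W`` is oriented row = target,
column = source: entry ``W[i, j]`` is the weight of the connection from
population ``j`` onto population ``i``, so the recurrent input is the
matrix-vector product ``W @ r`` and silencing a population's outputs means
zeroing its column.

Construction from raw pairwise data follows the pipeline used to convert
paired-recording measurements into population weights:

1. element-wise product of the mean EPSP/IPSP amplitude and the connection
   probability over morphological cell types;
2. merge the PV subtypes of each layer (basket + chandelier superficially;
   basket + shrub + horizontally elongated in the deep layer) by summing
   their source columns and averaging their target rows; split VIP cells
   into ``VIP_sup`` (bitufted, superficial targets) and ``VIP_deep``
   (bipolar, deep targets);
3. scale all inhibitory columns by ``inhibitory_scale`` (default 0.2,
   reflecting the roughly 5:1 pyramidal:interneuron head count);
4. multiply each interneuron column by that type's relative prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .populations import (
    EXCITATORY_INDICES,
    INHIBITORY_INDICES,
    N_POP,
    POPULATIONS,
    index_of,
)

__all__ = [
    "MORPHOLOGICAL_TYPES",
    "MORPH_TO_POPULATION",
    "RawConnectivityData",
    "ConnectivityMatrix",
    "LesionSpec",
    "build_corrected_matrix",
    "scale_by_G",
    "apply_lesion",
    "jitter_matrix",
]


#: Morphological cell types of the raw pairwise tables, in table order.
MORPHOLOGICAL_TYPES: tuple[str, ...] = (
    "pyramidal_sup",
    "basket_sup",
    "chandelier_sup",
    "martinotti_sup",
    "bitufted",
    "bipolar",
    "pyramidal_deep",
    "basket_deep",
    "shrub_deep",
    "horizontally_elongated_deep",
    "martinotti_deep",
)

#: Morphological type -> merged model population.
MORPH_TO_POPULATION: dict[str, str] = {
    "pyramidal_sup": "PYR_sup",
    "basket_sup": "PV_sup",
    "chandelier_sup": "PV_sup",
    "martinotti_sup": "SST_sup",
    "bitufted": "VIP_sup",
    "bipolar": "VIP_deep",
    "pyramidal_deep": "PYR_deep",
    "basket_deep": "PV_deep",
    "shrub_deep": "PV_deep",
    "horizontally_elongated_deep": "PV_deep",
    "martinotti_deep": "SST_deep",
}

_EXCITATORY_MORPHS = {"pyramidal_sup", "pyramidal_deep"}
_INTERNEURON_POPULATIONS = tuple(
    lbl for lbl in POPULATIONS if not lbl.startswith("PYR")
)


class ConnectivityError(ValueError):
    """Raised for malformed raw tables or invalid manipulations."""


@dataclass
class RawConnectivityData:
    """Pairwise connectivity measurements over morphological cell types.

    Parameters
    ----------
    probability
        Connection probability, rows = target morphological type,
        columns = source type, entries in [0, 1].
    amplitude
        Mean EPSP/IPSP amplitude (mV), same orientation; columns of
        inhibitory source types must be non-positive (signed IPSPs).
    prevalence
        Relative prevalence fraction of each merged interneuron population
        (indexed by population label, e.g. ``PV_sup``).
    inhibitory_scale
        Scale factor applied to all inhibitory columns (default 0.2).
    """

    probability: pd.DataFrame
    amplitude: pd.DataFrame
    prevalence: pd.Series
    inhibitory_scale: float = 0.2

    def validate(self) -> None:
        for name, table in (("probability", self.probability),
                            ("amplitude", self.amplitude)):
            missing_rows = [t for t in MORPHOLOGICAL_TYPES if t not in table.index]
            missing_cols = [t for t in MORPHOLOGICAL_TYPES if t not in table.columns]
            if missing_rows or missing_cols:
                raise ConnectivityError(
                    f"{name} table is missing morphological types: "
                    f"rows {missing_rows}, columns {missing_cols}"
                )
        p = self.probability.loc[list(MORPHOLOGICAL_TYPES), list(MORPHOLOGICAL_TYPES)]
        if ((p.values < 0) | (p.values > 1)).any():
            raise ConnectivityError("connection probabilities must lie in [0, 1]")
        amp = self.amplitude.loc[list(MORPHOLOGICAL_TYPES), list(MORPHOLOGICAL_TYPES)]
        for morph in MORPHOLOGICAL_TYPES:
            col = amp[morph].values
            if morph in _EXCITATORY_MORPHS:
                if (col < 0).any():
                    raise ConnectivityError(
                        f"excitatory source {morph!r} has negative amplitudes"
                    )
            elif (col > 0).any():
                raise ConnectivityError(
                    f"inhibitory source {morph!r} has positive amplitudes; "
                    "IPSP columns must be signed non-positive"
                )
        missing_prev = [t for t in _INTERNEURON_POPULATIONS
                        if t not in self.prevalence.index]
        if missing_prev:
            raise ConnectivityError(
                f"prevalence missing for interneuron populations: {missing_prev}"
            )
        if (self.prevalence.loc[list(_INTERNEURON_POPULATIONS)].values < 0).any():
            raise ConnectivityError("prevalence fractions must be non-negative")


@dataclass(frozen=True)
class LesionSpec:
    """One surgical manipulation of the connectivity matrix.

    ``kind`` is one of ``silence_cell`` (zero the source's column, i.e.
    remove all its outputs), ``remove_connection`` (zero a single
    target<-source entry), ``set_connection`` (overwrite one entry),
    ``equalize_pv_self`` (set the superficial PV self-weight equal to the
    deep one), ``swap_self_connections`` (exchange PV and SST self-weights
    within each layer) and ``jitter`` (Gaussian perturbation of nonzero
    entries).
    """

    kind: str
    source: str | None = None
    target: str | None = None
    value: float | None = None
    scale: float | None = None
    seed: int | None = None

    _KINDS = (
        "silence_cell",
        "remove_connection",
        "set_connection",
        "equalize_pv_self",
        "swap_self_connections",
        "jitter",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConnectivityError(
                f"unknown lesion kind {self.kind!r}; expected one of {self._KINDS}"
            )
        for attr in ("source", "target"):
            lbl = getattr(self, attr)
            if lbl is not None:
                index_of(lbl)  # raises KeyError on invalid labels


@dataclass
class ConnectivityMatrix:
    """Signed 8x8 effective-weight matrix with manipulation provenance.

    ``W[i, j]`` is the weight FROM population ``j`` TO population ``i``
    in the canonical order :data:`microswitch.populations.POPULATIONS`.
    """

    W: np.ndarray
    G: float = 1.0
    manipulations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (N_POP, N_POP):
            raise ConnectivityError(f"W must be {N_POP}x{N_POP}, got {self.W.shape}")

    # ------------------------------------------------------------------
    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(self.W.copy(), self.G, list(self.manipulations))

    def entry(self, target: str, source: str) -> float:
        return float(self.W[index_of(target), index_of(source)])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=list(POPULATIONS), columns=list(POPULATIONS))

    # -- validation ----------------------------------------------------
    def check_sign_pattern(self) -> bool:
        """True when excitatory columns are >= 0 and inhibitory ones <= 0."""
        W = self.W
        ok_exc = all((W[:, j] >= 0).all() for j in EXCITATORY_INDICES)
        ok_inh = all((W[:, j] <= 0).all() for j in INHIBITORY_INDICES)
        return bool(ok_exc and ok_inh)

    def check_motifs(self) -> None:
        """Assert the structural motifs of the unmanipulated matrix.

        Raises :class:`ConnectivityError` when the matrix violates the
        canonical structure: absent SST self-inhibition, PV self-inhibition
        as the strongest entry of the matrix, and deep PV self-inhibition
        stronger than superficial.
        """
        W = self.W
        if not self.check_sign_pattern():
            raise ConnectivityError("sign pattern violated")
        for lbl in ("SST_sup", "SST_deep"):
            k = index_of(lbl)
            if W[k, k] != 0.0:
                raise ConnectivityError(f"{lbl} self-connection must be exactly 0")
        pv_s, pv_d = index_of("PV_sup"), index_of("PV_deep")
        amax = np.unravel_index(np.argmax(np.abs(W)), W.shape)
        if amax not in ((pv_s, pv_s), (pv_d, pv_d)):
            raise ConnectivityError(
                "strongest absolute entry must be a PV self-connection, "
                f"found {POPULATIONS[amax[0]]}<-{POPULATIONS[amax[1]]}"
            )
        if not abs(W[pv_d, pv_d]) > abs(W[pv_s, pv_s]):
            raise ConnectivityError(
                "deep PV self-inhibition must exceed the superficial one"
            )

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the labeled matrix; round-trips at full float precision."""
        self.as_frame().to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, G: float = 1.0) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        missing = [p for p in POPULATIONS if p not in df.index or p not in df.columns]
        if missing:
            raise ConnectivityError(f"matrix CSV missing populations: {missing}")
        return cls(df.loc[list(POPULATIONS), list(POPULATIONS)].values, G=G)


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def build_corrected_matrix(raw: RawConnectivityData) -> ConnectivityMatrix:
    """Corrected 8x8 matrix from raw pairwise tables (see module docstring)."""
    raw.validate()
    morphs = list(MORPHOLOGICAL_TYPES)
    prob = raw.probability.loc[morphs, morphs].values.astype(float)
    amp = raw.amplitude.loc[morphs, morphs].values.astype(float)
    eff = amp * prob  # element-wise product over morphological types

    eff_df = pd.DataFrame(eff, index=morphs, columns=morphs)
    W = np.zeros((N_POP, N_POP))
    for i, tgt_pop in enumerate(POPULATIONS):
        tgt_morphs = [m for m in morphs if MORPH_TO_POPULATION[m] == tgt_pop]
        for j, src_pop in enumerate(POPULATIONS):
            src_morphs = [m for m in morphs if MORPH_TO_POPULATION[m] == src_pop]
            # outputs of merged subtypes add; a merged target receives the
            # input of a representative (average) subtype cell
            block = eff_df.loc[tgt_morphs, src_morphs].values
            W[i, j] = block.sum(axis=1).mean()

    for lbl in _INTERNEURON_POPULATIONS:
        j = index_of(lbl)
        W[:, j] *= raw.inhibitory_scale * float(raw.prevalence[lbl])
    return ConnectivityMatrix(W, G=1.0)


def scale_by_G(C: ConnectivityMatrix, G: float) -> ConnectivityMatrix:
    """Multiply every weight by the global coupling factor ``G`` (>= 0)."""
    if G < 0:
        raise ConnectivityError(f"G must be non-negative, got {G}")
    out = C.copy()
    out.W = out.W * float(G)
    out.G = C.G * float(G)
    return out


def apply_lesion(C: ConnectivityMatrix, spec: LesionSpec) -> ConnectivityMatrix:
    """Apply one :class:`LesionSpec` and log it in the provenance record."""
    out = C.copy()
    W = out.W
    if spec.kind == "silence_cell":
        if spec.source is None:
            raise ConnectivityError("silence_cell requires a source population")
        W[:, index_of(spec.source)] = 0.0
        out.manipulations.append(f"silence_cell({spec.source})")
    elif spec.kind == "remove_connection":
        if spec.source is None or spec.target is None:
            raise ConnectivityError("remove_connection requires source and target")
        W[index_of(spec.target), index_of(spec.source)] = 0.0
        out.manipulations.append(f"remove_connection({spec.source}->{spec.target})")
    elif spec.kind == "set_connection":
        if spec.source is None or spec.target is None or spec.value is None:
            raise ConnectivityError("set_connection requires source, target, value")
        W[index_of(spec.target), index_of(spec.source)] = float(spec.value)
        out.manipulations.append(
            f"set_connection({spec.source}->{spec.target}={spec.value})"
        )
    elif spec.kind == "equalize_pv_self":
        pv_s, pv_d = index_of("PV_sup"), index_of("PV_deep")
        W[pv_s, pv_s] = W[pv_d, pv_d]
        out.manipulations.append("equalize_pv_self")
    elif spec.kind == "swap_self_connections":
        for pv_lbl, sst_lbl in (("PV_sup", "SST_sup"), ("PV_deep", "SST_deep")):
            pv, sst = index_of(pv_lbl), index_of(sst_lbl)
            W[pv, pv], W[sst, sst] = W[sst, sst], W[pv, pv]
        out.manipulations.append("swap_self_connections")
    elif spec.kind == "jitter":
        if spec.scale is None or spec.seed is None:
            raise ConnectivityError("jitter requires scale and seed")
        return jitter_matrix(C, spec.scale, spec.seed)
    return out


def jitter_matrix(C: ConnectivityMatrix, scale: float, seed: int) -> ConnectivityMatrix:
    """Add zero-mean Gaussian perturbations of SD ``scale`` to nonzero entries.

    Absent connections (exact zeros) stay absent: only measured weights carry
    measurement variability.  Jittered matrices may violate the sign pattern;
    this operation is deliberately exempt from that invariant.
    """
    if scale < 0:
        raise ConnectivityError(f"jitter scale must be non-negative, got {scale}")
    out = C.copy()
    rng = np.random.default_rng(seed)
    mask = out.W != 0.0
    noise = rng.standard_normal(out.W.shape) * float(scale)
    out.W = out.W + np.where(mask, noise, 0.0)
    out.manipulations.append(f"jitter(scale={scale}, seed={seed})")
    return out


def apply_lesions(C: ConnectivityMatrix,
                  specs: Sequence[LesionSpec]) -> ConnectivityMatrix:
    """Apply a sequence of lesions in order."""
    for spec in specs:
        C = apply_lesion(C, spec)
    return C
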