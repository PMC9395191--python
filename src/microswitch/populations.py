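"""Population identities of the two-layer microcircuit.

The circuit comprises eight populations: pyramidal (PYR) cells and three
interneuron classes (PV, SST, VIP) in a superficial (L2/3-like) and a deep
(L5-like) layer.  ``VIP_deep`` cells sit anatomically in the superficial
layer but are functionally assigned to the deep layer because their axons
innervate deep-layer targets.
"""

from __future__ import annotations

from dataclasses import dataclass


#: Canonical population order used by every matrix, vector and CSV.
POPULATIONS: tuple[str, ...] = (
    "PYR_sup",
    "PV_sup",
    "SST_sup",
    "VIP_sup",
    "PYR_deep",
    "PV_deep",
    "SST_deep",
    "VIP_deep",
)

N_POP = len(POPULATIONS)

LAYERS = ("superficial", "deep")
CELL_CLASSES = ("PYR", "PV", "SST", "VIP")


@dataclass(frozen=True)
class Population:
    """Identity card of one modeled population."""

    label: str
    layer: str          # functional layer assignment
    cell_class: str
    sign: str           # "excitatory" or "inhibitory"

    @property
    def index(self) -> int:
        return POPULATIONS.index(self.label)


def _make(label: str) -> Population:
    cls, layer_tag = label.split("_")
    layer = "superficial" if layer_tag == "sup" else "deep"
    sign = "excitatory" if cls == "PYR" else "inhibitory"
    return Population(label=label, layer=layer, cell_class=cls, sign=sign)


POPULATION_INFO: dict[str, Population] = {lbl: _make(lbl) for lbl in POPULATIONS}

#: Indices of excitatory (PYR) populations.
EXCITATORY_INDICES: tuple[int, ...] = tuple(
    i for i, lbl in enumerate(POPULATIONS) if POPULATION_INFO[lbl].sign == "excitatory"
)
#: Indices of inhibitory populations.
INHIBITORY_INDICES: tuple[int, ...] = tuple(
    i for i, lbl in enumerate(POPULATIONS) if POPULATION_INFO[lbl].sign == "inhibitory"
)


def index_of(label: str) -> int:
    """Index of a population label in the canonical order."""
    try:
        return POPULATIONS.index(label)
    except ValueError:
        raise KeyError(
            f"unknown population {label!r}; expected one of {POPULATIONS}"
        ) from None


def layer_indices(layer: str) -> tuple[int, ...]:
    """Indices of all populations functionally assigned to *layer*."""
    if layer not in LAYERS:
        raise KeyError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    return tuple(
        i for i, lbl in enumerate(POPULATIONS) if POPULATION_INFO[lbl].layer == layer
    )


def class_indices(cell_class: str) -> tuple[int, ...]:
    """Indices of both layers' populations of one cell class."""
    if cell_class not in CELL_CLASSES:
        raise KeyError(f"unknown cell class {cell_class!r}")
    return tuple(
        i
        for i, lbl in enumerate(POPULATIONS)
        if POPULATION_INFO[lbl].cell_class == cell_class
    )


def pyr_index(layer: str) -> int:
    """Index of the pyramidal population of *layer* (the LFP-proxy source)."""
    return index_of("PYR_sup" if layer == "superficial" else "PYR_deep")
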