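"""Composite material properties of the healing defect.

Each lattice element is a mixture of newly formed bone, cartilage and
fibrous tissue (proportional to the resident cell counts), the residual
scaffold material, and granulation tissue filling the remainder (MSCs
and empty space both carry granulation-tissue properties).  Every
poroelastic property channel is the volume-weighted (arithmetic) average
of its constituents:

    X = [ (N_max - sum_i N_i) * X_gran + sum_i X_i * N_i ] / N_max

with N_i the per-species load (cell counts 1:1; the scaffold volume
fraction scaled by N_max).  Formed bone carries the subchondral-bone
constants, cartilage the poroelastic-cartilage constants and fibrous
tissue its own table row.  The void ratio is not averaged; it follows
the dominant species of the element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig, TissueProperties, load_tissue_table
from .degradation import ScaffoldState
from .cells import CellField
from .mechanics import StimulusField

__all__ = ["CompositeProperties", "homogenize", "classify_repair_map"]

#: Table rows backing each formed tissue.
SPECIES_TISSUE = {"osteoblast": "subchondral bone",
                  "chondrocyte": "poroelastic cartilage",
                  "fibroblast": "fibrous tissue"}

_CHANNELS = ("elastic_modulus", "poisson_ratio", "permeability",
             "grain_bulk_modulus", "cell_diffusivity")


class CompositionError(ValueError):
    """Species loads exceed the element capacity."""


@dataclass
class CompositeProperties:
    """Per-element homogenised poroelastic constants (lattice maps)."""

    elastic_modulus: np.ndarray
    poisson_ratio: np.ndarray
    permeability: np.ndarray
    grain_bulk_modulus: np.ndarray
    cell_diffusivity: np.ndarray
    void_ratio: np.ndarray


def homogenize(cells: CellField, scaffold: ScaffoldState | None,
               tissue_table: dict[str, TissueProperties] | None = None,
               config: RunConfig | None = None,
               scaffold_poisson_ratio: float | None = None) -> CompositeProperties:
    """Volume-weighted average of the materials occupying each element.

    The scaffold channel uses the *current* degraded modulus of each
    element; a fully degraded element contributes nothing.  Raises
    :class:`CompositionError` if the species loads exceed capacity.
    """
    table = tissue_table or load_tissue_table()
    config = config or RunConfig()
    n_max = config.cell_cap
    shape = cells.msc.shape

    w_scaffold = np.zeros(shape)
    e_scaffold = np.zeros(shape)
    if scaffold is not None:
        w_scaffold = scaffold.N_map(shape[1])
        e_scaffold = scaffold.E_map(shape[1])

    weights = {
        "osteoblast": cells.osteoblast / n_max,
        "chondrocyte": cells.chondrocyte / n_max,
        "fibroblast": cells.fibroblast / n_max,
    }
    # MSCs belong to the granulation remainder, so the Eq-2 species load
    # is the formed phenotypes plus the scaffold fraction only
    w_sum = sum(weights.values()) + w_scaffold
    if np.any(w_sum > 1.0 + 1e-9):
        worst = float(np.max(w_sum))
        raise CompositionError(
            f"species loads exceed element capacity (max total {worst:.4f})")

    gran = table["granulation tissue"]
    scaffold_props = table["scaffold material"]
    nu_scaffold = (scaffold_poisson_ratio
                   if scaffold_poisson_ratio is not None
                   else (config.scaffold_poisson_ratio
                         if config else scaffold_props.poisson_ratio))

    remainder = 1.0 - (sum(weights.values()) + w_scaffold)
    out = {}
    for channel in _CHANNELS:
        acc = remainder * getattr(gran, channel)
        for species, w in weights.items():
            acc = acc + w * getattr(table[SPECIES_TISSUE[species]], channel)
        if channel == "elastic_modulus":
            acc = acc + w_scaffold * e_scaffold
        elif channel == "poisson_ratio":
            acc = acc + w_scaffold * nu_scaffold
        else:
            acc = acc + w_scaffold * getattr(scaffold_props, channel)
        out[channel] = acc

    # void ratio: dominant species (not a homogenised channel)
    stacked = np.stack([remainder, weights["osteoblast"],
                        weights["chondrocyte"], weights["fibroblast"],
                        w_scaffold])
    dominant = np.argmax(stacked, axis=0)
    voids = np.array([gran.void_ratio,
                      table["subchondral bone"].void_ratio,
                      table["poroelastic cartilage"].void_ratio,
                      table["fibrous tissue"].void_ratio,
                      scaffold_props.void_ratio])
    out["void_ratio"] = voids[dominant]
    return CompositeProperties(**out)


def classify_repair_map(stimulus: StimulusField):
    """Tissue-class lattice plus the per-class area-fraction summary.

    Returns ``(class_map, fractions)`` where fractions are percentages
    of defect elements per class (summing to 100).
    """
    return stimulus.tissue_class.copy(), stimulus.class_fractions()
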