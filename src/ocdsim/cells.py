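"""Cell populations on the defect lattice.

Mesenchymal stromal cells (MSCs) enter from the cancellous base and
spread by diffusion; the local mechanical stimulus class then drives
differentiation into osteoblasts, chondrocytes or fibroblasts, mitosis
of the matching phenotype, apoptosis of the mismatched ones and — in the
resorption class — osteoblast loss.  Counts are continuous, bounded by
an effective per-element capacity of ``cell_cap * (1 - N_scaffold)``
(an undegraded strut element holds 50 of the nominal 100 cells; the
room grows as the scaffold erodes).

Daily update order (fixed by design, covered by regression tests):
(1) MSC differentiation, (2) phenotype mitosis/apoptosis, (3) MSC
mitosis limited by the remaining room, (4) proportional down-scaling of
every phenotype on residual overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .config import DefectLattice, RunConfig
from .mechanics import BONE, CARTILAGE, FIBROUS, RESORPTION

__all__ = ["CellField", "init_cells", "effective_capacity", "diffuse_msc",
           "update_populations"]


@dataclass
class CellField:
    """Continuous per-element counts of MSCs and the three phenotypes."""

    msc: np.ndarray
    osteoblast: np.ndarray
    chondrocyte: np.ndarray
    fibroblast: np.ndarray

    def copy(self) -> "CellField":
        return CellField(self.msc.copy(), self.osteoblast.copy(),
                         self.chondrocyte.copy(), self.fibroblast.copy())

    @property
    def total(self) -> np.ndarray:
        return self.msc + self.osteoblast + self.chondrocyte + self.fibroblast

    def totals(self) -> dict[str, float]:
        return {"msc": float(self.msc.sum()),
                "osteoblast": float(self.osteoblast.sum()),
                "chondrocyte": float(self.chondrocyte.sum()),
                "fibroblast": float(self.fibroblast.sum())}


def effective_capacity(config: RunConfig,
                       scaffold_fraction: np.ndarray | None,
                       shape: tuple[int, int]) -> np.ndarray:
    """Per-element cell capacity reduced by the scaffold volume fraction."""
    cap = np.full(shape, config.cell_cap)
    if scaffold_fraction is not None:
        cap = config.cell_cap * (1.0 - np.asarray(scaffold_fraction))
    return cap


def init_cells(lattice: DefectLattice,
               config: RunConfig | None = None) -> CellField:
    """Seed the base-adjacent row with MSCs at capacity; all else empty."""
    config = config or RunConfig()
    shape = (lattice.n_rows, lattice.n_cols)
    msc = np.zeros(shape)
    for (row, col) in lattice.boundary_tags["cancellous_base"]:
        msc[row, col] = config.cell_cap
    z = np.zeros(shape)
    return CellField(msc, z.copy(), z.copy(), z.copy())


def _diffusion_matrix(diffusivity: np.ndarray, h: float, dt: float,
                      source_rows: np.ndarray | None):
    """Implicit 5-point diffusion operator with zero-flux edges.

    Face diffusivities are arithmetic means of the neighbouring element
    values; rows listed in ``source_rows`` become Dirichlet rows (the
    persistent MSC supply from cancellous bone).
    """
    nr, nc = diffusivity.shape
    n = nr * nc
    idx = np.arange(n).reshape(nr, nc)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def add_face(a, b, d_face):
        coeff = dt * d_face / h**2
        rows.extend([a, b]); cols.extend([b, a]); vals.extend([-coeff, -coeff])
        diag[a] += coeff; diag[b] += coeff

    dv = diffusivity
    for i in range(nr):
        for j in range(nc):
            a = idx[i, j]
            if i + 1 < nr:
                add_face(a, idx[i + 1, j], 0.5 * (dv[i, j] + dv[i + 1, j]))
            if j + 1 < nc:
                add_face(a, idx[i, j + 1], 0.5 * (dv[i, j] + dv[i, j + 1]))
    rows.extend(range(n)); cols.extend(range(n)); vals.extend(1.0 + diag)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tolil()
    if source_rows is not None and source_rows.size:
        A[source_rows, :] = 0.0
        A[source_rows, source_rows] = 1.0
    return A.tocsr()


def diffuse_msc(cells: CellField, diffusivity: np.ndarray,
                dt: float, config: RunConfig,
                capacity: np.ndarray | None = None,
                base_source: bool = True) -> CellField:
    """One implicit diffusion step of the MSC field on the defect grid.

    Zero-flux boundaries everywhere except the cancellous base, which —
    when ``base_source`` is set — is held at its effective capacity (the
    continuous MSC supply).  With all-closed boundaries the scheme
    conserves total MSC mass to rounding.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nr, nc = cells.msc.shape
    cap = capacity if capacity is not None else np.full((nr, nc),
                                                        config.cell_cap)
    # room left for MSCs once the differentiated phenotypes are counted
    room = np.maximum(
        cap - (cells.osteoblast + cells.chondrocyte + cells.fibroblast), 0.0)
    source = None
    rhs = cells.msc.ravel().copy()
    if base_source:
        source = np.arange(nc)  # row 0 = cancellous base
        rhs[source] = room.ravel()[source]
    # element size in mm: diffusivities are mm^2/day, dt in days
    h = getattr(config, "element_size", 0.125)
    A = _diffusion_matrix(np.asarray(diffusivity, float), h, dt, source)
    msc = spsolve(A, rhs).reshape(nr, nc)
    out = cells.copy()
    out.msc = np.minimum(np.maximum(msc, 0.0), room)
    return out


def update_populations(cells: CellField, tissue_class: np.ndarray,
                       config: RunConfig,
                       capacity: np.ndarray | None = None) -> CellField:
    """Apply one day of stimulus-driven population dynamics."""
    c = cells.copy()
    cap = capacity if capacity is not None else np.full(c.msc.shape,
                                                        config.cell_cap)
    phen = {BONE: c.osteoblast, CARTILAGE: c.chondrocyte, FIBROUS: c.fibroblast}

    # (1) differentiation: a fraction of local MSCs adopts the phenotype
    # the stimulus favours (cell-conserving transfer); the transferred
    # cells join after this day's mitosis ("already existing" cells only
    # divide)
    moved = {}
    for cls in phen:
        mask = tissue_class == cls
        moved[cls] = config.differentiation_rate * c.msc * mask
        c.msc = c.msc - moved[cls]

    # (2) mechanics-dependent mitosis / apoptosis of pre-existing cells
    for cls, target in phen.items():
        mask = tissue_class == cls
        target *= np.where(mask, 1.0 + config.tissue_mitosis_rate, 1.0)
        for other_cls, other in phen.items():
            if other_cls != cls:
                other *= np.where(mask, 1.0 - config.apoptosis_rate, 1.0)
    resorb = tissue_class == RESORPTION
    c.osteoblast *= np.where(resorb, 1.0 - config.resorption_rate, 1.0)
    for cls, target in phen.items():
        target += moved[cls]

    # (3) mechanics-independent MSC mitosis, limited by the free room
    grown = c.msc * (1.0 + config.msc_mitosis_rate)
    room = np.maximum(cap - (c.osteoblast + c.chondrocyte + c.fibroblast), 0.0)
    c.msc = np.minimum(grown, room)

    # (4) proportional down-scaling on residual overflow
    total = c.total
    over = total > cap
    if np.any(over):
        scale = np.where(over & (total > 0), cap / np.maximum(total, 1e-300),
                         1.0)
        c.msc *= scale
        c.osteoblast *= scale
        c.chondrocyte *= scale
        c.fibroblast *= scale
    return c
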