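"""Condyle-scale poroelastic load case and the mechanoregulation stimulus.

A simplified axisymmetric block of the femoral condyle is solved daily:
articular cartilage at the contact face, subchondral bone above it,
cancellous bone on top, and the cylindrical defect (radius = depth =
5 mm) opening at the articular surface.  The joint contact is idealised
as a rigid, frictionless, freely draining support at the articular
surface; the 0.637 MPa load is ramped over a 1 s compression step on the
top (cancellous) surface and held during a 0.5 s consolidation step.

The octahedral shear strain is sampled at the end of the compression
ramp; the fluid speed is the maximum Darcy flux magnitude over the
consolidation window (drainage peaks there).  Both feed the stimulus

    S = gamma[%] / a + v / b,   a = 3.75 %, b = 3e-3 mm/s,

partitioned into bone resorption (S < 0.01), bone (0.01 <= S < 1),
cartilage (1 <= S < 3) and fibrous tissue (S >= 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fem
from .config import (FLUID_BULK_MODULUS, FLUID_SPECIFIC_WEIGHT,
                     ConfigurationError, DefectLattice, RunConfig,
                     TissueProperties, hyperelastic_linearisation,
                     load_tissue_table)

__all__ = [
    "RESORPTION", "BONE", "CARTILAGE", "FIBROUS", "CLASS_NAMES",
    "StimulusField", "CondyleModel", "MechanicalFailureSignal",
    "octahedral_shear_strain", "classify_stimulus", "storage_coefficient",
]

RESORPTION, BONE, CARTILAGE, FIBROUS = 0, 1, 2, 3
CLASS_NAMES = ("resorption", "bone", "cartilage", "fibrous")


class MechanicalFailureSignal(Exception):
    """Mechanical collapse of the scaffolded defect (run-terminating).

    Mirrors the in-vivo interpretation of a non-converging load case;
    carries the day and the peak element strain observed.
    """

    def __init__(self, day: int, max_strain: float, cause: str):
        self.day = day
        self.max_strain = max_strain
        self.cause = cause
        super().__init__(f"day {day}: {cause} (max strain {max_strain:.3g})")


@dataclass
class StimulusField:
    """Per-lattice-element mechanical state and tissue class."""

    gamma_pct: np.ndarray    # octahedral shear strain, %
    v: np.ndarray            # Darcy flux magnitude, mm/s
    S: np.ndarray            # dimensionless stimulus
    tissue_class: np.ndarray  # int codes, see CLASS_NAMES
    #: e_zz at the compression-load peak (compression negative); the
    #: failure surrogate reads the undrained elastic response here even
    #: when the stimulus samples the consolidated state
    axial_strain: np.ndarray

    def class_fractions(self) -> dict[str, float]:
        """Percent of defect elements per tissue class."""
        n = self.tissue_class.size
        return {name: 100.0 * float(np.sum(self.tissue_class == code)) / n
                for code, name in enumerate(CLASS_NAMES)}


def octahedral_shear_strain(strain: np.ndarray) -> np.ndarray:
    """Octahedral shear strain of axisymmetric tensor strain(s).

    ``strain[..., :] = [e_rr, e_zz, e_tt, e_rz]`` with the *tensor* shear
    component e_rz (half the engineering shear).  The hoop strain is a
    principal strain; the remaining two follow from the in-plane 2x2
    block.  gamma_oct = (2/3) sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2).
    """
    e = np.asarray(strain, float)
    err, ezz, ett, erz = e[..., 0], e[..., 1], e[..., 2], e[..., 3]
    mean = (err + ezz) / 2.0
    rad = np.sqrt(((err - ezz) / 2.0) ** 2 + erz**2)
    e1, e2, e3 = mean + rad, mean - rad, ett
    return (2.0 / 3.0) * np.sqrt((e1 - e2) ** 2 + (e2 - e3) ** 2
                                 + (e3 - e1) ** 2)


def classify_stimulus(S: np.ndarray,
                      thresholds: tuple[float, float, float]) -> np.ndarray:
    """Map stimulus values onto the half-open threshold partition."""
    t_res, t_bone, t_cart = thresholds
    S = np.asarray(S, float)
    out = np.full(S.shape, FIBROUS, int)
    out[S < t_cart] = CARTILAGE
    out[S < t_bone] = BONE
    out[S < t_res] = RESORPTION
    return out


def storage_coefficient(void_ratio, grain_bulk_modulus,
                        fluid_bulk_modulus: float = FLUID_BULK_MODULUS):
    """Specific storage (1/MPa): fluid plus solid-grain compressibility.

    A zero grain bulk modulus means incompressible grains (its term is
    dropped); the effective-stress coefficient is taken as 1 throughout.
    """
    e = np.asarray(void_ratio, float)
    ks = np.asarray(grain_bulk_modulus, float)
    n = e / (1.0 + e)
    grain = np.where(ks > 0, (1.0 - n) / np.where(ks > 0, ks, 1.0), 0.0)
    return n / fluid_bulk_modulus + grain


# ---------------------------------------------------------------------------


class CondyleModel:
    """Axisymmetric condyle mesh with a lattice-conforming defect window.

    The defect sub-region maps onto the repair lattice: every FE element
    inside the defect covers an integer block of lattice elements whose
    composite properties are averaged into it (the FE mesh may therefore
    be coarser than the lattice — the reduced-resolution mode).
    """

    def __init__(self, config: RunConfig, lattice: DefectLattice,
                 tissue_table: dict[str, TissueProperties] | None = None):
        self.config = config
        self.lattice = lattice
        self.table = tissue_table or load_tissue_table()
        h = config.fe_element_size
        for name, extent in (("domain radius", config.domain_radius),
                             ("domain height", config.domain_height),
                             ("defect radius", config.defect_radius),
                             ("defect depth", config.defect_depth)):
            if abs(extent / h - round(extent / h)) > 1e-9:
                raise ConfigurationError(
                    f"FE element size {h} does not divide {name} {extent}")
        ratio = h / lattice.element_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "FE element size must be an integer multiple of the lattice size")
        self.block = round(ratio)
        self.grid = fem.Grid(0.0, config.domain_radius, 0.0,
                             config.domain_height,
                             round(config.domain_radius / h),
                             round(config.domain_height / h))
        self._label_regions()
        self._lattice_points()

    def _label_regions(self) -> None:
        cfg = self.config
        rc, zc = self.grid.element_centroids()
        self.defect_mask = (rc < cfg.defect_radius) & (zc < cfg.defect_depth)
        cart, nu_cart = hyperelastic_linearisation(
            self.table["hyperelastic cartilage"])
        region_E = np.where(zc < cfg.cartilage_thickness, cart,
                            np.where(zc < cfg.defect_depth,
                                     self.table["subchondral bone"].elastic_modulus,
                                     self.table["cancellous bone"].elastic_modulus))
        region_nu = np.where(zc < cfg.cartilage_thickness, nu_cart,
                             np.where(zc < cfg.defect_depth,
                                      self.table["subchondral bone"].poisson_ratio,
                                      self.table["cancellous bone"].poisson_ratio))
        region_k = np.where(zc < cfg.cartilage_thickness,
                            self.table["hyperelastic cartilage"].permeability,
                            np.where(zc < cfg.defect_depth,
                                     self.table["subchondral bone"].permeability,
                                     self.table["cancellous bone"].permeability))
        region_s = np.where(
            zc < cfg.cartilage_thickness,
            storage_coefficient(self.table["hyperelastic cartilage"].void_ratio,
                                self.table["hyperelastic cartilage"].grain_bulk_modulus),
            np.where(zc < cfg.defect_depth,
                     storage_coefficient(
                         self.table["subchondral bone"].void_ratio,
                         self.table["subchondral bone"].grain_bulk_modulus),
                     storage_coefficient(
                         self.table["cancellous bone"].void_ratio,
                         self.table["cancellous bone"].grain_bulk_modulus)))
        self.region_E, self.region_nu = region_E, region_nu
        self.region_k, self.region_s = region_k, region_s

    def _lattice_points(self) -> None:
        """Global (r, z) of lattice centroids and the FE->lattice blocks."""
        cfg = self.config
        rr, zz_lat = self.lattice.centroids()
        self.lat_r = rr
        self.lat_z = cfg.defect_depth - zz_lat  # lattice z=0 at defect base
        # block-average operator: FE defect element -> mean over its
        # (block x block) lattice cells
        b = self.block
        nrow, ncol = self.lattice.n_rows, self.lattice.n_cols
        self._defect_els = np.where(self.defect_mask)[0]
        blocks = []
        rc, zc = self.grid.element_centroids()
        h = cfg.fe_element_size
        for e in self._defect_els:
            c0 = int(round((rc[e] - h / 2) / self.lattice.element_size))
            zg_lo = zc[e] - h / 2
            # lattice rows covered: z_lat in [depth - zg_hi, depth - zg_lo]
            r0_lat = int(round((cfg.defect_depth - (zg_lo + h))
                               / self.lattice.element_size))
            rows = slice(r0_lat, r0_lat + b)
            cols = slice(c0, c0 + b)
            blocks.append((rows, cols))
        self._defect_blocks = blocks

    def _block_average(self, lattice_map: np.ndarray) -> np.ndarray:
        return np.array([float(np.mean(lattice_map[rs, cs]))
                         for rs, cs in self._defect_blocks])

    # -- assembly and solve -------------------------------------------------

    def assemble(self, composite) -> fem.BiotSystem:
        """Assemble the Biot system for one day's defect composition.

        ``composite`` provides lattice maps ``elastic_modulus``,
        ``poisson_ratio``, ``permeability``, ``void_ratio`` and
        ``grain_bulk_modulus`` (see regulation.homogenize).
        """
        E = self.region_E.copy()
        nu = self.region_nu.copy()
        k = self.region_k.copy()
        s = self.region_s.copy()
        E[self._defect_els] = self._block_average(composite.elastic_modulus)
        nu[self._defect_els] = self._block_average(composite.poisson_ratio)
        k[self._defect_els] = self._block_average(composite.permeability)
        s_lat = storage_coefficient(composite.void_ratio,
                                    composite.grain_bulk_modulus)
        s[self._defect_els] = self._block_average(s_lat)
        D = fem.isotropic_D(E, nu)
        mobility = k / FLUID_SPECIFIC_WEIGHT
        return fem.assemble_system(
            self.grid, D, mobility, s,
            support_r_max=self.config.support_radius,
            foundation_stiffness=self.config.support_stiffness)

    def solve_load_case(self, system: fem.BiotSystem) -> fem.LoadCaseResult:
        cfg = self.config
        # the articular surface bathes in joint fluid: free drainage along
        # the whole bottom edge during consolidation
        drainage = np.array([self.grid.pnode_id(i, 0)
                             for i in range(self.grid.nr + 1)])
        return fem.solve_consolidation(
            system, cfg.load_pressure, cfg.compression_duration,
            cfg.n_compression_steps, cfg.consolidation_duration,
            cfg.n_consolidation_steps, drainage)

    def extract_stimulus(self, system: fem.BiotSystem,
                         result: fem.LoadCaseResult,
                         composite) -> StimulusField:
        """Sample gamma, v and S at every lattice-element centroid."""
        cfg = self.config
        r = self.lat_r.ravel()
        z = self.lat_z.ravel()
        u = (result.u_final if cfg.gamma_sampling == "consolidation_end"
             else result.u_compression)
        strain = fem.eval_strain(self.grid, u, r, z)
        tensor = strain.copy()
        tensor[:, 3] *= 0.5  # engineering -> tensor shear
        gamma = octahedral_shear_strain(tensor)
        strain_peak = fem.eval_strain(self.grid, result.u_compression, r, z)
        mobility = (composite.permeability.ravel() / FLUID_SPECIFIC_WEIGHT)
        v = np.zeros(r.size)
        for p in result.p_consolidation:
            grad = fem.eval_pressure_gradient(self.grid, p, r, z)
            v = np.maximum(v, mobility * np.hypot(grad[:, 0], grad[:, 1]))
        gamma_pct = 100.0 * gamma
        S = gamma_pct / cfg.stimulus_a + v / cfg.stimulus_b
        cls = classify_stimulus(S, cfg.stimulus_thresholds())
        shape = (self.lattice.n_rows, self.lattice.n_cols)
        return StimulusField(
            gamma_pct=gamma_pct.reshape(shape),
            v=v.reshape(shape),
            S=S.reshape(shape),
            tissue_class=cls.reshape(shape),
            axial_strain=strain_peak[:, 1].reshape(shape),
        )

    def run_day(self, composite) -> StimulusField:
        """Assemble, solve and sample one daily load case."""
        system = self.assemble(composite)
        result = self.solve_load_case(system)
        return self.extract_stimulus(system, result, composite)
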