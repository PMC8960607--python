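"""Domain types, tissue-property tables, geometry and run configuration.

Units used throughout the package: mm, N, MPa, s for mechanics;
days for the repair/degradation calendar; cells per lattice element for
populations.  Volume fractions are stored in [0, 1] and rendered as
percentages only in reports.

Coordinate conventions
----------------------
Defect lattice: ``z = 0`` at the defect base (interface with cancellous
bone), ``z = 5`` mm at the articular surface; the symmetry axis is at
``r = 0``.  The finite-element model uses a global axial coordinate with
the articular surface at ``z_g = 0``, so ``z_g = defect_depth - z``.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TissueProperties",
    "DefectLattice",
    "ScaffoldLayout",
    "DegradationParams",
    "RunConfig",
    "ConfigurationError",
    "FLUID_SPECIFIC_WEIGHT",
    "FLUID_BULK_MODULUS",
    "load_tissue_table",
    "build_defect_lattice",
    "build_scaffold_layout",
    "hyperelastic_linearisation",
    "load_config",
    "PRESETS",
    "preset",
    "scaled_fixture_config",
    "MODALITIES",
]

#: Specific weight of the wetting liquid, N/mm^3 (all poroelastic tissues).
FLUID_SPECIFIC_WEIGHT = 9.74e-6
#: Bulk modulus of the pore fluid, MPa.
FLUID_BULK_MODULUS = 2300.0


class ConfigurationError(ValueError):
    """Raised for inconsistent geometry or run configuration."""


@dataclass(frozen=True)
class TissueProperties:
    """Per-material constants of one tissue (or the scaffold material).

    ``elastic_modulus`` in MPa, ``permeability`` is the hydraulic
    conductivity in mm/s, ``grain_bulk_modulus`` in MPa (0 means
    incompressible grains), ``cell_diffusivity`` in mm^2/day.
    """

    name: str
    elastic_modulus: float
    poisson_ratio: float
    permeability: float
    void_ratio: float
    grain_bulk_modulus: float
    cell_diffusivity: float = 0.0
    is_transversely_isotropic: bool = False
    #: directional constants for transversely isotropic tissues
    #: (axis 1 = axial, 2 = radial, 3 = circumferential)
    directional: dict[str, float] | None = None
    is_hyperelastic: bool = False
    c10: float = 0.0  # neo-Hookean C10, MPa
    d1: float = 0.0   # neo-Hookean D1, MPa^-1 (inverse-modulus convention)

    def __post_init__(self) -> None:
        if not self.is_hyperelastic and self.elastic_modulus < 0:
            raise ConfigurationError(f"{self.name}: negative modulus")
        if not -1.0 < self.poisson_ratio <= 0.5:
            raise ConfigurationError(f"{self.name}: Poisson ratio out of (-1, 0.5]")
        if self.permeability < 0:
            raise ConfigurationError(f"{self.name}: negative permeability")


def _tissue_table() -> dict[str, TissueProperties]:
    t = {}
    t["subchondral bone"] = TissueProperties(
        "subchondral bone", 17000.0, 0.3, 9.74e-11, 0.042, 13920.0, 0.01)
    t["cancellous bone"] = TissueProperties(
        "cancellous bone", 6000.0, 0.3, 3.63e-8, 4.0, 13920.0, 0.01)
    t["poroelastic cartilage"] = TissueProperties(
        "poroelastic cartilage", 10.0, 0.167, 4.87e-8, 4.0, 3700.0, 0.05)
    t["fibrous tissue"] = TissueProperties(
        "fibrous tissue", 2.0, 0.167, 9.74e-8, 4.0, 2300.0, 0.10)
    t["granulation tissue"] = TissueProperties(
        "granulation tissue", 0.2, 0.167, 9.74e-8, 4.0, 2300.0, 0.80)
    t["meniscus"] = TissueProperties(
        "meniscus", 100.0, 0.0015, 4.87e-8, 4.0, 3700.0, 0.0,
        is_transversely_isotropic=True,
        directional={
            "E1": 0.5, "E2": 0.5, "E3": 100.0,
            "nu12": 0.5, "nu23": 0.0015, "nu31": 0.0015,
            "G12": 0.167, "G23": 0.05, "G31": 0.05,
        })
    t["hyperelastic cartilage"] = TissueProperties(
        "hyperelastic cartilage", 10.0, 0.167, 4.87e-8, 4.0, 3700.0, 0.0,
        is_hyperelastic=True, c10=2.14, d1=0.399)
    # Synthetic scaffold material: 50% porosity, E = 1000 MPa.  The Poisson
    # ratio is not tabulated for the scaffold; 0.3 (typical rigid polymer)
    # is the package default and is configurable.
    t["scaffold material"] = TissueProperties(
        "scaffold material", 1000.0, 0.3, 3.63e-8, 4.0, 0.0, 0.01)
    return t


def load_tissue_table() -> dict[str, TissueProperties]:
    """Return the per-tissue material constants used by every stage."""
    return _tissue_table()


def hyperelastic_linearisation(props: TissueProperties) -> tuple[float, float]:
    """Small-strain (E, nu) equivalent of a neo-Hookean material.

    G = 2*C10 and K = 2/D1 with D1 in MPa^-1.  For the tabulated healthy
    cartilage (C10 = 2.14, D1 = 0.399) this gives E = 10.0 MPa and
    nu = 0.167, i.e. exactly the poroelastic-cartilage constants, which
    is the internal consistency check for the D1 unit convention.
    """
    if not props.is_hyperelastic:
        raise ValueError("not a hyperelastic material")
    g = 2.0 * props.c10
    k = 2.0 / props.d1
    e = 9.0 * k * g / (3.0 * k + g)
    nu = (3.0 * k - 2.0 * g) / (2.0 * (3.0 * k + g))
    return e, nu


# ---------------------------------------------------------------------------
# Lattice and scaffold geometry


@dataclass(frozen=True)
class DefectLattice:
    """Regular grid of square elements covering the axisymmetric defect.

    Row 0 sits at the defect base (cancellous interface, lattice z = 0);
    the last row touches the articular surface.  Column 0 touches the
    symmetry axis.
    """

    n_rows: int
    n_cols: int
    element_size: float
    boundary_tags: dict[str, frozenset[tuple[int, int]]]

    @property
    def n_elements(self) -> int:
        return self.n_rows * self.n_cols

    def centroid(self, row: int, col: int) -> tuple[float, float]:
        """(r, z) centroid in mm, lattice z-convention (z=0 at base)."""
        h = self.element_size
        return ((col + 0.5) * h, (row + 0.5) * h)

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (n_rows, n_cols) of r and z centroids."""
        h = self.element_size
        r = (np.arange(self.n_cols) + 0.5) * h
        z = (np.arange(self.n_rows) + 0.5) * h
        rr, zz = np.meshgrid(r, z)
        return rr, zz


def build_defect_lattice(config: "RunConfig") -> DefectLattice:
    """Mesh the defect into square elements and tag its edges.

    The four lattice edges are partitioned into boundary tags with the
    priority base > articular surface > axis > side; the side wall is
    split into a cartilage-adjacent top band and a subchondral band.
    """
    h = config.element_size
    for name, extent in (("radius", config.defect_radius),
                         ("depth", config.defect_depth)):
        n = extent / h
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"element size {h} does not divide defect {name} {extent}")
    n_cols = round(config.defect_radius / h)
    n_rows = round(config.defect_depth / h)

    tags: dict[str, set[tuple[int, int]]] = {
        "cancellous_base": set(), "articular_surface": set(),
        "axis": set(), "subchondral_side": set(), "cartilage_side": set(),
    }
    for c in range(n_cols):
        tags["cancellous_base"].add((0, c))
        tags["articular_surface"].add((n_rows - 1, c))
    z_cart = config.defect_depth - config.cartilage_thickness
    for r in range(1, n_rows - 1):
        tags["axis"].add((r, 0))
        z = (r + 0.5) * h
        side = "cartilage_side" if z > z_cart else "subchondral_side"
        tags[side].add((r, n_cols - 1))
    frozen = {k: frozenset(v) for k, v in tags.items()}
    return DefectLattice(n_rows, n_cols, h, frozen)


@dataclass(frozen=True)
class ScaffoldLayout:
    """Placement of the vertical struts on the defect lattice.

    Each strut occupies a block of adjacent element columns over the full
    defect height; the outermost column on each side of a strut is a
    *surface* column, interior columns are *bulk*.
    """

    strut_center_radii: tuple[float, ...]
    strut_thickness: float
    strut_height: float
    element_size: float
    n_rows: int
    #: per strut: lattice column indices, ordered by radius
    strut_columns: tuple[tuple[int, ...], ...]

    @property
    def all_columns(self) -> tuple[int, ...]:
        return tuple(c for cols in self.strut_columns for c in cols)

    @property
    def surface_columns(self) -> tuple[int, ...]:
        out = []
        for cols in self.strut_columns:
            if len(cols) == 1:
                out.append(cols[0])
            else:
                out.extend((cols[0], cols[-1]))
        return tuple(out)

    @property
    def bulk_columns(self) -> tuple[int, ...]:
        out = []
        for cols in self.strut_columns:
            if len(cols) > 2:
                out.extend(cols[1:-1])
        return tuple(out)

    @property
    def n_elements(self) -> int:
        return self.n_rows * len(self.all_columns)

    def element_ids(self, strut: int) -> list[tuple[int, int]]:
        return [(r, c) for c in self.strut_columns[strut]
                for r in range(self.n_rows)]

    def column_radii(self, col: int) -> tuple[float, float]:
        """Inner and outer radius of a lattice column (annulus bounds)."""
        h = self.element_size
        return col * h, (col + 1) * h


def build_scaffold_layout(
    lattice: DefectLattice,
    strut_center_radii: tuple[float, ...] = (1.25, 2.5, 3.75),
    strut_thickness: float = 0.5,
) -> ScaffoldLayout:
    h = lattice.element_size
    n_per = strut_thickness / h
    if abs(n_per - round(n_per)) > 1e-9:
        raise ConfigurationError(
            f"element size {h} does not divide strut thickness {strut_thickness}")
    n_per = round(n_per)
    struts = []
    used: set[int] = set()
    for rc in sorted(strut_center_radii):
        start = (rc - strut_thickness / 2.0) / h
        if abs(start - round(start)) > 1e-6:
            raise ConfigurationError(
                f"strut at r={rc} is not aligned with the element grid")
        start = round(start)
        cols = tuple(range(start, start + n_per))
        if cols[0] < 0 or cols[-1] >= lattice.n_cols:
            raise ConfigurationError(f"strut at r={rc} extends outside the defect")
        if used.intersection(cols):
            raise ConfigurationError("struts overlap")
        used.update(cols)
        struts.append(cols)
    return ScaffoldLayout(
        strut_center_radii=tuple(sorted(strut_center_radii)),
        strut_thickness=strut_thickness,
        strut_height=lattice.n_rows * h,
        element_size=h,
        n_rows=lattice.n_rows,
        strut_columns=tuple(struts),
    )


# ---------------------------------------------------------------------------
# Degradation parameters and presets


MODALITIES = ("surface_erosion", "bulk", "bulk_autocatalytic", "exponential")


@dataclass(frozen=True)
class DegradationParams:
    """Rates and constants of one hydrolytic-degradation modality.

    Rates are stored as fractions (``k_N`` in fraction-of-element-volume
    per day, not %/day); percentage tables are converted once at load.
    """

    modality: str
    E0: float = 1000.0           # initial material modulus, MPa
    N0: float = 0.5              # initial volume fraction (porosity 50%)
    k_N: float = 0.0             # erosion rate, fraction/day
    k_E: float = 0.0             # linear modulus-loss rate, MPa/day
    k_e: float = 0.0             # exponential modulus-loss rate, 1/day
    autocatalysis_bulk_multiplier: float = 2.0
    onset_fraction: float = 0.1  # erosion begins at this fraction of E0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if min(self.k_N, self.k_E, self.k_e) < 0:
            raise ConfigurationError("degradation rates must be >= 0")
        if not 0.0 < self.onset_fraction < 1.0:
            raise ConfigurationError("onset_fraction must lie in (0, 1)")


#: Rate presets, keyed (modality, speed).  Linear presets satisfy
#: E0/k_E = nominal completion time (25/50/100 days) and the erosion
#: rates make modulus and volume fraction hit zero on the same day.
PRESETS: dict[tuple[str, str], DegradationParams] = {
    ("surface_erosion", "fast"): DegradationParams("surface_erosion", k_N=0.04),
    ("surface_erosion", "matched"): DegradationParams("surface_erosion", k_N=0.02),
    ("surface_erosion", "slow"): DegradationParams("surface_erosion", k_N=0.01),
    ("bulk", "fast"): DegradationParams("bulk", k_E=40.0, k_N=0.20),
    ("bulk", "matched"): DegradationParams("bulk", k_E=20.0, k_N=0.10),
    ("bulk", "slow"): DegradationParams("bulk", k_E=10.0, k_N=0.05),
    ("bulk_autocatalytic", "fast"):
        DegradationParams("bulk_autocatalytic", k_E=40.0, k_N=0.20),
    ("bulk_autocatalytic", "matched"):
        DegradationParams("bulk_autocatalytic", k_E=20.0, k_N=0.10),
    ("bulk_autocatalytic", "slow"):
        DegradationParams("bulk_autocatalytic", k_E=10.0, k_N=0.05),
    # Experimentally derived exponential rates: slow emulates porous PCL /
    # PDLLA scaffolds, fast porous PLGA.  The slow preset's erosion would
    # only begin at day 768, far beyond every simulated horizon; it reuses
    # the 5%/day erosion rate so the analytic calendar stays total.
    ("exponential", "fast"): DegradationParams("exponential", k_e=0.022, k_N=0.05),
    ("exponential", "slow"): DegradationParams("exponential", k_e=0.003, k_N=0.05),
}


def preset(modality: str, speed: str) -> DegradationParams:
    try:
        return PRESETS[(modality, speed)]
    except KeyError:
        raise ConfigurationError(
            f"no preset for modality={modality!r}, speed={speed!r}") from None


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Everything a simulation run needs besides the degradation rates."""

    # calendar and loading
    total_days: int = 125
    load_pressure: float = 0.637          # MPa, on top of the cancellous bone
    compression_duration: float = 1.0     # s
    consolidation_duration: float = 0.5   # s

    # mechanoregulation stimulus S = gamma[%]/a + v/b and its thresholds
    stimulus_a: float = 3.75              # % octahedral shear strain
    stimulus_b: float = 3.0e-3            # mm/s fluid speed
    threshold_resorption: float = 0.01    # S below: bone resorption
    threshold_bone: float = 1.0           # S below: bone formation
    threshold_cartilage: float = 3.0      # S below: cartilage; above: fibrous

    # cell rules (fractions per day)
    cell_cap: float = 100.0
    differentiation_rate: float = 0.05
    tissue_mitosis_rate: float = 0.05
    apoptosis_rate: float = 0.15
    msc_mitosis_rate: float = 0.15
    resorption_rate: float = 0.10

    # defect geometry
    defect_radius: float = 5.0
    defect_depth: float = 5.0
    element_size: float = 0.125
    strut_center_radii: tuple[float, ...] = (1.25, 2.5, 3.75)
    strut_thickness: float = 0.5

    # condyle finite-element model
    domain_radius: float = 10.0
    domain_height: float = 10.0
    cartilage_thickness: float = 1.0
    #: contact idealisation of the condyle/meniscus/tibial-plateau
    #: interface: a rigid, frictionless, freely draining vertical support
    #: under the central contact footprint (``support_radius``); the
    #: articular surface further out curves away from the plateau and is
    #: free.  Setting ``support_stiffness`` > 0 replaces the rigid
    #: support with a Winkler foundation of that modulus (MPa/mm).
    support_radius: float = 5.0
    support_stiffness: float = 0.0
    #: sampling instant of the octahedral shear strain: "consolidation_end"
    #: (skeleton strain after the load cycle, default) or "compression_end"
    gamma_sampling: str = "consolidation_end"
    fe_element_size: float = 0.5          # resolves the 0.5 mm struts
    n_compression_steps: int = 5
    n_consolidation_steps: int = 5
    scaffold_poisson_ratio: float = 0.3

    # failure surrogate (configuration, not physics constants)
    strain_cap: float = 1.0               # octahedral shear strain, fraction
    #: an element counts as load-bearing scaffold while its effective
    #: modulus E_t*N_t exceeds this fraction of the initial E0*N0
    load_bearing_fraction: float = 0.01
    enable_strain_check: bool = True
    enable_buckling_check: bool = True

    # stiffness evaluation
    reference_stiffness: float = 2445.0   # K0, N/mm
    stiffness_strain: float = 0.03        # applied compressive strain

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("differentiation_rate", "tissue_mitosis_rate",
                     "apoptosis_rate", "msc_mitosis_rate", "resorption_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.threshold_resorption < self.threshold_bone
                < self.threshold_cartilage):
            raise ConfigurationError("stimulus thresholds must be increasing")

    def stimulus_thresholds(self) -> tuple[float, float, float]:
        return (self.threshold_resorption, self.threshold_bone,
                self.threshold_cartilage)


_SECTION_FIELDS = {
    "geometry": ("defect_radius", "defect_depth", "element_size",
                 "strut_center_radii", "strut_thickness", "domain_radius",
                 "domain_height", "cartilage_thickness"),
    "cells": ("cell_cap", "differentiation_rate", "tissue_mitosis_rate",
              "apoptosis_rate", "msc_mitosis_rate", "resorption_rate"),
    "mechanics": ("load_pressure", "compression_duration",
                  "consolidation_duration", "fe_element_size",
                  "n_compression_steps", "n_consolidation_steps",
                  "stimulus_a", "stimulus_b", "scaffold_poisson_ratio",
                  "strain_cap", "enable_strain_check", "enable_buckling_check"),
    "run": ("total_days", "rng_seed", "reference_stiffness",
            "stiffness_strain"),
}


def load_config(path: str | Path) -> tuple[RunConfig, DegradationParams]:
    """Read a TOML run configuration.

    Sections: ``[geometry]``, ``[degradation]``, ``[cells]``,
    ``[mechanics]``, ``[run]``.  ``[degradation]`` selects either a
    preset (``modality`` + ``speed``) or explicit rates; every RunConfig
    default is overridable from its section.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    run_kwargs: dict = {}
    valid = {f.name for f in fields(RunConfig)}
    for section, allowed in _SECTION_FIELDS.items():
        for key, value in raw.get(section, {}).items():
            if key not in allowed or key not in valid:
                raise ConfigurationError(f"unknown key [{section}] {key}")
            if isinstance(value, list):
                value = tuple(value)
            run_kwargs[key] = value
    config = RunConfig(**run_kwargs)

    deg = raw.get("degradation", {})
    if "speed" in deg:
        params = preset(deg.get("modality", "bulk"), deg["speed"])
        overrides = {k: v for k, v in deg.items()
                     if k not in ("modality", "speed")}
        if overrides:
            params = replace(params, **overrides)
    else:
        params = DegradationParams(**deg)
    return config, params


def scaled_fixture_config(**overrides) -> RunConfig:
    """8x8 test-scale configuration (see driver.make_fixture)."""
    base = dict(
        element_size=0.625,
        strut_center_radii=(2.5,),
        strut_thickness=1.25,
        fe_element_size=2.5,
        total_days=5,
        n_compression_steps=3,
        n_consolidation_steps=3,
    )
    base.update(overrides)
    return RunConfig(**base)
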