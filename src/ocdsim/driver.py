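"""Daily simulation loop, failure surrogate, outputs and fixtures.

One iteration corresponds to one day of the in-vivo repair process:
solve the condyle load case, classify the stimulus, update the cell
populations, advance scaffold degradation, re-homogenise the defect
properties.  The loop is fully deterministic for a given configuration
(no randomness in the core model; the configured seed is reserved for
perturbation studies).

Mechanical failure is a surrogate for the structural collapse that a
full-contact FE model signals by non-convergence: the run ends when the
solver diverges, when a load-bearing scaffold element exceeds the
configured octahedral-strain cap, or when a strut's remaining contiguous
material column becomes slender enough that its axial compression
exceeds the Euler buckling strain pi^2 t^2 / (12 L^2).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cells import (CellField, diffuse_msc, effective_capacity, init_cells,
                    update_populations)
from .config import (DefectLattice, DegradationParams, RunConfig,
                     build_defect_lattice, build_scaffold_layout,
                     load_tissue_table, scaled_fixture_config)
from .degradation import (MilestoneReport, ScaffoldState, init_scaffold_state,
                          milestones, step)
from .fem import SolverError
from .mechanics import CLASS_NAMES, CondyleModel, StimulusField
from .regulation import homogenize
from .stiffness import StiffnessModel, scaffold_stiffness

__all__ = ["Failure", "SimulationResult", "run_simulation", "detect_failure",
           "write_outputs", "make_fixture", "Fixture"]


@dataclass(frozen=True)
class Failure:
    day: int
    cause: str
    max_strain: float


@dataclass
class SimulationResult:
    """Per-day bookkeeping of one simulation run."""

    records: pd.DataFrame
    final_maps: dict[str, np.ndarray]
    failure: Failure | None
    milestones: MilestoneReport
    config: RunConfig
    params: DegradationParams

    def class_fraction_drift(self, day_a: int, day_b: int) -> float:
        """Largest change (percentage points) of any tissue-class area
        fraction between two recorded days."""
        rec = self.records.set_index("day")
        cols = [f"frac_{name}" for name in CLASS_NAMES]
        return float((rec.loc[day_b, cols] - rec.loc[day_a, cols]).abs().max())


def detect_failure(state: ScaffoldState, stimulus: StimulusField,
                   config: RunConfig) -> Failure | None:
    """Failure surrogate for the degrading strut scaffold.

    Two checks (beyond solver divergence, which the loop handles):

    * strain cap — any element still holding scaffold material whose
      octahedral shear strain exceeds ``config.strain_cap``;
    * empty-shell buckling — once a strut's interior columns are fully
      degraded its remaining face sheets stand as independent slender
      pillars; each surviving contiguous run of columns fails when its
      height-averaged axial compression (at the undrained load peak)
      exceeds the Euler strain pi^2 t^2 / (12 L^2).

    The buckling clause applies only to hollowed struts: a strut eroding
    from the outside inward keeps a contiguous core of intact material
    and is treated as stable, mirroring the observation that gradual
    thinning does not destabilise the load path the way interior
    degradation does.
    """
    layout = state.layout
    n_cols = stimulus.gamma_pct.shape[1]
    if config.enable_strain_check:
        n_map = state.N_map(n_cols)
        e_map = state.E_map(n_cols)
        floor = config.load_bearing_fraction * state.E0 * state.N0
        mask = e_map * n_map > floor
        if np.any(mask):
            worst = float(np.max(stimulus.gamma_pct[mask])) / 100.0
            if worst > config.strain_cap:
                return Failure(state.day + 1, "excessive_strain", worst)

    if config.enable_buckling_check:
        h = layout.element_size
        L = layout.strut_height
        flat_cols = list(layout.all_columns)
        bulk_cols = set(layout.bulk_columns)
        for sl_cols, sl in zip(layout.strut_columns, _strut_slices(state)):
            interior = [i for i, c in enumerate(sl_cols) if c in bulk_cols]
            if not interior:
                continue  # strut has no bulk: cannot become an empty shell
            idx = [flat_cols.index(c) for c in sl_cols]
            if not all(state.fully_degraded[idx[i]] for i in interior):
                continue
            alive = state.N[sl] > 0.0
            for run in _contiguous_runs(alive):
                cols = [sl_cols[i] for i in run]
                t_eff = len(cols) * h
                eps_cr = math.pi**2 * t_eff**2 / (12.0 * L**2)
                eps = float(np.mean(np.maximum(
                    -stimulus.axial_strain[:, cols], 0.0)))
                if eps > eps_cr:
                    return Failure(state.day + 1, "empty_shell_buckling", eps)
    return None


def _strut_slices(state: ScaffoldState) -> list[slice]:
    return state.column_slices()


def _contiguous_runs(alive: np.ndarray) -> list[list[int]]:
    runs, current = [], []
    for i, a in enumerate(alive):
        if a:
            current.append(i)
        elif current:
            runs.append(current); current = []
    if current:
        runs.append(current)
    return runs


def run_simulation(config: RunConfig,
                   params: DegradationParams) -> SimulationResult:
    """Run the iterative repair model until total_days or failure."""
    table = load_tissue_table()
    lattice = build_defect_lattice(config)
    layout = build_scaffold_layout(lattice, config.strut_center_radii,
                                   config.strut_thickness)
    state = init_scaffold_state(layout, params)
    cells = init_cells(lattice, config)
    model = CondyleModel(config, lattice, table)
    smodel = StiffnessModel(config.reference_stiffness,
                            config.stiffness_strain)
    calendar = milestones(params, layout)

    shape = (lattice.n_rows, lattice.n_cols)
    rows = []
    failure: Failure | None = None
    stim: StimulusField | None = None

    for day in range(1, config.total_days + 1):
        composite = homogenize(cells, state, table, config)
        try:
            stim = model.run_day(composite)
        except SolverError:
            failure = Failure(day, "solver_divergence", float("nan"))
            rows.append(_record(day, state, smodel, stim, cells, lattice))
            break
        failure = detect_failure(state, stim, config)
        if failure is not None:
            rows.append(_record(day, state, smodel, stim, cells, lattice))
            break
        cap = effective_capacity(config, state.N_map(lattice.n_cols), shape)
        cells = diffuse_msc(cells, composite.cell_diffusivity, 1.0, config,
                            capacity=cap)
        cells = update_populations(cells, stim.tissue_class, config,
                                   capacity=cap)
        state = step(state, params)
        rows.append(_record(day, state, smodel, stim, cells, lattice))

    records = pd.DataFrame(rows)
    final_maps = {
        "scaffold_modulus": state.E_map(lattice.n_cols),
        "scaffold_fraction": state.N_map(lattice.n_cols),
        "msc": cells.msc, "osteoblast": cells.osteoblast,
        "chondrocyte": cells.chondrocyte, "fibroblast": cells.fibroblast,
    }
    if stim is not None:
        final_maps.update({
            "stimulus": stim.S, "gamma_pct": stim.gamma_pct,
            "tissue_class": stim.tissue_class.astype(float),
        })
    return SimulationResult(records, final_maps, failure, calendar,
                            config, params)


def _record(day: int, state: ScaffoldState, smodel: StiffnessModel,
            stim: StimulusField | None, cells: CellField,
            lattice: DefectLattice) -> dict:
    row = {
        "day": day,
        "stiffness": scaffold_stiffness(state, smodel),
        "mean_modulus": state.mean_modulus(),
        "scaffold_fraction_pct":
            100.0 * state.total_fraction(lattice.n_elements),
    }
    if stim is not None:
        for name, value in stim.class_fractions().items():
            row[f"frac_{name}"] = value
        row["max_gamma_pct"] = float(np.max(stim.gamma_pct))
    else:
        for name in CLASS_NAMES:
            row[f"frac_{name}"] = float("nan")
        row["max_gamma_pct"] = float("nan")
    for name, value in cells.totals().items():
        row[f"n_{name}"] = value
    return row


# ---------------------------------------------------------------------------
# Outputs


def write_outputs(result: SimulationResult, out_dir: str | Path,
                  vtk: bool = False) -> list[Path]:
    """Write time-series CSV, lattice snapshot grids and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    ts = out / "timeseries.csv"
    result.records.to_csv(ts, index=False, float_format="%.10g")
    written.append(ts)

    for name, grid in result.final_maps.items():
        p = out / f"final_{name}.csv"
        np.savetxt(p, grid, delimiter=",", fmt="%.10g")
        written.append(p)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(result.config),
        "degradation": dataclasses.asdict(result.params),
        "milestones": result.milestones.as_dict(),
        "failure": dataclasses.asdict(result.failure)
        if result.failure else None,
        "days_recorded": int(len(result.records)),
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(mp)

    if vtk:
        from .vtkio import write_lattice_vtk
        vp = out / "final_fields.vtk"
        write_lattice_vtk(vp, result.config, result.final_maps)
        written.append(vp)
    return written


# ---------------------------------------------------------------------------
# Fixtures


@dataclass(frozen=True)
class Fixture:
    config: RunConfig
    lattice: DefectLattice
    params: DegradationParams


def make_fixture(scale: str = "small",
                 modality: str = "bulk",
                 speed: str = "matched") -> Fixture:
    """Run configurations for tests.

    ``small`` is an 8x8 defect lattice with a single 2-column strut and
    degradation rates sped up 5x so every stage runs in seconds;
    ``full`` is the reference configuration.
    """
    from .config import preset

    params = preset(modality, speed)
    if scale == "small":
        config = scaled_fixture_config()
        params = dataclasses.replace(
            params, k_N=5 * params.k_N, k_E=5 * params.k_E,
            k_e=5 * params.k_e)
    elif scale == "full":
        config = RunConfig()
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    lattice = build_defect_lattice(config)
    return Fixture(config, lattice, params)
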