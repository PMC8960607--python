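"""Hydrolytic scaffold degradation: daily state evolution and milestones.

Four modalities are modelled, all phenomenological:

* ``surface_erosion`` — the volume fraction N_t of *surface* elements
  drops linearly (N_t = N0 - k_N t) while the material modulus is
  untouched; a fully eroded column exposes its neighbour, and the part of
  a day's decrement exceeding the dying layer carries over to the newly
  exposed layer, so a 2-layer strut finishes in exactly 2*N0/k_N days.
* ``bulk`` — the material modulus drops linearly and homogeneously
  (E_t = E0 - k_E t) at constant volume; once E_t reaches the onset
  threshold (10% of E0) every element additionally erodes at k_N.
* ``bulk_autocatalytic`` — as bulk, but elements in the strut interior
  degrade at twice the surface rates (trapped acidic by-products).
* ``exponential`` — E_t = E0 exp(-k_e t) homogeneously, with the same
  10%-of-E0 erosion onset; rates taken from degradation experiments on
  porous polyester scaffolds.

Molecular weight is assumed directly proportional to the compressive
modulus and is therefore never stored: every law operates on E_t.

Day convention: iteration ``d`` applies the day-``d`` decrement, and a
milestone "day X" is the first integer day at or after the continuous
crossing time (ceil).  Within the crossing day the erosion decrement is
pro-rated to the post-crossing part of the day, which makes the daily
stepping reproduce the analytic calendar exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DegradationParams, ScaffoldLayout

__all__ = [
    "ScaffoldState",
    "MilestoneReport",
    "init_scaffold_state",
    "step_surface_erosion",
    "step_bulk",
    "step_bulk_autocatalytic",
    "step_exponential",
    "step",
    "milestones",
    "observe_milestones_by_stepping",
    "trajectory",
]

SURFACE, BULK = 0, 1


class ModalityError(ValueError):
    """A step function was called with the wrong modality."""


@dataclass
class ScaffoldState:
    """Per-column scaffold state, broadcast to per-element maps on demand.

    Every degradation law acts uniformly along a strut column, so the
    state is stored once per scaffold column; ``E_map``/``N_map`` expand
    it to full (n_rows, n_cols) lattice arrays.
    """

    layout: ScaffoldLayout
    day: int
    #: flat per-column arrays, ordered as layout.all_columns
    E: np.ndarray          # material modulus, MPa
    N: np.ndarray          # volume fraction in [0, N0]
    label: np.ndarray      # SURFACE or BULK
    eroding: np.ndarray    # bool: volume-fraction loss active
    fully_degraded: np.ndarray  # bool: E = N = 0
    E0: float = 1000.0
    N0: float = 0.5

    def copy(self) -> "ScaffoldState":
        return ScaffoldState(self.layout, self.day, self.E.copy(),
                             self.N.copy(), self.label.copy(),
                             self.eroding.copy(), self.fully_degraded.copy(),
                             self.E0, self.N0)

    # -- per-element views --------------------------------------------------
    def _expand(self, values: np.ndarray, n_cols: int) -> np.ndarray:
        out = np.zeros((self.layout.n_rows, n_cols))
        for v, col in zip(values, self.layout.all_columns):
            out[:, col] = v
        return out

    def E_map(self, n_cols: int) -> np.ndarray:
        """(n_rows, n_cols) lattice map of the material modulus."""
        return self._expand(self.E, n_cols)

    def N_map(self, n_cols: int) -> np.ndarray:
        """(n_rows, n_cols) lattice map of the scaffold volume fraction."""
        return self._expand(self.N, n_cols)

    def column_slices(self) -> list[slice]:
        """Index ranges of each strut within the flat column arrays."""
        out, start = [], 0
        for cols in self.layout.strut_columns:
            out.append(slice(start, start + len(cols)))
            start += len(cols)
        return out

    def mean_modulus(self) -> float:
        """Mean E_t over all scaffold columns (degraded columns count 0)."""
        return float(np.mean(self.E))

    def total_fraction(self, n_lattice_elements: int) -> float:
        """Scaffold material volume as a fraction of the defect volume."""
        n_rows = self.layout.n_rows
        return float(np.sum(self.N) * n_rows / n_lattice_elements)


def init_scaffold_state(layout: ScaffoldLayout,
                        params: DegradationParams) -> ScaffoldState:
    n = len(layout.all_columns)
    label = np.full(n, BULK, dtype=int)
    surface = set(layout.surface_columns)
    for i, col in enumerate(layout.all_columns):
        if col in surface:
            label[i] = SURFACE
    return ScaffoldState(
        layout=layout, day=0,
        E=np.full(n, params.E0), N=np.full(n, params.N0),
        label=label, eroding=np.zeros(n, bool),
        fully_degraded=np.zeros(n, bool),
        E0=params.E0, N0=params.N0)


def _require(params: DegradationParams, modality: str) -> None:
    if params.modality != modality:
        raise ModalityError(
            f"step for {modality!r} called with modality {params.modality!r}")


# ---------------------------------------------------------------------------
# Daily steps


def step_surface_erosion(state: ScaffoldState,
                         params: DegradationParams) -> ScaffoldState:
    """Advance one day of surface erosion (volume loss at the strut faces).

    Each currently-exposed column loses k_N of volume fraction; when a
    column empties its modulus is zeroed, the adjacent interior column
    becomes surface and receives the unspent part of the decrement.
    """
    _require(params, "surface_erosion")
    s = state.copy()
    s.day += 1
    for sl in s.column_slices():
        idx = list(range(sl.start, sl.stop))
        # erode from the outer end of the strut inwards, then from the
        # inner end outwards; each front consumes its own daily budget
        for front in (idx, idx[::-1]):
            budget = params.k_N
            for j in front:
                if budget <= 1e-15:
                    break
                if s.N[j] <= 0.0:
                    continue  # already consumed (possibly by this front)
                dec = min(budget, s.N[j])
                s.N[j] -= dec
                budget -= dec
                if s.N[j] <= 1e-12:
                    s.N[j] = 0.0
                    s.E[j] = 0.0
                    s.fully_degraded[j] = True
                else:
                    s.label[j] = SURFACE
                    s.eroding[j] = True
                    break
        # relabel: any live column adjacent to a dead (or missing)
        # neighbour is now a surface column
        for k, j in enumerate(idx):
            if s.N[j] <= 0.0:
                continue
            left_dead = k == 0 or s.N[idx[k - 1]] <= 0.0
            right_dead = k == len(idx) - 1 or s.N[idx[k + 1]] <= 0.0
            if left_dead or right_dead:
                s.label[j] = SURFACE
                s.eroding[j] = True
    return s


def _bulk_day(state: ScaffoldState, params: DegradationParams,
              rate_E: np.ndarray, rate_N: np.ndarray,
              exponential: bool = False) -> ScaffoldState:
    """Shared modulus-decay + onset-gated erosion logic for the bulk laws.

    The erosion decrement on the day the modulus crosses the onset
    threshold is pro-rated to the post-crossing fraction of the day; the
    crossing time is interpolated exactly for the respective decay law.
    """
    s = state.copy()
    s.day += 1
    e_onset = params.onset_fraction * params.E0
    E_prev = s.E.copy()
    if exponential:
        s.E = params.E0 * np.exp(-params.k_e * s.day)
        s.E = np.where(state.fully_degraded, 0.0, s.E)
    else:
        s.E = np.maximum(E_prev - rate_E, 0.0)

    # fraction of this day spent below the onset threshold
    frac = np.zeros_like(s.E)
    below_now = s.E <= e_onset + 1e-12
    already = E_prev <= e_onset + 1e-12
    frac[already] = 1.0
    crossing = below_now & ~already
    if np.any(crossing):
        if exponential:
            # E_prev * exp(-k_e * f) = e_onset
            f = np.log(E_prev[crossing] / e_onset) / params.k_e
        else:
            f = (E_prev[crossing] - e_onset) / rate_E[crossing]
        frac[crossing] = np.clip(1.0 - f, 0.0, 1.0)

    s.eroding = below_now & (s.N > 0.0)
    s.N = np.maximum(s.N - rate_N * frac, 0.0)
    dead = (s.N <= 1e-12) & below_now
    s.N[dead] = 0.0
    s.E[dead] = 0.0
    s.fully_degraded |= dead
    s.eroding &= ~s.fully_degraded
    return s


def step_bulk(state: ScaffoldState, params: DegradationParams) -> ScaffoldState:
    """One day of homogeneous linear bulk degradation (+ late erosion)."""
    _require(params, "bulk")
    n = len(state.E)
    return _bulk_day(state, params,
                     np.full(n, params.k_E), np.full(n, params.k_N))


def step_bulk_autocatalytic(state: ScaffoldState,
                            params: DegradationParams) -> ScaffoldState:
    """One day of bulk degradation with autocatalysed strut interiors."""
    _require(params, "bulk_autocatalytic")
    m = np.where(state.label == BULK, params.autocatalysis_bulk_multiplier, 1.0)
    return _bulk_day(state, params, m * params.k_E, m * params.k_N)


def step_exponential(state: ScaffoldState,
                     params: DegradationParams) -> ScaffoldState:
    """One day of exponential modulus decay (+ erosion past the onset)."""
    _require(params, "exponential")
    n = len(state.E)
    return _bulk_day(state, params, np.zeros(n), np.full(n, params.k_N),
                     exponential=True)


_STEPPERS = {
    "surface_erosion": step_surface_erosion,
    "bulk": step_bulk,
    "bulk_autocatalytic": step_bulk_autocatalytic,
    "exponential": step_exponential,
}


def step(state: ScaffoldState, params: DegradationParams) -> ScaffoldState:
    """Dispatch the daily step for the configured modality."""
    return _STEPPERS[params.modality](state, params)


# ---------------------------------------------------------------------------
# Analytic milestone calendar


NEVER = None  # sentinel for events that never occur (zero rates)


@dataclass(frozen=True)
class MilestoneReport:
    """Closed-form calendar of the degradation events (integer days)."""

    modality: str
    erosion_onset_day_surface: int | None = NEVER
    erosion_onset_day_bulk: int | None = NEVER
    bulk_complete_day: int | None = NEVER
    first_surface_layer_complete_day: int | None = NEVER
    full_degradation_day: int | None = NEVER

    def as_dict(self) -> dict[str, int | None]:
        return {
            "erosion_onset_day_surface": self.erosion_onset_day_surface,
            "erosion_onset_day_bulk": self.erosion_onset_day_bulk,
            "bulk_complete_day": self.bulk_complete_day,
            "first_surface_layer_complete_day":
                self.first_surface_layer_complete_day,
            "full_degradation_day": self.full_degradation_day,
        }


def _ceil_day(t: float) -> int:
    d = math.ceil(t - 1e-9)
    return max(d, 1)


def _n_layers(layout: ScaffoldLayout) -> int:
    """Erosion layers per strut when peeling from both sides."""
    return max(math.ceil(len(cols) / 2) for cols in layout.strut_columns)


def milestones(params: DegradationParams,
               layout: ScaffoldLayout) -> MilestoneReport:
    """Closed-form degradation calendar for one parameter set.

    Linear onset at (E0 - onset*E0)/rate, exponential onset at
    ln(1/onset)/k_e, completion at onset + N0/k_N; all converted to the
    first integer day at/after the continuous crossing.
    """
    p = params
    if p.modality == "surface_erosion":
        if p.k_N == 0:
            return MilestoneReport(p.modality)
        layer = p.N0 / p.k_N
        return MilestoneReport(
            p.modality,
            erosion_onset_day_surface=1,
            first_surface_layer_complete_day=_ceil_day(layer),
            full_degradation_day=_ceil_day(_n_layers(layout) * layer),
        )
    if p.modality == "bulk":
        if p.k_E == 0:
            return MilestoneReport(p.modality)
        onset = (1.0 - p.onset_fraction) * p.E0 / p.k_E
        full = NEVER if p.k_N == 0 else _ceil_day(onset + p.N0 / p.k_N)
        return MilestoneReport(
            p.modality,
            erosion_onset_day_surface=_ceil_day(onset),
            erosion_onset_day_bulk=_ceil_day(onset),
            bulk_complete_day=full,
            full_degradation_day=full,
        )
    if p.modality == "bulk_autocatalytic":
        if p.k_E == 0:
            return MilestoneReport(p.modality)
        m = p.autocatalysis_bulk_multiplier
        onset_s = (1.0 - p.onset_fraction) * p.E0 / p.k_E
        onset_b = onset_s / m
        full_b = NEVER if p.k_N == 0 else _ceil_day(onset_b + p.N0 / (m * p.k_N))
        full_s = NEVER if p.k_N == 0 else _ceil_day(onset_s + p.N0 / p.k_N)
        return MilestoneReport(
            p.modality,
            erosion_onset_day_surface=_ceil_day(onset_s),
            erosion_onset_day_bulk=_ceil_day(onset_b),
            bulk_complete_day=full_b,
            full_degradation_day=full_s,
        )
    if p.modality == "exponential":
        if p.k_e == 0:
            return MilestoneReport(p.modality)
        onset = math.log(1.0 / p.onset_fraction) / p.k_e
        full = NEVER if p.k_N == 0 else _ceil_day(onset + p.N0 / p.k_N)
        return MilestoneReport(
            p.modality,
            erosion_onset_day_surface=_ceil_day(onset),
            erosion_onset_day_bulk=_ceil_day(onset),
            bulk_complete_day=full,
            full_degradation_day=full,
        )
    raise ValueError(p.modality)


def observe_milestones_by_stepping(
    params: DegradationParams, layout: ScaffoldLayout,
    max_days: int = 1000,
) -> MilestoneReport:
    """Milestone calendar read off the daily-stepped state (the oracle
    counterpart of :func:`milestones`; the two must agree)."""
    state = init_scaffold_state(layout, params)
    first_cols = set()
    for cols in layout.strut_columns:
        if len(cols) == 1:
            first_cols.add(cols[0])
        else:
            first_cols.update((cols[0], cols[-1]))
    first_idx = [i for i, c in enumerate(layout.all_columns) if c in first_cols]
    bulk0 = state.label == BULK

    onset_s = onset_b = bulk_done = first_layer = full = NEVER
    for _ in range(max_days):
        state = step(state, params)
        d = state.day
        surf0 = ~bulk0
        if onset_s is NEVER and np.any((state.eroding | state.fully_degraded)
                                       & surf0):
            onset_s = d
        if onset_b is NEVER and np.any(bulk0) and np.any(
                (state.eroding | state.fully_degraded) & bulk0):
            onset_b = d
        if bulk_done is NEVER and np.any(bulk0) and np.all(
                state.fully_degraded[bulk0]):
            bulk_done = d
        if first_layer is NEVER and np.all(state.fully_degraded[first_idx]):
            first_layer = d
        if full is NEVER and np.all(state.fully_degraded):
            full = d
            break
    if params.modality == "surface_erosion":
        onset_b = bulk_done = NEVER  # interior only erodes once exposed
    if params.modality in ("bulk", "exponential"):
        bulk_done = full
        first_layer = NEVER
    if params.modality == "bulk_autocatalytic":
        first_layer = NEVER
    return MilestoneReport(
        params.modality,
        erosion_onset_day_surface=onset_s,
        erosion_onset_day_bulk=onset_b,
        bulk_complete_day=bulk_done,
        first_surface_layer_complete_day=first_layer,
        full_degradation_day=full,
    )


def trajectory(params: DegradationParams, layout: ScaffoldLayout,
               days: int, n_lattice_elements: int):
    """Per-day (mean E_t, scaffold fraction of defect) via daily stepping.

    Returns a pandas DataFrame indexed by day 0..days with columns
    ``mean_modulus`` (MPa) and ``volume_fraction_pct`` (% of defect).
    """
    import pandas as pd

    state = init_scaffold_state(layout, params)
    rows = [(0, state.mean_modulus(),
             100.0 * state.total_fraction(n_lattice_elements))]
    for _ in range(days):
        state = step(state, params)
        rows.append((state.day, state.mean_modulus(),
                     100.0 * state.total_fraction(n_lattice_elements)))
    return pd.DataFrame(rows, columns=["day", "mean_modulus",
                                       "volume_fraction_pct"]).set_index("day")
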