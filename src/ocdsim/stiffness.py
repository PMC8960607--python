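"""Standalone scaffold stiffness during degradation.

The scaffold alone (three concentric rings under a 3% compressive
displacement) is idealised as parallel annular spring columns: each
strut column contributes E_eff * A / L, where E_eff = E_t * N_t is the
effective modulus combining material softening and volume loss, A the
annular cross-section of the column and L the strut height.  The model
is calibrated once so that the undegraded state returns the reference
initial stiffness K0 (2445 N/mm); homogeneous degradation then reduces
exactly to K(t) = K0 * E_eff(t) / E_eff(0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DegradationParams, ScaffoldLayout
from . import degradation

__all__ = ["StiffnessModel", "effective_modulus", "scaffold_stiffness",
           "stiffness_trajectory"]


@dataclass(frozen=True)
class StiffnessModel:
    """Ring-stack uniaxial model of the standalone scaffold."""

    K0: float = 2445.0           # reference initial stiffness, N/mm
    applied_strain: float = 0.03  # 3% compressive displacement


def effective_modulus(E_t: float, N_t: float) -> float:
    """Effective scaffold modulus E_eff = E_t * N_t (MPa).

    Initial value 1000 MPa * 0.5 = 500 MPa.
    """
    if np.any(np.asarray(E_t) < 0) or np.any(np.asarray(N_t) < 0):
        raise ValueError("modulus and volume fraction must be non-negative")
    return E_t * N_t


def _column_areas(layout: ScaffoldLayout) -> np.ndarray:
    """Annular cross-section area of every scaffold column (mm^2)."""
    areas = []
    for col in layout.all_columns:
        r_in, r_out = layout.column_radii(col)
        areas.append(math.pi * (r_out**2 - r_in**2))
    return np.asarray(areas)


def scaffold_stiffness(state: degradation.ScaffoldState,
                       model: StiffnessModel) -> float:
    """Stiffness K (N/mm) of the degrading scaffold.

    Parallel springs over columns; within a column the height average of
    E_eff is harmonic (stacked springs in series), which coincides with
    the arithmetic mean here because every degradation law leaves each
    column vertically uniform.  A single calibration factor maps the
    undegraded geometry onto K0.
    """
    layout = state.layout
    if layout.strut_height <= 0:
        raise ValueError("zero-height strut")
    areas = _column_areas(layout)
    L = layout.strut_height
    e_eff = effective_modulus(state.E, state.N)       # per column (uniform in z)
    e_eff0 = effective_modulus(state.E0, state.N0)    # undegraded reference
    raw0 = e_eff0 * float(np.sum(areas)) / L
    scale = model.K0 / raw0
    return scale * float(np.sum(e_eff * areas) / L)


def stiffness_trajectory(params: DegradationParams,
                         model: StiffnessModel,
                         layout: ScaffoldLayout,
                         days: int):
    """Per-day stiffness from daily-stepped degradation states.

    Returns a pandas Series indexed by day 0..days; non-increasing, and
    zero from the full-degradation day on for finite-time modalities.
    """
    import pandas as pd

    state = degradation.init_scaffold_state(layout, params)
    values = [scaffold_stiffness(state, model)]
    for _ in range(days):
        state = degradation.step(state, params)
        values.append(scaffold_stiffness(state, model))
    return pd.Series(values, index=pd.RangeIndex(days + 1, name="day"),
                     name="stiffness")
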