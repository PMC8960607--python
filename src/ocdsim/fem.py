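"""Axisymmetric Biot poroelastic finite elements on structured grids.

Small-strain u-p formulation with biquadratic displacement / bilinear
pore pressure (Q9/Q4 Taylor-Hood) quadrilaterals and backward-Euler time
stepping; the effective-stress coefficient is 1 and the storage term
collects fluid and grain compressibility.  Units: mm, N, MPa, s.

The strain vector ordering is ``[e_rr, e_zz, e_tt, gamma_rz]`` with the
engineering shear ``gamma_rz = 2 e_rz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "Grid", "BiotSystem", "SolverError", "AssemblyError",
    "isotropic_D", "transversely_isotropic_D",
    "assemble_system", "solve_elastic", "solve_consolidation",
    "eval_strain", "eval_pressure_gradient",
]


class SolverError(RuntimeError):
    """Linear solve failed (singular or non-finite system)."""


class AssemblyError(ValueError):
    """Inadmissible element properties; carries the offending elements."""


# -- reference shape functions ----------------------------------------------

_G1 = np.sqrt(3.0 / 5.0)
GAUSS_PTS = np.array([-_G1, 0.0, _G1])
GAUSS_WTS = np.array([5.0, 8.0, 5.0]) / 9.0


def _lag2(x):
    """1D quadratic Lagrange basis on [-1, 1] and its derivative."""
    n = np.array([x * (x - 1) / 2, 1 - x * x, x * (x + 1) / 2])
    d = np.array([x - 0.5, -2 * x, x + 0.5])
    return n, d


def _lag1(x):
    n = np.array([(1 - x) / 2, (1 + x) / 2])
    d = np.array([-0.5, 0.5])
    return n, d


def _tabulate():
    """Shape values at the 3x3 Gauss points.

    Returns N9 (9gp, 9), dN9 (9gp, 9, 2), N4 (9gp, 4), dN4 (9gp, 4, 2)
    with local node k = b*3 + a (a radial, b axial) for Q9 and
    k = b*2 + a for Q4, and gauss point g = gz*3 + gr.
    """
    N9 = np.zeros((9, 9)); dN9 = np.zeros((9, 9, 2))
    N4 = np.zeros((9, 4)); dN4 = np.zeros((9, 4, 2))
    for gz, eta in enumerate(GAUSS_PTS):
        for gr, xi in enumerate(GAUSS_PTS):
            g = gz * 3 + gr
            n1, d1 = _lag2(xi)
            n2, d2 = _lag2(eta)
            for b in range(3):
                for a in range(3):
                    k = b * 3 + a
                    N9[g, k] = n1[a] * n2[b]
                    dN9[g, k] = (d1[a] * n2[b], n1[a] * d2[b])
            m1, e1 = _lag1(xi)
            m2, e2 = _lag1(eta)
            for b in range(2):
                for a in range(2):
                    k = b * 2 + a
                    N4[g, k] = m1[a] * m2[b]
                    dN4[g, k] = (e1[a] * m2[b], m1[a] * e2[b])
    return N9, dN9, N4, dN4


_N9, _dN9, _N4, _dN4 = _tabulate()
_GW = np.outer(GAUSS_WTS, GAUSS_WTS).ravel()  # (9,)


# -- grid --------------------------------------------------------------------


@dataclass(frozen=True)
class Grid:
    """Uniform structured quadrilateral grid on [r0, r1] x [z0, z1]."""

    r0: float
    r1: float
    z0: float
    z1: float
    nr: int
    nz: int

    @property
    def dr(self) -> float:
        return (self.r1 - self.r0) / self.nr

    @property
    def dz(self) -> float:
        return (self.z1 - self.z0) / self.nz

    @property
    def n_elements(self) -> int:
        return self.nr * self.nz

    @property
    def n_unodes(self) -> int:
        return (2 * self.nr + 1) * (2 * self.nz + 1)

    @property
    def n_pnodes(self) -> int:
        return (self.nr + 1) * (self.nz + 1)

    def element_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.r0 + (np.arange(self.nr) + 0.5) * self.dr
        z = self.z0 + (np.arange(self.nz) + 0.5) * self.dz
        rr, zz = np.meshgrid(r, z)
        return rr.ravel(), zz.ravel()  # element e = ez*nr + er

    def unode_id(self, i, j):
        return j * (2 * self.nr + 1) + i

    def pnode_id(self, i, j):
        return j * (self.nr + 1) + i

    def element_unodes(self) -> np.ndarray:
        """(n_el, 9) displacement node ids, local k = b*3+a."""
        er, ez = np.meshgrid(np.arange(self.nr), np.arange(self.nz))
        er = er.ravel(); ez = ez.ravel()
        out = np.empty((self.n_elements, 9), int)
        for b in range(3):
            for a in range(3):
                out[:, b * 3 + a] = self.unode_id(2 * er + a, 2 * ez + b)
        return out

    def element_pnodes(self) -> np.ndarray:
        er, ez = np.meshgrid(np.arange(self.nr), np.arange(self.nz))
        er = er.ravel(); ez = ez.ravel()
        out = np.empty((self.n_elements, 4), int)
        for b in range(2):
            for a in range(2):
                out[:, b * 2 + a] = self.pnode_id(er + a, ez + b)
        return out

    def locate(self, r: np.ndarray, z: np.ndarray):
        """Element indices and local (xi, eta) of physical points."""
        er = np.clip(((r - self.r0) / self.dr).astype(int), 0, self.nr - 1)
        ez = np.clip(((z - self.z0) / self.dz).astype(int), 0, self.nz - 1)
        xi = 2 * (r - (self.r0 + er * self.dr)) / self.dr - 1
        eta = 2 * (z - (self.z0 + ez * self.dz)) / self.dz - 1
        return ez * self.nr + er, xi, eta


# -- constitutive matrices ---------------------------------------------------


def isotropic_D(E, nu) -> np.ndarray:
    """Drained isotropic stiffness for axisymmetric strain (vectorised).

    Accepts scalars or per-element arrays; returns (..., 4, 4).
    """
    E = np.asarray(E, float); nu = np.asarray(nu, float)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    shape = np.broadcast(E, nu).shape
    D = np.zeros(shape + (4, 4))
    for i in range(3):
        for j in range(3):
            D[..., i, j] = lam
        D[..., i, i] = lam + 2 * mu
    D[..., 3, 3] = mu
    return D


def transversely_isotropic_D(E1, E2, E3, nu12, nu23, nu31,
                             G12, G23, G31) -> np.ndarray:
    """Axisymmetric stiffness of a transversely isotropic material.

    Axis 1 = axial (z), 2 = radial (r), 3 = circumferential (theta),
    matching the tissue-table convention.  Built by inverting the
    orthotropic compliance and reordering into [rr, zz, tt, rz].
    """
    S = np.zeros((4, 4))
    # compliance in (1, 2, 3, shear12) ordering
    S[0, 0] = 1 / E1; S[1, 1] = 1 / E2; S[2, 2] = 1 / E3
    S[0, 1] = S[1, 0] = -nu12 / E1
    S[1, 2] = S[2, 1] = -nu23 / E2
    S[2, 0] = S[0, 2] = -nu31 / E3
    S[3, 3] = 1 / G12
    C = np.linalg.inv(S)
    # reorder (1=z, 2=r, 3=theta) -> rows [rr, zz, tt, rz]
    perm = [1, 0, 2, 3]
    return C[np.ix_(perm, perm)]


# -- assembly ----------------------------------------------------------------


@dataclass
class BiotSystem:
    """Assembled discrete system plus boundary-condition bookkeeping."""

    grid: Grid
    Kuu: sp.csr_matrix
    C: sp.csr_matrix        # coupling, (n_udof, n_pnodes)
    H: sp.csr_matrix        # permeability (mobility) matrix
    M: sp.csr_matrix        # storage matrix
    f_unit: np.ndarray      # load vector for unit applied pressure
    fixed_udofs: np.ndarray

    @property
    def n_udof(self) -> int:
        return 2 * self.grid.n_unodes


def assemble_system(
    grid: Grid,
    D_el: np.ndarray,          # (n_el, 4, 4) drained stiffness
    mobility_el: np.ndarray,   # (n_el,) k/gamma_w, mm^2/(MPa s)
    storage_el: np.ndarray,    # (n_el,) 1/MPa
    fix_ur_inner: bool = True,
    fix_ur_outer: bool = True,
    fix_uz_bottom: bool = True,
    support_r_max: float | None = None,
    support_r_min: float = 0.0,
    foundation_stiffness: float = 0.0,
) -> BiotSystem:
    """Assemble stiffness, coupling, flow and storage matrices.

    The unit load vector corresponds to a downward pressure of 1 MPa on
    the top edge (z = z1).  The bottom edge is either clamped vertically
    (``fix_uz_bottom``, within the optional radial window) or rests on a
    Winkler elastic foundation of modulus ``foundation_stiffness``
    (MPa/mm) — the compliant-contact idealisation.  Raises
    :class:`AssemblyError` naming the offending elements if any drained
    stiffness is not positive.
    """
    n_el = grid.n_elements
    bad = np.where(np.einsum("eii->e", D_el[:, :3, :3]) <= 0)[0]
    if bad.size:
        raise AssemblyError(
            f"non-positive drained stiffness in elements {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else ""))

    dr, dz = grid.dr, grid.dz
    detJ = dr * dz / 4.0
    rc, _ = grid.element_centroids()
    # gauss radii per element: r = rc + xi * dr/2
    xi_g = np.tile(GAUSS_PTS, 3)                      # (9,) radial coordinate
    r_eg = rc[:, None] + xi_g[None, :] * dr / 2.0      # (n_el, 9)
    w_eg = _GW[None, :] * detJ * r_eg                  # volume weight

    dNdr = _dN9[:, :, 0] * (2.0 / dr)                  # (9gp, 9)
    dNdz = _dN9[:, :, 1] * (2.0 / dz)

    B = np.zeros((n_el, 9, 4, 18))
    B[:, :, 0, 0::2] = dNdr[None]
    B[:, :, 1, 1::2] = dNdz[None]
    B[:, :, 2, 0::2] = _N9[None] / r_eg[:, :, None]
    B[:, :, 3, 0::2] = dNdz[None]
    B[:, :, 3, 1::2] = dNdr[None]

    K_el = np.einsum("egai,eab,egbj,eg->eij", B, D_el, B, w_eg, optimize=True)

    m = np.array([1.0, 1.0, 1.0, 0.0])
    mB = np.einsum("egai,a->egi", B, m)
    C_el = np.einsum("egi,gj,eg->eij", mB, _N4, w_eg, optimize=True)

    gradN4 = np.empty((9, 4, 2))
    gradN4[:, :, 0] = _dN4[:, :, 0] * (2.0 / dr)
    gradN4[:, :, 1] = _dN4[:, :, 1] * (2.0 / dz)
    H_geom = np.einsum("gja,gka,eg->ejk", gradN4, gradN4, w_eg, optimize=True)
    H_el = mobility_el[:, None, None] * H_geom
    M_geom = np.einsum("gj,gk,eg->ejk", _N4, _N4, w_eg, optimize=True)
    M_el = storage_el[:, None, None] * M_geom

    unodes = grid.element_unodes()
    udofs = np.empty((n_el, 18), int)
    udofs[:, 0::2] = 2 * unodes
    udofs[:, 1::2] = 2 * unodes + 1
    pnodes = grid.element_pnodes()

    n_udof = 2 * grid.n_unodes
    n_p = grid.n_pnodes

    def scatter(el_mats, rows_dofs, cols_dofs, shape):
        nr_, nc_ = el_mats.shape[1:]
        rows = np.repeat(rows_dofs, nc_, axis=1).ravel()
        cols = np.tile(cols_dofs, (1, nr_)).ravel()
        return sp.coo_matrix((el_mats.ravel(), (rows, cols)),
                             shape=shape).tocsr()

    Kuu = scatter(K_el, udofs, udofs, (n_udof, n_udof))
    C = scatter(C_el, udofs, pnodes, (n_udof, n_p))
    H = scatter(H_el, pnodes, pnodes, (n_p, n_p))
    M = scatter(M_el, pnodes, pnodes, (n_p, n_p))

    # unit downward pressure on the top edge (3-pt Gauss per edge element)
    f = np.zeros(n_udof)
    j_top = 2 * grid.nz
    for er in range(grid.nr):
        re0 = grid.r0 + er * dr
        for gp, w in zip(GAUSS_PTS, GAUSS_WTS):
            r = re0 + (gp + 1) / 2 * dr
            nvals, _ = _lag2(gp)
            for a in range(3):
                dof = 2 * grid.unode_id(2 * er + a, j_top) + 1
                f[dof] -= nvals[a] * w * (dr / 2.0) * r

    # Winkler foundation under the bottom edge: distributed vertical
    # springs k_s (traction = -k_s * u_z) within the radial window
    if foundation_stiffness > 0.0:
        rows_f, cols_f, vals_f = [], [], []
        for er in range(grid.nr):
            re0 = grid.r0 + er * dr
            ke = np.zeros((3, 3))
            for gp, w in zip(GAUSS_PTS, GAUSS_WTS):
                r = re0 + (gp + 1) / 2 * dr
                if support_r_max is not None and r > support_r_max + 1e-9:
                    continue
                if r < support_r_min - 1e-9:
                    continue
                nvals, _ = _lag2(gp)
                ke += foundation_stiffness * np.outer(nvals, nvals) \
                    * w * (dr / 2.0) * r
            dofs = [2 * grid.unode_id(2 * er + a, 0) + 1 for a in range(3)]
            for a in range(3):
                for b in range(3):
                    rows_f.append(dofs[a]); cols_f.append(dofs[b])
                    vals_f.append(ke[a, b])
        Kf = sp.coo_matrix((vals_f, (rows_f, cols_f)),
                           shape=(n_udof, n_udof)).tocsr()
    else:
        Kf = None
    # fixed displacement dofs
    fixed = []
    nri, nzi = 2 * grid.nr, 2 * grid.nz
    if fix_ur_inner:
        fixed += [2 * grid.unode_id(0, j) for j in range(nzi + 1)]
    if fix_ur_outer:
        fixed += [2 * grid.unode_id(nri, j) for j in range(nzi + 1)]
    if fix_uz_bottom and foundation_stiffness <= 0.0:
        for i in range(nri + 1):
            r_node = grid.r0 + i * grid.dr / 2.0
            if ((support_r_max is None or r_node <= support_r_max + 1e-9)
                    and r_node >= support_r_min - 1e-9):
                fixed.append(2 * grid.unode_id(i, 0) + 1)
    if Kf is not None:
        Kuu = (Kuu + Kf).tocsr()
    return BiotSystem(grid, Kuu, C, H, M, f, np.unique(fixed))


# -- solvers -----------------------------------------------------------------


def _free_mask(n, fixed):
    mask = np.ones(n, bool)
    mask[fixed] = False
    return mask


def solve_elastic(system: BiotSystem, pressure: float) -> np.ndarray:
    """Drained elastic solve (no pore fluid) under the top pressure."""
    n = system.n_udof
    free = _free_mask(n, system.fixed_udofs)
    u = np.zeros(n)
    K = system.Kuu[free][:, free]
    try:
        u[free] = splu(K.tocsc()).solve(pressure * system.f_unit[free])
    except RuntimeError as exc:  # pragma: no cover - singular input
        raise SolverError(str(exc)) from exc
    if not np.all(np.isfinite(u)):
        raise SolverError("non-finite displacement solution")
    return u


@dataclass
class LoadCaseResult:
    """Sampled fields of the compression + consolidation load case."""

    u_compression: np.ndarray          # displacements at end of ramp
    p_compression: np.ndarray          # pore pressure at end of ramp
    u_final: np.ndarray
    p_consolidation: list[np.ndarray]  # per consolidation step


def solve_consolidation(
    system: BiotSystem,
    pressure: float,
    t_compression: float,
    n_compression: int,
    t_consolidation: float,
    n_consolidation: int,
    drainage_pnodes: np.ndarray,
) -> LoadCaseResult:
    """Ramp the load over the compression step, then drain.

    The load is ramped linearly over ``t_compression`` with no drainage
    boundary; during consolidation the load is held and p = 0 is imposed
    on ``drainage_pnodes``.  Initial pore pressure 0, full saturation.
    """
    n_u = system.n_udof
    n_p = system.grid.n_pnodes
    u = np.zeros(n_u)
    p = np.zeros(n_p)
    free_u = _free_mask(n_u, system.fixed_udofs)

    def phase(dt, n_steps, load_factors, p_fixed, u, p, collect):
        free_p = _free_mask(n_p, p_fixed)
        A = sp.bmat([
            [system.Kuu[free_u][:, free_u], -system.C[free_u][:, free_p]],
            [system.C.T[free_p][:, free_u],
             (system.M + dt * system.H)[free_p][:, free_p]],
        ]).tocsc()
        try:
            lu = splu(A)
        except RuntimeError as exc:
            raise SolverError(str(exc)) from exc
        nfu = int(free_u.sum())
        for step in range(n_steps):
            rhs_u = load_factors[step] * pressure * system.f_unit[free_u]
            rhs_p = system.C.T[free_p] @ u + system.M[free_p][:, free_p] @ p[free_p]
            x = lu.solve(np.concatenate([rhs_u, rhs_p]))
            if not np.all(np.isfinite(x)):
                raise SolverError("divergent increment")
            u = np.zeros(n_u); u[free_u] = x[:nfu]
            p = np.zeros(n_p); p[free_p] = x[nfu:]
            if collect is not None:
                collect.append(p.copy())
        return u, p

    # compression: undrained ramp
    dt1 = t_compression / n_compression
    factors = (np.arange(1, n_compression + 1)) / n_compression
    u, p = phase(dt1, n_compression, factors, np.array([], int), u, p, None)
    u_c, p_c = u.copy(), p.copy()
    # consolidation: constant load, drainage active
    dt2 = t_consolidation / n_consolidation
    p[drainage_pnodes] = 0.0
    hist: list[np.ndarray] = []
    u, p = phase(dt2, n_consolidation, np.ones(n_consolidation),
                 np.asarray(drainage_pnodes, int), u, p, hist)
    return LoadCaseResult(u_c, p_c, u, hist)


# -- field evaluation --------------------------------------------------------


def eval_strain(grid: Grid, u: np.ndarray, r: np.ndarray,
                z: np.ndarray) -> np.ndarray:
    """Strain [e_rr, e_zz, e_tt, gamma_rz] at physical points."""
    el, xi, eta = grid.locate(np.asarray(r, float), np.asarray(z, float))
    unodes = grid.element_unodes()[el]                 # (n, 9)
    ur = u[2 * unodes]; uz = u[2 * unodes + 1]
    out = np.empty((len(el), 4))
    n1, d1 = _lag2_vec(xi); n2, d2 = _lag2_vec(eta)
    dNdr = np.empty((len(el), 9)); dNdz = np.empty((len(el), 9))
    N = np.empty((len(el), 9))
    for b in range(3):
        for a in range(3):
            k = b * 3 + a
            N[:, k] = n1[a] * n2[b]
            dNdr[:, k] = d1[a] * n2[b] * (2.0 / grid.dr)
            dNdz[:, k] = n1[a] * d2[b] * (2.0 / grid.dz)
    out[:, 0] = np.sum(dNdr * ur, axis=1)
    out[:, 1] = np.sum(dNdz * uz, axis=1)
    out[:, 2] = np.sum(N * ur, axis=1) / np.asarray(r, float)
    out[:, 3] = np.sum(dNdz * ur + dNdr * uz, axis=1)
    return out


def eval_pressure_gradient(grid: Grid, p: np.ndarray, r: np.ndarray,
                           z: np.ndarray) -> np.ndarray:
    """(dp/dr, dp/dz) at physical points from the bilinear p field."""
    el, xi, eta = grid.locate(np.asarray(r, float), np.asarray(z, float))
    pnodes = grid.element_pnodes()[el]
    pv = p[pnodes]
    m1, e1 = _lag1_vec(xi); m2, e2 = _lag1_vec(eta)
    dpdr = np.zeros(len(el)); dpdz = np.zeros(len(el))
    for b in range(2):
        for a in range(2):
            k = b * 2 + a
            dpdr += e1[a] * m2[b] * (2.0 / grid.dr) * pv[:, k]
            dpdz += m1[a] * e2[b] * (2.0 / grid.dz) * pv[:, k]
    return np.column_stack([dpdr, dpdz])


def _lag2_vec(x):
    n = [x * (x - 1) / 2, 1 - x * x, x * (x + 1) / 2]
    d = [x - 0.5, -2 * x, x + 0.5]
    return n, d


def _lag1_vec(x):
    n = [(1 - x) / 2, (1 + x) / 2]
    d = [np.full_like(x, -0.5), np.full_like(x, 0.5)]
    return n, d
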