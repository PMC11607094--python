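"""Quasistatic linear elasticity with growth-induced stress.

The tumor mass effect is modeled by momentum balance ``div(sigma) = 0`` with
the constitutive law

    sigma = lambda (div u) I + mu (grad u + grad u^T) - g_N (N / theta) I

so the normalized tumor cell density acts as an isotropic eigenstress, and a
Winkler (elastic-foundation) boundary ``sigma n = -k_w u`` on all six box
faces representing the restraint of the surrounding tissues. The von Mises
invariant of the resulting stress field feeds back on tumor cell mobility
through ``D = D0 exp(-gamma_N sigma_v)``.

Discretization: trilinear (Q1) hexahedral finite elements on the voxel
lattice (field samples are the nodes), 2x2x2 Gauss quadrature, with the
Winkler term entering as a boundary mass matrix. The material is homogeneous,
so the stiffness operator depends only on the grid and the elastic constants:
it is assembled and LU-factorized once and reused for every equilibrium
solve of a whole campaign (each solve is a pair of sparse triangular
back-substitutions, exact to machine rounding). The load vector is linear in
N and applied through a precomputed sparse operator.

Stress recovery evaluates the displacement gradient with second-order finite
differences at the nodes (one-sided at the boundary) and adds the eigenstress
term pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from . import constants
from .grid import Grid, ScalarField

__all__ = [
    "MechConstants",
    "MechState",
    "VectorField",
    "TensorField",
    "solve_equilibrium",
    "von_mises",
    "diffusivity",
    "ElasticOperator",
]


@dataclass(frozen=True)
class MechConstants:
    """Fixed mechanical constants. Lame parameters derive from (E, nu)."""

    E: float = constants.E_YOUNG      # Young's modulus, kPa
    nu: float = constants.NU          # Poisson's ratio
    gN: float = constants.G_N         # tumor-induced solid stress, kPa
    kw: float = constants.K_W         # Winkler constant, kPa/mm
    gammaN: float = constants.GAMMA_N  # stress-diffusivity coupling, 1/kPa
    theta: float = constants.THETA    # carrying capacity, cells/mm^3

    def __post_init__(self) -> None:
        if not 0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (0, 0.5)")
        for name in ("E", "gN", "kw", "gammaN", "theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def lam(self) -> float:
        return self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))

    @property
    def mu(self) -> float:
        return self.E / (2 * (1 + self.nu))


@dataclass
class VectorField:
    grid: Grid
    values: np.ndarray = field(repr=False)  # (3,) + grid.shape


@dataclass
class TensorField:
    """Symmetric stress tensor, Voigt-like component order
    (s11, s22, s33, s12, s23, s13)."""

    grid: Grid
    values: np.ndarray = field(repr=False)  # (6,) + grid.shape


@dataclass
class MechState:
    u: VectorField
    sigma: TensorField
    sigma_v: ScalarField


# ---------------------------------------------------------------------------
# element matrices (unit pattern, scaled by spacing at assembly)
# ---------------------------------------------------------------------------

def _gauss_points():
    g = 1.0 / np.sqrt(3.0)
    pts = np.array([(i, j, k) for i in (-g, g) for j in (-g, g) for k in (-g, g)])
    return pts


def _shape_functions(xi):
    """Trilinear shapes and parent-space gradients at a parent point xi.

    Local node order: (i, j, k) in {0,1}^3 flattened as 4i + 2j + k, with
    node coordinates (2i-1, 2j-1, 2k-1) in the parent cube [-1, 1]^3.
    """
    N = np.empty(8)
    dN = np.empty((8, 3))
    for n in range(8):
        sg = np.array([2 * ((n >> 2) & 1) - 1, 2 * ((n >> 1) & 1) - 1, 2 * (n & 1) - 1])
        f = (1 + sg * xi) / 2
        N[n] = f.prod()
        for a in range(3):
            g = f.copy()
            g[a] = sg[a] / 2
            dN[n, a] = g.prod()
    return N, dN


def _element_matrices(spacing, lam, mu, gN_over_theta):
    """Q1 hex stiffness (24x24) and density-load (24x8) matrices."""
    hx, hy, hz = spacing
    jac = np.array([hx, hy, hz]) / 2.0
    detJ = jac.prod()
    Ke = np.zeros((24, 24))
    Ge = np.zeros((24, 8))
    # isotropic stiffness in Voigt order (11, 22, 33, 12, 23, 13)
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    for xi in _gauss_points():
        N, dN = _shape_functions(xi)
        dNx = dN / jac  # physical gradients
        B = np.zeros((6, 24))
        for n in range(8):
            c = 3 * n
            B[0, c + 0] = dNx[n, 0]
            B[1, c + 1] = dNx[n, 1]
            B[2, c + 2] = dNx[n, 2]
            B[3, c + 0] = dNx[n, 1]
            B[3, c + 1] = dNx[n, 0]
            B[4, c + 1] = dNx[n, 2]
            B[4, c + 2] = dNx[n, 1]
            B[5, c + 0] = dNx[n, 2]
            B[5, c + 2] = dNx[n, 0]
        # engineering shear: off-diagonal C entries already account for the
        # symmetric pairing because B stacks both partners
        Ke += B.T @ C @ B * detJ
        # load: integral of (gN/theta) N_h * div(v)
        divv = np.zeros(24)
        for n in range(8):
            divv[3 * n: 3 * n + 3] = dNx[n]
        Ge += gN_over_theta * np.outer(divv, N) * detJ
    return Ke, Ge


def _face_mass(ha, hb):
    """Bilinear quad mass matrix for a face of edge lengths (ha, hb)."""
    m1 = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
    return np.kron(m1 * ha, m1 * hb)


class ElasticOperator:
    """Assembled elasticity operator for one grid + constants.

    Two solve paths share the assembly:

    * an exact double-precision sparse LU (built lazily) behind the public
      :func:`solve_equilibrium`;
    * a single-precision factor with a blocked (numba) triangular solve for
      campaign batches, where the factor is streamed once per chunk; its
      relative residual is ~1e-6, far below the discretization error of the
      stress field it feeds.
    """

    def __init__(self, grid: Grid, consts: MechConstants):
        self.grid = grid
        self.consts = consts
        nx, ny, nz = grid.shape
        self.n_nodes = nx * ny * nz
        self.ndof = 3 * self.n_nodes
        K = self._assemble_stiffness() + self._assemble_winkler()
        self.K = K.tocsc()
        self._lu = None
        self.G = self._assemble_load().tocsr()
        self._fast = None

    def _solve_exact(self, rhs: np.ndarray) -> np.ndarray:
        """Double-precision direct solve (nested-dissection ordered LU)."""
        if self._lu is None:
            perm = _nested_dissection_dofs(*self.grid.shape)
            Kp = self.K[perm][:, perm].tocsc()
            self._lu = (
                splu(Kp, permc_spec="NATURAL",
                     options={"SymmetricMode": True, "DiagPivotThresh": 0.0}),
                perm,
            )
        lu, perm = self._lu
        out = np.empty_like(rhs, dtype=np.float64)
        out[perm] = lu.solve(np.asarray(rhs, dtype=np.float64)[perm])
        return out

    def _fast_factor(self):
        if self._fast is None:
            from ._kernels import fwd_back_solve

            perm = _nested_dissection_dofs(*self.grid.shape)
            Kp = self.K[perm][:, perm].astype(np.float32).tocsc()
            lu = splu(Kp, permc_spec="NATURAL",
                      options={"SymmetricMode": True, "DiagPivotThresh": 0.0})
            L = sparse.tril(lu.L.tocsc(), k=-1).tocsc()
            U = lu.U.tocsc()
            dinv = (1.0 / U.diagonal()).astype(np.float32)
            Us = sparse.triu(U, k=1).tocsc()
            L.sort_indices()
            Us.sort_indices()
            G32 = self.G.astype(np.float32)
            in_idx = perm[np.argsort(lu.perm_r)]
            self._fast = (in_idx, lu.perm_c, perm, L, Us, dinv, G32,
                          fwd_back_solve)
        return self._fast

    # -- assembly ----------------------------------------------------------
    def _node_ids(self):
        nx, ny, nz = self.grid.shape
        return np.arange(self.n_nodes).reshape(nx, ny, nz)

    def _assemble_stiffness(self):
        g = self.grid
        c = self.consts
        Ke, _ = _element_matrices(g.spacing, c.lam, c.mu, c.gN / c.theta)
        nodes = self._node_ids()
        nx, ny, nz = g.shape
        # global node ids of the 8 local nodes for every element
        corner = nodes[:-1, :-1, :-1].ravel()
        offsets = []
        for n in range(8):
            i, j, k = (n >> 2) & 1, (n >> 1) & 1, n & 1
            offsets.append(nodes[i, j, k])  # == i*ny*nz + j*nz + k
        enodes = corner[:, None] + np.array(offsets)[None, :]  # (nel, 8)
        edofs = (3 * enodes[:, :, None] + np.arange(3)).reshape(-1, 24)
        rows = np.repeat(edofs, 24, axis=1).ravel()
        cols = np.tile(edofs, (1, 24)).ravel()
        data = np.tile(Ke.ravel(), edofs.shape[0])
        return sparse.coo_matrix((data, (rows, cols)), shape=(self.ndof, self.ndof))

    def _assemble_winkler(self):
        g = self.grid
        kw = self.consts.kw
        nodes = self._node_ids()
        rows_all, cols_all, data_all = [], [], []
        for axis in range(3):
            for side in (0, -1):
                face_nodes = np.take(nodes, side, axis=axis)  # (na, nb)
                ha, hb = [g.spacing[a] for a in range(3) if a != axis]
                Mf = _face_mass(ha, hb) * kw
                na, nb = face_nodes.shape
                corner = face_nodes[:-1, :-1].ravel()
                offs = [face_nodes[i, j] - face_nodes[0, 0]
                        for i in (0, 1) for j in (0, 1)]
                fnodes = corner[:, None] + np.array(offs)[None, :]  # (nfel, 4)
                for comp in range(3):
                    fdofs = 3 * fnodes + comp
                    rows_all.append(np.repeat(fdofs, 4, axis=1).ravel())
                    cols_all.append(np.tile(fdofs, (1, 4)).ravel())
                    data_all.append(np.tile(Mf.ravel(), fnodes.shape[0]))
        return sparse.coo_matrix(
            (np.concatenate(data_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(self.ndof, self.ndof),
        )

    def _assemble_load(self):
        g = self.grid
        c = self.consts
        _, Ge = _element_matrices(g.spacing, c.lam, c.mu, c.gN / c.theta)
        nodes = self._node_ids()
        corner = nodes[:-1, :-1, :-1].ravel()
        offsets = []
        for n in range(8):
            i, j, k = (n >> 2) & 1, (n >> 1) & 1, n & 1
            offsets.append(nodes[i, j, k])
        enodes = corner[:, None] + np.array(offsets)[None, :]
        edofs = (3 * enodes[:, :, None] + np.arange(3)).reshape(-1, 24)
        # for each element, pair (dof a, node b) -> Ge[a, b]
        cols = np.tile(enodes[:, None, :], (1, 24, 1)).ravel()
        rows = np.repeat(edofs[:, :, None], 8, axis=2).ravel()
        data = np.tile(Ge.ravel(), enodes.shape[0])
        return sparse.coo_matrix(
            (data, (rows, cols)), shape=(self.ndof, self.n_nodes)
        )

    # -- solves ------------------------------------------------------------
    def displacements(self, N_flat: np.ndarray) -> np.ndarray:
        """Solve equilibrium for nodal density values.

        N_flat: (n_nodes,) or (n_nodes, B). Returns matching (ndof,) or
        (ndof, B) displacement arrays (mm).
        """
        rhs = self.G @ N_flat
        return self._solve_exact(rhs)

    def stress_batch(self, U: np.ndarray, N_flat: np.ndarray) -> np.ndarray:
        """Recover the 6 stress components at nodes.

        U: (ndof, B), N_flat: (n_nodes, B). Returns (6, B) + grid.shape.
        """
        nx, ny, nz = self.grid.shape
        B = U.shape[1]
        u = U.reshape(nx, ny, nz, 3, B)
        c = self.consts
        lam, mu = c.lam, c.mu
        sp = self.grid.spacing
        grads = np.empty((3, 3, nx, ny, nz, B))
        for comp in range(3):
            for axis in range(3):
                grads[comp, axis] = np.gradient(u[..., comp, :], sp[axis], axis=axis)
        div = grads[0, 0] + grads[1, 1] + grads[2, 2]
        eig = (c.gN / c.theta) * N_flat.reshape(nx, ny, nz, B)
        s = np.empty((6, B, nx, ny, nz))
        s[0] = np.moveaxis(lam * div + 2 * mu * grads[0, 0] - eig, -1, 0)
        s[1] = np.moveaxis(lam * div + 2 * mu * grads[1, 1] - eig, -1, 0)
        s[2] = np.moveaxis(lam * div + 2 * mu * grads[2, 2] - eig, -1, 0)
        s[3] = np.moveaxis(mu * (grads[0, 1] + grads[1, 0]), -1, 0)
        s[4] = np.moveaxis(mu * (grads[1, 2] + grads[2, 1]), -1, 0)
        s[5] = np.moveaxis(mu * (grads[0, 2] + grads[2, 0]), -1, 0)
        return s

    def von_mises_batch(self, N_batch: np.ndarray) -> np.ndarray:
        """Density batch (B,) + shape -> von Mises stress (B,) + shape.

        Single-precision campaign path: blocked triangular solves plus the
        fused stress/von-Mises kernel (the isotropic growth eigenstress
        cancels in the deviatoric invariant, so only displacement gradients
        enter).
        """
        from ._kernels import stress_vonmises

        in_idx, perm_c, perm, L, Us, dinv, G32, fwd_back = self._fast_factor()
        Bn = N_batch.shape[0]
        nx, ny, nz = self.grid.shape
        rhs = G32 @ np.ascontiguousarray(
            N_batch.reshape(Bn, -1).T, dtype=np.float32)
        X = rhs[in_idx]
        fwd_back(L.indptr, L.indices, L.data, Us.indptr, Us.indices, Us.data,
                 dinv, X)
        sol = np.empty_like(X)
        sol[perm] = X[perm_c]
        u = np.ascontiguousarray(sol).reshape(nx, ny, nz, 3, Bn)
        sv = np.empty((nx, ny, nz, Bn), dtype=np.float32)
        hx, hy, hz = self.grid.spacing
        c = self.consts
        stress_vonmises(u, hx, hy, hz, np.float32(c.lam), np.float32(c.mu), sv)
        return np.moveaxis(sv, -1, 0).astype(np.float64)


def _nested_dissection_dofs(nx: int, ny: int, nz: int) -> np.ndarray:
    """Nested-dissection elimination order for the node lattice (recursive
    coordinate bisection, separator planes last), expanded to the 3
    displacement dofs per node. Roughly one third less factor fill than
    generic minimum-degree orderings on these box grids."""

    def rec(ix, iy, iz):
        if len(ix) * len(iy) * len(iz) <= 8:
            return [(i, j, k) for i in ix for j in iy for k in iz]
        ax = int(np.argmax([len(ix), len(iy), len(iz)]))
        arr = (ix, iy, iz)[ax]
        m = len(arr) // 2
        parts = []
        for part in (arr[:m], arr[m + 1:], [arr[m]]):
            if part:
                sub = [ix, iy, iz]
                sub[ax] = part
                parts.extend(rec(*sub))
        return parts

    order = rec(list(range(nx)), list(range(ny)), list(range(nz)))
    nodes = np.array([(i * ny + j) * nz + k for i, j, k in order])
    return (3 * nodes[:, None] + np.arange(3)).ravel()


_OPERATOR_CACHE: dict[tuple, ElasticOperator] = {}


def get_operator(grid: Grid, consts: MechConstants) -> ElasticOperator:
    key = (grid.shape, grid.spacing, consts.E, consts.nu, consts.gN,
           consts.kw, consts.theta)
    op = _OPERATOR_CACHE.get(key)
    if op is None:
        op = _OPERATOR_CACHE[key] = ElasticOperator(grid, consts)
    return op


def _von_mises_components(s: np.ndarray) -> np.ndarray:
    """Deviatoric (von Mises) invariant from stacked components
    (s11, s22, s33, s12, s23, s13) on the leading axis."""
    q = (
        s[0] ** 2 + s[1] ** 2 + s[2] ** 2
        - s[0] * s[1] - s[1] * s[2] - s[0] * s[2]
        + 3.0 * (s[3] ** 2 + s[4] ** 2 + s[5] ** 2)
    )
    return np.sqrt(np.maximum(q, 0.0))


def solve_equilibrium(N: ScalarField, consts: MechConstants | None = None) -> MechState:
    """Solve quasistatic mechanical equilibrium for a tumor density field.

    Raises ValueError if N leaves [0, theta]; the Winkler boundary makes the
    operator nonsingular, so the direct solve cannot fail to converge.
    """
    consts = consts or MechConstants()
    if np.any(N.values < -1e-9 * consts.theta) or np.any(
        N.values > consts.theta * (1 + 1e-9)
    ):
        raise ValueError("density must lie within [0, theta]")
    op = get_operator(N.grid, consts)
    N_flat = N.values.reshape(-1, 1)
    U = op.displacements(N_flat)
    s = op.stress_batch(U, N_flat)[:, 0]  # (6,) + shape
    sv = _von_mises_components(s)
    nx, ny, nz = N.grid.shape
    u = np.moveaxis(U.reshape(nx, ny, nz, 3), -1, 0)
    return MechState(
        u=VectorField(N.grid, u),
        sigma=TensorField(N.grid, s),
        sigma_v=ScalarField(N.grid, sv),
    )


def von_mises(sigma: TensorField) -> ScalarField:
    """Voxelwise von Mises stress of a symmetric stress tensor field."""
    return ScalarField(sigma.grid, _von_mises_components(sigma.values))


def diffusivity(D0: float, sigma_v: ScalarField, gammaN: float = constants.GAMMA_N) -> ScalarField:
    """Stress-inhibited tumor cell diffusivity ``D = D0 exp(-gamma_N sigma_v)``."""
    if D0 <= 0:
        raise ValueError("D0 must be > 0")
    return ScalarField(sigma_v.grid, D0 * np.exp(-gammaN * sigma_v.values))
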