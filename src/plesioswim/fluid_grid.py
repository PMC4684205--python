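"""Staggered-grid inviscid incompressible flow.

Water is modeled by the incompressible Euler equations (viscosity of water
is negligible at this scale): ``∂u/∂t + u·∇u + ∇p/ρ = g``, ``∇·u = 0`` on a
staggered MAC grid storing face-normal velocity components and cell-center
pressures.  Advection uses BFECC (back-and-forth error compensation and
correction, built from clamped semi-Lagrangian sweeps), gravity an explicit
Euler step, and incompressibility a pressure projection solved with a
preconditioned conjugate-gradient method.

Domain boundaries: no-penetration solid walls on the four sides and the
bottom, a free surface (``p = 0``) at the top plane.  The swimmer should be
placed deep enough that surface effects stay small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

__all__ = [
    "MacGrid",
    "sample_velocity",
    "advect_scalar_semi_lagrangian",
    "advect_scalar_bfecc",
    "advect_velocity_bfecc",
    "apply_gravity",
    "project_pure_fluid",
    "max_divergence",
    "PressureSolver",
]

_FACE_OFFSETS = (
    np.array([0.0, 0.5, 0.5]),
    np.array([0.5, 0.0, 0.5]),
    np.array([0.5, 0.5, 0.0]),
)


@dataclass
class MacGrid:
    """MAC-grid state: face velocities, pressure, labels and fractions."""

    shape: tuple
    dx: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rho: float = 1000.0
    g: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -9.81]))

    def __post_init__(self):
        nx, ny, nz = self.shape
        self.origin = np.asarray(self.origin, float)
        self.u = [
            np.zeros((nx + 1, ny, nz)),
            np.zeros((nx, ny + 1, nz)),
            np.zeros((nx, ny, nz + 1)),
        ]
        self.p = np.zeros(self.shape)
        self.solid = np.zeros(self.shape, dtype=bool)
        self.frac = np.ones(self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def cell_centers(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ax = [self.origin[d] + (np.arange(self.shape[d]) + 0.5) * self.dx for d in range(3)]
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

    def face_positions(self, axis: int) -> np.ndarray:
        off = _FACE_OFFSETS[axis]
        shp = self.u[axis].shape
        ax = [self.origin[d] + (np.arange(shp[d]) + off[d]) * self.dx for d in range(3)]
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

    def max_speed(self) -> float:
        return max(float(np.max(np.abs(c))) for c in self.u)

    def enforce_wall_bc(self) -> None:
        """Zero the normal velocity on the side and bottom walls."""
        self.u[0][0, :, :] = 0.0
        self.u[0][-1, :, :] = 0.0
        self.u[1][:, 0, :] = 0.0
        self.u[1][:, -1, :] = 0.0
        self.u[2][:, :, 0] = 0.0  # bottom; the top face is the free surface

    def copy_velocity(self):
        return [c.copy() for c in self.u]


# ---------------------------------------------------------------------------
# interpolation

def _trilinear(F: np.ndarray, idx: np.ndarray, with_bounds: bool = False):
    """Trilinear sample of F at fractional indices (n,3), edge-clamped."""
    n0, n1, n2 = F.shape
    ij = np.empty_like(idx)
    np.clip(idx[:, 0], 0.0, n0 - 1.0, out=ij[:, 0])
    np.clip(idx[:, 1], 0.0, n1 - 1.0, out=ij[:, 1])
    np.clip(idx[:, 2], 0.0, n2 - 1.0, out=ij[:, 2])
    i0 = np.minimum(ij.astype(np.int64), np.array([n0 - 2, n1 - 2, n2 - 2]))
    i0 = np.maximum(i0, 0)
    f = ij - i0
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    c = np.empty((8, len(ij)))
    c[0] = F[x0, y0, z0]
    c[1] = F[x0, y0, z0 + 1]
    c[2] = F[x0, y0 + 1, z0]
    c[3] = F[x0, y0 + 1, z0 + 1]
    c[4] = F[x0 + 1, y0, z0]
    c[5] = F[x0 + 1, y0, z0 + 1]
    c[6] = F[x0 + 1, y0 + 1, z0]
    c[7] = F[x0 + 1, y0 + 1, z0 + 1]
    w0 = (1 - fx) * (1 - fy)
    w1 = (1 - fx) * fy
    w2 = fx * (1 - fy)
    w3 = fx * fy
    val = ((c[0] * (1 - fz) + c[1] * fz) * w0 + (c[2] * (1 - fz) + c[3] * fz) * w1
           + (c[4] * (1 - fz) + c[5] * fz) * w2 + (c[6] * (1 - fz) + c[7] * fz) * w3)
    if not with_bounds:
        return val
    return val, c.min(axis=0), c.max(axis=0)


def sample_velocity(grid: MacGrid, points: np.ndarray) -> np.ndarray:
    """Velocity vectors at world points (n,3), each component from its faces."""
    pts = np.asarray(points, float)
    out = np.empty_like(pts)
    for a in range(3):
        idx = (pts - grid.origin) / grid.dx - _FACE_OFFSETS[a]
        out[:, a] = _trilinear(grid.u[a], idx)
    return out


# ---------------------------------------------------------------------------
# advection

def _backtrace(grid: MacGrid, positions: np.ndarray, dt: float) -> np.ndarray:
    v = sample_velocity(grid, positions)
    return positions - dt * v


@njit(cache=True, inline="always")
def _tri(F, x, y, z):
    """Trilinear sample at fractional indices, edge-clamped."""
    n0, n1, n2 = F.shape
    if x < 0.0: x = 0.0
    if x > n0 - 1.0: x = n0 - 1.0
    if y < 0.0: y = 0.0
    if y > n1 - 1.0: y = n1 - 1.0
    if z < 0.0: z = 0.0
    if z > n2 - 1.0: z = n2 - 1.0
    i = min(int(x), n0 - 2) if n0 > 1 else 0
    j = min(int(y), n1 - 2) if n1 > 1 else 0
    k = min(int(z), n2 - 2) if n2 > 1 else 0
    fx = x - i; fy = y - j; fz = z - k
    c00 = F[i, j, k] * (1 - fz) + F[i, j, k + 1] * fz
    c01 = F[i, j + 1, k] * (1 - fz) + F[i, j + 1, k + 1] * fz
    c10 = F[i + 1, j, k] * (1 - fz) + F[i + 1, j, k + 1] * fz
    c11 = F[i + 1, j + 1, k] * (1 - fz) + F[i + 1, j + 1, k + 1] * fz
    return (c00 * (1 - fy) + c01 * fy) * (1 - fx) + (c10 * (1 - fy) + c11 * fy) * fx


@njit(cache=True)
def _sl_kernel(F, ox, oy, oz, u0, u1, u2, gx, gy, gz, dx, dt, out, lo, hi,
               want_bounds):
    n0, n1, n2 = F.shape
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                px = gx + (i + ox) * dx
                py = gy + (j + oy) * dx
                pz = gz + (k + oz) * dx
                vx = _tri(u0, px / dx - gx / dx - 0.0, py / dx - gy / dx - 0.5, pz / dx - gz / dx - 0.5)
                vy = _tri(u1, px / dx - gx / dx - 0.5, py / dx - gy / dx - 0.0, pz / dx - gz / dx - 0.5)
                vz = _tri(u2, px / dx - gx / dx - 0.5, py / dx - gy / dx - 0.5, pz / dx - gz / dx - 0.0)
                bx = (px - dt * vx - gx) / dx - ox
                by = (py - dt * vy - gy) / dx - oy
                bz = (pz - dt * vz - gz) / dx - oz
                if bx < 0.0: bx = 0.0
                if bx > n0 - 1.0: bx = n0 - 1.0
                if by < 0.0: by = 0.0
                if by > n1 - 1.0: by = n1 - 1.0
                if bz < 0.0: bz = 0.0
                if bz > n2 - 1.0: bz = n2 - 1.0
                ii = min(int(bx), n0 - 2) if n0 > 1 else 0
                jj = min(int(by), n1 - 2) if n1 > 1 else 0
                kk = min(int(bz), n2 - 2) if n2 > 1 else 0
                fx = bx - ii; fy = by - jj; fz = bz - kk
                c000 = F[ii, jj, kk]; c001 = F[ii, jj, kk + 1]
                c010 = F[ii, jj + 1, kk]; c011 = F[ii, jj + 1, kk + 1]
                c100 = F[ii + 1, jj, kk]; c101 = F[ii + 1, jj, kk + 1]
                c110 = F[ii + 1, jj + 1, kk]; c111 = F[ii + 1, jj + 1, kk + 1]
                c00 = c000 * (1 - fz) + c001 * fz
                c01 = c010 * (1 - fz) + c011 * fz
                c10 = c100 * (1 - fz) + c101 * fz
                c11 = c110 * (1 - fz) + c111 * fz
                out[i, j, k] = (c00 * (1 - fy) + c01 * fy) * (1 - fx) \
                    + (c10 * (1 - fy) + c11 * fy) * fx
                if want_bounds:
                    mn = min(min(min(c000, c001), min(c010, c011)),
                             min(min(c100, c101), min(c110, c111)))
                    mx = max(max(max(c000, c001), max(c010, c011)),
                             max(max(c100, c101), max(c110, c111)))
                    lo[i, j, k] = mn
                    hi[i, j, k] = mx


def _sl_pass(grid: MacGrid, F: np.ndarray, offset: np.ndarray, dt: float,
             with_bounds: bool = False):
    out = np.empty_like(F)
    lo = np.empty_like(F) if with_bounds else out
    hi = np.empty_like(F) if with_bounds else out
    _sl_kernel(F, offset[0], offset[1], offset[2],
               grid.u[0], grid.u[1], grid.u[2],
               grid.origin[0], grid.origin[1], grid.origin[2],
               grid.dx, dt, out, lo, hi, with_bounds)
    if with_bounds:
        return out, lo, hi
    return out


def _bfecc_field(grid: MacGrid, F: np.ndarray, offset: np.ndarray, dt: float) -> np.ndarray:
    fwd, lo, hi = _sl_pass(grid, F, offset, dt, with_bounds=True)
    back = _sl_pass(grid, fwd, offset, -dt)
    corrected = F + 0.5 * (F - back)
    val = _sl_pass(grid, corrected, offset, dt)
    # clamp against the bounds of the *original* field at the backtrace point
    return np.clip(val, lo, hi)


def _cfl_substeps(grid: MacGrid, dt: float, cfl: float = 0.9) -> int:
    umax = grid.max_speed()
    if umax <= 0:
        return 1
    return max(1, int(np.ceil(dt * umax / (cfl * grid.dx))))


def advect_scalar_semi_lagrangian(grid: MacGrid, F: np.ndarray, dt: float) -> np.ndarray:
    """Plain first-order semi-Lagrangian advection of a cell-centered field."""
    off = np.array([0.5, 0.5, 0.5])
    out = F
    for _ in range(_cfl_substeps(grid, dt)):
        out = _sl_pass(grid, out, off, dt / _cfl_substeps(grid, dt))
    return out


def advect_scalar_bfecc(grid: MacGrid, F: np.ndarray, dt: float) -> np.ndarray:
    """BFECC advection of a cell-centered scalar.

    Forward semi-Lagrangian step, backward step of the result, error-halved
    correction of the source, final forward step, clamped to the local
    sample bounds (monotone: no new extrema are created).
    """
    off = np.array([0.5, 0.5, 0.5])
    n = _cfl_substeps(grid, dt)
    out = F
    for _ in range(n):
        out = _bfecc_field(grid, out, off, dt / n)
    return out


def advect_velocity_bfecc(grid: MacGrid, dt: float) -> None:
    """Self-advect the velocity field with BFECC (in place).

    All three components are advected through the same frozen velocity
    field, sub-stepped if the CFL number exceeds the configured bound.
    """
    n = _cfl_substeps(grid, dt)
    for _ in range(n):
        new_u = [
            _bfecc_field(grid, grid.u[a], _FACE_OFFSETS[a], dt / n)
            for a in range(3)
        ]
        grid.u = new_u
    grid.enforce_wall_bc()


def apply_gravity(grid: MacGrid, dt: float) -> None:
    """Explicit Euler gravity increment on face velocities (in place)."""
    for a in range(3):
        if grid.g[a] != 0.0:
            grid.u[a] += grid.g[a] * dt
    grid.enforce_wall_bc()


# ---------------------------------------------------------------------------
# divergence and the pure-fluid pressure solve

def _interior_face_weights(grid: MacGrid, fluid: np.ndarray):
    """Fluid-fluid interior face weights per axis (0 where not both fluid)."""
    f = grid.frac
    w = [
        np.minimum(f[:-1], f[1:]) * (fluid[:-1] & fluid[1:]),
        np.minimum(f[:, :-1], f[:, 1:]) * (fluid[:, :-1] & fluid[:, 1:]),
        np.minimum(f[:, :, :-1], f[:, :, 1:]) * (fluid[:, :, :-1] & fluid[:, :, 1:]),
    ]
    return w


def weighted_divergence(grid: MacGrid, fluid: np.ndarray | None = None,
                        face_w=None) -> np.ndarray:
    """Volume-weighted divergence (s^-1) per cell over fluid-fluid faces.

    The top boundary face (free surface) is included; wall faces carry zero
    normal velocity.  The solid-boundary contribution is added separately by
    the two-way coupling.
    """
    fluid = ~grid.solid if fluid is None else fluid
    w = _interior_face_weights(grid, fluid) if face_w is None else face_w
    div = np.zeros(grid.shape)
    ux, uy, uz = grid.u
    div += np.pad(w[0] * ux[1:-1], ((0, 1), (0, 0), (0, 0)))  # +x faces
    div -= np.pad(w[0] * ux[1:-1], ((1, 0), (0, 0), (0, 0)))  # -x faces
    div += np.pad(w[1] * uy[:, 1:-1], ((0, 0), (0, 1), (0, 0)))
    div -= np.pad(w[1] * uy[:, 1:-1], ((0, 0), (1, 0), (0, 0)))
    div += np.pad(w[2] * uz[:, :, 1:-1], ((0, 0), (0, 0), (0, 1)))
    div -= np.pad(w[2] * uz[:, :, 1:-1], ((0, 0), (0, 0), (1, 0)))
    # free-surface faces at the top plane
    div[:, :, -1] += grid.frac[:, :, -1] * fluid[:, :, -1] * uz[:, :, -1]
    return div / grid.dx


@njit(cache=True)
def _mic0_factor(diag, px, py, pz, tau=0.97, sigma=0.25):
    """Modified incomplete Cholesky (level 0) diagonal for a 7-point stencil.

    ``px/py/pz`` hold the off-diagonal coefficient between cell (i,j,k) and
    its +axis neighbor (non-positive).  Returns the inverse-sqrt pivot."""
    nx, ny, nz = diag.shape
    pre = np.zeros_like(diag)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                e = diag[i, j, k]
                if e == 0.0:
                    continue
                if i > 0:
                    a = px[i - 1, j, k] * pre[i - 1, j, k]
                    e -= a * a + tau * px[i - 1, j, k] * (
                        py[i - 1, j, k] + pz[i - 1, j, k]) * pre[i - 1, j, k] ** 2
                if j > 0:
                    a = py[i, j - 1, k] * pre[i, j - 1, k]
                    e -= a * a + tau * py[i, j - 1, k] * (
                        px[i, j - 1, k] + pz[i, j - 1, k]) * pre[i, j - 1, k] ** 2
                if k > 0:
                    a = pz[i, j, k - 1] * pre[i, j, k - 1]
                    e -= a * a + tau * pz[i, j, k - 1] * (
                        px[i, j, k - 1] + py[i, j, k - 1]) * pre[i, j, k - 1] ** 2
                if e < sigma * diag[i, j, k]:
                    e = diag[i, j, k]
                pre[i, j, k] = 1.0 / np.sqrt(e)
    return pre


@njit(cache=True)
def _mic0_apply(r, pre, px, py, pz):
    """Apply the MIC(0) preconditioner: forward then backward sweep."""
    nx, ny, nz = r.shape
    q = np.zeros_like(r)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if pre[i, j, k] == 0.0:
                    continue
                t = r[i, j, k]
                if i > 0:
                    t -= px[i - 1, j, k] * pre[i - 1, j, k] * q[i - 1, j, k]
                if j > 0:
                    t -= py[i, j - 1, k] * pre[i, j - 1, k] * q[i, j - 1, k]
                if k > 0:
                    t -= pz[i, j, k - 1] * pre[i, j, k - 1] * q[i, j, k - 1]
                q[i, j, k] = t * pre[i, j, k]
    z = np.zeros_like(r)
    for i in range(nx - 1, -1, -1):
        for j in range(ny - 1, -1, -1):
            for k in range(nz - 1, -1, -1):
                if pre[i, j, k] == 0.0:
                    continue
                t = q[i, j, k]
                if i < nx - 1:
                    t -= px[i, j, k] * pre[i, j, k] * z[i + 1, j, k]
                if j < ny - 1:
                    t -= py[i, j, k] * pre[i, j, k] * z[i, j + 1, k]
                if k < nz - 1:
                    t -= pz[i, j, k] * pre[i, j, k] * z[i, j, k + 1]
                z[i, j, k] = t * pre[i, j, k]
    return z


class PressureSolver:
    """Assembles and solves the (possibly coupled) pressure system.

    The matrix over cell pressures is ``A = (Δt/(ρ Δx²)) L + A_solid`` where
    ``L`` is the volume-weighted 7-point Laplacian over fluid-fluid faces
    (Dirichlet ``p = 0`` across the top free surface, Neumann at walls and
    solid boundaries) and ``A_solid`` the symmetric rank-structured two-way
    coupling block supplied by :mod:`plesioswim.coupling`.  Non-fluid cells
    keep identity rows so the sparsity pattern is grid-constant and a single
    incomplete-factorization preconditioner (built once from the all-fluid
    Laplacian) serves every time step.
    """

    def __init__(self, grid: MacGrid, rtol: float = 1e-8, max_iter: int = 500,
                 target_div: float = 1e-6):
        self.grid = grid
        self.rtol = rtol
        self.max_iter = max_iter
        self.target_div = target_div
        self._ilu = None
        self._ilu_dt = None

    def laplacian(self, dt: float, fluid: np.ndarray, face_w=None) -> sp.csr_matrix:
        grid = self.grid
        nx, ny, nz = grid.shape
        n = grid.n_cells
        if face_w is None:
            face_w = _interior_face_weights(grid, fluid)
        scale = dt / (grid.rho * grid.dx**2)
        idx = np.arange(n).reshape(grid.shape)
        rows, cols, vals = [], [], []
        diag = np.zeros(grid.shape)
        for a, w in enumerate(face_w):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[a] = slice(None, -1)
            sl_hi[a] = slice(1, None)
            lo, hi = idx[tuple(sl_lo)], idx[tuple(sl_hi)]
            m = w > 0
            rows += [lo[m], hi[m]]
            cols += [hi[m], lo[m]]
            vals += [-w[m] * scale, -w[m] * scale]
            diag[tuple(sl_lo)] += w * scale
            diag[tuple(sl_hi)] += w * scale
        # free-surface Dirichlet at the top plane: the surface lies half a
        # cell above the top cell center, so the ghost-mirror factor is 2
        diag[:, :, -1] += 2.0 * grid.frac[:, :, -1] * fluid[:, :, -1] * scale
        # decoupled rows for non-fluid cells (p = 0), scaled to the stencil
        # magnitude so the preconditioned spectrum stays clustered
        dvals = diag.ravel().copy()
        dvals[~fluid.ravel()] = 6.0 * scale
        # fluid cells with empty stencils (isolated): decoupled too (logged
        # upstream via interface pruning)
        lonely = fluid.ravel() & (dvals <= 0)
        dvals[lonely] = 6.0 * scale
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(dvals)
        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        return A

    def _preconditioner(self, dt: float):
        """MIC(0) of the constant all-fluid Laplacian (built once per Δt)."""
        if self._ilu is None or self._ilu_dt != dt:
            nx, ny, nz = self.grid.shape
            scale = dt / (self.grid.rho * self.grid.dx**2)
            px = np.zeros(self.grid.shape); px[:-1] = -scale
            py = np.zeros(self.grid.shape); py[:, :-1] = -scale
            pz = np.zeros(self.grid.shape); pz[:, :, :-1] = -scale
            diag = np.zeros(self.grid.shape)
            diag -= px + py + pz
            diag[1:] += scale; diag[:, 1:] += scale; diag[:, :, 1:] += scale
            diag[:, :, -1] += 2.0 * scale  # free-surface Dirichlet (half-cell ghost)
            pre = _mic0_factor(diag, px, py, pz)
            self._ilu = (pre, px, py, pz)
            self._ilu_dt = dt
        pre, px, py, pz = self._ilu
        shape = self.grid.shape
        n = self.grid.n_cells

        def apply(r):
            return _mic0_apply(r.reshape(shape), pre, px, py, pz).ravel()

        return spla.LinearOperator((n, n), matvec=apply)

    def solve(self, A, b: np.ndarray, dt: float, fluid: np.ndarray) -> np.ndarray:
        """Solve A p = b to the configured residual; returns p per cell."""
        Mpre = self._preconditioner(dt)
        bn = np.linalg.norm(b)
        if bn == 0:
            return np.zeros(self.grid.shape)
        p = np.zeros(self.grid.n_cells)
        matvec = A if callable(A) else (lambda x: A @ x)
        op = spla.LinearOperator((len(p), len(p)), matvec=matvec)
        for _ in range(4):
            p, info = spla.cg(op, b, x0=p, rtol=self.rtol, maxiter=self.max_iter, M=Mpre)
            r = b - matvec(p)
            if np.linalg.norm(r) <= self.rtol * bn * 10 or info == 0:
                break
        else:
            raise RuntimeError(
                f"pressure solver did not converge: |r|/|b| = {np.linalg.norm(r) / bn:.3e}"
            )
        return p.reshape(self.grid.shape)


def _apply_pressure_to_fluid(grid: MacGrid, p: np.ndarray, dt: float,
                             fluid: np.ndarray, face_w=None) -> None:
    """u ← u* − Δt ∇p / ρ on fluid-fluid and free-surface faces."""
    if face_w is None:
        face_w = _interior_face_weights(grid, fluid)
    c = dt / (grid.rho * grid.dx)
    for a in range(3):
        sl_int = [slice(None)] * 3
        sl_int[a] = slice(1, -1)
        dgrad = np.diff(p, axis=a)
        m = face_w[a] > 0
        grid.u[a][tuple(sl_int)][m] -= c * dgrad[m]
    # top free-surface faces: p = 0 at the surface, half a cell away
    mtop = (grid.frac[:, :, -1] > 0) & fluid[:, :, -1]
    grid.u[2][:, :, -1][mtop] -= 2.0 * c * (0.0 - p[:, :, -1][mtop])
    grid.enforce_wall_bc()


def project_pure_fluid(grid: MacGrid, dt: float, solver: PressureSolver | None = None) -> np.ndarray:
    """Pressure-project a solid-free grid; returns the pressure field (Pa).

    After projection the discrete divergence vanishes (to solver tolerance)
    in every cell; the top plane is a ``p = 0`` free surface and the other
    walls are no-penetration boundaries.
    """
    if np.any(grid.solid):
        raise ValueError("project_pure_fluid requires a solid-free grid")
    solver = solver or PressureSolver(grid)
    fluid = np.ones(grid.shape, dtype=bool)
    grid.enforce_wall_bc()
    face_w = _interior_face_weights(grid, fluid)
    A = solver.laplacian(dt, fluid, face_w)
    # constraint scaled to divergence units (s^-1): A p = -div(u*)
    b = -weighted_divergence(grid, fluid, face_w).ravel()
    p = solver.solve(A, b, dt, fluid)
    grid.p = p
    _apply_pressure_to_fluid(grid, p, dt, fluid, face_w)
    return p


def max_divergence(grid: MacGrid, fluid: np.ndarray | None = None) -> float:
    """Max |discrete divergence| (s^-1) over pure-fluid cells."""
    fluid = ~grid.solid if fluid is None else fluid
    div = weighted_divergence(grid, fluid)
    pure = fluid & (grid.frac >= 1.0)
    # exclude cells adjacent to solids (their balance closes via the body)
    return float(np.max(np.abs(div[pure]))) if np.any(pure) else 0.0
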