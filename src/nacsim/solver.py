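"""Coupled tumor dynamics: reaction-diffusion growth under treatment.

The tumor cell density obeys

    dN/dt = div(D grad N) + rho N (1 - N / theta),  grad N . n = 0 on the box

with the diffusivity ``D(x, t)`` inhibited by the tumor-induced mechanical
stress (mechanics module) and the net proliferation rate ``rho(x, t)``
modulated by the two-drug MuSyC surface driven by the perfusion-weighted
exponential pharmacokinetics (regimen + pharmacodynamics modules).

Numerics
--------
* cell-centered second-order finite-volume diffusion with arithmetic face
  averaging of D and zero-flux boundaries (no boundary leakage: the discrete
  operator conserves total mass exactly);
* backward Euler in time (dt = 0.25 day by default) solved with Newton
  iterations (relative residual tolerance 1e-8, at most 20 iterations); the
  Newton systems are symmetric positive definite and strongly diagonally
  dominant at this time step, so they are solved with a Jacobi-preconditioned
  conjugate-gradient iteration (relative tolerance 1e-10);
* staggering: mechanical equilibrium is re-solved every ``mech_every`` steps
  starting at t = 0 (default 4, i.e. daily at dt = 0.25) and D is frozen in
  between; rho is evaluated at the target time level of each implicit step
  and treated as a frozen coefficient within the step;
* drug concentrations factorize as (scalar dose history) x (static perfusion
  map), so the MuSyC surface is evaluated through precomputed perfusion-power
  basis fields — this makes campaigns of thousands of runs tractable.

Many independent parameter draws (a sensitivity-analysis design) are
advanced in lockstep as one vectorized batch. Convergence tests are applied
per run and converged runs are frozen, so every run performs exactly the
arithmetic it would perform alone: batched and solo executions are bitwise
identical, and results are invariant to how a campaign is chunked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import THETA
from .errors import NumericalError
from .grid import Grid, ScalarField
from .mechanics import MechConstants, get_operator
from .pharmacodynamics import PDParams, perfusion_powers, rho_coefficients
from .regimen import Regimen
from .scenario import Scenario

__all__ = ["ModelParams", "Trajectory", "BatchResult", "step", "simulate", "simulate_batch",
           "PARAM_ORDER"]

#: fixed order of the 15 sensitivity-analysis parameters
PARAM_ORDER = (
    "D0", "rho0", "h1", "h2", "C1", "C2", "E1n", "E2n",
    "a1", "a2", "beta", "dm1", "dm2", "g1", "g2",
)

NEWTON_RTOL = 1e-8
NEWTON_MAXIT = 20
INNER_RTOL = 1e-4   # inexact Newton: each outer iteration gains ~1e-4
INNER_MAXIT = 400
#: undershoots below -1e-10 * theta are a numerical failure
UNDERSHOOT_TOL = 1e-10


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of one simulation: baseline diffusivity, MuSyC
    pharmacodynamics, per-drug PK (normalized maximum concentration and decay
    rate) and the fixed mechanical constants."""

    D0: float
    pd: PDParams
    dm1: float
    g1: float
    dm2: float
    g2: float
    mech: MechConstants = field(default_factory=MechConstants)

    def __post_init__(self) -> None:
        if self.D0 <= 0:
            raise ValueError("D0 must be > 0")
        if self.dm1 < 0 or self.dm2 < 0:
            raise ValueError("normalized maximum concentrations must be >= 0")
        if self.g1 <= 0 or self.g2 <= 0:
            raise ValueError("decay rates must be > 0")

    def to_vector(self) -> np.ndarray:
        """The 15 SA parameters as a flat vector in :data:`PARAM_ORDER`."""
        p = self.pd
        return np.array([
            self.D0, p.rho0, p.h1, p.h2, p.C1, p.C2, p.E1n, p.E2n,
            p.a1, p.a2, p.beta, self.dm1, self.dm2, self.g1, self.g2,
        ])

    @classmethod
    def from_vector(cls, v, mech: MechConstants | None = None) -> "ModelParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (15,):
            raise ValueError(f"expected a 15-vector, got shape {v.shape}")
        pd = PDParams(rho0=v[1], h1=v[2], h2=v[3], C1=v[4], C2=v[5],
                      E1n=v[6], E2n=v[7], a1=v[8], a2=v[9], beta=v[10])
        return cls(D0=v[0], pd=pd, dm1=v[11], dm2=v[12], g1=v[13], g2=v[14],
                   mech=mech or MechConstants())


@dataclass
class Trajectory:
    """One simulation's output: per-step quantities of interest and optional
    density snapshots. ``VT`` in mm^3, ``NT`` in cells."""

    times: np.ndarray
    VT: np.ndarray
    NT: np.ndarray
    snapshots: dict[float, ScalarField]
    final: ScalarField


@dataclass
class BatchResult:
    """A lockstep campaign's output (leading axis = run)."""

    times: np.ndarray
    VT: np.ndarray       # (B, n_times)
    NT: np.ndarray       # (B, n_times)
    final: np.ndarray    # (B,) + grid.shape
    snapshots: dict[float, np.ndarray]
    grid: Grid


# ---------------------------------------------------------------------------
# one implicit step
# ---------------------------------------------------------------------------

def _face_coefficients(D: np.ndarray, spacing):
    """Arithmetic face averages of D divided by h^2, per axis, for a
    (B, nx, ny, nz) diffusivity batch."""
    hx, hy, hz = spacing
    fx = np.ascontiguousarray(0.5 * (D[:, 1:, :, :] + D[:, :-1, :, :]) / hx ** 2)
    fy = np.ascontiguousarray(0.5 * (D[:, :, 1:, :] + D[:, :, :-1, :]) / hy ** 2)
    fz = np.ascontiguousarray(0.5 * (D[:, :, :, 1:] + D[:, :, :, :-1]) / hz ** 2)
    return fx, fy, fz


def _postprocess_density(X, theta):
    """Zero tiny undershoots, clip tiny overshoots, fail on large ones."""
    lo = X.min()
    if lo < -UNDERSHOOT_TOL * theta:
        raise NumericalError(
            f"density undershoot {lo:.3e} exceeds tolerance "
            f"{-UNDERSHOOT_TOL * theta:.3e}"
        )
    hi = X.max()
    if hi > theta * (1 + UNDERSHOOT_TOL):
        raise NumericalError(f"density overshoot {hi:.3e} above carrying capacity")
    np.clip(X, 0.0, theta, out=X)
    return X


def step(N: ScalarField, D: ScalarField, rho: ScalarField, dt: float,
         theta: float = THETA) -> ScalarField:
    """Advance a density field by one implicit (backward Euler) step with
    given frozen diffusivity and net-proliferation fields."""
    from ._kernels import newton_step_rho

    if dt <= 0:
        raise ValueError("dt must be > 0")
    if N.grid.shape != D.grid.shape or N.grid.shape != rho.grid.shape:
        raise ValueError("N, D and rho must share a grid")
    fx, fy, fz = _face_coefficients(D.values[None], N.grid.spacing)
    X = np.ascontiguousarray(N.values[None])
    status = np.empty(1, dtype=np.int64)
    newton_step_rho(X, fx, fy, fz, np.ascontiguousarray(rho.values[None]),
                    dt, theta, NEWTON_RTOL, INNER_RTOL, NEWTON_MAXIT,
                    INNER_MAXIT, status)
    if status[0] < 0:
        raise NumericalError(
            f"Newton failed to converge in {NEWTON_MAXIT} iterations")
    X = _postprocess_density(X[0], theta)
    return ScalarField(N.grid, X)


# ---------------------------------------------------------------------------
# full simulations
# ---------------------------------------------------------------------------

def _dose_factors(days: np.ndarray, dm: np.ndarray, gamma: np.ndarray, t: float):
    """Per-run scalar dose history sum at time t (H(0) = 1 convention)."""
    active = days <= t + 1e-12
    if not active.any():
        return np.zeros_like(dm)
    dt_since = t - days[active]
    return dm * np.exp(-np.outer(gamma, dt_since)).sum(axis=1)


def simulate_batch(
    scenario: Scenario,
    param_matrix: np.ndarray,
    regimen: Regimen,
    dt: float = 0.25,
    mech_every: int = 4,
    snapshot_times: tuple[float, ...] = (),
    mech: MechConstants | None = None,
) -> BatchResult:
    """Advance a batch of parameter draws (rows of a (B, 15) matrix in
    :data:`PARAM_ORDER`) through a full regimen in lockstep."""
    mech = mech or MechConstants()
    theta = scenario.theta
    grid = scenario.grid
    P = np.atleast_2d(np.asarray(param_matrix, dtype=float))
    if P.shape[1] != 15:
        raise ValueError(f"parameter matrix must have 15 columns, got {P.shape[1]}")
    B = P.shape[0]
    cols = {name: P[:, i].copy() for i, name in enumerate(PARAM_ORDER)}
    if mech_every < 1:
        raise ValueError("mech_every must be >= 1")
    n_steps = int(round(regimen.horizon / dt))
    if abs(n_steps * dt - regimen.horizon) > 1e-9 * max(1.0, regimen.horizon):
        raise ValueError("regimen horizon must be divisible by dt")

    op = get_operator(grid, mech)
    N = np.broadcast_to(scenario.N0.values, (B,) + grid.shape).copy()
    p_flat = scenario.p.values.reshape(-1)

    pd_cols = {k: cols[k] for k in ("h1", "h2", "C1", "C2", "E1n", "E2n",
                                    "a1", "a2", "beta")}
    # (B, 8, n_vox), contiguous per run for the step kernel
    basis = np.ascontiguousarray(
        perfusion_powers(p_flat, cols["h1"], cols["h2"]).transpose(1, 0, 2))
    days1 = np.asarray(regimen.drug1.dose_days)
    days2 = np.asarray(regimen.drug2.dose_days)

    vol = grid.voxel_volume
    nth = theta / 4.0
    times = np.arange(n_steps + 1) * dt
    VT = np.empty((B, n_steps + 1))
    NT = np.empty((B, n_steps + 1))
    VT[:, 0] = (N.reshape(B, -1) >= nth).sum(axis=1) * vol
    NT[:, 0] = N.reshape(B, -1).sum(axis=1) * vol
    snap_set = {round(float(t) / dt): float(t) for t in snapshot_times}
    snapshots: dict[float, np.ndarray] = {}
    if 0 in snap_set:
        snapshots[snap_set[0]] = N.copy()

    from ._kernels import newton_step_batch

    fx = fy = fz = None
    status = np.empty(B, dtype=np.int64)
    for k in range(n_steps):
        if k % mech_every == 0:
            sv = op.von_mises_batch(N)  # (B,) + shape
            D = cols["D0"][:, None, None, None] * np.exp(-mech.gammaN * sv)
            fx, fy, fz = _face_coefficients(D, grid.spacing)
        t_next = times[k + 1]
        s1 = _dose_factors(days1, cols["dm1"], cols["g1"], t_next)
        s2 = _dose_factors(days2, cols["dm2"], cols["g2"], t_next)
        num_c, den_c = rho_coefficients(pd_cols, s1, s2)  # (8, B)
        newton_step_batch(N, fx, fy, fz, basis,
                          np.ascontiguousarray(num_c.T),
                          np.ascontiguousarray(den_c.T),
                          cols["rho0"], dt, theta, NEWTON_RTOL, INNER_RTOL,
                          NEWTON_MAXIT, INNER_MAXIT, status)
        if (status < 0).any():
            bad = int(np.flatnonzero(status < 0)[0])
            raise NumericalError(
                f"at t = {t_next:g} d: Newton failed to converge in "
                f"{NEWTON_MAXIT} iterations (run {bad} of the batch)")
        try:
            N = _postprocess_density(N, theta)
        except NumericalError as err:
            raise NumericalError(f"at t = {t_next:g} d: {err}") from err

        VT[:, k + 1] = (N.reshape(B, -1) >= nth).sum(axis=1) * vol
        NT[:, k + 1] = N.reshape(B, -1).sum(axis=1) * vol
        if (k + 1) in snap_set:
            snapshots[snap_set[k + 1]] = N.copy()

    return BatchResult(times=times, VT=VT, NT=NT, final=N,
                       snapshots=snapshots, grid=grid)


def simulate(
    scenario: Scenario,
    params: ModelParams,
    regimen: Regimen,
    dt: float = 0.25,
    mech_every: int = 4,
    snapshot_times: tuple[float, ...] = (),
) -> Trajectory:
    """Run one full simulation; see :func:`simulate_batch` for the scheme."""
    res = simulate_batch(
        scenario, params.to_vector()[None, :], regimen, dt=dt,
        mech_every=mech_every, snapshot_times=snapshot_times, mech=params.mech,
    )
    snaps = {t: ScalarField(res.grid, arr[0]) for t, arr in res.snapshots.items()}
    return Trajectory(
        times=res.times, VT=res.VT[0], NT=res.NT[0], snapshots=snaps,
        final=ScalarField(res.grid, res.final[0]),
    )
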