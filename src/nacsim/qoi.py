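"""Scalar model outcomes and agreement metrics.

Tumor volume counts voxels above the segmentation threshold
``N_th = theta / 4`` (ties count as tumor); total cell count integrates the
density map. Both use midpoint (voxel-sum) quadrature, consistent with
voxel-registered fields. The mean relative difference (MRD) summarizes how a
treated density map deviates from the no-treatment reference over the
reference tumor region, and Pearson / Lin concordance correlations quantify
original-vs-reduced model agreement.
"""

from __future__ import annotations

import numpy as np

from .constants import D0_REFERENCE, RHO0_REFERENCE, THETA
from .errors import UndefinedResultError
from .grid import ScalarField
from .pharmacodynamics import PDParams
from .regimen import standard_regimen
from .scenario import Scenario
from .solver import ModelParams, Trajectory, simulate

__all__ = ["tumor_volume", "total_cells", "mrd", "pcc", "ccc", "reference_run",
           "reference_params"]


def tumor_volume(N: ScalarField, theta: float = THETA) -> float:
    """Volume (mm^3) of the region with ``N >= theta / 4``."""
    nth = theta / 4.0
    return float((N.values >= nth).sum() * N.grid.voxel_volume)


def total_cells(N: ScalarField) -> float:
    """Total tumor cell count, midpoint quadrature of the density map."""
    return float(N.values.sum() * N.grid.voxel_volume)


def mrd(N: ScalarField, N_ref: ScalarField, theta: float = THETA) -> float:
    """Mean relative difference of N against a reference map over the
    reference tumor region (``N_ref >= theta/4``), normalized by the
    reference tumor volume."""
    if N.grid.shape != N_ref.grid.shape:
        raise ValueError("fields must share a grid")
    nth = theta / 4.0
    mask = N_ref.values >= nth
    if not mask.any():
        raise UndefinedResultError("reference tumor region is empty")
    rel = (N.values[mask] - N_ref.values[mask]) / N_ref.values[mask]
    # (1/V_ref) * sum(rel) * voxvol == mean over reference voxels
    return float(rel.mean())


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise UndefinedResultError("inputs must be equal-length vectors of size >= 2")
    if x.var() == 0 or y.var() == 0:
        raise UndefinedResultError("correlation undefined for zero-variance input")
    return x, y


def pcc(x, y) -> float:
    """Pearson correlation coefficient."""
    x, y = _check_pair(x, y)
    return float(np.corrcoef(x, y)[0, 1])


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient
    ``2 cov(x,y) / (var x + var y + (mean x - mean y)^2)`` (population
    moments), penalizing both dispersion and location shifts."""
    x, y = _check_pair(x, y)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * cov / (x.var() + y.var() + (x.mean() - y.mean()) ** 2))


def reference_params(mech=None) -> ModelParams:
    """No-treatment reference parameterization: fixed baseline diffusivity
    and proliferation, zero drug concentrations."""
    pd = PDParams(rho0=RHO0_REFERENCE, h1=1.0, h2=1.0, C1=1.0, C2=1.0,
                  E1n=0.0, E2n=0.0, a1=1.0, a2=1.0, beta=0.0)
    kwargs = {"mech": mech} if mech is not None else {}
    return ModelParams(D0=D0_REFERENCE, pd=pd, dm1=0.0, g1=1.0, dm2=0.0, g2=1.0,
                       **kwargs)


_REFERENCE_CACHE: dict[tuple, Trajectory] = {}


def reference_run(scenario: Scenario, regimen_kind: str = "dox_cyc",
                  dt: float = 0.25, mech_every: int = 4) -> Trajectory:
    """The cached no-treatment reference simulation for a scenario over the
    horizon of the named regimen (drug parameters are irrelevant: no dose is
    ever applied)."""
    key = (scenario.fingerprint(), regimen_kind, dt, mech_every)
    traj = _REFERENCE_CACHE.get(key)
    if traj is None:
        regimen = standard_regimen(regimen_kind).with_pk(0.0, 1.0, 0.0, 1.0)
        traj = simulate(scenario, reference_params(), regimen, dt=dt,
                        mech_every=mech_every)
        _REFERENCE_CACHE[key] = traj
    return traj
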