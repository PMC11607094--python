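"""Global variance-based (total-effects) sensitivity analysis.

The campaign follows the Saltelli design: two independent Latin-hypercube
samples ``A`` and ``B`` of the 15-parameter space (n_s rows each) plus the 15
column-swap matrices ``A_B^(i)`` (column i of A replaced by column i of B),
for ``n_s (n_p + 2)`` model evaluations in total. The total-effects index of
parameter i on a scalar outcome Y at time t is the Jansen estimator

    S_T,i(t) = sum_j (Y_A_j(t) - Y_AB^i_j(t))^2 / (2 n_s Var(Y_A, Y_B))

where the variance is taken over the pooled 2 n_s values from A and B
(population normalization). A parameter is influential when S_T,i at the end
of treatment exceeds the tolerance ``eps_s`` (default 0.1) for either
outcome (tumor volume V_T or total cell count N_T). 95% confidence
intervals come from paired percentile bootstrap over the sample index.

Parameter ranges and sampling scales (log-uniform vs uniform) are the
regimen-specific tables used to constrain the model from in vitro
dose-response measurements and prior imaging-informed modeling; they are
hard-coded here as the package's reference parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import UndefinedResultError
from .mechanics import MechConstants
from .qoi import ccc, mrd, pcc, reference_run
from .regimen import standard_regimen
from .scenario import Scenario
from .solver import PARAM_ORDER, simulate_batch
from .grid import ScalarField

__all__ = [
    "ParameterRange", "ParameterSpace", "SampleMatrices", "SAResult",
    "table1_space", "lhs", "saltelli_design", "total_effects", "bootstrap_ci",
    "run_sa", "reduced_model_comparison", "ComparisonReport",
]

N_PARAMS = 15
QOI_NAMES = ("VT", "NT")
EPS_S = 0.1


@dataclass(frozen=True)
class ParameterRange:
    name: str
    lower: float
    upper: float
    scale: str  # "log" | "regular"
    units: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("log", "regular"):
            raise ValueError(f"scale must be 'log' or 'regular', got {self.scale!r}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log-scaled range requires lower > 0")

    def from_unit(self, u):
        """Map unit-interval samples into the range on this row's scale."""
        if self.scale == "log":
            lo, hi = np.log10(self.lower), np.log10(self.upper)
            return 10.0 ** (lo + (hi - lo) * np.asarray(u))
        return self.lower + (self.upper - self.lower) * np.asarray(u)

    def midpoint(self) -> float:
        """Arithmetic midpoint; geometric midpoint for log-scaled rows."""
        if self.scale == "log":
            return float(np.sqrt(self.lower * self.upper))
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class ParameterSpace:
    regimen_kind: str
    rows: tuple[ParameterRange, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != N_PARAMS:
            raise ValueError(f"expected {N_PARAMS} parameter rows")
        if tuple(r.name for r in self.rows) != PARAM_ORDER:
            raise ValueError("parameter rows must follow the fixed order")

    def midpoints(self) -> np.ndarray:
        return np.array([r.midpoint() for r in self.rows])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rows)


_TABLE1 = {
    # name: (units, scale, dox_cyc bounds, ptx_cpt bounds)
    "D0":   ("mm^2/day", "log", (1.0e-6, 1.0e-1), (1.0e-6, 1.0e-1)),
    "rho0": ("1/day", "log", (1.0e-3, 1.0e-1), (1.0e-3, 1.0e-1)),
    "h1":   ("", "log", (1.0, 2.5e1), (1.0, 6.3)),
    "h2":   ("", "log", (0.4, 3.2), (0.3, 3.2)),
    "C1":   ("uM", "log", (6.3e-4, 1.6e-2), (1.0e-3, 4.0e-3)),
    "C2":   ("uM", "log", (1.3e-1, 1.6e3), (6.3e-2, 4.0e1)),
    "E1n":  ("", "regular", (-5.0, 0.5), (-3.0, 0.5)),
    "E2n":  ("", "regular", (-5.0, 0.5), (-3.0, 0.5)),
    "a1":   ("", "log", (1.0e-4, 1.3e3), (1.0e-4, 1.0e4)),
    "a2":   ("", "log", (1.0e-4, 4.0e1), (1.0e-4, 2.5)),
    "beta": ("", "regular", (-0.2, 0.3), (-0.1, 0.2)),
    "dm1":  ("", "log", (5.0, 1.0e3), (5.0, 1.0e3)),
    "dm2":  ("", "log", (5.0, 1.0e3), (5.0, 1.0e3)),
    "g1":   ("1/day", "regular", (0.3, 0.6), (0.3, 1.1)),
    "g2":   ("1/day", "regular", (1.7, 5.4), (0.1, 0.2)),
}


def table1_space(regimen_kind: str) -> ParameterSpace:
    """The 15-parameter space for one NAC regimen (bounds and sampling
    scales of the study's parameter table)."""
    if regimen_kind not in ("dox_cyc", "ptx_cpt"):
        raise ValueError(f"unknown regimen kind {regimen_kind!r}")
    idx = 2 if regimen_kind == "dox_cyc" else 3
    rows = tuple(
        ParameterRange(name, *_TABLE1[name][idx], scale=_TABLE1[name][1],
                       units=_TABLE1[name][0])
        for name in PARAM_ORDER
    )
    return ParameterSpace(regimen_kind, rows)


def lhs(space: ParameterSpace, n_s: int, seed: int) -> np.ndarray:
    """Latin-hypercube sample of the space: (n_s, 15) in physical units,
    one point per equal-probability stratum per column on each row's scale."""
    if n_s < 2:
        raise ValueError("n_s must be >= 2")
    sampler = qmc.LatinHypercube(d=N_PARAMS, seed=seed)
    unit = sampler.random(n_s)
    out = np.empty_like(unit)
    for i, row in enumerate(space.rows):
        out[:, i] = row.from_unit(unit[:, i])
    return out


@dataclass
class SampleMatrices:
    A: np.ndarray
    B: np.ndarray
    AB: list[np.ndarray]
    seed: int | None = None

    @property
    def n_s(self) -> int:
        return self.A.shape[0]

    def design_rows(self) -> np.ndarray:
        """All n_s (n_p + 2) design rows stacked: A, B, then AB^(1..n_p)."""
        return np.vstack([self.A, self.B] + self.AB)


def saltelli_design(A: np.ndarray, B: np.ndarray, seed: int | None = None) -> SampleMatrices:
    """Build the column-swap matrices ``A_B^(i)`` from two sample matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"A and B must share a shape, got {A.shape} vs {B.shape}")
    AB = []
    for i in range(A.shape[1]):
        M = A.copy()
        M[:, i] = B[:, i]
        AB.append(M)
    return SampleMatrices(A=A, B=B, AB=AB, seed=seed)


def _pooled_var(YA, YB):
    pooled = np.concatenate([YA, YB])
    return pooled.var()  # population normalization over the 2 n_s values


def total_effects(YA, YB, YAB_i) -> float:
    """Jansen total-effects estimator for one parameter and one outcome."""
    YA = np.asarray(YA, dtype=float)
    YB = np.asarray(YB, dtype=float)
    YAB_i = np.asarray(YAB_i, dtype=float)
    if YA.shape != YB.shape or YA.shape != YAB_i.shape or YA.ndim != 1:
        raise ValueError("YA, YB and YAB_i must be equal-length vectors")
    var = _pooled_var(YA, YB)
    if var == 0:
        raise UndefinedResultError("outcome variance is zero over A and B")
    n_s = YA.size
    return float(((YA - YAB_i) ** 2).sum() / (2 * n_s * var))


def bootstrap_ci(YA, YB, YAB_i, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Paired percentile bootstrap interval for the total-effects index:
    sample rows j with replacement jointly across Y_A, Y_B and Y_AB."""
    YA = np.asarray(YA, dtype=float)
    YB = np.asarray(YB, dtype=float)
    YAB_i = np.asarray(YAB_i, dtype=float)
    if _pooled_var(YA, YB) == 0:
        raise UndefinedResultError("outcome variance is zero over A and B")
    n_s = YA.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_s, size=(n_boot, n_s))
    ya, yb, yab = YA[idx], YB[idx], YAB_i[idx]
    num = ((ya - yab) ** 2).sum(axis=1)
    var = np.concatenate([ya, yb], axis=1).var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        st = num / (2 * n_s * var)
    st = np.where(num == 0, 0.0, st)  # degenerate resample of a null effect
    st = st[np.isfinite(st)]          # drop zero-variance resamples
    lo, hi = np.percentile(st, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


@dataclass
class SAResult:
    """Time-resolved total-effects indices with end-of-treatment CIs.

    ST has shape (n_times, n_qoi, n_p); Y arrays have shape
    (n_qoi, n_times, n_s); finals of the A and B rows are kept for the
    reduced-model comparison.
    """

    regimen_kind: str
    times: np.ndarray
    param_names: tuple[str, ...]
    ST: np.ndarray
    ci_lo: np.ndarray          # (n_qoi, n_p) at t = T
    ci_hi: np.ndarray
    influential: np.ndarray    # (n_qoi, n_p) bool at t = T
    eps_s: float
    YA: np.ndarray
    YB: np.ndarray
    YAB: np.ndarray            # (n_p, n_qoi, n_times, n_s)
    A: np.ndarray
    B: np.ndarray
    final_A: np.ndarray        # (n_s,) + grid shape
    final_B: np.ndarray
    seed: int | None = None

    def influential_union(self) -> np.ndarray:
        """Parameters influential for at least one outcome."""
        return self.influential.any(axis=0)

    def indices_frame(self) -> pd.DataFrame:
        """End-of-treatment S_T with CIs, one row per (QoI, parameter)."""
        recs = []
        for q, qn in enumerate(QOI_NAMES):
            for i, pn in enumerate(self.param_names):
                recs.append({
                    "qoi": qn, "parameter": pn, "ST": self.ST[-1, q, i],
                    "ci_lo": self.ci_lo[q, i], "ci_hi": self.ci_hi[q, i],
                    "influential": bool(self.influential[q, i]),
                })
        return pd.DataFrame(recs)


def _run_design(scenario, regimen, rows, dt, mech_every, mech, chunk,
                store_idx, checkpoint_dir=None, tag="design"):
    """Run design rows in lockstep chunks; returns (VT, NT) at the stored
    time indices and the end-of-treatment fields. Chunks are independent and
    cached to disk when a checkpoint directory is given (resumable)."""
    n_rows = rows.shape[0]
    n_t = len(store_idx)
    VT = np.empty((n_rows, n_t))
    NT = np.empty((n_rows, n_t))
    finals = np.empty((n_rows,) + scenario.grid.shape)
    ckdir = Path(checkpoint_dir) if checkpoint_dir else None
    if ckdir:
        ckdir.mkdir(parents=True, exist_ok=True)
    for start in range(0, n_rows, chunk):
        stop = min(start + chunk, n_rows)
        ckfile = ckdir / f"{tag}_{start:06d}_{stop:06d}.npz" if ckdir else None
        if ckfile and ckfile.exists():
            data = np.load(ckfile)
            VT[start:stop], NT[start:stop] = data["VT"], data["NT"]
            finals[start:stop] = data["final"]
            continue
        res = simulate_batch(scenario, rows[start:stop], regimen, dt=dt,
                             mech_every=mech_every, mech=mech)
        VT[start:stop] = res.VT[:, store_idx]
        NT[start:stop] = res.NT[:, store_idx]
        finals[start:stop] = res.final
        if ckfile:
            np.savez_compressed(ckfile, VT=VT[start:stop], NT=NT[start:stop],
                                final=finals[start:stop])
    return VT, NT, finals


def run_sa(
    scenario: Scenario,
    regimen_kind: str,
    n_s: int,
    seed: int,
    dt: float = 0.25,
    mech_every: int = 4,
    eps_s: float = EPS_S,
    n_boot: int = 1000,
    store_every_days: float = 1.0,
    chunk: int = 256,
    checkpoint_dir: str | Path | None = None,
    mech: MechConstants | None = None,
) -> SAResult:
    """Run the full Saltelli campaign and estimate time-resolved
    total-effects indices for tumor volume and total cell count."""
    space = table1_space(regimen_kind)
    regimen = standard_regimen(regimen_kind)
    s_a, s_b = (int(s) for s in
                np.random.SeedSequence(seed).generate_state(2) % (2 ** 31))
    A = lhs(space, n_s, s_a)
    B = lhs(space, n_s, s_b)
    design = saltelli_design(A, B, seed=seed)
    rows = design.design_rows()

    n_steps = int(round(regimen.horizon / dt))
    stride = max(1, int(round(store_every_days / dt)))
    store_idx = np.arange(0, n_steps + 1, stride)
    if store_idx[-1] != n_steps:
        store_idx = np.append(store_idx, n_steps)
    times = store_idx * dt

    VT, NT, finals = _run_design(
        scenario, regimen, rows, dt, mech_every, mech, chunk, store_idx,
        checkpoint_dir=checkpoint_dir, tag=f"sa_{regimen_kind}_{n_s}_{seed}",
    )

    n_t = len(store_idx)
    Y = np.stack([VT, NT])  # (n_qoi, n_rows, n_t)
    YA = Y[:, :n_s].transpose(0, 2, 1)                   # (n_qoi, n_t, n_s)
    YB = Y[:, n_s:2 * n_s].transpose(0, 2, 1)
    YAB = np.stack([
        Y[:, (2 + i) * n_s:(3 + i) * n_s].transpose(0, 2, 1)
        for i in range(N_PARAMS)
    ])                                                    # (n_p, n_qoi, n_t, n_s)

    pooled = np.concatenate([YA, YB], axis=2)
    var = pooled.var(axis=2)                              # (n_qoi, n_t)
    if np.any(var[:, -1] == 0):
        raise UndefinedResultError("outcome variance is zero at the horizon")
    with np.errstate(divide="ignore", invalid="ignore"):
        ST = ((YA[None] - YAB) ** 2).sum(axis=3) / (2 * n_s * var[None])
    ST = np.nan_to_num(ST, nan=0.0).transpose(2, 1, 0)    # (n_t, n_qoi, n_p)

    ci_lo = np.empty((len(QOI_NAMES), N_PARAMS))
    ci_hi = np.empty_like(ci_lo)
    boot_seeds = np.random.SeedSequence(seed + 1).generate_state(
        len(QOI_NAMES) * N_PARAMS) % (2 ** 31)
    for q in range(len(QOI_NAMES)):
        for i in range(N_PARAMS):
            ci_lo[q, i], ci_hi[q, i] = bootstrap_ci(
                YA[q, -1], YB[q, -1], YAB[i, q, -1], n_boot=n_boot,
                seed=int(boot_seeds[q * N_PARAMS + i]),
            )

    influential = ST[-1] > eps_s
    return SAResult(
        regimen_kind=regimen_kind, times=times, param_names=space.names,
        ST=ST, ci_lo=ci_lo, ci_hi=ci_hi, influential=influential, eps_s=eps_s,
        YA=YA, YB=YB, YAB=YAB, A=A, B=B,
        final_A=finals[:n_s], final_B=finals[n_s:2 * n_s], seed=seed,
    )


@dataclass
class ComparisonReport:
    """Paired original-vs-reduced model outcomes at the end of treatment."""

    rows: np.ndarray
    influential: np.ndarray
    fixed_values: np.ndarray
    VT_orig: np.ndarray
    VT_red: np.ndarray
    NT_orig: np.ndarray
    NT_red: np.ndarray
    MRD_orig: np.ndarray
    MRD_red: np.ndarray
    VT_baseline: float
    NT_baseline: float

    def correlations(self) -> dict[str, float]:
        return {
            "VT_pcc": pcc(self.VT_orig, self.VT_red),
            "VT_ccc": ccc(self.VT_orig, self.VT_red),
            "NT_pcc": pcc(self.NT_orig, self.NT_red),
            "NT_ccc": ccc(self.NT_orig, self.NT_red),
            "MRD_pcc": pcc(self.MRD_orig, self.MRD_red),
            "MRD_ccc": ccc(self.MRD_orig, self.MRD_red),
        }

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "VT_orig": self.VT_orig, "VT_red": self.VT_red,
            "NT_orig": self.NT_orig, "NT_red": self.NT_red,
            "MRD_orig": self.MRD_orig, "MRD_red": self.MRD_red,
        })


def reduced_model_comparison(
    scenario: Scenario,
    regimen_kind: str,
    influential: np.ndarray,
    rows: np.ndarray,
    fixed_values: np.ndarray | None = None,
    dt: float = 0.25,
    mech_every: int = 4,
    chunk: int = 256,
    originals: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    mech: MechConstants | None = None,
) -> ComparisonReport:
    """Compare the original model against the reduced model on a set of
    parameter rows (typically rows of the SA matrices A and B).

    The reduced model varies only the influential parameters; the rest are
    fixed (by default to the range midpoints, geometric for log-scaled
    rows). ``originals`` may carry precomputed end-of-treatment
    (V_T, N_T, N-field) arrays for the rows — e.g. straight from the SA
    campaign — to avoid re-running the original model.
    """
    influential = np.asarray(influential, dtype=bool)
    if influential.shape != (N_PARAMS,) or not influential.any():
        raise ValueError("influential must be a nonempty 15-entry mask")
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    space = table1_space(regimen_kind)
    if fixed_values is None:
        fixed_values = space.midpoints()
    fixed_values = np.asarray(fixed_values, dtype=float)

    regimen = standard_regimen(regimen_kind)
    n_steps = int(round(regimen.horizon / dt))
    store_idx = np.array([0, n_steps])

    if originals is None:
        VT_o, NT_o, fin_o = _run_design(scenario, regimen, rows, dt,
                                        mech_every, mech, chunk, store_idx)
        VT_orig, NT_orig = VT_o[:, -1], NT_o[:, -1]
        VT_base, NT_base = float(VT_o[0, 0]), float(NT_o[0, 0])
    else:
        VT_orig, NT_orig, fin_o = originals
        from .qoi import total_cells, tumor_volume
        VT_base = tumor_volume(scenario.N0, scenario.theta)
        NT_base = total_cells(scenario.N0)

    red_rows = rows.copy()
    red_rows[:, ~influential] = fixed_values[~influential]
    VT_r, NT_r, fin_r = _run_design(scenario, regimen, red_rows, dt,
                                    mech_every, mech, chunk, store_idx)

    ref = reference_run(scenario, regimen_kind, dt=dt, mech_every=mech_every)
    theta = scenario.theta
    MRD_orig = np.array([
        mrd(ScalarField(scenario.grid, f), ref.final, theta) for f in fin_o
    ])
    MRD_red = np.array([
        mrd(ScalarField(scenario.grid, f), ref.final, theta) for f in fin_r
    ])
    return ComparisonReport(
        rows=rows, influential=influential, fixed_values=fixed_values,
        VT_orig=VT_orig, VT_red=VT_r[:, -1],
        NT_orig=NT_orig, NT_red=NT_r[:, -1],
        MRD_orig=MRD_orig, MRD_red=MRD_red,
        VT_baseline=VT_base, NT_baseline=NT_base,
    )
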