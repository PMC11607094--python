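"""Normalized two-drug MuSyC pharmacodynamics.

The tumor cell net proliferation rate under a two-drug regimen is a rational
dose-response surface over the normalized concentrations
``d1 = d_1 / C_1`` and ``d2 = d_2 / C_2``:

    rho = rho0 * (g0 + g1 d1^h1 E1 + g2 d2^h2 E2 + g3 d1^h1 d2^h2 E3)
               / (g0 + g1 d1^h1 + g2 d2^h2 + g3 d1^h1 d2^h2)

where ``E_i`` are the maximal drug effects normalized by the drug-free rate
``rho0``, ``h_i`` are Hill coefficients, ``alpha_i`` the synergies of potency
and the synergy of efficacy ``beta`` enters through the combination effect

    E3 = (1 + beta) * min(E1, E2) - beta.

The prefactors ``g0..g3`` carry the un-normalized half-maximal concentrations
``C_i^{h_i}`` exactly as in the original MuSyC surface:

    g0 = C1^h1 + C2^h2 + (C1 a2 d1)^h1 + (C2 a1 d2)^h2
    g1 = C1^h1 + C2^h2 + (C1 a2 d1)^h1 + a2^h1 (C2 d2)^h2
    g2 = C1^h1 + C2^h2 + a1^h2 (C1 d1)^h1 + (C2 a1 d2)^h2
    g3 = (C1 a2)^h1 + (C2 a1)^h2 + a1^h2 (C1 a2 d1)^h1 + a2^h1 (C2 a1 d2)^h2

Individual terms can span hundreds of orders of magnitude (C2 up to 1.6e3 uM
with Hill exponents up to 25), so the surface is evaluated in log space: each
of the 16 elementary denominator terms is an exponential, the largest log is
subtracted before exponentiation, and the common scale cancels exactly in the
ratio. Powers ``d^h`` at ``d = 0`` are taken as 0 (continuous extension).

When the drugs are in detailed balance, ``alpha2^h1 == alpha1^h2``, the four
prefactors collapse (g0 = g1 = g2 = g3 / alpha1^h2) and the surface reduces to

    rho = rho0 * (1 + d1^h1 E1 + d2^h2 E2 + a1^h2 d1^h1 d2^h2 E3)
               / (1 + d1^h1 + d2^h2 + a1^h2 d1^h1 d2^h2)

implemented separately as :func:`musyc_rho_db`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ScalarField

__all__ = ["PDParams", "e3", "normalize", "musyc_rho", "musyc_rho_db",
           "response_curves"]


@dataclass(frozen=True)
class PDParams:
    """MuSyC parameters for one two-drug regimen.

    rho0 : drug-free net proliferation rate (1/day), > 0
    h1, h2 : Hill coefficients (dimensionless), > 0
    C1, C2 : half-maximal effective concentrations (uM), > 0
    E1n, E2n : normalized maximal effects E_i / rho0 (may be negative)
    a1, a2 : synergies of potency, > 0
    beta : synergy of efficacy (dimensionless)
    """

    rho0: float
    h1: float
    h2: float
    C1: float
    C2: float
    E1n: float
    E2n: float
    a1: float
    a2: float
    beta: float

    def __post_init__(self) -> None:
        if self.rho0 <= 0:
            raise ValueError("rho0 must be > 0")
        if self.h1 <= 0 or self.h2 <= 0:
            raise ValueError("Hill coefficients must be > 0")
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("half-maximal concentrations must be > 0")
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("synergies of potency must be > 0")

    @property
    def E3n(self) -> float:
        return e3(self.E1n, self.E2n, self.beta)


def e3(E1n: float, E2n: float, beta: float) -> float:
    """Normalized combination effect: ``(1 + beta) * min(E1, E2) - beta``.

    Not clamped; applied as printed even outside the single-drug effect range.
    """
    return (1.0 + beta) * min(E1n, E2n) - beta


def normalize(E_i: float, rho0: float, d_i, C_i: float):
    """Normalize a raw maximal effect (1/day) by rho0 and a raw concentration
    (uM) by the half-maximal concentration: returns ``(E_i/rho0, d_i/C_i)``."""
    if rho0 <= 0:
        raise ValueError("rho0 must be > 0")
    if C_i <= 0:
        raise ValueError("C_i must be > 0")
    return E_i / rho0, np.asarray(d_i) / C_i if np.ndim(d_i) else d_i / C_i


def _term_table(p: PDParams) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The 16 elementary denominator terms of the MuSyC ratio.

    Returns (log coefficient, power of d1^h1, power of d2^h2, effect factor)
    arrays of length 16. The numerator uses the same terms scaled by the
    effect factor (1 for the g0 group, E1/E2/E3 for the others).
    """
    lC1, lC2 = p.h1 * np.log(p.C1), p.h2 * np.log(p.C2)
    la1, la2 = p.h2 * np.log(p.a1), p.h1 * np.log(p.a2)
    # g0..g3 each contribute 4 terms; multiplying groups by 1, D1, D2, D1*D2
    logc = np.array([
        # g0 * 1
        lC1, lC2, lC1 + la2, lC2 + la1,
        # g1 * D1
        lC1, lC2, lC1 + la2, la2 + lC2,
        # g2 * D2
        lC1, lC2, la1 + lC1, lC2 + la1,
        # g3 * D1 * D2
        lC1 + la2, lC2 + la1, la1 + lC1 + la2, la2 + lC2 + la1,
    ])
    a_pow = np.array([0, 0, 1, 0, 1, 1, 2, 1, 0, 0, 1, 0, 1, 1, 2, 1], dtype=float)
    b_pow = np.array([0, 0, 0, 1, 0, 0, 0, 1, 1, 1, 1, 2, 1, 1, 1, 2], dtype=float)
    eff = np.concatenate([
        np.full(4, 1.0),
        np.full(4, p.E1n),
        np.full(4, p.E2n),
        np.full(4, p.E3n),
    ])
    return logc, a_pow, b_pow, eff


def _as_values(d):
    if isinstance(d, ScalarField):
        return d.values, d.grid
    return np.asarray(d, dtype=float), None


def musyc_rho(d1n, d2n, params: PDParams):
    """Net proliferation rate (1/day) on the full MuSyC surface.

    ``d1n``/``d2n`` are normalized concentrations — scalars, arrays or
    :class:`ScalarField`s (applied voxelwise). Returns the same kind.
    """
    v1, grid = _as_values(d1n)
    v2, grid2 = _as_values(d2n)
    grid = grid or grid2
    if np.any(v1 < 0) or np.any(v2 < 0):
        raise ValueError("normalized concentrations must be non-negative")

    logc, a_pow, b_pow, eff = _term_table(params)
    with np.errstate(divide="ignore"):
        # d = 0 maps to a huge negative log so d^h -> 0 without 0 * inf traps
        L1 = np.maximum(params.h1 * np.log(v1), -1e30)
        L2 = np.maximum(params.h2 * np.log(v2), -1e30)
    # term logs, shape (16, ...)
    ell = (
        logc.reshape((16,) + (1,) * np.ndim(L1 + L2))
        + np.multiply.outer(a_pow, L1)
        + np.multiply.outer(b_pow, L2)
    )
    M = ell.max(axis=0)
    w = np.exp(ell - M)  # M is finite: the constant C-terms are always present
    den = w.sum(axis=0)
    num = (eff.reshape((16,) + (1,) * (w.ndim - 1)) * w).sum(axis=0)
    rho = params.rho0 * num / den
    rho = rho if np.ndim(rho) else float(rho)
    if grid is not None:
        return ScalarField(grid, rho)
    return rho


def musyc_rho_db(d1n, d2n, params: PDParams):
    """Net proliferation rate under the detailed-balance reduction
    (valid surface in its own right; coincides with :func:`musyc_rho`
    whenever ``a2^h1 == a1^h2``)."""
    v1, grid = _as_values(d1n)
    v2, grid2 = _as_values(d2n)
    grid = grid or grid2
    if np.any(v1 < 0) or np.any(v2 < 0):
        raise ValueError("normalized concentrations must be non-negative")

    la = params.h2 * np.log(params.a1)
    with np.errstate(divide="ignore"):
        L1 = np.maximum(params.h1 * np.log(v1), -1e30)
        L2 = np.maximum(params.h2 * np.log(v2), -1e30)
    zero = np.zeros(np.broadcast_shapes(np.shape(L1), np.shape(L2)))
    ell = np.stack([zero, L1 + zero, L2 + zero, la + L1 + L2])
    eff = np.array([1.0, params.E1n, params.E2n, params.E3n])
    M = ell.max(axis=0)
    w = np.exp(ell - M)
    den = w.sum(axis=0)
    num = (eff.reshape((4,) + (1,) * (w.ndim - 1)) * w).sum(axis=0)
    rho = params.rho0 * num / den
    rho = rho if np.ndim(rho) else float(rho)
    if grid is not None:
        return ScalarField(grid, rho)
    return rho


def response_curves(params: PDParams, regimen, perfusion: float = 1.0,
                    dt: float = 0.25, csv_path=None):
    """Time courses of the normalized drug concentrations and the resulting
    proliferation rate at one perfused tissue point — the curves one plots
    to inspect a regimen's pharmacology. Columns: time (days), d1, d2,
    rho_combined, rho_drug1_alone, rho_drug2_alone (1/day).

    Returns a pandas DataFrame; optionally also written as CSV.
    """
    import pandas as pd

    from .regimen import dose_factor

    times = np.arange(0.0, regimen.horizon + dt / 2, dt)
    d1 = np.array([dose_factor(regimen.drug1, t) for t in times]) * perfusion
    d2 = np.array([dose_factor(regimen.drug2, t) for t in times]) * perfusion
    frame = pd.DataFrame({
        "time_days": times,
        "d1": d1,
        "d2": d2,
        "rho_combined": musyc_rho(d1, d2, params),
        "rho_drug1_alone": musyc_rho(d1, np.zeros_like(d2), params),
        "rho_drug2_alone": musyc_rho(np.zeros_like(d1), d2, params),
    })
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    return frame


# ---------------------------------------------------------------------------
# fast path for the simulator: perfusion-factorized concentrations
# ---------------------------------------------------------------------------

#: exponent pairs (a, b) of the 8 distinct basis fields p^(a*h1) * p^(b*h2)
_BASIS = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (2, 1), (1, 2)]
_TERM_TO_BASIS = None  # built lazily from the term table powers


def _term_basis_index() -> np.ndarray:
    global _TERM_TO_BASIS
    if _TERM_TO_BASIS is None:
        # powers are identical for every parameter set; probe with any params
        probe = PDParams(1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0)
        _, a_pow, b_pow, _ = _term_table(probe)
        _TERM_TO_BASIS = np.array(
            [_BASIS.index((int(a), int(b))) for a, b in zip(a_pow, b_pow)]
        )
    return _TERM_TO_BASIS


def perfusion_powers(p_values: np.ndarray, h1, h2) -> np.ndarray:
    """Precompute the basis fields ``p^(a*h1 + b*h2)`` for the factorized
    surface evaluation. ``h1``/``h2`` may be per-run vectors (batch leading
    axis); returns an array of shape (8, batch, n_voxels)."""
    h1 = np.atleast_1d(np.asarray(h1, dtype=float))
    h2 = np.atleast_1d(np.asarray(h2, dtype=float))
    flat = p_values.reshape(-1)
    with np.errstate(divide="ignore"):
        logp = np.log(flat)
    out = np.empty((len(_BASIS), h1.size, flat.size))
    for k, (a, b) in enumerate(_BASIS):
        expo = a * h1 + b * h2  # (batch,)
        with np.errstate(invalid="ignore", over="ignore"):
            out[k] = np.exp(np.multiply.outer(expo, logp))
        if a == 0 and b == 0:
            out[k] = 1.0
        else:
            # p = 0 with positive exponent -> 0 (continuous extension)
            out[k] = np.nan_to_num(out[k], nan=0.0, posinf=0.0)
    return out


def rho_coefficients(
    params_cols: dict[str, np.ndarray], s1: np.ndarray, s2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-run numerator/denominator coefficients of the factorized surface.

    With concentrations ``d_i(x, t) = s_i(t) * p(x)`` every elementary MuSyC
    term becomes (scalar coefficient) x (basis field); this returns the
    coefficients grouped per basis field, already rescaled by the largest
    denominator term so that ``rho = rho0 * (num . basis) / (den . basis)``
    is overflow-safe.

    params_cols maps parameter names (h1, h2, C1, C2, E1n, E2n, a1, a2, beta)
    to per-run vectors; s1, s2 are the scalar dose factors at the evaluation
    time. Returns (num, den), each of shape (8, batch).
    """
    h1, h2 = params_cols["h1"], params_cols["h2"]
    C1, C2 = params_cols["C1"], params_cols["C2"]
    a1, a2 = params_cols["a1"], params_cols["a2"]
    E1n, E2n, beta = params_cols["E1n"], params_cols["E2n"], params_cols["beta"]
    E3n = (1.0 + beta) * np.minimum(E1n, E2n) - beta

    lC1, lC2 = h1 * np.log(C1), h2 * np.log(C2)
    la1, la2 = h2 * np.log(a1), h1 * np.log(a2)
    with np.errstate(divide="ignore"):
        # huge negative log before a drug's first dose -> its terms vanish
        ls1 = np.maximum(h1 * np.log(s1), -1e30)
        ls2 = np.maximum(h2 * np.log(s2), -1e30)

    logc = np.stack([
        lC1, lC2, lC1 + la2 + ls1, lC2 + la1 + ls2,
        lC1 + ls1, lC2 + ls1, lC1 + la2 + 2 * ls1, la2 + lC2 + ls1 + ls2,
        lC1 + ls2, lC2 + ls2, la1 + lC1 + ls1 + ls2, lC2 + la1 + 2 * ls2,
        lC1 + la2 + ls1 + ls2, lC2 + la1 + ls1 + ls2,
        la1 + lC1 + la2 + 2 * ls1 + ls2, la2 + lC2 + la1 + ls1 + 2 * ls2,
    ])  # (16, batch)
    # effect factor per term group: 1, E1, E2, E3
    ones = np.ones_like(E1n)
    eff = np.stack([ones] * 4 + [E1n] * 4 + [E2n] * 4 + [E3n] * 4)

    M = logc.max(axis=0)
    with np.errstate(invalid="ignore"):
        w = np.exp(logc - M)
    w = np.nan_to_num(w, nan=0.0)

    idx = _term_basis_index()
    nb = len(_BASIS)
    den = np.zeros((nb,) + w.shape[1:])
    num = np.zeros_like(den)
    for k in range(16):
        den[idx[k]] += w[k]
        num[idx[k]] += eff[k] * w[k]
    return num, den
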