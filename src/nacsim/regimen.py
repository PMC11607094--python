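"""NAC drug schedules and perfusion-weighted pharmacokinetics.

Each drug dose is an instantaneous bolus whose local normalized concentration
decays exponentially (the terminal phase of clinical pharmacokinetics) and is
scaled by the static perfusion map:

    d_hat_i(x, t) = sum_j  d_hat_max_i * p(x) * exp(-gamma_i (t - t_ij)) * H(t - t_ij)

with the Heaviside convention H(0) = 1 (a dose contributes from its delivery
instant inclusive, so the delivery-day solver step already sees drug).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import ScalarField

__all__ = ["DrugSpec", "Regimen", "standard_regimen", "concentration", "dose_factor"]


@dataclass(frozen=True)
class DrugSpec:
    """One drug in a regimen: dose calendar (days), normalized maximum
    concentration ``d_hat_max = d_max / C`` (dimensionless) and decay rate
    (1/day)."""

    name: str
    dose_days: tuple[float, ...]
    dmax_norm: float
    decay: float

    def __post_init__(self) -> None:
        days = tuple(float(t) for t in self.dose_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("dose_days must be strictly increasing")
        if any(t < 0 for t in days):
            raise ValueError("dose_days must be non-negative")
        if self.dmax_norm < 0:
            raise ValueError("dmax_norm must be >= 0")
        if self.decay <= 0:
            raise ValueError("decay rate must be > 0")
        object.__setattr__(self, "dose_days", days)


@dataclass(frozen=True)
class Regimen:
    """A two-drug NAC plan over the horizon [0, T] days."""

    drug1: DrugSpec
    drug2: DrugSpec
    horizon: float

    def __post_init__(self) -> None:
        for d in (self.drug1, self.drug2):
            if any(t >= self.horizon for t in d.dose_days):
                raise ValueError(
                    f"{d.name}: all dose days must precede the horizon T={self.horizon}"
                )

    def with_pk(self, dmax1: float, gamma1: float, dmax2: float, gamma2: float) -> "Regimen":
        """Return a copy with overridden PK parameters (calendar unchanged)."""
        return Regimen(
            replace(self.drug1, dmax_norm=dmax1, decay=gamma1),
            replace(self.drug2, dmax_norm=dmax2, decay=gamma2),
            self.horizon,
        )


def standard_regimen(kind: str) -> Regimen:
    """Build one of the two standard NAC regimens.

    ``dox_cyc``: four 2-week cycles, both drugs on the first day of each cycle
    (days 0, 14, 28, 42), T = 56 days.

    ``ptx_cpt``: four 3-week cycles; paclitaxel weekly (days 0, 7, ..., 77 —
    12 doses) and carboplatin on the first day of each cycle (days 0, 21, 42,
    63), T = 84 days.

    PK parameters default to the midpoint of the sensitivity-analysis ranges
    and are normally overridden per run (:meth:`Regimen.with_pk`).
    """
    if kind == "dox_cyc":
        days = tuple(float(t) for t in range(0, 56, 14))
        return Regimen(
            DrugSpec("doxorubicin", days, dmax_norm=70.0, decay=0.45),
            DrugSpec("cyclophosphamide", days, dmax_norm=70.0, decay=3.55),
            horizon=56.0,
        )
    if kind == "ptx_cpt":
        ptx_days = tuple(float(t) for t in range(0, 84, 7))
        cpt_days = tuple(float(t) for t in range(0, 84, 21))
        return Regimen(
            DrugSpec("paclitaxel", ptx_days, dmax_norm=70.0, decay=0.7),
            DrugSpec("carboplatin", cpt_days, dmax_norm=70.0, decay=0.15),
            horizon=84.0,
        )
    raise ValueError(f"unknown regimen kind {kind!r}; expected 'dox_cyc' or 'ptx_cpt'")


def dose_factor(drug: DrugSpec, t: float) -> float:
    """Scalar part of the concentration field at time t:
    ``d_hat_max * sum_j exp(-gamma (t - t_j)) H(t - t_j)``.

    The full field is this factor times the perfusion map.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    days = np.asarray(drug.dose_days)
    active = days <= t
    if not active.any():
        return 0.0
    return float(drug.dmax_norm * np.exp(-drug.decay * (t - days[active])).sum())


def concentration(drug: DrugSpec, p: ScalarField, t: float) -> ScalarField:
    """Normalized perfusion-weighted drug concentration field at time t."""
    return ScalarField(p.grid, dose_factor(drug, t) * p.values)
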