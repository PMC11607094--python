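"""Synthetic tissue-box scenarios.

A scenario bundles the initial tumor cell density map ``N(x, 0)`` and the
static normalized blood perfusion map ``p(x)`` over a box of breast tissue.
Clinically these come from DW-MRI (cellularity) and DCE-MRI (perfusion); the
generator below replaces them with a parametric stand-in — an ellipsoidal
tumor with a smooth rim inside a healthy margin, and a perfusion plateau that
is either uniform (well-perfused tumor) or suppressed inside the tumor core
(poorly perfused tumor). Only the well-vs-poor perfusion contrast is
controlled; patient anatomy is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .constants import THETA
from .grid import Grid, ScalarField, read_volume, write_volume

__all__ = ["Scenario", "synth_scenario", "save_scenario", "load_scenario"]

#: normalized perfusion outside the tumor (and everywhere for a well-perfused
#: tumor); straddles the high range of normalized AUC perfusion maps
PLATEAU_PERFUSION = 0.9
#: suppressed perfusion in the core of a poorly perfused tumor
CORE_PERFUSION = 0.2
#: default initial peak density as a fraction of carrying capacity
DEFAULT_PEAK_FRACTION = 0.6
#: tumor segmentation threshold fraction (N_th = theta / 4)
TUMOR_THRESHOLD_FRACTION = 0.25


@dataclass
class Scenario:
    """A tissue box: initial cell density ``N0`` (cells/mm^3), perfusion ``p``
    (dimensionless in [0, 1]) and a label.

    Invariants: ``0 <= N0 <= theta``, ``0 <= p <= 1`` and the region
    ``N0 > theta/4`` does not touch the box boundary (a ring of healthy
    tissue surrounds the initial tumor).
    """

    grid: Grid
    N0: ScalarField
    p: ScalarField
    label: str = "custom"
    theta: float = THETA

    def __post_init__(self) -> None:
        if self.N0.grid.shape != self.grid.shape or self.p.grid.shape != self.grid.shape:
            raise ValueError("N0 and p must live on the scenario grid")
        if np.any(self.N0.values < 0) or np.any(self.N0.values > self.theta * (1 + 1e-12)):
            raise ValueError("N0 must lie in [0, theta]")
        if np.any(self.p.values < 0) or np.any(self.p.values > 1):
            raise ValueError("p must lie in [0, 1]")
        mask = self.N0.values > self.theta * TUMOR_THRESHOLD_FRACTION
        if _touches_boundary(mask):
            raise ValueError(
                "initial tumor (N0 > theta/4) touches the box boundary; "
                "a healthy-tissue margin is required"
            )

    def fingerprint(self) -> bytes:
        """Stable content hash input, used for caching reference runs."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.asarray(self.grid.shape).tobytes())
        h.update(np.asarray(self.grid.spacing).tobytes())
        h.update(self.N0.values.tobytes())
        h.update(self.p.values.tobytes())
        h.update(np.float64(self.theta).tobytes())
        return h.digest()


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def synth_scenario(
    grid: Grid,
    tumor_radius_mm: float | tuple[float, float, float],
    peak_density_fraction: float = DEFAULT_PEAK_FRACTION,
    perfusion: str = "well",
    smooth_mm: float = 2.0,
    seed: int = 0,
    noise_amplitude: float = 0.02,
    theta: float = THETA,
) -> Scenario:
    """Generate a synthetic tumor scenario.

    The initial density is ``peak_density_fraction * theta`` inside a centered
    ellipsoid of the given semi-axes (mm), smoothed by a Gaussian of width
    ``smooth_mm`` and clipped to ``[0, theta]``. Perfusion is a plateau of
    :data:`PLATEAU_PERFUSION` with small seeded spatial noise; for
    ``perfusion='poor'`` it is smoothly suppressed to :data:`CORE_PERFUSION`
    inside the tumor core. Deterministic given all arguments and the seed.
    """
    if perfusion not in ("well", "poor"):
        raise ValueError(f"perfusion must be 'well' or 'poor', got {perfusion!r}")
    if not 0 < peak_density_fraction <= 1:
        raise ValueError("peak_density_fraction must be in (0, 1]")
    if smooth_mm < 0:
        raise ValueError("smooth_mm must be non-negative")
    radii = np.broadcast_to(np.asarray(tumor_radius_mm, dtype=float), (3,)).copy()
    if np.any(radii <= 0):
        raise ValueError("tumor radius must be positive")

    extent = np.array(grid.shape) * np.array(grid.spacing)
    # the smoothed rim spills ~one smoothing width past the ellipsoid; demand
    # that the ellipsoid plus two voxels of margin fits in the box
    margin = 2 * np.array(grid.spacing)
    if np.any(radii + margin >= extent / 2):
        raise ValueError(
            f"tumor radii {tuple(radii)} mm do not fit in the box "
            f"{tuple(extent)} mm with a 2-voxel healthy margin"
        )

    xs = [
        (np.arange(n) - (n - 1) / 2) * h
        for n, h in zip(grid.shape, grid.spacing)
    ]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    r2 = (X / radii[0]) ** 2 + (Y / radii[1]) ** 2 + (Z / radii[2]) ** 2
    inside = (r2 <= 1.0).astype(float)

    sigma_vox = [smooth_mm / h for h in grid.spacing]
    if smooth_mm > 0:
        core = ndimage.gaussian_filter(inside, sigma_vox)
    else:
        core = inside
    n0 = np.clip(peak_density_fraction * theta * core, 0.0, theta)

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    if smooth_mm > 0:
        noise = ndimage.gaussian_filter(noise, sigma_vox)
        scale = noise.std()
        if scale > 0:
            noise = noise / scale
    p = PLATEAU_PERFUSION + noise_amplitude * noise
    if perfusion == "poor":
        # blend towards the suppressed core value inside the tumor
        p = p * (1 - core) + (CORE_PERFUSION + noise_amplitude * noise) * core
    p = np.clip(p, 0.0, 1.0)

    return Scenario(
        grid=grid,
        N0=ScalarField(grid, n0),
        p=ScalarField(grid, p),
        label=f"{perfusion}_perfused",
        theta=theta,
    )


def save_scenario(scenario: Scenario, directory: str | Path, stem: str = "scenario") -> tuple[Path, Path]:
    """Write the N0/p volume pair as NIfTI files; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n0_path = directory / f"{stem}_N0.nii.gz"
    p_path = directory / f"{stem}_p.nii.gz"
    write_volume(scenario.N0, n0_path)
    write_volume(scenario.p, p_path)
    return n0_path, p_path


def load_scenario(
    n0_path: str | Path, p_path: str | Path, label: str = "custom", theta: float = THETA
) -> Scenario:
    n0 = read_volume(n0_path)
    p = read_volume(p_path)
    return Scenario(grid=n0.grid, N0=n0, p=p, label=label, theta=theta)
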