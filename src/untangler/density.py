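"""Real-space density synthesis and model-vs-target misfit.

Atoms are single isotropic Gaussians with amplitude occupancy·Z and
variance (B + B_base)/(8π²) — the simplest atom shape that preserves the
occupancy and B-factor semantics the untangling maneuvers rely on.  The
density of an ensemble is the occupancy-weighted sum of its conformers'
densities, so any relabeling of conformer letters leaves the map untouched:
that symmetry is the formal reason density misfit barrier traps exist.

The misfit used as the refinement target is a normalized sum of squared
voxel differences (a real-space stand-in for reciprocal-space residuals;
no structure factors, bulk solvent or free sets here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import EnsembleModel

B_BASE = 2.0         # Å², added to every atom's B before widthing
GAUSS_CUTOFF = 6.0   # evaluation radius in units of the atom's sigma
GRID_MARGIN = 3.0    # Å, atoms must stay inside grid bounds plus this

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15}


@dataclass
class DensityGrid:
    """Isotropically spaced 3-D scalar field."""

    origin: np.ndarray   # (3,) Å, position of voxel (0,0,0)
    spacing: float       # Å per voxel
    values: np.ndarray   # (nx, ny, nz)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if min(self.values.shape) < 8:
            raise ValueError("grid must be at least 8 voxels per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def sigma_level(self) -> float:
        return float(self.values.std())

    def copy_empty(self) -> "DensityGrid":
        return DensityGrid(self.origin.copy(), self.spacing,
                           np.zeros_like(self.values))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.spacing * np.arange(self.shape[i])
                     for i in range(3))

    def voxel_volume(self) -> float:
        return self.spacing ** 3


def grid_around(model: EnsembleModel, spacing: float = 0.3,
                pad: float = 4.0) -> DensityGrid:
    """An empty grid enclosing the model with ``pad`` Å on every side."""
    xyz = model.coords()
    lo = xyz.min(axis=0) - pad
    hi = xyz.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 8)
    return DensityGrid(lo, spacing, np.zeros(tuple(shape)))


def atom_gaussian_params(model: EnsembleModel,
                         b_base: float = B_BASE) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Gaussian amplitude (occ·Z) and variance ((B+B_base)/8π²)."""
    amps = np.array([s.occupancy * ATOMIC_NUMBER.get(s.element, 6)
                     for s in model.atoms], dtype=float)
    var = np.array([(s.b_factor + b_base) / (8.0 * np.pi ** 2)
                    for s in model.atoms], dtype=float)
    return amps, var


def _check_bounds(grid: DensityGrid, positions: np.ndarray) -> None:
    lo = grid.origin - GRID_MARGIN
    hi = grid.origin + grid.spacing * (np.array(grid.shape) - 1) + GRID_MARGIN
    if np.any(positions < lo) or np.any(positions > hi):
        raise ValueError("atom outside grid bounds plus margin")


def _patch(grid: DensityGrid, pos: np.ndarray, radius: float):
    """Index slices and axis offsets of the voxel patch around ``pos``."""
    slices, axes = [], []
    for k in range(3):
        lo = int(np.floor((pos[k] - radius - grid.origin[k]) / grid.spacing))
        hi = int(np.ceil((pos[k] + radius - grid.origin[k]) / grid.spacing))
        lo = max(lo, 0)
        hi = min(hi, grid.shape[k] - 1)
        if hi < lo:
            return None
        slices.append(slice(lo, hi + 1))
        axes.append(grid.origin[k] + grid.spacing * np.arange(lo, hi + 1)
                    - pos[k])
    return tuple(slices), axes


def synthesize_density(model: EnsembleModel, grid: DensityGrid,
                       b_base: float = B_BASE) -> DensityGrid:
    """Occupancy-weighted Gaussian density of all atom sites on ``grid``."""
    positions = model.coords()
    _check_bounds(grid, positions)
    amps, var = atom_gaussian_params(model, b_base)
    out = grid.copy_empty()
    _add_gaussians(out, positions, amps, var)
    return out


def _add_gaussians(grid: DensityGrid, positions, amps, var) -> None:
    vals = grid.values
    for pos, amp, v in zip(positions, amps, var):
        sig = np.sqrt(v)
        res = _patch(grid, pos, GAUSS_CUTOFF * sig)
        if res is None:
            continue
        slc, (dx, dy, dz) = res
        norm = amp / (2.0 * np.pi * v) ** 1.5
        gx = np.exp(-dx ** 2 / (2 * v))
        gy = np.exp(-dy ** 2 / (2 * v))
        gz = np.exp(-dz ** 2 / (2 * v))
        vals[slc] += norm * gx[:, None, None] * gy[None, :, None] \
            * gz[None, None, :]


def density_misfit(model: EnsembleModel, target: DensityGrid,
                   b_base: float = B_BASE,
                   positions: np.ndarray | None = None,
                   params: tuple[np.ndarray, np.ndarray] | None = None,
                   ) -> tuple[float, np.ndarray]:
    """Normalized squared-difference misfit and its coordinate gradient.

    E_dens = Σ_v (ρ_model − ρ_target)² / Σ_v ρ_target², zero iff the model
    density reproduces the target everywhere.  The gradient is analytic.
    """
    if positions is None:
        positions = model.coords()
    if params is None:
        params = atom_gaussian_params(model, b_base)
    amps, var = params
    norm = float(np.sum(target.values ** 2))
    if norm <= 0:
        raise ValueError("target grid is identically zero")
    mod = target.copy_empty()
    _add_gaussians(mod, positions, amps, var)
    diff = mod.values - target.values
    e = float(np.sum(diff ** 2)) / norm
    grad = np.zeros_like(positions)
    for i, (pos, amp, v) in enumerate(zip(positions, amps, var)):
        sig = np.sqrt(v)
        res = _patch(mod, pos, GAUSS_CUTOFF * sig)
        if res is None:
            continue
        slc, (dx, dy, dz) = res
        gauss = (amp / (2.0 * np.pi * v) ** 1.5) \
            * np.exp(-dx ** 2 / (2 * v))[:, None, None] \
            * np.exp(-dy ** 2 / (2 * v))[None, :, None] \
            * np.exp(-dz ** 2 / (2 * v))[None, None, :]
        w = diff[slc] * gauss
        # dρ/dx0 = ρ_atom · (x_v − x0)/v ; chain rule through Σ diff²
        grad[i, 0] = np.sum(w * dx[:, None, None]) / v
        grad[i, 1] = np.sum(w * dy[None, :, None]) / v
        grad[i, 2] = np.sum(w * dz[None, None, :]) / v
    grad *= 2.0 / norm
    return e, grad


def difference_map(model: EnsembleModel, target: DensityGrid,
                   b_base: float = B_BASE, peak_threshold: float = 3.0,
                   ) -> tuple[DensityGrid, list[dict]]:
    """Target-minus-model map in units of its own standard deviation.

    A deleted atom therefore shows as a positive peak.  Peaks are local
    extrema of |difference| above ``peak_threshold`` sigmas, sorted by
    magnitude.
    """
    mod = synthesize_density(model, target, b_base=b_base)
    diff = target.values - mod.values
    sd = diff.std()
    if sd <= 0:
        sd = 1.0
    diff_sigma = diff / sd
    absd = np.abs(diff_sigma)
    local_max = ndimage.maximum_filter(absd, size=3) == absd
    mask = local_max & (absd >= peak_threshold)
    peaks = []
    for ijk in np.argwhere(mask):
        pos = target.origin + target.spacing * ijk
        peaks.append({"position": pos.tolist(),
                      "height_sigma": float(diff_sigma[tuple(ijk)])})
    peaks.sort(key=lambda p: -abs(p["height_sigma"]))
    grid = DensityGrid(target.origin.copy(), target.spacing, diff_sigma)
    return grid, peaks


def peaks_to_json(peaks: list[dict]) -> str:
    return json.dumps(peaks)


# ------------------------------------------------------------------ MRC I/O

def write_ccp4(grid: DensityGrid, path) -> None:
    """Write the grid as a CCP4/MRC map (orthogonal P1 cell, MRC origin)."""
    import gemmi

    g = gemmi.FloatGrid(*grid.shape)
    g.spacegroup = gemmi.SpaceGroup("P1")
    g.set_unit_cell(gemmi.UnitCell(*(grid.spacing * np.array(grid.shape)),
                                   90, 90, 90))
    np.asarray(g.array)[:] = grid.values
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for k, word in enumerate((50, 51, 52)):
        m.set_header_float(word, float(grid.origin[k]))
    m.write_ccp4_map(str(path))


def read_ccp4(path) -> DensityGrid:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid.array, dtype=float)
    cell = m.grid.unit_cell
    spacing = cell.a / values.shape[0]
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    return DensityGrid(origin, spacing, values)
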