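"""Local real-space refinement: density misfit vs geometry, fixed letters.

Minimizes T = wx·E_dens + Σ E_geom + Σ E_LJ over all site coordinates with
conformer assignments frozen, via L-BFGS with analytic gradients.  ``wx``
plays the role of the density-vs-geometry weight that refinement programs
expose (the knob the weight-snap maneuver manipulates).  B factors and
occupancies are never refined.

The weight-snap schedule runs three refinements with wx scaled by a very
high, then a very low, then the unit factor; the temporary dominance of one
term can roll the model through a density misfit barrier that the balanced
weight cannot cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import geometry
from .density import DensityGrid, atom_gaussian_params, density_misfit
from .model import EnsembleModel
from .restraints import RestraintSet, build_restraints
from .wescore import we_score

#: default density-term weight; calibrated once against the synthetic
#: fixtures so that planted swaps stay trapped under plain refinement
DEFAULT_WX = 3.0e5


@dataclass
class RefineConfig:
    wx: float = DEFAULT_WX
    max_iter: int = 120
    tol: float = 1e-9          # relative decrease of T at convergence
    restrained_sites: list[tuple[int, np.ndarray, float]] = field(
        default_factory=list)  # (site_id, anchor position, force constant)
    seed: int = 0
    snap_factors: tuple[float, float, float] = (100.0, 0.01, 1.0)

    def __post_init__(self):
        if self.wx <= 0:
            raise ValueError("wx must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def with_(self, **kw) -> "RefineConfig":
        d = dict(wx=self.wx, max_iter=self.max_iter, tol=self.tol,
                 restrained_sites=list(self.restrained_sites),
                 seed=self.seed, snap_factors=self.snap_factors)
        d.update(kw)
        return RefineConfig(**d)


def total_energy_grad(x: np.ndarray, rset: RestraintSet,
                      target: DensityGrid | None, wx: float,
                      params, anchors) -> tuple[float, np.ndarray]:
    """T = wx·E_dens + Σ E_geom + Σ E_LJ (+ harmonic anchors), with gradient."""
    grad = np.zeros_like(x)
    total = 0.0
    for cat in rset.bonded_categories:
        idx, v0, sigma, per = rset.compiled(cat)
        kind = idx.shape[1]
        if kind == 2:
            total += geometry.bond_energy_grad(x, idx, v0, sigma, grad)
        elif kind == 3:
            total += geometry.angle_energy_grad(x, idx, v0, sigma, grad)
        else:
            total += geometry.torsion_energy_grad(x, idx, v0, sigma, per, grad)
    if len(rset.nonbond_idx):
        total += geometry.lj_energy_grad(x, rset.nonbond_idx,
                                         rset.nonbond_r0, grad)
    if target is not None and wx > 0:
        e_dens, g_dens = density_misfit(None, target, positions=x,
                                        params=params)
        total += wx * e_dens
        grad += wx * g_dens
    for site_id, anchor, k in anchors:
        d = x[site_id] - anchor
        total += k * float(d @ d)
        grad[site_id] += 2.0 * k * d
    return total, grad


def local_refine(model: EnsembleModel, target: DensityGrid | None,
                 config: RefineConfig | None = None,
                 rset: RestraintSet | None = None,
                 ) -> tuple[EnsembleModel, dict]:
    """Deterministic local minimization of the total energy.

    Returns the refined model and an info dict with the per-iteration
    energy trajectory (non-increasing across accepted iterations) and the
    start/end energies.
    """
    config = config or RefineConfig()
    if rset is None:
        rset = build_restraints(model)
    params = atom_gaussian_params(model) if target is not None else None
    anchors = [(sid, np.asarray(pos, dtype=float), float(k))
               for sid, pos, k in config.restrained_sites]
    x0 = model.coords()
    if not np.isfinite(x0).all():
        bad = int(np.argwhere(~np.isfinite(x0).all(axis=1))[0][0])
        raise ValueError(f"non-finite starting coordinates at site {bad} "
                         f"({model.atoms[bad].atom_key})")

    def fun(flat):
        x = flat.reshape(-1, 3)
        e, g = total_energy_grad(x, rset, target, config.wx, params, anchors)
        return e, g.ravel()

    e0, _ = fun(x0.ravel())
    if not np.isfinite(e0):
        _diagnose_nonfinite(x0, rset, target, config.wx, params)
    trajectory = [e0]

    def cb(flat):
        e, _ = fun(flat)
        trajectory.append(e)

    res = optimize.minimize(
        fun, x0.ravel(), jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": config.max_iter, "ftol": config.tol,
                 "gtol": 1e-10, "maxcor": 20})
    out = model.copy()
    out.set_coords(res.x.reshape(-1, 3))
    info = {"trajectory": trajectory, "e_start": e0, "e_end": float(res.fun),
            "n_iter": int(res.nit), "converged": bool(res.success)}
    return out, info


def _diagnose_nonfinite(x, rset, target, wx, params):
    devs = rset.category_deviate_arrays(x)
    for cat, d in devs.items():
        if d.size and not np.all(np.isfinite(d)):
            raise ValueError(f"non-finite starting energy in category {cat}")
    if len(rset.nonbond_idx) and not np.all(np.isfinite(rset.lj_energies(x))):
        raise ValueError("non-finite starting Lennard-Jones energy")
    if target is not None:
        e, _ = density_misfit(None, target, positions=x, params=params)
        if not np.isfinite(e):
            raise ValueError("non-finite starting density misfit")
    raise ValueError("non-finite starting total energy")


def weight_snap(model: EnsembleModel, target: DensityGrid,
                base: RefineConfig | None = None,
                rset: RestraintSet | None = None,
                ) -> tuple[EnsembleModel, list[float]]:
    """Three-stage wx schedule: very high, very low, then the base weight.

    Returns the final model and the wE after each stage.
    """
    base = base or RefineConfig()
    if rset is None:
        rset = build_restraints(model)
    current = model
    we_traj: list[float] = []
    for factor in base.snap_factors:
        current, _ = local_refine(current, target,
                                  base.with_(wx=base.wx * factor), rset)
        we_traj.append(we_score(current, rset).wE)
    return current, we_traj
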