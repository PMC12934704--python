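"""Vectorized geometric measurements with analytic gradients.

All functions act on an ``(n, 3)`` coordinate array and integer index
arrays, so the refiner can evaluate whole restraint categories in single
numpy passes.  Angles and torsions are measured in degrees; torsion
differences are wrapped to (−180°, 180°].
"""

from __future__ import annotations

import numpy as np

RAD2DEG = 180.0 / np.pi

# sin(theta) below this is treated as colinear / degenerate
_COLINEAR_EPS = 1e-8


def wrap_degrees(delta: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle difference (degrees) into (−180, 180]."""
    return -((-np.asarray(delta) + 180.0) % 360.0 - 180.0)


def bond_lengths(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    d = x[idx[:, 0]] - x[idx[:, 1]]
    return np.linalg.norm(d, axis=1)


def bond_energy_grad(x, idx, v0, sigma, grad=None):
    """Sum of ((r − v0)/σ)² and its gradient accumulated into ``grad``."""
    d = x[idx[:, 0]] - x[idx[:, 1]]
    r = np.linalg.norm(d, axis=1)
    dev = (r - v0) / sigma
    if grad is not None:
        coef = (2.0 * dev / (sigma * np.maximum(r, 1e-12)))[:, None] * d
        np.add.at(grad, idx[:, 0], coef)
        np.add.at(grad, idx[:, 1], -coef)
    return float(np.sum(dev * dev))


def angle_values(x: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Angles i-j-k in degrees plus a validity mask (False = colinear)."""
    u = x[idx[:, 0]] - x[idx[:, 1]]
    v = x[idx[:, 2]] - x[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / np.maximum(nu * nv, 1e-12)
    c = np.clip(c, -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c * c, 0.0))
    return np.degrees(np.arccos(c)), s > _COLINEAR_EPS


def angle_energy_grad(x, idx, v0, sigma, grad=None):
    u = x[idx[:, 0]] - x[idx[:, 1]]
    v = x[idx[:, 2]] - x[idx[:, 1]]
    nu = np.maximum(np.linalg.norm(u, axis=1), 1e-12)
    nv = np.maximum(np.linalg.norm(v, axis=1), 1e-12)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c * c, 0.0))
    ok = s > _COLINEAR_EPS
    theta = np.degrees(np.arccos(c))
    dev = np.where(ok, (theta - v0) / sigma, 0.0)
    if grad is not None:
        ssafe = np.maximum(s, _COLINEAR_EPS)
        # dθ/dxi and dθ/dxk in radians per Å
        gi = (c[:, None] * uh - vh) / (nu * ssafe)[:, None]
        gk = (c[:, None] * vh - uh) / (nv * ssafe)[:, None]
        pref = np.where(ok, 2.0 * dev / sigma, 0.0)[:, None] * RAD2DEG
        np.add.at(grad, idx[:, 0], pref * gi)
        np.add.at(grad, idx[:, 2], pref * gk)
        np.add.at(grad, idx[:, 1], -pref * (gi + gk))
    return float(np.sum(dev * dev))


def torsion_values(x: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dihedral angles i-j-k-l in degrees plus validity mask."""
    b1 = x[idx[:, 1]] - x[idx[:, 0]]
    b2 = x[idx[:, 2]] - x[idx[:, 1]]
    b3 = x[idx[:, 3]] - x[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m = np.cross(n1, b2 / np.maximum(nb2, 1e-12)[:, None])
    phi = np.degrees(np.arctan2(np.einsum("ij,ij->i", m, n2),
                                np.einsum("ij,ij->i", n1, n2)))
    ok = (np.linalg.norm(n1, axis=1) > _COLINEAR_EPS) \
        & (np.linalg.norm(n2, axis=1) > _COLINEAR_EPS)
    return phi, ok


def torsion_energy_grad(x, idx, v0, sigma, periodicity, grad=None):
    phi, ok = torsion_values(x, idx)
    delta = wrap_degrees(phi - v0)
    per = np.asarray(periodicity, dtype=float)
    has_per = per > 1
    if np.any(has_per):
        width = np.where(has_per, 360.0 / np.maximum(per, 1.0), 360.0)
        delta = np.where(
            has_per, (delta + width / 2.0) % width - width / 2.0, delta)
    dev = np.where(ok, delta / sigma, 0.0)
    if grad is not None:
        b1 = x[idx[:, 1]] - x[idx[:, 0]]
        b2 = x[idx[:, 2]] - x[idx[:, 1]]
        b3 = x[idx[:, 3]] - x[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.maximum(np.linalg.norm(b2, axis=1), 1e-12)
        sn1 = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-24)
        sn2 = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-24)
        # dφ/dx in radians per Å (classic rigid-rotation formulas, signed
        # to match the atan2 convention of torsion_values)
        gi = (nb2 / sn1)[:, None] * n1
        gl = -(nb2 / sn2)[:, None] * n2
        c12 = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
        c32 = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
        gj = -(1.0 + c12) * gi + c32 * gl
        gk = c12 * gi - (1.0 + c32) * gl
        pref = np.where(ok, 2.0 * dev / sigma, 0.0)[:, None] * RAD2DEG
        np.add.at(grad, idx[:, 0], pref * gi)
        np.add.at(grad, idx[:, 1], pref * gj)
        np.add.at(grad, idx[:, 2], pref * gk)
        np.add.at(grad, idx[:, 3], pref * gl)
    return float(np.sum(dev * dev))


def lj_pair_energies(x, idx, r0):
    """Normalized 12-6 energy per pair: (r0/r)¹² − 2(r0/r)⁶, minimum −1 at r0."""
    d = x[idx[:, 0]] - x[idx[:, 1]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r <= 0):
        raise ValueError("coincident non-bonded atoms (r = 0)")
    q = (r0 / r) ** 6
    return q * q - 2.0 * q


def lj_energy_grad(x, idx, r0, grad=None):
    """Sum of normalized 12-6 energies over pairs, gradient accumulated."""
    d = x[idx[:, 0]] - x[idx[:, 1]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r <= 0):
        raise ValueError("coincident non-bonded atoms (r = 0)")
    q = (r0 / r) ** 6
    e = q * q - 2.0 * q
    if grad is not None:
        # dE/dr = −12 (q² − q)/r
        coef = (-12.0 * (q * q - q) / (r * r))[:, None] * d
        np.add.at(grad, idx[:, 0], coef)
        np.add.at(grad, idx[:, 1], -coef)
    return float(np.sum(e))
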