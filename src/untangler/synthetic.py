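"""Synthetic tangled two-conformer fixtures with a known ground truth.

The generator builds "bead-peptide" chains (residue ``BEA``: a three-atom
backbone analog N–CA–C plus a one-atom side chain CB) with exactly ideal
library geometry, then splits every atom into two alternate locations
displaced rigidly by ±amplitude/2 along z with occupancy 0.5 each.  Because
the displacement is rigid, both conformers have perfect geometry, while any
mis-assignment of conformer letters creates cognate bonds that straddle the
two displacement sheets — the tangling phenomenon the trap-escape
algorithms must undo.

Motion modes: with two chains, "correlated" (windshield wiper) assigns
letter A to the +z sheet of both chains, "anti-correlated" (jumping jacks)
assigns opposite sheets.  The two modes have identical atom positions and
therefore synthesize identical density; only the ground-truth assignment
differs, which is exactly why density alone cannot distinguish them.

A fixture is only emitted when it is a genuine trap: plain local refinement
of the tangled start must fail to recover the ground-truth assignment and
must leave the wE score strictly above the ground truth's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .density import DensityGrid, density_misfit, grid_around, \
    synthesize_density
from .model import AtomSite, EnsembleModel, SplitGroup, SwapSet, \
    apply_swaps, assignment_string
from .refine import RefineConfig, local_refine
from .restraints import RestraintLibrary, RestraintSet, build_restraints
from .wescore import we_score

_BEAD_ATOMS = ("N", "CA", "C", "CB")
_CHAIN_OFFSET = 7.0  # Å between the two parallel chains (contact, no clash)

#: internal coordinates matching the bundled BEA/link restraint ideals
_IDEALS = dict(b_n_ca=1.47, b_ca_c=1.53, b_ca_cb=1.53, b_c_n=1.33,
               a_n_ca_c=111.0, a_ca_c_n=116.0, a_c_n_ca=122.0,
               a_n_ca_cb=110.0, t_psi=150.0, t_omega=180.0, t_phi=-140.0,
               t_cb=-120.0)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic fixture."""

    n_residues: int = 4            # per chain
    n_chains: int = 1
    mode: str = "correlated"       # or "anti-correlated"
    split_amplitude: float = 1.2   # Å between the two conformer sheets
    tangle_mode: str = "single_swap"  # none|single_swap|random_swaps|block_swap
    swap_fraction: float = 0.3     # random_swaps only
    block_window: int = 2          # block_swap only, residues
    noise_sd: float = 0.01         # density noise, fraction of peak
    seed: int = 0
    b_factor: float = 8.0          # Å², isotropic, all sites
    spacing: float = 0.3           # Å, density grid
    waters: int = 0                # split waters placed off side-chain tips
    water_gap: float = 2.55        # Å, lateral tip-to-water distance

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues per chain")
        if self.split_amplitude <= 0:
            raise ValueError("split amplitude must be positive")
        if self.tangle_mode == "random_swaps" \
                and not 0.0 < self.swap_fraction < 1.0:
            raise ValueError("swap fraction must be in (0,1)")
        if self.mode not in ("correlated", "anti-correlated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "anti-correlated" and self.n_chains < 2:
            raise ValueError("anti-correlated mode needs two chains")


@dataclass
class Fixture:
    """Ground truth, its (noisy) target density, and a tangled start."""

    truth: EnsembleModel
    target: DensityGrid
    tangled: EnsembleModel
    planted: SwapSet
    spec: FixtureSpec
    restraints: RestraintSet
    config: RefineConfig

    def __iter__(self):
        return iter((self.truth, self.target, self.tangled))


# ------------------------------------------------------------- construction

def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: position d with |cd| = bond, ∠bcd, dihedral abcd."""
    ang = np.radians(angle_deg)
    tor = -np.radians(torsion_deg)  # sign matches geometry.torsion_values
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_bead_chain(n_residues: int) -> dict[str, np.ndarray]:
    """Single-conformer bead chain with exactly ideal internal geometry."""
    p = _IDEALS
    coords: dict[tuple[int, str], np.ndarray] = {}
    n1 = np.zeros(3)
    ca1 = np.array([p["b_n_ca"], 0.0, 0.0])
    ang = np.radians(180.0 - p["a_n_ca_c"])
    c1 = ca1 + p["b_ca_c"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords[(1, "N")], coords[(1, "CA")], coords[(1, "C")] = n1, ca1, c1
    for i in range(2, n_residues + 1):
        pn, pca, pc = (coords[(i - 1, k)] for k in ("N", "CA", "C"))
        n = _place(pn, pca, pc, p["b_c_n"], p["a_ca_c_n"], p["t_psi"])
        ca = _place(pca, pc, n, p["b_n_ca"], p["a_c_n_ca"], p["t_omega"])
        c = _place(pc, n, ca, p["b_ca_c"], p["a_n_ca_c"], p["t_phi"])
        coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")] = n, ca, c
    for i in range(1, n_residues + 1):
        coords[(i, "CB")] = _place(coords[(i, "C")], coords[(i, "N")],
                                   coords[(i, "CA")], p["b_ca_cb"],
                                   p["a_n_ca_cb"], p["t_cb"])
    return coords


def _ground_truth_model(spec: FixtureSpec) -> EnsembleModel:
    half = spec.split_amplitude / 2.0
    atoms: list[AtomSite] = []
    base = ideal_bead_chain(spec.n_residues)
    for ichain in range(spec.n_chains):
        chain_id = "XY"[ichain]
        offset = np.array([0.0, _CHAIN_OFFSET * ichain, 0.0])
        # anti-correlated: letter A rides the −z sheet on the second chain
        flip = (spec.mode == "anti-correlated" and ichain == 1)
        for i in range(1, spec.n_residues + 1):
            rkey = (chain_id, i, "", "BEA")
            for name in _BEAD_ATOMS:
                pos = base[(i, name)] + offset
                for letter, sign in (("A", +1.0), ("B", -1.0)):
                    s = -sign if flip else sign
                    atoms.append(AtomSite(
                        site_id=0, element="C" if name.startswith("C") else "N",
                        atom_name=name, residue_key=rkey, altloc=letter,
                        occupancy=0.5, b_factor=spec.b_factor,
                        position=pos + np.array([0.0, 0.0, s * half])))
    # split waters off interior side-chain tips of the first chain, paired
    # anti-sheet (water A rides −z while protein A rides +z) so that only a
    # mis-assigned water clashes with its cognate side chain
    for iw in range(spec.waters):
        ires = 2 + iw
        if ires >= spec.n_residues + 1:
            break
        p_cb = base[(ires, "CB")]
        p_ca = base[(ires, "CA")]
        u = p_cb - p_ca
        u[2] = 0.0
        u /= np.linalg.norm(u)
        wpos = p_cb + spec.water_gap * u
        rkey = ("W", iw + 1, "", "HOH")
        for letter, sign in (("A", -1.0), ("B", +1.0)):
            atoms.append(AtomSite(
                site_id=0, element="O", atom_name="O", residue_key=rkey,
                altloc=letter, occupancy=0.5, b_factor=spec.b_factor,
                position=wpos + np.array([0.0, 0.0, sign * half])))
    return EnsembleModel(atoms)


def _planted_swaps(truth: EnsembleModel, spec: FixtureSpec,
                   rng: np.random.Generator) -> SwapSet:
    groups = sorted(truth.split_groups)
    if spec.tangle_mode == "none":
        return SwapSet()
    if spec.tangle_mode == "single_swap":
        # a side-chain bead away from the termini, where strain is sharpest
        cbs = [k for k in groups
               if k[1] == "CB" and 1 < k[0][1] < spec.n_residues]
        pool = cbs or [k for k in groups if k[1] == "CB"]
        return SwapSet.exchange([pool[rng.integers(len(pool))]])
    if spec.tangle_mode == "random_swaps":
        picked = [k for k in groups if rng.random() < spec.swap_fraction]
        if not picked:
            picked = [groups[rng.integers(len(groups))]]
        return SwapSet.exchange(picked)
    if spec.tangle_mode == "water_swap":
        waters = [k for k in groups if k[0][3] == "HOH"]
        if not waters:
            raise ValueError("water_swap needs waters in the spec")
        return SwapSet.exchange([waters[rng.integers(len(waters))]])
    if spec.tangle_mode == "block_swap":
        w = min(spec.block_window, spec.n_residues - 1)
        chain = "XY"[int(rng.integers(spec.n_chains))]
        start = int(rng.integers(1, spec.n_residues - w + 1))
        keys = [k for k in groups
                if k[0][0] == chain and start <= k[0][1] < start + w]
        return SwapSet.exchange(keys)
    raise ValueError(f"unknown tangle mode {spec.tangle_mode!r}")


def make_toy_ensemble(spec: FixtureSpec,
                      library: RestraintLibrary | None = None,
                      config: RefineConfig | None = None,
                      max_retries: int = 3) -> Fixture:
    """Generate (ground truth, target density, tangled start).

    The ground truth is gated on clean geometry (all bonded deviates within
    1σ, no Lennard-Jones pair above +0.5); the tangled model is gated on
    being a genuine trap (plain local refinement neither recovers the
    ground-truth assignment nor reaches its wE).
    """
    config = config or RefineConfig()
    truth = _ground_truth_model(spec)
    rset = build_restraints(truth, library)
    x = truth.coords()
    devs = rset.category_deviate_arrays(x)
    worst = max((float(d.max()) for c, d in devs.items()
                 if d.size and c != "clash"), default=0.0)
    if worst > 1.0:
        raise RuntimeError(f"ground truth has a {worst:.2f}σ bonded deviate")
    lj = rset.lj_energies(x)
    if lj.size and float(lj.max()) > 0.5:
        raise RuntimeError("ground truth has a strained non-bond contact")

    grid = grid_around(truth, spacing=spec.spacing)
    target = synthesize_density(truth, grid)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        peak = float(target.values.max())
        target.values = target.values + rng.normal(
            0.0, spec.noise_sd * peak, size=target.shape)

    we_truth = we_score(truth, rset).wE
    last_err = "no attempt"
    for _attempt in range(max_retries):
        swaps = _planted_swaps(truth, spec, rng)
        tangled0 = apply_swaps(truth, swaps)
        # cognate restraint instances follow the letters, so rebuild
        rset_tangled = build_restraints(tangled0, library)
        tangled, _info = local_refine(tangled0, target, config, rset_tangled)
        if spec.tangle_mode == "none":
            return Fixture(truth, target, tangled, swaps, spec, rset, config)
        we_tangled = we_score(tangled, rset_tangled).wE
        match = assignment_string(tangled, truth).percent_match
        if we_tangled > we_truth and match < 100.0:
            return Fixture(truth, target, tangled, swaps, spec, rset, config)
        last_err = (f"refined tangled model escaped the trap "
                    f"(wE {we_tangled:.3f} vs truth {we_truth:.3f}, "
                    f"match {match:.0f}%)")
    raise RuntimeError(f"could not build a genuine trap: {last_err}")


# ----------------------------------------------------------- barrier profile

def barrier_profile(model: EnsembleModel, group: SplitGroup,
                    target: DensityGrid, n_steps: int = 21,
                    rset: RestraintSet | None = None) -> pd.DataFrame:
    """Energy profile of the altloc exchange path of one split group.

    Both members are interpolated linearly through each other (λ = 0 the
    current assignment, 0.5 coincident, 1 fully exchanged) with everything
    else frozen; returns density misfit and geometry energy at each λ.
    The density misfit is symmetric in λ → 1 − λ and maximal near the
    midpoint — the density misfit barrier.
    """
    if rset is None:
        rset = build_restraints(model)
    letters = group.letters
    if len(letters) != 2:
        raise ValueError("barrier profile needs a 2-member group")
    sa, sb = (group.members[letter] for letter in letters)
    xa, xb = sa.position.copy(), sb.position.copy()
    from .density import atom_gaussian_params
    params = atom_gaussian_params(model)
    x = model.coords()
    rows = []
    for lam in np.linspace(0.0, 1.0, n_steps):
        x[sa.site_id] = (1 - lam) * xa + lam * xb
        x[sb.site_id] = (1 - lam) * xb + lam * xa
        e_dens, _ = density_misfit(None, target, positions=x, params=params)
        devs = rset.category_deviate_arrays(x)
        e_geom = sum(float(np.sum(d * d)) for c, d in devs.items()
                     if c != "clash")
        if len(rset.nonbond_idx):
            e_geom += float(np.sum(rset.lj_energies(x)))
        rows.append({"lam": float(lam), "e_dens": e_dens, "e_geom": e_geom})
    return pd.DataFrame(rows)
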