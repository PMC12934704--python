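"""Statistical geometry restraints and per-category energies.

Each restraint term scores a squared sigma-normalized deviation from a
library ideal: ``E = ((v − v0)/σ)²``.  Terms are instantiated per conformer
letter (cognate instances only — a bond is evaluated between sites that
share a letter, or involve an unsplit atom).  Non-bonded interactions use a
normalized 12-6 Lennard-Jones form whose minimum is exactly −1 at the
optimal separation, plus a harsher "clash" deviate for overlaps past the
0.4 Å margin, mirroring how validation separates clash counts from packing
quality.

The 11 validation categories are fixed by name; libraries and fixtures may
leave any of them empty (an empty category contributes nothing to the wE
score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import geometry
from .model import BLANK, AtomKey, EnsembleModel

CATEGORIES = ("bond", "angle", "torsion", "planarity", "chirality", "omega",
              "cbeta", "rotamer", "ramachandran", "clash", "nonbond")

#: categories evaluated as generic distance / angle / dihedral terms
_ARITY_KIND = {2: "bond", 3: "angle", 4: "torsion"}

NONBOND_CUTOFF = 5.0   # Å, pair-list cutoff on build coordinates
EXCLUDE_BONDED_DEPTH = 3  # exclude 1-2, 1-3 and 1-4 pairs
CLASH_MARGIN = 0.4     # Å of vdW overlap before a pair counts as a clash
CLASH_SCALE = 0.1      # Å of overlap per sigma of clash deviate


@dataclass(frozen=True)
class RestraintTerm:
    """One geometry term over an ordered tuple of atom sites."""

    category: str
    site_ids: tuple[int, ...]
    v0: float
    sigma: float
    periodicity: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


# ------------------------------------------------------------------ library

@dataclass
class LibraryRecord:
    category: str
    atom_names: tuple[str, ...]  # "+X" refers to the next residue
    v0: float
    sigma: float
    periodicity: int = 0


@dataclass
class RestraintLibrary:
    """Plain-text restraint dictionary: per-residue templates + link terms."""

    templates: dict[str, list[LibraryRecord]] = field(default_factory=dict)
    links: list[LibraryRecord] = field(default_factory=list)
    vdw_radii: dict[str, float] = field(default_factory=dict)

    @staticmethod
    def from_text(text: str) -> "RestraintLibrary":
        lib = RestraintLibrary()
        current: list[LibraryRecord] | None = None
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if tok[0] == "template":
                current = lib.templates.setdefault(tok[1], [])
            elif tok[0] == "link":
                current = lib.links
            elif tok[0] == "vdw":
                lib.vdw_radii[tok[1]] = float(tok[2])
            else:
                category = tok[0]
                if category not in CATEGORIES:
                    raise ValueError(f"unknown restraint category: {line!r}")
                arity = {"bond": 2, "angle": 3}.get(category, 4)
                if category in ("torsion", "omega"):
                    arity = 4
                names = tuple(tok[1:1 + arity])
                vals = tok[1 + arity:]
                v0, sigma = float(vals[0]), float(vals[1])
                per = int(vals[2]) if len(vals) > 2 else 0
                if current is None:
                    raise ValueError("record before any template/link header")
                current.append(LibraryRecord(category, names, v0, sigma, per))
        return lib

    @staticmethod
    def load(path=None) -> "RestraintLibrary":
        """Load a library file; default is the bundled bead/amino-acid set."""
        if path is None:
            text = resources.files("untangler.data").joinpath(
                "restraints.txt").read_text()
        else:
            text = Path(path).read_text()
        return RestraintLibrary.from_text(text)


# -------------------------------------------------------------- restraint set

class RestraintSet:
    """Compiled geometry terms + non-bond pair list for one model."""

    def __init__(self, model: EnsembleModel):
        self.n_sites = len(model.atoms)
        self.terms: dict[str, list[RestraintTerm]] = {c: [] for c in CATEGORIES}
        self.nonbond_idx = np.zeros((0, 2), dtype=int)
        self.nonbond_r0 = np.zeros(0)
        self.nonbond_rsum = np.zeros(0)
        self._compiled: dict[str, tuple] = {}

    # -- compilation ------------------------------------------------------
    def compile(self) -> None:
        self._compiled = {}
        for cat, terms in self.terms.items():
            if not terms:
                continue
            idx = np.array([t.site_ids for t in terms], dtype=int)
            v0 = np.array([t.v0 for t in terms])
            sigma = np.array([t.sigma for t in terms])
            per = np.array([t.periodicity for t in terms], dtype=int)
            self._compiled[cat] = (idx, v0, sigma, per)

    def compiled(self, cat: str):
        return self._compiled.get(cat)

    @property
    def bonded_categories(self) -> list[str]:
        return [c for c in CATEGORIES
                if c not in ("clash", "nonbond") and self.terms[c]]

    # -- evaluation -------------------------------------------------------
    def category_deviate_arrays(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Absolute sigma-deviates per category, deterministic term order."""
        out: dict[str, np.ndarray] = {}
        for cat in CATEGORIES:
            comp = self._compiled.get(cat)
            if comp is None:
                if cat == "clash":
                    out[cat] = self._clash_deviates(x)
                continue
            idx, v0, sigma, per = comp
            kind = _ARITY_KIND[idx.shape[1]]
            if kind == "bond":
                v = geometry.bond_lengths(x, idx)
                dev = np.abs((v - v0) / sigma)
            elif kind == "angle":
                v, ok = geometry.angle_values(x, idx)
                dev = np.abs((v - v0) / sigma)
                if not ok.all():
                    warnings.warn(f"{(~ok).sum()} degenerate {cat} term(s) "
                                  "excluded (colinear atoms)", stacklevel=2)
                    dev = dev[ok]
            else:
                v, ok = geometry.torsion_values(x, idx)
                delta = geometry.wrap_degrees(v - v0)
                hasper = per > 1
                if hasper.any():
                    width = np.where(hasper, 360.0 / np.maximum(per, 1), 360.0)
                    delta = np.where(hasper,
                                     (delta + width / 2) % width - width / 2,
                                     delta)
                dev = np.abs(delta / sigma)
                if not ok.all():
                    warnings.warn(f"{(~ok).sum()} degenerate {cat} term(s) "
                                  "excluded (colinear atoms)", stacklevel=2)
                    dev = dev[ok]
            out[cat] = dev
        if "clash" not in out:
            out["clash"] = self._clash_deviates(x)
        return out

    def _clash_deviates(self, x: np.ndarray) -> np.ndarray:
        if len(self.nonbond_idx) == 0:
            return np.zeros(0)
        r = geometry.bond_lengths(x, self.nonbond_idx)
        overlap = self.nonbond_rsum - r
        return np.where(overlap > CLASH_MARGIN, overlap / CLASH_SCALE, 0.0)

    def lj_energies(self, x: np.ndarray) -> np.ndarray:
        if len(self.nonbond_idx) == 0:
            return np.zeros(0)
        return geometry.lj_pair_energies(x, self.nonbond_idx, self.nonbond_r0)

    def mean_lj(self, x: np.ndarray) -> float:
        e = self.lj_energies(x)
        return float(e.mean()) if len(e) else 0.0

    def per_atom_energies(self, x: np.ndarray) -> np.ndarray:
        """Per-site energy: full E of every term containing the site, plus
        the site's Lennard-Jones pair energies.

        Each term's energy is counted once for every member atom (not
        apportioned), so summing over atoms overcounts each term by its
        arity — the intended behaviour for atom-by-atom rectification.
        """
        acc = np.zeros(self.n_sites)
        for cat in self.bonded_categories:
            idx, v0, sigma, per = self._compiled[cat]
            kind = _ARITY_KIND[idx.shape[1]]
            if kind == "bond":
                v = geometry.bond_lengths(x, idx)
                e = ((v - v0) / sigma) ** 2
            elif kind == "angle":
                v, ok = geometry.angle_values(x, idx)
                e = np.where(ok, ((v - v0) / sigma) ** 2, 0.0)
            else:
                v, ok = geometry.torsion_values(x, idx)
                delta = geometry.wrap_degrees(v - v0)
                hasper = per > 1
                if hasper.any():
                    width = np.where(hasper, 360.0 / np.maximum(per, 1), 360.0)
                    delta = np.where(hasper,
                                     (delta + width / 2) % width - width / 2,
                                     delta)
                e = np.where(ok, (delta / sigma) ** 2, 0.0)
            for col in range(idx.shape[1]):
                np.add.at(acc, idx[:, col], e)
        if len(self.nonbond_idx):
            elj = self.lj_energies(x)
            np.add.at(acc, self.nonbond_idx[:, 0], elj)
            np.add.at(acc, self.nonbond_idx[:, 1], elj)
        return acc


# ------------------------------------------------------------------ builders

def build_restraints(model: EnsembleModel,
                     library: RestraintLibrary | None = None) -> RestraintSet:
    """Instantiate the library over a model: cognate bonded terms per
    conformer letter plus the conformer-compatible non-bond pair list."""
    if library is None:
        library = RestraintLibrary.load()
    rset = RestraintSet(model)
    residues = _residue_order(model)
    for rkey in residues:
        resname = rkey[3]
        if resname not in library.templates:
            raise ValueError(f"residue {resname!r} missing from restraint "
                             "library")
        for rec in library.templates[resname]:
            _instantiate(model, rset, rec, rkey, None)
    # link records between consecutive peptide-bonded residues
    for prev, nxt in zip(residues, residues[1:]):
        if frozenset(((prev, "C"), (nxt, "N"))) in model.bonds:
            for rec in library.links:
                _instantiate(model, rset, rec, prev, nxt)
    _build_nonbonds(model, rset, library)
    rset.compile()
    return rset


def _residue_order(model: EnsembleModel) -> list:
    order = []
    seen = set()
    for site in model.atoms:
        if site.residue_key not in seen:
            seen.add(site.residue_key)
            order.append(site.residue_key)
    return order


def _instantiate(model, rset, rec, rkey, next_rkey) -> None:
    akeys = []
    for name in rec.atom_names:
        if name.startswith("+"):
            if next_rkey is None:
                return
            akeys.append((next_rkey, name[1:]))
        else:
            akeys.append((rkey, name))
    if any(k not in model.sites_by_atom for k in akeys):
        return
    seen_ids = set()
    for letter in model.conformer_letters:
        try:
            sites = [model.site(k, letter) for k in akeys]
        except KeyError:
            continue
        ids = tuple(s.site_id for s in sites)
        if ids in seen_ids:
            continue  # all-blank instance is letter-independent
        seen_ids.add(ids)
        rset.terms[rec.category].append(RestraintTerm(
            rec.category, ids, rec.v0, rec.sigma, rec.periodicity))


def _bonded_within(model: EnsembleModel, depth: int) -> set[frozenset]:
    """Atom-key pairs within ``depth`` bonds of each other."""
    adj: dict[AtomKey, list[AtomKey]] = {}
    for pair in model.bonds:
        a, b = tuple(pair)
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    close: set[frozenset] = set()
    for start in model.sites_by_atom:
        frontier = {start}
        visited = {start}
        for _ in range(depth):
            nxt = set()
            for u in frontier:
                for v in adj.get(u, ()):
                    if v not in visited:
                        visited.add(v)
                        nxt.add(v)
                        close.add(frozenset((start, v)))
            frontier = nxt
    return close


def _build_nonbonds(model, rset, library) -> None:
    close = _bonded_within(model, EXCLUDE_BONDED_DEPTH)
    radii = library.vdw_radii
    x = model.coords()
    idx, r0, rsum = [], [], []
    n = len(model.atoms)
    for i in range(n):
        si = model.atoms[i]
        for j in range(i + 1, n):
            sj = model.atoms[j]
            if si.atom_key == sj.atom_key:
                continue  # alternates of the same atom never interact
            if si.altloc and sj.altloc and si.altloc != sj.altloc:
                continue  # A↔B pairs excluded: density-symmetric ensemble
            if frozenset((si.atom_key, sj.atom_key)) in close:
                continue
            d = float(np.linalg.norm(x[i] - x[j]))
            if d > NONBOND_CUTOFF:
                continue
            ri = radii.get(si.element, 1.6)
            rj = radii.get(sj.element, 1.6)
            idx.append((i, j))
            r0.append(ri + rj)
            rsum.append(ri + rj)
    rset.nonbond_idx = np.array(idx, dtype=int).reshape(-1, 2)
    rset.nonbond_r0 = np.array(r0)
    rset.nonbond_rsum = np.array(rsum)


# ----------------------------------------------------------- single queries

def term_deviate(term: RestraintTerm, model: EnsembleModel) -> float:
    """Signed sigma-deviate of one term; NaN (with a warning) if degenerate."""
    x = model.coords()
    idx = np.array([term.site_ids], dtype=int)
    kind = _ARITY_KIND[len(term.site_ids)]
    if kind == "bond":
        v = geometry.bond_lengths(x, idx)[0]
        return float((v - term.v0) / term.sigma)
    if kind == "angle":
        v, ok = geometry.angle_values(x, idx)
        if not ok[0]:
            warnings.warn("degenerate angle term (colinear atoms)",
                          stacklevel=2)
            return float("nan")
        return float((v[0] - term.v0) / term.sigma)
    v, ok = geometry.torsion_values(x, idx)
    if not ok[0]:
        warnings.warn("degenerate torsion term (colinear atoms)", stacklevel=2)
        return float("nan")
    delta = float(geometry.wrap_degrees(v[0] - term.v0))
    if term.periodicity > 1:
        width = 360.0 / term.periodicity
        delta = (delta + width / 2) % width - width / 2
    return delta / term.sigma


def lj_energy(x_i: np.ndarray, x_j: np.ndarray, r0: float) -> float:
    """Normalized 12-6 energy of one pair: minimum −1 at r = r0, → 0 at ∞."""
    r = float(np.linalg.norm(np.asarray(x_i) - np.asarray(x_j)))
    if r <= 0:
        raise ValueError("coincident non-bonded atoms (r = 0)")
    q = (r0 / r) ** 6
    return q * q - 2.0 * q


def per_atom_energy(model: EnsembleModel, rset: RestraintSet,
                    site_id: int) -> float:
    return float(rset.per_atom_energies(model.coords())[site_id])


def category_deviates(model: EnsembleModel,
                      rset: RestraintSet) -> dict[str, np.ndarray]:
    return rset.category_deviate_arrays(model.coords())
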