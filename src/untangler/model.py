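"""Multi-conformer model container and conformer-assignment bookkeeping.

The central object is :class:`EnsembleModel`: a flat list of atom sites
(each carrying an altloc letter, blank for unsplit atoms), a covalent bond
graph over *atoms* (letters ignored), and the set of split groups — atoms
represented by two or more alternate locations.  Conformer assignment is the
mapping of each split atom's sites to conformer letters; the untangling
algorithms operate by permuting those letters (:func:`apply_swaps`) while
leaving coordinates, occupancies and B factors untouched.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import templates

# (chain id, residue number, insertion code, residue name)
ResidueKey = tuple[str, int, str, str]
# (residue_key, atom_name)
AtomKey = tuple[ResidueKey, str]

BLANK = ""  # altloc of an unsplit atom

_DISULFIDE_MAX = 2.5  # Å, SG–SG detection cutoff


@dataclass
class AtomSite:
    """One atom site: a single (possibly alternate) location of an atom."""

    site_id: int
    element: str
    atom_name: str
    residue_key: ResidueKey
    altloc: str  # single letter, or "" for unsplit
    occupancy: float
    b_factor: float
    position: np.ndarray  # (3,) Å

    @property
    def atom_key(self) -> AtomKey:
        return (self.residue_key, self.atom_name)

    def copy(self) -> "AtomSite":
        return AtomSite(self.site_id, self.element, self.atom_name,
                        self.residue_key, self.altloc, self.occupancy,
                        self.b_factor, self.position.copy())


@dataclass
class SplitGroup:
    """An atom with alternate locations: conformer letter -> site."""

    atom_key: AtomKey
    members: dict[str, AtomSite]

    @property
    def letters(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


class EnsembleModel:
    """Atom sites + covalent topology + split-group bookkeeping."""

    def __init__(self, atoms: list[AtomSite],
                 conformer_letters: tuple[str, ...] = ("A", "B"),
                 infer_topology: bool = True):
        self.atoms = atoms
        for i, site in enumerate(self.atoms):
            site.site_id = i
        letters_seen = sorted({s.altloc for s in atoms if s.altloc})
        self.conformer_letters = tuple(
            sorted(set(conformer_letters) | set(letters_seen)))
        self._index_sites()
        self.bonds: set[frozenset] = set()
        self.disulfides: set[frozenset] = set()
        if infer_topology:
            self._infer_bonds()
        self._validate()

    # ---------------------------------------------------------------- index
    def _index_sites(self) -> None:
        self.sites_by_atom: dict[AtomKey, list[AtomSite]] = {}
        for site in self.atoms:
            self.sites_by_atom.setdefault(site.atom_key, []).append(site)
        self.split_groups: dict[AtomKey, SplitGroup] = {}
        for akey, sites in self.sites_by_atom.items():
            lettered = {s.altloc: s for s in sites if s.altloc}
            if len(lettered) >= 2:
                self.split_groups[akey] = SplitGroup(akey, lettered)

    def _validate(self) -> None:
        for site in self.atoms:
            if not (0.0 <= site.occupancy <= 1.0):
                raise ValueError(f"occupancy out of [0,1] for {site.atom_key}")
            if site.b_factor <= 0:
                raise ValueError(f"non-positive B factor for {site.atom_key}")
            if site.altloc and site.altloc not in self.conformer_letters:
                raise ValueError(
                    f"altloc {site.altloc!r} not in conformer letters")
        for akey, group in self.split_groups.items():
            total = sum(s.occupancy for s in group.members.values())
            if total > 1.0 + 1e-6:
                warnings.warn(
                    f"occupancies of split group {akey} sum to {total:.3f} > 1",
                    stacklevel=2)

    # ------------------------------------------------------------- topology
    def _infer_bonds(self) -> None:
        """Bonds from residue templates + peptide links + disulfides."""
        residues: list[ResidueKey] = []
        seen: set[ResidueKey] = set()
        atoms_of: dict[ResidueKey, set[str]] = {}
        for site in self.atoms:
            rkey = site.residue_key
            if rkey not in seen:
                seen.add(rkey)
                residues.append(rkey)
            atoms_of.setdefault(rkey, set()).add(site.atom_name)
        for rkey in residues:
            resname = rkey[3]
            if not templates.known_residue(resname):
                raise ValueError(f"no template for residue {resname!r}")
            present = atoms_of[rkey]
            for a, b in templates.RESIDUE_BONDS[resname]:
                if a in present and b in present:
                    self.bonds.add(frozenset(((rkey, a), (rkey, b))))
        # peptide links between consecutive residue numbers in a chain
        for prev, nxt in zip(residues, residues[1:]):
            if prev[0] == nxt[0] and nxt[1] == prev[1] + 1 \
                    and prev[3] != "HOH" and nxt[3] != "HOH":
                c, n = templates.PEPTIDE_LINK
                if c in atoms_of[prev] and n in atoms_of[nxt]:
                    self.bonds.add(frozenset(((prev, c), (nxt, n))))
        # disulfides by SG–SG proximity
        sg_keys = [k for k in self.sites_by_atom
                   if k[1] == "SG" and k[0][3] == "CYS"]
        for i, ka in enumerate(sg_keys):
            for kb in sg_keys[i + 1:]:
                dmin = min(
                    float(np.linalg.norm(sa.position - sb.position))
                    for sa in self.sites_by_atom[ka]
                    for sb in self.sites_by_atom[kb])
                if dmin < _DISULFIDE_MAX:
                    pair = frozenset((ka, kb))
                    self.bonds.add(pair)
                    self.disulfides.add(pair)

    def neighbours(self, atom_key: AtomKey) -> list[AtomKey]:
        out = []
        for pair in self.bonds:
            if atom_key in pair:
                (other,) = pair - {atom_key}
                out.append(other)
        return sorted(out)

    # ---------------------------------------------------------- coordinates
    def coords(self) -> np.ndarray:
        return np.array([s.position for s in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for site, row in zip(self.atoms, xyz):
            site.position = row.copy()

    def site(self, atom_key: AtomKey, letter: str) -> AtomSite:
        """Site of ``atom_key`` for conformer ``letter`` (blank matches any)."""
        blank = None
        for s in self.sites_by_atom[atom_key]:
            if s.altloc == letter:
                return s
            if s.altloc == BLANK:
                blank = s
        if blank is not None:
            return blank
        raise KeyError(f"no site for {atom_key} letter {letter!r}")

    def copy(self) -> "EnsembleModel":
        clone = EnsembleModel.__new__(EnsembleModel)
        clone.atoms = [s.copy() for s in self.atoms]
        clone.conformer_letters = self.conformer_letters
        clone.bonds = set(self.bonds)
        clone.disulfides = set(self.disulfides)
        clone._index_sites()
        return clone


# ---------------------------------------------------------------- swap sets

@dataclass
class SwapSet:
    """A list of conformer-letter permutations applied to split groups."""

    moves: list[tuple[tuple[AtomKey, ...], dict[str, str]]] = field(
        default_factory=list)

    @staticmethod
    def exchange(atom_keys, letters=("A", "B")) -> "SwapSet":
        """Convenience: the two-letter exchange on the given groups."""
        a, b = letters
        perm = {a: b, b: a}
        keys = tuple(atom_keys)
        return SwapSet(moves=[(keys, dict(perm))])

    def to_json(self) -> str:
        return json.dumps([
            {"atoms": [[list(k[0]), k[1]] for k in keys], "perm": perm}
            for keys, perm in self.moves])

    @staticmethod
    def from_json(text: str) -> "SwapSet":
        moves = []
        for rec in json.loads(text):
            keys = tuple(((r[0][0], r[0][1], r[0][2], r[0][3]), r[1])
                         for r in rec["atoms"])
            moves.append((keys, dict(rec["perm"])))
        return SwapSet(moves=moves)


def apply_swaps(model: EnsembleModel, swaps: SwapSet) -> EnsembleModel:
    """Permute conformer letters of split groups; nothing else changes.

    For a 2-letter model, applying the same SwapSet twice restores the
    original assignment (each move is an involution).
    """
    out = model.copy()
    letters = set(out.conformer_letters)
    for keys, perm in swaps.moves:
        if set(perm) != letters or set(perm.values()) != letters:
            raise ValueError(f"permutation {perm} is not a bijection on "
                             f"{sorted(letters)}")
        for akey in keys:
            if akey not in out.split_groups:
                raise ValueError(f"swap requested on unsplit atom {akey}")
            for s in out.sites_by_atom[akey]:
                if s.altloc:
                    s.altloc = perm[s.altloc]
    out._index_sites()
    return out


# --------------------------------------------------------------- downstream

def downstream_atoms(model: EnsembleModel, atom_key: AtomKey) -> set[AtomKey]:
    """The atom plus everything downstream of it in the chain direction.

    Direction convention: increasing residue number along each chain
    (N → C); within a residue main chain before side chain, side-chain
    edges directed outward from CA by bond distance.  Traversal never
    crosses disulfide bonds, and ring-closure edges that do not strictly
    increase the distance from CA are not followed, so rings (His, Phe,
    Tyr, Trp, Pro, His) never cause loops.
    """
    if atom_key not in model.sites_by_atom:
        raise KeyError(f"unknown atom {atom_key}")
    directed = _directed_edges(model)
    seen: set[AtomKey] = set()
    stack = [atom_key]
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(directed.get(cur, ()))
    return seen


def _directed_edges(model: EnsembleModel) -> dict[AtomKey, list[AtomKey]]:
    edges: dict[AtomKey, list[AtomKey]] = {}

    def add(u: AtomKey, v: AtomKey) -> None:
        edges.setdefault(u, []).append(v)

    residues: dict[ResidueKey, set[str]] = {}
    for akey in model.sites_by_atom:
        residues.setdefault(akey[0], set()).add(akey[1])
    main = set(templates.MAIN_CHAIN)
    for rkey, names in residues.items():
        for u, v in (("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")):
            if u in names and v in names:
                add((rkey, u), (rkey, v))
        # side chain: BFS levels from CA over intra-residue bonds that stay
        # off the main chain; only distance-increasing edges are directed
        if "CA" not in names:
            continue
        side = {n for n in names if n not in main}
        dist = {"CA": 0}
        frontier = ["CA"]
        while frontier:
            nxt = []
            for u in frontier:
                for vkey in model.neighbours((rkey, u)):
                    if vkey[0] != rkey or frozenset(((rkey, u), vkey)) \
                            in model.disulfides:
                        continue
                    v = vkey[1]
                    if v not in side or v in dist:
                        continue
                    dist[v] = dist[u] + 1
                    add((rkey, u), (rkey, v))
                    nxt.append(v)
            frontier = nxt
    # peptide links, N→C direction
    for pair in model.bonds:
        (ka, kb) = sorted(pair)
        if ka[0] != kb[0] and ka[1] == "C" and kb[1] == "N" \
                and pair not in model.disulfides:
            add(ka, kb)
        elif ka[0] != kb[0] and ka[1] == "N" and kb[1] == "C":
            add(kb, ka)
    return edges


# --------------------------------------------------------- assignment match

@dataclass
class MatchReport:
    """Per-group conformer-assignment agreement against a reference."""

    per_group: dict[AtomKey, bool]
    percent_match: float
    relabeling: dict[str, str]

    def to_json(self) -> str:
        return json.dumps({
            "percent_match": self.percent_match,
            "relabeling": self.relabeling,
            "groups": [{"atom": [list(k[0]), k[1]], "match": bool(v)}
                       for k, v in sorted(self.per_group.items())],
        })


def assignment_string(model: EnsembleModel,
                      reference: EnsembleModel) -> MatchReport:
    """Compare conformer assignments group-by-group against a reference.

    Because conformer naming is arbitrary (a global A/B exchange is a pure
    relabeling), the global letter relabeling that maximizes the number of
    matching groups is chosen first.  A group matches when, under that
    relabeling, each of its sites is closer to the reference site of the
    same letter than to any other letter's site.
    """
    keys_m = set(model.split_groups)
    keys_r = set(reference.split_groups)
    if keys_m != keys_r:
        only_m = sorted(keys_m - keys_r)
        only_r = sorted(keys_r - keys_m)
        raise ValueError(f"split-group sets differ: model-only {only_m}, "
                         f"reference-only {only_r}")
    letters = sorted(set(model.conformer_letters)
                     & set(reference.conformer_letters))
    import itertools
    best = None
    for perm_letters in itertools.permutations(letters):
        relab = dict(zip(letters, perm_letters))
        per_group = {}
        for akey in sorted(keys_m):
            gm = model.split_groups[akey].members
            gr = reference.split_groups[akey].members
            ok = True
            for lm, sm in gm.items():
                if relab.get(lm, lm) not in gr:
                    ok = False
                    break
                target = gr[relab[lm]].position
                d_own = float(np.linalg.norm(sm.position - target))
                d_other = min(float(np.linalg.norm(sm.position - s.position))
                              for letter, s in gr.items()
                              if letter != relab[lm])
                if d_own > d_other:
                    ok = False
                    break
            per_group[akey] = ok
        n_match = sum(per_group.values())
        if best is None or n_match > best[0]:
            best = (n_match, relab, per_group)
    n_match, relab, per_group = best
    pct = 100.0 * n_match / max(1, len(per_group))
    return MatchReport(per_group=per_group, percent_match=pct,
                       relabeling=relab)


# ------------------------------------------------------------------- PDB IO

def read_multiconf_structure(path) -> EnsembleModel:
    """Read a PDB file into an :class:`EnsembleModel`.

    Every (residue, atom name) with two or more altloc letters becomes a
    split group; bonds are inferred from residue templates plus peptide and
    disulfide links.
    """
    import gemmi

    path = Path(path)
    _prescan_pdb(path)
    st = gemmi.read_pdb(str(path))
    atoms: list[AtomSite] = []
    for chain in st[0]:
        for res in chain:
            rkey = (chain.name, res.seqid.num, res.seqid.icode.strip(),
                    res.name)
            for at in res:
                alt = at.altloc if at.altloc not in ("\0", " ", "") else BLANK
                elem = at.element.name if at.element.name != "X" \
                    else templates.element_of(at.name)
                atoms.append(AtomSite(
                    site_id=len(atoms), element=elem, atom_name=at.name,
                    residue_key=rkey, altloc=alt, occupancy=at.occ,
                    b_factor=at.b_iso,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z])))
    return EnsembleModel(atoms)


def _prescan_pdb(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"{path}: truncated record at line {lineno}")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unparsable coordinates at line {lineno}") from exc


def write_structure(model: EnsembleModel, path) -> None:
    """Write the model as PDB (altloc column 17 carries conformer letters)."""
    import gemmi

    # group sites first: gemmi's add_residue/add_chain copy their argument,
    # so the hierarchy must be assembled bottom-up
    order: list[ResidueKey] = []
    by_res: dict[ResidueKey, list[AtomSite]] = {}
    for site in model.atoms:
        if site.residue_key not in by_res:
            order.append(site.residue_key)
            by_res[site.residue_key] = []
        by_res[site.residue_key].append(site)
    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    chain_order: list[str] = []
    chain_res: dict[str, list[gemmi.Residue]] = {}
    for rkey in order:
        cname, resseq, icode, resname = rkey
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(resseq, icode or " ")
        res.het_flag = "A" if resname in templates.AMINO_ACIDS else "H"
        for site in by_res[rkey]:
            at = gemmi.Atom()
            at.name = site.atom_name
            at.altloc = site.altloc or "\0"
            at.occ = site.occupancy
            at.b_iso = site.b_factor
            at.element = gemmi.Element(site.element)
            at.pos = gemmi.Position(*site.position)
            res.add_atom(at)
        if cname not in chain_res:
            chain_order.append(cname)
            chain_res[cname] = []
        chain_res[cname].append(res)
    for cname in chain_order:
        chain = gemmi.Chain(cname)
        for res in chain_res[cname]:
            chain.add_residue(res)
        st[0].add_chain(chain)
    st.write_pdb(str(path))
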