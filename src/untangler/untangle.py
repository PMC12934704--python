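"""Trap-escape search algorithms over conformer assignments.

All searches share one acceptance rule: a candidate move (a letter
permutation on one or more split groups) is applied, the whole structure is
re-refined, and the move is kept only if the wE score strictly decreases —
otherwise it is reverted.  Scoring with wE rather than the refinement
energy mirrors its role as the cross-program judge of model quality.  Every
algorithm is therefore wE-non-increasing end-to-end, and every attempted
move is recorded in a ledger.

Because cognate restraint instances and the conformer-compatible non-bond
pair list both follow the letters, restraints are rebuilt after every
letter permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .density import DensityGrid, atom_gaussian_params, density_misfit
from .model import AtomKey, EnsembleModel, SwapSet, apply_swaps
from .refine import RefineConfig, local_refine
from .restraints import RestraintLibrary, RestraintSet, build_restraints
from .wescore import we_score

#: a move must beat the current wE by at least this much to be accepted
MIN_DECREASE = 1e-6


@dataclass
class MoveRecord:
    swaps: SwapSet
    wE_before: float
    wE_after: float
    e_dens_before: float
    e_dens_after: float
    accepted: bool
    order: int

    def as_dict(self) -> dict:
        return {"swaps": json.loads(self.swaps.to_json()),
                "wE_before": self.wE_before, "wE_after": self.wE_after,
                "e_dens_before": self.e_dens_before,
                "e_dens_after": self.e_dens_after,
                "accepted": self.accepted, "order": self.order}


@dataclass
class UntangleLedger:
    moves: list[MoveRecord] = field(default_factory=list)
    budget_exhausted: bool = False

    @property
    def n_accepted(self) -> int:
        return sum(m.accepted for m in self.moves)

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps({"budget_exhausted": self.budget_exhausted,
                           "moves": [m.as_dict() for m in self.moves]},
                          indent=indent)


class _State:
    """Current model + matching restraints + cached scores."""

    def __init__(self, model: EnsembleModel, target: DensityGrid,
                 library: RestraintLibrary):
        self.library = library
        self.target = target
        self.set_model(model)

    def set_model(self, model: EnsembleModel) -> None:
        self.model = model
        self.rset = build_restraints(model, self.library)
        x = model.coords()
        self.wE = we_score(model, self.rset, x).wE
        self.e_dens, _ = density_misfit(
            None, self.target, positions=x,
            params=atom_gaussian_params(model))


def _evaluate_move(state: _State, swaps: SwapSet, config: RefineConfig):
    """Swap + re-refine a trial; returns (trial model, rset, wE, E_dens)."""
    trial0 = apply_swaps(state.model, swaps)
    rset = build_restraints(trial0, state.library)
    trial, _ = local_refine(trial0, state.target, config, rset)
    x = trial.coords()
    we_new = we_score(trial, rset, x).wE
    e_dens_new, _ = density_misfit(None, state.target, positions=x,
                                   params=atom_gaussian_params(trial))
    return trial, rset, we_new, e_dens_new


def _steepest_passes(state: _State, candidate_fn, config: RefineConfig,
                     budget: int) -> UntangleLedger:
    """Repeatedly apply the single best wE-decreasing move until none helps.

    Every pass evaluates all candidates from the current state, so the
    search is independent of candidate ordering; the accepted flag marks
    the move actually applied.
    """
    ledger = UntangleLedger()
    while True:
        best = None
        for swaps in candidate_fn(state):
            if len(ledger.moves) >= budget:
                ledger.budget_exhausted = True
                return ledger
            trial, rset, we_new, e_dens_new = _evaluate_move(
                state, swaps, config)
            ledger.moves.append(MoveRecord(
                swaps=swaps, wE_before=state.wE, wE_after=we_new,
                e_dens_before=state.e_dens, e_dens_after=e_dens_new,
                accepted=False, order=len(ledger.moves)))
            if we_new < state.wE - MIN_DECREASE and \
                    (best is None or we_new < best[2]):
                best = (trial, rset, we_new, e_dens_new, len(ledger.moves) - 1)
        if best is None:
            return ledger
        trial, rset, we_new, e_dens_new, imove = best
        ledger.moves[imove].accepted = True
        state.model = trial
        state.rset = rset
        state.wE = we_new
        state.e_dens = e_dens_new


def _ranked_groups(state: _State,
                   candidates: list[AtomKey] | None) -> list[AtomKey]:
    """Candidate groups ordered most-strained first (ties by atom key)."""
    keys = sorted(candidates if candidates is not None
                  else state.model.split_groups)
    per_atom = state.rset.per_atom_energies(state.model.coords())
    def strain(akey):
        sites = state.model.sites_by_atom[akey]
        return max(float(per_atom[s.site_id]) for s in sites)
    return sorted(keys, key=lambda k: (-strain(k), k))


def swap_and_rerefine_scan(model: EnsembleModel, target: DensityGrid,
                           candidates: list[AtomKey] | None = None,
                           arity: int = 1,
                           config: RefineConfig | None = None,
                           library: RestraintLibrary | None = None,
                           move_budget: int | None = None,
                           ) -> tuple[EnsembleModel, UntangleLedger]:
    """Trial conformer swaps of single groups (or pairs) with re-refinement.

    Scans candidates in order of decreasing local strain, iterating passes
    until a fixed point (no accepted move in a full pass) or until the move
    budget is exhausted.
    """
    if arity not in (1, 2):
        raise ValueError("arity must be 1 or 2")
    config = config or RefineConfig()
    library = library or RestraintLibrary.load()
    state = _State(model, target, library)
    budget = move_budget if move_budget is not None else \
        (10_000 if arity == 1 else 500)

    def candidate_fn(st):
        ranked = _ranked_groups(st, candidates)
        if arity == 1:
            pool = [(k,) for k in ranked]
        else:
            pool = [(a, b) for i, a in enumerate(ranked)
                    for b in ranked[i + 1:]]
        return [SwapSet.exchange(keys) for keys in pool]

    ledger = _steepest_passes(state, candidate_fn, config, budget)
    return state.model, ledger


def rectified_sa(model: EnsembleModel, target: DensityGrid,
                 temps: list[float] | None = None,
                 seeds: list[int] | None = None,
                 worse_threshold: float = 4.0,
                 config: RefineConfig | None = None,
                 library: RestraintLibrary | None = None,
                 kick_scale: float = 0.012,
                 ) -> tuple[EnsembleModel, UntangleLedger]:
    """Rectified simulated annealing: kick, re-refine, restore the losers.

    For each (temperature, seed) sweep, coordinates get Gaussian kicks of
    scale kick_scale·√T and the structure is re-refined.  Atoms whose local
    (per-atom) energy worsened by more than ``worse_threshold`` are restored
    to their pre-kick positions and the structure is refined again.  The
    sweep result is kept only if the wE score decreased — the one-way-valve
    rule, so the outcome is never worse than the input.
    """
    temps = temps if temps is not None else [2000.0, 4000.0, 8000.0]
    seeds = seeds if seeds is not None else [0, 1]
    config = config or RefineConfig()
    library = library or RestraintLibrary.load()
    state = _State(model, target, library)
    ledger = UntangleLedger()
    for temp in temps:
        for seed in seeds:
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, int(temp), seed)))
            x0 = state.model.coords()
            e_atom0 = state.rset.per_atom_energies(x0)
            kicked = state.model.copy()
            kicked.set_coords(x0 + rng.normal(
                0.0, kick_scale * np.sqrt(temp), x0.shape))
            annealed, _ = local_refine(kicked, target, config, state.rset)
            xa = annealed.coords()
            worsened = state.rset.per_atom_energies(xa) \
                > e_atom0 + worse_threshold
            xa[worsened] = x0[worsened]
            annealed.set_coords(xa)
            final, _ = local_refine(annealed, target, config, state.rset)
            xf = final.coords()
            we_new = we_score(final, state.rset, xf).wE
            e_dens_new, _ = density_misfit(
                None, target, positions=xf,
                params=atom_gaussian_params(final))
            accepted = we_new < state.wE - MIN_DECREASE
            ledger.moves.append(MoveRecord(
                swaps=SwapSet(), wE_before=state.wE, wE_after=we_new,
                e_dens_before=state.e_dens, e_dens_after=e_dens_new,
                accepted=accepted, order=len(ledger.moves)))
            if accepted:
                state.model = final
                state.wE = we_new
                state.e_dens = e_dens_new
    return state.model, ledger


def pincer(model: EnsembleModel, target: DensityGrid,
           groups: list[AtomKey] | None = None,
           config: RefineConfig | None = None,
           library: RestraintLibrary | None = None,
           anchor_k: float = 200.0,
           ) -> EnsembleModel:
    """Collapse both alternates of each group to their midpoint, restrain,
    relax the rest, release, and re-refine; keep only if wE improves.

    Pinching at the top of the density hill gives the geometry term the
    best chance of pulling each member down the correct side on release.
    """
    config = config or RefineConfig()
    library = library or RestraintLibrary.load()
    state = _State(model, target, library)
    keys = sorted(groups if groups is not None else state.model.split_groups)
    pinched = state.model.copy()
    anchors = []
    for akey in keys:
        members = list(pinched.split_groups[akey].members.values())
        mid = np.mean([s.position for s in members], axis=0)
        for s in members:
            s.position = mid.copy()
            anchors.append((s.site_id, mid.copy(), anchor_k))
    held, _ = local_refine(pinched, target,
                           config.with_(restrained_sites=anchors),
                           state.rset)
    released, _ = local_refine(held, target, config, state.rset)
    we_new = we_score(released, state.rset).wE
    return released if we_new < state.wE - MIN_DECREASE else state.model


def residue_windows(model: EnsembleModel, size: int) -> list[list[AtomKey]]:
    """Sliding contiguous residue windows (stride 1) of split groups.

    Stride-1 windows ensure a planted block can never hide by straddling a
    tiling boundary.
    """
    by_res: dict[tuple[str, int], list[AtomKey]] = {}
    for akey in sorted(model.split_groups):
        rkey = akey[0]
        by_res.setdefault((rkey[0], rkey[1]), []).append(akey)
    chains: dict[str, list[tuple[int, list[AtomKey]]]] = {}
    for (chain, resnum), keys in sorted(by_res.items()):
        chains.setdefault(chain, []).append((resnum, keys))
    windows = []
    for chain, entries in chains.items():
        n = len(entries)
        for start in range(0, max(1, n - size + 1)):
            win = [k for _, keys in entries[start:start + size] for k in keys]
            if win:
                windows.append(win)
    return windows


def block_swap_search(model: EnsembleModel, target: DensityGrid,
                      windows: list[list[AtomKey]] | int = 2,
                      config: RefineConfig | None = None,
                      library: RestraintLibrary | None = None,
                      move_budget: int | None = None,
                      ) -> tuple[EnsembleModel, UntangleLedger]:
    """Swap whole contiguous blocks of split groups at once.

    Long-range traps leave little strain at their borders, so single-group
    scans cannot see them; flipping every group in a window (and in unions
    of adjacent windows) can.  Windows may be given explicitly or as a
    residue count used to tile each chain.
    """
    config = config or RefineConfig()
    library = library or RestraintLibrary.load()
    state = _State(model, target, library)
    if isinstance(windows, int):
        windows = residue_windows(state.model, windows)
    blocks = list(windows)
    blocks += [wa + wb for wa, wb in zip(windows, windows[1:])]
    budget = move_budget if move_budget is not None else 10_000
    ledger = _steepest_passes(
        state, lambda st: [SwapSet.exchange(win) for win in blocks],
        config, budget)
    return state.model, ledger


# ------------------------------------------------------------ diagnostics

@dataclass
class BondTangleRecord:
    atom_a: AtomKey
    atom_b: AtomKey
    cognate: dict[str, float]      # "AA", "BB" -> energy
    non_cognate: dict[str, float]  # "AB", "BA" -> energy
    flagged: bool

    def as_dict(self) -> dict:
        return {"atom_a": [list(self.atom_a[0]), self.atom_a[1]],
                "atom_b": [list(self.atom_b[0]), self.atom_b[1]],
                "cognate": self.cognate, "non_cognate": self.non_cognate,
                "flagged": self.flagged}


@dataclass
class TangleReport:
    records: list[BondTangleRecord] = field(default_factory=list)

    @property
    def flagged(self) -> list[BondTangleRecord]:
        return [r for r in self.records if r.flagged]

    def suggested_swaps(self) -> list[AtomKey]:
        """Downstream-end atoms of flagged bonds, candidates for swapping."""
        return sorted({r.atom_b for r in self.flagged})

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps([r.as_dict() for r in self.records], indent=indent)


def tangle_report(model: EnsembleModel,
                  library: RestraintLibrary | None = None) -> TangleReport:
    """Cognate vs non-cognate bond scoring across every fully split bond.

    For each covalent bond whose two ends are both split, the bond-length
    energy is evaluated for the current (cognate, AA and BB) pairings and
    for the crossed (non-cognate, AB and BA) pairings.  A bond is flagged
    when its best non-cognate score beats its worst cognate score — the
    signature of a tangled assignment.  Flags are invariant under a global
    letter exchange, which only relabels AA↔BB and AB↔BA.
    """
    library = library or RestraintLibrary.load()
    rset = build_restraints(model, library)
    ideal: dict[frozenset, tuple[float, float]] = {}
    for term in rset.terms["bond"]:
        akeys = frozenset(model.atoms[i].atom_key for i in term.site_ids)
        ideal[akeys] = (term.v0, term.sigma)
    report = TangleReport()
    letters = model.conformer_letters
    if len(letters) != 2:
        raise ValueError("tangle report requires a 2-conformer model")
    la, lb = letters
    for pair in sorted(model.bonds, key=sorted):
        ka, kb = sorted(pair)
        if ka not in model.split_groups or kb not in model.split_groups:
            continue
        if pair not in ideal:
            continue
        v0, sigma = ideal[pair]
        def energy(letter_a, letter_b):
            pa = model.split_groups[ka].members[letter_a].position
            pb = model.split_groups[kb].members[letter_b].position
            d = float(np.linalg.norm(pa - pb))
            return ((d - v0) / sigma) ** 2
        cog = {"AA": energy(la, la), "BB": energy(lb, lb)}
        non = {"AB": energy(la, lb), "BA": energy(lb, la)}
        flagged = min(non.values()) < max(cog.values())
        report.records.append(BondTangleRecord(ka, kb, cog, non, flagged))
    return report
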