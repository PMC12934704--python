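"""Trap-escape searches: acceptance valves, recovery, diagnostics."""

import numpy as np
import pytest

from untangler.model import SwapSet, apply_swaps, assignment_string
from untangler.restraints import build_restraints
from untangler.untangle import (block_swap_search, pincer, rectified_sa,
                                residue_windows, swap_and_rerefine_scan,
                                tangle_report)
from untangler.wescore import we_score


def _we(model, library):
    return we_score(model, build_restraints(model, library)).wE


class TestSwapScan:
    def test_untangled_fixture_is_a_fixed_point(self, fx_none, library):
        best, ledger = swap_and_rerefine_scan(
            fx_none.tangled, fx_none.target, config=fx_none.config,
            library=library)
        assert ledger.n_accepted == 0

    def test_recovers_the_planted_single_swap(self, fx_single, library):
        best, ledger = swap_and_rerefine_scan(
            fx_single.tangled, fx_single.target, config=fx_single.config,
            library=library)
        assert ledger.n_accepted >= 1
        assert assignment_string(best, fx_single.truth).percent_match == 100.0
        accepted = [m for m in ledger.moves if m.accepted]
        assert accepted[0].swaps.moves[0][0] == fx_single.planted.moves[0][0]

    def test_result_never_scores_worse_than_input(self, fx_single, library):
        before = _we(fx_single.tangled, library)
        best, ledger = swap_and_rerefine_scan(
            fx_single.tangled, fx_single.target, config=fx_single.config,
            library=library)
        assert _we(best, library) <= before
        for move in ledger.moves:
            if move.accepted:
                assert move.wE_after < move.wE_before

    def test_arity1_cannot_release_a_block_trap(self, fx_block, library):
        """Long-range traps have little strain at their borders; single
        swaps only create new borders, so none is accepted."""
        best, ledger = swap_and_rerefine_scan(
            fx_block.tangled, fx_block.target, config=fx_block.config,
            library=library)
        assert ledger.n_accepted == 0
        assert assignment_string(best, fx_block.truth).percent_match < 100.0

    def test_budget_exhaustion_is_flagged(self, fx_single, library):
        best, ledger = swap_and_rerefine_scan(
            fx_single.tangled, fx_single.target, config=fx_single.config,
            library=library, move_budget=3)
        assert ledger.budget_exhausted
        assert len(ledger.moves) == 3


class TestBlockSwap:
    def test_recovers_the_planted_block(self, fx_block, library):
        best, ledger = block_swap_search(
            fx_block.tangled, fx_block.target, windows=2,
            config=fx_block.config, library=library)
        assert assignment_string(best, fx_block.truth).percent_match == 100.0

    def test_untangled_fixture_accepts_nothing(self, fx_none, library):
        best, ledger = block_swap_search(
            fx_none.tangled, fx_none.target, windows=2,
            config=fx_none.config, library=library)
        assert ledger.n_accepted == 0

    def test_single_group_windows_degenerate_to_arity1_scan(
            self, fx_single, library):
        windows = [[k] for k in sorted(fx_single.tangled.split_groups)]
        b1, l1 = block_swap_search(
            fx_single.tangled, fx_single.target, windows=windows,
            config=fx_single.config, library=library)
        b2, l2 = swap_and_rerefine_scan(
            fx_single.tangled, fx_single.target, config=fx_single.config,
            library=library)
        assert _we(b1, library) == pytest.approx(_we(b2, library), abs=1e-6)

    def test_residue_windows_cover_every_group(self, fx_block):
        wins = residue_windows(fx_block.tangled, 2)
        covered = {k for win in wins for k in win}
        assert covered == set(fx_block.tangled.split_groups)
        # sliding (stride-1) windows over 4 residues: 1-2, 2-3, 3-4
        assert len(wins) == 3


class TestRectifiedSA:
    def test_one_way_valve_never_worsens(self, fx_block, library):
        before = _we(fx_block.tangled, library)
        out, ledger = rectified_sa(
            fx_block.tangled, fx_block.target, temps=[2000.0, 5000.0],
            seeds=[0], config=fx_block.config, library=library)
        assert _we(out, library) <= before + 1e-9
        for move in ledger.moves:
            if move.accepted:
                assert move.wE_after < move.wE_before

    def test_already_optimal_input_passes_through(self, fx_none, library):
        before = _we(fx_none.tangled, library)
        out, ledger = rectified_sa(
            fx_none.tangled, fx_none.target, temps=[3000.0], seeds=[0, 1],
            config=fx_none.config, library=library)
        assert _we(out, library) <= before + 1e-9

    def test_resolves_swaps_on_a_many_swap_fixture(self, library):
        """Scaled-down annealing study on a random-swaps (many things
        wrong) fixture: wE strictly decreases and planted swaps resolve."""
        from untangler.synthetic import FixtureSpec, make_toy_ensemble
        fx = make_toy_ensemble(
            FixtureSpec(n_residues=3, tangle_mode="random_swaps",
                        swap_fraction=0.3, seed=11), library=library)
        before_we = _we(fx.tangled, library)
        before_match = assignment_string(fx.tangled, fx.truth).percent_match
        out, ledger = rectified_sa(
            fx.tangled, fx.target, temps=list(np.linspace(2000, 8000, 9)),
            seeds=[0, 1, 2], config=fx.config, library=library)
        after_we = _we(out, library)
        after_match = assignment_string(out, fx.truth).percent_match
        assert after_we < before_we
        assert after_match > before_match


class TestPincer:
    def test_releases_high_strain_trap(self, fx_single, library):
        out = pincer(fx_single.tangled, fx_single.target,
                     groups=[fx_single.planted.moves[0][0][0]],
                     config=fx_single.config, library=library)
        assert assignment_string(out, fx_single.truth).percent_match == 100.0

    def test_never_accepts_a_worse_model(self, fx_none, library):
        before = _we(fx_none.tangled, library)
        out = pincer(fx_none.tangled, fx_none.target,
                     config=fx_none.config, library=library)
        assert _we(out, library) <= before + 1e-9

    def test_coincident_group_is_a_noop_up_to_refinement(self, fx_none,
                                                         library):
        model = fx_none.tangled.copy()
        akey = sorted(model.split_groups)[0]
        group = model.split_groups[akey]
        mid = np.mean([s.position for s in group.members.values()], axis=0)
        for s in group.members.values():
            s.position = mid.copy()
        before = _we(model, library)
        out = pincer(model, fx_none.target, groups=[akey],
                     config=fx_none.config, library=library)
        assert _we(out, library) <= before + 1e-9


class TestTangleReport:
    def test_ground_truth_flags_nothing(self, fx_single, library):
        rep = tangle_report(fx_single.truth, library)
        assert rep.records
        assert rep.flagged == []

    def test_flags_cluster_at_the_planted_swap(self, fx_single, library):
        rep = tangle_report(fx_single.tangled, library)
        assert rep.flagged
        planted_res = fx_single.planted.moves[0][0][0][0]
        for rec in rep.flagged:
            assert planted_res in (rec.atom_a[0], rec.atom_b[0])

    def test_flags_invariant_under_global_letter_exchange(self, fx_single,
                                                          library):
        tangled = fx_single.tangled
        flipped = apply_swaps(tangled,
                              SwapSet.exchange(sorted(tangled.split_groups)))
        r1 = tangle_report(tangled, library)
        r2 = tangle_report(flipped, library)
        assert [r.flagged for r in r1.records] == \
            [r.flagged for r in r2.records]

    def test_high_wx_refinement_enhances_score_contrast(self, fx_single,
                                                        library):
        """Refining with a dominant density weight squeezes atoms onto
        their blobs, sharpening the cognate/non-cognate contrast."""
        from untangler.refine import local_refine
        rset = build_restraints(fx_single.tangled, library)
        high, _ = local_refine(fx_single.tangled, fx_single.target,
                               fx_single.config.with_(
                                   wx=fx_single.config.wx * 100), rset)

        def contrast(model):
            rep = tangle_report(model, library)
            vals = [min(r.non_cognate.values()) - max(r.cognate.values())
                    for r in rep.records if r.flagged]
            return min(vals) if vals else 0.0

        assert contrast(high) <= contrast(fx_single.tangled)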