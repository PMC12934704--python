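"""Density synthesis, misfit gradients, difference maps, map round trips."""

import numpy as np
import pytest

from untangler.density import (ATOMIC_NUMBER, DensityGrid, density_misfit,
                               difference_map, grid_around, read_ccp4,
                               synthesize_density, write_ccp4)
from untangler.model import AtomSite, EnsembleModel, SwapSet, apply_swaps


def _one_atom_model(occ=1.0, b=8.0, pos=(0.0, 0.0, 0.0)):
    site = AtomSite(0, "O", "O", ("W", 1, "", "HOH"), "", occ, b,
                    np.asarray(pos, dtype=float))
    return EnsembleModel([site])


class TestSynthesis:
    def test_single_atom_peak_is_at_the_atom(self):
        model = _one_atom_model()
        grid = grid_around(model, spacing=0.25, pad=3.0)
        rho = synthesize_density(model, grid)
        ijk = np.unravel_index(np.argmax(rho.values), rho.shape)
        peak_pos = rho.origin + rho.spacing * np.array(ijk)
        assert np.linalg.norm(peak_pos) < rho.spacing

    def test_spherical_symmetry_of_one_atom(self):
        model = _one_atom_model(pos=(0.0, 0.0, 0.0))
        grid = DensityGrid(np.array([-2.0, -2.0, -2.0]), 0.25,
                           np.zeros((17, 17, 17)))
        rho = synthesize_density(model, grid).values
        assert np.allclose(rho, rho[::-1, :, :], atol=1e-12)
        assert np.allclose(rho, np.transpose(rho, (2, 0, 1)), atol=1e-12)

    def test_two_half_atoms_at_one_point_equal_one_atom(self):
        full = _one_atom_model(occ=1.0)
        halves = EnsembleModel([
            AtomSite(0, "O", "O", ("W", 1, "", "HOH"), "A", 0.5, 8.0,
                     np.zeros(3)),
            AtomSite(1, "O", "O", ("W", 1, "", "HOH"), "B", 0.5, 8.0,
                     np.zeros(3))])
        grid = grid_around(full, spacing=0.25, pad=3.0)
        r1 = synthesize_density(full, grid).values
        r2 = synthesize_density(halves, grid).values
        assert np.abs(r1 - r2).max() < 1e-12

    def test_integral_equals_occupancy_weighted_atom_numbers(self, fx_none):
        model = fx_none.truth
        grid = grid_around(model, spacing=0.25, pad=4.0)
        rho = synthesize_density(model, grid)
        total = rho.values.sum() * rho.voxel_volume()
        expected = sum(s.occupancy * ATOMIC_NUMBER[s.element]
                       for s in model.atoms)
        assert total == pytest.approx(expected, rel=1e-3)

    def test_letter_exchange_leaves_the_map_untouched(self, fx_single):
        """Density is blind to conformer assignment — why traps exist."""
        truth = fx_single.truth
        flipped = apply_swaps(truth,
                              SwapSet.exchange(sorted(truth.split_groups)))
        grid = grid_around(truth, spacing=0.3, pad=3.0)
        r1 = synthesize_density(truth, grid).values
        r2 = synthesize_density(flipped, grid).values
        assert np.abs(r1 - r2).max() < 1e-10

    def test_atom_outside_margin_raises(self):
        model = _one_atom_model(pos=(50.0, 0.0, 0.0))
        grid = DensityGrid(np.zeros(3), 0.3, np.zeros((10, 10, 10)))
        with pytest.raises(ValueError, match="outside"):
            synthesize_density(model, grid)


class TestMisfit:
    def test_zero_iff_model_generates_target(self, fx_none):
        model = fx_none.truth
        grid = grid_around(model, spacing=0.3, pad=3.0)
        target = synthesize_density(model, grid)
        e, grad = density_misfit(model, target)
        assert e == pytest.approx(0.0, abs=1e-20)
        assert np.abs(grad).max() < 1e-12

    def test_strictly_increases_with_displacement(self, fx_none):
        model = fx_none.truth
        grid = grid_around(model, spacing=0.3, pad=4.0)
        target = synthesize_density(model, grid)
        errs = []
        for shift in (0.5, 1.5, 3.0):
            moved = model.copy()
            moved.atoms[0].position = model.atoms[0].position \
                + np.array([shift, 0, 0])
            e, _ = density_misfit(moved, target)
            errs.append(e)
        assert errs[0] > 0
        assert errs[0] < errs[1] < errs[2]

    def test_gradient_matches_finite_differences(self, fx_none):
        from untangler.density import atom_gaussian_params
        model = fx_none.truth
        grid = grid_around(model, spacing=0.3, pad=3.0)
        target = synthesize_density(model, grid)
        rng = np.random.default_rng(5)
        x = model.coords() + rng.normal(0, 0.15, (len(model.atoms), 3))
        params = atom_gaussian_params(model)
        e, grad = density_misfit(None, target, positions=x, params=params)
        h = 1e-5
        for k in rng.integers(0, x.size, 20):
            xp = x.ravel().copy(); xp[k] += h
            xm = x.ravel().copy(); xm[k] -= h
            ep, _ = density_misfit(None, target, positions=xp.reshape(-1, 3),
                                   params=params)
            em, _ = density_misfit(None, target, positions=xm.reshape(-1, 3),
                                   params=params)
            fd = (ep - em) / (2 * h)
            assert grad.ravel()[k] == pytest.approx(fd, rel=1e-4, abs=1e-10)


class TestDifferenceMap:
    def test_perfect_model_under_noise_peaks_match_noise_statistics(
            self, fx_none):
        """A perfect model's difference map is pure noise, so its tallest
        peak stays below the expected extreme of |N(0,1)| over the grid."""
        model = fx_none.truth
        grid = grid_around(model, spacing=0.3, pad=3.0)
        target = synthesize_density(model, grid)
        rng = np.random.default_rng(9)
        noise = 0.01 * target.values.max()
        target.values = target.values + rng.normal(0, noise, target.shape)
        diff, peaks = difference_map(model, target)
        from scipy import stats
        n_vox = target.values.size
        bound = stats.norm.isf(0.005 / n_vox)  # P(max exceeds) ~ 1%
        assert peaks
        assert abs(peaks[0]["height_sigma"]) < bound

    def test_deleted_atom_leaves_positive_peak_at_its_position(self, fx_none):
        model = fx_none.truth
        grid = grid_around(model, spacing=0.3, pad=3.0)
        target = synthesize_density(model, grid)
        # drop both alternates of the last atom; the resulting positive
        # feature sits on their (overlapping) blob
        removed = EnsembleModel([s.copy() for s in model.atoms[:-2]])
        gone = [model.atoms[-1].position, model.atoms[-2].position]
        diff, peaks = difference_map(removed, target)
        assert peaks
        top = peaks[0]
        assert top["height_sigma"] > 0
        dist = min(np.linalg.norm(np.array(top["position"]) - g)
                   for g in gone)
        assert dist < 1.0

    def test_mid_swap_state_shows_paired_difference_features(self, fx_single):
        """Halfway through an exchange the map shows flanking +/− features."""
        model = fx_single.truth.copy()
        akey = fx_single.planted.moves[0][0][0]
        group = model.split_groups[akey]
        pa = group.members["A"].position.copy()
        pb = group.members["B"].position.copy()
        mid = 0.5 * (pa + pb)
        grid = grid_around(model, spacing=0.3, pad=3.0)
        target = synthesize_density(model, grid)
        group.members["A"].position = mid.copy()
        group.members["B"].position = mid.copy()
        diff, peaks = difference_map(model, target, peak_threshold=3.0)
        signs = {np.sign(p["height_sigma"]) for p in peaks[:6]}
        assert {1.0, -1.0} <= signs


class TestMapIO:
    def test_ccp4_round_trip(self, tmp_path, fx_none):
        model = fx_none.truth
        grid = grid_around(model, spacing=0.3, pad=3.0)
        rho = synthesize_density(model, grid)
        path = tmp_path / "map.ccp4"
        write_ccp4(rho, path)
        back = read_ccp4(path)
        assert back.shape == rho.shape
        assert back.spacing == pytest.approx(rho.spacing, rel=1e-6)
        assert np.allclose(back.origin, rho.origin, atol=1e-5)
        assert np.abs(back.values - rho.values).max() < 1e-5
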