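# untangler

Tools for escaping **density misfit barrier traps** in multi-conformer
(altloc) macromolecular models.

When a crystallographic model represents a 2-member ensemble, each split
atom carries two alternate locations labeled by conformer letters (A, B).
The average electron density is blind to those labels: exchanging the
letters of any split atom leaves the map unchanged. Refinement is not
blind to them — covalent geometry is evaluated between sites of the same
letter — so a model whose letters are assigned to the wrong positions
("tangled") refines into a stable local minimum. The atoms cannot exchange
positions because the intermediate, coincident state fits the density
badly: the density misfit forms a barrier, and the strain cannot relax.
This package implements the machinery for detecting, scoring, and escaping
such traps, exercised end-to-end on synthetic two-conformer fixtures with
a known ground truth.

## What's inside

**The wE score.** Every validation category (bonds, angles, torsions,
clashes, …) is put on a common scale as statistical energies
E = ((v − v0)/σ)². Per category, the worst energy is clipped by a plateau
(identity up to 10, then 10 + ln(1 + E − 10)) and weighted by *softPnn* —
the probability (2Φ(d) − 1)ⁿ that the largest of n standard-normal
magnitudes stays below the worst deviate d, i.e. that the worst outlier is
not noise. The mean energy is weighted by the χ²ₙ cumulative probability of
Σd². The score is

    wE = Σ_category [ χ²·⟨E⟩ + softPnn·clip(max E) ] + ⟨E_LJ⟩

where ⟨E_LJ⟩ is the mean normalized 12-6 Lennard-Jones energy over
non-bond pairs, exactly −1 when every pair rests at its optimal
separation. A 6σ worst outlier gets softPnn weight 1, a 1σ worst gets 0,
and a deviate distribution exactly at expectation gets χ² weight 0.5.

**A real-space toy refiner.** L-BFGS minimization of
wx·E_dens + Σ E_geom + Σ E_LJ over coordinates with conformer letters
frozen, where E_dens is a normalized squared-voxel-difference misfit
against a target map of occupancy-weighted Gaussian atoms. Analytic
gradients throughout; deterministic; monotone in the total energy.

**Four trap-escape maneuvers.** The *weight snap* (wx × 100, × 0.01, × 1 in
sequence), *rectified simulated annealing* (Gaussian kicks with a one-way
valve: atoms whose local energy worsened are restored, sweeps kept only if
wE drops), *swap-and-rerefine* (trial letter exchanges followed by full
re-refinement, accepted only on strict wE decrease), and the *pincer*
(collapse both alternates to their midpoint under restraint, then release
so geometry pulls each down the correct side). A sliding-window *block
swap* search handles long-range traps whose borders carry almost no
strain, and a *tangle report* scores every fully split bond in its cognate
(AA, BB) and non-cognate (AB, BA) pairings to point at suspect regions.

**A fixture generator** that builds bead-peptide chains with exactly ideal
geometry, splits every atom into two sheets ±amplitude/2 apart, plants
known tangles (single swap, many random swaps, contiguous block swaps, a
mis-assigned water), and only emits fixtures that are genuine traps —
plain refinement must fail to untangle them.

## Worked example

```
$ untangler makefixture --spec spec.json --out fx      # {"n_residues": 3, "tangle_mode": "single_swap", "seed": 1}
$ untangler score fx/truth.pdb
wE = -0.1848
$ untangler score fx/tangled.pdb
wE = 227.6070
$ untangler swapscan fx/tangled.pdb fx/target.ccp4 --out scan
wE 227.6070 -> -0.1849
$ untangler report fx/tangled.pdb
1 flagged bond(s)
$ untangler barrier fx/tangled.pdb fx/target.ccp4 --atom X,2,BEA,CB
density misfit maximal at lambda = 0.50
```

The ground truth scores wE ≈ −0.18: all geometry is ideal, so only the
(negative) mean Lennard-Jones term remains. The tangled model — one
side-chain bead with exchanged letters, re-refined into its trap — scores
227.6, dominated by clipped severe outliers in several bonded categories.
The swap scan tries each split group, finds that exchanging the planted
group's letters and re-refining drops wE back to −0.18, and accepts
exactly that move; the tangle report flags the one bond whose crossed
(non-cognate) pairing scores better than its cognate pairing, and the
barrier profile confirms the density misfit peaks at the midpoint of the
exchange path — the barrier that made the trap stable in the first place.

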