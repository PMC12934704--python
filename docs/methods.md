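# Methods

## The model-quality score

All geometry validation is expressed as statistical energies
E = ((v − v0)/σ)², with v measured from coordinates, v0 the library ideal,
and σ the library spread (Å for lengths, degrees for angles and torsions;
torsion differences are wrapped into (−180°, 180°] before division, and a
periodicity p > 1 reduces the wrap window to 360°/p). Eleven category
names are fixed — bond, angle, torsion, planarity, chirality, omega,
cbeta, rotamer, ramachandran, clash, nonbond — and any of them may be
empty for a given library; an empty category contributes exactly zero.
Probability-based scores, where a library supplies them, are converted to
the sigma deviate whose two-sided normal tail probability equals the
observed probability (`prob_to_sigma_deviate`), so every category lives on
one scale. The bead fixtures leave the probability categories inactive.

Per category the score combines two summaries:

* **w_avg · ⟨E⟩** with w_avg the χ²ₙ CDF at Σd². This calibrates itself:
  if the deviates are genuine standard-normal noise the weight hovers
  around 0.5 (its Monte-Carlo average converges there), saturating to 1
  for broad distributions and 0 for over-tight ones.
* **w_worst · clip(max E)** with w_worst = (2Φ(d_max) − 1)ⁿ, the
  probability that the largest of n standard-normal magnitudes stays below
  the observed worst deviate, and clip the plateau: identity up to E = 10,
  then 10 + ln(1 + (E − 10)). The plateau's derivative falls below 1
  beyond the knee, which makes reducing a 6σ outlier to 3σ strictly
  outweigh letting an outlier already at 20σ creep to 20.4σ — without the
  plateau the squared energies would order that trade the other way.

The scalar wE adds the mean normalized Lennard-Jones energy ⟨E_LJ⟩ over
all non-bond pairs, unweighted and unclipped. The 12-6 form is normalized
to a minimum of exactly −1 at the pair's optimal separation r0 (sum of
van-der-Waals radii), so wE ≥ −1 always, and a model with severe outliers
in k categories scores on the order of 10·k because each affected
category's clipped worst saturates near the knee.

Clashes are scored twice on purpose, in different roles: the `clash`
category counts overlaps beyond a 0.4 Å margin as deviates of
overlap/0.1 Å (a validation-style count of unacceptable contacts), while
the smooth Lennard-Jones term carries packing quality into both the score
and the refinement gradient. Only the LJ term enters the refiner.

## Restraints and their letter dependence

Bonded terms are instantiated per conformer letter from plain-text
residue templates (cognate instances only: all sites in a term share a
letter or are unsplit). Non-bond pairs exclude 1-2/1-3/1-4 neighbours,
pairs beyond a 5 Å cutoff at build time, alternates of the same atom, and
crossed-letter (A↔B) pairs — the two conformers are independent copies
that only share unsplit atoms, which is the density-symmetric reading of
a two-member ensemble. The pair list is built once per model and kept
static through a refinement, as is standard practice.

A consequence worth stating explicitly because the algorithms depend on
it: the restraint set is a function of the letters. After any letter
permutation the cognate instances and the compatible pair list both
change, so every search rebuilds restraints after every trial swap.

The bundled library carries full-precision templates for the bead-peptide
residue and water, plus a reduced amino-acid set (backbone and Cβ bonds
and angles) intended for topology-faithful reading of real PDB files;
side-chain restraint values beyond Cβ are out of the library's scope.
Covalent connectivity templates, by contrast, cover all twenty amino
acids, so bond graphs, downstream traversal and disulfide detection
(SG–SG < 2.5 Å) work on real protein files.

### Downstream direction

Swap propagation "downstream" follows increasing residue number along
each chain (C→N peptide edges), and within a residue main chain before
side chain, with side-chain edges directed outward from CA by bond-graph
distance. Ring-closure edges that do not strictly increase that distance
are not followed, and disulfide edges are never followed, so traversal
terminates on every input including proline and the aromatic rings. The
tie-break at branch points (both branches of Val, Ile, aromatic rings) is
breadth-first by distance, alphabetical within a level; this convention is
a package choice, fixed here for reproducibility.

## Density model and misfit

Atoms are single isotropic Gaussians with amplitude occupancy·Z and
variance (B + B_base)/(8π²), B_base = 2 Å². A single-term Gaussian keeps
the occupancy/B semantics the maneuvers need while staying cheap enough
to evaluate thousands of times per search; B_base was set low enough that
the default fixture (B = 8 Å², grid spacing 0.3 Å) resolves the two
conformer sheets of a 1.2 Å split — the sub-Å-resolution regime in which
assignment traps are sharpest and easiest to study.

The misfit is E_dens = Σ(ρ_model − ρ_target)²/Σρ_target² over voxels:
zero iff the model reproduces the target, scale-free, with analytic
gradients (verified against finite differences to 1e-4 relative). It is a
real-space stand-in for reciprocal-space residuals: no structure factors,
bulk solvent, or free-set machinery, and no R factors. Whether maneuver
effectiveness differs under a reciprocal-space target with a free set is
untested here and a known limitation. During refinement, atoms that stray
outside the grid simply lose their density force (geometry pulls them
back); the hard bounds check applies only to map synthesis.

Difference maps are target minus model in units of the difference map's
own standard deviation, so a deleted atom appears as a positive peak.
Under pure noise the tallest peak follows extreme-value statistics — about
√(2 ln N) σ for N voxels (≈ 4.6σ at N ≈ 10⁵) — which is the calibrated
bound the tests use for a perfect model.

## Refinement

`local_refine` minimizes T = wx·E_dens + ΣE_geom + ΣE_LJ with L-BFGS
(analytic gradients, fixed iteration cap 120, relative decrease tolerance
1e-9). It is deterministic given its inputs, and the per-iteration energy
trajectory is recorded and non-increasing. Positional restraints enter as
harmonic anchors. B factors and occupancies are never refined; occupancies
default to 1/(number of conformer letters) when a model is built without
them.

The density weight wx defaults to 3·10⁵. The number is meaningless in
itself (E_dens is normalized per map, so wx absorbs the map scale); it was
calibrated once so that the synthetic fixtures behave like genuine traps:
at the default weight a planted swap survives refinement with a ≥6σ
residual outlier, while scaling wx down by the snap factor 0.01 lets the
strain of a high-amplitude swap push the atoms through the barrier. The
fixture generator enforces this trap behaviour as a gate rather than
assuming it.

The weight snap runs three refinements at wx × (100, 0.01, 1). The factors
are package choices ("very high" and "very low" are the operative
properties); both are exposed in the configuration.

## The synthetic fixtures

Bead-peptide residues (N, CA, C backbone + one CB side-chain bead) are
placed by internal coordinates exactly at the library ideals, so the
single-conformer chain has identically zero bonded deviates. Every atom
is split into A/B sites displaced rigidly by ±amplitude/2 along z with
occupancy 0.5 — rigid displacement keeps both conformers' internal
geometry perfect at any amplitude. Defaults: amplitude 1.2 Å, B = 8 Å²,
grid spacing 0.3 Å, 1% peak-height Gaussian map noise, seeded. Two
parallel chains (7 Å apart) support the correlated ("windshield wiper")
versus anti-correlated ("jumping jacks") letter modes, which share every
atom position — and therefore synthesize identical maps to 1e-10 — while
differing in ground-truth assignment.

Tangle modes plant known errors: `single_swap` (one CB group), 
`random_swaps` (each group with a given probability), `block_swap`
(all groups in a contiguous residue window), and `water_swap`. Each
fixture passes two gates or is regenerated: the ground truth must be
clean (all bonded deviates within 1σ, no LJ pair above +0.5), and the
tangled start, after refinement at the default weight, must be a genuine
trap (wE strictly above the truth's, assignment not recovered).

The water fixture deserves a note because it realizes the *low-strain*
trap class. A split water pairs anti-sheet with a nearby side-chain bead:
correctly assigned, its cognate contacts are comfortable; with its letters
exchanged, both cognate pairs land on a shared sheet at clashing distance.
The mis-assignment therefore costs a clash rather than bonded strain, and
the force pushing the water across the barrier is only the tiny
Lennard-Jones preference — too small to cross at any snap weight, because
during the low-weight phase the clash relaxes laterally and the final
phase pulls everything back. Purely amplitude-scaled swaps cannot
reproduce this recalcitrance: in this toy, shrinking the amplitude weakens
the density barrier faster than it weakens the strain, so *small*
-amplitude traps release more easily under a weight snap, not less. The
clash-dominated water trap restores the intended phenomenology (released
by swap-and-rerefine, immune to the weight snap).

Fixture generation is bit-reproducible from its seed.

## Search algorithms

All searches accept a move only on strict wE decrease (threshold 1e-6)
and are therefore wE-non-increasing end-to-end; every attempted move is
recorded in a ledger with wE and E_dens before and after. wE — not the
refinement energy — is the judge, and the acceptance engine is shared.

The swap scan and block search use steepest-descent passes: every
candidate is evaluated from the current state (swap, rebuild restraints,
re-refine) and the single best improving move is applied before
rescanning. Best-of-pass acceptance makes the outcome independent of
candidate order; first-improvement greed was observed to walk into
path-dependent dead ends (accepting a backbone swap next to the planted
side-chain swap, after which no single move improved). Candidates are
still ranked most-strained-first (by per-atom energy, full term counting)
so the ledger reads in diagnostic order. Pair (arity-2) scans are capped
by a move budget rather than full enumeration.

Block windows slide with stride 1 over each chain's residues, plus unions
of adjacent windows; stride-1 is load-bearing, since a planted block that
straddles a disjoint tiling boundary would otherwise never be a
candidate. Windows of single groups reduce the block search to the
arity-1 scan.

Rectified simulated annealing kicks all coordinates by Gaussian noise of
scale 0.012·√T Å — about 1 Å at the hottest default step, comparable to
the split amplitude, which is what a kick must span to hop a barrier —
then refines, restores every atom whose per-atom energy worsened by more
than 4 (a 2σ-equivalent), refines again, and keeps the sweep only if wE
decreased. Per-atom energy counts each term fully for every member atom
(not apportioned), which overcounts shared terms but is the right
bookkeeping for deciding whether *this* atom's environment got worse.

The pincer collapses both alternates of each chosen group to their
midpoint, holds them there with harmonic anchors (k = 200) while the rest
relaxes, releases, re-refines, and keeps the result only if wE improved.

The tangle report evaluates each fully split bond's length energy in its
cognate (AA, BB) and crossed (AB, BA) pairings — bond length is the one
score per pairing; richer per-bond score sets would be a straightforward
extension — and flags bonds whose best crossed score beats their worst
cognate score. Flags are invariant under global letter exchange, which is
the gauge symmetry of the whole problem: a global flip relabels AA↔BB and
AB↔BA without changing any number.

Assignment agreement against a reference is reported after choosing the
global letter relabeling that maximizes per-group matches, with matches
decided by proximity (each site nearer the reference site of its mapped
letter than any other). Proximity, not labels, so a search that fixes a
tangle by moving atoms across (as annealing does) is credited the same as
one that relabels.

## Problem sizes and numerical choices

The study fixtures are deliberately small: 2-residue chains (8 split
groups) for single-swap recovery and exhaustive-enumeration equivalence
(2⁸ assignments, each re-refined), 4-residue chains for block traps, 3
residues plus a water for the low-strain trap, with 20 seeds per recovery
study. Degenerate geometry (colinear angle/torsion atoms) is excluded
from scoring with a warning rather than propagated as NaN; coincident
non-bonded atoms are a hard error; ties in candidate ranking break by
atom key for determinism.

## What the fixtures do and do not show

The bead fixtures isolate the trap mechanism — label-blind density plus
letter-dependent geometry — with ideal-geometry ground truths, one
Gaussian per atom, flat solvent-free background, and no experimental-data
model beyond voxel noise. Passing tests demonstrate the algorithms'
behaviour on that mechanism; they do not demonstrate performance on real
diffraction data, reciprocal-space targets, anisotropic displacement,
multi-copy (>2) ensembles, or chemically realistic strain distributions.
Rotamer/Ramachandran scoring is structurally supported but exercised only
through its probability-to-sigma conversion, since the bead world has no
rotamers.
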