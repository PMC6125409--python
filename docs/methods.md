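# Methods

`oligostate` asks one question of a homo-dimeric protein: do its dimers
assemble further — in particular into the membrane-bridging (trans)
tetramer that would make the protein a direct adhesion receptor?  Three
independent lines of evidence are implemented end to end: cross-linking
mass-spectrometry restraints scored on candidate assemblies, small-angle
X-ray scattering (SAXS) analysed for size and state composition, and two
cell-level assays (bead aggregation, lifetime-based FRET).  This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## Cross-link restraints and MNXL scoring

A lysine–lysine cross-link formed by DSS constrains the *solvent
accessible surface distance* (SASD) between the two residues: the
shortest path joining them that stays in solvent, outside the protein
body.  SASD, not the straight-line distance, is what the cross-linker
arm must span; the empirical match threshold for DSS is 33 Å.

**Grid construction.**  The structure is voxelised (default 1 Å).  A
voxel is blocked when it lies within (van der Waals radius + probe
radius, default probe 1.4 Å) of any atom.  Free space is then restricted
to the components connected to the bounding-box boundary: an interior
cavity sealed off from bulk solvent is not accessible to a cross-linker
and must not carry paths.  Paths run on the 26-connected grid with
Euclidean edge weights (1, √2, √3 × spacing) and are found with
Dijkstra's algorithm on a sparse adjacency matrix.

**Endpoints.**  The endpoint atom is the Cα of each cross-linked residue
(the 33 Å threshold used here was calibrated on Cα distances;
configurable).  Each endpoint maps to its nearest solvent voxel; among
near-equidistant candidates the voxel facing the partner endpoint is
preferred, so a residue's "exit point" is not chosen arbitrarily among
symmetric surface positions.  The reported SASD includes the straight
legs from each atom to its exit voxel, which guarantees SASD ≥ Euclidean
distance.  A residue with no solvent voxel within 8 Å is buried:
NOT_ACCESSIBLE, not an error.

**Euclidean prefilter.**  Since SASD ≥ Euclidean, any intra/inter
variant whose straight-line distance already exceeds 33 Å cannot match
and skips the path search; it is counted non-accessible directly.

**Scoring.**  A matched SASD s scores the normal density
N(μ = 18.62 Å, σ² = 35.94 Å²) evaluated at s; an SASD above 33 Å, or no
path at all, scores a flat −0.1.  The dispersion constant is read as a
variance (σ ≈ 6.0 Å), giving the peak score 1/√(2π·35.94) ≈ 0.0666; a
flag treats it as σ instead for sensitivity analyses.  Two homo-oligomer
adaptations: (i) every intra- and inter-subunit placement of a
cross-link is evaluated and only the best-scoring variant counts, so a
symmetric model is not rewarded twice for one observation; (ii) when
ranking tetramer candidates against a dimer reference, the −0.1 penalty
is replaced by 0 for cross-links the dimer already matches — tetramers
are ranked by their ability to explain the cross-links the dimer
*cannot*, not punished for the ones it can.  A model's total is the
plain sum over cross-links, reported with matched / non-accessible
counts.

**State assignment.**  Cross-links seen exclusively in monomer gel bands
are intra-subunit by construction and assigned to the monomer — except
self-pairs (residue linked to its own copy), which require two subunits
regardless of band.  All other cross-links go to the state whose model
scores them highest, ties broken toward the smaller oligomer
(parsimony).  Cross-links from trimer bands are treated as candidate
tetramer evidence (partially cross-linked tetramers).

**Restraint scanning.**  For occupancy-style analyses each cross-link is
chain-assigned to minimise its distance in a reference tetramer, the
2-fold symmetric counterpart is added (A–D implies C–B), and an ensemble
is scanned for the number of satisfied restraints per model; the full
satisfaction table is reported because some cross-links may be false
positives.

## SAXS

Model profiles use the Debye sum over residue-level scatterers: one
scatterer per residue at the Cα position, weighted by the residue's
electron count.  No hydration layer is added and intensities carry
arbitrary units; the systematic offset against an all-atom,
hydration-corrected computation is acceptable because every use in the
pipeline is relative (dimer vs tetramer, state weights, series
consistency).  I(0) = (Σf)², so a tetramer scatters 4× its dimer
forward.

*Guinier.*  ln I vs q² is fitted on the largest low-q window with
qmax·Rg below a limit, iterated to self-consistency; Rg = √(−3·slope).
The conventional limit 1.3 is adequate for globular shapes (≤ 2% error
on test shapes); the sharp sphere form factor needs a conservative 0.9
window for 1% accuracy, which is what the sphere-oracle test uses.  A
non-decreasing Guinier region warns of aggregation/repulsion instead of
failing.

*Molecular weight.*  Porod invariant Q = ∫ q²I dq with a Guinier fill-in
below the first measured point and a K/q⁴ tail beyond q_max (default
0.25–0.3 Å⁻¹); Vp = 2π²I(0)/Q; MW = Vp × 0.83×10⁻³ kDa/Å³ (standard
protein density ≈ 1.37 g/cm³).  Scale-invariant by construction.
Limitation: for particles large enough that the q-window misses the
Porod regime — or, for point-scatterer toy models, where the constant
self-term floor becomes comparable to the coherent signal — the estimate
degrades; the recovery test uses globular sizes (≈ 8–15 kDa toys) where
the method is calibrated to ±15%.

*Concentration-series merge.*  Low-concentration profiles supply
q < 0.15 Å⁻¹ (inter-particle structure factor distorts concentrated
samples at small angles), high-concentration profiles supply
q > 0.12 Å⁻¹ (better statistics), members are least-squares scaled to a
common reference in the overlap, averaged per region and across groups
in the overlap, with standard-error propagation.

*Fitting.*  Single-profile χ² uses the closed-form optimal scale
c = Σ(I_e I_m/σ²)/Σ(I_m²/σ²), χ² normalised by N.  The multi-state fit
enumerates all single states and beam-searches larger combinations
(default beam width 10,000): each k-state combination in the beam is
expanded by every ensemble member; weights are solved by non-negative
least squares on σ-whitened intensities and renormalised; states below
the minimal weight 0.01 are dropped.  The selected number of states is
the smallest k whose successor improves relative χ by less than 0.1%.
χ² is non-increasing in k by construction (supersets can only fit
better).

*Equilibrium.*  For 2 D ↔ T with Kd = [D]²/[T] and total dimer-unit
concentration C, [D] = Kd(−1 + √(1 + 8C/Kd))/4 and the tetramer mass
fraction is 1 − [D]/C; at C = Kd it is exactly ½.  When converting
mg/ml, the monomer-equivalent molar concentration (mg/ml over subunit
mass) is used as the dimer-unit concentration — the reading under which
the printed headline fraction (≈ 93% at Kd 10 µM and 919.4 µM) is
reproduced.

## Ensemble generation

*Random tetramers* replace geometric-hashing docking with rejection
sampling: a second dimer copy in a uniform SO(3) orientation approaches
along a uniformly random direction until the surfaces touch (bisection
on the approach distance).  Acceptance requires ≥ 10 atom pairs within
5 Å and no pair below the 1.5 Å clash floor (both configurable,
invented — adequacy here is orientation *coverage*, verified by a Kuiper
test on the rotation-angle distribution, not docking-score fidelity).
Duplicates are removed at 2 Å symmetric RMSD.

*D2 trans-tetramers.*  The dimer's C2 axis is recovered from the
rotation superposing chain A onto chain B.  The second dimer is flipped
180° about an axis perpendicular to the C2 axis and displaced *along*
the C2 axis until contact; this is the unique construction in which both
2-folds remain point symmetries, i.e. the tetramer is exactly D2.  The
perpendicular flip axis sweeps n orientations (default 12).  Symmetry is
verified with a direct (no-superposition) RMSD under each D2 rotation,
tolerance 0.5 Å; a superposed RMSD would be blind to the question.

*Flexible tails.*  Unresolved C-terminal stretches are grown as Cα-trace
coils: 3.8 Å virtual bonds in uniformly random directions, rejected on
clashes with the folded body or other chains' tails.  A tail may
approach itself — direction memory and self-avoidance are deliberately
left out so that short-tail ensemble statistics follow the
freely-jointed chain, which is the oracle the sampler is tested against
(mean end-to-end within 15%).  Side-chain packing is not modelled.

## Assay statistics

*Bead aggregation.*  The segmentation pipeline mirrors the standard
ImageJ recipe: 3×3 mean smooth → Sobel gradient magnitude → automatic
threshold (Otsu by default; the exact ImageJ variant is unrecorded, so
the method used is stored in the output metadata) → mask → fill holes →
8-connected components.  Classification against a supplied reference of
single-bead areas (the digital stand-in for manually selecting 10 single
beads): area > mean + 2·sd ⇒ aggregate, area < mean − 2·sd ⇒ artifact
(excluded), comparisons strict.  Aggregation ratio = total aggregate
area / total single area.  Note the rule presumes a non-degenerate
reference spread; the synthetic generator therefore gives beads a
few-percent size polydispersity (three discrete sizes), as real bead
preparations have.

*TCSPC lifetimes.*  The measured decay is IRF ⊛ Σ A_k exp(−t/τ_k) +
background.  Fits maximise the Poisson likelihood (appropriate for
counting data; weighted least squares available as a flag) with
multi-start Nelder–Mead, falling back to bounded Powell when a parameter
runs to its identifiability limit — lifetimes are bounded by the
acquisition window, since a component longer than the window is
indistinguishable from background.  The decay kernel is bin-integrated
with a half-bin offset: the IRF mass of a bin sits on average at the bin
centre, and evaluating the exponential at bin left edges instead shifts
the effective time origin by Δt/2, which measurably biases short
lifetimes (this was visible as a +15% error on a 1 ns component at
50 ps bins before the correction).  Lifetimes are reported in canonical
ascending order with the amplitude-weighted mean τ_avg = ΣA_kτ_k/ΣA_k,
the quantity that drops when FRET opens an extra decay channel.
Mono-, bi- and tri-exponential models are supported.

## Synthetic data: what it shows and what it does not

Generators produce every input class with ground truth: parametric toy
structures (sphere shell, slab with aperture, two-lobe) from 1.7 Å
pseudo-atoms, with an exact C2 axis for two-chain dimers; cross-link
sets drawn from accessible site pairs with a controlled false-positive
rate; noisy SAXS mixtures of known weights (2% Gaussian default);
bead images with known particle classes; photon-sampled decays with
Gaussian IRF jitter (photon shares ∝ A_kτ_k, the pre-exponential
convention).  All generators are seed-deterministic.

Passing tests demonstrate that the estimators recover known truth under
their own noise models at desk scale: weight recovery to ±0.05 at 2%
noise, τ_avg bias < 2% at 10⁵ counts, exact bead-class recovery in
clean scenes, SASD agreement with an independent Dijkstra oracle.  They
do not demonstrate robustness to the pathologies of real data — radiation
damage and inter-particle structure factors in SAXS, glycosylation
heterogeneity, detector afterpulsing, uneven illumination — nor absolute
SAXS calibration, all of which are out of scope.

## Problem sizes and defaults

Tests run on toy scenes of 60–300 pseudo-atoms, solvent grids of ≤ ~10⁵
voxels (1–2 Å spacing), ensembles of 5–400 models and 50 decay
replicates; these sizes were chosen so that every stage remains a
few-second computation while keeping each estimator in its calibrated
regime.  Production-scale settings (1 Å grids on full ectodomain
assemblies, tens of thousands of docked tetramers, beam width 10,000)
use the same code paths unchanged.

## Known limitations

- SASD is grid-quantised; values carry O(grid spacing) error and the
  raw weighted path length is reported without grid-artifact
  normalisation.
- The residue-level Debye profile underestimates wide-angle features and
  carries a point-scatterer self-term floor; comparisons must stay
  relative.
- Chain-permutation RMSD enumerates all equivalent chain permutations
  (capped at 6 chains), a superset of the physical symmetry group; it
  can therefore slightly underestimate distances between genuinely
  different arrangements.
- The trans-plausibility test (anchor directions ≥ 120° apart plus
  plane separability through the centroid) is an operationalisation of
  a qualitative structural judgement; both pieces are configurable.
- The bead segmenter merges touching aggregates into single components
  by design; it does not split clumps, and classification quality is
  bounded by the representativeness of the single-bead reference.
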