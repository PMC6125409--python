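# oligostate

Oligomeric-state analysis of homo-oligomeric proteins from chemical
cross-linking restraints, small-angle X-ray scattering and cell-assay
statistics.

## The problem

Cell-adhesion receptors are often drawn as tidy cartoons: dimers on one
cell clasping dimers on the opposing cell into a membrane-bridging
(*trans*) tetramer.  Whether such a tetramer actually exists is a
question three independent kinds of data can answer, and this package
implements the computational side of all three for anyone testing an
oligomerisation hypothesis on a homo-dimeric protein:

- **Cross-linking mass spectrometry (XL-MS).**  A lysine-reactive
  cross-linker (DSS) reports residue pairs whose *solvent accessible
  surface distance* (SASD) — the shortest path between them through
  solvent, around the protein body — is below 33 Å.  Candidate
  assemblies are ranked by the MNXL score: a matched SASD *s* earns the
  Gaussian reward N(μ = 18.62 Å, σ² = 35.94 Å²)(s), an unmatched or
  inaccessible cross-link costs −0.1.  Only the best intra/inter-subunit
  variant of each cross-link counts, and tetramer candidates are judged
  only on the cross-links a dimer cannot explain.
- **SAXS.**  Debye-computed model profiles, Guinier Rg, Porod-volume
  molecular weight, concentration-series merging, and a multi-state fit
  that decomposes a measured profile I(q) ≈ c·Σ wₖ Iₖ(q) over an
  ensemble of candidate states (non-negative weights, beam-search
  enumeration).  A mass-action dimer ↔ tetramer model
  (K_d = [D]²/[T]) predicts how much tetramer *should* be visible at a
  given concentration if the interaction were real.
- **Assays.**  Bead-aggregation image statistics (segment, classify by
  the mean ± 2·sd single-bead rule, aggregation ratio) and TCSPC
  lifetime fits (IRF-convolved multi-exponential, Poisson maximum
  likelihood, amplitude-weighted mean lifetime τ_avg = ΣAₖτₖ/ΣAₖ).

Every pipeline stage is exercisable on synthetic data with known ground
truth; see `docs/methods.md` for the models, defaults and limitations.

## Worked example

Score a known 70/30 dimer/tetramer mixture against a two-state
ensemble, on synthetic data generated by the package itself:

```python
import numpy as np
from oligostate.structure import build_assembly, RigidTransform, radius_of_gyration
from oligostate.synthetic import ToyStructureSpec, make_toy_structure, simulate_saxs
from oligostate.saxs import compute_profile, multistate_fit, tetramer_fraction

spec = ToyStructureSpec(n_chains=2, atoms_per_chain=100, shape="sphere-shell",
                        labeled_sites=(1, 25, 50, 75, 100), seed=2,
                        radius=10.0, separation=24.0)
dimer, _ = make_toy_structure(spec)
dimer_asm = build_assembly(dimer, [RigidTransform.identity()], "dimer")
print(f"dimer Rg: {radius_of_gyration(dimer_asm):.1f} A")

tet = build_assembly(dimer, [RigidTransform.identity(),
                             RigidTransform(np.eye(3), np.array([0., 0., 30.]))],
                     "tetramer")
q = np.linspace(5e-3, 0.3, 250)
ens = {"dimer": compute_profile(dimer_asm, q), "tetramer": compute_profile(tet, q)}
data, truth = simulate_saxs(ens, [0.7, 0.3], seed=11)   # 70/30 mixture, 2% noise
print(multistate_fit(data, ens, max_states=2).summary())
print(f"tetramer fraction at Kd=10 uM, C=919.4 uM: "
      f"{100*tetramer_fraction(10.0, 919.4):.1f}%")
```

prints

```
dimer Rg: 15.6 A
Multi-state SAXS fit
==========================================
  n       chi2  states (weights)
  1    57.4777  dimer:1.000
* 2     0.8484  dimer:0.702, tetramer:0.298
selected n_states = 2
tetramer fraction at Kd=10 uM, C=919.4 uM: 92.9%
```

Reading this: a single dimer state cannot explain the mixed profile
(χ² ≈ 57), the two-state fit recovers the generating 70/30 weights
within 0.005 at χ² ≈ 0.85, and the equilibrium model says that at the
highest concentration of a typical SAXS series (919.4 µM of dimer
units) a K_d of 10 µM would put ≈ 93% of the material into tetramers —
an amount a concentration series could not miss.  A flat Rg across
concentrations plus a vanishing tetramer weight is therefore positive
evidence *against* tetramer formation, not merely absence of evidence.

The same objects drive the cross-link side: `xlms.score_model` ranks
assemblies against `xlms.CrossLink` restraints,
`ensemble.sample_tetramers` / `generate_d2_tetramers` build candidate
tetramers, `structure.cluster_models` groups the top scorers, and
`structure.trans_plausibility` asks whether a candidate's membrane
anchors could face two opposing cells.  A `click` CLI (`oligostate …`)
wraps the common one-shot computations.

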