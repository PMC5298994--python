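# poreperm

Analysis toolkit for connexin hemichannel permeability studies. Connexin
hemichannels are plasma-membrane channels that, when open, pass ions and
small molecules; which fluorescent tracers permeate a given channel — and
which physicochemical features of a molecule predict that — is a central
question when characterizing a new connexin such as Cx39. `poreperm`
bundles the computational side of such a study into a tested, reusable
package:

- **Reference tables** — a 16-dye uptake panel (molecular weight, net
  charge, permeant/non-permeant class, blocker sensitivity) and a
  9-molecule × 11-descriptor matrix, shipped as checksummed package data.
- **Descriptor preprocessing** — removal of non-informative descriptors
  (missing for >1 molecule, or zero for all but one), standardization,
  physicochemical category annotation (electronegativity, ionization
  potential, polarizability, size and geometry, topological flexibility,
  valence), and per-descriptor class-separation reports.
- **Subset selection** — an elitist genetic algorithm over binary
  descriptor subsets (population 5,000; top 1,000 elite; 4,000 offspring
  by single-point crossover; per-bit mutation 10⁻³) whose fitness is the
  number of molecules correctly classified by k-nearest-neighbor
  leave-one-out classification on the selected descriptors. Exposed both
  as functions (`run_ga`, `loo_fitness`) and as sklearn-compatible
  estimators (`GAFeatureSelector`, `SubsetKNNClassifier`).
- **Pore profiling** — fixed-axis pore-radius profiles of channel
  structures from PDB files: at each axial position, the radius of the
  largest axis-centered sphere not overlapping any van der Waals sphere
  (Bondi radii), with hemichannel/gap-junction axial extents of 120/200 Å,
  a 0.5 Å grid and a 16 Å scanning cap.
- **Assay quantification** — junctional conductance
  g_j = −I_b/(V_a − V_b); half-amplitude-threshold idealization of
  single-channel current traces into open/closed dwells; unitary
  conductance histograms and open probability; per-phase dye-uptake
  slopes (AU/min); ratiometric Fura-2 calcium signal F340/F380.
- **Synthetic data** — seeded generators for every input (planted
  descriptor matrices, two-state channel traces, phase-structured uptake
  traces, ring pore geometries with closed-form radius oracles), so the
  full pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from poreperm import (load_descriptor_table, standardize, loo_fitness,
                      run_ga, GAConfig, separation_report)

matrix = load_descriptor_table()          # 9 molecules x 11 descriptors, labelled

rep = separation_report(matrix)["TDB6e"]
print(f"TDB6e: permeant range [{rep.min_permeant}, {rep.max_permeant}], "
      f"non-permeant range [{rep.min_nonpermeant}, {rep.max_nonpermeant}] "
      f"-> {rep.direction}")

z = standardize(matrix)
mask = np.array([n == "TDB6e" for n in z.descriptor_names])
loo = loo_fitness(z, subset=mask, k=1)
print(f"LOO 1-NN on TDB6e alone: {loo.n_correct}/{loo.n_total} correct")

cfg = GAConfig(population_size=500, elite_size=100, offspring_size=400,
               max_generations=30, stall_generations=5, seed=1)
result = run_ga(matrix, cfg)
print(f"GA: best fitness {result.best_fitness}/9 in {result.generations_run} "
      f"generations; selected {result.best_descriptors}")
```

prints

```
TDB6e: permeant range [41.75, 53.62], non-permeant range [40.9, 41.28] -> permeant_higher
LOO 1-NN on TDB6e alone: 9/9 correct
GA: best fitness 9/9 in 6 generations; selected ('VP-6',)
```

The electronegativity descriptor TDB6e alone already separates the two
classes — every permeant dye scores above every non-permeant one — and
1-NN leave-one-out classifies all nine reference molecules correctly from
it. The GA, run at a desk-scale configuration, converges within a few
generations to a perfect-fitness subset; with several descriptors
individually sufficient on this small panel, the parsimony tie-break
settles on a single descriptor (here VP-6, a valence path descriptor that
is lower in permeant dyes).

A command-line interface mirrors the library
(`poreperm prep|classify|select|pore|assay|simulate`), e.g.

```bash
poreperm simulate pore --seed 3 --out rings.pdb
poreperm pore --pdb rings.pdb --channel hc --out profile.tsv
```

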