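# Methods

`poreperm` implements the computational workflow used to characterize the
permeability of connexin-39 (Cx39) hemichannels: which fluorescent tracers
pass through the open channel, which physicochemical descriptors of a
molecule predict that passage, how wide the channel lumen is along its
axis, and how the underlying electrophysiological and imaging measurements
are quantified. This note records the models, parameter choices and known
limitations.

## Descriptor-based permeability classification

### Data model

The unit of analysis is a molecules × descriptors matrix of real-valued
molecular descriptors (PaDEL-style output), with a binary permeability
label per molecule (`permeant` / `non_permeant`). The package ships two
reference tables: a 16-dye uptake panel (10 permeant, 6 non-permeant) and
a 9-molecule × 11-descriptor matrix covering the subset of dyes whose
descriptor values were published. Descriptor computation itself is out of
scope — descriptor tables are ingested, not derived from structures.

### Preprocessing

Non-informative descriptors are removed by two literal rules: a descriptor
missing for more than one molecule is dropped, and a descriptor equal to
zero (exact equality on parsed values) for all molecules but exactly one is
dropped. A descriptor missing for exactly one molecule is kept; the single
missing cell is imputed with the column mean and logged, so KNN distances
remain defined without discarding a usable column. The filter is
idempotent.

Columns are standardized (z-scored with sample statistics, ddof = 1) by
default before any distance computation. Descriptor scales in the reference
table span roughly 0.5 (RotBtFrac) to 1,800 (TDB10i); unscaled Euclidean
distance would be dominated by the largest columns. Scaling statistics are
computed once on the full matrix — the simplest reading, at the cost of a
mild leave-one-out leakage (the held-out molecule contributes to the column
mean/sd it is judged against). At n = 9–16 this bias is small and
conservative in direction for the fitness used here; callers who want
strictly fold-independent scaling can standardize per fold around
`loo_fitness` themselves, and a `--no-scale` path reproduces the raw-value
alternative.

On the reference table, all eleven published descriptors have disjoint
class ranges. Eight (TDB6e, GATS5s, TDB8i, TDB10i, TDB6p, TDB6r, TDB6v,
TDB5u) are higher in permeant dyes, RotBtFrac and VP-6 lower. ATSC5s is a
special case: its permeant range sits *below* the non-permeant range,
driven by the strongly negative values of the sulfonated dyes (Evans blue
−311.14, Procion orange −37.82), so it does not share the permeant-higher
trend of the other electronegativity descriptors. `separation_report`
reports ranges and direction exactly as computed from the data.

### KNN with leave-one-out scoring

Classification restricted to a descriptor subset uses Euclidean distance
over the selected (standardized) columns with majority vote among the k
nearest training molecules. Defaults and tie rules, all deterministic:

- **k = 1.** No value of k is canonical for panels of 9–16 molecules, and
  larger k degenerates rapidly at these sizes; k is a parameter.
- **Distance ties** resolve to the lower molecule index (the stored row
  order), via a stable sort.
- **Vote ties** (possible at even k) resolve to `non_permeant` — the
  conservative call for a permeability assay — configurable via
  `tie_label`.

The leave-one-out score (`loo_fitness`) predicts each molecule from the
remaining n−1 and counts correct predictions; an empty subset scores 0 by
convention. The implementation is validated against a brute-force
enumeration oracle on random small instances and against
scikit-learn's `KNeighborsClassifier` on tie-free data.

A note on invariances: 1-NN predictions on a single descriptor are
invariant to positive affine rescaling of that descriptor (relative
distances are preserved) but *not* to arbitrary strictly increasing
transforms, which preserve ordering, not distance ratios.

### Genetic-algorithm subset search

The GA searches binary genomes of length n_descriptors with the LOO
correct-count as fitness. Per the published protocol: population 5,000;
the top 1,000 genomes pass unaltered to the next generation (elitism); the
remaining 4,000 are produced by drawing parent pairs uniformly with
replacement from that elite, single-point crossover at a uniformly random
cut, and independent per-bit mutation at 10⁻³. The initial population is
the all-ones genome, every singleton, and random genomes at density 0.5.

Decisions where the protocol is silent:

- **Elite ranking ties**: fitness descending, then subset cardinality
  ascending (a mild parsimony pressure), then lexicographic bit order.
  Makes runs fully reproducible from the seed.
- **Termination**: none is published; the run stops at `max_generations`
  (default 200) or once the best genome classifies every molecule
  correctly and has been unchanged for `stall_generations` (default 20)
  generations.
- **Duplicates** are allowed after crossover; uniqueness is only a
  property of how the initial population is described, and enforcing it
  later is ill-defined.
- **Fitness caching** keyed on genome bits: large populations over a
  dozen molecules revisit many identical genomes.

Elitism guarantees the best fitness is monotone non-decreasing; this is
asserted in tests on every run. Tests and the acceptance script use a
desk-scale configuration (population 500 / elite 100 / offspring 400,
≤ 30 generations), which preserves every structural property of the
protocol while converging in seconds on the problem sizes involved; the
published 5,000/1,000/4,000 configuration is the constructor default.

**Selection at small n.** On planted synthetic data (20 molecules, 5
informative columns at 3-sd class separation among 495 N(0,1) noise
columns) the GA reliably reaches a perfect LOO score. Whether the winning
subset contains a *planted* column is itself stochastic: with ~500 noise
columns and only 20 molecules, occasionally a noise column separates the
classes perfectly by chance, and the parsimony tie-break then reports that
singleton. This is a real property of subset selection at these sample
sizes, not an implementation artifact, and is worth remembering when
interpreting any selected descriptor set of this kind.

## Pore-radius profiling

For channels deposited with the permeation pathway along the
crystallographic Z axis, the profile reports, at each axial grid point z,

    r(z) = clamp( min_i ( ‖p(z) − x_i‖ − vdw_i ), 0, r_cap )

— the radius of the largest sphere centered on the fixed axis that
overlaps no atomic van der Waals sphere. This is a fixed-axis variant of
the HOLE analysis (no axis optimization, no slab volume accounting): it is
deterministic, closed-form per sample, and exact on ring geometries, which
is what makes it property-testable. Cavity-detection tools that integrate
free volume per slab can differ slightly in absolute values; published
benchmark radii for real structures (e.g. the ~4.5 Å constriction at the
N-terminal helix of the human Cx26 hemichannel) should be treated as
benchmark targets for that reason, not unit-test values.

Defaults: axial extent 120 Å for a hemichannel and 200 Å for a
gap-junction channel, grid step 0.5 Å, scanning-radius cap 16 Å (grid
points with no atom nearer than the cap report the cap). The default axis
is +Z through the x,y centroid of the alpha-carbons, with the profiled
window centered on the atomic z-range. Van der Waals radii are Bondi
values per element (C 1.70, N 1.55, O 1.52, S 1.80 Å, …), configurable;
unknown elements get 1.70 Å with a warning; hydrogens, absent from
crystal structures, are simply not present. Waters are always excluded,
other heteroatoms optionally.

Verified invariants: exact agreement (≤ 1e−9 Å) with the closed-form
radius on synthetic atom rings; invariance under rigid motion of atoms and
axis together; adding an atom can only decrease the radius at every z.

## Assay quantification

**Junctional conductance.** g_j = −I_b / (V_a − V_b), with I_b the current
in the non-stepped cell (pA) and the potentials in mV, giving nS directly.
Zero transjunctional current at every step — the Cx39 phenotype — yields
g_j = 0; the formula is antisymmetric under swapping cell roles with the
current negated.

**Event idealization.** Two-state traces are idealized by half-amplitude
threshold crossing. The closed and open current levels are estimated by an
iterative two-means (Ridler–Calvard) split of the samples — robust to open
probabilities far from 0.5, where a median-based baseline would land on
the wrong level. A trace whose level separation is under `min_snr`
(default 4) closed-state noise SDs is treated as eventless (a flat trace
returns an empty event list, not an error). States are assigned by
threshold at `threshold_fraction` (default 0.5) of the separation; dwells
shorter than `min_dwell_ms` (default 2 ms, shortest-first) are merged into
their surroundings. Open-event amplitude is the mean of above-threshold
samples in the dwell relative to baseline (a plain mean would be diluted
by merged sub-dwell closures); entry transitions are timed 10–90%. The
idealizer cannot see events in a trace that never visits the closed state:
an always-open recording has no level structure to threshold. Limitations
relative to HMM/Viterbi idealization: no sub-threshold event recovery, a
single conductance class, no missed-event correction.

**Conductance and open probability.** Per open event,
g = amplitude / (V − V_rev) × 1000 (pA/mV → pS), with V_rev = 0 mV by
default (the current reverses at 0 mV for a non-selective channel). The
modal conductance is the center of the tallest histogram bin; bins are
5 pS wide by default — matching the granularity at which unitary
conductances of this channel family are reported — and centered on
multiples of the width so an exact value reports itself. P_o is total open
time over total trace time.

**Dye uptake.** Fluorescence slope per annotated phase by ordinary least
squares over all in-phase samples (no outlier rejection), in AU/min;
phases with fewer than three samples are skipped with a warning.
Fold-change and percent-block helpers compare named phases.

**Calcium signal.** Elementwise Fura-2 ratio F340/F380; invariant under a
common gain; requires strictly positive F380.

## Synthetic data

Every pipeline input has a seeded generator, and each generator satisfies
a closed-loop identity: its noiseless output, fed to the consuming stage,
returns the generating parameters exactly (slopes recovered exactly by
OLS; square-wave dwell times to one sample; ring radii to float
precision).

- **Descriptor matrices**: informative columns N(±effect/2, 1) by class,
  noise columns N(0, 1); optional scattered missing values, missing-heavy
  columns and all-but-one-zero columns for filter tests. Default effect
  size 3 sd — strong but not trivial separation at n ≈ 20.
- **Channel traces**: alternating-renewal two-state chain with
  exponential dwells. The user gives P_o and the mean open dwell (default
  50 ms, the order of magnitude of this channel's slow transitions); the
  mean closed dwell is derived as τ_o(1 − P_o)/P_o so the parameterization
  cannot be over-determined. Open current g·V/1000 pA plus Gaussian noise
  (default σ 0.5 pA at 5 kHz over 40 s, matching the step-protocol
  recording conditions).
- **Uptake traces**: continuous piecewise-linear mean over labelled
  phases, sampled every 0.5 min (the 30-s imaging interval), plus noise.
- **Pore geometries**: rings of pseudo-atoms around the z-axis; at a ring
  plane the profile radius is exactly ring_radius − vdw. Written PDB files
  use generic carbon records (coordinates quantized to 3 decimals by the
  format); exact per-atom radii travel in a JSON sidecar so oracle tests
  bypass the element table.

What the generators do *not* emulate: photobleaching and focus drift in
imaging, capacitive transients and series-resistance artifacts in
recordings, multi-channel superposition, correlated descriptor blocks.
Tests passing on synthetic data therefore demonstrate correctness of the
computations under the stated models, not robustness to every artifact of
real recordings.

## Numerical choices

- Standardization uses ddof = 1; constant columns map to zero with a
  warning rather than raising.
- "Equal to zero" in the descriptor filter is exact equality on parsed
  values, matching how descriptor software emits hard zeros.
- Descriptor CSVs are written with 17 significant digits (the shortest
  exact decimal for a double) and parsed with correctly-rounded float
  conversion, so write→read is bit-exact, property-tested on random
  matrices including NaN placement.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator and the GA are bitwise reproducible from their seed.
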