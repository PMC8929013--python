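# Methods

## Problem and model

Pseudouridine (Ψ) is the most abundant post-transcriptional RNA
modification. The prediction task is binary classification of U-centered
sequence windows: given a fixed-length window (λ = 21 or 31 nt, odd, with
U at position (λ+1)/2), decide whether the central uridine is a
pseudouridylation site. `pseusite` implements a feature-fusion predictor:

1. **Six feature descriptors** map a window to real vectors with exact
   dimensionality contracts (λ = window length):

   | descriptor | content | dimension |
   |---|---|---|
   | ONEHOT | per-position mono- and dinucleotide indicators | 20λ − 16 |
   | KMER | mono-/dinucleotide frequencies (k = 1, 2) | 20 |
   | KD | prefix-normalized running density of the residue at each position | 2λ − 1 |
   | PSEDNC | dinucleotide composition + sequence-order correlation factors | 16 + λ_pse |
   | PSKP | per-position site-vs-nonsite frequency differences | 2λ − 1 |
   | NCP | chemical-property triplets (ring, functional group, H-bond) | 3λ |

2. **Joint feature/hyperparameter selection** by binary particle swarm
   optimization (BPSO) over a hybrid bit-string: an n_features-bit mask
   plus 10 bits indexing a (C, γ) pair on the geometric grid
   2⁻¹⁶ … 2¹⁵ (ratio 2; 32 × 32 = 1024 combinations). Fitness is the
   mean stratified ten-fold CV accuracy of an RBF-SVM on the masked
   columns.

3. **Parallel fusion**: one RBF-SVM base predictor per descriptor,
   trained on its selected subset; predictions fused by majority vote
   over the six hard labels. A serial-fusion baseline (concatenate the
   six masked blocks, retrain one SVM) ships for comparison only.

4. **Sliding-window scanning** applies the fixed-window ensemble at
   every eligible U of an arbitrary-length RNA.

## Encoder details and numerical choices

- One canonical ordering everywhere: nucleotides A, U, C, G;
  dinucleotides lexicographic over that order (AA, AU, AC, AG, UA, …, GG).
- **KD**: the density at position i is the count of the residue observed
  there within the prefix 1..i, divided by i; the same prefix rule is
  applied over dinucleotide positions. The prefix form is the standard
  k-density definition and is what makes the value position-dependent.
- **PSEDNC**: d_k = f_k / (1 + w·Σθ) for the 16 composition components
  (f normalized to sum 1) and d_{16+j} = w·θ_j / (1 + w·Σθ) for the
  correlation tiers, where θ_j averages, over all positions i, the mean
  squared difference of three standardized physicochemical properties
  (free energy, stacking energy, hydrophilicity) between dinucleotides
  i and i+j. The property values ship as a versioned TSV
  (`pseusite/data/dinucleotide_properties.tsv`): the unified
  nearest-neighbour duplex free energies, the Ornstein base-stacking
  energies, and the standard hydrophilicity table of the PseDNC
  literature, transcribed T→U and standardized to zero mean / unit
  variance over the 16 dinucleotides at load. Defaults λ_pse = 2,
  w = 0.1 (both configurable; λ_pse must satisfy λ_pse < λ − 1). All
  components are non-negative and sum to one by construction.
- **PSKP** is label-derived, so the propensity table is always fitted on
  training data only: inside every cross-validation split the table is
  re-fitted from the training fold — including inside the BPSO fitness
  evaluation, where per-fold encoded matrices are prepared once per run
  (the fold partition is fixed per run, so this costs one extra encoding
  pass, not one per particle).
- Inputs are normalized to uppercase RNA with T→U (DNA-alphabet
  benchmark files are common); ambiguity codes are rejected rather than
  imputed because every encoder is defined only over {A,C,G,U}.

## BPSO

Defaults follow the published full-scale search: 80 particles, 300
iterations, velocity clamped to (−6, 6), ten-fold CV fitness, phase
switch at iteration 200. Settings the method's description leaves open
were fixed as follows and exposed in `BpsoConfig`:

- Inertia decreases linearly 0.9 → 0.4 over the run; c1 = c2 = 2.0
  (standard PSO practice).
- Phase 1 is canonical sigmoid-transfer binary PSO: v′ = w·v +
  c1·r1·(pbest − x) + c2·r2·(gbest − x), clamped; bit_i = 1 with
  probability s(v_i) = 1/(1+e^(−v_i)).
- Phase 2 is a convergence accelerator: bit_i adopts the global-best bit
  with probability s(|v_i|) and is kept otherwise. This reproduces the
  intended end-game behavior — the swarm collapses onto the incumbent
  best and stops moving — and the rule is pluggable
  (`BpsoConfig.phase2_update`) so alternatives can be swapped without
  touching the loop.
- Hyperparameter bits decode most-significant-bit first, C block before
  γ block. The choice is arbitrary but frozen; it affects reproducibility
  of a given seed, not reachability (the grid is fully enumerable either
  way).
- An all-zero feature mask has undefined fitness and is repaired by
  setting one uniformly random mask bit.
- One stratified fold partition per run, derived from the run seed, is
  shared by all particles and iterations so fitness values are
  comparable; fitness values are memoized on the exact bit pattern.
- The global-best fitness history is non-decreasing by construction and
  is asserted in tests on every run.

Ensemble training derives one child seed per descriptor from the master
seed, so the six searches are independent but jointly reproducible from
a single integer.

## Evaluation

SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total, MCC =
(TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)), with MCC defined as 0
when any denominator factor vanishes. Cross-validated metrics are pooled
over concatenated out-of-fold predictions rather than averaged per fold
— stable with small folds, and stated so that benchmark-style tables are
comparable. The formulas are hand-implemented (they are part of the
method's contract) and cross-checked against scikit-learn's MCC in the
tests.

`cross_validate_ensemble` holds the six BPSO selections fixed and
re-fits the six SVMs (and the PSKP table) inside each training fold.
Selection itself is not re-run per outer fold: the search's own fitness
is already a cross-validated quantity, and nesting six swarm searches
inside each of ten folds would multiply the cost ~60-fold while leaving
the reported comparison (ensemble vs. its own bases, same protocol)
unbiased.

A 6-voter majority can tie 3–3; the tie is resolved by the sign of the
summed signed margins, falling back to positive at exactly zero —
deterministic and evidence-based rather than a coin flip.

The incremental-feature-selection (IFS) baseline ranks features by the
one-way ANOVA F-statistic (configurable) and evaluates nested prefixes
of the ranking with grid-searched (C, γ) by stratified CV; it is the
greedy comparator to the swarm search.

## Synthetic data

`FixtureSpec` emulates the benchmark structure: balanced U-centered
windows with planted position-specific composition bias. Defaults are
100 + 100 windows of length 21, uniform background, and a 0.6 excess
probability of G at positions 6, 8, 14, 16 — at that strength single
descriptors classify well above chance but below ceiling, so the
ensemble's gain stays measurable. The designated-nucleotide probability
at a signal position is background + excess, with the remaining three
nucleotides renormalized. The center is always U in both classes.

A composition bias (rather than a fixed motif string) gives the
position-sensitive encoders (ONEHOT, NCP, PSKP) and the compositional
ones (KMER, KD, PSEDNC) partially independent signal, which is what
makes the six base predictors heterogeneous and the vote useful.

What the generator does **not** emulate: real pseudouridylation
sequence biology — structural context, motif grammar
(e.g. the H/ACA snoRNA guide duplex), species-specific composition, or
class imbalance. Passing tests demonstrate that the machinery (encoding,
search, fusion, scanning) behaves as specified under controlled signal;
they do not certify accuracy on biological data. Published-scale
accuracy requires the public benchmark datasets and the full search
budget (`scripts/full_benchmark.py`).

Two auxiliary generators serve specific tests: a raw feature matrix
with 10 informative (1 σ class shift) + 90 pure-noise Gaussian columns
(n = 120, balanced, columns shuffled) for selection-recovery
experiments, and long background RNAs with non-overlapping
positive-class windows spliced in at known positions for end-to-end
scanner recovery.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest scales at which the measured properties are
stable across seeds: BPSO recovery uses 20 particles × 30 iterations
(phase switch 20) on the 100-column fixture, 5 seeds; ensemble and
scanner checks use 10 particles × 12 iterations (switch 8) per
descriptor on the n = 200 fixture, 3 seeds; the published-scale defaults
(80 × 300, switch 200) remain the library defaults throughout.

## Known limitations

- The two-phase update rules are this package's own explicit choices
  (canonical sigmoid-transfer BPSO, then the gbest-adoption
  accelerator); other implementations of two-phase binary PSO will
  differ at identical seeds even when the qualitative dynamics —
  phase-1 exploration, phase-2 collapse onto the incumbent best —
  match.
- BPSO with a pure CV-accuracy fitness has no parsimony pressure: it
  typically retains roughly half of all features (a property the method
  shares with its original description). It prunes features only insofar
  as they hurt accuracy.
- Fitness caching assumes the fold partition is fixed per run; do not
  reuse a `FoldData` across label permutations.
- The serial-fusion baseline predictor is evaluation-only; it cannot
  re-encode raw sequences by itself.
- No probability calibration, no kernels other than RBF, no k > 2, and
  no ROC/AUC reporting — all deliberately outside the method's scope.
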