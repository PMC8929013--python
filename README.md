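# pseusite

Pseudouridine (Ψ) site prediction from RNA sequence.

Pseudouridine is the most abundant post-transcriptional RNA modification;
locating Ψ sites matters for understanding RNA structure, stability and
translation, but transcriptome-wide mapping experiments are costly. This
package implements a sequence-based predictor for computational
biologists who want to score candidate sites: given fixed-length
U-centered windows (21 or 31 nt), it classifies the central uridine as
site / non-site, and a sliding-window scanner extends the classifier to
RNAs of arbitrary length.

The method is a feature-fusion ensemble:

- **Six feature descriptors** per window of length λ: one-hot indicators
  (20λ−16 dims), k-mer frequencies for k ∈ {1,2} (20), k-nucleotide
  prefix densities (2λ−1), pseudo dinucleotide composition
  (16 + λ_pse), position-specific k-nucleotide propensities (2λ−1), and
  nucleotide chemical properties (3λ).
- **Binary particle swarm optimization (BPSO)** selects, per descriptor,
  a feature subset *jointly* with SVM hyperparameters: each particle is
  a bit-string of n_features mask bits plus 10 bits indexing (C, γ) on
  the geometric grid 2⁻¹⁶…2¹⁵ (1024 combinations); fitness is ten-fold
  cross-validated accuracy of an RBF-SVM, and the search runs 80
  particles for 300 iterations with a convergence-accelerating update
  after iteration 200.
- **Majority voting** fuses the six per-descriptor RBF-SVMs
  (label 1 ⇔ more than three positive votes; 3–3 ties resolved by the
  summed signed margins).
- Evaluation reports SN, SP, ACC and MCC.

See `docs/methods.md` for the exact formulas, default parameters and
design choices.

## Worked example

Everything below runs on synthetic data generated by the package itself
(no downloads). Generate a 200-window training set with a planted
composition bias, train a scaled-down ensemble, and evaluate it:

```bash
pseusite simulate --n-pos 100 --n-neg 100 --seed 1 --out run/sim
pseusite train --fasta run/sim/windows.fasta --labels run/sim/labels.tsv \
    --particles 10 --iterations 12 --phase-switch 8 --seed 1 --out run/model
pseusite evaluate --model run/model/ensemble.joblib \
    --fasta run/sim/windows.fasta --labels run/sim/labels.tsv --out run/eval
```

The train step prints one line per descriptor — its cross-validated
fitness and selected subset size, e.g.

```
ONEHOT: fitness 0.9200, 203 features
KMER: fitness 0.7900, 11 features
KD: fitness 0.7350, 18 features
PSEDNC: fitness 0.7700, 10 features
PSKP: fitness 0.9400, 24 features
NCP: fitness 0.8900, 25 features
```

(fitness = mean 10-fold CV accuracy of that descriptor's SVM on its
selected features; the position-sensitive descriptors score highest
because the planted signal is positional), and the evaluate step prints
the fused predictor's training-set metrics, e.g.

```
ACC=0.9200 MCC=0.8402 SN=0.9100 SP=0.9300
```

To scan an arbitrary-length RNA for candidate sites:

```bash
pseusite scan --model run/model/ensemble.joblib --fasta my_rna.fasta \
    --bed --out run/scan
```

which writes `site_calls.tsv` (seq_id, 1-based center position, label,
six votes, six margins), a list of U positions too close to the ends to
window, and an optional BED track of positive calls.

The same pipeline is available as a library (`pseusite.generate_dataset`,
`pseusite.train_ensemble`, `pseusite.scan_sequence`, …); the CLI is a
thin wrapper.

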