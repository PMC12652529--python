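# Methods

## The problem

BrdU (5-bromo-2'-deoxyuridine) is a thymidine analog incorporated into
nascent DNA during replication, widely used to map where and when replication
forks run. On Oxford Nanopore R9 flow cells the ionic current at each
position is set by the 5-mer occupying the pore, and BrdU perturbs that
current relative to thymidine — but a standard basecaller still reports it as
T. Detecting BrdU therefore means classifying, for every position basecalled
T, whether the underlying base was really T or BrdU, from the local
resquiggled-signal context.

`nanobrdu` implements that pipeline at desk scale: event-level simulation,
feature engineering, a three-layer bidirectional-GRU (BiGRU) classifier over
the five classes {A, BrdU, C, G, T}, read-level substitution-rate estimation
with bimodal-mixture relabeling, and evaluation. The upstream path on real
data (Dorado basecalling, Minimap2 alignment, MAPQ/length filtering, Tombo
resquiggling, event export) is out of scope here; the package starts from the
event table those tools produce, and the built-in simulator generates tables
with the same structure so every stage is testable without downloads.

## The synthetic pore model and event simulator

A pore model maps each of the 5^5 = 3125 5-mers over {A,C,G,T,B} (B = BrdU)
to an expected normalized current level and spread. Real R9 tables are
proprietary/tabulated; we instead draw the 1024 canonical (B-free) levels
once from a standard normal, reproducibly per seed, and give every
B-containing 5-mer the level of its B→T homolog plus a displacement
`delta * sum(w_i)` over its B positions, with position weights
w = (0.25, 0.25, 1.0, 0.25, 0.25). This keeps the middle base most
informative — matching the classification target — while giving flanking
BrdU a weaker, confounding footprint. Level spreads are drawn uniformly from
[0.05, 0.15] and shared with the homolog, so at `delta = 0` a B-containing
5-mer is *exactly* indistinguishable from its homolog — the basis of the null
control.

Magnitude of `delta`: no quantitative estimate of the BrdU-induced R9 shift
is established, so it is a free simulation parameter. The default 1.5
normalized units represents a strongly detectable analog (comparable to the
between-k-mer level spread); tests also run `delta = 0` as the null.

Per event the simulator draws

* `norm_mean ~ Normal(level_mean of the true centered 5-mer, noise_sd)`,
  with `noise_sd = 0.3` by default — a realistic event-to-event spread for
  Tombo-normalized R9 signal, large enough that single events are ambiguous
  without k-mer context;
* `norm_sd ~ |Normal(level_sd, level_sd/4)|`;
* `dwell ~ 1 + Poisson(dwell_mean - 1)` (dwell is only defined as a count of
  raw samples; a shifted Poisson is the simplest one-parameter positive
  integer law — real dwells are more over-dispersed, which no downstream
  stage depends on).

Reads are uniform-random over ACGT by default. Two structural knobs emulate
real experiment designs: `labeled_fraction` makes only a fraction of reads
receive substitutions at all (the bimodal mixtures of primer-extension
preparations, where renatured plasmid strands carry no BrdU), and `template`
fixes a repeating sequence scaffold with `N` positions drawn at random (the
synthetic 5-mer reference standards, where variable 5-mers sit inside fixed
linker/barcode context). Template linkers used by the standards preset are
T-free so substitution stays confined to the variable 5-mers. Reads are
padded with A at the ends for level lookup; edge events are emitted but never
become window centers.

Basecall errors are off by default (`base_called` = true base with B→T):
the real pipeline filters reads at MAPQ 20/60 so residual error is low. A
uniform `basecall_error_rate` is available for robustness experiments.

What the simulator does *not* emulate: raw current waveforms, resquiggle
misalignment (skips/stays), k-mer-level correlations of real pore chemistry,
homopolymer pathologies, read-length distributions, or base-composition bias.
Passing tests therefore demonstrate that the *method* — features, network,
rate estimator, relabeling logic — behaves correctly on data with the stated
statistical structure, not that a given accuracy will transfer to any real
flow cell.

## Features, labels and windows

Each event is the 7-vector `[f_m, f_d, f_l, f_A, f_C, f_G, f_T]`: normalized
mean, standard deviation, dwell, and the one-hot *basecalled* identity of
that event (per-row identity, not the center's). A training unit is the 5×7
matrix of five consecutive events (offsets −2..+2) with a 5-class one-hot
label `[A, BrdU, C, G, T]` for the true center base when known. Dwell enters
unscaled by default (an optional `log1p` switch exists but is off, matching
the description of the original pipeline). Windows are extracted either at
every interior position (`all` — 5-class data such as standards) or only
where the center is basecalled T (`t` — thymidine candidates, all a
basecaller can offer on genomic data). Reads shorter than five events yield
nothing, mirroring the upstream length filters. Alignment filtering
(MAPQ ≥ 20 & length ≥ 270 for standards, ≥ 60 & ≥ 500 for genomic reads,
optional SAM-flag-0 selection for 2D primer-extension strands) is provided as
a table operation for users bringing their own alignments.

Datasets are shuffled and split 80/10/10 into train/validation/test with
floor arithmetic (`floor(0.8n)`, `floor(0.1n)`, remainder) under a fixed
shuffle seed; the partition is exact.

## The classifier

Three stacked BiGRU layers, 128 units per direction by default. Layers 1–2
return the full 5-step sequence of concatenated forward/backward states
(dimension 256); layer 3 returns the concatenation of the two directions'
final states; a dense layer with softmax yields probabilities over
[A, BrdU, C, G, T]. The GRU convention is

    z = σ(W_z x + U_z h + b_z)
    r = σ(W_r x + U_r h + b_r)
    h~ = tanh(W_h x + U_h (r ⊙ h) + b_h)
    h' = (1 − z) ⊙ h + z ⊙ h~

with the reset gate inside the candidate's recurrent term. The final-state
readout (rather than flattening the full last-layer sequence) is the
standard sequence-to-one choice and keeps the dense layer small.

Everything — forward pass, backpropagation through time, Adam — is
implemented in NumPy float64. This makes training bit-deterministic for a
fixed seed on a single device, a property the test suite asserts directly,
and keeps the package free of deep-learning-framework dependencies.
Initialization is Glorot-uniform (zero biases), seeded. Loss is categorical
cross-entropy (forced by the softmax head); the optimizer is Adam at 1e-3.
Training runs up to 30 epochs (default) with early stopping on validation
loss (default patience 3) and restoration of the best-validation epoch's
weights. Argmax ties on prediction break toward the earlier class in
[A, BrdU, C, G, T].

A practical note on convergence: because the canonical level table is random,
the network must effectively memorize ~1024 k-mer levels from noisy windows.
Validation accuracy typically plateaus near the no-context optimum for
several epochs before breaking through; generous patience (≥ 6–8) matters
more than the epoch cap. With a 1.5-unit shift, held-out T-vs-BrdU accuracy
crosses 0.90 around epoch 12–15 at the default learning rate.

Models persist as a directory: `weights.npz` plus a JSON sidecar carrying the
configuration and training log; loading verifies the 5-timestep (R9) contract
and round-trips forward outputs bit-identically.

## Read-level rates and bimodal relabeling

The read-level BrdU substitution rate is the fraction of a read's thymidine
candidates (windows with basecalled-T centers — truth is unknown on real
data, so the denominator is defined by the basecaller) called BrdU. Reads
with zero candidates are skipped, not assigned rate 0, to avoid deflating
mixture histograms. In mixtures of fully substituted and pristine molecules
the rate distribution is bimodal; reads with rate strictly greater than
12.5% are classified as fully BrdU-labeled and their candidate windows can be
relabeled with BrdU truth to construct positive training data
(`bootstrap_relabel`). The histogram uses 20 equal bins on [0, 1]. A caution
established by analysis here: the relabeling threshold is only reliable when
the window classifier's error rate is well below 12.5% — a symmetric ~9%
error rate pushes unsubstituted reads' rates to ~Binomial(n, 0.09), which
crosses the threshold with non-negligible probability even at 75 candidates
per read.

`OracleWindowClassifier` is an independent reference: it classifies a
candidate window by whichever of the center-T / center-B pore-model levels
lies nearer the observed center mean (flanking-B displacement is deliberately
ignored, costing a little accuracy at high substitution). It calibrates the
rate estimator and mixture recovery without involving the network, so the
learned and analytic routes check each other.

## Evaluation

Binary metrics follow the standard formulas (accuracy, precision,
sensitivity = recall, specificity); metrics with zero denominators are
reported as missing, never coerced. Multiclass precision/recall aggregate
per-class one-vs-rest values support-weighted by default (macro optional) —
the aggregation behind single-number summaries in standard toolkits. AUPRC
is average precision with step interpolation (sum of precision × recall-gain
at each distinct score threshold), not trapezoidal, which avoids optimistic
interpolation; users comparing against PR areas from other tools should mind
the convention.

## The three-model workflow

`run_workflow` reproduces, in kind, the progressive-augmentation story on
simulator presets named for the experimental designs they emulate:

1. **Model I** trains only on standards-like reads (fixed T-free linkers
   around variable 5-mers, 50% substitution, every read labeled). It scores
   well on its own held-out split but loses specificity on foreign
   genomic-context negatives, because cross-linker windows dominate its
   training context — the same restricted-context failure mode seen with
   real 5-mer reference standards.
2. **Model II** adds BrdU-free genomic-like reads (thymidine candidates
   labeled T) and recovers foreign-negative specificity.
3. **Model III** runs Model II over a primer-extension-like bimodal mixture
   (100%-substituted vs pristine molecules), relabels reads above the 12.5%
   threshold as fully BrdU, adds their windows as positives, retrains, and
   gains sensitivity on a 20%-substituted cohort. If no read crosses the
   threshold the training input is unchanged and Model III *is* Model II
   (exact tie, preserving monotonicity honestly).

Desk-scale defaults (300 standards reads, 120 reads per genomic-like set,
64 units, 4 epochs, training capped at 12 000 windows) complete the full
workflow in about a minute and a half on one CPU core while leaving the
qualitative contrasts large; all sizes are plain `RunConfig` fields for
larger runs. One seed derives every stage's seed, and a `manifest.json`
records config, presets and versions sufficient to re-run bit-identically.

## Numerical and degenerate-input choices

* Per-read signal normalization (for un-normalized tables only):
  median-shift, MAD-scale with the 1.4826 normal-consistency factor; zero MAD
  falls back to standard-deviation scaling; constant reads are an error.
* Window extraction demands contiguous positions within a read and errors
  otherwise; sub-5-event reads warn and yield nothing.
* Event tables are UTF-8 TSV with full-precision floats (exact round trip);
  validation errors name the offending line. `true_base` `.` means unknown.
* Softmax is computed with max-subtraction; cross-entropy clips
  probabilities at 1e-12.
* `split_dataset` refuses n < 10; `confusion` refuses unknown symbols.

## Known limitations

* The NumPy implementation targets correctness and determinism, not
  throughput; at the published scale (~800k windows, 30 epochs) a GPU
  framework re-implementation of the same architecture would be the
  practical choice. Published accuracies from A100-scale training on the
  real SRA datasets are not reproducible here and are not claimed.
* The simulator's independence assumptions (noise i.i.d. across events,
  uniform base composition) understate real-data difficulty; conversely its
  random level table slightly overstates the memorization burden.
* R10 chemistry (9-mers) is out of scope; the window length is fixed at 5.
* Barcode decoding for real 5-mer standards, and all FAST5/POD5 parsing,
  are upstream of this package.
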