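# nanobrdu

BrdU basecalling from nanopore resquiggled events with a bidirectional-GRU
classifier — a desk-scale, fully tested implementation of the complete
method: synthetic event simulation, 5-mer feature engineering, a three-layer
BiGRU over {A, BrdU, C, G, T}, read-level substitution-rate estimation with
bimodal relabeling, metrics, and a three-model training workflow.

## The problem

BrdU (5-bromo-2'-deoxyuridine) is a thymidine analog incorporated into
newly synthesized DNA, the workhorse label for tracking DNA replication. On
Oxford Nanopore R9 flow cells the ionic current at each position is set by
the 5-mer of bases in the pore, and BrdU shifts that current — but standard
basecallers report it as T. Detecting BrdU at single-nucleotide resolution
is therefore a classification problem: given the resquiggled signal window
around a position basecalled T, was the base really T or BrdU?

Each event contributes a feature vector
`x_i = [f_m, f_d, f_l, f_A, f_C, f_G, f_T]` (normalized current mean,
standard deviation, dwell, one-hot basecalled identity); five consecutive
events form the 5×7 input of a three-layer BiGRU (128 units per direction)
whose softmax head emits `P(A), P(BrdU), P(C), P(G), P(T)` for the center
base. Per read, the BrdU substitution rate is the fraction of
thymidine-candidate positions called BrdU; thresholding it at 12.5%
classifies whole molecules as fully substituted vs unlabeled — the
relabeling trick that turns mixed primer-extension preparations into
positive training data.

The package is aimed at people building or studying modified-base
basecallers: everything runs from simulated event tables with known ground
truth, so training behavior, rate calibration and the data-augmentation
workflow can be studied quantitatively on one CPU. The network (forward and
backprop) is pure NumPy float64 — no deep-learning framework — which makes
training bit-deterministic under a fixed seed.

## Worked example

```python
import nanobrdu as nb

pore_model = nb.build_pore_model(seed=1, shift_magnitude=1.5)
events = nb.simulate_reads(pore_model, nb.SimConfig(
    n_reads=400, read_length=300, substitution_rate=0.5, seed=2))
windows = nb.extract_windows(events, mode="t")      # thymidine candidates
train, val, test = nb.split_dataset(windows, nb.SplitSpec(shuffle_seed=0))
model = nb.train(train.subset(slice(0, 6000)), val,
                 nb.ModelConfig(units_per_direction=64, max_epochs=4,
                                early_stop_patience=2, train_seed=0))
calls = nb.predict(model, test)
cm = nb.confusion(test.truth, calls["call"])
print(nb.multiclass_summary(cm))
print(nb.binary_metrics(nb.binary_counts(cm, positive="B")))
```

Running `python examples/train_and_evaluate.py` (the same computation)
prints:

```
epoch 0: train_acc=0.664 val_loss=0.5709 val_acc=0.706
epoch 1: train_acc=0.720 val_loss=0.5316 val_acc=0.740
epoch 2: train_acc=0.734 val_loss=0.5110 val_acc=0.757
epoch 3: train_acc=0.761 val_loss=0.4882 val_acc=0.765

held-out windows: 2963
accuracy=0.7587 precision=0.7587 recall=0.7587
BrdU sensitivity=0.7534 specificity=0.7640 AUPRC=0.8383
```

meaning: after four quick epochs on 6 000 windows the network already
separates T from BrdU well above the 0.5 chance level (the BrdU current
shift is learnable from 5-mer context); trained longer on more windows it
crosses 0.95 (see the acceptance run below). The other examples cover
simulation (`simulate_events.py`), read rates and bimodal relabeling
(`read_rates_and_relabeling.py`), and the three-model workflow
(`three_model_workflow.py`).

A thin CLI mirrors the library:

```bash
nanobrdu simulate --n-reads 100 --out events.tsv
nanobrdu featurize --events events.tsv --mode t --out windows.tsv
nanobrdu train --features windows.tsv --out model_dir
nanobrdu predict --model model_dir --features windows.tsv --out calls.tsv
nanobrdu rate --calls calls.tsv --out rates.tsv
nanobrdu pipeline --config run.yaml
```

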