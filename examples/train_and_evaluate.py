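"""Train the BiGRU classifier on simulated windows and evaluate it.

Simulates 400 reads, extracts thymidine-candidate windows (center basecalled
T — the only positions where BrdU can hide), trains a small BiGRU for a few
epochs and prints held-out metrics.  Accuracy well above 0.5 shows the
network has learned the k-mer-dependent BrdU current shift; the AUPRC is the
area under the BrdU precision-recall curve.
"""

import nanobrdu as nb

pore_model = nb.build_pore_model(seed=1, shift_magnitude=1.5)
events = nb.simulate_reads(
    pore_model, nb.SimConfig(n_reads=400, read_length=300, substitution_rate=0.5, seed=2)
)
windows = nb.extract_windows(events, mode="t")
train_set, val_set, test_set = nb.split_dataset(windows, nb.SplitSpec(shuffle_seed=0))
train_set = train_set.subset(slice(0, 6000))

config = nb.ModelConfig(units_per_direction=64, max_epochs=4, early_stop_patience=2,
                        train_seed=0)
model = nb.train(train_set, val_set, config)
for epoch in model.training_log:
    print(f"epoch {epoch['epoch']}: train_acc={epoch['train_acc']:.3f} "
          f"val_loss={epoch['val_loss']:.4f} val_acc={epoch['val_acc']:.3f}")

calls = nb.predict(model, test_set)
cm = nb.confusion(test_set.truth, calls["call"])
summary = nb.multiclass_summary(cm)
binary = nb.binary_metrics(nb.binary_counts(cm, positive="B"))
prc = nb.auprc(calls["p_BrdU"].to_numpy(), test_set.truth == "B")
print(f"\nheld-out windows: {len(test_set)}")
print(f"accuracy={summary['accuracy']:.4f} precision={summary['precision']:.4f} "
      f"recall={summary['recall']:.4f}")
print(f"BrdU sensitivity={binary['sensitivity']:.4f} "
      f"specificity={binary['specificity']:.4f} AUPRC={prc:.4f}")
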