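# connstack

Construction and classification of "RGB-mimicking" functional-connectivity
stacks from ROI time series:

1. **Connectivity estimation** — per-subject Pearson correlation, covariance
   (empirical or Ledoit–Wolf shrunk), and tangent-space embedding relative to
   a group geometric (Karcher) mean of SPD covariances.
2. **Spanning-tree enhancement** — each connectivity matrix becomes a complete
   weighted graph; Kruskal's algorithm (union-find, deterministic tie-break)
   extracts its minimum and maximum spanning trees. The *enhanced* N×N×3 stack
   layers the original matrix (channel 0) with the MaxST layer (channel 1) and
   the MST layer (channel 2). The *plain* stack splits the matrix into three
   row bands that sum back to the original.
3. **Classification** — transfer-learning workflow: frozen convolutional
   backbone → flatten → dropout → single-sigmoid head (binary cross-entropy),
   optional end-to-end fine-tuning at a much lower learning rate, evaluated by
   stratified 10-fold cross-validation with the confusion-count accuracy
   (TP+TN)/(TP+TN+FP+FN).

A synthetic-cohort generator (`connstack.synthio`) draws zero-mean Gaussian
ROI time series with planted over-/under-connected edges, so the full pipeline
is testable offline.

## Backbones

The registry describes the exact spatial down-sampling chain of seven classic
ImageNet architectures (VGG16/19, ResNet50, ResNet152V2, InceptionV3,
InceptionResNetV2, Xception), so final feature-map geometry is computed
without weights (`connstack.cnnclf.feature_geometry`). Pretrained ImageNet
weights cannot be shipped or downloaded in this environment, so actual
training uses **TinyConv**, a small randomly initialized 3-block conv-pool
surrogate implemented on pure-numpy layers with full backprop; it exercises
the identical two-phase transfer contract (frozen feature extraction, then
fine-tuning).

## CLI

```bash
connstack simulate --n-per-group 100 --rois 30 --timepoints 150 --effect 0.3 \
    --seed 0 --out-dir data/cohort
connstack connect --method correlation --in-dir data/cohort --out-dir data/cm
connstack stack --strategy enhanced --method correlation \
    --in-dir data/cm --out-dir data/stacks
connstack train --backbone TinyConv --method correlation --strategy enhanced \
    --folds 10 --seed 0 --in-dir data/cohort --out report.json
connstack grid     # prints the 126-tuple experiment grid
```

`connect --method tangent` accepts `--fit-ids <file>` to restrict the group
reference fit (e.g. to training-fold subjects). `stack` accepts
`--absolute/--signed` to extract trees on weight magnitudes instead of signed
values. `train --config config.yaml` overrides schedule hyperparameters
(`lr_head`, `lr_finetune`, `epochs_head`, `epochs_finetune`, `patience`,
`batch_size`, `dropout_rate`).

## Layout

| module | contents |
|---|---|
| `connstack.synthio` | cohort specs, Gaussian simulator, toy graph fixture |
| `connstack.tsio` | `.1D`-style time-series reader, phenotype CSV, HDF5 stack I/O |
| `connstack.connectivity` | correlation / covariance / tangent estimators |
| `connstack.enhance` | graphs, Kruskal trees, enhanced & plain stacks |
| `connstack.cnnclf` | numpy NN kernels, backbone registry, training, cross-validation |
| `connstack.pipeline` | experiment grid, cached end-to-end runs |
| `connstack.cli` | `connstack` command group |
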