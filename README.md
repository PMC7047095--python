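# srna-augment

Metadata augmentation for small-RNA expression profiles: predict missing
sample annotations (tissue group, sex, age interval) from an sRNA count
matrix with a dense neural network or a two-stage random forest, validate
with fivefold cross-validation or one-dataset-out splits, and explain the
network's decisions with DeepLIFT (Rescale rule) attribution — including
class-average difference scores (D1), top-N marker lists, per-rival score
differences (D2) and an ablation-until-flip class-stability analysis.

A synthetic cohort simulator (negative-binomial counts, planted class
markers, per-dataset batch shifts, weak sex/age signal, zero inflation)
makes the whole pipeline testable without any external data.

## Layout

| module | contents |
|---|---|
| `srna_augment.simulate` | synthetic cohort generator + ground truth |
| `srna_augment.preprocess` | TSV I/O, RPM, >30%-zeros filter, min-max scaling, tissue-ontology grouping, age binning, small-class filter |
| `srna_augment.classify_dl` | numpy dense net (1000/250/250 hidden, dropout 0.5/0.4/0.4, Adam, 50 epochs, batch 30) with exposed per-layer pre-activations |
| `srna_augment.classify_rf` | two-stage forest: 100 trees → Gini top-1000 → 500 trees, mtry = ⌊√p⌋, per-stage class downsampling |
| `srna_augment.validate` | stratified k-fold and one-dataset-out splits (class-retention rule), confusion/precision/accuracy reports |
| `srna_augment.explain` | DeepLIFT Rescale attribution (zero reference, pre-softmax target), D1/top-N/D2, ablation-until-flip stability & similarity matrices |
| `srna_augment.cli` | `srna-augment` command with `simulate / preprocess / train / evaluate / explain / stability` subcommands |

## CLI

```bash
# generate a synthetic cohort
srna-augment simulate --out cohort/ --seed 7

# cross-validated evaluation of the dense net on tissue labels
srna-augment evaluate --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --target tissue --model dl --validation cv5 --min-class-size 9 \
    --seed 7 --out results/

# one-dataset-out with the two-stage random forest
srna-augment evaluate --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --target tissue --model rf --validation one_dataset_out --seed 7 --out results_odo/

# train on everything, then explain and run the stability analysis
srna-augment train    --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --target tissue --model dl --seed 7 --out model/
srna-augment explain  --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --target tissue --model-dir model/ --top-n 300 --out explain/
srna-augment stability --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --target tissue --model-dir model/ --out stability/
```

All inputs and reports are TSV; every command writes a `manifest.json`
(config echo, seed, library versions, input checksums). By default the
min-max scaler is fitted on the training split of each evaluation fold;
`--paper-faithful` fits it on the full matrix instead.

Targets: `--target tissue` groups labels through the packaged
tissue-ontology table (`srna_augment/data/tissue_groups.tsv`);
`--target age --age-bins {2,3,4}` discretizes ages into the packaged
interval schemes ([0;65](65;110] etc.); `--feature-set {srna,contaminant,both}`
selects the feature block.

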