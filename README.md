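# lgfc

Prediction of lncRNA–protein interactions from multiple feature views: raw
sequence composition (global and local one-hot encodings), handcrafted
composition features, and secondary-structure/propensity tracks unified by a
cosine-series (Fourier) reduction — classified by a four-branch convolutional
neural network, with a similarity-ranked negative-sampling strategy and a
full evaluation suite. Everything runs on synthetic data; no downloads.

## Layout

| module | what it does |
|---|---|
| `lgfc.io_data` | FASTA / pair-table IO, 200-nt lncRNA filter, dataset assembly, stratified 70/15/15 splits |
| `lgfc.sequence_encoding` | fixed-length global one-hot matrices (4×L RNA, 7×L reduced protein) and multi-channel windowed tensors |
| `lgfc.handcrafted_features` | RED (coding-potential descriptors), DNC, RNA 3-mer, AAC, grouped protein 3/4-mers; A1/A2 assembly; plug-in encoder registry |
| `lgfc.structure_features` | Nussinov folding (ViennaRNA pluggable), propensity tracks, 10-term cosine reduction → B1 (30) / B2 (50) |
| `lgfc.negative_sampling` | all-vs-all global-alignment protein similarity, per-lncRNA candidate ranking, 20%/80% two-half negative drawing |
| `lgfc.model_cnn` | the four-branch classifier (GloCNN/LocCNN/FC/SS) implemented in pure NumPy with manual backprop + Adam; train/predict/ablate/persist |
| `lgfc.evaluation` | ACC/MCC/F1/SN/SP/PPV, ROC/PR areas, random-forest feature-combination ranking |
| `lgfc.synthetic_fixtures` | seeded synthetic datasets with a plantable, recoverable signal; the `worked_toy()` mini-dataset |
| `lgfc.pipeline` | dataset → model-input arrays; end-to-end `signal_recovery_auroc` |

The neural network is implemented directly in NumPy (no deep-learning
framework dependency); training is bit-deterministic for a fixed seed.

## CLI

```bash
lgfc fixtures --seed 1 --n-pairs 400 --out fx/           # synthetic data
lgfc build-dataset --pos fx/pairs.tsv --lnc fx/lnc.fa --prot fx/prot.fa \
     --min-lnc-len 200 --out ds/
lgfc make-negatives --pos pos.tsv --prot ds/prot.fa --low-frac 0.2 \
     --seed 42 --out neg.tsv
lgfc encode    --lnc ds/lnc.fa --prot ds/prot.fa --pairs ds/pairs.tsv --out enc.npz
lgfc featurize --lnc ds/lnc.fa --prot ds/prot.fa --pairs ds/pairs.tsv --out feats.tsv
lgfc structure --lnc ds/lnc.fa --prot ds/prot.fa --pairs ds/pairs.tsv --out struct.tsv
lgfc train     --lnc ds/lnc.fa --prot ds/prot.fa --pairs ds/pairs.tsv \
     --seed 1 --out model/
lgfc predict   --model model/ --lnc ds/lnc.fa --prot ds/prot.fa \
     --pairs ds/pairs.tsv --out scores.tsv
lgfc evaluate  --scores scores.tsv --labels ds/pairs.tsv --out report.json
```

## Notes

* k-mer frequency denominators follow the source formulas literally
  (sequence length N, not N−k+1); the DNC divides by N−1.
* The default folding engine maximizes base pairs (Watson–Crick + GU,
  hairpin ≥ 3) rather than free energy; pass `engine="vienna"` to use
  ViennaRNA's MFE fold when its Python bindings are installed.
* The RNA hydrogen-bond/van-der-Waals propensity tables ship as editable
  TSVs under `src/lgfc/data/` (see the `#source:` headers) and can be
  overridden via `structure_features.read_scale`.
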