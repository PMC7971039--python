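# aptapred

Aptamer–protein interaction (API) prediction from sequence alone. The
pipeline encodes aptamers as cumulative k-mer / reverse-complement
canonical k-mer window frequencies and proteins as AAC / PseAAC vectors
over triples of physicochemical properties, cleans majority-class noise
with the neighborhood cleaning rule (ENN-based), ranks features with a
random forest, and classifies pairs with a seven-layer MLP (ReLU hidden
layers, dropout, sigmoid output, RMSprop on binary cross-entropy),
evaluated by stratified fivefold cross-validation.

## Layout

| module | contents |
| --- | --- |
| `aptapred.seqio` | FASTA / pair-table I/O, sequence validation, RNA→DNA conversion |
| `aptapred.aptamer` | `kmer_vector`, `revc_kmer_vector`, canonical k-mer counting |
| `aptapred.protein` | AAC, property standardization, PseAAC, `build_feature_matrix`, packaged 24-property table |
| `aptapred.balancing` | ENN mask, NCL resampling, seeded random undersampling |
| `aptapred.selection` | random-forest importance ranking, top-N column filter |
| `aptapred.model` | numpy MLP (+ serialization) and the four baseline classifiers |
| `aptapred.evaluation` | confusion metrics (incl. MCC), ROC/AUC, stratified CV of a full pipeline |
| `aptapred.synthetic` | seeded generators with planted motif / composition signal |
| `aptapred.cli` | `aptapred` command-line interface |

Key defaults follow the published configuration: k ≤ 3 (or 4) k-mer
blocks, PseAAC λ = 30 and ω = 0.05 (50 features per property group),
NCL with 3 nearest neighbors, random-forest selection with 300 trees of
depth 9 keeping the top 193 features, MLP learning rate 0.00014, batch
size 5000 (capped at the dataset size) and 260 epochs.

## CLI

```bash
aptapred simulate --preset strong --out sim/          # synthetic FASTA + pairs
aptapred encode --aptamers sim/aptamers.fasta --proteins sim/proteins.fasta \
                --pairs sim/pairs.csv --kmax 3 --groups ABCDEFGH --out features.csv
aptapred balance --features features.csv --method ncl --out balanced.csv
aptapred select --features balanced.csv --top 193 --out selected.csv
aptapred train --features selected.csv --model-out model.npz
aptapred evaluate --features features.csv --folds 5 --report report.json
aptapred run --config config.yaml --out results/     # all stages end to end
```

`run` accepts a YAML config (see `aptapred.cli.DEFAULT_CONFIG` for the
schema); every artifact records a hash of the resolved configuration.

## Notes

- The packaged amino-acid property table (`aptapred/data/properties.csv`,
  24 properties × 20 residues, grouped A–H in triples) is replaceable via
  `load_property_table(properties_csv, groups_csv)`.
- Published sources disagree on the k = 4 encoder widths (339/179); the
  closed forms give 340/180, which is what the encoders produce.
- Feature selection documentation also mentions nine-tree forests; the
  explicit parameter listing (300 trees, depth 9) is used.
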