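# vhfold

End-to-end backbone structure prediction and repertoire-scale structural
analysis for antibody heavy-chain variable domains (VH), nanobodies (VHH)
and TCR Vβ domains.

Homology-free modelling of these ~110–130-residue domains is dominated by
the three hypervariable CDR loops — CDR3 above all — sitting on a rigid,
highly conserved β-sandwich frame. `vhfold` exploits that conservation:
every training structure is superposed onto one reference structure by its
frame Cα atoms, and a convolutional network then regresses the coordinate
matrix directly from sequence,

  x ∈ {0,1}^(140×22)  →  ŷ ∈ ℝ^(140×15),

where the 22 input channels one-hot encode the residues (plus unknown and
insertion/padding channels) and the 15 outputs per position are the N, Cα,
C, O, Cβ coordinate triples in the shared reference frame. The network is a
pair of 1-D ResNets (kernel 25, then kernel 5 with dilations 1, 2, 4, 8, 16;
~2M parameters at the default widths) trained with Adam on the loss

  L(y, ŷ) = MSE(y, ŷ) + Σᵢ (d(Cαᵢ, Cαᵢ₊₁) − 3.8 Å)²,

the mean squared atom displacement (the squared RMSD in the common frame)
plus a chain-continuity term pulling consecutive Cα atoms toward ideal
peptide spacing. Because predictions land in a common frame, repertoire-scale
structural comparison needs no superposition: the structural distance

  d(V, W) = 1 − #(Cα pairs within 1 Å) / min(|V|, |W|)

feeds k-medoids clustering, which is compared with a 2,646-dimensional
canonical sequence embedding (126 Chothia-style positions × 21 symbols)
projected by t-SNE.

The package implements the full pipeline: PDB/FASTA I/O, Chothia region
assignment, Kabsch superposition and frame-fit region RMSD evaluation,
dataset encoding and identity-based splitting, the network and its training
loop (pure numpy, exactly reproducible), transfer retraining for small
datasets such as TCRs, CAPRI-style docking metrics, repertoire clustering —
and a synthetic structure-family generator so everything is testable without
downloading a single structure.

Who it is for: computational immunologists modelling nanobody/VH repertoires
at scale, and method developers who want a small, fully inspectable
coordinate-regression baseline with a deterministic benchmark.

## Worked example

Train a reduced-width model on a synthetic 4-family benchmark, evaluate
held-out structures, and cluster the repertoire:

```python
from vhfold.synthetic_data import FamilyConfig, generate_family, records_to_examples
from vhfold.model_core import ModelConfig, build_model, predict_coords, prediction_to_structure
from vhfold.training import TrainConfig, train
from vhfold.evaluation import evaluate_pair, aggregate, format_table
from vhfold.repertoire import distance_matrix, k_medoids, concordance

cfg = FamilyConfig(n_structures=120, n_families=4, noise_sd=0.1,
                   conformation_rule_seed=0, global_seed=1)
records = generate_family(cfg)
examples = records_to_examples(records)          # aligned to one reference
train_ex, test_ex = examples[:100], examples[100:]

model = build_model(ModelConfig.small(seed=0))
model, history = train(model, train_ex, test_ex,
                       TrainConfig(seed=0, ca_average=True), max_epochs=20)
print(f"best validation loss: {history['val_loss'].min():.2f} A^2")

evals = []
for rec, ex in zip(records[100:], test_ex):
    pred = predict_coords(model, ex.input)
    struct = prediction_to_structure(pred, rec.sequence, source_id=rec.record_id)
    evals.append(evaluate_pair(struct, rec.structure))
print(format_table(aggregate(evals)))

matrix = distance_matrix([r.structure for r in records],
                         [r.record_id for r in records])
clusters = k_medoids(matrix, k=4, seed=0)
print(f"ARI: {concordance(clusters, {r.record_id: r.family for r in records}):.2f}")
```

Output:

```
best validation loss: 6.46 A^2
region	mean±sd	median	n
whole_domain	2.14±0.18	2.12	20
frame	1.82±0.14	1.80	20
cdr1	3.62±0.57	3.78	20
cdr2	3.37±0.45	3.49	20
cdr3	3.12±0.66	2.98	20

ARI: 1.00
```

Reading it: after only 20 epochs on 100 examples, held-out domains are
predicted to ~2.1 Å mean whole-domain backbone RMSD; frame accuracy (1.8 Å)
exceeds loop accuracy, and CDR loops measured in the frame superposition sit
near 3 Å — the same qualitative profile variable-domain predictors show on
experimental data (training to 30 epochs on the full 200-example benchmark
brings the whole-domain mean under 1.5 Å; see `tests/test_acceptance.py`).
The adjusted Rand index of 1.00 means structural k-medoids clusters of the
predicted-frame structures recover the four planted sequence families
exactly.

The same pipeline is available from the shell:

```bash
vhfold make-benchmark --out-dir bench --n-structures 200 --n-families 4 --seed 0
vhfold train --train-manifest bench/train_manifest.tsv \
             --val-manifest bench/validation_manifest.tsv \
             --checkpoint model.npz --small --epochs 30
vhfold predict --checkpoint model.npz --fasta bench/sequences.fasta --out-dir models
vhfold evaluate --model-dir models --reference-manifest bench/test_manifest.tsv --out report.tsv
vhfold cluster --model-dir models --fasta bench/sequences.fasta --out-dir clusters --k 12
```

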