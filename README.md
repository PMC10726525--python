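# gpdrp

Multimodal drug-response prediction: drugs as molecular graphs, cell lines
as pathway-activity-score vectors, regressed onto scaled LN IC50.

Predicting how sensitive a cancer cell line is to a compound (LN IC50 —
lower means more sensitive) is a core task in computational pharmacology
and personalised oncology. `gpdrp` implements a graph-neural-network
regressor for this task:

* **Drug branch** — the SMILES string becomes a heavy-atom graph whose
  nodes carry a 78-dimensional binary feature vector (element, degree,
  attached hydrogens, implicit valence, aromaticity). Four encoders are
  available — GCN (`H' = σ(D̃^{-1/2}ÃD̃^{-1/2}HW)`), GAT (softmax
  neighbourhood attention, 10 heads), GIN (`MLP((1+μ)x_i + Σ_{j∈N(i)}x_j)`
  with batch norm), and the default hybrid of two GIN layers with one
  Graph-Transformer layer using Laplacian eigenvector positional
  encodings. Each ends in global max pooling and a 128-dim projection.
* **Cell-line branch** — pathway activity scores (GSVA-style, min–max
  normalised per pathway) through a dense 512 → 1024 → dropout(0.2) → 128
  network.
* **Fusion** — the 256-dim concatenation passes through FC layers of 1024
  and 128 units to a single (0, 1) output on the scale of the transformed
  response `ŷ = 1/(1 + e^{-0.1·x})`, with the exact inverse used to report
  LN IC50.

Training minimises MSE with Adam under a **cell-line-grouped** 80/10/10
split (no cell line is shared between train, validation and test), with
early stopping on validation RMSE. Metrics are RMSE and Pearson r.

The neural-network core (reverse-mode autodiff, graph message passing,
Adam) is implemented in NumPy in `gpdrp.nn`; RDKit handles chemistry,
pandas/SciPy/scikit-learn handle tables, clustering and metrics.

A synthetic-data module generates chemically valid drug panels
(scaffold decoration), bounded low-rank pathway-score matrices,
planted-signal response tables with a known linear oracle, and a 54-sample
xenograft-style fixture with a planted 3-cluster structure — so the entire
pipeline is testable without external downloads.

## Worked example

```python
import numpy as np
from gpdrp import (
    AtomFeatureSchema, GPDRP, ModelConfig, EncoderConfig,
    SyntheticSpec, generate_dataset, minmax_normalize, split_by_cellline,
)
from gpdrp.response_scaling import ResponseTable

# a synthetic screen: 20 drugs x 30 cell lines x 50 pathways
spec = SyntheticSpec(n_drugs=20, n_cell_lines=30, n_pathways=50, seed=3)
drugs, raw_scores, responses, truth = generate_dataset(spec)

split = split_by_cellline(raw_scores.cell_line_ids, seed=3)
stats = minmax_normalize(raw_scores.subset_cell_lines(split.cell_lines("train"))).norm_stats
scores = minmax_normalize(raw_scores, stats=stats)   # leak-free normalisation

cfg = ModelConfig(encoder=EncoderConfig(variant="GIN_TRANSFORMER"),
                  learning_rate=1e-3, batch_size=128, max_epochs=15, patience=10, seed=3)
model = GPDRP(cfg, AtomFeatureSchema(), scores.pathway_ids)
model.fit(drugs, scores, responses, split)

test_cells = set(split.cell_lines("test"))
keep = responses.records["cell_line_id"].isin(test_cells)
report = model.evaluate(drugs, scores,
                        ResponseTable(responses.records[keep].reset_index(drop=True)))
print(f"test RMSE {report.rmse:.4f}  PCC {report.pccs:.4f}  ({report.n_pairs} pairs)")
```

Output:

```
test RMSE 0.0262  PCC 0.8224  (51 pairs)
```

The model recovers most of the planted drug × cell-line signal on cell
lines it has never seen: held-out Pearson r of 0.82 against a ceiling of
0.96 for a least-squares oracle that reads the planted features directly,
with RMSE on the (0, 1) response scale.

The same workflow is available from the shell:

```bash
gpdrp simulate --out data --seed 3
gpdrp train --drugs data/drugs.csv --pathways data/scores.csv \
            --responses data/responses.csv --out run
gpdrp predict --checkpoint run/checkpoint --drugs data/drugs.csv \
              --pathways data/scores.csv --pairs pairs.csv --out pred.csv
gpdrp analyze --pred pred_matrix.csv --scores data/scores.csv \
              --pathway-set proliferation.txt --k 3 --out analysis
```

`gpdrp analyze` ranks drugs by median predicted LN IC50, clusters samples
by Euclidean distance on Z-scored predictions (cluster 1 = most resistant),
and summarises a chosen pathway subset per cluster.

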