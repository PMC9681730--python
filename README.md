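# protacdeg

Structure-based prediction of PROTAC degradation capacity.

PROTACs (proteolysis-targeting chimeras) are heterobifunctional molecules —
a warhead that binds a protein of interest (POI), a linker, and a ligand
that recruits an E3 ubiquitin ligase — that degrade their target through
the ubiquitin–proteasome system. Whether a given PROTAC actually degrades
its target depends on the whole POI–PROTAC–E3 system, and measuring it
(DC₅₀, the half-maximal degradation concentration, and Dmax, the maximal
degradation) is slow and expensive. `protacdeg` is a library and CLI for
medicinal-chemistry and machine-learning practitioners that predicts a
binary degradation label from structure:

* **Featurization** — extract the ligand-binding pocket (all residues with
  a heavy atom within 5 Å of the bound ligand) from PDB/Mol2 complexes;
  build typed molecular graphs (atom-type node codes, bond-type edge codes
  including aromatic and amide) for pockets, warheads and E3 ligands;
  tokenize linker SMILES per character against a frequency-ranked
  39-character table (PAD = 0, out-of-vocabulary = 40).
* **Model** — five parallel branches (POI pocket, warhead, linker,
  E3 ligand, E3 pocket), each emitting a 64-vector: two-layer graph
  convolutions (64→128→64, symmetric-normalized adjacency with self-loops,
  learned bond-type messages, max-pool readout) for graphs, and
  embedding → BiLSTM(64/direction) → FC for the linker. Pocket branches
  share weights, ligand branches share weights. The concatenated 320-vector
  feeds a two-layer MLP to two logits. Labeling rule for training data:
  active iff DC₅₀ < 100 nM and Dmax > 80 % (strict).
* **Protocols** — random 8:1:1 / 8:2 splits, under-/over-sampling and 2×
  weighted loss for class imbalance, the 8-configuration branch-ablation
  suite, leave-one-target-out generalization, mean ± SD over repeated
  seeds, paired t-tests.
* **Baselines** — linear SVM (C=1) and random forest (100 trees, depth 5)
  on ternary-complex features: ACC(POI) ⊕ ACC(E3) ⊕ MACCS/Morgan
  fingerprint of the assembled PROTAC (18+18+166 or 18+18+1024).
* **Synthetic data** — a generator that emulates the full data regime
  (pockets, scaffolds, alkyl/PEG linkers, planted activity rules, the
  ~1:2 active:inactive cohort ratio) so every stage is testable offline.

The network is implemented in NumPy with an internal reverse-mode autodiff
(gradients verified against finite differences in the test suite); no
deep-learning framework is required. See `docs/methods.md` for the full
model description and its assumptions.

## Worked example

Generate a synthetic dataset whose activity is planted in the linker
(active iff the linker has 6–12 heavy atoms), train the five-branch model,
and evaluate:

```bash
protacdeg simulate --out runs/demo --n-records 120 --seed 3
protacdeg train --manifest runs/demo/manifest.csv --out runs/demo_train \
    --seed 3 --split 8:1:1 --epochs 10
```

which prints (exact numbers for this seed):

```
test accuracy 83.33% AUROC 0.9259259259259258
```

i.e. after only 10 epochs on 96 training records the model already ranks
actives above inactives on the 12-record test split with AUROC ≈ 0.93 and
calls 10/12 labels correctly at the 0.5 threshold; the default 30-epoch
regime on more data drives this to ≈ 1 (see the acceptance script below).
The run directory holds `checkpoint.npz` (+ JSON sidecar with config,
seed and parameter checksum), `metrics.json`, `split_ids.json` and a
config snapshot, so the run is fully reconstructable.

The same library surface in Python:

```python
from protacdeg import (SynthSpec, generate_dataset, read_manifest,
                       apply_labels, prepare_samples, ModelConfig,
                       TrainConfig, train, evaluate, split, SplitSpec)

manifest = generate_dataset(SynthSpec(n_records=120, seed=3), "runs/demo")
records = apply_labels(read_manifest(manifest))
samples = prepare_samples(records, "runs/demo")
tr, te = split(samples, SplitSpec((0.8, 0.2), seed=3))
params, history = train(ModelConfig(), tr, None, TrainConfig(seed=3))
print(evaluate(params, te))
```

Other subcommands: `featurize` (serialize graph/token caches), `evaluate`,
`predict`, `ablate` (the 8-item suite), `baseline --fp {maccs,morgan}`,
`loto --target <POI>`.

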