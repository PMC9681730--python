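# Methods

## Problem and model

A PROTAC degrades its target protein (POI) only if the whole
POI–PROTAC–E3 system cooperates: the warhead must engage the POI pocket,
the E3 ligand must engage the E3-ligase pocket, and the linker must allow a
productive ternary complex. `protacdeg` casts degradation capacity as
binary classification over five structure-derived inputs:

| branch | input | encoder |
|---|---|---|
| POI pocket | typed graph, 5-element vocabulary | 2-layer GCN, shared pocket weights |
| warhead | typed graph, 10-element vocabulary | 2-layer GCN, shared ligand weights |
| linker | SMILES character tokens | embedding → BiLSTM(64/direction) → FC |
| E3 ligand | typed graph, 10-element vocabulary | shared with warhead |
| E3 pocket | typed graph, 5-element vocabulary | shared with POI pocket |

Each branch emits a 64-vector; the concatenation (320 when all five
branches are active) feeds a two-layer MLP (64 hidden units, Leaky ReLU,
2 logits). Probabilities come from the softmax of the logits; a record is
called active when `P(active) > 0.5`, with the tie resolved to inactive.

### Pocket extraction

The pocket is every complete residue having at least one heavy atom within
5.0 Å (closed boundary) of any ligand heavy atom — the residue-level
"byres … around" selection of molecular viewers. Hydrogens are parsed but
excluded from distance tests and graphs (crystal-derived structures
typically lack them, and the node vocabulary has no hydrogen code).
Ligand atoms never enter the pocket graph: the pocket branch encodes
protein environment only. Waters, common ions and altLoc entries other
than ''/'A' are dropped at parse time. Coordinates are used as-is; no
minimization or protonation is attempted.

### Graphs

Nodes are heavy atoms coded C/N/O/S/other → 0–4 for pockets and
C/N/O/S/F/Cl/Br/I/P/other → 0–9 for small molecules. Edges are covalent
bonds typed single/double/triple/aromatic/amide → 1–5; TRIPOS Mol2 bond
records are trusted as-is (including `am`), and for SMILES-derived
molecules the amide label is assigned to the C–N bond of any C(=O)N group,
taking precedence over single. Graphs are undirected (each bond stored in
both directions) with no stereochemistry and no 3-D coordinates.

The graph convolution uses the symmetrically normalized adjacency with
self-loops, `D^{-1/2}(A+I)D^{-1/2}`. Bond types enter as a learned
per-edge-type embedding added to the neighbor messages with the same
normalization coefficient — the mechanism is our choice; only *that* bond
types are encoded is fixed by the architecture contract. The readout is a
node-wise feature maximum (mean/sum are configurable alternatives).
Node features start from a learned 64-wide embedding of the integer code,
not a one-hot vector.

### Linker tokenization

SMILES are tokenized per character; two-character element symbols such as
`Cl` are deliberately two tokens, mirroring how the character-frequency
table is defined. The 39 most frequent characters of a reference corpus
receive codes 1–39 (frequency ties broken by Unicode code point, making
the table order-invariant and deterministic); padding is 0 and every other
character is 40. Sequences are right-padded/truncated to `max_len`
(default 100; far above any linker in practice). The default table is
built from a deterministic synthetic lead-like corpus
(`synthdata.smiles_corpus`, 2 000 assemblies plus a fixed tail of
rare-character molecules); it is a stand-in, and any table can be supplied
as JSON `{char: code}`.

The linker branch embeds tokens (64-wide), runs a bidirectional LSTM with
64 hidden units per direction, concatenates the two final hidden states
(128) and maps them through a fully connected layer to 64. An empty
(all-pad) linker yields the zero recurrent state through the FC layer — a
well-defined vector, which is what the linker-ablation protocol relies on.

### Weight sharing

The two pocket branches reference one parameter set, and the two ligand
branches reference another; sharing is by object identity, so gradient
contributions from both branches accumulate into the same arrays and the
"two" branches remain bitwise identical after any number of updates.
Pocket and ligand embeddings are *not* shared with each other (different
vocabularies).

## Training

Adam (lr 1e-4, β₁ 0.9, β₂ 0.999), cross-entropy over the two logits,
batch size 1 for exactly 30 epochs, with sample order reshuffled per epoch
under the run seed. For batch sizes ≠ 1 the epoch count is instead chosen
by validation loss (patience 5, cap 300 epochs) and the best-validation
parameters are restored. Class imbalance can be addressed by
undersampling (inactives down to the active count), oversampling (actives
resampled with replacement up to the inactive count; the training loop can
assert the resulting 1:1 ratio), or a weighted loss that multiplies the
active-class loss by exactly 2. No dropout or other regularization is
used. The network is small enough that everything runs on one CPU; the
implementation is NumPy with an internal reverse-mode autodiff tape whose
gradients are finite-difference-checked in the test suite.

## Labeling, splits, protocols

A record is an **active** degrader iff DC₅₀ < 100 nM **and**
Dmax > 80 % — strict inequalities, so equality at a cutoff is inactive,
and a missing measurement is inactive. A relaxed scheme (1000 nM / 70 %)
is provided. Range-valued entries such as "<10 nM" resolve to the bound,
logged per record; when multiple measurements exist upstream, we expect
the manifest to carry the most potent pair.

Splits are plain uniform random permutations sliced by ratio (floor each
partition, remainder to the first; 8:1:1 and 8:2 presets), deliberately
unstratified. The ablation suite retrains from scratch for each of the 8
configurations (full; minus each single branch; minus each pocket+ligand
pair) and reports mean ± sample SD (ddof = 1) over 3 seeds; a two-sided
paired t-test is provided for comparing configurations, with no
multiple-comparison adjustment. Leave-one-target-out removes every record
of one POI from training and evaluates the held-out target and a residual
test split separately.

Evaluation: accuracy at the 0.5 threshold, AUROC as a rank statistic over
`P(active)` (undefined and reported as missing on single-class sets),
TPR = TP/(TP+FN), precision = TP/(TP+FP), all on the percent scale except
AUROC.

## Baselines

ACC (auto cross-covariance) maps a protein sequence to 18 components:
3 physicochemical scales (the first three Sandberg z-scales — the minimal
standard configuration giving length 18), lags {1, 2}, all 3×3 ordered
scale pairs, each component `(1/(n-ℓ)) Σᵢ (x_{p,i}-x̄_p)(x_{q,i+ℓ}-x̄_q)`.
Unknown residues take the scale mean (zero after centering). Small
molecules use MACCS keys (166 bits) or Morgan fingerprints (radius 2,
1024 bits). A ternary complex is (POI ACC, E3 ACC, PROTAC fingerprint) —
202 or 1060 features — classified by a linear-kernel SVM (C = 1) or a
random forest (100 trees, depth 5). Baseline protein sequences come from
the manifest/FASTA, not from structure; on synthetic data a deterministic
per-name random sequence stands in.

## Synthetic data

The generator emulates the data regime end to end: six POIs and two E3s,
each with its own pocket built from rigid residue templates (GLY/SER/ASN
plus planted MET or selenocysteine) placed on shells around a six-carbon
aromatic ring ligand — 3.6–4.6 Å centers inside the 5 Å selection, 9–12 Å
outside, so extraction is always exercised non-trivially. Warheads and E3
ligands come from a 20-scaffold pool; linkers are alkyl (Cₙ) or PEG
((CCO)ₙ) chains. Activity follows a planted rule — by default
`linker_band`: active iff the linker has 6–12 heavy atoms (medium linkers
degrade; very short and very long ones do not); alternatives plant a
pocket-composition/warhead-aromaticity match, or both. Labels may be
flipped with probability `label_noise`, and DC₅₀/Dmax values are then
drawn consistently with the final label so the cutoff rule recovers it
exactly. Everything is byte-reproducible from (spec, seed).

What the generator does **not** emulate: real pocket geometry and
chemistry, conformational strain, binding poses, assay noise structure,
or any distributional property of curated PROTAC databases beyond class
ratio and linker-family mix. Passing tests on this data demonstrate that
the pipeline is wired correctly and that the model can recover a signal
placed where the architecture claims to look — not that it reaches any
particular accuracy on real degradation data.

## Study sizes and verification

The packaged study conditions are 400 records (80/20 split), batch size 1,
30 epochs — sizes chosen so the full pipeline trains in a few minutes on
one CPU while leaving the planted signal clearly recoverable. Under these
conditions the full model reaches held-out AUROC ≥ 0.9 on noise-free
linker-band data, and retraining with the linker branch ablated collapses
to chance level (≤ 0.6): the signal sits in exactly one branch, and the
ablation machinery demonstrably removes it. `scripts/acceptance.py`
recomputes these numbers, plus the SVM/RF baselines on the same data, from
scratch at any seed.

Reproducing published full-scale results is possible but external to the
test suite: export a manifest from a PROTAC database (≈2 800 records,
≈1 000 active), supply PDB/Mol2 complex structures per POI/E3, and train
with the default configuration. That path is stochastic and
data-dependent and is documented in the README rather than asserted by
tests.

## Numerical choices and limitations

* Leaky ReLU slope 0.01 (recorded in config); Glorot-uniform
  initialization; classification ties at exactly 0.5 go to inactive.
* Max-pool gradients follow the first argmax on exact ties (measure-zero
  under continuous weights).
* Softmax/cross-entropy are fused and max-shifted for stability; AUROC
  uses scikit-learn's rank implementation (tested against an O(n²)
  concordance oracle at 1e-9).
* The MLP applies an activation after the first layer only; the BiLSTM
  readout is the concatenated final states. Both are our choices where
  the architecture contract is silent.
* Graphs ignore chirality and 3-D coordinates; pockets keep only element,
  coordinates, residue identity and bonds (partial charges and atom types
  are discarded).
* Whole-PROTAC variants (single graph or single SMILES branch plus the two
  pockets) are provided for comparison but are not the recommended model.
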