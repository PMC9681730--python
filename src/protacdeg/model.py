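"""The five-branch degradation-capacity network.

Five parallel encoders embed the parts of the POI–PROTAC–E3 system:

* two *pocket* branches (POI pocket, E3 pocket) — graph convolutions over
  the 5-element protein vocabulary; their weights are **shared**;
* two *ligand* branches (warhead, E3 ligand) — graph convolutions over the
  10-element small-molecule vocabulary; weights likewise shared;
* one *linker* branch — character tokens through an embedding, a
  bidirectional LSTM (64 hidden units per direction) and a fully connected
  layer.

Each branch emits a 64-vector; the concatenation (320 with all branches)
passes through a two-layer MLP to two logits (inactive, active).  Graph
convolutions use a symmetrically normalized adjacency with self-loops; bond
types contribute a learned per-edge-type embedding added to the neighbor
messages; Leaky ReLU follows every layer; the graph readout is a node-wise
max pool (mean/sum configurable).

Ablations remove branches (the MLP input shrinks accordingly); two
whole-PROTAC variants replace warhead/linker/E3-ligand with a single PROTAC
branch, either a ligand-vocabulary graph or the full SMILES sequence.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .featurize import (
    LIGAND_VOCAB_SIZE,
    N_BOND_TYPES,
    PROTEIN_VOCAB_SIZE,
    TOKEN_VOCAB_SIZE,
    DEFAULT_MAX_LEN,
    MolecularGraph,
    TokenSequence,
)

ALL_BRANCHES = ("poi_pocket", "warhead", "linker", "e3_ligand", "e3_pocket")
POCKET_BRANCHES = ("poi_pocket", "e3_pocket")
LIGAND_BRANCHES = ("warhead", "e3_ligand")

#: the eight ablation settings: item -> branches removed
ABLATION_ITEMS = {
    1: (),
    2: ("e3_pocket",),
    3: ("e3_ligand",),
    4: ("poi_pocket",),
    5: ("warhead",),
    6: ("linker",),
    7: ("e3_pocket", "e3_ligand"),
    8: ("poi_pocket", "warhead"),
}

INACTIVE_INDEX, ACTIVE_INDEX = 0, 1


@dataclass(frozen=True)
class ModelConfig:
    node_embed_dim: int = 64
    gcn1_dim: int = 128
    gcn2_dim: int = 64
    pooling: str = "max"  # {max, mean, sum}
    use_bond_encoding: bool = True
    lstm_hidden: int = 64
    token_embed_dim: int = 64
    linker_fc_dim: int = 64
    mlp_hidden: int = 64
    output_dim: int = 2
    leaky_relu_slope: float = 0.01
    active_branches: tuple[str, ...] = ALL_BRANCHES
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self) -> None:
        if not self.active_branches:
            raise ValueError("active_branches must be non-empty")
        if self.pooling not in ("max", "mean", "sum"):
            raise ValueError(f"unknown pooling {self.pooling!r}")

    @property
    def concat_dim(self) -> int:
        return self.linker_fc_dim * len(self.active_branches)


@dataclass(frozen=True)
class PredictionOutput:
    logits: tuple[float, float]
    prob_active: float
    label: str  # {active, inactive}; ties at 0.5 -> inactive


def ablated_config(base: ModelConfig, ablated_item: int) -> ModelConfig:
    """Apply one of the eight ablation settings (1 = full model)."""
    try:
        removed = ABLATION_ITEMS[ablated_item]
    except KeyError:
        raise ValueError(f"ablated_item must be 1..8, got {ablated_item}") from None
    branches = tuple(b for b in ALL_BRANCHES if b not in removed)
    return replace(base, active_branches=branches)


def variant_config(kind: str, base: ModelConfig | None = None) -> ModelConfig:
    """Three-branch whole-PROTAC variants: pockets + one PROTAC branch
    (graph or SMILES)."""
    base = base or ModelConfig()
    if kind == "whole_graph":
        branches = ("poi_pocket", "protac_graph", "e3_pocket")
    elif kind == "whole_smiles":
        branches = ("poi_pocket", "protac_smiles", "e3_pocket")
    else:
        raise ValueError(f"unknown variant kind {kind!r}")
    return replace(base, active_branches=branches)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _init_gcn_group(rng, vocab: int, cfg: ModelConfig) -> dict[str, nn.Parameter]:
    g = {
        "embed": nn.Parameter(nn.glorot_uniform(rng, (vocab, cfg.node_embed_dim))),
        "W1": nn.Parameter(nn.glorot_uniform(rng, (cfg.node_embed_dim, cfg.gcn1_dim))),
        "b1": nn.Parameter(np.zeros(cfg.gcn1_dim)),
        "W2": nn.Parameter(nn.glorot_uniform(rng, (cfg.gcn1_dim, cfg.gcn2_dim))),
        "b2": nn.Parameter(np.zeros(cfg.gcn2_dim)),
    }
    if cfg.use_bond_encoding:
        # rows indexed by bond code 1..5; row 0 unused
        g["E1"] = nn.Parameter(
            nn.glorot_uniform(rng, (N_BOND_TYPES + 1, cfg.gcn1_dim))
        )
        g["E2"] = nn.Parameter(
            nn.glorot_uniform(rng, (N_BOND_TYPES + 1, cfg.gcn2_dim))
        )
    return g


def _init_seq_group(rng, cfg: ModelConfig) -> dict[str, nn.Parameter]:
    H, D = cfg.lstm_hidden, cfg.token_embed_dim
    g = {
        "embed": nn.Parameter(nn.glorot_uniform(rng, (TOKEN_VOCAB_SIZE, D))),
        "fc_W": nn.Parameter(nn.glorot_uniform(rng, (2 * H, cfg.linker_fc_dim))),
        "fc_b": nn.Parameter(np.zeros(cfg.linker_fc_dim)),
    }
    for direction in ("fwd", "bwd"):
        g[f"{direction}_Wih"] = nn.Parameter(nn.glorot_uniform(rng, (D, 4 * H)))
        g[f"{direction}_Whh"] = nn.Parameter(nn.glorot_uniform(rng, (H, 4 * H)))
        g[f"{direction}_b"] = nn.Parameter(np.zeros(4 * H))
    return g


class ModelParameters:
    """Learnable state keyed by branch, with the two sharing constraints:
    both pocket branches reference one parameter group, and both ligand
    branches reference one group (identical objects, hence bitwise equal
    after any update)."""

    def __init__(self, config: ModelConfig, seed: int) -> None:
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.groups: dict[str, dict[str, nn.Parameter]] = {}
        branches = config.active_branches
        if any(b in POCKET_BRANCHES for b in branches):
            self.groups["pocket_gcn"] = _init_gcn_group(
                rng, PROTEIN_VOCAB_SIZE, config
            )
        if any(b in LIGAND_BRANCHES for b in branches) or "protac_graph" in branches:
            self.groups["ligand_gcn"] = _init_gcn_group(
                rng, LIGAND_VOCAB_SIZE, config
            )
        if "linker" in branches or "protac_smiles" in branches:
            self.groups["seq"] = _init_seq_group(rng, config)
        self.groups["mlp"] = {
            "W1": nn.Parameter(
                nn.glorot_uniform(rng, (config.concat_dim, config.mlp_hidden))
            ),
            "b1": nn.Parameter(np.zeros(config.mlp_hidden)),
            "W2": nn.Parameter(
                nn.glorot_uniform(rng, (config.mlp_hidden, config.output_dim))
            ),
            "b2": nn.Parameter(np.zeros(config.output_dim)),
        }

    def branch_group(self, branch: str) -> dict[str, nn.Parameter]:
        if branch in POCKET_BRANCHES:
            return self.groups["pocket_gcn"]
        if branch in LIGAND_BRANCHES or branch == "protac_graph":
            return self.groups["ligand_gcn"]
        if branch in ("linker", "protac_smiles"):
            return self.groups["seq"]
        raise KeyError(branch)

    def all_parameters(self) -> list[nn.Parameter]:
        seen: dict[int, nn.Parameter] = {}
        for group in self.groups.values():
            for p in group.values():
                seen[id(p)] = p
        return list(seen.values())

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.groups):
            for key in sorted(self.groups[name]):
                h.update(name.encode())
                h.update(key.encode())
                h.update(np.ascontiguousarray(self.groups[name][key].data).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        """Checkpoint: npz arrays plus a JSON sidecar with config and seed."""
        path = Path(path)
        arrays = {
            f"{g}.{k}": p.data
            for g, group in self.groups.items()
            for k, p in group.items()
        }
        np.savez(path, **arrays)
        sidecar = {
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in self.config.__dict__.items()},
            "seed": self.seed,
            "checksum": self.checksum(),
        }
        sidecar.update(metadata or {})
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        cfg_dict = dict(sidecar["config"])
        cfg_dict["active_branches"] = tuple(cfg_dict["active_branches"])
        config = ModelConfig(**cfg_dict)
        params = cls(config, int(sidecar["seed"]))
        with np.load(path if path.suffix == ".npz" else str(path)) as data:
            for key in data.files:
                g, k = key.split(".", 1)
                params.groups[g][k].data[...] = data[key]
        return params


def init_model(config: ModelConfig, seed: int = 0) -> ModelParameters:
    """Deterministic initialization with the sharing contract established
    at construction."""
    return ModelParameters(config, seed)


# ---------------------------------------------------------------------------
# Branch forward passes
# ---------------------------------------------------------------------------

def _normalized_adjacency(graph: MolecularGraph) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} as a dense constant."""
    n = graph.node_count
    a = graph.adjacency() + np.eye(n)
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return a * dinv[:, None] * dinv[None, :]


def gcn_branch(
    graph: MolecularGraph, params: ModelParameters | dict, config: ModelConfig
) -> nn.Tensor:
    """Two graph-convolution layers (embed 64 -> 128 -> 64) with
    symmetric-normalized adjacency and self-loops, optional learned bond
    embeddings added to neighbor messages, Leaky ReLU, then the configured
    node-wise pooling -> 64-vector."""
    group = (
        params.branch_group("poi_pocket" if graph.kind == "protein_pocket" else "warhead")
        if isinstance(params, ModelParameters)
        else params
    )
    vocab = group["embed"].data.shape[0]
    codes = np.asarray(graph.node_codes, dtype=np.intp)
    if codes.size and (codes.min() < 0 or codes.max() >= vocab):
        raise ValueError(
            f"node code out of range [0, {vocab - 1}] for graph kind {graph.kind}"
        )
    ahat = _normalized_adjacency(graph)
    h = nn.gather_rows(group["embed"], codes)

    slope = config.leaky_relu_slope
    for layer in ("1", "2"):
        msg = nn.left_matmul_const(ahat, nn.matmul(h, group[f"W{layer}"]))
        if config.use_bond_encoding and graph.edges:
            src = np.array([e[0] for e in graph.edges], dtype=np.intp)
            dst = np.array([e[1] for e in graph.edges], dtype=np.intp)
            codes_e = np.array([e[2] for e in graph.edges], dtype=np.intp)
            coeff = ahat[dst, src][:, None]  # same normalization as messages
            bond = nn.scatter_sum(
                nn.scale(nn.gather_rows(group[f"E{layer}"], codes_e), coeff),
                dst,
                graph.node_count,
            )
            msg = nn.add(msg, bond)
        h = nn.leaky_relu(nn.add(msg, group[f"b{layer}"]), slope)

    if config.pooling == "max":
        return nn.reduce_max(h, axis=0)
    if config.pooling == "mean":
        return nn.reduce_mean(h, axis=0)
    return nn.reduce_sum(h, axis=0)


def _lstm_direction(
    xs: nn.Tensor, length: int, group: dict, prefix: str, hidden: int, reverse: bool
) -> nn.Tensor:
    """Run one LSTM direction over the first ``length`` embedded tokens and
    return the final hidden state (1, hidden)."""
    Wih, Whh, b = group[f"{prefix}_Wih"], group[f"{prefix}_Whh"], group[f"{prefix}_b"]
    h = nn.Tensor(np.zeros((1, hidden)))
    c = nn.Tensor(np.zeros((1, hidden)))
    steps = range(length - 1, -1, -1) if reverse else range(length)
    for t in steps:
        x_t = nn.row(xs, t)
        gates = nn.add(nn.add(nn.matmul(x_t, Wih), nn.matmul(h, Whh)), b)
        i = nn.sigmoid(nn.slice_cols(gates, 0, hidden))
        f = nn.sigmoid(nn.slice_cols(gates, hidden, 2 * hidden))
        g = nn.tanh(nn.slice_cols(gates, 2 * hidden, 3 * hidden))
        o = nn.sigmoid(nn.slice_cols(gates, 3 * hidden, 4 * hidden))
        c = nn.add(nn.mul(f, c), nn.mul(i, g))
        h = nn.mul(o, nn.tanh(c))
    return h


def linker_branch(
    tokens: TokenSequence, params: ModelParameters | dict, config: ModelConfig
) -> nn.Tensor:
    """Token embedding -> bidirectional LSTM (64 hidden per direction) ->
    concatenated final states (128) -> fully connected -> 64-vector.  An
    all-pad sequence yields a well-defined output (zero recurrent states
    through the FC layer)."""
    group = (
        params.groups["seq"] if isinstance(params, ModelParameters) else params
    )
    H = config.lstm_hidden
    L = tokens.true_length
    if L > 0:
        codes = np.asarray(tokens.codes[:L], dtype=np.intp)
        xs = nn.gather_rows(group["embed"], codes)
        h_f = _lstm_direction(xs, L, group, "fwd", H, reverse=False)
        h_b = _lstm_direction(xs, L, group, "bwd", H, reverse=True)
    else:
        h_f = nn.Tensor(np.zeros((1, H)))
        h_b = nn.Tensor(np.zeros((1, H)))
    hcat = nn.concat([h_f, h_b], axis=1)
    out = nn.leaky_relu(
        nn.add(nn.matmul(hcat, group["fc_W"]), group["fc_b"]),
        config.leaky_relu_slope,
    )
    return out  # (1, 64)


def _branch_output(
    branch: str, value, params: ModelParameters, config: ModelConfig
) -> nn.Tensor:
    if branch in POCKET_BRANCHES:
        out = gcn_branch(value, params.groups["pocket_gcn"], config)
        return nn.reshape(out, (1, -1))
    if branch in LIGAND_BRANCHES or branch == "protac_graph":
        out = gcn_branch(value, params.groups["ligand_gcn"], config)
        return nn.reshape(out, (1, -1))
    if branch in ("linker", "protac_smiles"):
        return linker_branch(value, params.groups["seq"], config)
    raise KeyError(branch)


def forward_logits(
    inputs: dict[str, object], params: ModelParameters, config: ModelConfig
) -> nn.Tensor:
    """Concatenate the active branch outputs and apply the two-layer MLP;
    returns the (1, 2) logit tensor (kept differentiable for training)."""
    outs = []
    for branch in config.active_branches:
        if branch not in inputs or inputs[branch] is None:
            raise ValueError(f"missing input for active branch {branch!r}")
        outs.append(_branch_output(branch, inputs[branch], params, config))
    hcat = nn.concat(outs, axis=1)
    mlp = params.groups["mlp"]
    h = nn.leaky_relu(
        nn.add(nn.matmul(hcat, mlp["W1"]), mlp["b1"]), config.leaky_relu_slope
    )
    return nn.add(nn.matmul(h, mlp["W2"]), mlp["b2"])


def forward(
    poi_pocket: MolecularGraph | None = None,
    warhead: MolecularGraph | None = None,
    linker: TokenSequence | None = None,
    e3_ligand: MolecularGraph | None = None,
    e3_pocket: MolecularGraph | None = None,
    *,
    params: ModelParameters,
    config: ModelConfig,
    **extra,
) -> PredictionOutput:
    """Full inference pass: probabilities from the normalized exponential
    of the logits; label active iff prob_active > 0.5 (ties -> inactive)."""
    inputs = {
        "poi_pocket": poi_pocket,
        "warhead": warhead,
        "linker": linker,
        "e3_ligand": e3_ligand,
        "e3_pocket": e3_pocket,
        **extra,
    }
    logits = forward_logits(inputs, params, config).data.ravel()
    probs = nn.softmax(logits)
    p_active = float(probs[ACTIVE_INDEX])
    return PredictionOutput(
        logits=(float(logits[0]), float(logits[1])),
        prob_active=p_active,
        label="active" if p_active > 0.5 else "inactive",
    )


def variant_forward(
    kind: str,
    poi_pocket: MolecularGraph,
    e3_pocket: MolecularGraph,
    protac: MolecularGraph | TokenSequence,
    *,
    params: ModelParameters,
) -> PredictionOutput:
    """Whole-PROTAC variants: three branches (two shared-weight pockets
    plus one PROTAC graph or SMILES branch)."""
    cfg = params.config
    branch = "protac_graph" if kind == "whole_graph" else "protac_smiles"
    if kind not in ("whole_graph", "whole_smiles"):
        raise ValueError(f"unknown variant kind {kind!r}")
    if branch not in cfg.active_branches:
        raise ValueError(
            f"parameters were initialized without the {branch!r} branch; "
            "build them with variant_config(kind)"
        )
    return forward(
        poi_pocket=poi_pocket,
        e3_pocket=e3_pocket,
        params=params,
        config=cfg,
        **{branch: protac},
    )
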