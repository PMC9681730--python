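"""Graph and token featurization.

Pockets and small molecules become typed graphs: integer node codes over a
small element vocabulary (5 protein types, 10 ligand types) and typed
undirected edges over the five covalent bond classes (single, double,
triple, aromatic, amide -> 1..5).  Linker SMILES become padded integer token
sequences via a frequency-ranked character table: the 39 most frequent
characters of a reference corpus get codes 1..39, padding is 0, and every
out-of-vocabulary character is 40.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .chem_io import BOND_LABELS, MoleculeRecord, PocketSelection

logger = logging.getLogger(__name__)

PAD_CODE = 0
OOV_CODE = 40
N_TABLE_CHARS = 39
DEFAULT_MAX_LEN = 100

#: protein-pocket node vocabulary: C, N, O, S, other -> 0..4
PROTEIN_ELEMENTS = ("C", "N", "O", "S")
PROTEIN_OTHER_CODE = 4
#: ligand node vocabulary: C, N, O, S, F, Cl, Br, I, P, other -> 0..9
LIGAND_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
LIGAND_OTHER_CODE = 9

BOND_CODES = {"single": 1, "double": 2, "triple": 3, "aromatic": 4, "amide": 5}

PROTEIN_VOCAB_SIZE = 5
LIGAND_VOCAB_SIZE = 10
N_BOND_TYPES = 5
TOKEN_VOCAB_SIZE = 41  # codes 0..40


def protein_atom_code(element: str) -> int:
    """C→0, N→1, O→2, S→3, any other heavy element→4; hydrogens are an
    error (they must be filtered upstream)."""
    el = element.capitalize()
    if el in ("H", "D"):
        raise ValueError("hydrogen reached the protein atom coder; filter upstream")
    try:
        return PROTEIN_ELEMENTS.index(el)
    except ValueError:
        return PROTEIN_OTHER_CODE


def ligand_atom_code(element: str) -> int:
    """C,N,O,S,F,Cl,Br,I,P → 0..8 in that order; other heavy elements → 9."""
    el = element.capitalize()
    if el in ("H", "D"):
        raise ValueError("hydrogen reached the ligand atom coder; filter upstream")
    try:
        return LIGAND_ELEMENTS.index(el)
    except ValueError:
        return LIGAND_OTHER_CODE


def bond_code(label: str) -> int:
    """single→1, double→2, triple→3, aromatic→4, amide→5."""
    try:
        return BOND_CODES[label]
    except KeyError:
        raise ValueError(f"unknown bond label {label!r}") from None


@dataclass
class MolecularGraph:
    """Typed molecular graph: integer node codes plus symmetric typed edges.

    ``edges`` stores each bond once per direction (``(i, j, code)`` and
    ``(j, i, code)``), so the implied adjacency matrix is symmetric with a
    zero diagonal.
    """

    kind: str  # {protein_pocket, ligand}
    node_codes: list[int]
    edges: list[tuple[int, int, int]]

    @property
    def node_count(self) -> int:
        return len(self.node_codes)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.node_count, self.node_count))
        for i, j, _ in self.edges:
            a[i, j] = 1.0
        return a

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "node_codes": self.node_codes,
             "edges": [list(e) for e in self.edges]}
        )

    @classmethod
    def from_json(cls, text: str) -> "MolecularGraph":
        d = json.loads(text)
        return cls(d["kind"], list(d["node_codes"]),
                   [tuple(e) for e in d["edges"]])


def to_graph(mol: MoleculeRecord | PocketSelection, kind: str) -> MolecularGraph:
    """Convert a molecule or pocket to a typed graph over heavy atoms.

    Node i is the i-th retained heavy atom; each input bond yields one
    symmetric edge pair.  Isolated atoms are kept as isolated nodes.
    """
    if kind not in ("protein_pocket", "ligand"):
        raise ValueError(f"unknown graph kind {kind!r}")
    coder = protein_atom_code if kind == "protein_pocket" else ligand_atom_code

    if isinstance(mol, PocketSelection):
        atoms = [a for a in mol.atoms if a.is_heavy]
        bonds: list[tuple[int, int, str]] = []
        remap = {}
    else:
        atoms = [a for a in mol.atoms if a.is_heavy]
        remap = {
            old: new
            for new, old in enumerate(
                k for k, a in enumerate(mol.atoms) if a.is_heavy
            )
        }
        bonds = [
            (remap[i], remap[j], label)
            for i, j, label in mol.bonds
            if i in remap and j in remap
        ]
    if not atoms:
        raise ValueError("cannot build a graph from an empty molecule")

    node_codes = [coder(a.element) for a in atoms]
    edges: list[tuple[int, int, int]] = []
    for i, j, label in bonds:
        c = bond_code(label)
        edges.append((i, j, c))
        edges.append((j, i, c))
    return MolecularGraph(kind=kind, node_codes=node_codes, edges=edges)


# ---------------------------------------------------------------------------
# SMILES tokenization
# ---------------------------------------------------------------------------

@dataclass
class EncodingTable:
    """Character → integer code map; 39 in-vocabulary codes plus PAD=0 and
    OOV=40."""

    char_to_code: dict[str, int]
    pad_code: int = PAD_CODE
    oov_code: int = OOV_CODE

    def __post_init__(self) -> None:
        codes = sorted(self.char_to_code.values())
        if len(self.char_to_code) != N_TABLE_CHARS or codes != list(
            range(1, N_TABLE_CHARS + 1)
        ):
            raise ValueError(
                f"encoding table must map exactly {N_TABLE_CHARS} characters "
                f"to unique codes 1..{N_TABLE_CHARS}"
            )

    def code_to_char(self) -> dict[int, str]:
        return {v: k for k, v in self.char_to_code.items()}

    def to_json(self) -> str:
        return json.dumps(self.char_to_code, ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EncodingTable":
        return cls(char_to_code={str(k): int(v) for k, v in json.loads(text).items()})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "EncodingTable":
        return cls.from_json(Path(path).read_text())


@dataclass
class TokenSequence:
    """Fixed-length integer encoding of a linker SMILES."""

    codes: list[int]
    true_length: int

    def __post_init__(self) -> None:
        if any(not (0 <= c <= OOV_CODE) for c in self.codes):
            raise ValueError("token codes must lie in [0, 40]")
        if any(c != PAD_CODE for c in self.codes[self.true_length:]):
            raise ValueError("positions beyond true_length must be PAD")


def build_encoding_table(corpus: Iterable[str]) -> EncodingTable:
    """Rank characters of a SMILES corpus by descending frequency; the top
    39 get codes 1..39.  Frequency ties break by Unicode code point so the
    table is invariant to corpus order."""
    counts: Counter[str] = Counter()
    for smiles in corpus:
        counts.update(smiles)
    if len(counts) < N_TABLE_CHARS:
        raise ValueError(
            f"corpus has only {len(counts)} distinct characters; "
            f"{N_TABLE_CHARS} are required"
        )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return EncodingTable(
        char_to_code={ch: rank + 1 for rank, (ch, _) in enumerate(ranked[:N_TABLE_CHARS])}
    )


_DEFAULT_TABLE: EncodingTable | None = None


def default_encoding_table() -> EncodingTable:
    """The table used when none is supplied: character frequencies of the
    deterministic synthetic lead-like corpus (see ``synthdata.smiles_corpus``).
    Users reproducing a published table can load their own JSON instead."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        from .synthdata import smiles_corpus

        _DEFAULT_TABLE = build_encoding_table(smiles_corpus())
    return _DEFAULT_TABLE


def tokenize(
    smiles: str, table: EncodingTable, max_len: int = DEFAULT_MAX_LEN
) -> TokenSequence:
    """Character-by-character lookup; unknown characters map to 40;
    right-padded with 0 to ``max_len``.  An empty string yields an all-pad
    sequence (a valid, ablated linker); longer strings are truncated with a
    warning."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(smiles) > max_len:
        logger.warning(
            "SMILES of length %d truncated to max_len=%d", len(smiles), max_len
        )
    kept = smiles[:max_len]
    codes = [table.char_to_code.get(ch, table.oov_code) for ch in kept]
    codes.extend([table.pad_code] * (max_len - len(codes)))
    return TokenSequence(codes=codes, true_length=len(kept))


def detokenize(seq: TokenSequence, table: EncodingTable) -> str:
    """Inverse map over in-table codes (pads skipped, OOV becomes '?')."""
    inv = table.code_to_char()
    return "".join(
        inv.get(c, "?") for c in seq.codes[: seq.true_length] if c != PAD_CODE
    )
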