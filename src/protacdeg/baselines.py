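"""Classical feature constructions for the SVM / random-forest baselines.

Proteins are described by auto cross-covariance (ACC) over three
physicochemical z-scales; small molecules by MACCS keys (166 bits) or
hashed Morgan/circular fingerprints (1024 bits).  A ternary complex is the
concatenation (POI ACC, E3 ACC, PROTAC fingerprint): 202 features with
MACCS, 1060 with Morgan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chem_io import MoleculeRecord, read_small_molecule

ACC_LENGTH = 18
MACCS_LENGTH = 166
MORGAN_LENGTH = 1024

#: Sandberg z-scales z1 (lipophilicity), z2 (steric bulk), z3 (polarity)
#: for the 20 standard residues.
_ZSCALES = {
    "A": (0.24, -2.32, 0.60),
    "R": (3.52, 2.50, -3.50),
    "N": (3.05, 1.62, 1.04),
    "D": (3.98, 0.93, 1.93),
    "C": (0.84, -1.67, 3.71),
    "Q": (1.75, 0.50, -1.44),
    "E": (3.11, 0.26, -0.11),
    "G": (2.05, -4.06, 0.36),
    "H": (2.47, 1.95, 0.26),
    "I": (-3.89, -1.73, -1.71),
    "L": (-4.28, -1.30, -1.49),
    "K": (2.29, 0.89, -2.49),
    "M": (-2.85, -0.22, 0.47),
    "F": (-4.22, 1.94, 1.06),
    "P": (-1.66, 0.27, 1.84),
    "S": (2.39, -1.07, 1.15),
    "T": (0.75, -2.18, -1.12),
    "W": (-4.36, 3.94, 0.59),
    "V": (-2.59, -2.64, -1.54),
    "Y": (-2.54, 2.44, 0.43),
}
_ZSCALE_MEAN = tuple(
    float(np.mean([v[k] for v in _ZSCALES.values()])) for k in range(3)
)
ACC_LAGS = (1, 2)
N_SCALES = 3


@dataclass
class FeatureVector:
    """A real-valued descriptor with its provenance contract."""

    values: np.ndarray
    provenance: str  # {acc, maccs, morgan, ternary_concat}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = {
            "acc": (ACC_LENGTH,),
            "maccs": (MACCS_LENGTH,),
            "morgan": (MORGAN_LENGTH,),
        }.get(self.provenance)
        if expected is not None and self.values.shape != expected:
            raise ValueError(
                f"{self.provenance} feature must have shape {expected}, "
                f"got {self.values.shape}"
            )

    @property
    def length(self) -> int:
        return int(self.values.size)


def acc_descriptor(sequence: str) -> FeatureVector:
    """Auto cross-covariance of a protein sequence: 18 components.

    For lags l in {1, 2} and all ordered pairs (p, q) of the 3 z-scales,
    component(l, p, q) = (1/(n-l)) * sum_i (x[p,i] - mean_p)(x[q,i+l] - mean_q),
    ordered lexicographically by (l, p, q).  Unknown residues take the mean
    property value (hence contribute zero after centering in that scale).
    """
    sequence = sequence.strip().upper()
    n = len(sequence)
    if n < 3:
        raise ValueError(f"sequence too short for ACC (length {n} < 3)")
    if n < max(ACC_LAGS) + 1:
        raise ValueError(f"sequence length {n} below lag_max + 1")
    x = np.array(
        [_ZSCALES.get(aa, _ZSCALE_MEAN) for aa in sequence], dtype=float
    ).T  # (3, n)
    xc = x - x.mean(axis=1, keepdims=True)
    comps = []
    for lag in ACC_LAGS:
        for p in range(N_SCALES):
            for q in range(N_SCALES):
                comps.append((xc[p, : n - lag] * xc[q, lag:]).sum() / (n - lag))
    return FeatureVector(np.array(comps), "acc")


def _as_rdkit(mol: MoleculeRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    if isinstance(mol, MoleculeRecord):
        m = Chem.MolFromSmiles(mol.name)
        if m is not None:
            return m
        raise ValueError(
            f"cannot rebuild an RDKit molecule for {mol.name!r}; "
            "pass a SMILES string instead"
        )
    m = Chem.MolFromSmiles(str(mol))
    if m is None:
        raise ValueError(f"invalid SMILES for fingerprinting: {mol!r}")
    return m


def maccs_fp(mol: MoleculeRecord | Chem.Mol | str) -> FeatureVector:
    """Standard 166-key MACCS substructure fingerprint (binary)."""
    m = _as_rdkit(mol)
    bv = MACCSkeys.GenMACCSKeys(m)  # 167 bits, bit 0 unused
    arr = np.array([bv.GetBit(i) for i in range(1, 167)], dtype=float)
    return FeatureVector(arr, "maccs")


def morgan_fp(
    mol: MoleculeRecord | Chem.Mol | str, radius: int = 2, nbits: int = MORGAN_LENGTH
) -> FeatureVector:
    """Hashed circular (Morgan/ECFP-style) fingerprint, 1024 bits default."""
    m = _as_rdkit(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(m)
    arr = np.zeros(nbits)
    for bit in bv.GetOnBits():
        arr[bit] = 1.0
    fv = FeatureVector(arr, "morgan" if nbits == MORGAN_LENGTH else "morgan_custom")
    return fv


def ternary_features(
    poi_seq: str,
    e3_seq: str,
    protac: MoleculeRecord | Chem.Mol | str,
    fp_kind: str = "morgan",
) -> FeatureVector:
    """Concatenate (POI ACC, E3 ACC, PROTAC fingerprint) -> 202 (MACCS) or
    1060 (Morgan) features describing the ternary complex."""
    if fp_kind == "maccs":
        fp = maccs_fp(protac)
    elif fp_kind == "morgan":
        fp = morgan_fp(protac)
    else:
        raise ValueError(f"unknown fingerprint kind {fp_kind!r}")
    vec = np.concatenate(
        [acc_descriptor(poi_seq).values, acc_descriptor(e3_seq).values, fp.values]
    )
    return FeatureVector(vec, "ternary_concat")


def read_fasta_sequences(path) -> dict[str, str]:
    """Read protein sequences for the baselines from a FASTA file,
    keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def feature_matrix_to_csv(path, vectors: list[FeatureVector], ids: list[str]) -> None:
    """Write a feature matrix as CSV with a provenance header row."""
    import pandas as pd

    if len({v.provenance for v in vectors}) > 1:
        raise ValueError("mixed provenances in one feature matrix")
    df = pd.DataFrame(
        np.stack([v.values for v in vectors]),
        index=ids,
        columns=[f"{vectors[0].provenance}_{k}" for k in range(vectors[0].length)],
    )
    df.to_csv(path, index_label="record_id")


def protac_smiles(warhead: str, linker: str, e3_ligand: str) -> str:
    """Assemble a whole-PROTAC SMILES by linear concatenation of the three
    component SMILES (warhead-linker-ligand), used for baseline
    fingerprints and the whole-molecule model variants on synthetic data."""
    combined = warhead + linker + e3_ligand
    if Chem.MolFromSmiles(combined) is None:
        # fall back to a dot-separated (disconnected) assembly, always valid
        combined = ".".join(s for s in (warhead, linker, e3_ligand) if s)
    return combined
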