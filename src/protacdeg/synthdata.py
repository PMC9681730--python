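"""Synthetic study-condition generator.

Builds everything the pipeline consumes without any download: protein
pockets as rigid residue templates placed on a sphere around a small bound
ligand (chemically naive, geometrically exact — which is what pocket
extraction and graph construction need), warheads and E3 ligands drawn from
a fixed pool of small scaffolds, alkyl and PEG linkers of varying length,
and degradation records whose activity follows a planted, recoverable rule:

* ``linker_band`` — active iff the linker has 6..12 heavy atoms (medium
  linker lengths degrade well, long and short ones do not);
* ``pocket_match`` — active iff the POI pocket carries a planted sulfur
  marker exactly when the warhead is aromatic;
* ``mixed`` — both conditions must hold.

DC50/Dmax measurements are then drawn consistently with the (optionally
noise-flipped) label, so the labeling rule recovers the planted classes
from the manifest alone.  Every artefact is byte-reproducible from
(spec, seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_io import AtomRecord, MoleculeRecord, write_mol2
from .dataset import DegradationRecord, apply_labels, write_manifest

LINKER_BAND = (6, 12)  # heavy atoms, inclusive

#: warhead / E3-ligand scaffold pool: small molecules whose graphs and
#: fingerprints vary but stay tiny.
SCAFFOLD_POOL = (
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "c1ccc2ccccc2c1", "Clc1ccccc1", "Fc1ccccc1", "Brc1ccccc1",
    "N#Cc1ccccc1", "COc1ccccc1", "CC(=O)Nc1ccccc1", "OCc1ccccc1",
    "C1CCNCC1", "C1CCOC1", "O=C1CCCCC1", "CC(C)CC(N)C(=O)O",
    "OC(=O)c1ccccc1", "NC(=O)C1CCCC1", "CSCC(N)C(=O)O",
)
_AROMATIC_SCAFFOLDS = tuple(s for s in SCAFFOLD_POOL if "c" in s)
_ALIPHATIC_SCAFFOLDS = tuple(s for s in SCAFFOLD_POOL if "c" not in s)

POI_NAMES = ("POI_A", "POI_B", "POI_C", "POI_D", "POI_E", "POI_F")
E3_NAMES = ("VHL", "CRBN")


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters for one synthetic dataset."""

    n_records: int = 400
    seed: int = 0
    active_rule: str = "linker_band"  # {linker_band, pocket_match, mixed}
    linker_families: tuple[str, ...] = ("alkyl", "PEG")
    label_noise: float = 0.0
    pocket_residues: tuple[int, int] = (6, 10)
    #: default emulates the curated cohort's class ratio (~988:1844)
    active_fraction: float = 0.35

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not (0.0 < self.active_fraction < 1.0):
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.active_rule not in ("linker_band", "pocket_match", "mixed"):
            raise ValueError(f"unknown active_rule {self.active_rule!r}")
        if not self.linker_families or any(
            f not in ("alkyl", "PEG") for f in self.linker_families
        ):
            raise ValueError("linker_families must be a subset of {alkyl, PEG}")
        if self.n_records < 4:
            raise ValueError("n_records too small to be useful")


# ---------------------------------------------------------------------------
# Linkers
# ---------------------------------------------------------------------------

def make_linker(family: str, length: int) -> str:
    """Alkyl chain ``C*length`` or PEG chain ``(CCO)*length`` as SMILES."""
    if length < 1:
        raise ValueError("linker length must be >= 1")
    if family == "alkyl":
        return "C" * length
    if family == "PEG":
        return "CCO" * length
    raise ValueError(f"unknown linker family {family!r}")


def linker_heavy_atoms(family: str, length: int) -> int:
    return length if family == "alkyl" else 3 * length


# ---------------------------------------------------------------------------
# Pockets
# ---------------------------------------------------------------------------

# local residue templates: (residue name, [(element, offset)], [(i, j, label)])
# atom 0 sits at the placement center so the "inside" distance guarantee holds.
_RESIDUE_TEMPLATES = [
    ("GLY", [("N", (0, 0, 0)), ("C", (1.45, 0, 0)), ("C", (2.2, 1.2, 0)),
             ("O", (3.4, 1.2, 0.3))],
     [(0, 1, "single"), (1, 2, "single"), (2, 3, "double")]),
    ("SER", [("N", (0, 0, 0)), ("C", (1.45, 0, 0)), ("C", (2.2, 1.2, 0)),
             ("O", (3.4, 1.2, 0.3)), ("O", (1.9, -1.3, 0.4))],
     [(0, 1, "single"), (1, 2, "single"), (2, 3, "double"), (1, 4, "single")]),
    ("CYS", [("N", (0, 0, 0)), ("C", (1.45, 0, 0)), ("C", (2.2, 1.2, 0)),
             ("O", (3.4, 1.2, 0.3)), ("S", (1.9, -1.6, 0.4))],
     [(0, 1, "single"), (1, 2, "single"), (2, 3, "double"), (1, 4, "single")]),
    ("ASN", [("N", (0, 0, 0)), ("C", (1.45, 0, 0)), ("C", (2.2, 1.2, 0)),
             ("O", (3.4, 1.2, 0.3)), ("C", (1.9, -1.4, 0.2)),
             ("O", (3.1, -1.6, 0.2)), ("N", (1.0, -2.4, 0.1))],
     [(0, 1, "single"), (1, 2, "single"), (2, 3, "double"), (1, 4, "single"),
      (4, 5, "double"), (4, 6, "amide")]),
    ("MET", [("N", (0, 0, 0)), ("C", (1.45, 0, 0)), ("C", (2.2, 1.2, 0)),
             ("O", (3.4, 1.2, 0.3)), ("C", (1.9, -1.4, 0.2)),
             ("S", (1.2, -2.9, 0.4)), ("C", (2.3, -4.1, 0.2))],
     [(0, 1, "single"), (1, 2, "single"), (2, 3, "double"), (1, 4, "single"),
      (4, 5, "single"), (5, 6, "single")]),
]
# selenocysteine-like template: the Se atom exercises the "other" node code.
_SEC_TEMPLATE = (
    "SEC",
    [("N", (0, 0, 0)), ("C", (1.45, 0, 0)), ("C", (2.2, 1.2, 0)),
     ("O", (3.4, 1.2, 0.3)), ("Se", (1.9, -1.7, 0.4))],
    [(0, 1, "single"), (1, 2, "single"), (2, 3, "double"), (1, 4, "single")],
)

_LIGAND_RING_RADIUS = 1.4
_INSIDE_SHELL = (3.6, 4.6)   # guarantees min atom distance <= 5.0 (see below)
_OUTSIDE_SHELL = (9.0, 12.0)  # guarantees min atom distance > 5.0


def _rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random 3x3 rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_pocket(
    seed: int,
    n_residues: int = 8,
    plant_selenium: bool = False,
    plant_sulfur: bool = False,
    name: str = "pocket",
) -> tuple[MoleculeRecord, dict]:
    """Build a protein/ligand complex with at least one residue inside and
    one outside the 5 Å shell, so pocket extraction is exercised
    non-trivially.

    The ligand is a six-membered aromatic carbon ring at the origin
    (radius 1.4 Å).  Inside residues are centered 3.6-4.6 Å from the
    origin with their anchor atom at the center: the nearest ligand atom is
    then at most sqrt(4.6^2 + 1.4^2) ≈ 4.8 Å away.  Outside residues sit
    9-12 Å out with template atoms within ~4.3 Å of the center, keeping
    every atom > 5 Å from the ligand.

    Returns the complex plus a manifest of planted facts (residue names,
    inside/outside keys, special-atom counts) used by tests.
    """
    if n_residues < 2:
        raise ValueError("need at least one inside and one outside residue")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int, str]] = []

    # ligand ring
    for k in range(6):
        ang = 2 * math.pi * k / 6
        atoms.append(
            AtomRecord(
                element="C",
                position=(
                    _LIGAND_RING_RADIUS * math.cos(ang),
                    _LIGAND_RING_RADIUS * math.sin(ang),
                    0.0,
                ),
                residue_name="LIG",
                residue_id=999,
                chain_id="A",
                role="ligand",
            )
        )
    for k in range(6):
        bonds.append((k, (k + 1) % 6, "aromatic"))

    n_inside = max(1, n_residues // 2)
    manifest: dict = {
        "name": name,
        "n_residues": n_residues,
        "inside_keys": [],
        "outside_keys": [],
        "residue_names": [],
        "n_selenium": 0,
        "n_sulfur": 0,
    }
    special: list[tuple[str, list, list]] = []
    if plant_selenium:
        special.append(_SEC_TEMPLATE)
    if plant_sulfur:
        special.append(_RESIDUE_TEMPLATES[4])  # MET

    for ridx in range(n_residues):
        inside = ridx < n_inside
        if special and inside:
            resname, template_atoms, template_bonds = special.pop(0)
        else:
            # sulfur-free pool (GLY/SER/ASN) so S atoms appear only when
            # planted and remain a clean pocket marker
            pick = (0, 1, 3)[rng.integers(0, 3)]
            resname, template_atoms, template_bonds = _RESIDUE_TEMPLATES[pick]
        lo, hi = _INSIDE_SHELL if inside else _OUTSIDE_SHELL
        center = _random_direction(rng) * rng.uniform(lo, hi)
        rot = _rotation(rng)
        offset = len(atoms)
        resid = ridx + 1
        for element, local in template_atoms:
            pos = center + rot @ np.asarray(local, dtype=float)
            atoms.append(
                AtomRecord(
                    element=element,
                    position=tuple(float(c) for c in pos),
                    residue_name=resname,
                    residue_id=resid,
                    chain_id="A",
                    role="protein",
                )
            )
            if element == "Se":
                manifest["n_selenium"] += 1
            if element == "S":
                manifest["n_sulfur"] += 1
        for i, j, label in template_bonds:
            bonds.append((offset + i, offset + j, label))
        key = ["A", resid]
        manifest["residue_names"].append(resname)
        (manifest["inside_keys"] if inside else manifest["outside_keys"]).append(key)

    mol = MoleculeRecord(name=name, atoms=atoms, bonds=bonds)
    manifest["n_atoms"] = len(atoms)
    manifest["n_bonds"] = len(bonds)
    return mol, manifest


def write_pocket_files(mol: MoleculeRecord, out_stem: Path) -> dict[str, str]:
    """Write the complex as Mol2 (with bonds) and PDB (coordinates only)."""
    mol2_path = out_stem.with_suffix(".mol2")
    pdb_path = out_stem.with_suffix(".pdb")
    write_mol2(mol, mol2_path)
    lines = []
    for idx, a in enumerate(mol.atoms, start=1):
        rec = "HETATM" if a.role == "ligand" else "ATOM"
        name = f"{a.element}{idx % 100}"
        lines.append(
            f"{rec:<6}{idx:>5} {name:<4} {a.residue_name:>3} "
            f"{a.chain_id:1}{a.residue_id:>4}    "
            f"{a.position[0]:>8.3f}{a.position[1]:>8.3f}{a.position[2]:>8.3f}"
            f"{1.0:>6.2f}{0.0:>6.2f}          {a.element:>2}"
        )
    lines.append("END")
    pdb_path.write_text("\n".join(lines) + "\n")
    return {"mol2": str(mol2_path), "pdb": str(pdb_path)}


# ---------------------------------------------------------------------------
# SMILES corpus (for the default encoding table)
# ---------------------------------------------------------------------------

#: short valid SMILES covering rarer characters (charges, stereo, isotopes,
#: large-ring closures) so a generated corpus always spans >= 39 characters.
_RARE_SMILES = (
    "C[C@H](N)C(=O)O", "C[C@@H](O)C", "C/C=C/C", "C/C=C\\C",
    "[NH4+].[Cl-]", "CC(=O)[O-]", "C[N+](C)(C)C", "[13CH4]",
    "c1ccc2c(c1)ccc1ccccc12", "C%10CCCCC%10", "[Se]1CCCC1", "[nH]1cccc1",
    "O=[N+]([O-])c1ccccc1", "FC(F)(F)c1ccccc1", "C#N", "C#CC",
    "c1ccc(-c2ccccc2)cc1", "O=S(=O)(O)O", "OP(=O)(O)O", "II",
    "B1OCCO1", "CCCCCCCC", "N1C=CC=C1C2=CC=CC=C2", "Clc1cc(Br)ccc1I",
    "C1CC2CCC1C2", "O=C(O)CCCCC(=O)O", "CN1CCN(C)CC1", "S=C=S",
    "[2H]OC", "CC(C)(C)OC(=O)N", "COC(=O)c1ccc(N)cc1", "CCOC(=O)C",
    # ring closures deliberately numbered 5..9 to cover those digits
    "C5CCCCC5", "C6CCCCC6", "C7CCOCC7", "C8CCNCC8", "C9CCSCC9",
)


def synthetic_sequences(
    names: list[str], length: int = 120, seed: int = 0
) -> dict[str, str]:
    """Deterministic stand-in protein sequences for baseline features on
    synthetic data (real datasets supply FASTA); one fixed random sequence
    per name, independent of the name order."""
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = {}
    for name in names:
        # per-name seed: stable across processes and list orders
        digest = hashlib.sha256(name.encode()).digest()
        sub = np.random.default_rng([seed, int.from_bytes(digest[:4], "little")])
        out[name] = "".join(sub.choice(alphabet, size=length))
    return out


def smiles_corpus(n: int = 2000, seed: int = 20) -> list[str]:
    """A deterministic synthetic lead-like SMILES corpus: random
    scaffold/linker assemblies plus a fixed tail of rarer-character
    molecules, guaranteeing the >= 39 distinct characters an encoding
    table needs.  A stand-in corpus, not an export of any database."""
    rng = np.random.default_rng(seed)
    corpus: list[str] = []
    for _ in range(n):
        parts = [str(SCAFFOLD_POOL[rng.integers(0, len(SCAFFOLD_POOL))])]
        if rng.random() < 0.7:
            parts.append(make_linker(
                "alkyl" if rng.random() < 0.6 else "PEG",
                int(rng.integers(1, 6)),
            ))
        if rng.random() < 0.5:
            parts.append(str(SCAFFOLD_POOL[rng.integers(0, len(SCAFFOLD_POOL))]))
        corpus.append("".join(parts))
    corpus.extend(_RARE_SMILES)
    return corpus


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _rule_predicate(
    rule: str, linker_atoms: int, poi_marker: bool, warhead_aromatic: bool
) -> bool:
    band = LINKER_BAND[0] <= linker_atoms <= LINKER_BAND[1]
    match = poi_marker == warhead_aromatic
    if rule == "linker_band":
        return band
    if rule == "pocket_match":
        return match
    return band and match


def _draw_linker(rng: np.random.Generator, families, want_in_band: bool | None):
    """Sample (family, length); when ``want_in_band`` is set, condition the
    heavy-atom count on the activity band to keep classes balanced."""
    for _ in range(1000):
        family = str(families[rng.integers(0, len(families))])
        if family == "alkyl":
            length = int(rng.integers(2, 21))
        else:
            length = int(rng.integers(1, 7))
        n_heavy = linker_heavy_atoms(family, length)
        in_band = LINKER_BAND[0] <= n_heavy <= LINKER_BAND[1]
        if want_in_band is None or in_band == want_in_band:
            return family, length, n_heavy
    raise RuntimeError("could not sample a linker satisfying the band constraint")


def _draw_measurements(rng: np.random.Generator, active: bool) -> tuple[float, float]:
    """DC50 (nM) and Dmax (%) consistent with the label under the default
    cutoffs (DC50 < 100 and Dmax > 80 for actives)."""
    if active:
        return float(rng.uniform(1, 90)), float(rng.uniform(85, 99))
    if rng.random() < 0.5:  # low potency
        return float(rng.uniform(150, 5000)), float(rng.uniform(20, 95))
    return float(rng.uniform(1, 90)), float(rng.uniform(20, 75))  # low efficacy


def generate_dataset(spec: SynthSpec, out_dir: str | Path) -> Path:
    """Generate structures + manifest + ground-truth sidecar under
    ``out_dir``; returns the manifest path.

    Labels follow the planted rule XOR a Bernoulli(label_noise) flip, and
    DC50/Dmax are drawn consistently with the resulting label, so the
    labeling cutoffs recover it exactly.
    """
    out_dir = Path(out_dir)
    structures = out_dir / "structures"
    structures.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # one pocket per POI/E3 name; POI sulfur markers planted on half
    poi_info: dict[str, dict] = {}
    for k, poi in enumerate(POI_NAMES):
        n_res = int(rng.integers(spec.pocket_residues[0], spec.pocket_residues[1] + 1))
        marker = k % 2 == 0
        mol, man = make_pocket(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_residues=n_res,
            plant_sulfur=marker,
            name=poi,
        )
        paths = write_pocket_files(mol, structures / poi)
        poi_info[poi] = {"marker": marker, "path": paths["mol2"], **man}
    e3_info: dict[str, dict] = {}
    for e3 in E3_NAMES:
        n_res = int(rng.integers(spec.pocket_residues[0], spec.pocket_residues[1] + 1))
        mol, man = make_pocket(
            seed=int(rng.integers(0, 2**31 - 1)), n_residues=n_res, name=e3
        )
        paths = write_pocket_files(mol, structures / e3)
        e3_info[e3] = {"path": paths["mol2"], **man}

    records: list[DegradationRecord] = []
    truth: dict[str, dict] = {}
    for idx in range(spec.n_records):
        rid = f"R{idx:05d}"
        poi = POI_NAMES[idx % len(POI_NAMES)]
        e3 = E3_NAMES[idx % len(E3_NAMES)]
        want = bool(rng.random() < spec.active_fraction)

        if spec.active_rule in ("linker_band", "mixed"):
            family, length, n_heavy = _draw_linker(rng, spec.linker_families, want)
        else:
            family, length, n_heavy = _draw_linker(rng, spec.linker_families, None)

        if spec.active_rule in ("pocket_match", "mixed"):
            pool = (
                _AROMATIC_SCAFFOLDS
                if (want == poi_info[poi]["marker"])
                else _ALIPHATIC_SCAFFOLDS
            )
            warhead = str(pool[rng.integers(0, len(pool))])
        else:
            warhead = str(SCAFFOLD_POOL[rng.integers(0, len(SCAFFOLD_POOL))])
        e3_ligand = str(SCAFFOLD_POOL[rng.integers(0, len(SCAFFOLD_POOL))])

        warhead_aromatic = "c" in warhead
        predicate = _rule_predicate(
            spec.active_rule, n_heavy, poi_info[poi]["marker"], warhead_aromatic
        )
        flipped = bool(rng.random() < spec.label_noise)
        active = predicate != flipped
        dc50, dmax = _draw_measurements(rng, active)

        records.append(
            DegradationRecord(
                record_id=rid,
                poi_name=poi,
                e3_name=e3,
                poi_structure=str(Path("structures") / f"{poi}.mol2"),
                e3_structure=str(Path("structures") / f"{e3}.mol2"),
                warhead=warhead,
                e3_ligand=e3_ligand,
                linker_smiles=make_linker(family, length),
                dc50=dc50,
                dmax=dmax,
            )
        )
        truth[rid] = {
            "linker_family": family,
            "linker_heavy_atoms": n_heavy,
            "poi_marker": poi_info[poi]["marker"],
            "warhead_aromatic": warhead_aromatic,
            "predicate": predicate,
            "noise_flipped": flipped,
            "label": "active" if active else "inactive",
        }

    records = apply_labels(records)
    for r in records:
        if r.label != truth[r.record_id]["label"]:  # pragma: no cover
            raise AssertionError("measurement draw inconsistent with planted label")

    manifest_path = out_dir / "manifest.csv"
    write_manifest(records, manifest_path)
    (out_dir / "ground_truth.json").write_text(
        json.dumps(
            {
                "rule": spec.active_rule,
                "seed": spec.seed,
                "label_noise": spec.label_noise,
                "poi_markers": {k: v["marker"] for k, v in poi_info.items()},
                "records": truth,
            },
            indent=1,
        )
    )
    return manifest_path
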