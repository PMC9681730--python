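"""Degradation-record curation: labeling, splitting, and class rebalancing.

A record couples one POI / PROTAC / E3 data point with its measured potency
(DC50, the half-maximal degradation concentration in nM) and efficacy
(Dmax, the maximal degradation in %).  A compound is an active (good)
degrader only when DC50 is strictly below the cutoff AND Dmax strictly
above it — by default DC50 < 100 nM and Dmax > 80%; a relaxed alternative
scheme (1000 nM / 70%) is provided.  Splits are plain uniform random
partitions; under-/over-sampling and a 2x active-class loss weight address
the active:inactive imbalance.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"

MANIFEST_COLUMNS = [
    "record_id", "poi_name", "e3_name", "poi_structure", "poi_ligand",
    "e3_structure", "e3_ligand", "warhead", "linker_smiles",
    "dc50_nM", "dmax_pct",
]


@dataclass(frozen=True)
class CutoffScheme:
    """Labeling thresholds: DC50 upper cutoff (nM), Dmax lower cutoff (%)."""

    dc50_max: float = 100.0
    dmax_min: float = 80.0

    def __post_init__(self) -> None:
        if self.dc50_max <= 0 or self.dmax_min <= 0:
            raise ValueError("cutoffs must be positive")


DEFAULT_CUTOFF = CutoffScheme(100.0, 80.0)
RELAXED_CUTOFF = CutoffScheme(1000.0, 70.0)


@dataclass
class DegradationRecord:
    """One POI/PROTAC/E3 data point with measured potency and efficacy."""

    record_id: str
    poi_name: str = ""
    e3_name: str = ""
    poi_structure: str = ""
    e3_structure: str = ""
    warhead: str = ""
    e3_ligand: str = ""
    linker_smiles: str = ""
    dc50: float | None = None  # nM
    dmax: float | None = None  # %
    label: str | None = None

    def __post_init__(self) -> None:
        if self.dc50 is not None and self.dc50 <= 0:
            raise ValueError(f"{self.record_id}: dc50 must be positive")
        if self.dmax is not None and not (0 <= self.dmax <= 100):
            raise ValueError(f"{self.record_id}: dmax must lie in [0, 100]")


@dataclass(frozen=True)
class SplitSpec:
    """Random-split proportions (must sum to 1) plus seed."""

    ratios: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def label_record(r: DegradationRecord, scheme: CutoffScheme = DEFAULT_CUTOFF) -> str:
    """Active iff dc50 < dc50_max AND dmax > dmax_min (strict); a missing
    measurement labels the record inactive."""
    if r.dc50 is None or r.dmax is None:
        return INACTIVE
    return ACTIVE if (r.dc50 < scheme.dc50_max and r.dmax > scheme.dmax_min) else INACTIVE


def apply_labels(
    records: list[DegradationRecord], scheme: CutoffScheme = DEFAULT_CUTOFF
) -> list[DegradationRecord]:
    return [replace(r, label=label_record(r, scheme)) for r in records]


def split(records: list, spec: SplitSpec) -> list[list]:
    """Uniform random permutation under the seed, then contiguous slicing
    by ratios (floor each size, remainder to the first partition)."""
    if not records:
        raise ValueError("cannot split an empty record list")
    if len(records) < len(spec.ratios):
        raise ValueError("fewer records than partitions")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(records))
    sizes = [int(np.floor(ratio * len(records))) for ratio in spec.ratios]
    sizes[0] += len(records) - sum(sizes)
    parts: list[list] = []
    start = 0
    for size in sizes:
        parts.append([records[k] for k in order[start : start + size]])
        start += size
    return parts


def _partition(records: list[DegradationRecord]) -> tuple[list, list]:
    active = [r for r in records if r.label == ACTIVE]
    inactive = [r for r in records if r.label == INACTIVE]
    return active, inactive


def undersample(records: list[DegradationRecord], seed: int = 0) -> list:
    """Keep all actives; subsample inactives without replacement down to
    the active count (e.g. 988:1844 -> 988:988)."""
    active, inactive = _partition(records)
    rng = np.random.default_rng(seed)
    if len(inactive) > len(active):
        keep = rng.choice(len(inactive), size=len(active), replace=False)
        inactive = [inactive[k] for k in sorted(keep)]
    return active + inactive


def oversample(records: list[DegradationRecord], seed: int = 0) -> list:
    """Keep everything; resample actives with replacement until the counts
    match (e.g. 988:1844 -> 1844:1844)."""
    active, inactive = _partition(records)
    rng = np.random.default_rng(seed)
    extra: list = []
    if active and len(active) < len(inactive):
        picks = rng.integers(0, len(active), size=len(inactive) - len(active))
        extra = [active[k] for k in picks]
    return active + extra + inactive


def class_loss_weights(mode: str = "normal") -> tuple[float, float]:
    """(w_active, w_inactive): normal -> (1, 1); weighted doubles the loss
    of active samples."""
    if mode == "normal":
        return (1.0, 1.0)
    if mode == "weighted":
        return (2.0, 1.0)
    raise ValueError(f"unknown loss mode {mode!r}")


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^\s*[<>]=?\s*(\d+\.?\d*)\s*$")


def _parse_measure(value, record_id: str, what: str) -> float | None:
    """Parse a numeric or range-valued measurement; '<10' resolves to 10
    (the bound taken as the value, logged per record)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip()
    if not s or s.lower() in ("na", "nan", "none", ""):
        return None
    m = _RANGE_RE.match(s)
    if m:
        logger.info("record %s: range-valued %s %r resolved to %s",
                    record_id, what, s, m.group(1))
        return float(m.group(1))
    return float(s)


def read_manifest(path: str | Path) -> list[DegradationRecord]:
    """Read a dataset manifest CSV (UTF-8, header required)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("record_id", "linker_smiles") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns {missing}")
    records = []
    for _, row in df.iterrows():
        rid = str(row["record_id"])
        records.append(
            DegradationRecord(
                record_id=rid,
                poi_name=str(row.get("poi_name", "") or ""),
                e3_name=str(row.get("e3_name", "") or ""),
                poi_structure=str(row.get("poi_structure", "") or ""),
                e3_structure=str(row.get("e3_structure", "") or ""),
                warhead=str(row.get("warhead", "") or ""),
                e3_ligand=str(row.get("e3_ligand", "") or ""),
                linker_smiles=str(row.get("linker_smiles", "") or ""),
                dc50=_parse_measure(row.get("dc50_nM"), rid, "DC50"),
                dmax=_parse_measure(row.get("dmax_pct"), rid, "Dmax"),
                label=(str(row["label"]) if "label" in df.columns
                       and isinstance(row.get("label"), str) else None),
            )
        )
    return records


def write_manifest(records: list[DegradationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id, "poi_name": r.poi_name,
                "e3_name": r.e3_name, "poi_structure": r.poi_structure,
                "poi_ligand": "", "e3_structure": r.e3_structure,
                "e3_ligand": r.e3_ligand, "warhead": r.warhead,
                "linker_smiles": r.linker_smiles,
                "dc50_nM": "" if r.dc50 is None else repr(r.dc50),
                "dmax_pct": "" if r.dmax is None else repr(r.dmax),
                "label": r.label or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_split_ids(parts: list[list[DegradationRecord]], path: str | Path) -> None:
    """Persist a split as JSON lists of record_ids per partition."""
    Path(path).write_text(
        json.dumps([[r.record_id for r in part] for part in parts], indent=1)
    )
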