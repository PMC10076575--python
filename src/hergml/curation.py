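"""Activity-data curation: from raw measurement tables to one labeled
record per unique standardized structure.

The pipeline is: optional target/organism filtering (upstream selection),
exclusion of censored measurements (relation ``>`` or ``<``), conversion of
IC50/EC50/Ki/Kd concentrations to pK = -log10(molar value), structure
standardization (largest organic fragment, neutralization, canonical
SMILES), median aggregation of replicate measurements per structure, and
binary labeling: binder iff pK >= 5 (10 uM), the usual HTS hit threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .evaluation import BINDER, NON_BINDER

logger = logging.getLogger(__name__)

ENDPOINTS = frozenset({"IC50", "EC50", "Ki", "Kd"})
RELATIONS = frozenset({"=", ">", "<"})

#: multiplicative factor to molar
UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,  # micro sign vs greek mu
    "nM": 1e-9,
}

DEFAULT_PK_THRESHOLD = 5.0


class CurationError(ValueError):
    """Raised on invalid activity records or units."""


@dataclass(frozen=True)
class ActivityRecord:
    """A single raw activity measurement."""

    compound_id: str
    smiles: str
    endpoint: str
    relation: str
    value: float
    unit: str

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise CurationError(f"unknown endpoint {self.endpoint!r}")
        if self.relation not in RELATIONS:
            raise CurationError(f"unknown relation {self.relation!r}")
        if not (self.value > 0):
            raise CurationError(f"non-positive activity value {self.value!r}")
        if self.unit not in UNIT_TO_MOLAR:
            raise CurationError(f"unknown unit {self.unit!r}")


@dataclass(frozen=True)
class CuratedCompound:
    """One standardized structure with its representative activity."""

    canonical_smiles: str
    pK: float
    label: str
    n_measurements: int
    compound_id: str = ""


def to_pK(value: float, unit: str) -> float:
    """Convert a concentration to pK = -log10(value in molar).

    (10, uM) -> 5.0; (100, nM) -> 7.0.
    """
    if not (value > 0) or not math.isfinite(value):
        raise CurationError(f"activity value must be positive and finite, got {value!r}")
    try:
        factor = UNIT_TO_MOLAR[unit]
    except KeyError:
        raise CurationError(f"unknown unit {unit!r}") from None
    return -math.log10(value * factor)


def filter_censored(records: Iterable[ActivityRecord]) -> list[ActivityRecord]:
    """Keep only exact measurements (relation '='), preserving order."""
    return [r for r in records if r.relation == "="]


_LARGEST_FRAGMENT = None
_UNCHARGER = None


def _standardizers():
    # lazy: rdMolStandardize objects are mildly expensive to construct
    global _LARGEST_FRAGMENT, _UNCHARGER
    if _LARGEST_FRAGMENT is None:
        _LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
        _UNCHARGER = rdMolStandardize.Uncharger()
    return _LARGEST_FRAGMENT, _UNCHARGER


def standardize_structure(smiles: str) -> str | None:
    """Standardize a structure: strip salts/solvents (keep the largest
    organic fragment), normalize functional groups, neutralize charges
    where a proton can be added or removed, and return canonical SMILES.

    Returns ``None`` (with a logged reason) for unparseable input; the
    caller drops such records.  Idempotent on its own output.
    """
    RDLogger.DisableLog("rdApp.error")
    try:
        mol = Chem.MolFromSmiles(smiles)
    finally:
        RDLogger.EnableLog("rdApp.error")
    if mol is None:
        logger.warning("dropping unparseable structure: %r", smiles)
        return None
    chooser, uncharger = _standardizers()
    try:
        mol = rdMolStandardize.Normalize(mol)
        mol = chooser.choose(mol)
        mol = uncharger.uncharge(mol)
    except Exception as exc:  # pragma: no cover - rdkit edge cases
        logger.warning("standardization failed for %r: %s", smiles, exc)
        return None
    return Chem.MolToSmiles(mol)


def label_compound(pK: float, threshold: float = DEFAULT_PK_THRESHOLD) -> str:
    """Binder iff pK >= threshold (boundary inclusive)."""
    if not math.isfinite(pK):
        raise CurationError(f"pK must be finite, got {pK!r}")
    return BINDER if pK >= threshold else NON_BINDER


def aggregate_duplicates(
    records: Sequence[ActivityRecord],
    canonical_smiles: str,
    threshold: float = DEFAULT_PK_THRESHOLD,
) -> CuratedCompound:
    """Collapse replicate measurements of one structure to its median pK.

    pK values are pooled across endpoint types (IC50/EC50/Ki/Kd) before
    the median; even-sized groups take the midpoint of the two central
    values.
    """
    if len(records) == 0:
        raise CurationError(f"empty record group for {canonical_smiles!r}")
    pks = [to_pK(r.value, r.unit) for r in records]
    pk = float(median(pks))
    return CuratedCompound(
        canonical_smiles=canonical_smiles,
        pK=pk,
        label=label_compound(pk, threshold),
        n_measurements=len(records),
        compound_id=records[0].compound_id,
    )


def curate(
    records: Iterable[ActivityRecord],
    threshold: float = DEFAULT_PK_THRESHOLD,
) -> list[CuratedCompound]:
    """Full curation: censored-value exclusion, standardization, duplicate
    aggregation by canonical structure, labeling.

    Output order follows first appearance of each standardized structure.
    """
    kept = filter_censored(records)
    groups: dict[str, list[ActivityRecord]] = {}
    for rec in kept:
        canonical = standardize_structure(rec.smiles)
        if canonical is None:
            continue
        groups.setdefault(canonical, []).append(rec)
    return [
        aggregate_duplicates(recs, smi, threshold) for smi, recs in groups.items()
    ]


# ---------------------------------------------------------------------------
# tabular I/O

ACTIVITY_COLUMNS = ["compound_id", "smiles", "endpoint", "relation", "value", "unit"]


def read_activity_table(path, target: str | None = None,
                        organism: str | None = None) -> list[ActivityRecord]:
    """Read a delimited activity table (TSV/CSV by extension).

    Optional ``target``/``organism`` columns, when present and when a
    filter value is given, are matched exactly and used as upstream
    selection before curation.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise CurationError(f"activity table missing columns: {missing}")
    if target is not None and "target" in df.columns:
        df = df[df["target"] == target]
    if organism is not None and "organism" in df.columns:
        df = df[df["organism"].str.lower().isin({organism.lower()})]
    return [
        ActivityRecord(
            compound_id=str(row.compound_id),
            smiles=row.smiles,
            endpoint=row.endpoint,
            relation=row.relation,
            value=float(row.value),
            unit=row.unit,
        )
        for row in df.itertuples(index=False)
    ]


def curated_to_frame(compounds: Sequence[CuratedCompound]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "canonical_smiles": [c.canonical_smiles for c in compounds],
            "pK": [c.pK for c in compounds],
            "label": [c.label for c in compounds],
            "n_measurements": [c.n_measurements for c in compounds],
        }
    )


def write_curated_table(compounds: Sequence[CuratedCompound], path) -> None:
    curated_to_frame(compounds).to_csv(path, sep="\t", index=False)
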