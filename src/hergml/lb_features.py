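"""Ligand-based features, fingerprint similarity and chemical-space summaries.

The ligand-based (LB) block is 2059 descriptors per compound: 11 basic
physicochemical properties plus two 1024-bit hashed circular fingerprints
of diameter 6 (radius 3) — one with plain connectivity invariants (ECFP6)
and one with functional-class invariants (FCFP6).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

FP_BITS = 1024
FP_RADIUS = 3  # diameter-6 convention

#: provenance tags for feature columns
TAG_LB_PHYSCHEM = "lb_physchem"
TAG_LB_FP = "lb_fp"
TAG_SB_SCORE = "sb_score"

NO_SCAFFOLD = "no-scaffold"


# ---------------------------------------------------------------------------
# feature matrix container


@dataclass
class FeatureMatrix:
    """Compounds x named features with per-column provenance tags."""

    values: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dups[:5]}")
        for col in self.values.columns:
            self.provenance.setdefault(col, "unknown")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        return FeatureMatrix(
            self.values[list(names)].copy(),
            {n: self.provenance[n] for n in names},
        )

    def join(self, other: "FeatureMatrix") -> "FeatureMatrix":
        """Column-wise join on the intersection of compound ids."""
        common = self.values.index.intersection(other.values.index)
        merged = pd.concat(
            [self.values.loc[common], other.values.loc[common]], axis=1
        )
        prov = {**self.provenance, **other.provenance}
        return FeatureMatrix(merged, prov)

    def write(self, path, schema_path=None) -> None:
        """Persist as TSV with a JSON schema sidecar."""
        self.values.to_csv(path, sep="\t", index_label="compound_id")
        if schema_path is None:
            schema_path = str(path) + ".schema.json"
        schema = {
            "columns": self.feature_names,
            "provenance": self.provenance,
            "fingerprint": {"bits": FP_BITS, "radius": FP_RADIUS},
        }
        with open(schema_path, "w") as fh:
            json.dump(schema, fh, indent=1)

    @classmethod
    def read(cls, path, schema_path=None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="compound_id")
        df.index = df.index.astype(str)
        df.index.name = None
        if schema_path is None:
            schema_path = str(path) + ".schema.json"
        try:
            with open(schema_path) as fh:
                schema = json.load(fh)
            prov = schema.get("provenance", {})
        except FileNotFoundError:
            prov = {}
        return cls(df, prov)


# ---------------------------------------------------------------------------
# descriptors


def _n_atoms_total(mol) -> int:
    return mol.GetNumHeavyAtoms() + sum(a.GetTotalNumHs() for a in mol.GetAtoms())


def _n_stereocenters(mol) -> int:
    return len(
        Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
    )


#: the 11 basic physicochemical properties of the LB block, in fixed order.
PHYSCHEM_DESCRIPTORS = {
    "logP": Descriptors.MolLogP,  # Crippen atom-contribution logP
    "TPSA": Descriptors.TPSA,
    "mol_weight": Descriptors.MolWt,
    "rotatable_bonds": Descriptors.NumRotatableBonds,
    "hbond_donors": Descriptors.NumHDonors,
    "hbond_acceptors": Descriptors.NumHAcceptors,
    "heteroatoms": Descriptors.NumHeteroatoms,
    "atoms": _n_atoms_total,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
    "stereocenters": _n_stereocenters,
    "fraction_csp3": rdMolDescriptors.CalcFractionCSP3,
}

_BASIC_AMINE = Chem.MolFromSmarts("[NX3;!$(N=*);!$(N-C=O);!$(N-S=O);!$(n)]")
_HALOGEN = Chem.MolFromSmarts("[F,Cl,Br,I]")

#: 15 additional 2-D descriptors completing the 26-descriptor set used for
#: chemical-space PCA.  The original analysis used a 26-descriptor panel
#: from a different toolkit that is not enumerated in public sources; this
#: stand-in panel covers the same property families (size, rings,
#: aromaticity, polarity, complexity).
EXTRA_PCA_DESCRIPTORS = {
    "ring_count": rdMolDescriptors.CalcNumRings,
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "aliphatic_rings": rdMolDescriptors.CalcNumAliphaticRings,
    "saturated_rings": rdMolDescriptors.CalcNumSaturatedRings,
    "aromatic_atoms": lambda m: sum(a.GetIsAromatic() for a in m.GetAtoms()),
    "amide_bonds": rdMolDescriptors.CalcNumAmideBonds,
    "bonds": lambda m: m.GetNumBonds(),
    "labute_asa": rdMolDescriptors.CalcLabuteASA,
    "molar_refractivity": Descriptors.MolMR,
    "n_nitrogen": lambda m: sum(a.GetAtomicNum() == 7 for a in m.GetAtoms()),
    "n_oxygen": lambda m: sum(a.GetAtomicNum() == 8 for a in m.GetAtoms()),
    "n_halogen": lambda m: len(m.GetSubstructMatches(_HALOGEN)),
    "basic_amines": lambda m: len(m.GetSubstructMatches(_BASIC_AMINE)),
    "hall_kier_alpha": rdMolDescriptors.CalcHallKierAlpha,
    "bertz_complexity": Descriptors.BertzCT,
}

PCA_DESCRIPTOR_NAMES = list(PHYSCHEM_DESCRIPTORS) + list(EXTRA_PCA_DESCRIPTORS)


@dataclass(frozen=True)
class LBFeatureSchema:
    """Fixed ordering of the 2059-column ligand-based block."""

    physchem_names: tuple[str, ...] = tuple(PHYSCHEM_DESCRIPTORS)
    fp_bits: int = FP_BITS

    @property
    def ecfp_names(self) -> list[str]:
        return [f"ecfp6_{i}" for i in range(self.fp_bits)]

    @property
    def fcfp_names(self) -> list[str]:
        return [f"fcfp6_{i}" for i in range(self.fp_bits)]

    @property
    def all_names(self) -> list[str]:
        return list(self.physchem_names) + self.ecfp_names + self.fcfp_names

    @property
    def n_features(self) -> int:
        return len(self.physchem_names) + 2 * self.fp_bits


_ECFP_GEN = None
_FCFP_GEN = None


def _fp_generators():
    global _ECFP_GEN, _FCFP_GEN
    if _ECFP_GEN is None:
        _ECFP_GEN = rdFingerprintGenerator.GetMorganGenerator(
            radius=FP_RADIUS, fpSize=FP_BITS
        )
        _FCFP_GEN = rdFingerprintGenerator.GetMorganGenerator(
            radius=FP_RADIUS,
            fpSize=FP_BITS,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
    return _ECFP_GEN, _FCFP_GEN


def ecfp6(mol_or_smiles) -> np.ndarray:
    """Plain-invariant 1024-bit circular fingerprint (radius 3)."""
    mol = _as_mol(mol_or_smiles)
    gen, _ = _fp_generators()
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


def fcfp6(mol_or_smiles) -> np.ndarray:
    """Functional-class 1024-bit circular fingerprint (radius 3)."""
    mol = _as_mol(mol_or_smiles)
    _, gen = _fp_generators()
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


def _as_mol(mol_or_smiles):
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"unparseable structure {mol_or_smiles!r}")
        return mol
    return mol_or_smiles


def physchem_row(mol, descriptors=PHYSCHEM_DESCRIPTORS) -> list[float]:
    return [float(fn(mol)) for fn in descriptors.values()]


def compute_lb_features(
    compounds: Iterable, schema: LBFeatureSchema | None = None
) -> FeatureMatrix:
    """Compute the 2059-column LB feature block.

    ``compounds`` may be curated-compound objects (``canonical_smiles`` +
    ``compound_id`` attributes), ``(id, smiles)`` pairs, or bare SMILES.
    Unparseable structures are skipped with a logged reason.
    """
    schema = schema or LBFeatureSchema()
    ids, rows = [], []
    for i, comp in enumerate(compounds):
        if isinstance(comp, str):
            cid, smi = f"cmpd_{i}", comp
        elif isinstance(comp, (tuple, list)):
            cid, smi = comp
        else:
            cid, smi = comp.compound_id, comp.canonical_smiles
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("skipping unparseable structure %s: %r", cid, smi)
            continue
        row = physchem_row(mol)
        row.extend(ecfp6(mol))
        row.extend(fcfp6(mol))
        ids.append(str(cid))
        rows.append(row)
    df = pd.DataFrame(rows, index=ids, columns=schema.all_names, dtype=float)
    prov = {n: TAG_LB_PHYSCHEM for n in schema.physchem_names}
    prov.update({n: TAG_LB_FP for n in schema.ecfp_names + schema.fcfp_names})
    return FeatureMatrix(df, prov)


# ---------------------------------------------------------------------------
# similarity


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two bit vectors.

    Defined as 1.0 when both vectors are all-zero (two featureless
    structures are treated as identical).
    """
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return float(np.sum(a & b) / union)


def bulk_tanimoto(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Tanimoto of one query fingerprint against a stacked reference
    matrix (n_ref x n_bits); all-zero pairs give 1.0."""
    q = np.asarray(query).astype(bool)
    ref = np.asarray(reference).astype(bool)
    inter = (ref & q).sum(axis=1)
    union = (ref | q).sum(axis=1)
    out = np.ones(len(ref), dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def nearest_neighbor_tc(query_fps: np.ndarray, reference_fps: np.ndarray) -> np.ndarray:
    """Max Tanimoto of each query fingerprint to the reference set."""
    ref = np.asarray(reference_fps).astype(bool)
    if ref.ndim != 2 or len(ref) == 0:
        raise ValueError("reference fingerprint set must be a non-empty matrix")
    return np.array([bulk_tanimoto(q, ref).max() for q in np.asarray(query_fps)])


# ---------------------------------------------------------------------------
# scaffold analysis


def murcko_scaffold_summary(compounds: Sequence) -> pd.DataFrame:
    """Frequency table of Murcko frameworks with per-scaffold pK stats.

    One row per distinct framework sorted by descending count (ties by
    scaffold SMILES); acyclic molecules are pooled under ``no-scaffold``.
    The pK standard deviation is the population SD (0 for singletons).
    """
    rows = []
    for comp in compounds:
        mol = Chem.MolFromSmiles(comp.canonical_smiles)
        if mol is None:
            continue
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
        rows.append((scaffold if scaffold else NO_SCAFFOLD, comp.pK))
    if not rows:
        return pd.DataFrame(columns=["scaffold", "count", "mean_pK", "sd_pK"])
    df = pd.DataFrame(rows, columns=["scaffold", "pK"])
    out = (
        df.groupby("scaffold")["pK"]
        .agg(count="size", mean_pK="mean", sd_pK=lambda s: float(np.std(s, ddof=0)))
        .reset_index()
        .sort_values(["count", "scaffold"], ascending=[False, True])
        .reset_index(drop=True)
    )
    out["count"] = out["count"].astype(int)
    return out


# ---------------------------------------------------------------------------
# chemical-space PCA


def compute_pca_descriptors(compounds: Iterable) -> pd.DataFrame:
    """The 26-descriptor panel used for chemical-space analysis."""
    descriptors = {**PHYSCHEM_DESCRIPTORS, **EXTRA_PCA_DESCRIPTORS}
    ids, rows = [], []
    for i, comp in enumerate(compounds):
        if isinstance(comp, str):
            cid, smi = f"cmpd_{i}", comp
        elif isinstance(comp, (tuple, list)):
            cid, smi = comp
        else:
            cid, smi = comp.compound_id, comp.canonical_smiles
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("skipping unparseable structure %s", cid)
            continue
        ids.append(str(cid))
        rows.append([float(fn(mol)) for fn in descriptors.values()])
    return pd.DataFrame(rows, index=ids, columns=list(descriptors))


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scaler: StandardScaler
    pca: PCA
    columns: list[str]

    def transform(self, descriptors: pd.DataFrame) -> np.ndarray:
        z = self.scaler.transform(descriptors[self.columns].to_numpy())
        return self.pca.transform(z) * self._signs

    _signs: np.ndarray = field(default_factory=lambda: np.array([1.0]))


def chemspace_pca(descriptors: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of standardized descriptors for chemical-space visualisation.

    Columns are standardized to zero mean / unit variance first; constant
    columns are dropped with a warning.  The sign of each component is
    fixed so its largest-magnitude loading is positive.
    """
    if len(descriptors) < 3:
        raise ValueError("PCA needs at least 3 compounds")
    X = descriptors.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(descriptors.columns, keep) if not k]
        warnings.warn(f"dropping constant descriptor columns: {dropped}")
        descriptors = descriptors.loc[:, keep]
        X = descriptors.to_numpy(dtype=float)
    n_components = min(n_components, X.shape[1], X.shape[0])
    scaler = StandardScaler()
    Z = scaler.fit_transform(X)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    # deterministic sign: largest |loading| positive per component
    signs = np.ones(n_components)
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            signs[k] = -1.0
    scores = scores * signs
    loadings = pd.DataFrame(
        (pca.components_.T * signs),
        index=descriptors.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    result = PCAResult(
        scores=pd.DataFrame(
            scores, index=descriptors.index,
            columns=[f"PC{k + 1}" for k in range(n_components)],
        ),
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scaler=scaler,
        pca=pca,
        columns=list(descriptors.columns),
    )
    result._signs = signs
    return result
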