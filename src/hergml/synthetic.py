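"""Synthetic compound cohorts and docking-like pose-score tables.

The generator stands in for the proprietary activity sources and docking
engines of a hERG-liability modelling campaign, so that every downstream
stage (curation, featurization, selection, modelling, applicability
domain) runs on data with known ground truth.

Structures are assembled from a closed fragment grammar (aryl heads,
short linkers, amine-bearing tails — the motifs that dominate hERG
binder scaffolds), so descriptor and fingerprint computation is real
chemistry on valid molecules.  Each compound carries a latent binding
affinity driven by its computed lipophilicity (binders more lipophilic)
and polar surface area (binders less polar), plus per-fragment
contributions and noise; the emitted pK is an affine function of that
affinity calibrated so a configurable fraction of the cohort sits at or
above the pK 5 binder threshold, with the bulk of the mass concentrated
near the threshold.  Pose scores follow a latent-factor model: every
scoring function loads positively on (affinity + a shared per-pose
geometry deviation), so averaging over poses denoises while best-pose
selection inflates the deviation of the top-ranked pose.

All magnitudes of the score model are artifact choices — the emulated
engines publish no distributional facts — and are documented as such.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .curation import ActivityRecord, label_compound
from .sb_features import PoseScoreTable, write_pose_table

# ---------------------------------------------------------------------------
# fragment grammar
#
# Each structure is head + linker + linker + tail; every fragment is a SMILES
# substring whose last written atom accepts a further bond (heads, linkers)
# or whose first atom bonds to the preceding fragment (linkers, tails), so
# plain concatenation always yields a valid molecule.

HEADS = (
    "c1ccccc1",            # phenyl
    "c1ccc(F)cc1",         # 4-fluorophenyl
    "c1ccc(Cl)cc1",        # 4-chlorophenyl
    "c1ccc(OC)cc1",        # 4-methoxyphenyl
    "c1ccncc1",            # pyridin-4-yl
    "c1cccnc1",            # pyridin-3-yl
    "c1ccc2ccccc2c1",      # naphthyl
    "C1CCCCC1",            # cyclohexyl
    "Cc1ccccc1",           # o-tolyl (attachment on ring)
    "c1ccc(C)cc1",         # p-tolyl
)

LINKERS = (
    "CC",       # ethylene
    "CCC",      # propylene
    "OCC",      # oxyethylene
    "CNC",      # methylaminomethyl
    "C(=O)C",   # keto
    "CCOC",     # ethoxymethyl
    "CCCC",     # butylene
    "OCCC",     # oxypropylene
)

TAILS = (
    "N1CCNCC1",      # piperazine
    "N1CCCCC1",      # piperidine
    "N1CCN(C)CC1",   # N-methylpiperazine
    "N1CCOCC1",      # morpholine
    "N1CCCC1",       # pyrrolidine
    "N(C)C",         # dimethylamine
    "NCC",           # ethylamine
    "NCCN",          # ethylenediamine
    "NC1CCCCC1",     # cyclohexylamine
    "NCCO",          # aminoethanol
)

#: disjoint sub-grammar used for external sets of rising dissimilarity
ALT_HEADS = (
    "c1ccsc1",        # thienyl
    "c1ccoc1",        # furyl
    "c1ncncc1",       # pyrimidinyl
    "C1CCCC1",        # cyclopentyl
    "C1CCCCCC1",      # cycloheptyl
    "c1ccc(Br)cc1",   # 4-bromophenyl
)

ALT_LINKERS = (
    "CCS",        # thioether
    "C(F)(F)C",   # gem-difluoro
    "CCCCC",      # pentylene
    "C(C)C",      # isopropylene
)

ALT_TAILS = (
    "N1CCSCC1",       # thiomorpholine
    "NC(C)C",         # isopropylamine
    "N1CCC(O)CC1",    # 4-hydroxypiperidine
    "OC1CCCCC1",      # cyclohexyl ether
    "NCCCN",          # propylenediamine
)

DISSIMILARITY_LEVELS = {"low": 0.25, "medium": 0.6, "high": 1.0}

#: fixed reference scales putting computed logP / TPSA on a common footing
#: across cohorts (roughly the grammar-wide mean and SD)
_LOGP_CENTER, _LOGP_SCALE = 2.0, 1.3
_TPSA_CENTER, _TPSA_SCALE = 25.0, 14.0

#: per-column pose noise as a fraction of the shared pose-deviation SD
_POSE_COLUMN_NOISE_RATIO = 0.3

DEFAULT_ENGINES = ("PLANTS", "LiGen", "GOLD")

#: native primary-score name and ranking convention per emulated engine
PRIMARY_SCORE = {"PLANTS": "CHEMPLP", "LiGen": "CSOPT", "GOLD": "GOLDFITNESS"}
PRIMARY_DIRECTION = {"PLANTS": "lower", "LiGen": "lower", "GOLD": "higher"}

LIGEN_MODE_ENGINES = {"LiGen"}


class ConfigError(ValueError):
    """Invalid generator configuration; names the offending field."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated campaign: a 7303/12789 binder fraction,
    pK mass centred on the 5.0 threshold, five poses per molecule per
    engine, one primary score plus 25 rescoring functions (a 29-column
    pharmacophore-distance block is added in LiGen mode for an engine
    total of 55), and a 2.4% per-engine docking-failure rate.
    """

    n_compounds: int = 1000
    binder_fraction: float = 7303 / 12789
    pk_center: float = 5.0
    pk_spread: float = 1.2
    pk_noise_sd: float = 0.3
    lipophilicity_shift: float = 1.0
    polarity_shift: float = 0.6
    fragment_effect_sd: float = 0.5
    affinity_noise_sd: float = 0.5
    n_poses: int = 5
    engines: tuple[str, ...] = DEFAULT_ENGINES
    n_rescoring: int = 25
    n_pharmacophore_distances: int = 29
    pose_noise_sd: float = 1.0
    compound_noise_sd: float = 0.8
    engine_bias_sd: float = 0.25
    undocked_fraction: float = 0.024
    stereoisomer_fraction: float = 0.2
    duplicate_fraction: float = 0.1
    censored_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 0:
            raise ConfigError("n_compounds must be >= 0")
        for name in ("binder_fraction",):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        for name in ("undocked_fraction", "stereoisomer_fraction",
                     "duplicate_fraction", "censored_fraction"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        for name in ("pk_spread", "pk_noise_sd", "pose_noise_sd",
                     "compound_noise_sd", "engine_bias_sd",
                     "fragment_effect_sd", "affinity_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_poses < 1:
            raise ConfigError("n_poses must be >= 1")
        if self.n_rescoring < 1:
            raise ConfigError("n_rescoring must be >= 1")
        if self.n_pharmacophore_distances < 0:
            raise ConfigError("n_pharmacophore_distances must be >= 0")
        if len(self.engines) == 0:
            raise ConfigError("engines must be non-empty")


@dataclass
class SyntheticCohort:
    """Generated compounds, their raw activity records, per-engine pose
    tables, and the latent truth behind them."""

    compounds: pd.DataFrame
    activity_records: list[ActivityRecord]
    pose_tables: dict[str, PoseScoreTable]
    truth: pd.DataFrame
    config: GeneratorConfig

    @property
    def compound_ids(self) -> list[str]:
        return list(self.compounds["compound_id"])

    @property
    def labels(self) -> pd.Series:
        return self.compounds.set_index("compound_id")["label"]

    def write_activity_table(self, path) -> None:
        rows = [
            {
                "compound_id": r.compound_id,
                "smiles": r.smiles,
                "endpoint": r.endpoint,
                "relation": r.relation,
                "value": r.value,
                "unit": r.unit,
            }
            for r in self.activity_records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_sdf(self, path) -> None:
        writer = Chem.SDWriter(str(path))
        for row in self.compounds.itertuples(index=False):
            mol = Chem.MolFromSmiles(row.smiles)
            if mol is None:
                continue
            mol.SetProp("_Name", row.compound_id)
            mol.SetProp("pK", f"{row.pK:.4f}")
            writer.write(mol)
        writer.close()


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf8"))


def _fragment_effect(fragment: str, seed: int, sd: float) -> float:
    """Per-fragment activity contribution, a deterministic function of
    (fragment, master seed) so training and external cohorts built from
    the same seed agree on shared fragments."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, _stable_hash(fragment)])
    return float(rng.normal(0.0, sd))


def _build_structures(
    n: int,
    rng: np.random.Generator,
    alt_probability: float = 0.0,
) -> pd.DataFrame:
    """Sample head + linker + linker + tail structures.

    ``alt_probability`` is the per-slot chance of drawing from the
    disjoint alternate sub-grammar (0 for training cohorts).
    """
    def pick(main: tuple, alt: tuple, size: int) -> np.ndarray:
        main_idx = rng.integers(len(main), size=size)
        choices = np.array(main, dtype=object)[main_idx]
        if alt_probability > 0:
            alt_idx = rng.integers(len(alt), size=size)
            use_alt = rng.random(size) < alt_probability
            choices = np.where(use_alt, np.array(alt, dtype=object)[alt_idx], choices)
        return choices

    heads = pick(HEADS, ALT_HEADS, n)
    link_a = pick(LINKERS, ALT_LINKERS, n)
    link_b = pick(LINKERS, ALT_LINKERS, n)
    tails = pick(TAILS, ALT_TAILS, n)
    smiles = [h + a + b + t for h, a, b, t in zip(heads, link_a, link_b, tails)]
    return pd.DataFrame(
        {"smiles": smiles, "head": heads, "link_a": link_a,
         "link_b": link_b, "tail": tails}
    )


def generate_cohort(
    config: GeneratorConfig,
    with_pose_tables: bool = True,
    id_prefix: str = "SYN",
    alt_probability: float = 0.0,
    effect_seed: int | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort under the given study conditions.

    Identical config (and prefix) gives byte-identical output.
    ``effect_seed`` keys the per-fragment activity contributions
    (defaults to ``config.seed``); external sets pass the training seed so
    shared fragments keep the same contribution across cohorts.
    """
    n = config.n_compounds
    if effect_seed is None:
        effect_seed = config.seed
    if n == 0:
        empty = pd.DataFrame(
            columns=["compound_id", "smiles", "pK", "label", "n_isomers"]
        )
        truth = pd.DataFrame(columns=["affinity", "logP", "TPSA", "pK_clean"])
        return SyntheticCohort(empty, [], {}, truth, config)

    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 1])
    parts = _build_structures(n, rng, alt_probability)

    logp = np.empty(n)
    tpsa = np.empty(n)
    for i, smi in enumerate(parts["smiles"]):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # cannot happen with the closed grammar
            raise RuntimeError(f"grammar produced invalid structure {smi!r}")
        logp[i] = Descriptors.MolLogP(mol)
        tpsa[i] = Descriptors.TPSA(mol)

    frag_eff = np.array(
        [
            _fragment_effect(h, effect_seed, config.fragment_effect_sd)
            + _fragment_effect(t, effect_seed, config.fragment_effect_sd)
            for h, t in zip(parts["head"], parts["tail"])
        ]
    )

    affinity = (
        config.lipophilicity_shift * (logp - _LOGP_CENTER) / _LOGP_SCALE
        - config.polarity_shift * (tpsa - _TPSA_CENTER) / _TPSA_SCALE
        + frag_eff
        + rng.normal(0.0, config.affinity_noise_sd, size=n)
    )

    # calibrate so that the binder_fraction quantile of clean pK sits at
    # the threshold (= pk_center)
    scale = affinity.std() or 1.0
    a_std = affinity / scale
    offset = float(np.quantile(a_std, 1.0 - config.binder_fraction))
    pk_clean = config.pk_center + config.pk_spread * (a_std - offset)
    pk = pk_clean + rng.normal(0.0, config.pk_noise_sd, size=n)

    ids = [f"{id_prefix}{i:06d}" for i in range(n)]
    n_isomers = np.where(
        rng.random(n) < config.stereoisomer_fraction, 2, 1
    ).astype(int)
    labels = [label_compound(v, config.pk_center) for v in pk]

    compounds = pd.DataFrame(
        {
            "compound_id": ids,
            "smiles": parts["smiles"].to_numpy(),
            "pK": pk,
            "label": labels,
            "n_isomers": n_isomers,
        }
    )
    truth = pd.DataFrame(
        {
            "affinity": a_std,
            "logP": logp,
            "TPSA": tpsa,
            "fragment_effect": frag_eff,
            "pK_clean": pk_clean,
        },
        index=pd.Index(ids, name="compound_id"),
    )

    records = _activity_records(compounds, rng, config)

    cohort = SyntheticCohort(compounds, records, {}, truth, config)
    if with_pose_tables:
        for engine in config.engines:
            cohort.pose_tables[engine] = generate_pose_scores(
                cohort, engine, config
            )
    return cohort


def _activity_records(
    compounds: pd.DataFrame, rng: np.random.Generator, config: GeneratorConfig
) -> list[ActivityRecord]:
    """Emit one exact measurement per compound, plus replicate
    measurements in a different unit for a fraction of compounds and
    extra censored rows (excluded downstream) for another fraction."""
    records: list[ActivityRecord] = []
    endpoints = np.array(["IC50", "EC50", "Ki", "Kd"])
    ep_idx = rng.integers(len(endpoints), size=len(compounds))
    dup_mask = rng.random(len(compounds)) < config.duplicate_fraction
    cens_mask = rng.random(len(compounds)) < config.censored_fraction
    for i, row in enumerate(compounds.itertuples(index=False)):
        molar = 10.0 ** (-row.pK)
        unit, factor = ("nM", 1e-9) if row.pK >= 7.5 else ("uM", 1e-6)
        records.append(
            ActivityRecord(
                compound_id=row.compound_id,
                smiles=row.smiles,
                endpoint=str(endpoints[ep_idx[i]]),
                relation="=",
                value=molar / factor,
                unit=unit,
            )
        )
        if dup_mask[i]:
            # same underlying measurement reported in another unit
            alt_unit, alt_factor = ("mM", 1e-3) if row.pK < 4.5 else ("nM", 1e-9)
            records.append(
                ActivityRecord(
                    compound_id=row.compound_id,
                    smiles=row.smiles,
                    endpoint="IC50",
                    relation="=",
                    value=molar / alt_factor,
                    unit=alt_unit,
                )
            )
        if cens_mask[i]:
            records.append(
                ActivityRecord(
                    compound_id=row.compound_id,
                    smiles=row.smiles,
                    endpoint="IC50",
                    relation=">",
                    value=10.0,
                    unit="uM",
                )
            )
    return records


def _engine_score_names(engine: str, config: GeneratorConfig) -> list[str]:
    primary = PRIMARY_SCORE.get(engine, f"{engine.upper()}_PRIMARY")
    names = [primary] + [f"rescore_{i:02d}" for i in range(1, config.n_rescoring + 1)]
    if engine in LIGEN_MODE_ENGINES:
        names += [
            f"pharmdist_{i:02d}"
            for i in range(1, config.n_pharmacophore_distances + 1)
        ]
    return names


def generate_pose_scores(
    cohort: SyntheticCohort, engine: str, config: GeneratorConfig | None = None
) -> PoseScoreTable:
    """Docking-like pose scores for one engine.

    Latent-factor model per row (compound c, isomer s, pose p, column f):

        raw = loading_f * (affinity_c + dev_{c,s,p}) + bias_f
              + compound_noise_{c} + eps_{c,s,p,f}

    with ``dev`` the shared per-pose geometry deviation (SD
    ``pose_noise_sd``), ``eps`` small per-column pose noise (30% of the
    deviation SD), per-column engine bias, and per-compound engine error.
    Pose rank 1 is the best raw primary score; engines whose native
    convention is lower-is-better emit the primary column negated.
    Stereoisomers share the compound's affinity and engine error but draw
    independent pose deviations.  A seeded per-engine fraction of
    compounds fails to dock and is absent from the table.
    """
    config = config or cohort.config
    if engine not in config.engines:
        raise ConfigError(f"unknown engine {engine!r} (have {list(config.engines)})")
    engine_idx = list(config.engines).index(engine)
    names = _engine_score_names(engine, config)
    n_cols = len(names)
    n_pharm = (
        config.n_pharmacophore_distances if engine in LIGEN_MODE_ENGINES else 0
    )

    load_rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 2, engine_idx])
    loadings = load_rng.uniform(0.3, 1.0, size=n_cols)
    if n_pharm:
        # pharmacophore distances: weakly informative, offset to a
        # distance-like scale
        loadings[-n_pharm:] = load_rng.uniform(0.1, 0.4, size=n_pharm)
    bias = load_rng.normal(0.0, config.engine_bias_sd, size=n_cols)
    if n_pharm:
        bias[-n_pharm:] += 6.0

    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 3, engine_idx])
    n = len(cohort.compounds)
    docked = rng.random(n) >= config.undocked_fraction
    cnoise = rng.normal(0.0, config.compound_noise_sd, size=n)

    affinity = cohort.truth["affinity"].to_numpy()
    n_isomers = cohort.compounds["n_isomers"].to_numpy()
    ids = cohort.compounds["compound_id"].to_numpy()

    frames = []
    n_poses = config.n_poses
    for c in np.flatnonzero(docked):
        for iso in range(1, int(n_isomers[c]) + 1):
            dev = rng.normal(0.0, config.pose_noise_sd, size=n_poses)
            eps = rng.normal(
                0.0,
                _POSE_COLUMN_NOISE_RATIO * config.pose_noise_sd,
                size=(n_poses, n_cols),
            )
            raw = (
                np.outer(affinity[c] + dev, loadings)
                + bias
                + cnoise[c]
                + eps
            )
            order = np.argsort(-raw[:, 0], kind="stable")
            ranked = raw[order]
            frames.append(
                pd.DataFrame(
                    ranked,
                    index=pd.MultiIndex.from_arrays(
                        [
                            [ids[c]] * n_poses,
                            [str(iso)] * n_poses,
                            np.arange(1, n_poses + 1),
                        ],
                        names=["compound_id", "isomer_id", "pose_rank"],
                    ),
                    columns=names,
                )
            )
    if not frames:
        data = pd.DataFrame(
            columns=names,
            index=pd.MultiIndex.from_arrays(
                [[], [], []], names=["compound_id", "isomer_id", "pose_rank"]
            ),
        )
    else:
        data = pd.concat(frames)

    directions = {name: "higher" for name in names}
    primary = names[0]
    if PRIMARY_DIRECTION.get(engine, "higher") == "lower":
        data[primary] = -data[primary]
        directions[primary] = "lower"
    return PoseScoreTable(engine=engine, data=data, directions=directions)


def write_pose_tables_dir(cohort: SyntheticCohort, outdir) -> list[str]:
    """Write each engine's pose table as ``poses_<engine>.tsv``."""
    from pathlib import Path

    outdir = Path(outdir)
    paths = []
    for engine, table in cohort.pose_tables.items():
        path = outdir / f"poses_{engine}.tsv"
        write_pose_table(table, path)
        paths.append(str(path))
    return paths


def generate_external_set(
    config: GeneratorConfig,
    dissimilarity_level: str = "medium",
    with_pose_tables: bool = False,
) -> SyntheticCohort:
    """An external validation cohort drawn partly from a disjoint
    fragment sub-grammar.

    ``dissimilarity_level`` in {low, medium, high} sets the per-slot
    probability of sampling the alternate grammar, shifting the
    nearest-neighbor Tanimoto distribution against a training cohort
    progressively downward.  Fragment activity contributions are shared
    with the training cohort for shared fragments (same master seed) and
    fresh for alternate fragments.
    """
    if dissimilarity_level not in DISSIMILARITY_LEVELS:
        raise ConfigError(
            f"dissimilarity_level must be one of {sorted(DISSIMILARITY_LEVELS)}"
        )
    level_idx = sorted(DISSIMILARITY_LEVELS).index(dissimilarity_level)
    ext_config = replace(
        config, seed=(config.seed & 0x3FFFFFFF) + 0x10000000 + level_idx
    )
    cohort = generate_cohort(
        ext_config,
        with_pose_tables=with_pose_tables,
        id_prefix=f"EXT{dissimilarity_level[0].upper()}",
        alt_probability=DISSIMILARITY_LEVELS[dissimilarity_level],
        effect_seed=config.seed,
    )
    return cohort
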