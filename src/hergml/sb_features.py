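"""Structure-based features from multi-engine, multi-pose docking scores.

Docking engines emit several ranked poses per ligand (per stereoisomer),
each rescored with a battery of scoring functions.  Two per-compound
aggregations are supported:

* **best pose (BP)** — take each isomer's rank-1 pose and average the
  score vectors across isomers;
* **average (AV)** — the pooled mean over all poses of all isomers,
  treating the pose ensemble as a sample of the compound's binding space.

A consensus feature set concatenates the per-engine matrices
(engine-prefixed column names) on the intersection of successfully docked
compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .lb_features import FeatureMatrix, TAG_SB_SCORE

logger = logging.getLogger(__name__)

POSE_COLUMNS = ["compound_id", "isomer_id", "engine", "pose_rank", "score_name", "value"]

BEST_POSE = "best_pose"
AVERAGE = "average"


class PoseTableError(ValueError):
    """Structured pose-table validation failure."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        msg = "; ".join(violations[:10])
        if len(violations) > 10:
            msg += f" (+{len(violations) - 10} more)"
        super().__init__(msg)


@dataclass(frozen=True)
class AggregationSpec:
    mode: str = BEST_POSE
    isomer_policy: str = "average_of_best"
    missing_policy: str = "drop"

    def __post_init__(self):
        if self.mode not in (BEST_POSE, AVERAGE):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")
        if self.isomer_policy not in ("average_of_best", "pooled_mean"):
            raise ValueError(f"unknown isomer policy {self.isomer_policy!r}")
        if self.missing_policy not in ("drop", "error"):
            raise ValueError(f"unknown missing policy {self.missing_policy!r}")


@dataclass
class PoseScoreTable:
    """Validated single-engine pose scores in wide form.

    ``data`` is indexed by (compound_id, isomer_id, pose_rank) with one
    column per scoring function.  ``directions`` records, per score name,
    whether higher or lower values indicate a better pose; it is metadata
    only and is never used to flip values during aggregation.
    """

    engine: str
    data: pd.DataFrame
    directions: dict[str, str] = field(default_factory=dict)

    @property
    def score_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self.data.index.get_level_values("compound_id").unique())

    def to_long(self) -> pd.DataFrame:
        long = (
            self.data.stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_3": "score_name"})
        )
        long.insert(2, "engine", self.engine)
        return long[POSE_COLUMNS]


def validate_pose_table(
    rows: pd.DataFrame, engine: str | None = None,
    directions: dict[str, str] | None = None,
) -> PoseScoreTable:
    """Validate long-format pose rows and return a typed wide table.

    Checks: required columns present; a single engine; no duplicate
    (compound, isomer, pose_rank, score_name) keys; pose ranks contiguous
    from 1 for every (compound, isomer); identical score-name set for
    every pose.  Violations are collected and raised together.
    """
    violations: list[str] = []
    missing = [c for c in POSE_COLUMNS if c not in rows.columns]
    if missing:
        raise PoseTableError([f"missing columns: {missing}"])

    engines = sorted(rows["engine"].unique())
    if engine is not None:
        rows = rows[rows["engine"] == engine]
        if rows.empty:
            raise PoseTableError([f"no rows for engine {engine!r} (found {engines})"])
    elif len(engines) > 1:
        raise PoseTableError(
            [f"multiple engines in one table: {engines}; pass engine= to select"]
        )
    else:
        engine = engines[0]

    key_cols = ["compound_id", "isomer_id", "pose_rank", "score_name"]
    dup = rows.duplicated(subset=key_cols, keep=False)
    if dup.any():
        for key in rows.loc[dup, key_cols].drop_duplicates().itertuples(index=False):
            violations.append(f"duplicate key {tuple(key)}")

    # rank contiguity per (compound, isomer)
    ranks = rows.groupby(["compound_id", "isomer_id"])["pose_rank"].agg(set)
    for (cid, iso), rankset in ranks.items():
        expected = set(range(1, len(rankset) + 1))
        if rankset != expected:
            violations.append(
                f"non-contiguous pose ranks {sorted(rankset)} for ({cid}, {iso})"
            )

    # score-name consistency across poses
    names_per_pose = rows.groupby(["compound_id", "isomer_id", "pose_rank"])[
        "score_name"
    ].agg(frozenset)
    if names_per_pose.nunique() > 1:
        counts = names_per_pose.value_counts()
        majority = counts.index[0]
        bad = names_per_pose[names_per_pose != majority]
        for key in bad.index[:20]:
            violations.append(f"inconsistent score names for {key}")

    if violations:
        raise PoseTableError(violations)

    wide = rows.pivot_table(
        index=["compound_id", "isomer_id", "pose_rank"],
        columns="score_name",
        values="value",
        aggfunc="first",
        sort=True,
    )
    wide.columns.name = None
    return PoseScoreTable(engine=engine, data=wide, directions=dict(directions or {}))


def _check_roster(
    table: PoseScoreTable,
    expected_compounds: Sequence[str] | None,
    spec: AggregationSpec,
) -> None:
    if expected_compounds is None:
        return
    docked = set(table.data.index.get_level_values("compound_id"))
    missing = sorted(set(map(str, expected_compounds)) - docked)
    if not missing:
        return
    if spec.missing_policy == "error":
        raise PoseTableError(
            [f"compound {c} has no poses for engine {table.engine}" for c in missing]
        )
    logger.info(
        "engine %s: %d compounds without poses dropped", table.engine, len(missing)
    )


def best_pose_features(
    table: PoseScoreTable,
    spec: AggregationSpec = AggregationSpec(mode=BEST_POSE),
    expected_compounds: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Best-pose (BP) features: each isomer's rank-1 score vector, averaged
    across stereoisomers of the same compound."""
    _check_roster(table, expected_compounds, spec)
    rank1 = table.data.xs(1, level="pose_rank")
    agg = rank1.groupby(level="compound_id").mean().sort_index()
    return FeatureMatrix(agg, {c: TAG_SB_SCORE for c in agg.columns})


def average_pose_features(
    table: PoseScoreTable,
    spec: AggregationSpec = AggregationSpec(mode=AVERAGE, isomer_policy="pooled_mean"),
    expected_compounds: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Average (AV) features: pooled column-wise mean over all poses of all
    isomers of each compound.  With equal pose counts per isomer this
    equals the mean of per-isomer means."""
    _check_roster(table, expected_compounds, spec)
    agg = table.data.groupby(level="compound_id").mean().sort_index()
    return FeatureMatrix(agg, {c: TAG_SB_SCORE for c in agg.columns})


def aggregate(table: PoseScoreTable, spec: AggregationSpec,
              expected_compounds: Sequence[str] | None = None) -> FeatureMatrix:
    if spec.mode == BEST_POSE:
        return best_pose_features(table, spec, expected_compounds)
    return average_pose_features(table, spec, expected_compounds)


def assemble_consensus_features(
    matrices: dict[str, FeatureMatrix] | Sequence[tuple[str, FeatureMatrix]],
) -> FeatureMatrix:
    """Concatenate per-engine feature matrices column-wise.

    Column names are prefixed ``<engine>__``; compounds are restricted to
    the intersection of all engines (a compound undocked by any single
    engine is dropped, with a log message).  Raises on an empty
    intersection or fewer than two engines.
    """
    items = list(matrices.items()) if isinstance(matrices, dict) else list(matrices)
    if len(items) < 2:
        raise ValueError("consensus assembly needs at least two engines")
    common = None
    for _, fm in items:
        ids = set(fm.values.index)
        common = ids if common is None else common & ids
    if not common:
        raise ValueError("no compound docked by every engine")
    n_union = len(set().union(*(set(fm.values.index) for _, fm in items)))
    if len(common) < n_union:
        logger.info(
            "consensus assembly: %d of %d compounds docked by all engines",
            len(common), n_union,
        )
    ordered = sorted(common)
    parts, prov = [], {}
    for engine, fm in items:
        part = fm.values.loc[ordered].copy()
        part.columns = [f"{engine}__{c}" for c in part.columns]
        parts.append(part)
        prov.update({c: TAG_SB_SCORE for c in part.columns})
    return FeatureMatrix(pd.concat(parts, axis=1), prov)


def read_pose_table(path, engine: str | None = None,
                    directions: dict[str, str] | None = None) -> PoseScoreTable:
    """Read a long-format delimited pose-score table and validate it."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    rows = pd.read_csv(path, sep=sep, dtype={"compound_id": str, "isomer_id": str})
    return validate_pose_table(rows, engine=engine, directions=directions)


def write_pose_table(table: PoseScoreTable, path) -> None:
    table.to_long().to_csv(path, sep="\t", index=False)
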