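"""Generator contracts: determinism, class structure, pose-score model."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from scipy.stats import pearsonr

from hergml.lb_features import ecfp6, nearest_neighbor_tc
from hergml.sb_features import average_pose_features, best_pose_features
from hergml.synthetic import (
    ConfigError,
    GeneratorConfig,
    PRIMARY_DIRECTION,
    generate_cohort,
    generate_external_set,
    generate_pose_scores,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("binder_fraction", 0.0),
            ("binder_fraction", 1.0),
            ("undocked_fraction", 1.0),
            ("undocked_fraction", -0.1),
            ("n_poses", 0),
            ("pose_noise_sd", -1.0),
            ("n_compounds", -5),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError, match=field):
            GeneratorConfig(**{field: value})


class TestCohortGeneration:
    def test_compound_count_and_class_balance(self):
        cohort = generate_cohort(
            GeneratorConfig(n_compounds=100, binder_fraction=0.5, seed=7),
            with_pose_tables=False,
        )
        assert len(cohort.compounds) == 100
        n_binders = (cohort.compounds["label"] == "binder").sum()
        # quantile calibration puts the count near 50; pK noise jitters it
        assert 35 <= n_binders <= 65

    def test_structures_are_valid_molecules(self, small_cohort):
        for smi in small_cohort.compounds["smiles"]:
            assert Chem.MolFromSmiles(smi) is not None

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(n_compounds=60, seed=21)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.compounds, b.compounds)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for engine in cfg.engines:
            pd.testing.assert_frame_equal(
                a.pose_tables[engine].data, b.pose_tables[engine].data
            )
        assert a.activity_records == b.activity_records

    def test_affinity_correlates_with_emitted_pk(self):
        cohort = generate_cohort(
            GeneratorConfig(n_compounds=2000, seed=1), with_pose_tables=False
        )
        r = pearsonr(cohort.truth["affinity"], cohort.compounds["pK"]).statistic
        assert r >= 0.9

    def test_null_property_effects_over_ten_seeds(self):
        """With both property effects switched off, the class logP gap
        averages to zero across seeds.  (Switching off lipophilicity alone
        leaves an indirect gap: affinity still tracks low TPSA, and logP
        and TPSA of the same molecules are anticorrelated.)"""
        diffs = []
        for seed in range(10):
            cohort = generate_cohort(
                GeneratorConfig(
                    n_compounds=200, seed=seed,
                    lipophilicity_shift=0.0, polarity_shift=0.0,
                ),
                with_pose_tables=False,
            )
            binder = cohort.compounds["label"] == "binder"
            logp = cohort.truth["logP"].to_numpy()
            diffs.append(logp[binder.to_numpy()].mean() - logp[~binder.to_numpy()].mean())
        diffs = np.array(diffs)
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        assert abs(t) < 3.5  # no systematic class shift

    def test_binders_more_lipophilic_under_defaults(self, small_cohort):
        binder = (small_cohort.compounds["label"] == "binder").to_numpy()
        logp = small_cohort.truth["logP"].to_numpy()
        tpsa = small_cohort.truth["TPSA"].to_numpy()
        assert logp[binder].mean() > logp[~binder].mean()
        assert tpsa[binder].mean() < tpsa[~binder].mean()

    def test_zero_compounds_gives_empty_cohort(self):
        cohort = generate_cohort(GeneratorConfig(n_compounds=0, seed=0))
        assert len(cohort.compounds) == 0
        assert cohort.activity_records == []


class TestPoseScores:
    def test_pose_count_conservation(self, small_cohort):
        cfg = small_cohort.config
        for table in small_cohort.pose_tables.values():
            counts = table.data.groupby(level=["compound_id", "isomer_id"]).size()
            assert (counts == cfg.n_poses).all()

    def test_isomer_groups_match_cohort(self, small_cohort):
        table = small_cohort.pose_tables["PLANTS"]
        iso = table.data.index.to_frame(index=False).groupby("compound_id")[
            "isomer_id"
        ].nunique()
        declared = small_cohort.compounds.set_index("compound_id")["n_isomers"]
        docked = iso.index
        assert (iso == declared.loc[docked]).all()

    def test_undocked_count_reproducible(self):
        cfg = GeneratorConfig(n_compounds=1000, seed=13, undocked_fraction=0.024)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for engine in cfg.engines:
            n_a = a.pose_tables[engine].data.index.get_level_values(0).nunique()
            n_b = b.pose_tables[engine].data.index.get_level_values(0).nunique()
            assert n_a == n_b
            assert 1000 - n_a == pytest.approx(24, abs=15)  # ~binomial(1000, .024)

    def test_zero_pose_noise_collapses_poses(self):
        cfg = GeneratorConfig(n_compounds=40, seed=3, pose_noise_sd=0.0)
        cohort = generate_cohort(cfg)
        for table in cohort.pose_tables.values():
            spread = table.data.groupby(level=["compound_id", "isomer_id"]).agg(
                lambda s: s.max() - s.min()
            )
            assert float(spread.to_numpy().max()) == pytest.approx(0.0, abs=1e-9)
            bp = best_pose_features(table)
            av = average_pose_features(table)
            pd.testing.assert_frame_equal(bp.values, av.values)

    def test_rank_one_is_best_primary_by_engine_convention(self, small_cohort):
        for engine, table in small_cohort.pose_tables.items():
            primary = table.score_names[0]
            grouped = table.data[primary].groupby(level=["compound_id", "isomer_id"])
            rank1 = table.data[primary].xs(1, level="pose_rank")
            if PRIMARY_DIRECTION.get(engine) == "lower":
                assert (rank1 <= grouped.min() + 1e-12).all()
            else:
                assert (rank1 >= grouped.max() - 1e-12).all()

    def test_rescoring_columns_correlate_positively_with_affinity(self, small_cohort):
        affinity = small_cohort.truth["affinity"]
        for table in small_cohort.pose_tables.values():
            av = average_pose_features(table).values
            aff = affinity.loc[av.index]
            for col in av.columns:
                if table.directions.get(col) == "lower":
                    continue  # flipped primary column anticorrelates by design
                r = pearsonr(av[col], aff).statistic
                assert r > 0, f"{table.engine}:{col} correlation {r:.3f}"

    def test_pose_averaging_reduces_variance(self, small_cohort):
        """Per-compound averages are less dispersed than best-pose values
        whenever pose-level noise is present."""
        for table in small_cohort.pose_tables.values():
            bp = best_pose_features(table).values
            av = average_pose_features(table).values
            rescoring = [c for c in bp.columns if c.startswith("rescore")]
            worse = (av[rescoring].var() >= bp[rescoring].var()).sum()
            assert worse <= len(rescoring) // 5

    def test_unknown_engine_rejected(self, small_cohort):
        with pytest.raises(ConfigError, match="FAKE"):
            generate_pose_scores(small_cohort, "FAKE")

    def test_ligen_mode_has_55_columns(self, small_cohort):
        assert len(small_cohort.pose_tables["LiGen"].score_names) == 55
        assert len(small_cohort.pose_tables["PLANTS"].score_names) == 26


class TestExternalSets:
    def test_dissimilarity_shifts_nearest_neighbor_tc_down(self, small_cohort):
        train_fps = np.stack([ecfp6(s) for s in small_cohort.compounds["smiles"]])
        cfg = GeneratorConfig(n_compounds=150, seed=11)
        medians = {}
        for level in ("low", "high"):
            ext = generate_external_set(cfg, level)
            fps = np.stack([ecfp6(s) for s in ext.compounds["smiles"]])
            medians[level] = np.median(nearest_neighbor_tc(fps, train_fps))
        assert medians["low"] > medians["high"]

    def test_same_seed_reproduces_external_set(self):
        cfg = GeneratorConfig(n_compounds=30, seed=5)
        a = generate_external_set(cfg, "medium")
        b = generate_external_set(cfg, "medium")
        pd.testing.assert_frame_equal(a.compounds, b.compounds)

    def test_empty_external_set(self):
        cohort = generate_external_set(
            GeneratorConfig(n_compounds=0, seed=1), "low"
        )
        assert len(cohort.compounds) == 0

    def test_unknown_level_rejected(self):
        with pytest.raises(ConfigError, match="dissimilarity"):
            generate_external_set(GeneratorConfig(n_compounds=5), "extreme")
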