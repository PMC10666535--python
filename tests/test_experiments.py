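import json

import numpy as np
import pandas as pd
import pytest

from aquameta.evaluation import LeakageAuditor, LeakageError
from aquameta.experiments import (AnchorSchedule, CurveResult, assay_orderings,
                                  bootstrap_bands, build_assay_curve,
                                  build_species_curve, run_experiment,
                                  select_species_curve_setup_r3,
                                  select_study_species_r2, summarize_curve)
from aquameta.learners import LearnerSpec
from aquameta.preprocess import clean_assays
from aquameta.synth import SynthConfig, generate_dataset

RF_TINY = {"n_estimators": 20}


@pytest.fixture(scope="module")
def curve_data():
    cfg = SynthConfig(n_phyla=2, n_classes_per_phylum=2, n_species=6,
                      n_chemicals=120, n_fp_bits=8, n_physchem=2,
                      n_assays=1200, zipf_exponent=0.3, replicate_rate=0.0,
                      bound_rate=0.0, missing_rate=0.0, seed=21)
    assays, chemicals, taxonomy, truth = generate_dataset(cfg)
    return clean_assays(assays), chemicals, taxonomy


def species_rows(n_rows, species, chems, value=100.0):
    rows = []
    for i in range(n_rows):
        rows.append({"species_id": species, "chemical_id": chems[i % len(chems)],
                     "class_name": "c0", "phylum_name": "p0",
                     "duration_days": 1.0 + (i % 3), "endpoint_value": value})
    return rows


class TestR2Selection:
    def test_threshold_application(self):
        # three species with well-separated assay counts: 2 qualify
        chems = [f"c{i}" for i in range(100)]
        rows = (species_rows(140, "s_big", chems)
                + species_rows(135, "s_mid", chems)
                + species_rows(30, "s_small", chems))
        records = pd.DataFrame(rows)
        setup = select_study_species_r2(records, test_fraction=0.1,
                                        min_train_assays=100, seed=0)
        assert set(setup.study_species) == {"s_big", "s_mid"}
        # recount oracle: qualification recomputed from the returned split
        train = records[records["chemical_id"].isin(setup.split.train_chemicals)]
        counts = train.groupby("species_id").size()
        assert set(setup.study_species) == set(counts.index[counts >= 100])

    def test_auxiliary_disjoint_from_study(self, curve_data):
        records, _, _ = curve_data
        setup = select_study_species_r2(records, min_train_assays=50, seed=1)
        assert not set(setup.auxiliary["species_id"]) & set(setup.study_species)
        assert set(setup.test["species_id"]) <= set(setup.study_species)

    def test_deterministic_pin(self, curve_data):
        records, _, _ = curve_data
        a = select_study_species_r2(records, min_train_assays=50, seed=2)
        b = select_study_species_r2(records, min_train_assays=50, seed=2)
        assert a.study_species == b.study_species
        assert a.split == b.split

    def test_unreachable_threshold_errors(self, curve_data):
        records, _, _ = curve_data
        with pytest.raises(ValueError, match="min_train_assays"):
            select_study_species_r2(records, min_train_assays=10_000)


class TestAssayCurve:
    def setup_curve(self, curve_data, min_train=60):
        records, chemicals, taxonomy = curve_data
        setup = select_study_species_r2(records, test_fraction=0.2,
                                        min_train_assays=min_train, seed=3)
        return setup, chemicals, taxonomy

    def test_nested_orderings(self, curve_data):
        setup, _, _ = self.setup_curve(curve_data)
        orderings = assay_orderings(setup, n_orderings=3, seed=0)
        assert len(orderings) == 3
        for perms in orderings:
            for s, perm in perms.items():
                assert set(perm[:5]) <= set(perm[:8])  # nestedness by prefix
        # different orderings differ
        s = setup.study_species[0]
        assert not np.array_equal(orderings[0][s][:10], orderings[1][s][:10])

    def test_multi_task_training_sizes_and_fixed_test(self, curve_data):
        setup, chemicals, taxonomy = self.setup_curve(curve_data)
        schedule = AnchorSchedule(anchors=(3, 5), n_orderings=1, seed=0)
        sizes = {}
        seen_tests = []

        from aquameta import experiments as exp
        original = exp._score

        def spy(learner, spec, test_table, auditor, train_table):
            sizes.setdefault((spec.family, len(train_table)), 0)
            sizes[(spec.family, len(train_table))] += 1
            seen_tests.append(tuple(sorted(set(test_table.chemical))))
            return original(learner, spec, test_table, auditor, train_table)

        exp._score = spy
        try:
            build_assay_curve(setup, chemicals, taxonomy,
                              [LearnerSpec("st_mean"), LearnerSpec("mt_mean")],
                              schedule, with_auxiliary=False)
        finally:
            exp._score = original
        n_study = len(setup.study_species)
        for anchor in (3, 5):
            # multi-task learners see n_study * anchor rows; single-task the same
            # pooled frame (their per-species models each see `anchor` rows)
            assert (("mt_mean", n_study * anchor)) in sizes
            assert (("st_mean", n_study * anchor)) in sizes
        assert len(set(seen_tests)) == 1  # test assays identical everywhere

    def test_auxiliary_increases_multitask_training_only(self, curve_data):
        setup, chemicals, taxonomy = self.setup_curve(curve_data)
        schedule = AnchorSchedule(anchors=(3,), n_orderings=1, seed=0)
        sizes = []
        from aquameta import experiments as exp
        original = exp._score

        def spy(learner, spec, test_table, auditor, train_table):
            sizes.append((spec.family, len(train_table)))
            return original(learner, spec, test_table, auditor, train_table)

        exp._score = spy
        try:
            build_assay_curve(setup, chemicals, taxonomy,
                              [LearnerSpec("st_mean"), LearnerSpec("mt_mean")],
                              schedule, with_auxiliary=True)
        finally:
            exp._score = original
        n_study = len(setup.study_species)
        by_family = dict(sizes)
        assert by_family["st_mean"] == n_study * 3
        assert by_family["mt_mean"] == n_study * 3 + len(setup.auxiliary)

    def test_anchor_exceeding_data_errors(self, curve_data):
        setup, chemicals, taxonomy = self.setup_curve(curve_data)
        schedule = AnchorSchedule(anchors=(10_000,), n_orderings=1)
        with pytest.raises(ValueError, match="anchor"):
            build_assay_curve(setup, chemicals, taxonomy,
                              [LearnerSpec("mt_mean")], schedule)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnchorSchedule(anchors=(5, 5))
        with pytest.raises(ValueError):
            AnchorSchedule(anchors=())

    def test_curves_drop_for_learning_learners(self, curve_data):
        setup, chemicals, taxonomy = self.setup_curve(curve_data)
        schedule = AnchorSchedule(anchors=(4, 40), n_orderings=2, seed=1)
        result = build_assay_curve(setup, chemicals, taxonomy,
                                   [LearnerSpec("st_rf", RF_TINY),
                                    LearnerSpec("mt_rf", RF_TINY)], schedule)
        points = result.points.query("aggregation == 'species'")
        for learner, block in points.groupby("learner"):
            lo = block[block.anchor == 4]["rmse"].mean()
            hi = block[block.anchor == 40]["rmse"].mean()
            assert hi < lo

    def test_leakage_audit_raises_on_tamper(self, curve_data):
        setup, chemicals, taxonomy = self.setup_curve(curve_data)
        # auditor that forbids every training chemical: any fit must trip it
        auditor = LeakageAuditor(set(setup.train_study["chemical_id"]))
        schedule = AnchorSchedule(anchors=(3,), n_orderings=1)
        with pytest.raises(LeakageError):
            build_assay_curve(setup, chemicals, taxonomy,
                              [LearnerSpec("mt_mean")], schedule, auditor=auditor)


def r3_records(seed=5, n_chem=40, n_aux=3):
    """Deterministic R3 toy: the split for this seed is known in advance, so
    auxiliary species can be placed on training chemicals only."""
    from aquameta.evaluation import split_by_chemicals

    chems = [f"c{i}" for i in range(n_chem)]
    plan = split_by_chemicals(chems, 0.25, seed=seed)
    train_chems = sorted(plan.train_chemicals)
    test_chems = sorted(plan.test_chemicals)
    rows = species_rows(80, "s_study1", chems) + species_rows(80, "s_study2", chems)
    for j in range(n_aux):
        rows += species_rows(40, f"s_aux{j}", train_chems)
    rows += species_rows(4, "s_rare", test_chems[:2])  # 2 test chems, no train
    return pd.DataFrame(rows)


class TestR3Selection:
    def test_test_chemical_threshold(self):
        records = r3_records()
        setup = select_species_curve_setup_r3(records, test_fraction=0.25,
                                              min_test_chemicals=3,
                                              aux_min_train=30, aux_cap=10, seed=5)
        assert set(setup.study_species) == {"s_study1", "s_study2"}
        assert "s_rare" not in setup.study_species  # only 2 test chemicals
        assert set(setup.auxiliary_species) == {"s_aux0", "s_aux1", "s_aux2"}
        assert not set(setup.study_species) & set(setup.auxiliary_species)
        # recount oracle on the returned split
        test = records[records["chemical_id"].isin(setup.split.test_chemicals)]
        counts = test.groupby("species_id")["chemical_id"].nunique()
        assert set(setup.study_species) == set(counts.index[counts >= 3])

    def test_empty_sets_error(self, curve_data):
        records, _, _ = curve_data
        with pytest.raises(ValueError):
            select_species_curve_setup_r3(records, min_test_chemicals=10_000)
        with pytest.raises(ValueError):
            select_species_curve_setup_r3(records, min_test_chemicals=1,
                                          aux_min_train=10_000)


class TestSpeciesCurve:
    def make_setup(self, curve_data=None):
        records = r3_records(seed=6)
        chems = sorted(records["chemical_id"].unique())
        rng = np.random.default_rng(0)
        chemicals = pd.DataFrame({"chemical_id": chems,
                                  "pc_x": rng.normal(size=len(chems))})
        taxonomy = pd.DataFrame({"species_id": sorted(records["species_id"].unique()),
                                 "class_name": "c0", "phylum_name": "p0"})
        setup = select_species_curve_setup_r3(records, test_fraction=0.25,
                                              min_test_chemicals=3,
                                              aux_min_train=30, aux_cap=20, seed=6)
        return setup, chemicals, taxonomy

    def test_counts_validation_and_single_task_rejection(self, curve_data):
        setup, chemicals, taxonomy = self.make_setup(curve_data)
        with pytest.raises(ValueError, match="single-task"):
            build_species_curve(setup, chemicals, taxonomy,
                                [LearnerSpec("st_rf", RF_TINY)], counts=[0])
        with pytest.raises(ValueError, match="counts"):
            build_species_curve(setup, chemicals, taxonomy,
                                [LearnerSpec("mt_mean")], counts=[999])

    def test_zero_aux_baseline_and_capping(self, curve_data):
        setup, chemicals, taxonomy = self.make_setup(curve_data)
        sizes = []
        from aquameta import experiments as exp
        original = exp._score

        def spy(learner, spec, test_table, auditor, train_table):
            sizes.append(len(train_table))
            return original(learner, spec, test_table, auditor, train_table)

        exp._score = spy
        try:
            n_aux_used = min(2, len(setup.auxiliary_species))
            build_species_curve(setup, chemicals, taxonomy,
                                [LearnerSpec("mt_mean")],
                                counts=[0, n_aux_used], n_seeds=1, seed=0)
        finally:
            exp._score = original
        train_counts = setup.train.groupby("species_id").size()
        per_study = [int(train_counts[s]) for s in setup.study_species]
        # count 0: training is the study species' own rows
        assert sizes[:len(per_study)] == per_study
        # count n: exactly n * aux_cap rows added (every aux species capped)
        added = [b - a for a, b in zip(per_study, sizes[len(per_study):])]
        assert all(x == n_aux_used * setup.aux_cap for x in added)

    def test_prefix_property_across_counts(self, curve_data):
        setup, chemicals, taxonomy = self.make_setup(curve_data)
        seen = {}
        from aquameta import experiments as exp
        original = exp._score

        def spy(learner, spec, test_table, auditor, train_table):
            key = len(train_table)
            seen.setdefault(key, set()).update(train_table.species)
            return original(learner, spec, test_table, auditor, train_table)

        exp._score = spy
        try:
            n = len(setup.auxiliary_species)
            build_species_curve(setup, chemicals, taxonomy, [LearnerSpec("mt_mean")],
                                counts=[min(1, n), min(2, n)], n_seeds=1, seed=1)
        finally:
            exp._score = original
        # species sets at the smaller count are subsets of those at the larger
        sizes_sorted = sorted(seen)
        assert seen[sizes_sorted[0]] <= seen[sizes_sorted[-1]]

    def test_mt_mean_flat_when_aux_shares_mean(self):
        # constructed oracle: auxiliary species with the same target mean
        # leave the pooled-mean prediction (hence its RMSE) unchanged
        records = r3_records(seed=7)  # all rows share endpoint 100.0
        chems = sorted(records["chemical_id"].unique())
        setup = select_species_curve_setup_r3(records, test_fraction=0.25,
                                              min_test_chemicals=3,
                                              aux_min_train=30, aux_cap=20, seed=7)
        result = build_species_curve(
            setup,
            pd.DataFrame({"chemical_id": chems,
                          "pc_x": np.linspace(-1, 1, len(chems))}),
            pd.DataFrame({"species_id": sorted(records.species_id.unique()),
                          "class_name": "c0", "phylum_name": "p0"}),
            [LearnerSpec("mt_mean")], counts=[0, 2], n_seeds=1, seed=0)
        rmses = result.points.query("aggregation == 'species'").groupby("n_aux")["rmse"].mean()
        assert rmses.loc[0] == pytest.approx(rmses.loc[2], abs=1e-12)


class TestBootstrap:
    def test_constant_errors_zero_width(self):
        lo, hi = bootstrap_bands([0.5, 0.5, 0.5], B=200, seed=0)
        assert lo == hi == pytest.approx(0.5)

    def test_band_contains_point_estimate(self):
        rng = np.random.default_rng(0)
        values = rng.random(50)
        lo, hi = bootstrap_bands(values, B=2000, seed=1)
        assert lo <= values.mean() <= hi

    def test_convergence_in_b(self):
        rng = np.random.default_rng(2)
        values = rng.normal(1.0, 0.2, size=100)
        lo1, hi1 = bootstrap_bands(values, B=1000, seed=3)
        lo2, hi2 = bootstrap_bands(values, B=10_000, seed=4)
        mc = 3 * 0.2 / np.sqrt(len(values))  # generous Monte-Carlo tolerance
        assert abs(lo1 - lo2) < mc and abs(hi1 - hi2) < mc

    def test_single_observation_degenerate(self):
        with pytest.warns(UserWarning):
            lo, hi = bootstrap_bands([0.7], B=10)
        assert lo == hi == pytest.approx(0.7)

    def test_validation(self):
        with pytest.raises(ValueError):
            bootstrap_bands([], B=10)
        with pytest.raises(ValueError):
            bootstrap_bands([1.0, 2.0], level=1.5)

    def test_summarize_curve_schema(self, curve_data):
        records, chemicals, taxonomy = curve_data
        setup = select_study_species_r2(records, test_fraction=0.2,
                                        min_train_assays=60, seed=3)
        schedule = AnchorSchedule(anchors=(3, 5), n_orderings=2, seed=0)
        result = build_assay_curve(setup, chemicals, taxonomy,
                                   [LearnerSpec("mt_mean")], schedule)
        summary = summarize_curve(result, B=100, seed=0)
        assert {"anchor", "learner", "aggregation", "rmse",
                "band_lo", "band_hi", "level"} <= set(summary.columns)
        assert (summary["band_lo"] <= summary["band_hi"]).all()


class TestRunExperiment:
    CONFIG = {
        "seed": 5,
        "synth": {"n_species": 5, "n_chemicals": 50, "n_fp_bits": 8,
                  "n_physchem": 2, "n_assays": 400, "replicate_rate": 0.0,
                  "bound_rate": 0.0},
        "split": {"test_fraction": 0.2},
        "learners": [{"family": "st_mean"}, {"family": "mt_mean"}],
        "internal_cv": {"k": 3, "repetitions": 1},
    }

    def test_smoke_outputs_and_manifest(self, tmp_path):
        outputs = run_experiment(self.CONFIG, tmp_path / "run")
        for key in ("external_predictions", "external_summary",
                    "internal_validation", "manifest"):
            assert outputs[key].exists()
        manifest = json.loads(outputs["manifest"].read_text())
        assert manifest["audit"]["n_checks"] > 0
        assert {"master", "synth", "split", "internal_cv",
                "learners"} <= set(manifest["seeds"])
        assert "numpy" in manifest["versions"]

    def test_rerun_byte_identical(self, tmp_path):
        out1 = run_experiment(self.CONFIG, tmp_path / "a")
        out2 = run_experiment(self.CONFIG, tmp_path / "b")
        assert (out1["external_predictions"].read_bytes()
                == out2["external_predictions"].read_bytes())
        assert (out1["external_summary"].read_bytes()
                == out2["external_summary"].read_bytes())

    def test_stage_tagged_failure(self, tmp_path):
        config = dict(self.CONFIG, synth={"n_species": -1})
        with pytest.raises(RuntimeError, match=r"\[generate\]"):
            run_experiment(config, tmp_path / "bad")
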