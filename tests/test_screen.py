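"""End-to-end screen orchestration, expression comparison, and ranking."""

import numpy as np
import pandas as pd
import pytest

import survscreen as ss
from survscreen import (
    BiosignatureScreen,
    ExpressionComparison,
    SubgroupSpec,
    compare_expression,
    rank_targets,
    run_screen,
)
from survscreen.screen import P_FLOOR


class TestRunScreen:
    def test_planted_effect_is_significant(self, small_cohort):
        table = run_screen(small_cohort, ["PROG", "G1"])
        prog = table[table["gene"] == "PROG"].iloc[0]
        assert prog["status"] == "ok"
        assert prog["significant"]
        assert prog["hr"] > 1.5

    def test_score_column_consistent_with_scoring_module(self, small_cohort):
        table = run_screen(small_cohort, ["PROG", "G1", "G2"])
        for _, row in table[table["status"] == "ok"].iterrows():
            expected = ss.hr_score([(row["hr"], row["logrank_p"])], p_floor=P_FLOOR)
            assert row["score"] == pytest.approx(expected, rel=1e-12)

    def test_default_subgroup_is_all(self, small_cohort):
        table = run_screen(small_cohort, ["PROG"])
        assert table["subgroup"].tolist() == ["all"]

    def test_subgroup_rows_one_per_request(self, small_cohort):
        specs = [SubgroupSpec("all"), SubgroupSpec("her2", "neg"), SubgroupSpec("her2", "pos")]
        table = run_screen(small_cohort, ["PROG", "G1"], specs)
        assert len(table) == 6
        assert set(table["subgroup"]) == {"all", "her2=neg", "her2=pos"}

    def test_constant_marker_recorded_not_dropped(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["FLAT"] = 7.0
        table = run_screen(cohort, ["FLAT", "PROG"])
        flat = table[table["gene"] == "FLAT"].iloc[0]
        assert flat["status"] == "failed"
        assert flat["reason"] == "constant_marker"
        assert (table["gene"] == "PROG").any()

    def test_no_events_recorded(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["event"] = 0
        table = run_screen(cohort, ["PROG"])
        assert table.iloc[0]["status"] == "failed"
        assert table.iloc[0]["reason"] == "no_events"

    def test_empty_gene_list_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="non-empty"):
            run_screen(small_cohort, [])

    def test_unknown_gene_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="NOPE"):
            run_screen(small_cohort, ["NOPE"])

    def test_pipeline_is_deterministic(self, small_cohort):
        a = run_screen(small_cohort, ["PROG", "G1"], [SubgroupSpec("stage", "3")])
        b = run_screen(small_cohort, ["PROG", "G1"], [SubgroupSpec("stage", "3")])
        pd.testing.assert_frame_equal(a, b)

    def test_estimator_wrapper_matches_function(self, small_cohort):
        est = BiosignatureScreen(genes=["PROG", "G1"]).fit(small_cohort)
        direct = run_screen(small_cohort, ["PROG", "G1"])
        pd.testing.assert_frame_equal(est.screen_table_, direct)

    def test_estimator_defaults_to_all_marker_columns(self, small_cohort):
        est = BiosignatureScreen().fit(small_cohort)
        assert set(est.screen_table_["gene"]) == {"PROG", "G1", "G2"}


class TestSubgroupEnrichment:
    def test_effect_confined_to_stage3_scores_higher_there(self):
        # plant the hazard effect only in stage-3 rows: the stage-3 score
        # should beat the all-patients score for most seeds
        wins = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cfg = ss.SimulationConfig(
                n_patients=600, n_genes=1, random_censor_rate=0.0, seed=seed
            )
            cohort = ss.simulate_cohort(cfg)
            stage3 = (cohort["stage"] == "3").to_numpy()
            high = ss.median_split(cohort["G1"].to_numpy())
            # re-draw event times with the effect only inside stage 3
            hazard = cfg.baseline_hazard * np.exp(np.log(2.5) * (high & stage3))
            event_time = rng.exponential(1.0 / hazard)
            cohort["time_months"] = np.minimum(event_time, 60.0)
            cohort["event"] = (event_time <= 60.0).astype(int)
            table = run_screen(
                cohort, ["G1"], [SubgroupSpec("all"), SubgroupSpec("stage", "3")]
            )
            scores = table.set_index("subgroup")["score"]
            wins += scores["stage=3"] > scores["all"]
        assert wins / n_seeds >= 0.9


class TestCompareExpression:
    def test_identical_arms_give_null(self):
        res = compare_expression([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "paired")
        assert res.t_statistic == 0.0
        assert res.p == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_expression([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0], "paired")

    def test_paired_matches_scipy(self, rng):
        normal = rng.normal(8, 1, 30)
        tumor = normal + rng.normal(0.5, 0.3, 30)
        res = compare_expression(normal, tumor, "paired", gene="ACSS3")
        from scipy import stats

        t, p = stats.ttest_rel(tumor, normal)
        assert res.t_statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)
        assert res.n == 30

    def test_unpaired_pooled_variance_student(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 2, 25)
        res = compare_expression(a, b, "unpaired")
        from scipy import stats

        t, p = stats.ttest_ind(b, a, equal_var=True)
        assert res.t_statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)
        welch = compare_expression(a, b, "unpaired", welch=True)
        assert welch.p == pytest.approx(stats.ttest_ind(b, a, equal_var=False).pvalue)

    def test_mismatched_paired_arms_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            compare_expression([1, 2, 3], [1, 2], "paired")

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="design"):
            compare_expression([1, 2], [3, 4], "bootstrap")

    def test_simulated_shift_detected(self):
        hits = 0
        for seed in range(100):
            paired = ss.simulate_paired_expression(
                ss.PairedConfig(n_pairs=30, log_fold_change=1.0, noise_sd=0.1, seed=seed)
            )
            res = compare_expression(paired["normal"], paired["tumor"], "paired")
            hits += res.p < 0.05
        assert hits / 100 > 0.99


def _mk_table(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "subgroup", "score", "significant", "status"],
    )


class TestRankTargets:
    def test_more_significant_subgroups_rank_first(self):
        rows = []
        for sub in ("all", "stage=3", "her2=neg", "histology=intestinal", "treatment=surgery"):
            rows.append(("A", sub, 800.0, sub != "all", "ok"))  # 4/5 significant
            rows.append(("B", sub, 900.0, sub in ("all", "stage=3"), "ok"))  # 2/5
        comps = [
            ExpressionComparison("A", "paired", 5.0, 7.0, 4.0, 0.001, 30),
            ExpressionComparison("B", "paired", 5.0, 7.0, 4.0, 0.001, 30),
        ]
        ranked = rank_targets(_mk_table(rows), comps)
        assert ranked["gene"].tolist() == ["A", "B"]

    def test_tie_broken_by_mean_score(self):
        rows = [
            ("LOW", "all", 400.0, True, "ok"),
            ("HIGH", "all", 900.0, True, "ok"),
        ]
        ranked = rank_targets(_mk_table(rows))
        assert ranked["gene"].tolist() == ["HIGH", "LOW"]

    def test_expression_unsupported_demoted(self):
        rows = [
            ("UP", "all", 400.0, True, "ok"),
            ("DOWN", "all", 2000.0, True, "ok"),
        ]
        comps = [
            ExpressionComparison("UP", "paired", 5.0, 7.0, 4.0, 0.001, 30),
            ExpressionComparison("DOWN", "paired", 7.0, 5.0, -4.0, 0.001, 30),
        ]
        ranked = rank_targets(_mk_table(rows), comps)
        assert ranked["gene"].tolist() == ["UP", "DOWN"]
        assert ranked.set_index("gene").loc["DOWN", "expression_support"] == "expression-unsupported"

    def test_missing_comparison_flagged(self):
        rows = [("X", "all", 500.0, True, "ok")]
        ranked = rank_targets(_mk_table(rows))
        assert ranked.iloc[0]["expression_support"] == "no-expression-data"

    def test_true_target_ranks_first_in_planted_simulation(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = ss.SimulationConfig(
                n_patients=500,
                n_genes=4,
                log_hr_by_gene={"TARGET": np.log(2.2)},
                seed=seed,
            )
            cohort = ss.simulate_cohort(cfg)
            table = run_screen(cohort, ["TARGET", "G1", "G2", "G3"])
            comps = []
            for gene in ("TARGET", "G1", "G2", "G3"):
                lfc = 1.0 if gene == "TARGET" else 0.0
                paired = ss.simulate_paired_expression(
                    ss.PairedConfig(n_pairs=34, log_fold_change=lfc, noise_sd=0.3, seed=seed)
                )
                comps.append(
                    compare_expression(paired["normal"], paired["tumor"], "paired", gene=gene)
                )
            ranked = rank_targets(table, comps)
            wins += ranked.iloc[0]["gene"] == "TARGET"
        assert wins / n_seeds >= 0.95
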