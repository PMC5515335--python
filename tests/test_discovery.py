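"""Recurrence-gene discovery, validation, and the compound significance rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bclandscape import discovery
from bclandscape.synthdata import simulate_recurrence_cohort

from oracles import brute_bh


def surv_frame(times, events):
    return pd.DataFrame(
        {"dfs_years": times, "dfs_event": events},
        index=[f"p{i}" for i in range(len(times))],
    )


class TestDichotomize:
    def test_classification_rules(self):
        data = surv_frame([3.0, 4.0, 5.0, 6.5, 7.0, 6.0], [1, 0, 1, 0, 1, 0])
        cohort = discovery.dichotomize(data)
        assert cohort.groups["p0"] == discovery.EARLY  # event at 3y
        assert "p1" in cohort.excluded.index  # censored at 4y: unclassifiable
        assert cohort.groups["p2"] == discovery.EARLY  # event at exactly 5.0y
        assert cohort.groups["p3"] == discovery.LATE
        assert "p4" in cohort.excluded.index  # event after horizon
        assert cohort.groups["p5"] == discovery.LATE

    def test_empty_group_rejected(self):
        data = surv_frame([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="empty group"):
            discovery.dichotomize(data)


def toy_test_data(n_per=30, diff=0.0, sd=1.0, seed=0, n_genes=4):
    rng = np.random.default_rng(seed)
    early = rng.normal(5.0, sd, size=(n_per, n_genes))
    late = rng.normal(5.0 + diff, sd, size=(n_per, n_genes))
    expr = pd.DataFrame(
        np.vstack([early, late]),
        index=[f"e{i}" for i in range(n_per)] + [f"l{i}" for i in range(n_per)],
        columns=[f"g{i}" for i in range(n_genes)],
    )
    groups = pd.Series(
        [discovery.EARLY] * n_per + [discovery.LATE] * n_per, index=expr.index
    )
    cohort = discovery.DichotomizedCohort(
        groups=groups, excluded=pd.DataFrame(columns=["reason"]), horizon=5.0
    )
    return expr, cohort


class TestGeneTests:
    def test_null_gene_is_unremarkable(self):
        expr = pd.DataFrame(
            {
                "null": [5.0, 6.0, 5.0, 6.0, 5.0, 6.0, 5.0, 6.0],
            },
            index=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(
            [discovery.EARLY] * 4 + [discovery.LATE] * 4, index=expr.index
        )
        # identical group compositions -> t = 0, p = 1, fold change 1
        expr.iloc[4:, 0] = expr.iloc[:4, 0].to_numpy()
        cohort = discovery.DichotomizedCohort(
            groups=groups, excluded=pd.DataFrame(columns=["reason"]), horizon=5.0
        )
        table = discovery.gene_tests(expr, cohort)
        row = table.loc["null"]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)
        assert row["fold_change"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_matches_closed_form_t_and_bh_oracle(self):
        early = np.array([[5.1, 4.9], [5.4, 5.2], [4.8, 5.3], [5.2, 5.1]])
        late = np.array([[6.2, 5.0], [6.5, 5.2], [6.1, 4.9], [6.6, 5.3]])
        expr = pd.DataFrame(
            np.vstack([early, late]),
            index=[f"e{i}" for i in range(4)] + [f"l{i}" for i in range(4)],
            columns=["up", "flat"],
        )
        groups = pd.Series(
            [discovery.EARLY] * 4 + [discovery.LATE] * 4, index=expr.index
        )
        cohort = discovery.DichotomizedCohort(
            groups=groups, excluded=pd.DataFrame(columns=["reason"]), horizon=5.0
        )
        table = discovery.gene_tests(expr, cohort)
        for j, gene in enumerate(["up", "flat"]):
            a, b = late[:, j], early[:, j]
            sp = np.sqrt(((a.var(ddof=1) * 3) + (b.var(ddof=1) * 3)) / 6)
            t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 4 + 1 / 4))
            p = 2 * stats.t.sf(abs(t), df=6)
            assert table.loc[gene, "t"] == pytest.approx(t, abs=1e-10)
            assert table.loc[gene, "p"] == pytest.approx(p, abs=1e-10)
        np.testing.assert_allclose(
            table["q"].to_numpy(), brute_bh(table["p"].tolist()), atol=1e-12
        )

    def test_compound_significance_rule(self):
        # fold change 1.6 with tiny p -> significant; fold change 1.4 with
        # even tinier p -> still not significant (fails the fold-change arm)
        expr, cohort = toy_test_data(n_per=60, diff=0.0, sd=0.02, seed=1, n_genes=2)
        expr.loc[cohort.groups == discovery.LATE, "g0"] += np.log2(1.6)
        expr.loc[cohort.groups == discovery.LATE, "g1"] += np.log2(1.4)
        table = discovery.gene_tests(expr, cohort)
        assert table.loc["g0", "q"] < 0.05 and table.loc["g1", "q"] < 0.05
        assert bool(table.loc["g0", "significant"])
        assert not bool(table.loc["g1", "significant"])

    def test_fold_change_symmetry_under_group_swap(self):
        expr, cohort = toy_test_data(n_per=25, diff=0.9, seed=2, n_genes=6)
        swapped = discovery.DichotomizedCohort(
            groups=cohort.groups.map(
                {discovery.EARLY: discovery.LATE, discovery.LATE: discovery.EARLY}
            ),
            excluded=cohort.excluded,
            horizon=5.0,
        )
        a = discovery.gene_tests(expr, cohort)
        b = discovery.gene_tests(expr, swapped)
        np.testing.assert_allclose(
            b["fold_change"].to_numpy(), 1.0 / a["fold_change"].to_numpy(), atol=1e-12
        )
        assert (a["significant"] == b["significant"]).all()
        assert (a["direction"] != b["direction"]).all()

    def test_degenerate_zero_variance_gene_flagged(self):
        expr, cohort = toy_test_data(n_per=5, seed=3, n_genes=2)
        expr["g0"] = 7.0
        table = discovery.gene_tests(expr, cohort)
        assert bool(table.loc["g0", "degenerate"])
        assert not bool(table.loc["g0", "significant"])

    def test_welch_option_runs(self):
        expr, cohort = toy_test_data(seed=4)
        t_pooled = discovery.gene_tests(expr, cohort, equal_var=True)
        t_welch = discovery.gene_tests(expr, cohort, equal_var=False)
        assert not np.allclose(t_pooled["p"], t_welch["p"])


class TestValidation:
    def test_pipeline_recovers_planted_genes_and_validates(self):
        expr, surv, planted = simulate_recurrence_cohort(
            n_samples=500, n_genes=300, n_prognostic=20, seed=71
        )
        cohort = discovery.dichotomize(surv)
        table = discovery.gene_tests(expr, cohort)
        discovered = table.index[table["significant"]].tolist()
        sensitivity = len(set(discovered) & set(planted)) / len(planted)
        assert sensitivity >= 0.8

        v_expr, v_surv, _ = simulate_recurrence_cohort(
            n_samples=500, n_genes=300, n_prognostic=20, seed=72
        )
        v_cohort = discovery.dichotomize(v_surv)
        val = discovery.validate(
            discovered, v_expr, v_cohort, discovery_table=table
        )
        assert set(val.index) == set(discovered)  # never validates undiscovered
        true_disc = [g for g in discovered if g in planted]
        frac = val.loc[true_disc, "validated"].mean()
        assert frac >= 0.8

    def test_nulled_validation_cohort_validates_almost_nothing(self):
        expr, surv, planted = simulate_recurrence_cohort(
            n_samples=400, n_genes=200, n_prognostic=15, seed=73
        )
        cohort = discovery.dichotomize(surv)
        table = discovery.gene_tests(expr, cohort)
        discovered = table.index[table["significant"]].tolist()
        assert discovered
        v_expr, v_surv, _ = simulate_recurrence_cohort(
            n_samples=400, n_genes=200, n_prognostic=15, log2_shift=0.0, seed=74
        )
        v_cohort = discovery.dichotomize(v_surv)
        val = discovery.validate(discovered, v_expr, v_cohort, discovery_table=table)
        assert val["validated"].mean() <= 0.05 + 2 * np.sqrt(
            0.05 * 0.95 / len(discovered)
        )

    def test_empty_discovery_set_rejected(self):
        expr, _, _ = simulate_recurrence_cohort(n_samples=50, n_genes=20, seed=75)
        with pytest.raises(ValueError, match="empty"):
            discovery.validate([], expr, None)

    def test_missing_gene_flagged_untestable(self):
        expr, surv, _ = simulate_recurrence_cohort(
            n_samples=200, n_genes=50, n_prognostic=5, seed=76
        )
        cohort = discovery.dichotomize(surv)
        val = discovery.validate(
            ["GENE_0001", "NOT_A_GENE"], expr, cohort
        )
        assert bool(val.loc["NOT_A_GENE", "untestable"])
        assert not bool(val.loc["GENE_0001", "untestable"])


class TestProliferationCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        r, q = discovery.proliferation_correlation(expr, ["a"], ["a", "b"])
        assert r.loc["a", "a"] == pytest.approx(1.0)

    def test_independent_genes_center_at_zero(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(
            rng.normal(size=(500, 6)), columns=[f"g{i}" for i in range(6)]
        )
        r, _ = discovery.proliferation_correlation(
            expr, ["g0", "g1", "g2"], ["g3", "g4", "g5"]
        )
        assert np.abs(r.to_numpy()).max() < 0.2

    def test_shared_latent_factor_detected(self):
        rng = np.random.default_rng(7)
        factor = rng.normal(size=200)
        expr = pd.DataFrame(
            {
                "disc": 0.9 * factor + np.sqrt(1 - 0.81) * rng.normal(size=200),
                "prol": 0.9 * factor + np.sqrt(1 - 0.81) * rng.normal(size=200),
                "noise": rng.normal(size=200),
            }
        )
        r, q = discovery.proliferation_correlation(expr, ["disc"], ["prol", "noise"])
        assert r.loc["disc", "prol"] > 0.5
        assert q.loc["disc", "prol"] < 0.01

    def test_missing_gene_rejected(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="absent"):
            discovery.proliferation_correlation(expr, ["a"], ["zz"])
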