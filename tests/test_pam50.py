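"""Nearest-centroid calls, consensus labelling and the forest classifier."""

import numpy as np
import pandas as pd
import pytest

from bclandscape import pam50
from bclandscape.qcnorm import normalize, run_qc
from bclandscape.synthdata import SimulationConfig, simulate_cohort

from oracles import brute_spearman


def toy_centroids():
    genes = [f"g{i}" for i in range(6)]
    return pam50.CentroidSet(
        centroids=pd.DataFrame(
            {"A": [5, 4, 3, 2, 1, 0], "B": [0, 1, 2, 3, 4, 5]}, index=genes
        ).astype(float)
    )


class TestNearestCentroid:
    def test_centroid_sample_maps_to_itself(self):
        cs = toy_centroids()
        # two samples so per-gene median centering stays rank-preserving
        expr = pd.DataFrame(
            [cs.centroids["A"], cs.centroids["B"]], index=["sA", "sB"]
        )
        calls = pam50.nearest_centroid_call(expr, cs)
        assert list(calls["label"]) == ["A", "B"]
        assert calls["correlation"].tolist() == pytest.approx([1.0, 1.0])

    def test_negated_centroid_maps_to_opposite(self):
        cs = toy_centroids()
        expr = pd.DataFrame(
            [-cs.centroids["A"], cs.centroids["A"]], index=["neg", "pos"]
        )
        calls = pam50.nearest_centroid_call(expr, cs)
        assert calls.loc["neg", "label"] == "B"
        assert calls.loc["pos", "label"] == "A"

    def test_agrees_with_brute_force_spearman(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(5)]
        cs = pam50.CentroidSet(
            centroids=pd.DataFrame(
                rng.normal(size=(5, 3)), index=genes, columns=["A", "B", "C"]
            )
        )
        expr = pd.DataFrame(
            rng.normal(size=(8, 5)), columns=genes,
            index=[f"s{i}" for i in range(8)],
        )
        calls = pam50.nearest_centroid_call(expr, cs)
        centered = expr - expr.median(axis=0)
        for s in expr.index:
            cors = {
                c: brute_spearman(centered.loc[s], cs.centroids[c])
                for c in ["A", "B", "C"]
            }
            best = max(sorted(cors), key=lambda c: cors[c])
            assert calls.loc[s, "label"] == best

    def test_too_few_shared_genes_rejected(self):
        cs = toy_centroids()
        expr = pd.DataFrame({"g0": [1.0, 2.0], "zz": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="centroid genes"):
            pam50.nearest_centroid_call(expr, cs)


class TestConsensusLabels:
    def test_separable_cohort_fully_labelled(self):
        cfg = SimulationConfig(n_samples=80, n_genes=60, noise_sd=0.3, seed=21)
        cohort = simulate_cohort(cfg)
        expr = normalize(cohort.counts, run_qc(cohort.counts))
        labels = pam50.consensus_labels(
            expr.values[cohort.panel.classifier], cohort.centroids
        )
        assert (labels != pam50.UNASSIGNED).all()
        assert (labels == cohort.truth.loc[labels.index, "subtype"]).all()

    def test_disagreement_yields_unassigned(self):
        # Two tight clusters plus one sample whose nearest centroid differs
        # from the cluster it joins.
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        cA = np.linspace(0, 3, 10)
        cB = cA[::-1].copy()
        cs = pam50.CentroidSet(
            centroids=pd.DataFrame({"A": cA, "B": cB}, index=genes)
        )
        rows = [cA + rng.normal(0, 0.01, 10) for _ in range(5)]
        rows += [cB + rng.normal(0, 0.01, 10) for _ in range(5)]
        # impostor: sits in the A cluster spatially but correlates with B
        rows.append(cA * 0.05 + cB * 0.95)
        expr = pd.DataFrame(rows, columns=genes,
                            index=[f"s{i}" for i in range(11)])
        labels = pam50.consensus_labels(expr, cs, k=2)
        nc = pam50.nearest_centroid_call(expr, cs)
        consistent = labels != pam50.UNASSIGNED
        assert (labels[consistent] == nc.loc[consistent, "label"]).all()

    def test_consensus_subset_purer_than_nearest_centroid(self):
        cfg = SimulationConfig(n_samples=250, n_genes=60, noise_sd=1.6, seed=23)
        cohort = simulate_cohort(cfg)
        expr = normalize(cohort.counts, run_qc(cohort.counts))
        X = expr.values[cohort.panel.classifier]
        truth = cohort.truth.loc[X.index, "subtype"]
        nc = pam50.nearest_centroid_call(X, cohort.centroids)
        labels = pam50.consensus_labels(X, cohort.centroids)
        kept = labels != pam50.UNASSIGNED
        purity_consensus = (labels[kept] == truth[kept]).mean()
        purity_nc = (nc["label"] == truth).mean()
        assert purity_consensus >= purity_nc


@pytest.fixture(scope="module")
def trained():
    cfg = SimulationConfig(n_samples=200, n_genes=60, seed=31)
    cohort = simulate_cohort(cfg)
    expr = normalize(cohort.counts, run_qc(cohort.counts))
    X = expr.values[cohort.panel.classifier]
    labels = cohort.truth.loc[X.index, "subtype"]
    clf = pam50.train_classifier(X, labels, n_trees=400, seed=0)
    return cohort, X, labels, clf


class TestClassifier:
    def test_separable_training_data_zero_oob_error(self):
        cfg = SimulationConfig(
            n_samples=60, n_genes=60, noise_sd=0.0, scale_sd=0.0, seed=33
        )
        cohort = simulate_cohort(cfg)
        expr = normalize(cohort.counts, run_qc(cohort.counts))
        X = expr.values[cohort.panel.classifier]
        clf = pam50.train_classifier(
            X, cohort.truth.loc[X.index, "subtype"], n_trees=200, seed=0
        )
        assert clf.oob_error == 0.0

    def test_oob_error_invariant_to_label_renaming(self, trained):
        _, X, labels, clf = trained
        renamed = labels.map(lambda s: f"Z_{s}")
        clf2 = pam50.train_classifier(X, renamed, n_trees=400, seed=0)
        assert clf2.oob_error == pytest.approx(clf.oob_error)

    def test_oob_error_stable_across_seeds(self, trained):
        # cross-seed agreement of the OOB estimate within 2 percentage points
        _, X, labels, clf = trained
        errors = [
            pam50.train_classifier(X, labels, n_trees=400, seed=s).oob_error
            for s in (1, 2)
        ]
        for e in errors:
            assert abs(e - clf.oob_error) <= 0.02

    def test_probabilities_sum_to_one_and_gate_applies(self, trained):
        cohort, X, labels, clf = trained
        proba = clf.model.predict_proba(X.to_numpy())
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        calls = pam50.predict(clf, X)
        assert ((calls["probability"] > 0.4) == calls["confident"]).all()

    def test_training_samples_predicted_with_high_confidence(self):
        cfg = SimulationConfig(
            n_samples=60, n_genes=60, noise_sd=0.0, scale_sd=0.0, seed=35
        )
        cohort = simulate_cohort(cfg)
        expr = normalize(cohort.counts, run_qc(cohort.counts))
        X = expr.values[cohort.panel.classifier]
        labels = cohort.truth.loc[X.index, "subtype"]
        clf = pam50.train_classifier(X, labels, n_trees=200, seed=0)
        calls = pam50.predict(clf, X)
        assert (calls["label"] == labels).all()
        assert (calls["probability"] > 0.9).all()

    def test_structureless_sample_is_low_confidence(self, trained):
        cohort, X, labels, clf = trained
        rng = np.random.default_rng(9)
        noise = pd.DataFrame(
            rng.uniform(0, 14, size=(40, X.shape[1])), columns=X.columns
        )
        calls = pam50.predict(clf, noise)
        # votes scatter across the 4 classes: typical probability near 1/4
        assert calls["probability"].median() < 0.6

    def test_gating_improves_purity(self):
        cfg_train = SimulationConfig(n_samples=250, n_genes=60, noise_sd=1.8, seed=37)
        cfg_test = SimulationConfig(n_samples=250, n_genes=60, noise_sd=1.8, seed=38)
        train, test = simulate_cohort(cfg_train), simulate_cohort(cfg_test)
        Xtr = normalize(train.counts, run_qc(train.counts)).values[
            train.panel.classifier
        ]
        clf = pam50.train_classifier(
            Xtr, train.truth.loc[Xtr.index, "subtype"], n_trees=400, seed=0
        )
        Xte = normalize(test.counts, run_qc(test.counts)).values[
            test.panel.classifier
        ]
        calls = pam50.predict(clf, Xte)
        truth = test.truth.loc[Xte.index, "subtype"]
        acc_all = (calls["label"] == truth).mean()
        conf = calls["confident"]
        acc_conf = (calls.loc[conf, "label"] == truth[conf]).mean()
        assert acc_conf >= acc_all

    def test_error_conditions(self, trained):
        _, X, labels, clf = trained
        with pytest.raises(ValueError, match="2 classes"):
            pam50.train_classifier(X, pd.Series("LumA", index=X.index))
        small = labels.copy()
        small.iloc[:] = "LumA"
        small.iloc[0] = "Basal"
        with pytest.raises(ValueError, match="fewer than 5"):
            pam50.train_classifier(X, small)
        with pytest.raises(ValueError, match="classifier genes"):
            pam50.predict(clf, X.iloc[:, :10])
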