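import numpy as np
import pytest

from fragmentomics.models import (
    CANCER_LABELS,
    export_nf_coefficients,
    gini_impurity,
    log2_ca19_9,
    predict,
    select_cutoff,
    train_base_model,
    train_cf,
    train_stacked,
    train_subtype_models,
)
from fragmentomics.pipeline import FAMILIES, CohortFeatureMatrix
from fragmentomics.evaluate import roc_auc

DIMS = {"fragment": 40, "motif": 60, "nf": 150}


def gaussian_matrix(
    seed,
    n0=40,
    n1=40,
    effect=None,
    n_informative=10,
    labels=("non_cancer", "PAC"),
    ca_sep=True,
):
    """Feature blocks with a planted mean shift on the first features of the
    positive class — a transparent stand-in cohort for model unit tests."""
    effect = effect or {}
    rng = np.random.default_rng(seed)
    y = [labels[0]] * n0 + [labels[1]] * n1
    blocks = {}
    for fam, dim in DIMS.items():
        X = rng.normal(size=(n0 + n1, dim))
        X[n0:, :n_informative] += effect.get(fam, 0.0)
        blocks[fam] = X
    mu = (np.log(10), np.log(200)) if ca_sep else (np.log(10), np.log(10))
    ca = np.concatenate(
        [np.exp(rng.normal(mu[0], 0.8, n0)), np.exp(rng.normal(mu[1], 1.5, n1))]
    )
    return CohortFeatureMatrix(
        [f"s{i:03d}" for i in range(n0 + n1)], np.array(y), blocks, ca
    )


class TestBaseModel:
    def test_separable_data_perfect_oof_auc(self):
        m = gaussian_matrix(0, effect={"fragment": 6.0})
        y = m.binary_labels(CANCER_LABELS)
        res = train_base_model(m.blocks["fragment"], y, "fragment", seed=0)
        assert roc_auc(res.oof_scores, y).auc == 1.0
        assert (res.oof_scores >= 0).all() and (res.oof_scores <= 1).all()

    def test_null_labels_give_chance_level_oof_auc(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 30))
        y = rng.permutation([0] * 100 + [1] * 100)
        res = train_base_model(X, y, "fragment", seed=1)
        assert 0.35 <= roc_auc(res.oof_scores, y).auc <= 0.65

    def test_deterministic_given_seed(self):
        m = gaussian_matrix(2, effect={"nf": 1.0})
        y = m.binary_labels(CANCER_LABELS)
        a = train_base_model(m.blocks["nf"], y, "nf", seed=5)
        b = train_base_model(m.blocks["nf"], y, "nf", seed=5)
        np.testing.assert_array_equal(a.folds, b.folds)
        np.testing.assert_allclose(a.oof_scores, b.oof_scores)

    def test_oof_scores_exclude_own_fold(self):
        """Refitting without fold f reproduces fold f's out-of-fold scores."""
        from fragmentomics.models import _fit_family, _fold_assignment

        m = gaussian_matrix(3, effect={"fragment": 1.5})
        y = m.binary_labels(CANCER_LABELS)
        X = m.blocks["fragment"]
        res = train_base_model(X, y, "fragment", seed=7)
        splits = _fold_assignment(y, seed=7, n_splits=10)
        tr, te = splits[0]
        refit = _fit_family(X[tr], y[tr], "fragment", seed=7)
        np.testing.assert_allclose(res.oof_scores[te], refit.predict_score(X[te]))

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            train_base_model(X, np.zeros(10, dtype=int), "fragment", seed=0)


class TestCutoff:
    def test_perfect_split(self):
        cut = select_cutoff(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert cut == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_cutoff(np.array([0.1, 0.9]), np.array([1, 1]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_partition_scan(self, seed):
        """The chosen cutoff achieves the same impurity as enumerating every
        possible split of the sorted scores."""
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 12), size=20)
        labels = rng.integers(0, 2, size=20)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        cut = select_cutoff(scores, labels)

        order = np.argsort(scores)
        s, l = scores[order], labels[order]
        best = np.inf
        for i in range(1, len(s)):  # every partition point of the sorted scores
            if s[i - 1] == s[i]:
                continue
            left, right = l[:i], l[i:]
            imp = len(left) / len(l) * gini_impurity(left) + len(right) / len(l) * gini_impurity(right)
            best = min(best, imp)
        right = scores >= cut
        achieved = (
            right.sum() / len(l) * gini_impurity(labels[right])
            + (~right).sum() / len(l) * gini_impurity(labels[~right])
        )
        assert achieved == pytest.approx(best)

    def test_tie_break_prefers_higher_specificity(self):
        # impurity ties at the 0.15 and 0.35 midpoints; the larger cutoff
        # (higher specificity) must win
        scores = np.array([0.1, 0.2, 0.3, 0.4])
        labels = np.array([0, 1, 0, 1])
        assert select_cutoff(scores, labels) == pytest.approx(0.35)


class TestStacked:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_stacking_not_worse_than_best_base(self, seed):
        m = gaussian_matrix(seed, effect={"fragment": 1.2, "motif": 1.2, "nf": 1.2})
        y = m.binary_labels(CANCER_LABELS)
        st = train_stacked(m, seed=seed)
        base_aucs = [roc_auc(st.base[f].oof_scores, y).auc for f in FAMILIES]
        stacked_auc = roc_auc(st.oof_stacked, y).auc
        assert stacked_auc > max(base_aucs) - 0.02

    def test_noise_block_does_not_drag_stack_down(self):
        m = gaussian_matrix(4, effect={"fragment": 2.0, "nf": 2.0})  # motif pure noise
        y = m.binary_labels(CANCER_LABELS)
        st = train_stacked(m, seed=4)
        best_informative = max(
            roc_auc(st.base[f].oof_scores, y).auc for f in ("fragment", "nf")
        )
        assert roc_auc(st.oof_stacked, y).auc > best_informative - 0.05

    def test_missing_block_rejected(self):
        m = gaussian_matrix(5)
        del m.blocks["motif"]
        with pytest.raises(ValueError):
            train_stacked(m, seed=0)

    def test_predict_report(self):
        m = gaussian_matrix(6, effect={"fragment": 3.0, "motif": 3.0, "nf": 3.0})
        st = train_stacked(m, seed=6)
        rep = predict(st, m)
        assert set(rep.columns) >= {"sample_id", "stacked_score", "predicted"}
        assert rep["stacked_score"].between(0, 1).all()
        # duplicated input rows score identically
        m2 = m.subset(np.arange(len(m)) < 4)
        r1 = predict(st, m2)
        r2 = predict(st, m2)
        np.testing.assert_allclose(r1["stacked_score"], r2["stacked_score"])

    def test_dimension_mismatch_rejected(self):
        m = gaussian_matrix(7, effect={"fragment": 3.0})
        st = train_stacked(m, seed=7)
        bad = gaussian_matrix(8)
        bad.blocks["fragment"] = bad.blocks["fragment"][:, :10]
        with pytest.raises(ValueError):
            predict(st, bad)


class TestCF:
    def test_log2_transform_values(self):
        np.testing.assert_allclose(log2_ca19_9(np.array([39.0])), [5.321928], atol=1e-6)
        assert log2_ca19_9(np.array([0.0]))[0] == 0.0
        with pytest.raises(ValueError):
            log2_ca19_9(np.array([-1.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fusion_not_worse_than_either_input(self, seed):
        """CA19-9 separates moderately, fragmentomics strongly: the fused
        model should not fall below the better single input on held-out data."""
        tr = gaussian_matrix(seed, effect={"fragment": 1.5, "motif": 1.5, "nf": 1.5})
        va = gaussian_matrix(seed + 100, effect={"fragment": 1.5, "motif": 1.5, "nf": 1.5})
        st = train_stacked(tr, seed=seed)
        cf = train_cf(tr, st, seed=seed)
        y = va.binary_labels(CANCER_LABELS)
        stacked_scores = st.stacked_scores(va)
        auc_stacked = roc_auc(stacked_scores, y).auc
        auc_ca = roc_auc(log2_ca19_9(va.ca19_9), y).auc
        auc_cf = roc_auc(cf.predict_score(stacked_scores, va.ca19_9), y).auc
        assert auc_cf >= max(auc_stacked, auc_ca) - 0.02

    def test_missing_ca19_9_rejected(self):
        m = gaussian_matrix(9, effect={"fragment": 2.0})
        m.ca19_9 = None
        st = train_stacked(m, seed=9)
        with pytest.raises(ValueError):
            train_cf(m, st, seed=9)

    def test_decision_line_separates_plane(self):
        m = gaussian_matrix(10, effect={"fragment": 3.0, "motif": 3.0, "nf": 3.0})
        st = train_stacked(m, seed=10)
        cf = train_cf(m, st, seed=10)
        a, b, c = cf.decision_line()
        X = np.column_stack([st.oof_stacked, log2_ca19_9(m.ca19_9)])
        side = np.sign(a * X[:, 0] + b * X[:, 1] + c)
        y = m.binary_labels(CANCER_LABELS)
        assert (side == np.where(y == 1, 1, -1)).mean() > 0.9


class TestSubtypes:
    def test_family_specific_effect_ranks_families(self):
        m = gaussian_matrix(
            11, n0=30, n1=30, effect={"nf": 2.0}, labels=("CCA", "PAC")
        )
        st = train_subtype_models(m, positive="PAC", negative="CCA", seed=11)
        y = m.binary_labels(frozenset({"PAC"}))
        aucs = {f: roc_auc(st.base[f].oof_scores, y).auc for f in FAMILIES}
        assert aucs["nf"] > aucs["fragment"]
        assert aucs["nf"] > aucs["motif"]

    def test_null_contrast_near_chance(self):
        m = gaussian_matrix(12, n0=40, n1=40, labels=("CCA", "GBC"))
        st = train_subtype_models(m, positive="GBC", negative="CCA", seed=12)
        y = m.binary_labels(frozenset({"GBC"}))
        assert 0.25 <= roc_auc(st.oof_stacked, y).auc <= 0.75

    def test_empty_group_rejected(self):
        m = gaussian_matrix(13)
        with pytest.raises(ValueError):
            train_subtype_models(m, positive="GBC", negative="CCA", seed=0)


class TestNFCoefficients:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_genes_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n0 = n1 = 45
        X = rng.normal(size=(n0 + n1, 500))
        informative = rng.choice(500, size=10, replace=False)
        X[n1:, informative] += 1.5
        y = np.array([0] * n0 + [1] * n1)
        res = train_base_model(X, y, "nf", seed=seed)
        gene_ids = [f"g{i}" for i in range(500)]
        top = export_nf_coefficients(res, gene_ids, top_n=20)
        hits = len({f"g{i}" for i in informative} & set(top["gene_id"]))
        assert hits >= 8

    def test_top_n_zero_empty(self):
        m = gaussian_matrix(14, effect={"nf": 2.0})
        y = m.binary_labels(CANCER_LABELS)
        res = train_base_model(m.blocks["nf"], y, "nf", seed=14)
        assert len(export_nf_coefficients(res, [f"g{i}" for i in range(150)], 0)) == 0

    def test_zero_variance_feature_gets_zero_coefficient(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(60, 20))
        X[:, 5] = 3.14  # constant
        y = np.array([0] * 30 + [1] * 30)
        res = train_base_model(X, y, "nf", seed=15)
        table = export_nf_coefficients(res, [f"g{i}" for i in range(20)], 20)
        assert table.set_index("gene_id").loc["g5", "coefficient"] == 0.0

    def test_forest_learner_rejected(self):
        m = gaussian_matrix(16, effect={"motif": 2.0})
        y = m.binary_labels(CANCER_LABELS)
        res = train_base_model(m.blocks["motif"], y, "motif", seed=16)
        with pytest.raises(ValueError):
            export_nf_coefficients(res, [f"g{i}" for i in range(60)], 10)
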