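"""Task heads and metrics: CE, Cox partial likelihood vs brute-force
risk-set oracle, C-index pair counting, log-rank, classification /
imputation / silhouette metrics, and fine-tuning contracts."""

import copy

import numpy as np
import pandas as pd
import pytest

from omicsfuse import (FreezePolicy, FineTuneConfig, ce_classification_loss,
                       classification_metrics, concordance_index, cox_loss,
                       finetune_classifier, imputation_metrics, silhouette,
                       stratify_and_logrank)
from omicsfuse.tasks import predict_classes


def records(times, events):
    return pd.DataFrame({"time": times, "event": events})


class TestCrossEntropy:
    def test_uniform_logits(self):
        assert ce_classification_loss(np.zeros(4), [0]) == pytest.approx(np.log(4))

    def test_confident_correct_approaches_zero(self):
        logits = np.array([50.0, 0.0, 0.0])
        assert ce_classification_loss(logits, [0]) == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_manual_oracle(self):
        logits = np.array([[1.0, 2.0, 0.5], [0.0, -1.0, 3.0]])
        y = [1, 2]
        expected = np.mean([
            -np.log(np.exp(2.0) / np.exp(logits[0]).sum()),
            -np.log(np.exp(3.0) / np.exp(logits[1]).sum()),
        ])
        assert ce_classification_loss(logits, y) == pytest.approx(expected)

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError):
            ce_classification_loss(np.zeros((1, 3)), [3])


def brute_force_cox(h, t, e):
    """Direct risk-set enumeration of the negative log partial likelihood."""
    total = 0.0
    for i in range(len(h)):
        if e[i] != 1:
            continue
        risk = [j for j in range(len(h)) if t[j] >= t[i]]
        total += h[i] - np.log(np.sum(np.exp([h[j] for j in risk])))
    return -total


class TestCoxLoss:
    def test_single_event_zero(self):
        assert cox_loss([2.5], records([1.0], [1])) == pytest.approx(0.0, abs=1e-12)

    def test_two_symmetric_events_log2(self):
        assert cox_loss([0.0, 0.0], records([1.0, 2.0], [1, 1])) == \
            pytest.approx(np.log(2))

    def test_matches_brute_force_on_random_instances(self, rng):
        """100 random small datasets with ties and censoring."""
        for _ in range(100):
            n = rng.integers(2, 11)
            h = rng.standard_normal(n)
            t = rng.integers(1, 6, n).astype(float)  # integer times force ties
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            assert cox_loss(h, records(t, e)) == pytest.approx(
                brute_force_cox(h, t, e), abs=1e-8)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="uncensored|empty"):
            cox_loss([0.0, 1.0], records([1.0, 2.0], [0, 0]))


def brute_force_cindex(h, t, e):
    conc = comp = 0.0
    n = len(h)
    for i in range(n):
        for j in range(n):
            if e[i] == 1 and t[i] < t[j]:
                comp += 1
                if h[i] > h[j]:
                    conc += 1
                elif h[i] == h[j]:
                    conc += 0.5
    return conc / comp


class TestConcordance:
    def test_perfect_reverse_ordering(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        h = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance_index(h, records(t, [1, 1, 1, 1])) == 1.0

    def test_constant_hazards_half(self):
        t = np.array([1.0, 2.0, 3.0])
        assert concordance_index(np.zeros(3), records(t, [1, 1, 1])) == 0.5

    def test_matches_pair_counting_with_censoring(self, rng):
        for _ in range(30):
            n = rng.integers(4, 21)
            h = np.round(rng.standard_normal(n), 1)  # rounding creates ties
            t = rng.integers(1, 8, n).astype(float)
            e = rng.integers(0, 2, n)
            # distinct times so the oracle's comparable-pair definition
            # matches exactly; earliest record is an event so pairs exist
            t = t + rng.permutation(n) * 1e-3
            e[np.argmin(t)] = 1
            assert concordance_index(h, records(t, e)) == pytest.approx(
                brute_force_cindex(h, t, e), abs=1e-10)

    def test_flip_symmetry_without_ties(self, rng):
        n = 15
        h = rng.standard_normal(n)
        t = np.sort(rng.random(n)) + 0.1
        rec = records(t, np.ones(n, dtype=int))
        assert concordance_index(h, rec) + concordance_index(-h, rec) == \
            pytest.approx(1.0)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        e = np.ones(8, dtype=int)
        h = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        groups, chi2, p = stratify_and_logrank(h, records(t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_median_split_balanced(self, rng):
        h = rng.standard_normal(9)
        t = rng.random(9) + 0.1
        groups, _, _ = stratify_and_logrank(h, records(t, np.ones(9, dtype=int)))
        assert abs(int(groups.sum()) - (9 - int(groups.sum()))) <= 1

    def test_textbook_two_group_computation(self):
        """8-sample hand computation of the observed-minus-expected log-rank
        statistic (no censoring, distinct times)."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        e = np.ones(8, dtype=int)
        h = np.array([2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0])  # high risk die first
        groups, chi2, p = stratify_and_logrank(h, records(t, e))
        # hand computation: at each death time, expected deaths in group 1 =
        # n1/(n0+n1); O1=4, E1 = 4/8+3/7+2/6+1/5 = 1.5595..; var term per time
        o1 = 4.0
        n1 = np.array([4, 3, 2, 1, 0, 0, 0, 0], dtype=float)
        ntot = np.arange(8, 0, -1, dtype=float)
        e1 = (n1 / ntot).sum()
        v = (n1 / ntot * (1 - n1 / ntot)).sum()
        expected_chi2 = (o1 - e1) ** 2 / v
        assert chi2 == pytest.approx(expected_chi2, rel=1e-6)
        assert p < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            stratify_and_logrank([1.0, 2.0], records([1.0, 2.0], [1, 1]))


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        m = classification_metrics([0, 1, 2], [0, 1, 2])
        assert m["accuracy"] == m["f1_macro"] == 1.0

    def test_binary_confusion_arithmetic(self):
        # TP=2, FP=1, FN=1 for class 1
        pred = [1, 1, 1, 0, 0]
        true = [1, 1, 0, 1, 0]
        m = classification_metrics(pred, true)
        assert m["per_class"]["1"]["precision"] == pytest.approx(2 / 3)
        assert m["per_class"]["1"]["recall"] == pytest.approx(2 / 3)
        assert m["per_class"]["1"]["f1"] == pytest.approx(2 / 3)

    def test_multiclass_matches_confusion_matrix_oracle(self, rng):
        pred = rng.integers(0, 3, 60)
        true = rng.integers(0, 3, 60)
        m = classification_metrics(pred, true)
        f1s = []
        for c in range(3):
            tp = np.sum((pred == c) & (true == c))
            fp = np.sum((pred == c) & (true != c))
            fn = np.sum((pred != c) & (true == c))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert m["f1_macro"] == pytest.approx(np.mean(f1s))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])


class TestImputationMetrics:
    def test_perfect_imputation(self, rng):
        x = rng.standard_normal((20, 5))
        m = imputation_metrics(x, x, "continuous")
        assert m["r2"] == pytest.approx(1.0)
        assert m["pearson_r"] == pytest.approx(1.0)

    def test_column_means_give_zero_r2(self, rng):
        x = rng.standard_normal((30, 4))
        xm = np.tile(x.mean(axis=0), (30, 1))
        assert imputation_metrics(x, xm, "continuous")["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_binary_perfect_separation_auc_one(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        p = np.array([[0.1], [0.2], [0.8], [0.9]])
        assert imputation_metrics(x, p, "binary")["auc"] == 1.0

    def test_constant_truth_column_skipped(self, rng):
        x = np.column_stack([np.ones(10), rng.standard_normal(10)])
        m = imputation_metrics(x, x + 0.01, "continuous")
        assert m["n_features"] == 1


class TestSilhouette:
    def test_two_tight_distant_clusters(self, rng):
        a = rng.standard_normal((30, 3)) * 0.01
        b = rng.standard_normal((30, 3)) * 0.01 + 50
        emb = np.vstack([a, b])
        labels = np.array([0] * 30 + [1] * 30)
        assert silhouette(emb, labels) > 0.9

    def test_random_labels_near_zero(self, rng):
        emb = np.vstack([rng.standard_normal((40, 3)),
                         rng.standard_normal((40, 3)) + 20])
        labels = rng.integers(0, 2, 80)
        assert abs(silhouette(emb, labels)) < 0.2

    def test_duplication_invariance(self, rng):
        """Duplicating every point changes a(i) only through the |C|-1
        denominator, an O(1/n) effect."""
        emb = rng.standard_normal((200, 4))
        labels = rng.integers(0, 2, 200)
        s1 = silhouette(emb, labels)
        s2 = silhouette(np.vstack([emb, emb]), np.concatenate([labels, labels]))
        assert s1 == pytest.approx(s2, abs=0.02)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette(rng.standard_normal((10, 2)), np.zeros(10))


class TestFineTuning:
    def test_freeze_backbone_leaves_params_bitwise(self, sim_dataset, pretrained):
        dataset, _ = sim_dataset
        model = pretrained.model_
        before = {k: v.copy() for k, v in model.state_dict().items()}
        finetune_classifier(model, dataset, policy=FreezePolicy("freeze_backbone"),
                            config=FineTuneConfig(max_epochs=3, seed=0))
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_separable_data_high_f1(self, sim_dataset, pretrained):
        dataset, _ = sim_dataset
        vae = copy.deepcopy(pretrained)
        head = finetune_classifier(vae.model_, dataset,
                                   config=FineTuneConfig(max_epochs=25, seed=0))
        pred = predict_classes(vae.model_, head, dataset)
        m = classification_metrics(pred, dataset.clinical["subtype"].to_numpy())
        assert m["f1_macro"] >= 0.9

    def test_cross_encoders_of_missing_modality_frozen(self, sim_dataset, pretrained):
        from omicsfuse.io_prep import MultiOmicsDataset
        dataset, _ = sim_dataset
        vae = copy.deepcopy(pretrained)
        mask = dataset.presence_mask.copy()
        mask[:, 1] = 0.0  # second modality missing throughout fine-tuning
        ds_missing = MultiOmicsDataset(dataset.modalities, mask, dataset.clinical)
        model = vae.model_
        tgt = model.order[1]
        frozen_keys = [k for k in model.state_dict()
                       if k.startswith("cross_enc.") and f"->{tgt}" in k]
        assert frozen_keys
        before = {k: model.state_dict()[k].copy() for k in frozen_keys}
        finetune_classifier(model, ds_missing,
                            config=FineTuneConfig(max_epochs=3, seed=0))
        after = model.state_dict()
        for k in frozen_keys:
            np.testing.assert_array_equal(before[k], after[k])

    def test_single_class_labels_rejected(self, sim_dataset, pretrained):
        dataset, _ = sim_dataset
        with pytest.raises(ValueError, match="classes"):
            finetune_classifier(pretrained.model_, dataset,
                                labels=np.zeros(dataset.n_samples, dtype=int))
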