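"""Evaluation metrics checked against independent brute-force enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from funbench.evaluation import (
    AnnotationMethod,
    ConfusionCounts,
    EvaluationError,
    compare_methods,
    confusion_at,
    delta_s,
    delta_s_max,
    evaluate_binary_reference,
    evaluate_once,
    pr_roc_auc,
    precision_recall_f1,
    recall_max_ppf50,
    run_resampled_evaluation,
    sweep_f1max,
)
from funbench.pair_dataset import SIBLING, label_siblings
from funbench.predictions import PredictionTable
from funbench.similarity import jaccard

from conftest import make_pairs


# ---------------------------------------------------------------------------
# Independent oracles: plain loops over every threshold pair


def brute_sweep_f1max(method, dataset):
    labels = dataset.labels()
    best = None
    for tau_p in method.tau_p_grid():
        scores = method.score(tau_p, dataset.pairs)
        if not scores:
            continue
        for tau_s in sorted(set(scores.values())):
            p, r, f1 = precision_recall_f1(confusion_at(scores, labels, tau_s))
            if best is None or f1 > best[0]:
                best = (f1, float(tau_p), tau_s)
    return best


def brute_roc_auc(scores, labels):
    pos = [s for k, s in scores.items() if labels[k] == SIBLING]
    neg = [s for k, s in scores.items() if labels[k] != SIBLING]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_pr_auc(scores, labels):
    # step-wise summation over descending distinct thresholds
    lab = dict(labels)
    items = sorted(scores.items(), key=lambda kv: -kv[1])
    n_pos = sum(1 for k, _ in items if lab[k] == SIBLING)
    ap, prev_recall = 0.0, 0.0
    tp = pp = 0
    for i, (key, s) in enumerate(items):
        tp += lab[key] == SIBLING
        pp += 1
        if i + 1 < len(items) and items[i + 1][1] == s:
            continue  # not a distinct threshold yet
        precision = tp / pp
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_delta_s_max(method, dataset):
    labels = dataset.labels()
    n_sib = dataset.n_siblings
    best = -np.inf
    for tau_p in method.tau_p_grid():
        scores = method.score(tau_p, dataset.pairs)
        sib = [s for k, s in scores.items() if labels[k] == SIBLING]
        unl = [s for k, s in scores.items() if labels[k] != SIBLING]
        if not sib or not unl:
            continue
        value = (len(sib) / n_sib) * (np.mean(sib) - np.mean(unl))
        best = max(best, value)
    return best


def brute_recall_max_ppf50(method, dataset):
    labels = dataset.labels()
    best = 0.0
    for tau_p in method.tau_p_grid():
        scores = method.score(tau_p, dataset.pairs)
        if not scores:
            continue
        for tau_s in sorted(set(scores.values())):
            c = confusion_at(scores, labels, tau_s)
            ppf = (c.tp + c.fp) / len(scores)
            if ppf < 0.5 and (c.tp + c.fn):
                best = max(best, c.tp / (c.tp + c.fn))
    return best


def random_instance(seed, n_proteins=6, n_terms=5):
    """A small random prediction table + labelled pair set (<= 15 pairs)."""
    rng = np.random.default_rng(seed)
    proteins = [f"p{i}" for i in range(n_proteins)]
    rows = []
    for p in proteins:
        for t in rng.choice(n_terms, size=rng.integers(1, 4), replace=False):
            rows.append((p, f"t{t}", round(float(rng.uniform()), 1)))
    table = PredictionTable(data=pd.DataFrame(rows, columns=["protein", "term", "score"]))
    raw = [
        (a, b, round(float(rng.uniform()), 2), round(float(rng.uniform()), 2))
        for a, b in itertools.combinations(proteins, 2)
    ]
    raw[0] = (raw[0][0], raw[0][1], 0.9, 0.99)  # guarantee a sibling
    dataset = label_siblings(make_pairs(raw))
    return AnnotationMethod(table=table, kernel=jaccard), dataset


# ---------------------------------------------------------------------------


class TestConfusionAndPointMetrics:
    def test_confusion_examples(self, tiny_dataset):
        scores = {p.key: 1.0 if p.label == SIBLING else 0.9 if p.id2 == "p3" else 0.0
                  for p in tiny_dataset.pairs}
        c = confusion_at(scores, tiny_dataset.labels(), 0.5)
        assert c.tp == 3 and c.fp == 3  # the 0.9-scored unlabeled pairs are FP
        assert c.tp + c.fn == tiny_dataset.n_siblings
        assert c.fp + c.tn == tiny_dataset.n_unlabeled

    def test_tau_s_zero_calls_everything_positive(self, tiny_dataset):
        scores = {p.key: 0.0 for p in tiny_dataset.pairs}
        c = confusion_at(scores, tiny_dataset.labels(), 0.0)
        assert c.fn == 0 and c.tn == 0

    def test_unlabelled_scored_pair_is_error(self):
        with pytest.raises(EvaluationError):
            confusion_at({("x", "y"): 1.0}, {}, 0.5)

    def test_enzyme_benchmark_arithmetic(self):
        # printed sibling-gate counts: 1927 called, 1693 same-EC, 70 735 total same-EC
        c = ConfusionCounts(tp=1693, fp=1927 - 1693, fn=70735 - 1693, tn=0)
        precision, recall, _ = precision_recall_f1(c)
        assert precision == pytest.approx(0.8786, abs=5e-5)
        assert recall == pytest.approx(0.0239, abs=5e-5)

    @pytest.mark.parametrize(
        "tp,fp,fn,expected_f1",
        [(5, 0, 0, 1.0), (1, 1, 0, 2 / 3), (0, 0, 5, 0.0)],
    )
    def test_f1_conventions(self, tp, fp, fn, expected_f1):
        _, _, f1 = precision_recall_f1(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0))
        assert f1 == pytest.approx(expected_f1)


class TestSweepAgainstOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_f1max_matches_enumeration(self, seed):
        method, dataset = random_instance(seed)
        got = sweep_f1max(method, dataset)
        f1, tau_p, tau_s = brute_sweep_f1max(method, dataset)
        assert got.f1max == pytest.approx(f1)
        assert got.tau_p_opt == tau_p
        assert got.tau_s_opt == pytest.approx(tau_s)

    @pytest.mark.parametrize("seed", range(8))
    def test_delta_s_max_matches_enumeration(self, seed):
        method, dataset = random_instance(seed)
        assert delta_s_max(method, dataset) == pytest.approx(
            brute_delta_s_max(method, dataset)
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_recall_ppf50_matches_enumeration(self, seed):
        method, dataset = random_instance(seed)
        assert recall_max_ppf50(method, dataset) == pytest.approx(
            brute_recall_max_ppf50(method, dataset)
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_matches_enumeration(self, seed):
        method, dataset = random_instance(seed)
        scores = method.score(-np.inf, dataset.pairs)
        labels = dataset.labels()
        if len({labels[k] for k in scores}) < 2:
            pytest.skip("single-class draw")
        pr, roc = pr_roc_auc(scores, labels)
        assert roc == pytest.approx(brute_roc_auc(scores, labels))
        assert pr == pytest.approx(brute_pr_auc(scores, labels))

    @pytest.mark.parametrize("seed", range(4))
    def test_fused_pass_equals_standalone_ops(self, seed):
        method, dataset = random_instance(seed, n_proteins=7)
        row = evaluate_once(method, dataset)
        sweep = sweep_f1max(method, dataset)
        assert row["f1max"] == sweep.f1max
        assert row["tau_p_opt"] == sweep.tau_p_opt
        assert row["tau_s_opt"] == sweep.tau_s_opt
        assert row["delta_s_max"] == pytest.approx(delta_s_max(method, dataset))
        assert row["recall_max_ppf50"] == recall_max_ppf50(method, dataset)

    def test_f1max_dominates_every_grid_point(self):
        method, dataset = random_instance(99)
        got = sweep_f1max(method, dataset)
        labels = dataset.labels()
        for tau_p in method.tau_p_grid():
            scores = method.score(tau_p, dataset.pairs)
            for tau_s in set(scores.values()):
                _, _, f1 = precision_recall_f1(confusion_at(scores, labels, tau_s))
                assert f1 <= got.f1max + 1e-12

    def test_constant_similarity_gives_all_positive_f1(self, tiny_dataset):
        # one shared term everywhere -> S = 1 for every pair, only one tau_s
        rows = [(f"p{i}", "t0", 0.9) for i in range(5)]
        table = PredictionTable(data=pd.DataFrame(rows, columns=["protein", "term", "score"]))
        method = AnnotationMethod(table=table, kernel=jaccard)
        got = sweep_f1max(method, tiny_dataset)
        c = ConfusionCounts(tp=3, fp=7, fn=0, tn=0)
        _, _, expected = precision_recall_f1(c)
        assert got.f1max == pytest.approx(expected)

    def test_perfect_predictor_reaches_one(self, tiny_dataset):
        # distinct term per sibling-component vs the rest
        rows = []
        sib_proteins = {"p0", "p1", "p2"}
        for i in range(5):
            rows.append((f"p{i}", "sib" if f"p{i}" in sib_proteins else f"solo{i}", 0.9))
        table = PredictionTable(data=pd.DataFrame(rows, columns=["protein", "term", "score"]))
        method = AnnotationMethod(table=table, kernel=jaccard)
        assert sweep_f1max(method, tiny_dataset).f1max == 1.0


class TestDeltaS:
    def test_maximal_separation(self):
        scores = {("a", "b"): 1.0, ("c", "d"): 0.0}
        labels = {("a", "b"): SIBLING, ("c", "d"): "unlabeled"}
        assert delta_s(scores, labels, 1.0) == 1.0
        assert delta_s(scores, labels, 0.5) == 0.5

    def test_identical_distributions_zero(self):
        scores = {("a", "b"): 0.4, ("c", "d"): 0.4}
        labels = {("a", "b"): SIBLING, ("c", "d"): "unlabeled"}
        assert delta_s(scores, labels, 1.0) == 0.0

    def test_empty_class_is_error(self):
        with pytest.raises(EvaluationError):
            delta_s({("a", "b"): 1.0}, {("a", "b"): SIBLING}, 1.0)

    def test_bounded_on_random_configurations(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(2, 40)
            keys = [(f"x{i}", f"y{i}") for i in range(n)]
            labels = {k: SIBLING if rng.uniform() < 0.5 else "unlabeled" for k in keys}
            if len(set(labels.values())) < 2:
                continue
            scores = {k: float(rng.uniform()) for k in keys}
            value = delta_s(scores, labels, float(rng.uniform()))
            assert -1.0 <= value <= 1.0


class TestResampledProtocol:
    def make_perfect_method(self, dataset):
        rows = []
        groups = {"p0": "g0", "p1": "g0", "p2": "g0"}
        for i in range(5):
            pid = f"p{i}"
            rows.append((pid, groups.get(pid, f"solo{i}"), 0.9))
        table = PredictionTable(data=pd.DataFrame(rows, columns=["protein", "term", "score"]))
        return AnnotationMethod(table=table, kernel=jaccard, name="perfect")

    def test_perfect_predictor_mean_one_std_zero(self, tiny_dataset):
        method = self.make_perfect_method(tiny_dataset)
        report = run_resampled_evaluation(tiny_dataset, method, n_iter=10, seed=1)
        s = report.summary()
        assert s["f1max_mean"] == 1.0 and s["f1max_std"] == 0.0

    def test_report_carries_all_iterations(self, tiny_dataset):
        method = self.make_perfect_method(tiny_dataset)
        report = run_resampled_evaluation(tiny_dataset, method, n_iter=7, seed=1)
        assert len(report.per_iteration) == 7

    def test_same_seed_identical_report(self, tiny_dataset):
        method = self.make_perfect_method(tiny_dataset)
        a = run_resampled_evaluation(tiny_dataset, method, n_iter=5, seed=9)
        b = run_resampled_evaluation(tiny_dataset, method, n_iter=5, seed=9)
        pd.testing.assert_frame_equal(a.per_iteration, b.per_iteration)


class TestBinaryReference:
    def test_reference_equal_to_gate_labels(self, tiny_dataset):
        labels = {
            p.key: "same" if p.label == SIBLING else "different" for p in tiny_dataset.pairs
        }
        precision, recall = evaluate_binary_reference(labels, tiny_dataset, n_iter=5, seed=0)
        assert precision == 1.0 and recall == 1.0

    def test_all_same_forces_recall_one_precision_half(self, tiny_dataset):
        labels = {p.key: "same" for p in tiny_dataset.pairs}
        precision, recall = evaluate_binary_reference(labels, tiny_dataset, n_iter=5, seed=0)
        assert recall == 1.0
        assert precision == pytest.approx(0.5)  # balanced subsets

    def test_planted_confusion_rates(self, tiny_dataset):
        # mislabel exactly one sibling as 'different': recall 2/3, precision 1
        labels = {}
        flipped = False
        for p in tiny_dataset.pairs:
            if p.label == SIBLING and not flipped:
                labels[p.key] = "different"
                flipped = True
            else:
                labels[p.key] = "same" if p.label == SIBLING else "different"
        precision, recall = evaluate_binary_reference(labels, tiny_dataset, n_iter=5, seed=0)
        assert precision == 1.0
        assert recall == pytest.approx(2 / 3)


class TestCompareMethods:
    def _report(self, values, name):
        df = pd.DataFrame({m: values for m in ("delta_s", "f1max", "pr_auc", "roc_auc")})
        from funbench.evaluation import MetricReport

        return MetricReport(method=name, per_iteration=df, n_iter=len(values), seed=0)

    def test_identical_samples_p_one(self):
        a = self._report(list(np.linspace(0, 1, 20)), "a")
        b = self._report(list(np.linspace(0, 1, 20)), "b")
        df = compare_methods([a, b])
        assert (df["wilcoxon_p"] == 1.0).all()
        assert (df["t_p"] == 1.0).all()

    def test_disjoint_support_extreme_statistic(self):
        rng = np.random.default_rng(1)
        a = self._report(list(rng.uniform(0.8, 1.0, 100)), "hi")
        b = self._report(list(rng.uniform(0.0, 0.2, 100)), "lo")
        df = compare_methods([a, b])
        assert (df["wilcoxon_p"] < 1e-30).all()
        # rank-sum z-statistic at its extreme value for n=m=100
        expected_z = (100 * 100 / 2) / np.sqrt(100 * 100 * 201 / 12)
        assert df["wilcoxon_stat"].abs().iloc[0] == pytest.approx(expected_z)

    def test_mismatched_iterations_rejected(self):
        a = self._report([0.1, 0.2], "a")
        b = self._report([0.1, 0.2, 0.3], "b")
        with pytest.raises(EvaluationError):
            compare_methods([a, b])

    def test_bh_within_metric_family(self):
        rng = np.random.default_rng(2)
        reports = [self._report(list(rng.uniform(size=10)), f"m{i}") for i in range(3)]
        df = compare_methods(reports)
        for metric, sub in df.groupby("metric"):
            assert (sub["wilcoxon_p_bh"] >= sub["wilcoxon_p"] - 1e-15).all()
            assert (sub["wilcoxon_p_bh"] <= 1.0).all()
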