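import numpy as np
import pytest

from funbench.evaluation import AnnotationMethod, EvaluationError, evaluate_once
from funbench.pair_dataset import label_siblings
from funbench.predictions import threshold_annotations
from funbench.similarity import cosine_similarity, jaccard
from funbench.synthetic import (
    PredictorFidelity,
    WorldParams,
    generate_world,
    simulate_embeddings,
    simulate_predictor,
    write_world,
)

SMALL = WorldParams(n_proteins=60, n_clusters=10)


class TestGenerateWorld:
    def test_same_seed_identical_world(self):
        a = generate_world(SMALL, seed=5)
        b = generate_world(SMALL, seed=5)
        assert a.proteins.equals(b.proteins)
        assert a.pairs == b.pairs
        assert a.true_annotations == b.true_annotations

    def test_every_protein_in_one_cluster(self):
        w = generate_world(SMALL, seed=1)
        assert w.proteins["cluster"].between(0, SMALL.n_clusters - 1).all()
        assert len(w.proteins) == SMALL.n_proteins

    def test_full_separation_gate_recovers_planted_pairs(self):
        w = generate_world(WorldParams(n_proteins=60, n_clusters=10, separation="full"), seed=2)
        ds = label_siblings(w.pairs)
        assert {p.key for p in ds.siblings} == w.same_cluster

    def test_same_cluster_scores_dominate(self):
        w = generate_world(SMALL, seed=3)
        same_tm = [p.tm_score for p in w.pairs if p.key in w.same_cluster]
        diff_tm = [p.tm_score for p in w.pairs if p.key not in w.same_cluster]
        assert np.mean(same_tm) > np.mean(diff_tm) + 0.2

    def test_gate_rate_tracks_planted_fraction(self):
        # gate positives ~= planted same-function pairs x gate sensitivity
        w = generate_world(seed=4)
        ds = label_siblings(w.pairs)
        planted = len(w.same_cluster)
        recovered = sum(1 for p in ds.siblings if p.key in w.same_cluster)
        sensitivity = recovered / planted
        assert ds.n_siblings == pytest.approx(planted * sensitivity, rel=0.05)
        assert 0.5 < sensitivity < 0.95  # partial-overlap regime

    def test_infeasible_params_rejected(self):
        with pytest.raises(ValueError):
            WorldParams(n_proteins=10, n_clusters=10)
        with pytest.raises(ValueError):
            generate_world(WorldParams(n_proteins=300, n_clusters=100, ontology_branching=2), seed=0)


class TestSimulatePredictor:
    def test_perfect_predictor_scores_one(self):
        # gate-consistent (fully separated) world: siblings == planted truth,
        # so an error-free predictor separates the classes perfectly
        w = generate_world(
            WorldParams(n_proteins=60, n_clusters=10, separation="full"), seed=1
        )
        table = simulate_predictor(w, PredictorFidelity(), seed=0)
        sets = threshold_annotations(table, -np.inf)
        for protein, truth in w.true_annotations.items():
            assert sets[protein] == truth
        ds = label_siblings(w.pairs)
        method = AnnotationMethod(table=table, kernel=jaccard)
        assert evaluate_once(method, ds)["f1max"] == 1.0

    def test_total_dropout_means_no_annotatable_pairs(self):
        w = generate_world(SMALL, seed=1)
        table = simulate_predictor(w, PredictorFidelity(dropout=1.0), seed=0)
        ds = label_siblings(w.pairs)
        method = AnnotationMethod(table=table, kernel=jaccard)
        with pytest.raises(EvaluationError, match="no annotatable pair"):
            evaluate_once(method, ds)

    def test_coverage_removes_proteins(self):
        w = generate_world(SMALL, seed=1)
        table = simulate_predictor(w, PredictorFidelity(coverage=0.5), seed=0)
        assert 10 < len(table.proteins) < 50

    def test_deterministic(self):
        w = generate_world(SMALL, seed=1)
        a = simulate_predictor(w, PredictorFidelity(dropout=0.3, noise=0.1), seed=9)
        b = simulate_predictor(w, PredictorFidelity(dropout=0.3, noise=0.1), seed=9)
        assert a.data.equals(b.data)


class TestSimulateEmbeddings:
    def test_deterministic(self):
        w = generate_world(SMALL, seed=1)
        a = simulate_embeddings(w, seed=2)
        b = simulate_embeddings(w, seed=2)
        assert all(np.array_equal(a[p], b[p]) for p in w.protein_ids)

    def test_tight_clusters_cosine_near_one(self):
        w = generate_world(SMALL, seed=1)
        emb = simulate_embeddings(w, within_cluster_sd=1e-6, between_cluster_sd=2.0, seed=3)
        for key in list(w.same_cluster)[:20]:
            assert cosine_similarity(emb[key[0]], emb[key[1]]) == pytest.approx(1.0, abs=1e-6)

    def test_separated_clusters_beat_chance(self):
        from funbench.evaluation import pr_roc_auc

        w = generate_world(WorldParams(n_proteins=60, n_clusters=10, separation="full"), seed=4)
        ds = label_siblings(w.pairs)
        emb = simulate_embeddings(w, within_cluster_sd=0.2, between_cluster_sd=2.0, seed=5)
        scores = {p.key: cosine_similarity(emb[p.id1], emb[p.id2]) for p in ds.pairs}
        _, roc = pr_roc_auc(scores, ds.labels())
        assert roc > 0.9


class TestWriteWorld:
    def test_files_written_and_readable(self, tmp_path):
        from funbench.io import read_pairs, read_proteins
        from funbench.ontology import parse_obo

        w = generate_world(SMALL, seed=1)
        paths = write_world(w, tmp_path / "world")
        pairs = read_pairs(paths["pairs"])
        assert len(pairs) == len(w.pairs)
        proteins = read_proteins(paths["proteins"])
        assert len(proteins) == SMALL.n_proteins
        dag = parse_obo(paths["ontology"])
        assert dag.terms == w.dag.terms
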