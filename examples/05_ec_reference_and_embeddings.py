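"""Two further evaluation modes: binary EC reference labels and embeddings.

First, an 'ideal predictor' check: pairs are called same-function when
their EC numbers agree at the third level, with no threshold sweep — the
protocol used to put an upper bound on achievable performance.  Second,
embedding-based similarity: cosine and Euclidean kernels on simulated
per-protein vectors, evaluated like any other method.
"""

import funbench as fb
from funbench.evaluation import EmbeddingMethod

world = fb.generate_world(fb.WorldParams(n_proteins=120, n_clusters=15), seed=9)
dataset = fb.label_siblings(world.pairs)

# EC-style reference: each cluster gets its own EC-third-level code
ec_of_cluster = {c: f"1.{1 + c // 8}.{1 + c % 8}.1" for c in range(world.params.n_clusters)}
annotations = {
    row.protein: {ec_of_cluster[int(row.cluster)]} for row in world.proteins.itertuples()
}
labels = fb.binary_ec_labels(annotations, dataset.pairs, level=3)
precision, recall = fb.evaluate_binary_reference(labels, dataset, n_iter=20, seed=0)
print(f"EC3 reference labels: precision = {precision:.3f}, recall = {recall:.3f}")
print("(bounded below 1.0 exactly when the gate and the EC grouping disagree)\n")

# embedding kernels
embeddings = fb.simulate_embeddings(world, dim=16, within_cluster_sd=0.3,
                                    between_cluster_sd=1.5, seed=1)
for kernel in (fb.cosine_similarity, fb.euclidean_similarity):
    method = EmbeddingMethod(embeddings=embeddings, kernel=kernel, name=kernel.__name__)
    report = fb.run_resampled_evaluation(dataset, method, n_iter=10, seed=0)
    s = report.summary()
    print(f"{kernel.__name__:<22} F1max = {s['f1max_mean']:.3f}  "
          f"ROC AUC = {s['roc_auc_mean']:.3f}  Delta-S = {s['delta_s_mean']:.3f}")
print("\nWell-separated simulated embeddings recover the planted structure; "
      "shrinking the between-cluster scale degrades both kernels toward chance.")
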