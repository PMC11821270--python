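"""funbench: ontology-blind benchmarking of protein function annotation.

Function prediction methods emit per-protein term sets drawn from different
vocabularies (GO, EC, Pfam, ortholog groups), which makes direct comparison
across tools awkward.  This package implements a pair-based alternative:
protein pairs confidently labelled as functionally similar *siblings* (via a
structural TM-score gate and a functional SNN-score gate) form the positive
class of a positive-unlabeled test set, each method's per-protein predictions
are turned into a pairwise similarity score, and methods are ranked by how
well that score separates siblings from the rest — F1max over joint
prediction/similarity thresholds, PR/ROC AUC, the recall-weighted score
separation Delta-S, and recall under an overprediction cap, all under
balanced under-sampling with empirical random baselines.
"""

__version__ = "0.1.0"

from .baselines import BaselineSpec, baseline_report, random_annotator_labels, random_classifier_scores
from .enrichment import BinScheme, bh_adjust, bin_pairs, enrichment_table, fisher_enrichment
from .evaluation import (
    AnnotationMethod,
    ConfusionCounts,
    EmbeddingMethod,
    MetricReport,
    compare_methods,
    confusion_at,
    delta_s,
    delta_s_max,
    evaluate_binary_reference,
    pr_roc_auc,
    precision_recall_f1,
    recall_max_ppf50,
    run_resampled_evaluation,
    score_pairs,
    sweep_f1max,
)
from .ontology import (
    ECNumber,
    OntologyDAG,
    compute_information_accretion,
    parse_obo,
    propagate,
    truncate_ec,
)
from .pair_dataset import (
    PairDataset,
    PairRecord,
    ProteinRecord,
    binary_ec_labels,
    filter_orphans,
    label_siblings,
    undersample_balanced,
)
from .predictions import (
    AnnotationSets,
    EmbeddingTable,
    PredictionTable,
    annotatable_pairs,
    load_predictions,
    threshold_annotations,
)
from .similarity import (
    binary_shared,
    cosine_similarity,
    euclidean_similarity,
    ia_weighted_jaccard,
    jaccard,
)
from .synthetic import (
    PredictorFidelity,
    SyntheticWorld,
    WorldParams,
    generate_world,
    simulate_embeddings,
    simulate_predictor,
    write_world,
)
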