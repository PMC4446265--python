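"""Standard synthetic benchmarks exercising the full method end to end.

These protocols fix the study conditions used throughout the test suite
and the reproduction script: 150-bp windows over order-1 background with
two strong 8-bp core motifs (an AP-1-like TGACTCAT and an E-box-like
CACGTGAC, 0.95 major-base probability per position, about 1.7
bits/position) planted in disjoint 60%/40% subsets of the positives.
Each benchmark is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from kmerlasso.evaluation import auroc
from kmerlasso.feature_grouping import GroupAssignment, cluster_features
from kmerlasso.group_analysis import call_significant, locate_hits
from kmerlasso.kmer_features import (
    FeatureMatrix,
    canonical,
    count_features,
    enumerate_features,
    select_features,
)
from kmerlasso.sequence_io import LabeledSequence
from kmerlasso.sgl_model import (
    MultitaskFit,
    SGLFit,
    cross_validate,
    fit,
    fit_multitask,
    lambda_max,
)
from kmerlasso.synthetic import PlantSpec, SyntheticTruth, generate, ppm_from_consensus

logger = logging.getLogger(__name__)

MOTIF_A = "TGACTCAT"  # AP-1-like core
MOTIF_B = "CACGTGAC"  # E-box-like core
PWM_SHARPNESS = 0.95
# lambda grids as fractions of the data-derived maxima
L1_FRACTIONS = (0.6, 0.3, 0.1, 0.03)
L2_FRACTIONS = (0.003, 0.0003)


def _split_even(seqs: list[LabeledSequence], seed: int
                ) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
    """Seeded even split into train/test halves, stratified by label."""
    rng = np.random.default_rng(seed + 10000)
    pos = [s for s in seqs if s.label > 0]
    neg = [s for s in seqs if s.label < 0]
    train: list[LabeledSequence] = []
    test: list[LabeledSequence] = []
    for group in (pos, neg):
        perm = rng.permutation(len(group))
        half = len(group) // 2
        train.extend(group[i] for i in perm[:half])
        test.extend(group[i] for i in perm[half:])
    return train, test


def _train_model(train: list[LabeledSequence], n_top: int, G: int, folds: int,
                 seed: int, cv_max_iter: int = 400,
                 final_max_iter: int = 3000) -> tuple[SGLFit, FeatureMatrix, GroupAssignment]:
    space = enumerate_features(8, 2)
    _, M = select_features(count_features(train, space), n_top=n_top)
    A = cluster_features(M, G=min(G, M.n_features))
    l1m, l2m = lambda_max(M, A)
    l1, l2, _ = cross_validate(
        M, A, l1m * np.asarray(L1_FRACTIONS), l2m * np.asarray(L2_FRACTIONS),
        folds=folds, seed=seed, max_iter=cv_max_iter)
    model = fit(M, A, l1, l2, max_iter=final_max_iter)
    return model, M, A


@dataclass
class RecoveryResult:
    seed: int
    test_auroc: float
    recovered: dict[str, bool]
    distinct_groups: bool
    consensus_rank: dict[str, int | None]
    model: SGLFit = field(repr=False, default=None)
    train_matrix: FeatureMatrix = field(repr=False, default=None)
    test_matrix: FeatureMatrix = field(repr=False, default=None)
    test_seqs: list = field(repr=False, default=None)
    truth: SyntheticTruth = field(repr=False, default=None)
    motif_group: dict[str, int | None] = field(default_factory=dict)


def recovery_benchmark(seed: int, n_pos: int = 500, n_neg: int = 500,
                       n_top: int = 2000, G: int = 10, folds: int = 5,
                       top_rank: int = 100) -> RecoveryResult:
    """Plant two motifs in 60%/40% of positives; train; check recovery.

    A motif counts as recovered when its consensus canonical 8-mer
    carries positive weight inside a positive-associated group and ranks
    within the top ``top_rank`` absolute weights of that group; the two
    motifs must additionally land in distinct groups.
    """
    plants = [PlantSpec("A", ppm_from_consensus(MOTIF_A, PWM_SHARPNESS), fraction=0.6),
              PlantSpec("B", ppm_from_consensus(MOTIF_B, PWM_SHARPNESS), fraction=0.4)]
    seqs, truth = generate(n_pos, n_neg, width=150, plants=plants,
                           seed=seed, exclusive=True)
    train, test = _split_even(seqs, seed)
    model, M, A = _train_model(train, n_top, G, folds, seed)
    Mte = count_features(test, M.space)
    test_auroc = auroc(model.decision_values(Mte), Mte.labels)
    recovered: dict[str, bool] = {}
    ranks: dict[str, int | None] = {}
    groups: dict[str, int | None] = {}
    from kmerlasso.group_analysis import class_scores

    for name, cons in (("A", MOTIF_A), ("B", MOTIF_B)):
        can = canonical(cons)
        if can not in M.space:
            recovered[name], ranks[name], groups[name] = False, None, None
            continue
        i = M.space.index_of(can)
        g = int(A.group_of[i])
        groups[name] = g
        idx = A.members(g)
        rank = int(np.sum(np.abs(model.w[idx]) > abs(model.w[i])))
        ranks[name] = rank
        _, _, cls = class_scores(model, M, g)
        recovered[name] = bool(model.w[i] > 0.0 and cls == 1 and rank < top_rank)
    distinct = (groups["A"] is not None and groups["B"] is not None
                and groups["A"] != groups["B"])
    return RecoveryResult(seed=seed, test_auroc=float(test_auroc),
                          recovered=recovered, distinct_groups=distinct,
                          consensus_rank=ranks, model=model, train_matrix=M,
                          test_matrix=Mte, test_seqs=test, truth=truth,
                          motif_group=groups)


def hit_localization(result: RecoveryResult, fdr: float = 0.05,
                     min_examples: int = 25, tol_bp: int = 10) -> tuple[int, int]:
    """Fraction of significant hit centers near a planted instance center.

    Returns (n_within, n_hits) over all motif-eligible positive groups
    of the recovery model, with significance called on the held-out
    half (as in the null benchmark, so eligibility reflects signal, not
    training-half overfitting); a hit is "near" when its matched k-mer
    center lies within ``tol_bp`` of any planted instance center in
    that sequence.
    """
    model, M = result.model, result.test_matrix
    seq_by_id = {s.id: s for s in result.test_seqs}
    k = 8
    n_within = n_hits = 0
    for g in range(1, model.assignment.G + 1):
        rep = call_significant(model, M, g, fdr=fdr, min_examples=min_examples)
        if rep.class_label != 1 or not rep.eligible_for_motif:
            continue
        hits = locate_hits(model, M, g, seq_by_id, rep)
        for h in hits:
            instances = result.truth.plants.get(h.example_id, [])
            if not instances:
                continue
            hit_center = h.position + k // 2
            near = any(abs(hit_center - (start + k // 2)) <= tol_bp
                       for _, start, _ in instances)
            n_hits += 1
            n_within += int(near)
    return n_within, n_hits


@dataclass
class NullResult:
    seed: int
    significant_fraction: float
    max_n_significant: int
    any_eligible: bool


def null_benchmark(seed: int, n_pos: int = 500, n_neg: int = 500,
                   n_top: int = 2000, G: int = 10, folds: int = 5,
                   fdr: float = 0.05, min_examples: int = 25) -> NullResult:
    """No planted signal: classes exchangeable, calls should be rare.

    The model is trained on one half and the significance calls are
    evaluated on the held-out half, where the empirical-null p-values
    are exchangeable by construction (calling on the training half
    measures overfitting, not calibration). Reports the worst per-group
    fraction of class examples called significant at the nominal FDR
    and whether any group reached the motif-eligibility threshold.
    """
    seqs, _ = generate(n_pos, n_neg, width=150, plants=[], seed=seed)
    train, test = _split_even(seqs, seed)
    model, Mtr, A = _train_model(train, n_top, G, folds, seed)
    M = count_features(test, Mtr.space)
    worst_frac = 0.0
    worst_n = 0
    any_elig = False
    for g in range(1, A.G + 1):
        rep = call_significant(model, M, g, fdr=fdr, min_examples=min_examples)
        if rep.class_label is None:
            continue
        n_class = len(rep.class_example_idx)
        worst_frac = max(worst_frac, rep.n_significant / max(n_class, 1))
        worst_n = max(worst_n, rep.n_significant)
        any_elig = any_elig or rep.eligible_for_motif
    return NullResult(seed=seed, significant_fraction=worst_frac,
                      max_n_significant=worst_n, any_eligible=any_elig)


# ---------------------------------------------------------------------------
# multitask benchmark

def build_multitask_inputs(task_seqs: dict[str, list[LabeledSequence]],
                           n_top: int = 1000, G: int = 5
                           ) -> tuple[FeatureMatrix, dict[str, GroupAssignment],
                                      GroupAssignment]:
    """Union feature space + per-task and common group assignments.

    Features are selected per task, their union forms the shared space,
    all examples are recounted over it; the common assignment clusters
    the union on all examples pooled, each task's assignment clusters it
    on that task's examples only.
    """
    space = enumerate_features(8, 2)
    union: dict[str, None] = {}
    for t, seqs in task_seqs.items():
        sub, _ = select_features(count_features(seqs, space), n_top=n_top)
        for p in sub.pattern_strings:
            union.setdefault(p, None)
    union_idx = [space.index_of(p) for p in union]
    union_space = space.subset(union_idx)
    all_seqs = [s for seqs in task_seqs.values() for s in seqs]
    M = count_features(all_seqs, union_space)
    if M.tasks is None:
        raise ValueError("sequences must carry task ids")
    common = cluster_features(M, G=min(G, M.n_features))
    per_task: dict[str, GroupAssignment] = {}
    tasks = np.asarray(M.tasks)
    for t in task_seqs:
        Mt = M.subset_examples(np.nonzero(tasks == t)[0])
        per_task[t] = cluster_features(Mt, G=min(G, Mt.n_features))
    return M, per_task, common


def _multitask_fixture(seed: int, n_per_class: int
                       ) -> dict[str, list[LabeledSequence]]:
    """Two tasks: motif A discriminative in both; motif B discriminative
    only in task 1, while occurring label-balanced in task 2's sequences
    (a motif present genome-wide but unused in that context)."""
    ppm_a = ppm_from_consensus(MOTIF_A, PWM_SHARPNESS)
    ppm_b = ppm_from_consensus(MOTIF_B, PWM_SHARPNESS)
    # disjoint planting within task 1 so the two signals form separate
    # co-occurrence clusters
    seqs1, _ = generate(
        n_per_class, n_per_class, width=150,
        plants=[PlantSpec("A", ppm_a, fraction=0.5),
                PlantSpec("B", ppm_b, fraction=0.5)],
        seed=seed, task="T1", id_prefix="t1_", exclusive=True)
    seqs2, _ = generate(
        n_per_class, n_per_class, width=150,
        plants=[PlantSpec("A", ppm_a, fraction=0.8),
                PlantSpec("B", ppm_b, fraction=0.5)],
        neg_plants=[PlantSpec("B", ppm_b, fraction=0.5)],
        seed=seed + 5000, task="T2", id_prefix="t2_")
    return {"T1": seqs1, "T2": seqs2}


@dataclass
class MultitaskResult:
    seed: int
    shared_in_common: bool
    taskonly_in_task1: bool
    common_weight: float
    task1_weight: float
    fit: MultitaskFit = field(repr=False, default=None)
    matrix: FeatureMatrix = field(repr=False, default=None)


def multitask_benchmark(seed: int, n_per_class: int = 250,
                        lambda1_frac: float = 0.02, lambda2_frac: float = 0.001,
                        alpha: float = 1.5, beta: float = 1.0,
                        n_top: int = 1000, G: int = 10) -> MultitaskResult:
    """Two tasks sharing one motif, task 1 carrying a private second motif.

    The shared motif should surface in the common block w_c and the
    task-1-only motif in that task's block w_t1.
    """
    M, per_task, common = build_multitask_inputs(
        _multitask_fixture(seed, n_per_class), n_top=n_top, G=G)
    l1m, l2m = lambda_max(M, common)
    mt = fit_multitask(M, per_task, common,
                       lambda1=l1m * lambda1_frac, lambda2=l2m * lambda2_frac,
                       alpha=alpha, beta=beta, max_iter=3000)
    canA, canB = canonical(MOTIF_A), canonical(MOTIF_B)
    space = M.space
    wA_c = float(mt.w_common[space.index_of(canA)]) if canA in space else 0.0
    wB_t1 = float(mt.w_task["T1"][space.index_of(canB)]) if canB in space else 0.0
    return MultitaskResult(seed=seed, shared_in_common=wA_c > 0.0,
                           taskonly_in_task1=wB_t1 > 0.0,
                           common_weight=wA_c, task1_weight=wB_t1,
                           fit=mt, matrix=M)


def multitask_decoupling_gap(seed: int, beta_large: float = 1e4,
                             alpha: float = 1.5,
                             lambda1_frac: float = 0.02,
                             lambda2_frac: float = 0.001,
                             n_per_class: int = 150, n_top: int = 500,
                             G: int = 5) -> float:
    """Relative objective gap between the large-beta multitask fit and
    two independent per-task fits with alpha-scaled penalties.

    As beta grows the common block is forced to zero and the stacked
    problem separates; the gap should vanish.
    """
    M, per_task, common = build_multitask_inputs(
        _multitask_fixture(seed, n_per_class), n_top=n_top, G=G)
    l1m, l2m = lambda_max(M, common)
    lam1, lam2 = l1m * lambda1_frac, l2m * lambda2_frac
    mt = fit_multitask(M, per_task, common, lambda1=lam1, lambda2=lam2,
                       alpha=alpha, beta=beta_large, max_iter=5000, tol=1e-9)
    tasks = np.asarray(M.tasks)
    total_indep = 0.0
    for t in ("T1", "T2"):
        Mt = M.subset_examples(np.nonzero(tasks == t)[0])
        r = fit(Mt, per_task[t], lam1 * alpha, lam2 * alpha,
                max_iter=5000, tol=1e-9)
        total_indep += float(r.objective_trace[-1])
    return abs(mt.objective_value - total_indep) / abs(total_indep)
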