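"""Sparse group lasso logistic regression by accelerated proximal gradient.

The single-task objective over weights w with feature groups g is

    sum_i log(1 + exp(-y_i w.x_i)) + lambda1 sum_g l_g^gamma ||w_g||_2
                                   + lambda2 sum_m |w_m|

where l_g is the number of features in group g and gamma is the group
weight exponent (default 0.5, the conventional sqrt(l_g) weighting;
gamma=1 penalizes proportionally to group size, which zeroes the
largest groups first -- see docs/methods.md). The group term zeroes
whole groups exactly; the l1 term sparsifies within surviving groups.
There is no intercept by default; an unpenalized intercept can be
enabled.

The solver is FISTA with backtracking line search and a monotone
restart: whenever the accelerated candidate would increase the
objective, momentum is reset and a plain proximal step from the current
iterate is taken instead, so the recorded objective trace is
non-increasing. Zero groups are exactly zero (a property of the prox),
never epsilon-thresholded.

Multitask training stacks a common weight block w_c with per-task blocks
w_t; an example of task t is scored by (w_c + w_t).x and the penalties
of the task blocks and the common block are scaled by alpha and beta
respectively, which trades off context-specific against shared signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold

from kmerlasso.feature_grouping import GroupAssignment
from kmerlasso.kmer_features import FeatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# penalty bookkeeping

def _group_weights(A: GroupAssignment, exponent: float = 1.0,
                   mult: np.ndarray | None = None) -> np.ndarray:
    """Per-group penalty weight: mult_g * l_g**exponent, for g = 1..G."""
    lg = A.sizes[1:].astype(np.float64)
    w = lg ** exponent
    if mult is not None:
        w = w * np.asarray(mult, dtype=np.float64)
    return w


def _penalty(w: np.ndarray, A: GroupAssignment, lam1: float, lam2: float,
             gw: np.ndarray, l1w: np.ndarray) -> float:
    gid = A.group_of - 1
    norms = np.sqrt(np.bincount(gid, weights=w ** 2, minlength=A.G))
    return float(lam1 * (gw * norms).sum() + lam2 * (l1w * np.abs(w)).sum())


def _logistic_loss(z: np.ndarray, y: np.ndarray) -> float:
    return float(np.logaddexp(0.0, -y * z).sum())


def _logistic_grad_margin(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d loss / d z_i = -y_i * sigmoid(-y_i z_i), computed stably."""
    m = y * z
    return -y / (1.0 + np.exp(m))


def objective(w: np.ndarray, M: FeatureMatrix, A: GroupAssignment,
              lambda1: float, lambda2: float,
              group_weight_exponent: float = 0.5,
              intercept: float = 0.0) -> float:
    """Penalized logistic objective at w."""
    w = np.asarray(w, dtype=np.float64)
    if not np.isfinite(w).all():
        raise ValueError("weights must be finite")
    z = M.counts @ w + intercept
    gw = _group_weights(A, group_weight_exponent)
    l1w = np.ones(len(w))
    return _logistic_loss(z, M.labels.astype(np.float64)) + _penalty(
        w, A, lambda1, lambda2, gw, l1w)


def prox_sgl(v: np.ndarray, A: GroupAssignment, tlam1: float, tlam2: float,
             group_weight_exponent: float = 0.5,
             group_mult: np.ndarray | None = None,
             l1_mult: np.ndarray | None = None) -> np.ndarray:
    """Proximal operator of t*(lambda1 group term + lambda2 l1 term).

    Componentwise soft threshold at t*lambda2, then groupwise shrinkage
    u_g -> max(0, 1 - t*lambda1*l_g/||u_g||) u_g. Groups whose
    soft-thresholded norm falls below the group threshold come out
    exactly zero.
    """
    v = np.asarray(v, dtype=np.float64)
    if len(v) != A.n_features:
        raise ValueError("dimension mismatch between v and group assignment")
    l1w = np.ones(len(v)) if l1_mult is None else np.asarray(l1_mult, dtype=np.float64)
    u = np.sign(v) * np.maximum(np.abs(v) - tlam2 * l1w, 0.0)
    gw = _group_weights(A, group_weight_exponent, group_mult)
    gid = A.group_of - 1
    norms = np.sqrt(np.bincount(gid, weights=u ** 2, minlength=A.G))
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > 0.0, np.maximum(0.0, 1.0 - tlam1 * gw / norms), 0.0)
    return u * scale[gid]


def lambda_max(M: FeatureMatrix, A: GroupAssignment,
               group_weight_exponent: float = 0.5) -> tuple[float, float]:
    """Data-derived penalty bounds (lambda1_max, lambda2_max).

    Either lambda2 >= lambda2_max alone, or lambda1 >= lambda1_max with
    lambda2 = 0, makes w = 0 the exact optimum from a cold start.
    """
    y = M.labels.astype(np.float64)
    g = np.asarray(-0.5 * (M.counts.T @ y)).ravel()  # gradient of the loss at w=0
    lam2 = float(np.abs(g).max())
    gw = _group_weights(A, group_weight_exponent)
    gid = A.group_of - 1
    gnorm = np.sqrt(np.bincount(gid, weights=g ** 2, minlength=A.G))
    lam1 = float((gnorm / gw).max())
    return lam1, lam2


# ---------------------------------------------------------------------------
# fits

@dataclass
class SGLFit:
    """A trained sparse group lasso logistic model."""

    w: np.ndarray
    lambda1: float
    lambda2: float
    assignment: GroupAssignment
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    intercept: float = 0.0
    group_weight_exponent: float = 0.5
    feature_names: list[str] | None = None
    cv_table: pd.DataFrame | None = None

    def decision_values(self, M: FeatureMatrix) -> np.ndarray:
        return np.asarray(M.counts @ self.w).ravel() + self.intercept

    def group_weights_of(self, g: int) -> np.ndarray:
        return self.w[self.assignment.members(g)]

    @property
    def nonzero_groups(self) -> list[int]:
        return [g for g in range(1, self.assignment.G + 1)
                if np.any(self.w[self.assignment.members(g)] != 0.0)]


def _estimate_lipschitz(X: sp.spmatrix, n_iter: int = 60, seed: int = 0) -> float:
    """0.25 * sigma_max(X)^2 upper-bounds the logistic Hessian."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(X.shape[1])
    v /= np.linalg.norm(v)
    s = 1.0
    for _ in range(n_iter):
        u = X.T @ (X @ v)
        s = np.linalg.norm(u)
        if s == 0.0:
            return 0.25
        v = u / s
    return 0.25 * float(s)


def _fit_core(X: sp.spmatrix, y: np.ndarray, A: GroupAssignment,
              lam1: float, lam2: float,
              gw_mult: np.ndarray | None, l1_mult: np.ndarray | None,
              exponent: float, fit_intercept: bool,
              tol: float, max_iter: int,
              w0: np.ndarray | None) -> tuple[np.ndarray, float, list[float], bool, int]:
    n, p = X.shape
    y = y.astype(np.float64)
    l1w = np.ones(p) if l1_mult is None else l1_mult
    gw = _group_weights(A, exponent, gw_mult)

    def F(w: np.ndarray, b: float) -> float:
        return _logistic_loss(X @ w + b, y) + _penalty(w, A, lam1, lam2, gw, l1w)

    def grad(w: np.ndarray, b: float) -> tuple[np.ndarray, float]:
        r = _logistic_grad_margin(X @ w + b, y)
        return np.asarray(X.T @ r).ravel(), float(r.sum())

    def prox(v: np.ndarray, t: float) -> np.ndarray:
        return prox_sgl(v, A, t * lam1, t * lam2, exponent, gw_mult, l1w)

    L = max(_estimate_lipschitz(X), 1e-12)
    if fit_intercept:
        L += 0.25 * n
    t = 1.0 / L
    w = np.zeros(p) if w0 is None else w0.astype(np.float64).copy()
    b = 0.0
    vw, vb = w.copy(), b
    theta = 1.0
    trace = [F(w, b)]
    converged = False
    flat = 0
    it = 0
    for it in range(1, max_iter + 1):
        gv, gb = grad(vw, vb)
        fv = _logistic_loss(X @ vw + vb, y)
        # backtracking on the smooth part
        while True:
            wp = prox(vw - t * gv, t)
            bp = vb - t * gb if fit_intercept else 0.0
            dw, db = wp - vw, bp - vb
            quad = fv + gv @ dw + gb * db + (dw @ dw + db * db) / (2.0 * t)
            if _logistic_loss(X @ wp + bp, y) <= quad + 1e-12 * abs(quad):
                break
            t *= 0.5
            if t < 1e-18:
                break
        Fp = F(wp, bp)
        if Fp > trace[-1]:
            # monotone restart: plain proximal step from the best iterate
            theta = 1.0
            gv, gb = grad(w, b)
            fv = _logistic_loss(X @ w + b, y)
            while True:
                wp = prox(w - t * gv, t)
                bp = b - t * gb if fit_intercept else 0.0
                dw, db = wp - w, bp - b
                quad = fv + gv @ dw + gb * db + (dw @ dw + db * db) / (2.0 * t)
                if _logistic_loss(X @ wp + bp, y) <= quad + 1e-12 * abs(quad):
                    break
                t *= 0.5
                if t < 1e-18:
                    break
            Fp = F(wp, bp)
            if Fp > trace[-1]:
                # cannot descend further at machine precision
                converged = True
                break
        theta_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * theta ** 2))
        mom = (theta - 1.0) / theta_new
        vw = wp + mom * (wp - w)
        vb = bp + mom * (bp - b)
        theta = theta_new
        w, b = wp, bp
        trace.append(Fp)
        denom = max(abs(trace[-2]), 1.0)
        if abs(trace[-2] - trace[-1]) / denom < tol:
            flat += 1
            if flat >= 3:  # guard against transient FISTA plateaus
                converged = True
                break
        else:
            flat = 0
    if not converged:
        logger.warning("solver did not converge in %d iterations", max_iter)
    return w, b, trace, converged, it


def fit(M: FeatureMatrix, A: GroupAssignment, lambda1: float, lambda2: float,
        tol: float = 1e-7, max_iter: int = 2000,
        group_weight_exponent: float = 0.5, fit_intercept: bool = False,
        w0: np.ndarray | None = None) -> SGLFit:
    """Fit the sparse group lasso logistic regression.

    Deterministic from the cold start w = 0; ``w0`` enables warm starts
    along a regularization path. Non-convergence within ``max_iter``
    returns a flagged result rather than raising.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be nonnegative")
    labels = set(np.unique(M.labels))
    if not labels <= {-1, 1} or len(labels) < 2:
        raise ValueError("training data must contain both classes labeled +1/-1")
    w, b, trace, converged, it = _fit_core(
        sp.csr_matrix(M.counts), M.labels, A, lambda1, lambda2,
        None, None, group_weight_exponent, fit_intercept, tol, max_iter, w0)
    return SGLFit(w=w, lambda1=lambda1, lambda2=lambda2, assignment=A,
                  objective_trace=np.asarray(trace), converged=converged,
                  n_iter=it, intercept=b,
                  group_weight_exponent=group_weight_exponent,
                  feature_names=M.space.pattern_strings)


def kkt_residual(fit_result: SGLFit, M: FeatureMatrix) -> float:
    """Max violation of the subgradient optimality conditions.

    On features in nonzero groups: |grad_m + lam1 l_g w_m/||w_g|| + lam2 s_m|
    with s_m = sign(w_m) where w_m != 0, else the slack after removing the
    l1 interval. Zero groups require ||soft(grad_g, lam2)|| <= lam1 l_g.
    """
    A = fit_result.assignment
    w = fit_result.w
    y = M.labels.astype(np.float64)
    r = _logistic_grad_margin(M.counts @ w + fit_result.intercept, y)
    g = np.asarray(M.counts.T @ r).ravel()
    gw = _group_weights(A, fit_result.group_weight_exponent)
    lam1, lam2 = fit_result.lambda1, fit_result.lambda2
    res = 0.0
    for gi in range(1, A.G + 1):
        idx = A.members(gi)
        wg, gg = w[idx], g[idx]
        norm = np.linalg.norm(wg)
        if norm == 0.0:
            sg = np.sign(gg) * np.maximum(np.abs(gg) - lam2, 0.0)
            res = max(res, max(0.0, float(np.linalg.norm(sg)) - lam1 * gw[gi - 1]))
            continue
        grp = lam1 * gw[gi - 1] * wg / norm
        for m in range(len(idx)):
            if wg[m] != 0.0:
                res = max(res, abs(gg[m] + grp[m] + lam2 * np.sign(wg[m])))
            else:
                res = max(res, max(0.0, abs(gg[m] + grp[m]) - lam2))
    return res


def default_lambda_grids(M: FeatureMatrix, A: GroupAssignment,
                         n_points: int = 8, decades: float = 3.0,
                         group_weight_exponent: float = 0.5
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced grids descending from the data-derived maxima."""
    l1m, l2m = lambda_max(M, A, group_weight_exponent)
    g1 = l1m * np.logspace(0.0, -decades, n_points)
    g2 = l2m * np.logspace(0.0, -decades, n_points)
    return g1, g2


def cross_validate(M: FeatureMatrix, A: GroupAssignment,
                   lambda1_grid=None, lambda2_grid=None,
                   folds: int = 10, seed: int = 0,
                   tol: float = 1e-6, max_iter: int = 500,
                   group_weight_exponent: float = 0.5,
                   rule: str = "1se") -> tuple[float, float, pd.DataFrame]:
    """Choose (lambda1, lambda2) by stratified K-fold held-out auROC.

    With ``rule="1se"`` (default) the largest penalties whose mean
    held-out auROC is within one standard error of the best are chosen,
    the usual guard against selecting noise-level improvements; with
    ``rule="best"`` the maximum mean wins. Either way exact ties break
    toward larger penalties (more regularization). Returns the chosen
    pair and the full CV table.
    """
    if rule not in ("1se", "best"):
        raise ValueError(f"unknown selection rule {rule!r}")
    from kmerlasso.evaluation import auroc

    if folds < 2:
        raise ValueError("folds must be >= 2")
    if lambda1_grid is None or lambda2_grid is None:
        g1, g2 = default_lambda_grids(M, A, group_weight_exponent=group_weight_exponent)
        lambda1_grid = g1 if lambda1_grid is None else lambda1_grid
        lambda2_grid = g2 if lambda2_grid is None else lambda2_grid
    lambda1_grid = np.sort(np.asarray(lambda1_grid, dtype=float))[::-1]
    lambda2_grid = np.sort(np.asarray(lambda2_grid, dtype=float))[::-1]
    if lambda1_grid.size == 0 or lambda2_grid.size == 0:
        raise ValueError("lambda grids must be nonempty")
    y01 = (M.labels > 0).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros((len(lambda1_grid), len(lambda2_grid), folds))
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(y01)), y01)):
        if len(np.unique(M.labels[tr])) < 2 or len(np.unique(M.labels[te])) < 2:
            raise ValueError("a fold is missing a class; use fewer folds")
        Mtr, Mte = M.subset_examples(tr), M.subset_examples(te)
        for i2, l2 in enumerate(lambda2_grid):
            w_warm = None
            for i1, l1 in enumerate(lambda1_grid):
                res = fit(Mtr, A, l1, l2, tol=tol, max_iter=max_iter,
                          group_weight_exponent=group_weight_exponent, w0=w_warm)
                w_warm = res.w
                z = res.decision_values(Mte)
                if np.all(res.w == 0.0):
                    scores[i1, i2, f] = 0.5
                else:
                    scores[i1, i2, f] = auroc(z, Mte.labels)
    mean = scores.mean(axis=2)
    se = scores.std(axis=2, ddof=1) / np.sqrt(folds)
    rows = []
    for i1, l1 in enumerate(lambda1_grid):
        for i2, l2 in enumerate(lambda2_grid):
            rows.append({"lambda1": l1, "lambda2": l2,
                         "mean_auroc": mean[i1, i2], "se_auroc": se[i1, i2]})
    table = pd.DataFrame(rows)
    best_row = table.sort_values(
        ["mean_auroc", "lambda1", "lambda2"], ascending=False).iloc[0]
    if rule == "1se":
        thresh = best_row["mean_auroc"] - best_row["se_auroc"]
        eligible = table[table["mean_auroc"] >= thresh]
        pick = eligible.sort_values(["lambda1", "lambda2"], ascending=False).iloc[0]
    else:
        pick = best_row
    return float(pick["lambda1"]), float(pick["lambda2"]), table


# ---------------------------------------------------------------------------
# multitask

@dataclass
class MultitaskFit:
    """Common + per-task sparse group lasso weights.

    An example of task t is scored by (w_c + w_t) . x over the shared
    (union) feature space.
    """

    w_common: np.ndarray
    w_task: dict[str, np.ndarray]
    alpha: float
    beta: float
    lambda1: float
    lambda2: float
    common_assignment: GroupAssignment
    task_assignments: dict[str, GroupAssignment]
    objective_value: float
    converged: bool
    feature_names: list[str] | None = None

    def decision_values(self, M: FeatureMatrix, task: str) -> np.ndarray:
        return np.asarray(M.counts @ (self.w_common + self.w_task[task])).ravel()


def multitask_objective(w_common: np.ndarray, w_task: dict[str, np.ndarray],
                        M: FeatureMatrix,
                        common_assignment: GroupAssignment,
                        task_assignments: dict[str, GroupAssignment],
                        lambda1: float, lambda2: float,
                        alpha: float = 1.5, beta: float = 1.0,
                        group_weight_exponent: float = 0.5) -> float:
    """Stacked multitask objective value (loss + scaled penalties)."""
    tasks = np.asarray(M.tasks)
    y = M.labels.astype(np.float64)
    loss = 0.0
    for t, wt in w_task.items():
        rows = tasks == t
        z = np.asarray(M.counts[rows] @ (w_common + wt)).ravel()
        loss += _logistic_loss(z, y[rows])
    p = len(w_common)
    pen = beta * _penalty(w_common, common_assignment, lambda1, lambda2,
                          _group_weights(common_assignment, group_weight_exponent),
                          np.ones(p))
    for t, wt in w_task.items():
        At = task_assignments[t]
        pen += alpha * _penalty(wt, At, lambda1, lambda2,
                                _group_weights(At, group_weight_exponent), np.ones(p))
    return loss + pen


def fit_multitask(M: FeatureMatrix,
                  task_assignments: dict[str, GroupAssignment],
                  common_assignment: GroupAssignment,
                  lambda1: float, lambda2: float,
                  alpha: float = 1.5, beta: float = 1.0,
                  tol: float = 1e-7, max_iter: int = 3000,
                  group_weight_exponent: float = 0.5) -> MultitaskFit:
    """Jointly fit common and task-specific weight blocks.

    ``M`` must carry task ids and cover the union feature space; every
    group assignment partitions those same columns. Internally the
    problem is one sparse group lasso on the stacked block vector
    (w_c, w_t1, w_t2, ...) with the design replicated into the common
    block and the matching task block, penalty weights beta on the
    common block and alpha on task blocks.
    """
    if M.tasks is None:
        raise ValueError("feature matrix must carry task ids")
    task_ids = sorted(task_assignments)
    if len(task_ids) < 2:
        raise ValueError("multitask training needs at least two tasks")
    tasks = np.asarray(M.tasks)
    for t in task_ids:
        labs = np.unique(M.labels[tasks == t])
        if len(labs) < 2:
            raise ValueError(f"task {t!r} does not contain both classes")
    p = M.n_features
    X = sp.csr_matrix(M.counts)
    blocks = [X]
    for t in task_ids:
        D = sp.diags((tasks == t).astype(np.float64))
        blocks.append(D @ X)
    Xs = sp.hstack(blocks, format="csr")
    # stacked group assignment with relabeled ids and per-group multipliers
    offsets, gids, mults = [], [], []
    next_id = 0
    stacked_groups = np.empty(p * (len(task_ids) + 1), dtype=np.int64)
    for bi, (assign, mult) in enumerate(
            [(common_assignment, beta)] + [(task_assignments[t], alpha) for t in task_ids]):
        if assign.n_features != p:
            raise ValueError("group assignments must cover the union feature space")
        stacked_groups[bi * p:(bi + 1) * p] = assign.group_of + next_id
        mults.extend([mult] * assign.G)
        next_id += assign.G
    A_stacked = GroupAssignment(group_of=stacked_groups, G=next_id)
    l1_mult = np.concatenate([np.full(p, beta)] + [np.full(p, alpha) for _ in task_ids])
    w, _, trace, converged, _ = _fit_core(
        Xs, M.labels, A_stacked, lambda1, lambda2,
        np.asarray(mults), l1_mult, group_weight_exponent,
        False, tol, max_iter, None)
    w_common = w[:p]
    w_task = {t: w[(i + 1) * p:(i + 2) * p] for i, t in enumerate(task_ids)}
    return MultitaskFit(
        w_common=w_common, w_task=w_task, alpha=alpha, beta=beta,
        lambda1=lambda1, lambda2=lambda2,
        common_assignment=common_assignment, task_assignments=dict(task_assignments),
        objective_value=float(trace[-1]), converged=converged,
        feature_names=M.space.pattern_strings)
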