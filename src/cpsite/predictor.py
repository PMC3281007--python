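"""Viability prediction: feature integration and the classifier ensemble.

Pipeline: per-residue features are *oriented* so viable sites score higher
on every feature, *standardized* per protein (z-scores), then scored by
four models —

* HI: a hierarchical integration tree whose nodes average standardized
  features with exhaustively searched weights (two-decimal grid summing to
  1 per node), selected by cross-validated MCC, then AUC, then a
  two-sample p-value; the root integrated feature (IF) is mapped to a
  probability score through the training IF distributions.
* ANN: a 3-layer sigmoid perceptron trained by stochastic single-case
  backpropagation.
* RF: 1,000 unpruned CART trees on bootstrap samples and random feature
  subsets, ranked by out-of-bag MCC; the 500 best trees vote.
* SVM: an RBF-kernel soft-margin classifier with grid-searched (C, gamma),
  decision values calibrated to probabilities by a Platt sigmoid fitted on
  out-of-fold decision values.

The four scores, each in [0, 1], are averaged and smoothed along the chain
with a 3-residue weighted window; a residue with smoothed score >= 0.5 is
predicted to be a viable circular-permutation site.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .descriptors import FeatureMatrix
from .metrics import mcc_from_counts, stratified_folds

logger = logging.getLogger("cpsite")


# ---------------------------------------------------------------------------
# Orientation and standardization
# ---------------------------------------------------------------------------

def orient_features(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    rows: Optional[np.ndarray] = None,
) -> Tuple[FeatureMatrix, Dict[str, int]]:
    """Flip features so viable sites score higher on every one.

    ``labels`` holds 1/0 viability for the selected ``rows`` (all rows when
    None).  A feature whose viable-class mean is below its inviable-class
    mean is multiplied by -1; sign inversion (rather than reciprocal) keeps
    zero-crossing features well defined.  Returns the oriented matrix and
    the orientation table {feature: +1 or -1}.
    """
    y = np.asarray(labels).astype(int)
    df = matrix.data.copy()
    sub = df if rows is None else df.iloc[np.asarray(rows)]
    if len(y) != len(sub):
        raise ValueError("labels must align with the selected rows")
    table: Dict[str, int] = {}
    for f in matrix.feature_names:
        v = sub[f].to_numpy(dtype=float)
        mv = np.nanmean(v[y == 1]) if np.any(y == 1) else np.nan
        mi = np.nanmean(v[y == 0]) if np.any(y == 0) else np.nan
        if not np.isfinite(mv) or not np.isfinite(mi) or mv == mi:
            logger.warning("feature %s constant across classes; left unchanged", f)
            table[f] = 1
        else:
            table[f] = 1 if mv > mi else -1
        if table[f] == -1:
            df[f] = -df[f]
    return (
        FeatureMatrix(
            data=df, feature_names=list(matrix.feature_names),
            oriented=True, standardized=matrix.standardized,
        ),
        table,
    )


def apply_orientation(
    matrix: FeatureMatrix, table: Dict[str, int]
) -> FeatureMatrix:
    df = matrix.data.copy()
    for f in matrix.feature_names:
        if table.get(f, 1) == -1:
            df[f] = -df[f]
    return FeatureMatrix(
        data=df, feature_names=list(matrix.feature_names),
        oriented=True, standardized=matrix.standardized,
    )


def standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Per-protein, per-feature z-scores.

    Each protein is standardized independently (no pooling across
    proteins).  Constant columns become all zeros with a warning; undefined
    (NaN) cells are excluded from the mean/sd and then set to 0, i.e. to the
    protein mean.
    """
    df = matrix.data.copy()
    for pid, idx in df.groupby("protein_id").groups.items():
        if len(idx) < 2:
            raise ValueError(f"protein {pid} has fewer than 2 residues")
        for f in matrix.feature_names:
            v = df.loc[idx, f].to_numpy(dtype=float)
            mu = np.nanmean(v)
            sd = np.nanstd(v)
            if sd == 0 or not np.isfinite(sd):
                logger.warning("constant feature %s in %s; z set to 0", f, pid)
                z = np.zeros_like(v)
            else:
                z = (v - mu) / sd
            z[~np.isfinite(z)] = 0.0
            df.loc[idx, f] = z
    return FeatureMatrix(
        data=df, feature_names=list(matrix.feature_names),
        oriented=matrix.oriented, standardized=True,
    )


# ---------------------------------------------------------------------------
# Hierarchical integration (HI)
# ---------------------------------------------------------------------------

@dataclass
class HINode:
    name: str
    children: list                      # str (feature) or HINode
    weights: Optional[List[float]] = None
    mcc: Optional[float] = None         # CV mean MCC of this node's IF
    auc: Optional[float] = None


@dataclass
class HITree:
    root: HINode
    feature_names: List[str]
    train_if_pos: np.ndarray = field(default_factory=lambda: np.empty(0))
    train_if_neg: np.ndarray = field(default_factory=lambda: np.empty(0))
    weight_step: float = 0.05
    #: singleton cross-validated MCC of each leaf feature, on the same
    #: folds used for weight selection (the root IF can never do worse).
    leaf_mcc: Dict[str, float] = field(default_factory=dict)


def default_topology(feature_names: Sequence[str]) -> HINode:
    """Biologically grouped feature tree used when no topology is supplied.

    Groups: sequence propensities, SSE propensity, exposure, packing,
    flexibility, core distance.  Groups with no present feature are dropped.
    """
    groups = [
        ("sequence", ["R_aa", "R_aat3", "R_aat5"]),
        ("sse", ["R_sse"]),
        ("exposure", ["RSA", "depth", "CM"]),
        ("packing", ["hbonds", "closeness", "CN", "WCN"]),
        ("flexibility", ["bfactor", "gnmf"]),
        ("core", ["DIS_b", "DIS_hpho", "F_b", "F_hpho", "F_bh_union", "F_bh_inter"]),
    ]
    present = set(feature_names)
    children = []
    for name, feats in groups:
        kept = [f for f in feats if f in present]
        if len(kept) == 1:
            children.append(HINode(name=name, children=kept))
        elif kept:
            children.append(HINode(name=name, children=kept))
    ungrouped = [
        f for f in feature_names
        if not any(f in feats for _, feats in groups)
    ]
    for f in ungrouped:
        children.append(HINode(name=f"extra_{f}", children=[f]))
    return HINode(name="root", children=children)


def _weight_grid(n_children: int, step: float) -> np.ndarray:
    """All weight vectors on the step grid summing to 1.00."""
    s = round(1.0 / step)
    if abs(s * step - 1.0) > 1e-9:
        raise ValueError("weight_step must divide 1.00")
    est = math.comb(s + n_children - 1, n_children - 1)
    if est > 2_000_000:
        raise ValueError(
            f"{n_children} branches at step {step} give {est} weight "
            "combinations; use a coarser weight_step"
        )
    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest
    grid = np.asarray(list(compositions(s, n_children)), dtype=float) * step
    return grid


def _cv_mcc_auc(
    S: np.ndarray, y: np.ndarray, folds: List[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """Cross-validated mean MCC and AUC for K candidate score columns.

    Per fold, a decision threshold is chosen on the training part as the
    ROC point nearest (0, 1); MCC is evaluated on the held-out part at that
    threshold.  AUC uses the rank statistic on the held-out part.
    """
    n, K = S.shape
    all_idx = np.arange(n)
    mccs = np.zeros((len(folds), K))
    aucs = np.zeros((len(folds), K))
    for fi, test in enumerate(folds):
        train = np.setdiff1d(all_idx, test)
        S_tr, y_tr = S[train], y[train]
        S_te, y_te = S[test], y[test]
        P = y_tr.sum()
        N = len(y_tr) - P
        order = np.argsort(-S_tr, axis=0)
        st = np.take_along_axis(S_tr, order, axis=0)
        ls = y_tr[order]
        cum_tp = np.cumsum(ls, axis=0)
        k_idx = np.arange(1, len(y_tr) + 1)[:, None]
        tpr = cum_tp / max(P, 1)
        fpr = (k_idx - cum_tp) / max(N, 1)
        d2 = fpr ** 2 + (1.0 - tpr) ** 2
        best = np.argmin(d2, axis=0)
        thr = st[best, np.arange(K)]

        pred = S_te >= thr[None, :]
        pos = (y_te == 1)[:, None]
        tp = np.sum(pred & pos, axis=0).astype(float)
        fp = np.sum(pred & ~pos, axis=0).astype(float)
        fn = np.sum(~pred & pos, axis=0).astype(float)
        tn = np.sum(~pred & ~pos, axis=0).astype(float)
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)
        mccs[fi] = m

        Pt = y_te.sum()
        Nt = len(y_te) - Pt
        if Pt and Nt:
            ranks = np.argsort(np.argsort(S_te, axis=0), axis=0) + 1.0
            rank_pos = np.sum(np.where((y_te == 1)[:, None], ranks, 0.0), axis=0)
            aucs[fi] = (rank_pos - Pt * (Pt + 1) / 2.0) / (Pt * Nt)
    return mccs.mean(axis=0), aucs.mean(axis=0)


def _select_candidate(
    S: np.ndarray, y: np.ndarray, folds: List[np.ndarray]
) -> Tuple[int, float, float]:
    """Lexicographic selection: CV MCC, then CV AUC, then two-sample p."""
    K = S.shape[1]
    mcc = np.empty(K)
    auc = np.empty(K)
    chunk = 2048
    for lo in range(0, K, chunk):
        hi = min(lo + chunk, K)
        mcc[lo:hi], auc[lo:hi] = _cv_mcc_auc(S[:, lo:hi], y, folds)
    top = np.flatnonzero(mcc >= mcc.max() - 1e-9)
    top = top[auc[top] >= auc[top].max() - 1e-9]
    if len(top) > 1:
        pvals = []
        for k in top:
            a, b = S[y == 1, k], S[y == 0, k]
            try:
                pvals.append(mannwhitneyu(a, b).pvalue)
            except ValueError:
                pvals.append(1.0)
        best = top[int(np.argmin(pvals))]
    else:
        best = top[0]
    return int(best), float(mcc[best]), float(auc[best])


def hi_fit(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    topology: Optional[HINode] = None,
    weight_step: float = 0.05,
    folds: int = 10,
    seed: int = 0,
    rows: Optional[np.ndarray] = None,
) -> HITree:
    """Fit branch weights of the hierarchical integration tree.

    Bottom-up over nodes: each node's integrated feature is a weighted sum
    of its children's standardized values with exhaustively searched weight
    grids (two decimal places by default, summing to 1.00 per node),
    selected by 10-fold mean MCC, ties broken by mean AUC, then by the
    two-sample Mann-Whitney p-value of the IF between classes.  The fold
    split is fixed once per fit so every node (and every leaf, as a
    singleton weighting) is judged on identical data.
    """
    if not matrix.standardized:
        logger.warning("HI fitting expects standardized features")
    y = np.asarray(labels).astype(int)
    df = matrix.data if rows is None else matrix.data.iloc[np.asarray(rows)]
    if len(y) != len(df):
        raise ValueError("labels must align with the selected rows")
    topo = topology or default_topology(matrix.feature_names)
    fold_idx = stratified_folds(y, n_folds=folds, seed=seed)
    leaf_mcc: Dict[str, float] = {}

    def fit_node(node: HINode) -> Tuple[HINode, np.ndarray]:
        child_values = []
        fitted_children = []
        for child in node.children:
            if isinstance(child, HINode):
                fitted, vals = fit_node(child)
                fitted_children.append(fitted)
                child_values.append(vals)
            else:
                if child not in matrix.feature_names:
                    raise ValueError(f"unknown feature leaf {child!r}")
                fitted_children.append(child)
                vals = df[child].to_numpy(dtype=float)
                if child not in leaf_mcc:
                    m, _ = _cv_mcc_auc(vals[:, None], y, fold_idx)
                    leaf_mcc[child] = float(m[0])
                child_values.append(vals)
        X = np.column_stack(child_values)
        if X.shape[1] == 1:
            w = np.array([1.0])
            vals = X[:, 0]
            m, a = _cv_mcc_auc(vals[:, None], y, fold_idx)
            best_mcc, best_auc = float(m[0]), float(a[0])
        else:
            grid = _weight_grid(X.shape[1], weight_step)
            S = X @ grid.T
            best, best_mcc, best_auc = _select_candidate(S, y, fold_idx)
            w = grid[best]
            vals = S[:, best]
        out = HINode(
            name=node.name, children=fitted_children,
            weights=[round(float(x), 2) for x in w],
            mcc=best_mcc, auc=best_auc,
        )
        return out, vals

    root, if_values = fit_node(topo)
    return HITree(
        root=root,
        feature_names=list(matrix.feature_names),
        train_if_pos=np.sort(if_values[y == 1]),
        train_if_neg=np.sort(if_values[y == 0]),
        weight_step=weight_step,
        leaf_mcc=leaf_mcc,
    )


def hi_values(tree: HITree, matrix: FeatureMatrix) -> np.ndarray:
    """Root integrated-feature values for a (oriented, standardized) matrix."""
    df = matrix.data

    def node_values(node: HINode) -> np.ndarray:
        vals = []
        for child in node.children:
            if isinstance(child, HINode):
                vals.append(node_values(child))
            else:
                vals.append(df[child].to_numpy(dtype=float))
        X = np.column_stack(vals)
        return X @ np.asarray(node.weights)

    return node_values(tree.root)


def hi_probability(
    if_value: Union[float, np.ndarray],
    training_if_pos: np.ndarray,
    training_if_neg: np.ndarray,
) -> Union[float, np.ndarray]:
    """Probability score from the training IF distributions.

    N_p counts positives with IF >= value, N_n negatives with IF <= value;
    the score is N_n / (N_p + N_n) (0.5 when both counts are zero).  It is
    monotone non-decreasing in the IF value.
    """
    pos = np.sort(np.asarray(training_if_pos, dtype=float))
    neg = np.sort(np.asarray(training_if_neg, dtype=float))
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both training distributions must be non-empty")
    v = np.atleast_1d(np.asarray(if_value, dtype=float))
    n_p = len(pos) - np.searchsorted(pos, v, side="left")
    n_n = np.searchsorted(neg, v, side="right")
    denom = n_p + n_n
    score = np.where(denom > 0, n_n / np.maximum(denom, 1), 0.5)
    return float(score[0]) if np.isscalar(if_value) else score


# ---------------------------------------------------------------------------
# ANN
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class AnnModel:
    w1: np.ndarray  # (N_h, N_i + 1) with bias column
    w2: np.ndarray  # (1, N_h + 1)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = _sigmoid(X @ self.w1[:, :-1].T + self.w1[:, -1])
        o = _sigmoid(h @ self.w2[:, :-1].T + self.w2[:, -1])
        return o[:, 0]


def ann_fit(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    iterations: int = 5000,
    learning_rate: float = 0.5,
    momentum: float = 0.1,
    init_range: float = 2.0,
) -> AnnModel:
    """Train the 3-layer sigmoid perceptron by single-case backpropagation.

    Hidden layer size N_h = round(sqrt(N_i * N_o)); weights initialized
    uniformly in [-init_range, +init_range]; one randomly drawn training
    case (with replacement) per iteration.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_i = X.shape
    n_o = 1
    n_h = max(1, round(math.sqrt(n_i * n_o)))
    for attempt in range(5):
        rng = np.random.default_rng(seed + attempt)
        w1 = rng.uniform(-init_range, init_range, size=(n_h, n_i + 1))
        w2 = rng.uniform(-init_range, init_range, size=(n_o, n_h + 1))
        v1 = np.zeros_like(w1)
        v2 = np.zeros_like(w2)
        ok = True
        for _ in range(iterations):
            i = rng.integers(0, n)
            x = X[i]
            h = _sigmoid(w1[:, :-1] @ x + w1[:, -1])
            o = _sigmoid(w2[:, :-1] @ h + w2[:, -1])
            err_o = (y[i] - o) * o * (1.0 - o)
            err_h = h * (1.0 - h) * (w2[:, :-1].T @ err_o)
            g2 = np.concatenate([np.outer(err_o, h), err_o[:, None]], axis=1)
            g1 = np.concatenate([np.outer(err_h, x), err_h[:, None]], axis=1)
            v2 = learning_rate * g2 + momentum * v2
            v1 = learning_rate * g1 + momentum * v1
            w2 = w2 + v2
            w1 = w1 + v1
            if not (np.all(np.isfinite(w1)) and np.all(np.isfinite(w2))):
                ok = False
                break
        if ok:
            return AnnModel(w1=w1, w2=w2)
        logger.warning("non-finite ANN weights; re-initializing with next seed")
    raise RuntimeError("ANN training failed to produce finite weights")


# ---------------------------------------------------------------------------
# Random forest with out-of-bag MCC tree selection
# ---------------------------------------------------------------------------

def _gini_best_split(Xf: np.ndarray, y: np.ndarray):
    """Best (threshold, impurity decrease) for one feature column."""
    order = np.argsort(Xf, kind="mergesort")
    xs, ys = Xf[order], y[order]
    n = len(ys)
    cum_pos = np.cumsum(ys)
    total_pos = cum_pos[-1]
    # candidate boundaries: between distinct consecutive values
    boundary = np.flatnonzero(np.diff(xs) > 0)
    if len(boundary) == 0:
        return None
    nl = boundary + 1.0
    nr = n - nl
    pl = cum_pos[boundary] / nl
    pr = (total_pos - cum_pos[boundary]) / nr
    gini = nl / n * 2 * pl * (1 - pl) + nr / n * 2 * pr * (1 - pr)
    k = int(np.argmin(gini))
    b = boundary[k]
    thr = 0.5 * (xs[b] + xs[b + 1])
    parent_p = total_pos / n
    gain = 2 * parent_p * (1 - parent_p) - gini[k]
    return thr, float(gain)


def _grow_tree(X: np.ndarray, y: np.ndarray, features: np.ndarray) -> dict:
    """Unpruned CART tree; nodes reference global feature indices."""
    n = len(y)
    p = y.mean() if n else 0.0
    if n < 2 or p == 0.0 or p == 1.0:
        return {"leaf": True, "value": float(p)}
    best = None
    for f in features:
        res = _gini_best_split(X[:, f], y)
        if res is None:
            continue
        thr, gain = res
        if best is None or gain > best[2]:
            best = (int(f), thr, gain)
    if best is None or best[2] <= 0:
        return {"leaf": True, "value": float(p)}
    f, thr, _ = best
    mask = X[:, f] <= thr
    return {
        "leaf": False,
        "feature": f,
        "thr": float(thr),
        "left": _grow_tree(X[mask], y[mask], features),
        "right": _grow_tree(X[~mask], y[~mask], features),
    }


def _tree_votes(node: dict, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    idx = np.arange(len(X))

    def descend(nd, sel):
        if len(sel) == 0:
            return
        if nd["leaf"]:
            out[sel] = 1.0 if nd["value"] >= 0.5 else 0.0
            return
        mask = X[sel, nd["feature"]] <= nd["thr"]
        descend(nd["left"], sel[mask])
        descend(nd["right"], sel[~mask])

    descend(node, idx)
    return out


@dataclass
class RfModel:
    trees: list           # retained trees, ordered by descending OOB MCC
    oob_mcc: list
    n_features: int

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.zeros(len(X))
        for t in self.trees:
            votes += _tree_votes(t, X)
        return votes / len(self.trees)


def rf_fit(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_trees: int = 1000,
    n_keep: int = 500,
    feature_fraction: float = 0.5,
) -> RfModel:
    """Random forest with out-of-bag MCC tree retention.

    Each of ``n_trees`` unpruned CART trees is grown on a bootstrap sample
    of all cases (n' = n, expected ~63% unique) using a random subset of
    max(1, floor(feature_fraction * n_f)) features; each tree is evaluated
    by MCC on its out-of-bag cases and the ``n_keep`` best trees form the
    forest.  A tree's vote is its leaf majority class; the forest score is
    the fraction of retained trees voting viable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, n_f = X.shape
    if n_f < 2:
        raise ValueError("random forest needs at least 2 features")
    rng = np.random.default_rng(seed)
    n_sub = max(1, int(feature_fraction * n_f))
    scored = []
    for t in range(n_trees):
        feats = rng.choice(n_f, size=n_sub, replace=False)
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), np.unique(boot))
        tree = _grow_tree(X[boot], y[boot], feats)
        if len(oob) == 0 or len(np.unique(y[oob])) < 1:
            logger.warning("tree %d has empty out-of-bag set; MCC set to -1", t)
            mcc = -1.0
        else:
            pred = _tree_votes(tree, X[oob]).astype(int)
            c = {
                "TP": int(np.sum((pred == 1) & (y[oob] == 1))),
                "FP": int(np.sum((pred == 1) & (y[oob] == 0))),
                "TN": int(np.sum((pred == 0) & (y[oob] == 0))),
                "FN": int(np.sum((pred == 0) & (y[oob] == 1))),
            }
            mcc = mcc_from_counts(c)
        scored.append((mcc, t, tree))
    scored.sort(key=lambda s: (-s[0], s[1]))
    kept = scored[:n_keep]
    return RfModel(
        trees=[t for _, _, t in kept],
        oob_mcc=[m for m, _, _ in kept],
        n_features=n_f,
    )


# ---------------------------------------------------------------------------
# SVM with Platt-calibrated probability scores
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    cost: float
    platt_a: float
    platt_b: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = (
            (X ** 2).sum(axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + (self.support_vectors ** 2).sum(axis=1)[None, :]
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def score(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.platt_a * self.decision(X) + self.platt_b)


def svm_fit(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    costs: Sequence[float] = (0.5, 2.0, 8.0),
    gammas: Sequence[float] = (0.25, 1.0, 4.0),
    cv: int = 3,
) -> SvmModel:
    """RBF-kernel soft-margin classifier with cross-validated grid search.

    ``gammas`` are multiples of the 1/(n_f * var) heuristic.  The decision
    values of out-of-fold predictions are calibrated to probabilities with
    a Platt sigmoid (logistic fit of the label on the decision value).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit a single-class SVM")
    base_gamma = 1.0 / (X.shape[1] * max(X.var(), 1e-12))
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for c in costs:
        for gm in gammas:
            g = gm * base_gamma
            correct = 0
            for tr, te in splits:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(X[tr], y[tr])
                correct += int(np.sum(clf.predict(X[te]) == y[te]))
            if best is None or correct > best[0]:
                best = (correct, c, g)
    _, cost, gamma = best
    # out-of-fold decision values for Platt calibration
    df_oof = np.empty(len(y))
    for tr, te in splits:
        clf = SVC(C=cost, gamma=gamma, kernel="rbf")
        clf.fit(X[tr], y[tr])
        df_oof[te] = clf.decision_function(X[te])
    a, b = _platt_fit(df_oof, y)
    final = SVC(C=cost, gamma=gamma, kernel="rbf")
    final.fit(X, y)
    sign = 1.0 if final.classes_[1] == 1 else -1.0
    return SvmModel(
        support_vectors=final.support_vectors_.copy(),
        dual_coef=sign * final.dual_coef_[0].copy(),
        intercept=sign * float(final.intercept_[0]),
        gamma=gamma,
        cost=cost,
        platt_a=a,
        platt_b=b,
    )


def _platt_fit(decision: np.ndarray, y: np.ndarray, iters: int = 100) -> Tuple[float, float]:
    """Newton fit of P(y=1|d) = sigmoid(a*d + b)."""
    a, b = 1.0, 0.0
    d = np.asarray(decision, dtype=float)
    t = np.asarray(y, dtype=float)
    for _ in range(iters):
        p = _sigmoid(a * d + b)
        g_a = np.sum((p - t) * d)
        g_b = np.sum(p - t)
        w = p * (1 - p)
        h_aa = np.sum(w * d * d) + 1e-9
        h_ab = np.sum(w * d)
        h_bb = np.sum(w) + 1e-9
        det = h_aa * h_bb - h_ab ** 2
        if abs(det) < 1e-12:
            break
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        a, b = a - da, b - db
        if abs(da) + abs(db) < 1e-10:
            break
    return float(a), float(b)


# ---------------------------------------------------------------------------
# Combination and smoothing
# ---------------------------------------------------------------------------

def combine_scores(*score_arrays: np.ndarray) -> np.ndarray:
    """Unweighted mean of component probability scores (each in [0, 1])."""
    arrays = [np.atleast_1d(np.asarray(a, dtype=float)) for a in score_arrays]
    for a in arrays:
        if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
            raise ValueError("component scores must lie in [0, 1]")
    return np.clip(np.mean(arrays, axis=0), 0.0, 1.0)


def smooth_profile(
    raw_scores: np.ndarray,
    weights: Tuple[float, float, float] = (0.25, 0.50, 0.25),
) -> np.ndarray:
    """3-residue weighted window smoothing along the chain.

    ps'(i) = (w- * ps(i-1) + w0 * ps(i) + w+ * ps(i+1)) normalized over the
    weights of the neighbors that exist, so termini renormalize.
    """
    ps = np.atleast_1d(np.asarray(raw_scores, dtype=float))
    wm, w0, wp = weights
    n = len(ps)
    out = np.empty(n)
    for i in range(n):
        num = w0 * ps[i]
        den = w0
        if i > 0:
            num += wm * ps[i - 1]
            den += wm
        if i < n - 1:
            num += wp * ps[i + 1]
            den += wp
        out[i] = num / den
    return out


# ---------------------------------------------------------------------------
# The trained ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    hi_topology: Optional[HINode] = None
    hi_weight_step: float = 0.05
    hi_folds: int = 10
    ann_iterations: int = 5000
    ann_learning_rate: float = 0.5
    ann_momentum: float = 0.1
    rf_n_trees: int = 1000
    rf_n_keep: int = 500
    rf_feature_fraction: float = 0.5
    svm_costs: Tuple[float, ...] = (0.5, 2.0, 8.0)
    svm_gammas: Tuple[float, ...] = (0.25, 1.0, 4.0)
    smoothing: Tuple[float, float, float] = (0.25, 0.50, 0.25)


@dataclass
class TrainedEnsemble:
    feature_names: List[str]
    orientation: Dict[str, int]
    hi: HITree
    ann: AnnModel
    rf: RfModel
    svm: SvmModel
    config: EnsembleConfig

    def component_scores(self, matrix: FeatureMatrix) -> pd.DataFrame:
        """Raw component probability scores for a prepared matrix."""
        if not (matrix.oriented and matrix.standardized):
            raise ValueError("matrix must be oriented and standardized")
        X = matrix.data[self.feature_names].to_numpy(dtype=float)
        if_vals = hi_values(self.hi, matrix)
        return pd.DataFrame(
            {
                "hi": hi_probability(if_vals, self.hi.train_if_pos, self.hi.train_if_neg),
                "ann": self.ann.score(X),
                "rf": self.rf.score(X),
                "svm": self.svm.score(X),
            }
        )


def prepare_matrix(
    matrix: FeatureMatrix, orientation: Dict[str, int]
) -> FeatureMatrix:
    """Apply a learned orientation then per-protein standardization."""
    m = matrix
    if not m.oriented:
        m = apply_orientation(m, orientation)
    if not m.standardized:
        m = standardize(m)
    return m


def fit_ensemble(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    rows: Optional[np.ndarray] = None,
    config: Optional[EnsembleConfig] = None,
    seed: int = 0,
) -> TrainedEnsemble:
    """Train all four scorers on labeled residues of a raw feature matrix.

    ``rows`` selects the labeled residue rows (all rows when None);
    ``labels`` is the aligned 1/0 viability vector.
    """
    config = config or EnsembleConfig()
    y = np.asarray(labels).astype(int)
    oriented, table = orient_features(matrix, y, rows=rows)
    std = standardize(oriented)
    sub = std.data if rows is None else std.data.iloc[np.asarray(rows)]
    X = sub[matrix.feature_names].to_numpy(dtype=float)
    hi = hi_fit(
        std, y,
        topology=config.hi_topology,
        weight_step=config.hi_weight_step,
        folds=config.hi_folds,
        seed=seed,
        rows=rows,
    )
    ann = ann_fit(
        X, y, seed=seed,
        iterations=config.ann_iterations,
        learning_rate=config.ann_learning_rate,
        momentum=config.ann_momentum,
    )
    rf = rf_fit(
        X, y, seed=seed,
        n_trees=config.rf_n_trees,
        n_keep=config.rf_n_keep,
        feature_fraction=config.rf_feature_fraction,
    )
    svm = svm_fit(
        X, y, seed=seed, costs=config.svm_costs, gammas=config.svm_gammas,
    )
    return TrainedEnsemble(
        feature_names=list(matrix.feature_names),
        orientation=table,
        hi=hi,
        ann=ann,
        rf=rf,
        svm=svm,
        config=config,
    )


def predict_profile(
    ensemble: TrainedEnsemble, matrix: FeatureMatrix
) -> pd.DataFrame:
    """Per-residue probability profile for a raw feature matrix.

    Returns protein_id, seq_position, the four component scores, the
    combined raw score ps, the 3-residue smoothed score ps_smooth and the
    predicted label (viable iff ps_smooth >= 0.5).
    """
    prepared = prepare_matrix(matrix, ensemble.orientation)
    comp = ensemble.component_scores(prepared)
    ps = combine_scores(comp["hi"], comp["ann"], comp["rf"], comp["svm"])
    out = prepared.data[["protein_id", "seq_position"]].copy()
    out = pd.concat([out.reset_index(drop=True), comp], axis=1)
    out["ps"] = ps
    smoothed = np.empty(len(out))
    for _, idx in out.groupby("protein_id").groups.items():
        idx = np.asarray(idx)
        order = np.argsort(out.loc[idx, "seq_position"].to_numpy())
        sorted_idx = idx[order]
        smoothed[sorted_idx] = smooth_profile(
            out.loc[sorted_idx, "ps"].to_numpy(), ensemble.config.smoothing
        )
    out["ps_smooth"] = smoothed
    out["predicted_viable"] = (out["ps_smooth"] >= 0.5).astype(int)
    return out


def cross_validated_scores(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    rows: np.ndarray,
    config: Optional[EnsembleConfig] = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold combined (and component) scores for labeled residues.

    Folds are seeded and class-stratified over the labeled rows; for each
    fold the full ensemble is retrained on the remaining labeled residues
    and scores the held-out ones.  Returns one row per labeled residue with
    the component scores, the combined raw score ``ps``, the true label and
    the fold index.
    """
    config = config or EnsembleConfig()
    y = np.asarray(labels).astype(int)
    rows = np.asarray(rows)
    folds = stratified_folds(y, n_folds=n_folds, seed=seed)
    out = pd.DataFrame(
        index=np.arange(len(y)),
        columns=["hi", "ann", "rf", "svm", "ps", "label", "fold"],
        dtype=float,
    )
    for fi, test in enumerate(folds):
        train = np.setdiff1d(np.arange(len(y)), test)
        ens = fit_ensemble(
            matrix, y[train], rows=rows[train], config=config, seed=seed + fi
        )
        prepared = prepare_matrix(matrix, ens.orientation)
        comp = ensemble_component_rows(ens, prepared, rows[test])
        for c in ("hi", "ann", "rf", "svm"):
            out.loc[test, c] = comp[c].to_numpy()
        out.loc[test, "ps"] = combine_scores(
            comp["hi"], comp["ann"], comp["rf"], comp["svm"]
        )
        out.loc[test, "fold"] = fi
    out["label"] = y
    return out


def ensemble_component_rows(
    ens: TrainedEnsemble, prepared: FeatureMatrix, row_idx: np.ndarray
) -> pd.DataFrame:
    """Component scores restricted to selected rows of a prepared matrix."""
    sub = FeatureMatrix(
        data=prepared.data.iloc[np.asarray(row_idx)].reset_index(drop=True),
        feature_names=list(prepared.feature_names),
        oriented=True,
        standardized=True,
    )
    return ens.component_scores(sub)


# ---------------------------------------------------------------------------
# Text (JSON) model serialization
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def _node_to_dict(node: HINode) -> dict:
    return {
        "name": node.name,
        "weights": node.weights,
        "mcc": node.mcc,
        "auc": node.auc,
        "children": [
            _node_to_dict(c) if isinstance(c, HINode) else c
            for c in node.children
        ],
    }


def _node_from_dict(d: dict) -> HINode:
    return HINode(
        name=d["name"],
        weights=d["weights"],
        mcc=d.get("mcc"),
        auc=d.get("auc"),
        children=[
            _node_from_dict(c) if isinstance(c, dict) else c
            for c in d["children"]
        ],
    )


def ensemble_to_json(ens: TrainedEnsemble) -> str:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": ens.feature_names,
        "orientation": ens.orientation,
        "hi": {
            "root": _node_to_dict(ens.hi.root),
            "train_if_pos": ens.hi.train_if_pos.tolist(),
            "train_if_neg": ens.hi.train_if_neg.tolist(),
            "weight_step": ens.hi.weight_step,
            "leaf_mcc": ens.hi.leaf_mcc,
        },
        "ann": {"w1": ens.ann.w1.tolist(), "w2": ens.ann.w2.tolist()},
        "rf": {
            "trees": ens.rf.trees,
            "oob_mcc": ens.rf.oob_mcc,
            "n_features": ens.rf.n_features,
        },
        "svm": {
            "support_vectors": ens.svm.support_vectors.tolist(),
            "dual_coef": ens.svm.dual_coef.tolist(),
            "intercept": ens.svm.intercept,
            "gamma": ens.svm.gamma,
            "cost": ens.svm.cost,
            "platt_a": ens.svm.platt_a,
            "platt_b": ens.svm.platt_b,
        },
        "config": {
            "hi_weight_step": ens.config.hi_weight_step,
            "hi_folds": ens.config.hi_folds,
            "ann_iterations": ens.config.ann_iterations,
            "ann_learning_rate": ens.config.ann_learning_rate,
            "ann_momentum": ens.config.ann_momentum,
            "rf_n_trees": ens.config.rf_n_trees,
            "rf_n_keep": ens.config.rf_n_keep,
            "rf_feature_fraction": ens.config.rf_feature_fraction,
            "svm_costs": list(ens.config.svm_costs),
            "svm_gammas": list(ens.config.svm_gammas),
            "smoothing": list(ens.config.smoothing),
        },
    }
    return json.dumps(doc)


def ensemble_from_json(text: str) -> TrainedEnsemble:
    doc = json.loads(text)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    cfg = doc["config"]
    config = EnsembleConfig(
        hi_weight_step=cfg["hi_weight_step"],
        hi_folds=cfg["hi_folds"],
        ann_iterations=cfg["ann_iterations"],
        ann_learning_rate=cfg["ann_learning_rate"],
        ann_momentum=cfg["ann_momentum"],
        rf_n_trees=cfg["rf_n_trees"],
        rf_n_keep=cfg["rf_n_keep"],
        rf_feature_fraction=cfg["rf_feature_fraction"],
        svm_costs=tuple(cfg["svm_costs"]),
        svm_gammas=tuple(cfg["svm_gammas"]),
        smoothing=tuple(cfg["smoothing"]),
    )
    return TrainedEnsemble(
        feature_names=doc["feature_names"],
        orientation={k: int(v) for k, v in doc["orientation"].items()},
        hi=HITree(
            root=_node_from_dict(doc["hi"]["root"]),
            feature_names=doc["feature_names"],
            train_if_pos=np.asarray(doc["hi"]["train_if_pos"], dtype=float),
            train_if_neg=np.asarray(doc["hi"]["train_if_neg"], dtype=float),
            weight_step=doc["hi"]["weight_step"],
            leaf_mcc=doc["hi"].get("leaf_mcc", {}),
        ),
        ann=AnnModel(
            w1=np.asarray(doc["ann"]["w1"], dtype=float),
            w2=np.asarray(doc["ann"]["w2"], dtype=float),
        ),
        rf=RfModel(
            trees=doc["rf"]["trees"],
            oob_mcc=doc["rf"]["oob_mcc"],
            n_features=doc["rf"]["n_features"],
        ),
        svm=SvmModel(
            support_vectors=np.asarray(doc["svm"]["support_vectors"], dtype=float),
            dual_coef=np.asarray(doc["svm"]["dual_coef"], dtype=float),
            intercept=doc["svm"]["intercept"],
            gamma=doc["svm"]["gamma"],
            cost=doc["svm"]["cost"],
            platt_a=doc["svm"]["platt_a"],
            platt_b=doc["svm"]["platt_b"],
        ),
        config=config,
    )
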