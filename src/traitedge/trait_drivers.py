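"""Regression-tree analysis of which fraction-mean traits drive delta-D.

Implements CART for a continuous response: greedy binary splits minimizing
within-node SSE, cost-complexity (weakest-link) pruning, 10-fold
cross-validation with the 1-SE rule, percent variance explained per split,
and surrogate splits (variables sending at least 90% of a node's cases to
the same child as the primary splitter).

Split thresholds sit at midpoints between consecutive observed values; ties
in SSE reduction break by lower variable index, then lower threshold, so a
fitted tree is deterministic given the fold seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Surrogate:
    var: str
    threshold: float
    left_if_below: bool  # True: x <= threshold goes to the left child
    agreement: float


@dataclass
class TreeNode:
    node_id: int
    depth: int
    rows: np.ndarray  # training-row indices reaching this node
    n: int
    mean: float
    sse: float
    split_var: str | None = None
    split_var_idx: int | None = None
    threshold: float | None = None
    variance_pct: float = 0.0  # % of total SSE removed by this split
    surrogates: list[Surrogate] = field(default_factory=list)
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    crit_alpha: float = np.inf  # complexity level at which this split collapses

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class TreeModel:
    root: TreeNode
    feature_names: list[str]
    total_variance_pct: float
    cv_table: pd.DataFrame  # beta, n_leaves, cv_error, cv_se
    selected_beta: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        return np.array([_predict_row(self.root, row) for row in x])

    def n_leaves(self) -> int:
        return _count_leaves(self.root)

    def to_dict(self) -> dict:
        return {
            "total_variance_pct": self.total_variance_pct,
            "n_leaves": self.n_leaves(),
            "selected_beta": self.selected_beta,
            "root": _node_dict(self.root),
        }


def _predict_row(node: TreeNode, row: np.ndarray) -> float:
    while not node.is_leaf:
        node = node.left if row[node.split_var_idx] <= node.threshold else node.right
    return node.mean


def _count_leaves(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return _count_leaves(node.left) + _count_leaves(node.right)


def _node_dict(node: TreeNode) -> dict:
    out = {"n": node.n, "mean_delta_d": node.mean}
    if not node.is_leaf:
        out.update(
            {
                "split_var": node.split_var,
                "threshold": node.threshold,
                "variance_pct": node.variance_pct,
                "surrogates": [
                    {
                        "var": s.var,
                        "threshold": s.threshold,
                        "left_if_below": s.left_if_below,
                        "agreement": s.agreement,
                    }
                    for s in node.surrogates
                ],
                "left": _node_dict(node.left),
                "right": _node_dict(node.right),
            }
        )
    return out


def _sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0


def _best_split(
    x_col: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[float, float] | None:
    """Best (threshold, SSE reduction) for one predictor, or None."""
    order = np.argsort(x_col, kind="mergesort")
    xs, ys = x_col[order], y[order]
    n = len(ys)
    csum = np.cumsum(ys)
    csq = np.cumsum(ys**2)
    total_sum, total_sq = csum[-1], csq[-1]
    # split after position i (1-based count i on the left)
    i = np.arange(1, n)
    valid = (xs[1:] != xs[:-1]) & (i >= min_leaf) & (n - i >= min_leaf)
    if not valid.any():
        return None
    left_sse = csq[:-1] - csum[:-1] ** 2 / i
    right_n = n - i
    right_sum = total_sum - csum[:-1]
    right_sse = (total_sq - csq[:-1]) - right_sum**2 / right_n
    parent_sse = total_sq - total_sum**2 / n
    reduction = parent_sse - left_sse - right_sse
    reduction[~valid] = -np.inf
    best = int(np.argmax(reduction))
    if reduction[best] <= 1e-12:
        return None
    threshold = _midpoint(xs[best], xs[best + 1])
    return threshold, float(reduction[best])


def _midpoint(a: float, b: float) -> float:
    """Midpoint of adjacent observed values, guaranteed to split them.

    For ulp-close values the arithmetic midpoint can round to ``b``, which
    would send every case to one child; nudge it back below ``b``.
    """
    mid = (a + b) / 2.0
    if mid >= b:
        mid = np.nextafter(b, a)
    return float(max(mid, a))


def _grow(
    x: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    min_split: int,
    min_leaf: int,
    depth: int,
    counter: list[int],
) -> TreeNode:
    node = TreeNode(
        node_id=counter[0],
        depth=depth,
        rows=rows,
        n=rows.size,
        mean=float(y[rows].mean()),
        sse=_sse(y[rows]),
    )
    counter[0] += 1
    if rows.size < min_split or node.sse <= 1e-12:
        return node
    best: tuple[float, int, float] | None = None  # (reduction, var_idx, threshold)
    for j in range(x.shape[1]):
        result = _best_split(x[rows, j], y[rows], min_leaf)
        if result is None:
            continue
        threshold, reduction = result
        # deterministic tie-break: higher reduction, then lower var index,
        # then lower threshold
        if best is None or reduction > best[0] + 1e-12:
            best = (reduction, j, threshold)
        elif abs(reduction - best[0]) <= 1e-12 and (j, threshold) < (best[1], best[2]):
            best = (reduction, j, threshold)
    if best is None:
        return node
    _, j, threshold = best
    go_left = x[rows, j] <= threshold
    if not go_left.any() or go_left.all():  # degenerate; cannot happen post-_midpoint
        return node
    node.split_var_idx = j
    node.threshold = threshold
    node.left = _grow(x, y, rows[go_left], min_split, min_leaf, depth + 1, counter)
    node.right = _grow(x, y, rows[~go_left], min_split, min_leaf, depth + 1, counter)
    return node


def _internal_nodes(node: TreeNode) -> list[TreeNode]:
    if node.is_leaf:
        return []
    return [node] + _internal_nodes(node.left) + _internal_nodes(node.right)


def _assign_crit_alphas(root: TreeNode) -> None:
    """Weakest-link pruning: record for every internal node the complexity
    level at which its subtree collapses into a leaf."""
    collapsed: set[int] = set()

    def subtree_stats(node: TreeNode) -> tuple[float, int]:
        if node.is_leaf or node.node_id in collapsed:
            return node.sse, 1
        ls, ln = subtree_stats(node.left)
        rs, rn = subtree_stats(node.right)
        return ls + rs, ln + rn

    internal = _internal_nodes(root)
    for node in internal:
        node.crit_alpha = np.inf
    while True:
        live = [t for t in internal if t.node_id not in collapsed]
        if not live:
            break
        gs = []
        for t in live:
            r_subtree, n_leaves = subtree_stats(t)
            gs.append((t.sse - r_subtree) / (n_leaves - 1))
        g_min = min(gs)
        for t, g in zip(live, gs):
            if g <= g_min + 1e-12:
                t.crit_alpha = max(g_min, 0.0)
                collapsed.add(t.node_id)
                _collapse_descendants(t, collapsed)


def _collapse_descendants(node: TreeNode, collapsed: set[int]) -> None:
    for child in (node.left, node.right):
        if child is not None and not child.is_leaf:
            collapsed.add(child.node_id)
            child.crit_alpha = min(child.crit_alpha, node.crit_alpha)
            _collapse_descendants(child, collapsed)


def _predict_at_beta(node: TreeNode, row: np.ndarray, beta: float) -> float:
    while not node.is_leaf and node.crit_alpha > beta:
        node = node.left if row[node.split_var_idx] <= node.threshold else node.right
    return node.mean


def _leaves_at_beta(node: TreeNode, beta: float) -> int:
    if node.is_leaf or node.crit_alpha <= beta:
        return 1
    return _leaves_at_beta(node.left, beta) + _leaves_at_beta(node.right, beta)


def _prune_at_beta(node: TreeNode, beta: float) -> None:
    if node.is_leaf:
        return
    if node.crit_alpha <= beta:
        node.left = node.right = None
        node.split_var = node.split_var_idx = node.threshold = None
        return
    _prune_at_beta(node.left, beta)
    _prune_at_beta(node.right, beta)


def find_surrogates(
    node: TreeNode,
    x: np.ndarray,
    feature_names: list[str],
    agreement_threshold: float = 0.9,
) -> list[Surrogate]:
    """Surrogate splits for a non-terminal node.

    For every predictor other than the primary splitter, find the threshold
    and direction that maximize the fraction of the node's cases sent to the
    same child as the primary split; keep those with agreement >= the
    threshold (inclusive), sorted by agreement.
    """
    if node.is_leaf:
        raise ValueError("surrogates are defined for non-terminal nodes only")
    rows = node.rows
    go_left = x[rows, node.split_var_idx] <= node.threshold
    n = rows.size
    out: list[Surrogate] = []
    for j in range(x.shape[1]):
        if j == node.split_var_idx:
            continue
        col = x[rows, j]
        order = np.argsort(col, kind="mergesort")
        xs = col[order]
        gl = go_left[order].astype(float)
        # candidate split after position i: first i cases below threshold
        left_hits = np.concatenate(([0.0], np.cumsum(gl)))
        i = np.arange(n + 1)
        total_left = gl.sum()
        # agreement if "x <= t" assigns left: matches below + matches above
        agree_below = (left_hits + (n - i) - (total_left - left_hits)) / n
        agree_above = 1.0 - agree_below
        valid = np.zeros(n + 1, dtype=bool)
        valid[0] = valid[n] = False  # degenerate: all cases to one side
        valid[1:n] = xs[1:] != xs[:-1]
        if not valid.any():
            continue
        best_a, best_i, best_dir = -1.0, -1, True
        for direction, agree in ((True, agree_below), (False, agree_above)):
            masked = np.where(valid, agree, -np.inf)
            idx = int(np.argmax(masked))
            if masked[idx] > best_a + 1e-12:
                best_a, best_i, best_dir = float(masked[idx]), idx, direction
        if best_a >= agreement_threshold - 1e-12:
            threshold = _midpoint(xs[best_i - 1], xs[best_i])
            out.append(
                Surrogate(
                    var=feature_names[j],
                    threshold=float(threshold),
                    left_if_below=best_dir,
                    agreement=best_a,
                )
            )
    out.sort(key=lambda s: -s.agreement)
    return out


def _finalize(node: TreeNode, x: np.ndarray, feature_names: list[str], total_sse: float) -> None:
    if node.is_leaf:
        return
    node.split_var = feature_names[node.split_var_idx]
    child_sse = node.left.sse + node.right.sse
    node.variance_pct = 100.0 * (node.sse - child_sse) / total_sse if total_sse > 0 else 0.0
    node.surrogates = find_surrogates(node, x, feature_names)
    _finalize(node.left, x, feature_names, total_sse)
    _finalize(node.right, x, feature_names, total_sse)


def fit_tree(
    data: pd.DataFrame,
    response: str = "delta_d",
    predictors: list[str] | None = None,
    min_split: int = 20,
    min_leaf: int = 7,
    cv_folds: int = 10,
    seed: int = 0,
) -> TreeModel:
    """Fit a CART regression tree with 10-fold CV and the 1-SE pruning rule.

    The returned tree is the smallest subtree whose cross-validated error is
    within one standard error of the minimum. Percent variance explained per
    split is the split's SSE reduction over the root SSE; their sum equals
    the tree's total variance explained.
    """
    if predictors is None:
        predictors = [c for c in data.columns if c != response]
    if not predictors:
        raise ValueError("at least one predictor required")
    frame = data[predictors + [response]].astype(float)
    if frame.isna().any().any():
        raise ValueError("missing values in predictors or response")
    x = frame[predictors].to_numpy()
    y = frame[response].to_numpy()
    n = len(y)
    if n < min_split:
        raise ValueError(f"need >= {min_split} rows, got {n}")

    rows = np.arange(n)
    full = _grow(x, y, rows, min_split, min_leaf, 0, counter=[0])
    total_sse = full.sse
    if full.is_leaf:
        cv_table = pd.DataFrame(
            {"beta": [np.inf], "n_leaves": [1], "cv_error": [total_sse / n], "cv_se": [0.0]}
        )
        _finalize(full, x, predictors, total_sse)
        return TreeModel(full, predictors, 0.0, cv_table, np.inf)

    _assign_crit_alphas(full)
    alphas = sorted({t.crit_alpha for t in _internal_nodes(full)})
    betas = [0.0]
    for a, b in zip(alphas[:-1], alphas[1:]):
        betas.append(float(np.sqrt(a * b)))
    betas.append(np.inf)
    betas = sorted(set(betas))

    # cross-validated squared error per beta
    rng = np.random.default_rng(seed)
    folds = np.resize(np.arange(cv_folds), n)
    rng.shuffle(folds)
    sq_err = np.zeros((len(betas), n))
    for fold in range(cv_folds):
        test = folds == fold
        train = ~test
        sub = _grow(x, y, rows[train], min_split, min_leaf, 0, counter=[0])
        if not sub.is_leaf:
            _assign_crit_alphas(sub)
        for bi, beta in enumerate(betas):
            preds = np.array([_predict_at_beta(sub, x[r], beta) for r in rows[test]])
            sq_err[bi, test] = (y[test] - preds) ** 2
    cv_error = sq_err.mean(axis=1)
    cv_se = sq_err.std(axis=1, ddof=1) / np.sqrt(n)

    n_leaves = np.array([_leaves_at_beta(full, b) for b in betas])
    best = int(np.argmin(cv_error))
    threshold = cv_error[best] + cv_se[best]
    candidates = [i for i in range(len(betas)) if cv_error[i] <= threshold + 1e-12]
    selected = min(candidates, key=lambda i: (n_leaves[i], -betas[i]))
    selected_beta = betas[selected]

    _prune_at_beta(full, selected_beta)
    _finalize(full, x, predictors, total_sse)
    leaf_sse = _collect_leaf_sse(full)
    total_var = 100.0 * (total_sse - leaf_sse) / total_sse if total_sse > 0 else 0.0
    cv_table = pd.DataFrame(
        {"beta": betas, "n_leaves": n_leaves, "cv_error": cv_error, "cv_se": cv_se}
    )
    return TreeModel(full, predictors, total_var, cv_table, float(selected_beta))


def _collect_leaf_sse(node: TreeNode) -> float:
    if node.is_leaf:
        return node.sse
    return _collect_leaf_sse(node.left) + _collect_leaf_sse(node.right)


def build_driver_dataset(
    delta_d: pd.DataFrame,
    memberships: pd.DataFrame,
    std_coords: pd.DataFrame,
    fraction: str,
    comparison: str,
    life_forms: tuple[str, ...] | None = ("herb", "chamaephyte"),
) -> pd.DataFrame:
    """Assemble (plot, fraction) rows: response delta-D, predictors = mean
    standardized trait values of the fraction's members.

    ``memberships`` needs columns plot_id, species, status, life_form. When
    ``life_forms`` is given, only members of those life forms enter the trait
    means (and rows with no qualifying member are dropped).
    """
    resp = delta_d[
        (delta_d["comparison"] == comparison) & (delta_d["target"] == fraction)
    ].set_index("plot_id")["delta_d"]
    members = memberships[memberships["status"] == fraction]
    if life_forms is not None:
        members = members[members["life_form"].isin(life_forms)]
    rows = []
    for plot_id, grp in members.groupby("plot_id", sort=True):
        if plot_id not in resp.index:
            continue
        mean_traits = std_coords.loc[grp["species"]].mean(axis=0)
        row = {"plot_id": plot_id, "delta_d": resp.loc[plot_id]}
        row.update(mean_traits.to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot_id") if rows else pd.DataFrame()
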