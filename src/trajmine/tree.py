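"""Regression tree over concept membership explaining trajectory cost.

The filtered concepts overlap, so they cannot partition the cohort by
themselves. Recursive partitioning turns them into disjoint groups: each
concept becomes a boolean predictor (TRUE when the patient lies in its
extent) and a CART-style regression tree is grown on the per-patient total
trajectory cost. Splits are chosen by variance reduction

    ΔSSE = SSE(node) − SSE(members) − SSE(non-members)

and applied best-first: at each step the single best admissible split over
all current leaves is taken, so "k splits" always denotes the k globally
most informative ones. With boolean predictors each split is a membership
test, read directly as "has this morbidity profile / does not".

Generalisation error is estimated by k-fold cross-validation of the mean
squared prediction error as a function of the number of splits, reported
relative to the zero-split (cohort-mean) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from trajmine.fca import FormalConcept, support
from trajmine.trajectory import Trajectory


@dataclass
class MembershipMatrix:
    """Boolean patients × concepts design matrix with the cost response."""

    patients: list[str]
    concepts: list[FormalConcept]
    cells: np.ndarray  # bool, shape (n_patients, n_concepts)
    response: np.ndarray  # float, shape (n_patients,)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        self.response = np.asarray(self.response, dtype=float)
        if self.cells.shape != (len(self.patients), len(self.concepts)):
            raise ValueError("cells shape does not match patients × concepts")

    def degenerate_columns(self) -> np.ndarray:
        """Constant columns (e.g. the all-true top concept): never split on."""
        return np.all(self.cells == self.cells[:1, :], axis=0) if len(self.patients) else np.ones(len(self.concepts), bool)


@dataclass
class CostTreeNode:
    """A node of the cost tree: patient count, mean cost, optional split."""

    n: int
    mean_cost: float
    split_concept: FormalConcept | None = None
    child_in: "CostTreeNode | None" = None  # members of the split concept
    child_out: "CostTreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_concept is None

    def leaves(self) -> list["CostTreeNode"]:
        if self.is_leaf:
            return [self]
        return self.child_in.leaves() + self.child_out.leaves()

    def n_splits(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + self.child_in.n_splits() + self.child_out.n_splits()


def membership_matrix(
    filtered: list[FormalConcept],
    trajectories: list[Trajectory],
) -> MembershipMatrix:
    """Build the boolean design matrix from filtered concepts and costs."""
    patients = [t.patient_id for t in trajectories]
    costs = np.array([t.indicators.total_cost for t in trajectories], float)
    cells = np.zeros((len(patients), len(filtered)), bool)
    index = {pid: i for i, pid in enumerate(patients)}
    for j, concept in enumerate(filtered):
        for g in concept.extent:
            i = index.get(g)
            if i is not None:
                cells[i, j] = True
    return MembershipMatrix(patients, list(filtered), cells, costs)


def _sse(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    return float(np.sum((y - y.mean()) ** 2))


def _split_gains(
    rows: np.ndarray, matrix: MembershipMatrix, min_node: int
) -> np.ndarray:
    """SSE reduction of each predictor on the given node rows (vectorised).

    Inadmissible splits (a child below ``min_node`` or an empty side) get
    -inf.
    """
    X = matrix.cells[rows]
    y = matrix.response[rows]
    n = y.size
    n_in = X.sum(axis=0)
    n_out = n - n_in
    sum_in = X.T @ y
    sum_all = y.sum()
    gains = np.full(X.shape[1], -np.inf)
    ok = (n_in >= min_node) & (n_out >= min_node)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_in = sum_in[ok] / n_in[ok]
        mean_out = (sum_all - sum_in[ok]) / n_out[ok]
        gains[ok] = n_in[ok] * n_out[ok] / n * (mean_in - mean_out) ** 2
    return gains


def best_split(
    rows: np.ndarray,
    matrix: MembershipMatrix,
    min_node: int = 1,
    min_improvement: float = 0.0,
) -> tuple[int, float] | None:
    """Best predictor index and its SSE reduction on a node, or None.

    Ties break toward the predictor with larger concept support, then
    lexicographically smaller intent, then lower column index.
    """
    gains = _split_gains(rows, matrix, min_node)
    best = float(np.max(gains)) if gains.size else -np.inf
    if not np.isfinite(best) or best <= 0 or best < min_improvement:
        return None
    candidates = np.flatnonzero(np.isclose(gains, best, rtol=1e-12, atol=1e-9))
    j = min(
        candidates,
        key=lambda k: (-support(matrix.concepts[k]), matrix.concepts[k].intent, k),
    )
    return int(j), float(gains[j])


@dataclass
class _SplitEvent:
    """One applied split, in best-first order (for CV replay)."""

    node: CostTreeNode
    predictor: int
    gain: float


def _grow(
    matrix: MembershipMatrix,
    rows: np.ndarray,
    max_splits: int,
    min_node: int,
    min_improvement: float,
) -> tuple[CostTreeNode, list[_SplitEvent]]:
    y = matrix.response[rows]
    root = CostTreeNode(n=int(rows.size), mean_cost=float(y.mean()) if rows.size else 0.0)
    # frontier: (node, its rows, cached best split)
    frontier: list[tuple[CostTreeNode, np.ndarray, tuple[int, float] | None]] = [
        (root, rows, best_split(rows, matrix, min_node, min_improvement))
    ]
    events: list[_SplitEvent] = []
    while len(events) < max_splits:
        viable = [(i, f) for i, f in enumerate(frontier) if f[2] is not None]
        if not viable:
            break
        # global best split over all current leaves; stable among equal
        # gains: earliest leaf in the frontier wins
        i_best, (node, node_rows, (pred, gain)) = max(
            viable, key=lambda item: (item[1][2][1], -item[0])
        )
        mask = matrix.cells[node_rows, pred]
        rows_in, rows_out = node_rows[mask], node_rows[~mask]
        node.split_concept = matrix.concepts[pred]
        node.child_in = CostTreeNode(
            n=int(rows_in.size), mean_cost=float(matrix.response[rows_in].mean())
        )
        node.child_out = CostTreeNode(
            n=int(rows_out.size), mean_cost=float(matrix.response[rows_out].mean())
        )
        events.append(_SplitEvent(node, pred, gain))
        frontier.pop(i_best)
        for child, child_rows in ((node.child_in, rows_in), (node.child_out, rows_out)):
            frontier.append(
                (child, child_rows, best_split(child_rows, matrix, min_node, min_improvement))
            )
    return root, events


def grow_tree(
    matrix: MembershipMatrix,
    max_splits: int = 5,
    min_node: int = 7,
    min_improvement: float = 0.0,
) -> CostTreeNode:
    """Grow the cost tree best-first up to ``max_splits`` splits."""
    if len(matrix.patients) == 0:
        raise ValueError("empty membership matrix")
    rows = np.arange(len(matrix.patients))
    root, _ = _grow(matrix, rows, max_splits, min_node, min_improvement)
    return root


def predict(root: CostTreeNode, matrix: MembershipMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """Predicted mean cost for each row of the matrix."""
    if rows is None:
        rows = np.arange(len(matrix.patients))
    concept_col = {id(c): j for j, c in enumerate(matrix.concepts)}
    out = np.empty(rows.size, float)
    for k, i in enumerate(rows):
        node = root
        while not node.is_leaf:
            j = concept_col.get(id(node.split_concept))
            if j is None:  # concept object from another matrix: match by intent
                j = next(
                    jj
                    for jj, c in enumerate(matrix.concepts)
                    if c.intent == node.split_concept.intent
                )
            node = node.child_in if matrix.cells[i, j] else node.child_out
        out[k] = node.mean_cost
    return out


def training_sse_curve(matrix: MembershipMatrix, max_splits: int, min_node: int = 7) -> np.ndarray:
    """Training SSE after 0..max_splits best-first splits (non-increasing)."""
    rows = np.arange(len(matrix.patients))
    _, events = _grow(matrix, rows, max_splits, min_node, 0.0)
    sse = [_sse(matrix.response)]
    for ev in events:
        sse.append(sse[-1] - ev.gain)
    while len(sse) < max_splits + 1:
        sse.append(sse[-1])
    return np.array(sse)


def cv_mse(
    matrix: MembershipMatrix,
    max_splits: int = 8,
    k_folds: int = 10,
    seed: int = 0,
    min_node: int = 7,
) -> dict[str, np.ndarray]:
    """k-fold cross-validated MSE for each split count 0..max_splits.

    Folds are a seeded random partition. Returns ``{"mse": ...,
    "relative": ...}`` where ``relative`` is MSE normalised by the
    zero-split MSE (prediction by the training mean).
    """
    n = len(matrix.patients)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > n:
        raise ValueError("more folds than patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    sq_err = np.zeros(max_splits + 1)
    for fold in folds:
        test = np.sort(fold)
        train = np.setdiff1d(perm, fold)
        y_test = matrix.response[test]
        root, events = _grow(matrix, train, max_splits, min_node, 0.0)
        # replay the best-first split sequence on the test rows: after m
        # splits the model is the tree truncated to the first m events
        leaf_of_node = {id(root): 0}  # tree node -> leaf id
        leaf_mean = {0: float(matrix.response[train].mean())}
        row_leaf = np.zeros(test.size, dtype=int)
        next_leaf = 1
        err = float(np.sum((y_test - leaf_mean[0]) ** 2))
        sq_err[0] += err
        for m, ev in enumerate(events, start=1):
            parent_leaf = leaf_of_node.pop(id(ev.node))
            in_leaf, out_leaf = next_leaf, next_leaf + 1
            next_leaf += 2
            leaf_of_node[id(ev.node.child_in)] = in_leaf
            leaf_of_node[id(ev.node.child_out)] = out_leaf
            leaf_mean[in_leaf] = ev.node.child_in.mean_cost
            leaf_mean[out_leaf] = ev.node.child_out.mean_cost
            affected = row_leaf == parent_leaf
            member = matrix.cells[test, ev.predictor]
            row_leaf[affected & member] = in_leaf
            row_leaf[affected & ~member] = out_leaf
            pred = np.array([leaf_mean[l] for l in row_leaf])
            err = float(np.sum((y_test - pred) ** 2))
            sq_err[m] += err
        # no further admissible splits: error stays at its last value
        sq_err[len(events) + 1 :] += err
    mse = sq_err / n
    relative = mse / mse[0] if mse[0] > 0 else np.ones_like(mse)
    return {"mse": mse, "relative": relative}


def tree_to_dict(node: CostTreeNode) -> dict:
    """JSON-friendly nested representation of the tree."""
    out = {"n": node.n, "mean_cost": round(node.mean_cost, 2)}
    if not node.is_leaf:
        out["split"] = list(node.split_concept.intent)
        out["in"] = tree_to_dict(node.child_in)
        out["out"] = tree_to_dict(node.child_out)
    return out


def tree_to_dot(root: CostTreeNode) -> str:
    """DOT rendering: nodes carry n and mean cost, membership branch on top."""
    lines = ["digraph costtree {", "  node [shape=box];"]
    counter = [0]

    def visit(node: CostTreeNode) -> int:
        my_id = counter[0]
        counter[0] += 1
        lines.append(f'  n{my_id} [label="n={node.n}\\nmean={node.mean_cost:.0f}"];')
        if not node.is_leaf:
            intent = ",".join(node.split_concept.intent) or "∅"
            in_id = visit(node.child_in)
            out_id = visit(node.child_out)
            lines.append(f'  n{my_id} -> n{in_id} [label="({intent})"];')
            lines.append(f'  n{my_id} -> n{out_id} [label="not ({intent})"];')
        return my_id

    visit(root)
    lines.append("}")
    return "\n".join(lines)


__all__ = [
    "MembershipMatrix",
    "CostTreeNode",
    "membership_matrix",
    "best_split",
    "grow_tree",
    "predict",
    "training_sse_curve",
    "cv_mse",
    "tree_to_dict",
    "tree_to_dot",
]
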