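"""Conditional logistic regression trees.

A tree models the covariate effect as a step function
f(z) = delta_1 I(z in S_1) + ... + delta_t I(z in S_t) over terminal
nodes S_1..S_t, embedded in the conditional logistic model
logit P(y=1) = alpha_i + x*beta + f(z) (the dedicated exposure term
x*beta is optional).  Growth is global best-first: starting from the
root (strata intercepts plus, optionally, the exposure effect), each
iteration draws a fresh random subset of mtry covariates, scores every
(terminal node, variable, threshold) candidate by the gain in the
ridge-penalized conditional log-likelihood, and accepts the single best
split if its gain exceeds epsilon.  All node effects delta and beta are
refit jointly after every accepted split.

Candidate scoring comes in two flavours:

``exact``
    every candidate is scored by a full joint Newton refit of
    (delta, beta), warm-started at the incumbent fit;
``fast``
    candidates are ranked by optimizing only the two prospective child
    effects with all other coefficients held fixed (a 2-parameter
    Newton, vectorized across all thresholds of a variable); the
    winning candidate is then refit jointly, and acceptance is decided
    on its exact gain.

The terminal-node indicators sum to one, so the conditional likelihood
is invariant to a constant shift of all delta; the ridge makes the
reported coefficients the minimum-norm representative, and predictions
are unaffected either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .matched_data import MatchedDataset
from .cond_likelihood import PenaltyConfig, fit_clr, cond_loglik

__all__ = [
    "SplitRule",
    "TreeNode",
    "TreeControl",
    "FittedTree",
    "candidate_splits",
    "grow_tree",
    "predict_tree",
    "prune_bic",
]


@dataclass(frozen=True)
class SplitRule:
    """Binary split 'variable <= threshold' (left) vs '>' (right).

    Thresholds follow the midpoint convention: they lie strictly between
    two observed values of the variable.
    """

    var_index: int
    var_name: str
    threshold: float


@dataclass
class TreeNode:
    """Internal node (rule + children) or terminal node (index + effect)."""

    rule: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    node_id: int | None = None
    delta: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.rule is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.node_id, "delta": self.delta}
        return {
            "rule": {
                "var": self.rule.var_name,
                "index": self.rule.var_index,
                "threshold": self.rule.threshold,
            },
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "TreeNode":
        if "leaf" in d:
            return TreeNode(node_id=d["leaf"], delta=d["delta"])
        r = d["rule"]
        return TreeNode(
            rule=SplitRule(r["index"], r["var"], r["threshold"]),
            left=TreeNode.from_dict(d["left"]),
            right=TreeNode.from_dict(d["right"]),
        )


@dataclass
class TreeControl:
    """Growth controls for one conditional logistic regression tree.

    Parameters
    ----------
    mtry : int or None
        Number of covariates sampled per split search (None = all p).
    max_depth : int or None
        Maximum number of splits on any root-to-leaf path (None = unlimited).
    min_split_n : int or None
        Minimum rows in a node for it to be eligible for splitting.
        None resolves to 20 matched sets' worth of rows (20 times the
        mean stratum size): each stratum contributes a single
        conditional-likelihood term, so node-size guards count matched
        sets rather than rows — deep trees sized in rows alone drive the
        per-tree exposure estimate into the sparse-strata bias of
        conditional logit.
    min_bucket_n : int or None
        Minimum rows in any resulting child node; None resolves to 7
        matched sets' worth of rows.
    epsilon : float
        Minimum penalized log-likelihood gain to accept a split.
    lam : float
        Ridge weight applied to all coefficients (keeps the optimum
        finite under perfect within-stratum separation).
    penalize_beta : bool
        Whether the ridge also applies to the exposure effect.
    split_eval : {"exact", "fast"}
        Candidate scoring mode (see module docstring).
    mtry_per_node : bool
        Draw a separate mtry subset for every node within an iteration
        instead of one subset shared by all nodes.
    """

    mtry: int | None = None
    max_depth: int | None = None
    min_split_n: int | None = None
    min_bucket_n: int | None = None
    epsilon: float = 1e-8
    lam: float = 1e-20
    penalize_beta: bool = True
    split_eval: str = "exact"
    mtry_per_node: bool = False
    seed: int | None = None

    def resolved(self, data) -> "TreeControl":
        """Fill size defaults from the data's mean stratum size."""
        from dataclasses import replace
        mean_m = data.n_rows / data.n
        out = self
        if out.min_split_n is None:
            out = replace(out, min_split_n=int(round(20 * mean_m)))
        if out.min_bucket_n is None:
            out = replace(out, min_bucket_n=int(round(7 * mean_m)))
        return out


@dataclass
class FittedTree:
    """A grown (optionally pruned) conditional logistic regression tree."""

    root: TreeNode
    beta_hat: float | None
    var_names: list[str]
    n_leaves: int
    trace: list[float]                       # penalized log-lik per growth step
    history: list[tuple[int, int, float]]    # (leaf id split, var index, threshold)
    has_offset: bool = False
    converged: bool = True

    # ------------------------------------------------------------------
    def apply(self, Z: np.ndarray) -> np.ndarray:
        """Terminal-node id for each row of Z."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        out = np.empty(Z.shape[0], dtype=np.intp)

        def recurse(node, rows):
            if node.is_leaf:
                out[rows] = node.node_id
                return
            go_left = Z[rows, node.rule.var_index] <= node.rule.threshold
            recurse(node.left, rows[go_left])
            recurse(node.right, rows[~go_left])

        recurse(self.root, np.arange(Z.shape[0]))
        return out

    def leaf_deltas(self) -> np.ndarray:
        deltas = {}

        def recurse(node):
            if node.is_leaf:
                deltas[node.node_id] = node.delta
            else:
                recurse(node.left)
                recurse(node.right)

        recurse(self.root)
        return np.array([deltas[i] for i in range(len(deltas))])

    def predict(
        self,
        Z: np.ndarray,
        x: np.ndarray | None = None,
        offset: np.ndarray | None = None,
    ) -> np.ndarray:
        """Linear-predictor contribution x*beta + f(z) (+ offset) per row."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != len(self.var_names):
            raise ValueError(
                f"expected {len(self.var_names)} covariate columns, "
                f"got {Z.shape[1]}"
            )
        eta = self.leaf_deltas()[self.apply(Z)]
        if self.beta_hat is not None:
            if x is None:
                raise ValueError("tree has an exposure effect but x is missing")
            eta = eta + np.asarray(x, dtype=float) * self.beta_hat
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return eta

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "root": self.root.to_dict(),
            "beta_hat": self.beta_hat,
            "var_names": list(self.var_names),
            "n_leaves": self.n_leaves,
            "trace": list(self.trace),
            "history": [list(h) for h in self.history],
            "has_offset": self.has_offset,
            "converged": self.converged,
        }

    @staticmethod
    def from_dict(d: dict) -> "FittedTree":
        return FittedTree(
            root=TreeNode.from_dict(d["root"]),
            beta_hat=d["beta_hat"],
            var_names=list(d["var_names"]),
            n_leaves=d["n_leaves"],
            trace=list(d["trace"]),
            history=[tuple(h) for h in d["history"]],
            has_offset=d.get("has_offset", False),
            converged=d.get("converged", True),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def render(self) -> str:
        """Indented text dendrogram (rules and terminal-node effects)."""
        lines = []
        if self.beta_hat is not None:
            lines.append(f"exposure effect beta = {self.beta_hat:+.4f}")

        def recurse(node, indent, label):
            pad = "  " * indent
            if node.is_leaf:
                lines.append(
                    f"{pad}{label}-> S{node.node_id + 1}: "
                    f"delta = {node.delta:+.4f}"
                )
            else:
                lines.append(
                    f"{pad}{label}{node.rule.var_name} <= "
                    f"{node.rule.threshold:g}?"
                )
                recurse(node.left, indent + 1, "yes: ")
                recurse(node.right, indent + 1, "no:  ")

        recurse(self.root, 0, "")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# Candidate enumeration
# ----------------------------------------------------------------------

def candidate_splits(
    z: np.ndarray,
    min_bucket_n: int = 1,
) -> np.ndarray:
    """Admissible thresholds for one variable within one node.

    Midpoints between consecutive distinct observed values, excluding
    thresholds that would leave fewer than ``min_bucket_n`` rows in
    either child.  A binary variable with both levels present yields the
    single candidate 0.5.
    """
    z = np.asarray(z, dtype=float)
    u, counts = np.unique(z, return_counts=True)
    if u.size < 2:
        return np.empty(0)
    mids = 0.5 * (u[:-1] + u[1:])
    left = np.cumsum(counts)[:-1]
    ok = (left >= min_bucket_n) & (z.size - left >= min_bucket_n)
    return mids[ok]


# ----------------------------------------------------------------------
# Growth machinery
# ----------------------------------------------------------------------

class _GrowState:
    """Mutable bookkeeping during best-first growth."""

    def __init__(self, data: MatchedDataset, exposure: bool, offset, control):
        self.data = data
        self.exposure = exposure
        self.offset = (
            np.zeros(data.n_rows) if offset is None
            else np.asarray(offset, dtype=float)
        )
        self.control = control
        self.leaf_assign = np.zeros(data.n_rows, dtype=np.intp)
        self.leaf_depth = [0]
        self.nodes = [TreeNode(node_id=0)]     # leaf-id -> TreeNode
        self.root = self.nodes[0]
        self.theta = None                       # (deltas..., [beta])
        self.loglik = -np.inf
        self.history: list[tuple[int, int, float]] = []

    @property
    def n_leaves(self) -> int:
        return len(self.nodes)

    def design(self) -> np.ndarray:
        t = self.n_leaves
        D = np.zeros((self.data.n_rows, t + (1 if self.exposure else 0)))
        D[np.arange(self.data.n_rows), self.leaf_assign] = 1.0
        if self.exposure:
            D[:, t] = self.data.x
        return D

    def penalty(self, d: int) -> PenaltyConfig:
        mask = np.ones(d)
        if self.exposure and not self.control.penalize_beta:
            mask[-1] = 0.0
        return PenaltyConfig(lam=self.control.lam, mask=mask)

    def refit(self, init=None):
        D = self.design()
        fit = fit_clr(
            self.data, D, penalty=self.penalty(D.shape[1]),
            offset=self.offset, init=init,
        )
        return fit

    def eta(self) -> np.ndarray:
        t = self.n_leaves
        eta = self.theta[self.leaf_assign] + self.offset
        if self.exposure:
            eta = eta + self.data.x * self.theta[t]
        return eta

    def split_design(self, leaf: int, go_left: np.ndarray) -> np.ndarray:
        """Design with column `leaf` split into (left keeps id, right appended)."""
        t = self.n_leaves
        D = np.zeros((self.data.n_rows, t + 1 + (1 if self.exposure else 0)))
        assign = self.leaf_assign.copy()
        node_rows = assign == leaf
        assign[node_rows & ~go_left] = t
        D[np.arange(self.data.n_rows), assign] = 1.0
        if self.exposure:
            D[:, t + 1] = self.data.x
        return D

    def warm_start(self, leaf: int, dl: float, dr: float) -> np.ndarray:
        t = self.n_leaves
        init = np.empty(t + 1 + (1 if self.exposure else 0))
        init[:t] = self.theta[:t]
        init[leaf] = dl
        init[t] = dr
        if self.exposure:
            init[t + 1] = self.theta[t]
        return init

    def set_theta(self, theta: np.ndarray, loglik: float):
        """Install a fitted coefficient vector, re-centering the leaf
        effects to mean zero (the conditional likelihood is invariant to
        a common shift of all delta, so this changes no prediction and
        keeps coefficients away from the divergence guard)."""
        t = self.n_leaves
        theta = theta.copy()
        theta[:t] -= theta[:t].mean()
        self.theta = theta
        self.loglik = loglik

    def accept(self, leaf: int, var: int, threshold: float, fit):
        self.history.append((leaf, var, float(threshold)))
        node = self.nodes[leaf]
        t = self.n_leaves
        rule = SplitRule(var, self.data.variables[var].name, threshold)
        left = TreeNode(node_id=leaf)
        right = TreeNode(node_id=t)
        node.rule, node.left, node.right = rule, left, right
        node.node_id = None
        self.nodes[leaf] = left
        self.nodes.append(right)
        depth = self.leaf_depth[leaf] + 1
        self.leaf_depth[leaf] = depth
        self.leaf_depth.append(depth)
        node_rows = self.leaf_assign == leaf
        go_right = node_rows & (self.data.Z[:, var] > threshold)
        self.leaf_assign[go_right] = t
        self.set_theta(fit.coef, fit.loglik)


def _fast_score_node_var(state: _GrowState, leaf: int, var: int, e, E, newton_iter=15):
    """Best threshold for (node, variable) holding all other effects fixed.

    Optimizes only the two prospective child effects, vectorized over all
    admissible thresholds.  ``e`` are per-row exp(eta - stratum max) at
    the incumbent fit; ``E`` their per-stratum sums.  Returns
    (gain, threshold, delta_left, delta_right) or None.
    """
    data = state.data
    ctrl = state.control
    node_mask = state.leaf_assign == leaf
    idx = np.flatnonzero(node_mask)
    z = data.Z[idx, var]
    u, lvl, counts = np.unique(z, return_inverse=True, return_counts=True)
    if u.size < 2:
        return None
    left_counts = np.cumsum(counts)[:-1]
    valid = (left_counts >= ctrl.min_bucket_n) & (
        idx.size - left_counts >= ctrl.min_bucket_n
    )
    if not valid.any():
        return None
    thresholds = 0.5 * (u[:-1] + u[1:])[valid]
    T = thresholds.size

    sc = data.stratum_codes[idx]
    su, sidx = np.unique(sc, return_inverse=True)
    S = su.size
    b = e[idx]
    W = np.zeros((u.size, S))
    np.add.at(W, (lvl, sidx), b)
    node_sum = W.sum(axis=0)
    A = np.cumsum(W, axis=0)[:-1][valid]          # (T, S) left weight sums
    B = node_sum[None, :] - A
    R = E[su] - node_sum                           # out-of-node weight per stratum

    case_rows = data.case_rows[su]
    case_in = node_mask[case_rows]
    zcase = data.Z[case_rows, var]
    case_left = case_in[None, :] & (zcase[None, :] <= thresholds[:, None])
    n_case = case_in.sum()
    nL = case_left.sum(axis=1).astype(float)
    nR = float(n_case) - nL

    dL = np.zeros(T)
    dR = np.zeros(T)
    for _ in range(newton_iter):
        eL = np.exp(dL)[:, None] * A
        eR = np.exp(dR)[:, None] * B
        den = R[None, :] + eL + eR
        pA = eL / den
        pB = eR / den
        gL = nL - pA.sum(axis=1)
        gR = nR - pB.sum(axis=1)
        if max(np.abs(gL).max(), np.abs(gR).max()) < 1e-7:
            break
        iLL = (pA * (1.0 - pA)).sum(axis=1) + 1e-10
        iRR = (pB * (1.0 - pB)).sum(axis=1) + 1e-10
        iLR = -(pA * pB).sum(axis=1)
        det = iLL * iRR - iLR * iLR
        det = np.where(det > 1e-12, det, det + 1e-8)
        stepL = (iRR * gL - iLR * gR) / det
        stepR = (iLL * gR - iLR * gL) / det
        dL = np.clip(dL + np.clip(stepL, -4, 4), -30, 30)
        dR = np.clip(dR + np.clip(stepR, -4, 4), -30, 30)

    den = R[None, :] + np.exp(dL)[:, None] * A + np.exp(dR)[:, None] * B
    gains = nL * dL + nR * dR - np.log(den / E[su][None, :]).sum(axis=1)
    best = int(np.argmax(gains))
    base = state.theta[leaf]
    return (
        float(gains[best]),
        float(thresholds[best]),
        base + float(dL[best]),
        base + float(dR[best]),
    )


def _exact_score_node_var(state: _GrowState, leaf: int, var: int):
    """Best threshold for (node, variable) by full joint refit per candidate."""
    data = state.data
    ctrl = state.control
    idx = np.flatnonzero(state.leaf_assign == leaf)
    thresholds = candidate_splits(data.Z[idx, var], ctrl.min_bucket_n)
    best = None
    for c in thresholds:
        go_left = data.Z[:, var] <= c
        D = state.split_design(leaf, go_left)
        init = state.warm_start(leaf, state.theta[leaf], state.theta[leaf])
        fit = fit_clr(
            data, D, penalty=state.penalty(D.shape[1]),
            offset=state.offset, init=init, max_iter=50,
        )
        gain = fit.loglik - state.loglik
        if best is None or gain > best[0]:
            t = state.n_leaves
            best = (gain, float(c), float(fit.coef[leaf]), float(fit.coef[t]))
    return best


def grow_tree(
    data: MatchedDataset,
    control: TreeControl | None = None,
    exposure: bool = True,
    offset: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> FittedTree:
    """Grow one conditional logistic regression tree (unpruned).

    The tree starts from the strata intercepts (and the exposure effect
    when ``exposure`` is set) and accepts one globally best split per
    iteration until no admissible split improves the penalized
    conditional log-likelihood by more than epsilon.  Deterministic given
    ``control.seed`` (or an explicit ``rng``).
    """
    control = (control or TreeControl()).resolved(data)
    if exposure and data.x is None:
        raise ValueError("exposure=True but dataset has no exposure column")
    if rng is None:
        rng = np.random.default_rng(control.seed)
    p = data.p
    mtry = p if control.mtry is None else min(control.mtry, p)

    state = _GrowState(data, exposure, offset, control)
    fit = state.refit()
    state.set_theta(fit.coef, fit.loglik)
    trace = [fit.loglik]
    converged = fit.converged

    while True:
        eligible = [
            k for k in range(state.n_leaves)
            if (state.leaf_assign == k).sum() >= control.min_split_n
            and (control.max_depth is None
                 or state.leaf_depth[k] < control.max_depth)
        ]
        if not eligible:
            break
        shared_vars = None
        if not control.mtry_per_node:
            shared_vars = np.sort(rng.choice(p, size=mtry, replace=False))
        if control.split_eval == "fast":
            eta = state.eta()
            shift = np.repeat(
                np.maximum.reduceat(eta, data.stratum_starts), data.m
            )
            e = np.exp(eta - shift)
            E = np.add.reduceat(e, data.stratum_starts)
        best = None                      # (gain, leaf, var, threshold, dl, dr)
        for k in eligible:
            vars_k = shared_vars
            if vars_k is None:
                vars_k = np.sort(rng.choice(p, size=mtry, replace=False))
            for v in vars_k:
                if control.split_eval == "fast":
                    cand = _fast_score_node_var(state, k, int(v), e, E)
                else:
                    cand = _exact_score_node_var(state, k, int(v))
                if cand is None:
                    continue
                gain, c, dl, dr = cand
                if best is None or gain > best[0]:
                    best = (gain, k, int(v), c, dl, dr)
        if best is None:
            break
        _, leaf, var, c, dl, dr = best
        # exact acceptance: full joint refit of the winning candidate
        go_left = data.Z[:, var] <= c
        D = state.split_design(leaf, go_left)
        fit = fit_clr(
            data, D, penalty=state.penalty(D.shape[1]),
            offset=state.offset, init=state.warm_start(leaf, dl, dr),
        )
        if fit.loglik - state.loglik <= control.epsilon:
            break
        state.accept(leaf, var, c, fit)
        trace.append(fit.loglik)
        converged = converged and fit.converged

    # write fitted effects into the tree
    for k, node in enumerate(state.nodes):
        node.delta = float(state.theta[k])
    beta = float(state.theta[state.n_leaves]) if exposure else None
    return FittedTree(
        root=state.root,
        beta_hat=beta,
        var_names=data.variable_names,
        n_leaves=state.n_leaves,
        trace=trace,
        history=list(state.history),
        has_offset=offset is not None,
        converged=converged,
    )


def predict_tree(
    tree: FittedTree,
    Z: np.ndarray,
    x: np.ndarray | None = None,
    offset: np.ndarray | None = None,
) -> np.ndarray:
    """Linear-predictor contribution of a fitted tree for new rows."""
    return tree.predict(Z, x=x, offset=offset)


# ----------------------------------------------------------------------
# BIC pruning (standalone trees only; never inside forests)
# ----------------------------------------------------------------------

def tree_bic(tree: FittedTree, data: MatchedDataset,
             offset: np.ndarray | None = None) -> float:
    """BIC = -2 * conditional log-lik + df * log(n strata).

    df = (number of terminal nodes - 1) + 1 if a dedicated exposure
    effect is estimated.  The node effects contribute t - 1 free
    parameters because the conditional likelihood is invariant to a
    common shift of all delta.
    """
    eta = tree.predict(data.Z, x=data.x if tree.beta_hat is not None else None,
                       offset=offset)
    df = (tree.n_leaves - 1) + (1 if tree.beta_hat is not None else 0)
    return -2.0 * cond_loglik(data, eta) + df * np.log(data.n)


def prune_bic(
    tree: FittedTree,
    data: MatchedDataset,
    control: TreeControl | None = None,
    offset: np.ndarray | None = None,
) -> FittedTree:
    """Prune a grown tree to the BIC-minimal prefix of its growth sequence.

    Each prefix of the accepted-split sequence is refit jointly and
    scored by BIC; the smallest size attaining the minimum is returned
    (refit at that size).
    """
    control = (control or TreeControl()).resolved(data)
    exposure = tree.beta_hat is not None
    best_size, best_bic, best_state = None, np.inf, None
    state = _GrowState(data, exposure, offset, control)
    fit = state.refit()
    state.set_theta(fit.coef, fit.loglik)
    for size in range(len(tree.history) + 1):
        if size > 0:
            leaf, var, c = tree.history[size - 1]
            go_left = data.Z[:, var] <= c
            D = state.split_design(leaf, go_left)
            fit = fit_clr(
                data, D, penalty=state.penalty(D.shape[1]),
                offset=state.offset,
                init=state.warm_start(leaf, state.theta[leaf], state.theta[leaf]),
            )
            state.accept(leaf, var, c, fit)
        eta = state.eta()
        df = (state.n_leaves - 1) + (1 if exposure else 0)
        bic = -2.0 * cond_loglik(data, eta) + df * np.log(data.n)
        if bic < best_bic - 1e-12:
            best_bic = bic
            best_size = size
            for k, node in enumerate(state.nodes):
                node.delta = float(state.theta[k])
            best_state = (
                _copy_tree(state.root),
                float(state.theta[state.n_leaves]) if exposure else None,
                state.n_leaves,
            )
    root, beta, n_leaves = best_state
    return FittedTree(
        root=root,
        beta_hat=beta,
        var_names=tree.var_names,
        n_leaves=n_leaves,
        trace=tree.trace[: best_size + 1],
        history=tree.history[:best_size],
        has_offset=tree.has_offset,
        converged=tree.converged,
    )


def _copy_tree(node: TreeNode) -> TreeNode:
    if node.is_leaf:
        return TreeNode(node_id=node.node_id, delta=node.delta)
    return TreeNode(
        rule=node.rule,
        left=_copy_tree(node.left),
        right=_copy_tree(node.right),
    )
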