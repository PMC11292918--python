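"""Conditional logistic regression forests.

The ensemble draws stratum-level resamples of the training data (63.2%
subsamples without replacement by default, or n-out-of-n bootstrap),
grows one unpruned conditional logistic regression tree per resample
with mtry split-variable randomization, and aggregates by averaging:
per-row linear predictors for prediction, and per-tree exposure-effect
estimates for the final beta.

Optionally a linear offset is included: a CLR on the full training data
is fitted first, and the linear covariate fit z' gamma (exposure term
excluded) is passed to every tree as a fixed per-row offset, so trees
only model what the linear fit leaves unexplained.

mtry can be tuned internally: every value in {2..p} is scored by the
mean out-of-bag predictive conditional likelihood of a small forest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .matched_data import (
    MatchedDataset,
    StratumPartition,
    draw_inbag,
)
from .cond_likelihood import PenaltyConfig, fit_clr_model, stratum_probs
from .clogit_tree import FittedTree, TreeControl, grow_tree

__all__ = [
    "ForestControl",
    "ForestModel",
    "fit_forest",
    "predict_forest",
    "oob_pred_cond_lik",
    "tune_mtry",
]

MODEL_SCHEMA = "clogitforest-model-v1"


@dataclass
class ForestControl:
    """Configuration of a conditional logistic regression forest.

    Parameters
    ----------
    ntree : int
        Number of trees (default 500).
    mtry : int or "tune"
        Covariates sampled per split search; "tune" selects among 2..p
        by out-of-bag predictive conditional likelihood.
    sampling : {"subsample", "bootstrap"}
        Stratum-level resampling scheme.  ``subsample`` draws
        round(0.632 n) strata without replacement; ``bootstrap`` draws n
        strata with replacement (a stratum drawn twice contributes its
        likelihood term once per draw).
    tree : TreeControl
        Base-learner controls.  Trees inside the forest are never
        pruned; the minimum-node-size controls still apply.  Base
        learners default to the "fast" split scorer (candidate ranking
        by the two child effects, exact joint-refit acceptance), which
        makes ensembles of hundreds of trees tractable.
    offset : {"none", "linear"}
        Whether to include the linear CLR covariate fit (exposure
        excluded) as a fixed offset under every tree.
    exposure : bool
        Model a dedicated linear exposure effect in every tree.
    seed : int
        Master seed; one independent substream is spawned per tree
        index, so results are identical for any worker count.
    n_jobs : int
        Parallel workers for tree growth.
    ntree_tune : int
        Trees per candidate during mtry tuning.
    """

    ntree: int = 500
    mtry: int | str | None = None
    sampling: str = "subsample"
    tree: TreeControl = field(
        default_factory=lambda: TreeControl(split_eval="fast")
    )
    offset: str = "none"
    exposure: bool = True
    seed: int = 0
    n_jobs: int = 1
    ntree_tune: int = 50

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["tree"] = self.tree.__dict__.copy()
        return d

    @staticmethod
    def from_dict(d: dict) -> "ForestControl":
        d = dict(d)
        d["tree"] = TreeControl(**d["tree"])
        return ForestControl(**d)


@dataclass
class ForestModel:
    """A fitted conditional logistic regression forest."""

    trees: list[FittedTree]
    inbag: list[StratumPartition]
    control: ForestControl
    var_names: list[str]
    mtry_used: int
    offset_gamma: np.ndarray | None = None   # linear-offset coefficients

    @property
    def ntree(self) -> int:
        return len(self.trees)

    @property
    def beta_bar(self) -> float | None:
        """Averaged exposure effect: arithmetic mean of per-tree beta."""
        betas = [t.beta_hat for t in self.trees]
        if any(b is None for b in betas):
            return None
        return float(np.mean(betas))

    def offset_for(self, Z: np.ndarray) -> np.ndarray:
        if self.offset_gamma is None:
            return np.zeros(np.atleast_2d(Z).shape[0])
        return np.atleast_2d(Z) @ self.offset_gamma

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": MODEL_SCHEMA,
            "control": self.control.to_dict(),
            "var_names": list(self.var_names),
            "mtry_used": self.mtry_used,
            "offset_gamma": (
                None if self.offset_gamma is None
                else [float(g) for g in self.offset_gamma]
            ),
            "beta_bar": self.beta_bar,
            "inbag": [[int(s) for s in ib.inbag] for ib in self.inbag],
            "n_strata": self.inbag[0].n if self.inbag else 0,
            "trees": [t.to_dict() for t in self.trees],
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @staticmethod
    def from_dict(d: dict) -> "ForestModel":
        if d.get("schema") != MODEL_SCHEMA:
            raise ValueError(
                f"unsupported model schema {d.get('schema')!r}; "
                f"expected {MODEL_SCHEMA!r}"
            )
        n = d["n_strata"]
        return ForestModel(
            trees=[FittedTree.from_dict(t) for t in d["trees"]],
            inbag=[
                StratumPartition(n=n, inbag=np.asarray(ib, dtype=np.intp))
                for ib in d["inbag"]
            ],
            control=ForestControl.from_dict(d["control"]),
            var_names=list(d["var_names"]),
            mtry_used=d["mtry_used"],
            offset_gamma=(
                None if d["offset_gamma"] is None
                else np.asarray(d["offset_gamma"], dtype=float)
            ),
        )

    @staticmethod
    def from_json(path_or_str) -> "ForestModel":
        try:
            with open(path_or_str) as fh:
                d = json.load(fh)
        except (OSError, TypeError):
            d = json.loads(path_or_str)
        return ForestModel.from_dict(d)


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

def _grow_one(data, control, offset, inbag, seed_seq):
    rng = np.random.default_rng(seed_seq)
    sub = data.subset(inbag.inbag)
    sub_offset = None
    if offset is not None:
        rows = np.concatenate([
            np.arange(data.stratum_starts[s], data.stratum_starts[s] + data.m[s])
            for s in inbag.inbag
        ])
        sub_offset = offset[rows]
    return grow_tree(sub, control.tree, exposure=control.exposure,
                     offset=sub_offset, rng=rng)


def fit_forest(
    data: MatchedDataset,
    control: ForestControl | None = None,
    identity_sample: bool = False,
) -> ForestModel:
    """Fit a conditional logistic regression forest.

    ``identity_sample=True`` replaces resampling by the full training
    data for every tree (useful to check the degenerate single-tree
    forest against a directly grown tree).  Deterministic given
    ``control.seed`` regardless of ``n_jobs``.
    """
    control = control or ForestControl()
    if control.exposure and data.x is None:
        raise ValueError("exposure forest requires an exposure column")

    offset = None
    offset_gamma = None
    if control.offset == "linear":
        clr = fit_clr_model(
            data, exposure=control.exposure, covariates=True,
            penalty=PenaltyConfig(lam=control.tree.lam),
        )
        offset_gamma = clr.gamma_hat.copy()
        offset = data.Z @ offset_gamma
    elif control.offset != "none":
        raise ValueError(f"unknown offset mode {control.offset!r}")

    mtry = control.mtry
    if mtry == "tune":
        mtry = tune_mtry(data, control, offset=offset)
    if mtry is None:
        mtry = data.p
    mtry = int(min(max(mtry, 1), data.p))
    tree_control = replace(control.tree, mtry=mtry)
    run = replace(control, tree=tree_control)

    ss = np.random.SeedSequence(control.seed)
    seeds = ss.spawn(2 * control.ntree)
    inbags = []
    for b in range(control.ntree):
        if identity_sample:
            inbags.append(
                StratumPartition(n=data.n, inbag=np.arange(data.n))
            )
        else:
            inbags.append(draw_inbag(
                data, mode=control.sampling,
                seed=np.random.default_rng(seeds[2 * b]),
            ))

    jobs = (
        delayed(_grow_one)(data, run, offset, inbags[b], seeds[2 * b + 1])
        for b in range(control.ntree)
    )
    trees = Parallel(n_jobs=control.n_jobs)(jobs)
    for b, tree in enumerate(trees):
        if tree is None:
            raise RuntimeError(f"tree {b} failed to fit")
    return ForestModel(
        trees=list(trees),
        inbag=inbags,
        control=control,
        var_names=data.variable_names,
        mtry_used=mtry,
        offset_gamma=offset_gamma,
    )


# ----------------------------------------------------------------------
# Prediction and OOB machinery
# ----------------------------------------------------------------------

def predict_forest(
    model: ForestModel,
    data: MatchedDataset,
    scope: str = "all_trees",
    aggregate: str = "linear",
) -> np.ndarray:
    """Per-row forest prediction on the log-odds scale.

    ``scope="all_trees"`` averages every tree's linear predictor;
    ``scope="oob_only"`` (training data only) averages, per stratum,
    only trees whose in-bag sample excludes that stratum — rows of
    strata that are in-bag for every tree are returned as NaN.
    ``aggregate="prob"`` averages per-stratum conditional probabilities
    instead of linear predictors (then the return value is per-stratum
    probabilities under ``oob_only``; see :func:`oob_pred_cond_lik`).
    """
    if scope not in ("all_trees", "oob_only"):
        raise ValueError(f"unknown scope {scope!r}")
    x = data.x if model.control.exposure else None
    base_offset = model.offset_for(data.Z)

    if scope == "all_trees":
        eta = np.zeros(data.n_rows)
        for tree in model.trees:
            eta += tree.predict(data.Z, x=x)
        return eta / model.ntree + base_offset

    # oob_only
    eta_sum = np.zeros(data.n_rows)
    counts = np.zeros(data.n, dtype=np.intp)
    for tree, ib in zip(model.trees, model.inbag):
        oob = ib.oob
        if oob.size == 0:
            continue
        rows = _rows_of(data, oob)
        eta_sum[rows] += tree.predict(data.Z[rows], x=None if x is None else x[rows])
        counts[oob] += 1
    row_counts = counts[data.stratum_codes]
    with np.errstate(invalid="ignore"):
        eta = np.where(row_counts > 0, eta_sum / np.maximum(row_counts, 1), np.nan)
    return eta + base_offset


def _rows_of(data: MatchedDataset, strata: np.ndarray) -> np.ndarray:
    return np.concatenate([
        np.arange(data.stratum_starts[s], data.stratum_starts[s] + data.m[s])
        for s in strata
    ]) if strata.size else np.empty(0, dtype=np.intp)


def oob_pred_cond_lik(
    model: ForestModel, data: MatchedDataset
) -> tuple[np.ndarray, float]:
    """Out-of-bag predictive conditional likelihood.

    For every stratum that is out-of-bag for at least one tree, the
    conditional probability of its observed case under the OOB-averaged
    linear predictor.  Returns (per-stratum values with NaN for
    non-evaluable strata, mean over evaluable strata).
    """
    eta = predict_forest(model, data, scope="oob_only")
    probs = np.full(data.n, np.nan)
    ok_rows = np.isfinite(eta)
    if ok_rows.any():
        ok_strata = np.unique(data.stratum_codes[ok_rows])
        sub = data.subset(ok_strata)
        probs[ok_strata] = stratum_probs(sub, eta[_rows_of(data, ok_strata)])
    mean = float(np.nanmean(probs)) if np.isfinite(probs).any() else np.nan
    return probs, mean


def tune_mtry(
    data: MatchedDataset,
    control: ForestControl | None = None,
    ntree_tune: int | None = None,
    offset: np.ndarray | None = None,
) -> int:
    """Select mtry in {2..p} by out-of-bag predictive conditional likelihood.

    Each candidate is scored with a forest of ``ntree_tune`` trees grown
    under a seed substream derived from the master seed; ties go to the
    smaller mtry.  Deterministic given the control seed.
    """
    control = control or ForestControl()
    if data.p < 2:
        raise ValueError("mtry tuning needs at least 2 covariates")
    ntree_tune = ntree_tune or control.ntree_tune
    candidates = list(range(2, data.p + 1))
    if len(candidates) == 1:
        return candidates[0]
    scores = []
    for j, m in enumerate(candidates):
        sub_control = replace(
            control,
            ntree=ntree_tune,
            mtry=m,
            seed=control.seed + 100003 * (j + 1),
            offset="none",      # the offset, if any, is passed explicitly
        )
        model = _fit_with_fixed_offset(data, sub_control, offset)
        _, mean = oob_pred_cond_lik_with_offset(model, data, offset)
        scores.append(mean)
    scores = np.asarray(scores)
    return candidates[int(np.argmax(scores))]


def _fit_with_fixed_offset(data, control, offset):
    """Forest fit helper that reuses a precomputed per-row offset."""
    if offset is None:
        return fit_forest(data, control)
    ss = np.random.SeedSequence(control.seed)
    seeds = ss.spawn(2 * control.ntree)
    mtry = data.p if control.mtry is None else int(control.mtry)
    tree_control = replace(control.tree, mtry=mtry)
    run = replace(control, tree=tree_control)
    inbags = [
        draw_inbag(data, mode=control.sampling,
                   seed=np.random.default_rng(seeds[2 * b]))
        for b in range(control.ntree)
    ]
    trees = Parallel(n_jobs=control.n_jobs)(
        delayed(_grow_one)(data, run, offset, inbags[b], seeds[2 * b + 1])
        for b in range(control.ntree)
    )
    return ForestModel(
        trees=list(trees), inbag=inbags, control=control,
        var_names=data.variable_names, mtry_used=mtry, offset_gamma=None,
    )


def oob_pred_cond_lik_with_offset(model, data, offset):
    """OOB predictive conditional likelihood with an explicit offset."""
    eta = predict_forest(model, data, scope="oob_only")
    if offset is not None:
        eta = eta + offset
    probs = np.full(data.n, np.nan)
    ok_rows = np.isfinite(eta)
    if ok_rows.any():
        ok_strata = np.unique(data.stratum_codes[ok_rows])
        sub = data.subset(ok_strata)
        probs[ok_strata] = stratum_probs(sub, eta[_rows_of(data, ok_strata)])
    mean = float(np.nanmean(probs)) if np.isfinite(probs).any() else np.nan
    return probs, mean
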