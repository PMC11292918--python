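"""Model interpretation: permutation variable importance and bootstrap
confidence intervals for the exposure effect.

Importance of a covariate is the drop in the mean per-stratum predictive
conditional likelihood after randomly permuting that covariate's column
(predictions are re-evaluated; nothing is refitted).  Two variants:

``all_obs``
    the whole forest's aggregated prediction on all strata, before and
    after permutation;
``oob``
    for each tree, the comparison is restricted to that tree's
    out-of-bag strata, and per-tree differences are averaged — the
    package default, as it is more robust against overfitting to the
    training data.

The exposure variable, when modeled as a separate linear term, is not a
forest covariate and gets no importance value.

The uncertainty of the averaged exposure effect is quantified by a
nonparametric stratum-level bootstrap: the entire forest-fitting
procedure is re-applied to B bootstrap resamples and percentile bounds
are read off the B resulting estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matched_data import MatchedDataset
from .cond_likelihood import stratum_probs
from .clogit_forest import ForestControl, ForestModel, fit_forest, _rows_of

__all__ = [
    "ImportanceResult",
    "BootstrapCI",
    "variable_importance",
    "boot_ci_exposure",
    "empirical_quantile",
]


@dataclass
class ImportanceResult:
    """Per-variable permutation importance (probability units)."""

    names: list[str]
    importance: np.ndarray
    variant: str
    nperm: int

    def sorted_items(self):
        order = np.argsort(-self.importance)
        return [(self.names[i], float(self.importance[i])) for i in order]


@dataclass
class BootstrapCI:
    """Percentile bootstrap confidence interval for the exposure effect."""

    estimates: np.ndarray
    level: float
    lower: float
    upper: float


# ----------------------------------------------------------------------
# Variable importance
# ----------------------------------------------------------------------

def _forest_probs(model, data, Z, per_stratum=True):
    """Per-stratum case probabilities of the all-tree aggregated prediction."""
    x = data.x if model.control.exposure else None
    eta = np.zeros(data.n_rows)
    for tree in model.trees:
        eta += tree.predict(Z, x=x)
    eta = eta / model.ntree + model.offset_for(Z)
    return stratum_probs(data, eta)


def variable_importance(
    model: ForestModel,
    data: MatchedDataset,
    variant: str = "oob",
    nperm: int | None = None,
    seed: int = 0,
    within_stratum: bool = False,
) -> ImportanceResult:
    """Permutation importance of every forest covariate.

    Values of the permuted variable are shuffled globally across all
    rows (``within_stratum=True`` restricts the shuffle to run within
    each stratum).  Results are averaged over ``nperm`` permutations
    (default 1 for the oob variant, 5 for all_obs) and are deterministic
    given ``seed``.  The fitted model is never modified.
    """
    if variant not in ("oob", "all_obs"):
        raise ValueError(f"unknown importance variant {variant!r}")
    if nperm is None:
        nperm = 1 if variant == "oob" else 5
    rng = np.random.default_rng(seed)
    p = data.p
    x = data.x if model.control.exposure else None

    def permuted_column(col):
        if within_stratum:
            out = col.copy()
            for s in range(data.n):
                rows = np.arange(
                    data.stratum_starts[s], data.stratum_starts[s] + data.m[s]
                )
                out[rows] = col[rng.permutation(rows)]
            return out
        return col[rng.permutation(data.n_rows)]

    imp = np.zeros(p)
    if variant == "all_obs":
        baseline = float(_forest_probs(model, data, data.Z).mean())
        for v in range(p):
            drop = 0.0
            for _ in range(nperm):
                Zp = data.Z.copy()
                Zp[:, v] = permuted_column(data.Z[:, v])
                drop += baseline - float(_forest_probs(model, data, Zp).mean())
            imp[v] = drop / nperm
        return ImportanceResult(data.variable_names, imp, variant, nperm)

    # oob variant: per tree, on that tree's OOB strata only
    tree_cache = []
    for tree, ib in zip(model.trees, model.inbag):
        oob = ib.oob
        if oob.size == 0:
            tree_cache.append(None)
            continue
        rows = _rows_of(data, oob)
        sub = data.subset(oob)
        eta = tree.predict(data.Z[rows], x=None if x is None else x[rows])
        eta = eta + model.offset_for(data.Z[rows])
        base = float(stratum_probs(sub, eta).mean())
        tree_cache.append((oob, rows, sub, base))

    for v in range(p):
        diffs = []
        for _ in range(nperm):
            Zp = data.Z.copy()
            Zp[:, v] = permuted_column(data.Z[:, v])
            for tree, cache in zip(model.trees, tree_cache):
                if cache is None:
                    continue
                oob, rows, sub, base = cache
                eta = tree.predict(Zp[rows], x=None if x is None else x[rows])
                eta = eta + model.offset_for(Zp[rows])
                perm = float(stratum_probs(sub, eta).mean())
                diffs.append(base - perm)
        imp[v] = float(np.mean(diffs)) if diffs else 0.0
    return ImportanceResult(data.variable_names, imp, variant, nperm)


# ----------------------------------------------------------------------
# Bootstrap confidence interval
# ----------------------------------------------------------------------

def empirical_quantile(draws: np.ndarray, q: float) -> float:
    """Inverse-CDF empirical quantile (no interpolation).

    Returns the ceil(q*B)-th order statistic of the B draws; with B=50
    and q=0.025 this is the 2nd smallest draw.  The convention matters
    at small B and is therefore fixed here.
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    B = draws.size
    k = int(np.ceil(q * B))
    k = min(max(k, 1), B)
    return float(draws[k - 1])


def boot_ci_exposure(
    data: MatchedDataset,
    control: ForestControl,
    B: int = 50,
    level: float = 0.95,
    seed: int = 0,
    estimator=None,
) -> BootstrapCI:
    """Nonparametric bootstrap CI for the averaged exposure effect.

    Draws ``B`` stratum-level bootstrap resamples of the training data,
    re-applies the whole forest-fitting procedure (including mtry
    re-tuning when the control says "tune") to each, and returns the
    (1-level)/2 and 1-(1-level)/2 empirical quantiles of the B averaged
    exposure effects.

    ``estimator`` may override the refit with any callable
    ``(MatchedDataset, seed) -> float`` returning an exposure-effect
    estimate (e.g. a plain CLR fit for speed or cross-checks).
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap replicates")
    if not control.exposure:
        raise ValueError("bootstrap CI requires an exposure-mode control")
    rng = np.random.default_rng(seed)
    estimates = np.empty(B)
    for b in range(B):
        strata = rng.integers(0, data.n, size=data.n)
        boot = data.subset(strata)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if estimator is not None:
            estimates[b] = estimator(boot, rep_seed)
        else:
            from dataclasses import replace
            model = fit_forest(boot, replace(control, seed=rep_seed))
            if model.beta_bar is None:
                raise RuntimeError(f"bootstrap replicate {b} returned no beta")
            estimates[b] = model.beta_bar
    alpha = (1.0 - level) / 2.0
    return BootstrapCI(
        estimates=estimates,
        level=level,
        lower=empirical_quantile(estimates, alpha),
        upper=empirical_quantile(estimates, 1.0 - alpha),
    )
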