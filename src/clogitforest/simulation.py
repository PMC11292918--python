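"""Synthetic matched case-control studies and the evaluation harness.

The generator emulates a district-matched design: a hypothetical
population is randomly distributed over districts (the matching
variable); each district carries two uniform effects, one on disease
risk and one on exposure propensity; exposure is drawn from a logistic
model in the person characteristics and the district exposure effect
(which makes the covariates confounders); disease is drawn from

    eta = intercept + tau_district + beta_true * x + f_k(z_signal),

with ``f_k`` linear (setting A), a sum of two step-function trees
(setting B) or a sum of smooth transforms (setting C) of the signal
variables.  Noise variables never enter ``f_k``.  Finally a 1:m matched
study is sampled: cases are drawn from the diseased, and each case is
matched to ``controls_per_case`` non-diseased persons from its own
district; persons are never reused across strata.  The identities (and
order) of the signal variables are permuted anew in every replication.

The harness computes the two quality measures — the mean per-stratum
predictive conditional likelihood on an independent validation study,
and the absolute error of the estimated log exposure effect — and
offers a stratum-level 10-fold cross-validation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matched_data import MatchedDataset, VariableSpec, stratum_folds
from .cond_likelihood import (
    PenaltyConfig,
    fit_clr_model,
    stratum_probs,
)
from .clogit_tree import TreeControl, grow_tree, prune_bic
from .clogit_forest import ForestControl, fit_forest, predict_forest

__all__ = [
    "DGPConfig",
    "Population",
    "SimulatedStudy",
    "EvaluationReport",
    "sample_population",
    "sample_exposure",
    "sample_outcome",
    "sample_matched_study",
    "simulate_study",
    "evaluate",
    "run_comparison",
    "cross_validate",
    "METHODS",
]


def _logistic(eta):
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class DGPConfig:
    """Full parameterization of the data-generating process.

    Defaults reproduce the study-design constants: a population of
    500 000 persons in 1000 districts, district effects uniform on
    [-2, 2] for both disease and exposure, outcome intercept -2, true
    exposure effect log 2, and 1:3 matched studies of 400 strata.  The
    functional families of the exposure model and of f_A/f_B/f_C are
    fixed; their coefficients are configurable with documented defaults.
    """

    dgp: str = "A"                        # outcome model family: A, B or C
    population: int = 500_000
    n_districts: int = 1000
    district_effect_range: tuple = (-2.0, 2.0)
    p_total: int = 10
    n_signal: int = 10
    n_dichotomous: int = 2
    intercept: float = -2.0
    beta_true: float = float(np.log(2.0))
    n_strata: int = 400
    controls_per_case: int = 3
    # exposure model: logit P(x=1) = c0 + sum a_k z_signal_k + tau_x
    exposure_intercept: float = 0.0
    exposure_coef: float = 0.2            # |a_k|, alternating sign
    # f_A: sum of +-f_a_coef * z over signal variables, alternating sign
    f_a_coef: float = 0.4
    # f_B: two depth-2 trees with node effects in {-f_b_effect, 0, +f_b_effect}
    f_b_effect: float = 0.8
    # f_C amplitude target (per-variable standard deviation of the transform)
    f_c_scale: float = 0.4

    def __post_init__(self):
        if self.dgp not in ("A", "B", "C"):
            raise ValueError("dgp must be one of 'A', 'B', 'C'")
        if self.n_signal > self.p_total:
            raise ValueError("n_signal cannot exceed p_total")
        if self.dgp == "B" and self.n_signal < 4:
            raise ValueError("setting B needs at least 4 signal variables")

    # ------------------------------------------------------------------
    @staticmethod
    def paper(dgp: str = "A", n_signal: int = 10, n_noise: int = 0,
              **overrides) -> "DGPConfig":
        """Study-scale configuration for a signal/noise mix (10/0, 5/5, 10/20)."""
        return DGPConfig(
            dgp=dgp, n_signal=n_signal, p_total=n_signal + n_noise,
            **overrides,
        )

    @staticmethod
    def reduced(dgp: str = "A", n_signal: int = 10, n_noise: int = 0,
                **overrides) -> "DGPConfig":
        """Desk-scale configuration: population 20 000, 100 districts,
        100 strata; all other constants unchanged."""
        overrides.setdefault("population", 20_000)
        overrides.setdefault("n_districts", 100)
        overrides.setdefault("n_strata", 100)
        return DGPConfig.paper(dgp, n_signal, n_noise, **overrides)


@dataclass
class Population:
    """The simulated source population."""

    district: np.ndarray                  # per-person district index
    tau: np.ndarray                       # per-district disease effect
    tau_x: np.ndarray                     # per-district exposure effect
    Z: np.ndarray                         # person characteristics
    signal: np.ndarray                    # permuted signal column indices
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    eta: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.district.size


@dataclass
class SimulatedStudy:
    """A matched study, its validation twin, and the ground truth."""

    data: MatchedDataset
    validation: MatchedDataset
    beta_true: float
    signal: np.ndarray
    config: DGPConfig


@dataclass
class EvaluationReport:
    """The two quality measures for one fitted model."""

    stratum_probs: np.ndarray
    pred_cond_lik: float
    beta_hat: float | None
    abs_error_beta: float | None


# ----------------------------------------------------------------------
# Generation steps
# ----------------------------------------------------------------------

def sample_population(config: DGPConfig, rng: np.random.Generator) -> Population:
    """Steps 1-2: district structure and person characteristics.

    Persons are assigned to districts uniformly; the two district
    effects are uniform on the configured range; covariates are standard
    normal with the first ``n_dichotomous`` signal variables
    dichotomized at 0 (the population median).  The signal-variable
    order is permuted per call.
    """
    lo, hi = config.district_effect_range
    tau = rng.uniform(lo, hi, size=config.n_districts)
    tau_x = rng.uniform(lo, hi, size=config.n_districts)
    district = rng.integers(0, config.n_districts, size=config.population)
    Z = rng.standard_normal((config.population, config.p_total))
    signal = rng.permutation(config.p_total)[: config.n_signal]
    for k in signal[: config.n_dichotomous]:
        Z[:, k] = (Z[:, k] > 0).astype(float)
    return Population(district=district, tau=tau, tau_x=tau_x, Z=Z,
                      signal=signal)


def _signal_matrix(pop: Population) -> np.ndarray:
    """Signal columns, centered so binary (dichotomized) columns have
    roughly mean zero like the continuous ones."""
    S = pop.Z[:, pop.signal].copy()
    for j in range(S.shape[1]):
        vals = np.unique(S[:, j])
        if vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all():
            S[:, j] = S[:, j] - 0.5
    return S


def sample_exposure(pop: Population, config: DGPConfig,
                    rng: np.random.Generator) -> Population:
    """Step 3: logistic exposure model in the signal variables and the
    district exposure effect (creates confounding)."""
    S = _signal_matrix(pop)
    a = config.exposure_coef * (-1.0) ** np.arange(S.shape[1])
    lin = config.exposure_intercept + S @ a + pop.tau_x[pop.district]
    pop.x = (rng.random(pop.size) < _logistic(lin)).astype(float)
    return pop


def _f_A(S: np.ndarray, config: DGPConfig) -> np.ndarray:
    coefs = config.f_a_coef * (-1.0) ** np.arange(S.shape[1])
    return S @ coefs


def _step_tree(z1, z2, c1, c2, effect):
    """Depth-2 step function with values in {-effect, 0, +effect}."""
    out = np.zeros(z1.shape[0])
    out[(z1 <= c1) & (z2 <= c2)] = -effect
    out[(z1 > c1) & (z2 > c2)] = effect
    return out


def _f_B(S: np.ndarray, config: DGPConfig) -> np.ndarray:
    e = config.f_b_effect
    return (_step_tree(S[:, 0], S[:, 1], 0.0, 0.0, e)
            + _step_tree(S[:, 2], S[:, 3], 0.5, -0.5, e))


#: smooth transforms used cyclically in setting C, each scaled to a
#: population standard deviation of about 1 on standard-normal input
_SMOOTH = (
    lambda z: np.sin(np.pi * z) / 0.606,
    lambda z: (z * z - 1.0) / np.sqrt(2.0),
    lambda z: np.tanh(z) / 0.628,
)


def _f_C(S: np.ndarray, config: DGPConfig) -> np.ndarray:
    out = np.zeros(S.shape[0])
    for j in range(S.shape[1]):
        out += config.f_c_scale * _SMOOTH[j % len(_SMOOTH)](S[:, j])
    return out


_F = {"A": _f_A, "B": _f_B, "C": _f_C}


def sample_outcome(pop: Population, config: DGPConfig,
                   rng: np.random.Generator) -> Population:
    """Step 4: disease model eta = intercept + tau + beta*x + f_k(z)."""
    if pop.x is None:
        raise ValueError("sample exposure before the outcome")
    S = _signal_matrix(pop)
    f = _F[config.dgp](S, config)
    pop.eta = (config.intercept + pop.tau[pop.district]
               + config.beta_true * pop.x + f)
    pop.y = (rng.random(pop.size) < _logistic(pop.eta)).astype(float)
    return pop


def sample_matched_study(
    pop: Population,
    config: DGPConfig,
    rng: np.random.Generator,
    exclude: np.ndarray | None = None,
    max_retries: int | None = None,
) -> tuple[MatchedDataset, np.ndarray]:
    """Step 5: draw a 1:m district-matched study from the population.

    Cases are sampled without replacement from the diseased persons;
    each case's controls come from the non-diseased persons of the same
    district.  Persons in ``exclude`` (e.g. a previously drawn study)
    and persons already used are skipped.  A case whose district cannot
    supply enough controls is dropped and another diseased person is
    drawn instead; the sampling fails if the diseased pool is exhausted.
    Returns the study and the indices of all persons used.
    """
    if pop.y is None:
        raise ValueError("sample the outcome before the matched study")
    m = config.controls_per_case
    used = np.zeros(pop.size, dtype=bool)
    if exclude is not None:
        used[exclude] = True

    # per-district shuffled pools of available controls
    control_pool: dict[int, list] = {}
    noncase_idx = np.flatnonzero((pop.y == 0) & ~used)
    for d in np.unique(pop.district[noncase_idx]):
        members = noncase_idx[pop.district[noncase_idx] == d]
        control_pool[d] = list(rng.permutation(members))

    diseased = np.flatnonzero((pop.y == 1) & ~used)
    order = rng.permutation(diseased)
    if max_retries is None:
        max_retries = order.size

    rows_case, rows_ctrl, districts = [], [], []
    attempts = 0
    for person in order:
        if len(rows_case) == config.n_strata:
            break
        if used[person]:
            continue
        d = int(pop.district[person])
        pool = control_pool.get(d, [])
        if len(pool) < m:
            attempts += 1
            if attempts > max_retries:
                break
            continue
        ctrls = [pool.pop() for _ in range(m)]
        used[person] = True
        used[ctrls] = True
        rows_case.append(person)
        rows_ctrl.append(ctrls)
        districts.append(d)
    if len(rows_case) < config.n_strata:
        raise RuntimeError(
            f"could only form {len(rows_case)} of {config.n_strata} strata; "
            "population too small or too few controls per district"
        )

    n = config.n_strata
    rows = np.concatenate(
        [[c] + ctrl for c, ctrl in zip(rows_case, rows_ctrl)]
    ).astype(np.intp)
    codes = np.repeat(np.arange(n), 1 + m)
    variables = []
    for k in range(config.p_total):
        vals = np.unique(pop.Z[:, k])
        kind = "binary" if (vals.size <= 2
                            and np.isin(vals, (0.0, 1.0)).all()) else "continuous"
        variables.append(VariableSpec(f"z{k + 1}", kind))
    data = MatchedDataset(
        stratum_labels=np.array([f"s{i + 1}" for i in range(n)], dtype=object),
        stratum_codes=codes,
        y=pop.y[rows],
        x=pop.x[rows],
        Z=pop.Z[rows],
        variables=variables,
    )
    return data, rows


def simulate_study(config: DGPConfig, seed: int) -> SimulatedStudy:
    """Generate one complete replication: population, matched study, and
    an independent validation study of the same size from the same
    population (sharing no person with the training study)."""
    rng = np.random.default_rng(seed)
    pop = sample_population(config, rng)
    sample_exposure(pop, config, rng)
    sample_outcome(pop, config, rng)
    data, used = sample_matched_study(pop, config, rng)
    validation, _ = sample_matched_study(pop, config, rng, exclude=used)
    return SimulatedStudy(
        data=data, validation=validation,
        beta_true=config.beta_true, signal=pop.signal, config=config,
    )


# ----------------------------------------------------------------------
# Quality measures and harness
# ----------------------------------------------------------------------

def evaluate(
    predictions: np.ndarray,
    validation: MatchedDataset,
    beta_hat: float | None = None,
    beta_true: float | None = None,
) -> EvaluationReport:
    """Both quality measures for per-row linear predictors on validation
    data: mean per-stratum predictive conditional likelihood, and the
    absolute error of the log exposure effect."""
    probs = stratum_probs(validation, np.asarray(predictions, dtype=float))
    err = None
    if beta_hat is not None and beta_true is not None:
        err = float(abs(beta_hat - beta_true))
    return EvaluationReport(
        stratum_probs=probs,
        pred_cond_lik=float(probs.mean()),
        beta_hat=beta_hat,
        abs_error_beta=err,
    )


def _fit_and_predict(method, train, test, seed, forest_control, tree_control):
    """Fit one method on `train`, return (eta on test rows, beta_hat)."""
    pen = PenaltyConfig(lam=tree_control.lam)
    if method == "CLR0":
        fit = fit_clr_model(train, exposure=True, covariates=False, penalty=pen)
        return test.x * fit.beta_hat, fit.beta_hat
    if method == "CLR":
        fit = fit_clr_model(train, exposure=True, covariates=True, penalty=pen)
        return test.x * fit.beta_hat + test.Z @ fit.gamma_hat, fit.beta_hat
    if method == "tree":
        ctrl = replace(tree_control, seed=seed, mtry=None)
        tree = prune_bic(grow_tree(train, ctrl, exposure=True), train, ctrl)
        return tree.predict(test.Z, x=test.x), tree.beta_hat
    if method in ("forest", "forest_offset"):
        ctrl = replace(
            forest_control,
            seed=seed,
            offset="linear" if method == "forest_offset" else "none",
        )
        model = fit_forest(train, ctrl)
        return predict_forest(model, test), model.beta_bar
    raise ValueError(f"unknown method {method!r}")


METHODS = ("CLR0", "CLR", "tree", "forest", "forest_offset")


def run_comparison(
    config: DGPConfig,
    methods=("CLR", "tree", "forest"),
    replications: int = 20,
    seed: int = 0,
    forest_control: ForestControl | None = None,
    tree_control: TreeControl | None = None,
) -> pd.DataFrame:
    """Replicate the study comparison: per replication, simulate a
    training and a validation study, fit every requested method, and
    record both quality measures.  Returns a tidy data frame with one
    row per (replication, method)."""
    forest_control = forest_control or ForestControl(ntree=100)
    tree_control = tree_control or forest_control.tree
    rows = []
    base = np.random.SeedSequence(seed)
    rep_seeds = base.generate_state(2 * replications)
    for r in range(replications):
        study = simulate_study(config, int(rep_seeds[2 * r] % (2**31 - 1)))
        fit_seed = int(rep_seeds[2 * r + 1] % (2**31 - 1))
        for method in methods:
            eta, beta = _fit_and_predict(
                method, study.data, study.validation, fit_seed,
                forest_control, tree_control,
            )
            report = evaluate(eta, study.validation, beta, study.beta_true)
            rows.append({
                "replication": r,
                "method": method,
                "pred_cond_lik": report.pred_cond_lik,
                "abs_error_beta": report.abs_error_beta,
            })
    return pd.DataFrame(rows)


def cross_validate(
    data: MatchedDataset,
    methods=("CLR",),
    k: int = 10,
    seed: int = 0,
    forest_control: ForestControl | None = None,
    tree_control: TreeControl | None = None,
) -> pd.DataFrame:
    """Stratum-level k-fold cross-validation of the predictive
    conditional likelihood: strata are split into k folds, each fold is
    predicted by models trained on the remaining folds.  Returns one row
    per (stratum, method)."""
    forest_control = forest_control or ForestControl(ntree=100)
    tree_control = tree_control or forest_control.tree
    partition = stratum_folds(data, k, seed)
    rows = []
    for fold in range(k):
        test_strata = np.flatnonzero(partition.folds == fold)
        train_strata = np.flatnonzero(partition.folds != fold)
        train = data.subset(train_strata)
        test = data.subset(test_strata)
        for method in methods:
            eta, _ = _fit_and_predict(
                method, train, test, seed + fold, forest_control, tree_control,
            )
            probs = stratum_probs(test, eta)
            for s, prob in zip(test_strata, probs):
                rows.append({
                    "stratum": int(s), "fold": fold,
                    "method": method, "pred_cond_lik": float(prob),
                })
    return pd.DataFrame(rows)
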