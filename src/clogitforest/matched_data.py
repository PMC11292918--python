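"""Data model and I/O for 1:m matched case-control data.

A matched case-control study consists of *n* strata (one case plus its
matched controls).  All resampling, cross-validation and likelihood
computations in this package operate on whole strata, never on single
rows, because the rows within a stratum are not independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "MatchedDataset",
    "StratumPartition",
    "MatchedDataError",
    "read_matched_csv",
    "write_matched_csv",
    "stratum_folds",
    "draw_inbag",
    "SUBSAMPLE_FRACTION",
]

#: Fraction of strata drawn without replacement in ``subsample`` mode.
#: Equals the expected unique fraction 1 - 1/e of an n-out-of-n bootstrap.
SUBSAMPLE_FRACTION = 1.0 - np.exp(-1.0)


class MatchedDataError(ValueError):
    """Raised when matched case-control data violate the design constraints."""


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one covariate.

    Parameters
    ----------
    name : str
        Column name.
    kind : {"continuous", "binary", "ordinal"}
        Measurement scale.  Binary variables take values in {0, 1};
        ordinal variables are coded as consecutive integers preserving
        order and enter tree splits unchanged (no dichotomization).
    levels : tuple, optional
        Ordered original category codes (ordinal only).
    """

    name: str
    kind: str = "continuous"
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise MatchedDataError(f"unknown variable kind {self.kind!r}")


@dataclass
class MatchedDataset:
    """A validated 1:m matched case-control dataset.

    Rows are stored grouped by stratum (strata ordered by first appearance
    in the input); within-stratum row order is irrelevant to every
    downstream computation.

    Attributes
    ----------
    stratum_labels : ndarray of shape (n,)
        Original stratum identifiers, one per stratum.
    stratum_codes : ndarray of shape (n_rows,)
        Integer stratum index 0..n-1 per row; non-decreasing.
    y : ndarray of shape (n_rows,)
        Case indicator; exactly one 1 per stratum.
    x : ndarray of shape (n_rows,) or None
        Optional binary exposure.
    Z : ndarray of shape (n_rows, p)
        Covariate matrix.
    variables : list of VariableSpec
        Per-column metadata for ``Z``.
    """

    stratum_labels: np.ndarray
    stratum_codes: np.ndarray
    y: np.ndarray
    x: np.ndarray | None
    Z: np.ndarray
    variables: list[VariableSpec] = field(default_factory=list)

    # derived index arrays, filled by __post_init__
    stratum_starts: np.ndarray = field(init=False, repr=False)
    m: np.ndarray = field(init=False, repr=False)
    case_rows: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.stratum_codes = np.asarray(self.stratum_codes)
        self.y = np.asarray(self.y)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[0] != self.y.shape[0]:
            self.Z = self.Z.reshape(self.y.shape[0], -1)
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
        if not self.variables:
            self.variables = [
                VariableSpec(f"z{k + 1}") for k in range(self.Z.shape[1])
            ]
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self):
        codes = self.stratum_codes
        if codes.size == 0:
            raise MatchedDataError("empty dataset")
        if np.any(np.diff(codes) < 0):
            raise MatchedDataError("rows must be grouped by stratum")
        n = int(codes.max()) + 1
        if len(self.stratum_labels) != n:
            raise MatchedDataError("stratum_labels length mismatch")
        starts = np.searchsorted(codes, np.arange(n))
        self.stratum_starts = starts
        self.m = np.diff(np.append(starts, codes.size))
        if np.any(self.m < 2):
            bad = self.stratum_labels[np.argmax(self.m < 2)]
            raise MatchedDataError(f"stratum {bad!r} has fewer than 2 rows")
        if not np.isin(self.y, (0, 1)).all():
            raise MatchedDataError("case indicator must be 0/1")
        cases_per = np.add.reduceat(self.y.astype(np.int64), starts)
        if np.any(cases_per != 1):
            bad = self.stratum_labels[int(np.argmax(cases_per != 1))]
            raise MatchedDataError(
                f"stratum {bad!r} has {int(cases_per[cases_per != 1][0])} "
                "cases; exactly one case per stratum is required"
            )
        self.case_rows = np.flatnonzero(self.y == 1)
        if self.x is not None and not np.isin(self.x, (0.0, 1.0)).all():
            raise MatchedDataError("exposure must be binary 0/1")
        if not np.isfinite(self.Z).all():
            raise MatchedDataError(
                "missing or non-finite covariate values are not supported"
            )
        for k, v in enumerate(self.variables):
            if v.kind == "binary" and not np.isin(self.Z[:, k], (0.0, 1.0)).all():
                raise MatchedDataError(
                    f"binary variable {v.name!r} takes values outside {{0,1}}"
                )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        """Number of strata."""
        return len(self.stratum_labels)

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def has_exposure(self) -> bool:
        return self.x is not None

    # ------------------------------------------------------------------
    def subset(self, strata: np.ndarray) -> "MatchedDataset":
        """Dataset restricted to the given stratum indices.

        ``strata`` may contain repeats (bootstrap resampling); each draw
        becomes a distinct stratum in the result, so a stratum drawn twice
        contributes its conditional-likelihood term twice.
        """
        strata = np.asarray(strata, dtype=np.intp)
        rows, codes, labels = [], [], []
        for new_i, s in enumerate(strata):
            start = self.stratum_starts[s]
            stop = start + self.m[s]
            rows.append(np.arange(start, stop))
            codes.append(np.full(self.m[s], new_i, dtype=np.intp))
            labels.append(self.stratum_labels[s])
        rows = np.concatenate(rows)
        return MatchedDataset(
            stratum_labels=np.asarray(labels, dtype=object),
            stratum_codes=np.concatenate(codes),
            y=self.y[rows],
            x=None if self.x is None else self.x[rows],
            Z=self.Z[rows],
            variables=list(self.variables),
        )

    def to_frame(
        self,
        stratum_col: str = "stratum",
        case_col: str = "case",
        exposure_col: str = "exposure",
    ) -> pd.DataFrame:
        data = {stratum_col: self.stratum_labels[self.stratum_codes],
                case_col: self.y.astype(int)}
        if self.x is not None:
            data[exposure_col] = self.x.astype(int)
        for k, v in enumerate(self.variables):
            col = self.Z[:, k]
            if v.kind in ("binary", "ordinal"):
                col = col.astype(int)
            data[v.name] = col
        return pd.DataFrame(data)


@dataclass(frozen=True)
class StratumPartition:
    """Stratum-level fold assignment or in-bag multiset.

    Either ``folds`` (fold index per stratum) or ``inbag`` (possibly
    repeated in-bag stratum indices) is set.  Sampling always operates on
    whole strata; the out-of-bag set is the complement of the in-bag set.
    """

    n: int
    folds: np.ndarray | None = None
    inbag: np.ndarray | None = None

    @property
    def oob(self) -> np.ndarray:
        """Sorted indices of out-of-bag strata."""
        if self.inbag is None:
            raise ValueError("partition has no in-bag sample")
        mask = np.ones(self.n, dtype=bool)
        mask[np.unique(self.inbag)] = False
        return np.flatnonzero(mask)

    @property
    def inbag_unique(self) -> np.ndarray:
        return np.unique(self.inbag)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _infer_kind(col: np.ndarray) -> str:
    vals = np.unique(col)
    if np.isin(vals, (0.0, 1.0)).all():
        return "binary"
    if np.allclose(vals, np.round(vals)) and vals.size <= 12:
        return "ordinal"
    return "continuous"


def from_frame(
    df: pd.DataFrame,
    stratum_col: str,
    case_col: str,
    exposure_col: str | None = None,
    covariates: list[str] | None = None,
    kinds: dict[str, str] | None = None,
) -> MatchedDataset:
    """Build a :class:`MatchedDataset` from a data frame.

    Strata are ordered by first appearance; rows are regrouped by stratum.
    Covariate kinds are taken from ``kinds`` or inferred (0/1 columns are
    binary, small integer-valued columns ordinal, otherwise continuous).
    """
    for col in (stratum_col, case_col):
        if col not in df.columns:
            raise MatchedDataError(f"column {col!r} not found")
    if covariates is None:
        skip = {stratum_col, case_col}
        if exposure_col:
            skip.add(exposure_col)
        covariates = [c for c in df.columns if c not in skip]
    labels, codes = np.unique(
        df[stratum_col].to_numpy(), return_inverse=True
    )
    # reorder strata by first appearance in the file
    first = np.full(len(labels), df.shape[0], dtype=np.intp)
    np.minimum.at(first, codes, np.arange(df.shape[0]))
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(labels))
    codes = rank[codes]
    labels = labels[order]
    row_order = np.argsort(codes, kind="stable")

    Zdf = df[covariates]
    if Zdf.isna().to_numpy().any():
        raise MatchedDataError("missing covariate values are not supported")
    Z = Zdf.to_numpy(dtype=float)[row_order]
    kinds = kinds or {}
    variables = [
        VariableSpec(c, kinds.get(c) or _infer_kind(Z[:, k]))
        for k, c in enumerate(covariates)
    ]
    y = df[case_col].to_numpy(dtype=float)[row_order]
    x = None
    if exposure_col is not None:
        x = df[exposure_col].to_numpy(dtype=float)[row_order]
    return MatchedDataset(
        stratum_labels=labels.astype(object),
        stratum_codes=codes[row_order],
        y=y,
        x=x,
        Z=Z,
        variables=variables,
    )


def read_matched_csv(
    path,
    stratum_col: str,
    case_col: str,
    exposure_col: str | None = None,
    covariates: list[str] | None = None,
    kinds: dict[str, str] | None = None,
) -> MatchedDataset:
    """Read and validate a matched case-control CSV file.

    The file must have a header row naming a stratum column and a binary
    case column; every stratum must contain exactly one case and at least
    one control.  Missing covariate values are rejected (no imputation).
    """
    df = pd.read_csv(path)
    return from_frame(df, stratum_col, case_col, exposure_col, covariates, kinds)


def write_matched_csv(data: MatchedDataset, path, **frame_kwargs) -> None:
    data.to_frame(**frame_kwargs).to_csv(path, index=False)


# ----------------------------------------------------------------------
# Stratum-level partitioning
# ----------------------------------------------------------------------

def stratum_folds(data: MatchedDataset, k: int, seed: int) -> StratumPartition:
    """Assign each stratum to one of ``k`` cross-validation folds.

    Fold sizes differ by at most one stratum; the assignment is a
    deterministic function of ``seed``.
    """
    n = data.n
    if k > n:
        raise MatchedDataError(f"cannot make {k} folds from {n} strata")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.intp)
    folds[perm] = np.arange(n) % k
    return StratumPartition(n=n, folds=folds)


def draw_inbag(
    data_or_n,
    mode: str = "subsample",
    seed=None,
) -> StratumPartition:
    """Draw a stratum-level in-bag sample for one base learner.

    ``bootstrap`` draws n strata with replacement; ``subsample`` draws
    round(0.632 n) distinct strata without replacement, matching the
    expected unique fraction (1 - 1/e) of an n-out-of-n bootstrap.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    n = data_or_n if isinstance(data_or_n, (int, np.integer)) else data_or_n.n
    if n < 2:
        raise MatchedDataError("need at least 2 strata to resample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "bootstrap":
        inbag = rng.integers(0, n, size=n)
    elif mode == "subsample":
        # half-up rounding of 0.632 n
        size = int(np.floor(SUBSAMPLE_FRACTION * n + 0.5))
        size = max(1, min(size, n - 1))
        inbag = rng.choice(n, size=size, replace=False)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return StratumPartition(n=n, inbag=np.sort(inbag))
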