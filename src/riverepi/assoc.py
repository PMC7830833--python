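"""Mantel tests and multiple regression on distance matrices (MRM).

Both procedures work on the unfolded lower triangles of labelled,
site-aligned distance matrices.  Because the N(N-1)/2 pairwise entries
are not independent, significance comes from joint row-and-column
permutation of one matrix: relabelling sites preserves the internal
dependence structure of each matrix while breaking the association
between them.  For small site sets (N! below a cutoff) the complete
permutation group is enumerated and the p-value is exact.

MRM regresses one unfolded response matrix on several unfolded predictor
matrices by ordinary least squares, permuting the *response* matrix only
— the standard scheme for regression on distance matrices.  With a
single predictor its R^2 is algebraically the squared simple Mantel r.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    alternative: str = "greater"


@dataclass
class MrmResult:
    coefficients: dict[str, float]       # intercept first
    coefficient_p: dict[str, float]
    r_squared: float
    r_squared_p: float
    n_permutations: int


def _align(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray, int]:
    """Align two labelled matrices by site label; never by position."""
    if set(d1.ids) != set(d2.ids):
        off = sorted(set(d1.ids).symmetric_difference(d2.ids))[0]
        raise ValueError(f"site label {off!r} present in only one matrix")
    order = [d2.ids.index(i) for i in d1.ids]
    return d1.data, d2.data[np.ix_(order, order)], len(d1.ids)


def _tri(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 1000,
    alternative: str = "greater",
    seed=None,
    exhaustive_limit: int = 5040,
) -> MantelResult:
    """Simple Mantel test between two labelled distance matrices.

    r is the Pearson correlation over the lower-triangle entries; the
    null permutes rows and columns of the second matrix jointly.  When
    N! <= ``exhaustive_limit`` (default 5040, i.e. N <= 7) all
    relabellings are enumerated and the p-value is exact (the identity
    permutation puts the observed statistic in its own null); otherwise
    ``n_perm`` sampled permutations use the +1 convention.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b, n = _align(d1, d2)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 sites")
    x, y = _tri(a), _tri(b)
    for name, v in (("first", x), ("second", y)):
        if np.ptp(v) == 0:
            raise ValueError(
                f"all off-diagonal distances equal in the {name} matrix; "
                "Mantel r is undefined"
            )
    r_obs = _pearson(x, y)

    def extremity(r_null: np.ndarray) -> np.ndarray:
        if alternative == "greater":
            return r_null >= r_obs
        if alternative == "less":
            return r_null <= r_obs
        return np.abs(r_null) >= abs(r_obs)

    if math.factorial(n) <= exhaustive_limit:
        r_null = np.array(
            [_pearson(x, _tri(b[np.ix_(p, p)]))
             for p in itertools.permutations(range(n))]
        )
        total = len(r_null)
        p = float(extremity(r_null).sum()) / total
        return MantelResult(r_obs, p, total, True, alternative)

    rng = np.random.default_rng(seed)
    r_null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        r_null[k] = _pearson(x, _tri(b[np.ix_(perm, perm)]))
    p = (1 + int(extremity(r_null).sum())) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, False, alternative)


def mrm(
    response: DistanceMatrix,
    predictors: list[DistanceMatrix],
    n_perm: int = 1000,
    seed=None,
    predictor_names: list[str] | None = None,
) -> MrmResult:
    """Multiple regression on distance matrices.

    OLS of the unfolded response lower triangle on the unfolded predictor
    triangles plus an intercept.  Coefficient p-values are two-sided on
    magnitude, R^2's is one-sided greater, both from jointly permuting
    rows and columns of the response matrix only (+1 convention, sampled
    permutations).
    """
    if not predictors:
        raise ValueError("need at least one predictor matrix")
    names = predictor_names or [f"x{k + 1}" for k in range(len(predictors))]
    if len(names) != len(predictors):
        raise ValueError("predictor_names length mismatch")
    aligned = []
    for d in predictors:
        _, b, _ = _align(response, d)
        aligned.append(b)
    n = len(response.ids)
    y_mat = response.data
    npairs = n * (n - 1) // 2
    if npairs <= len(predictors) + 1:
        raise ValueError("number of site pairs must exceed number of predictors + 1")

    X = np.column_stack([np.ones(npairs)] + [_tri(b) for b in aligned])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cols = X[:, 1:]
        cc = np.corrcoef(cols, rowvar=False)
        for i in range(len(predictors)):
            for j in range(i + 1, len(predictors)):
                if abs(cc[i, j]) > 1 - 1e-10:
                    raise ValueError(
                        f"collinear predictors: {names[i]!r} and {names[j]!r}"
                    )
        raise ValueError("rank-deficient design (a predictor is constant or "
                         "a linear combination of others)")

    pinv = np.linalg.pinv(X)
    hat = X @ pinv

    def fit(yv: np.ndarray) -> tuple[np.ndarray, float]:
        beta = pinv @ yv
        fitted = hat @ yv
        ssr = float(((fitted - yv.mean()) ** 2).sum())
        sst = float(((yv - yv.mean()) ** 2).sum())
        return beta, (ssr / sst if sst > 0 else np.nan)

    y = _tri(y_mat)
    beta_obs, r2_obs = fit(y)

    rng = np.random.default_rng(seed)
    coef_count = np.zeros(len(beta_obs))
    r2_count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        beta_p, r2_p = fit(_tri(y_mat[np.ix_(perm, perm)]))
        coef_count += np.abs(beta_p) >= np.abs(beta_obs)
        if r2_p >= r2_obs:
            r2_count += 1

    labels = ["intercept"] + list(names)
    coef_p = (1 + coef_count) / (n_perm + 1)
    return MrmResult(
        coefficients=dict(zip(labels, beta_obs.tolist())),
        coefficient_p=dict(zip(labels, coef_p.tolist())),
        r_squared=r2_obs,
        r_squared_p=(1 + r2_count) / (n_perm + 1),
        n_permutations=n_perm,
    )
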