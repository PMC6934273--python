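"""Analyses of the accepted parameter set.

Four complementary views of how the accepted instances occupy the 6-D
parameter grid:

* **Connectivity** — connected components of the accepted set under the
  order-n neighbor relation (two instances are order-n neighbors when they
  differ by at most one grid step in at most n dimensions; an interior
  point has 12 order-1 neighbors).
* **Convexity** — accepted "parent" pairs are interpolated at fractions
  1/4, 1/2, 3/4 (m_e rounded to the nearest integer) and the children are
  re-screened; the accepted fraction measures how convex the set is.
* **Pairwise correlations** — Pearson coefficients between raw parameter
  values across accepted instances, flagged when |r| > 0.2 with p < 1e-9.
* **Polynomial input-output regression** — OLS fits of degree 1/2/3 on
  z-scored parameters against transformed output measures (log SR, log DR,
  CV', log(1-VS), log(1-EI)), plus an ordering-averaged incremental-R2
  decomposition of the variance each term explains.  The linear mode
  enumerates all 720 orderings of the six parameters, making the per-term
  mean gains exactly the Shapley values of R2; the quadratic mode samples
  random orderings of the 21 quadratic terms on top of the full linear
  fit, so no quadratic term is ever added before its linear components.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.preprocessing import PolynomialFeatures

from .model import GBCParameters
from .population import PARAM_NAMES, ParameterGrid

__all__ = [
    "neighbor_count",
    "connected_components",
    "convexity_test",
    "pairwise_correlations",
    "FitReport",
    "polynomial_fit",
    "variance_contribution",
    "transform_outputs",
    "OUTPUT_TRANSFORMS",
]


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def neighbor_count(order: int, n_dims: int = 6) -> int:
    """Number of order-n neighbors of an interior grid point.

    Sum over k = 1..order of C(n_dims, k) * 2**k: choose which k dimensions
    move by one step, each in either direction.  Order 1 gives 12 for six
    dimensions.
    """
    if not 1 <= order <= n_dims:
        raise ValueError("order must be between 1 and the number of dimensions")
    return sum(comb(n_dims, k) * 2**k for k in range(1, order + 1))


def connected_components(
    accepted_ids: Sequence[int],
    grid: ParameterGrid,
    order: int = 1,
) -> Tuple[pd.Series, int]:
    """Cluster accepted instances under the order-n neighbor relation.

    Returns (labels indexed by instance id, number of clusters).  The
    cluster count is weakly decreasing in ``order``.
    """
    shape = grid.shape
    mask = np.zeros(shape, dtype=bool)
    idx = np.unravel_index(np.asarray(accepted_ids, dtype=np.int64), shape)
    mask[idx] = True
    structure = ndimage.generate_binary_structure(len(shape), order)
    labeled, n_clusters = ndimage.label(mask, structure=structure)
    labels = pd.Series(labeled[idx], index=np.asarray(accepted_ids, dtype=np.int64),
                       name="cluster")
    return labels, int(n_clusters)


# ---------------------------------------------------------------------------
# Convexity
# ---------------------------------------------------------------------------

def convexity_test(
    accepted_params: pd.DataFrame,
    evaluator: Callable[[GBCParameters], bool],
    n_pairs: int = 3500,
    n_interp: int = 3,
    seed: int = 0,
) -> Tuple[float, pd.DataFrame]:
    """Fraction of interpolated children that still pass the acceptance rules.

    ``accepted_params`` must carry the six parameter columns; ``evaluator``
    judges one (possibly off-grid) parameter vector.  Each sampled parent
    pair yields ``n_interp`` children at evenly spaced interior fractions
    (1/4, 1/2, 3/4 for the default three); m_e is rounded to the nearest
    integer, the other parameters stay continuous.
    """
    if len(accepted_params) < 2:
        raise ValueError("need at least two accepted instances")
    rng = np.random.default_rng(seed)
    X = accepted_params[list(PARAM_NAMES)].to_numpy(dtype=float)
    fractions = np.arange(1, n_interp + 1) / (n_interp + 1)
    records = []
    for pair_id in range(n_pairs):
        i, j = rng.choice(len(X), size=2, replace=False)
        for frac in fractions:
            vec = (1.0 - frac) * X[i] + frac * X[j]
            kw = dict(zip(PARAM_NAMES, vec))
            kw["m_e"] = int(round(kw["m_e"]))
            child = GBCParameters(**kw)
            records.append({
                "pair": pair_id, "fraction": frac, **child.as_dict(),
                "accepted": bool(evaluator(child)),
            })
    children = pd.DataFrame(records)
    return float(children["accepted"].mean()), children


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pairwise_correlations(
    accepted_params: pd.DataFrame,
    r_threshold: float = 0.2,
    p_threshold: float = 1e-9,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix of the six parameters over accepted instances.

    Returns (r, p, flag) DataFrames; ``flag`` marks pairs with
    |r| > ``r_threshold`` and p < ``p_threshold``.  Raw parameter values
    are used (Pearson r is scale-invariant).  Zero-variance dimensions get
    NaN coefficients.
    """
    if len(accepted_params) < 3:
        raise ValueError("need at least three accepted instances")
    names = list(PARAM_NAMES)
    n = len(names)
    r = np.eye(n)
    p = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        x = accepted_params[names[i]].to_numpy(dtype=float)
        y = accepted_params[names[j]].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
            continue
        res = stats.pearsonr(x, y)
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=names, columns=names)
    p_df = pd.DataFrame(p, index=names, columns=names)
    flag = (r_df.abs() > r_threshold) & (p_df < p_threshold)
    np.fill_diagonal(flag.values, False)
    return r_df, p_df, flag


# ---------------------------------------------------------------------------
# Polynomial regression and variance decomposition
# ---------------------------------------------------------------------------

#: Output transforms applied before regression (CV' stays untransformed).
OUTPUT_TRANSFORMS: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sr": np.log,
    "dr": np.log,
    "cv_prime": lambda x: x,
    "vs": lambda x: np.log(1.0 - x),
    "ei": lambda x: np.log(1.0 - x),
}

#: Transform validity domains: rows outside are excluded (with counts reported).
_DOMAINS: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sr": lambda x: x > 0,
    "dr": lambda x: x > 0,
    "cv_prime": lambda x: np.isfinite(x),
    "vs": lambda x: x < 1.0,
    "ei": lambda x: x < 1.0,
}


def transform_outputs(table: pd.DataFrame) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-measure (transformed values, validity mask) for regression."""
    out = {}
    for name, fn in OUTPUT_TRANSFORMS.items():
        raw = table[name].to_numpy(dtype=float)
        mask = _DOMAINS[name](raw) & np.isfinite(raw)
        vals = np.full(raw.shape, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals[mask] = fn(raw[mask])
        out[name] = (vals, mask)
    return out


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance parameter column; cannot z-score")
    return (X - X.mean(axis=0)) / sd


def polynomial_design(X: np.ndarray, degree: int) -> Tuple[np.ndarray, List[str]]:
    """Monomial design matrix (no intercept) on z-scored parameters.

    Degree 1 has 6 columns, degree 2 adds 21 (6 squares + 15 cross terms,
    27 total), degree 3 has 83 columns in all.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    poly = PolynomialFeatures(degree=degree, include_bias=False)
    Z = poly.fit_transform(_zscore(X))
    names = list(poly.get_feature_names_out(list(PARAM_NAMES)))
    return Z, names


def _ols_r2(Z: np.ndarray, y: np.ndarray) -> float:
    """R2 of OLS with intercept; raises on rank deficiency."""
    A = np.column_stack([np.ones(len(y)), Z])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {A.shape[1]}); "
            "refusing to silently regularize"
        )
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")  # constant output: R2 undefined
    return float(1.0 - np.sum(resid**2) / ss_tot)


@dataclass
class FitReport:
    """Polynomial-fit summary: total R2 and per-term mean variance gains."""

    degree: int
    r2: Dict[str, float]
    n_used: Dict[str, int] = field(default_factory=dict)
    n_excluded: Dict[str, int] = field(default_factory=dict)
    term_gains: Dict[str, pd.Series] = field(default_factory=dict)
    n_orderings: Optional[int] = None


def polynomial_fit(
    params: pd.DataFrame,
    outputs: pd.DataFrame,
    degree: int,
) -> FitReport:
    """OLS polynomial fit of the six z-scored parameters to each output measure.

    Outputs are transformed per ``OUTPUT_TRANSFORMS``; rows outside a
    transform's domain (e.g. VS = 1) are excluded for that measure and the
    exclusion count reported.
    """
    X = params[list(PARAM_NAMES)].to_numpy(dtype=float)
    transformed = transform_outputs(outputs)
    r2: Dict[str, float] = {}
    n_used: Dict[str, int] = {}
    n_excl: Dict[str, int] = {}
    for name, (vals, mask) in transformed.items():
        Z, _ = polynomial_design(X[mask], degree)
        r2[name] = _ols_r2(Z, vals[mask])
        n_used[name] = int(mask.sum())
        n_excl[name] = int((~mask).sum())
    return FitReport(degree=degree, r2=r2, n_used=n_used, n_excluded=n_excl)


def _incremental_gains(Z: np.ndarray, y: np.ndarray, ordering: Sequence[int],
                       base: Optional[np.ndarray] = None) -> np.ndarray:
    """Sequential R2 gains when adding columns of Z in ``ordering``.

    Equivalent to refitting OLS at each step: columns are Gram-Schmidt
    orthogonalized against the intercept, the optional ``base`` block and
    all previously added columns, and each gain is the squared projection
    of y on the new orthonormal direction (as a fraction of total SS).
    """
    y = y - y.mean()
    ss_tot = float(np.sum(y**2))
    basis: List[np.ndarray] = []
    if base is not None:
        B = base - base.mean(axis=0)
        for k in range(B.shape[1]):
            v = B[:, k].copy()
            for b in basis:
                v -= (b @ v) * b
            nrm = np.linalg.norm(v)
            if nrm > 1e-10 * np.sqrt(len(y)):
                basis.append(v / nrm)
    gains = np.zeros(len(ordering))
    for pos, j in enumerate(ordering):
        v = Z[:, j] - Z[:, j].mean()
        for b in basis:
            v -= (b @ v) * b
        nrm = np.linalg.norm(v)
        if nrm > 1e-10 * np.sqrt(len(y)):
            v = v / nrm
            basis.append(v)
            gains[pos] = (v @ y) ** 2 / ss_tot
    return gains


def variance_contribution(
    params: pd.DataFrame,
    y: np.ndarray,
    degree: int = 1,
    n_orderings: int = 40_000,
    seed: int = 0,
) -> pd.Series:
    """Mean incremental R2 per term, averaged over term orderings.

    ``y`` is one (already transformed) output vector.  Linear mode
    (degree 1) enumerates all 720 orderings of the six parameters — the
    per-term mean gains are then exactly the Shapley values of R2 and sum
    to the total linear R2.  Quadratic mode (degree 2) starts from the
    full linear fit and samples ``n_orderings`` random orderings of the 21
    quadratic terms, so quadratic terms are never added before their
    linear components.
    """
    if degree not in (1, 2):
        raise ValueError("variance contributions are defined for degree 1 or 2")
    X = params[list(PARAM_NAMES)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    X, y = X[mask], y[mask]
    Z, names = polynomial_design(X, degree)

    if degree == 1:
        orderings = list(itertools.permutations(range(6)))
        total = np.zeros(6)
        for ordering in orderings:
            gains = _incremental_gains(Z, y, ordering)
            for pos, j in enumerate(ordering):
                total[j] += gains[pos]
        return pd.Series(total / len(orderings), index=names, name="mean_gain")

    rng = np.random.default_rng(seed)
    linear = Z[:, :6]
    quad_idx = np.arange(6, Z.shape[1])
    total = np.zeros(quad_idx.size)
    for _ in range(n_orderings):
        ordering = rng.permutation(quad_idx)
        gains = _incremental_gains(Z, y, ordering, base=linear)
        for pos, j in enumerate(ordering):
            total[j - 6] += gains[pos]
    return pd.Series(total / n_orderings, index=names[6:], name="mean_gain")
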