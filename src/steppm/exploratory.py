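"""Exploratory spatial statistics for areal panels.

Event rates per head of population, global Moran's I (univariate, and the
bivariate form correlating a map with the spatial lag of another —
typically the same variable one period later), permutation-based pseudo
p-values, and Spearman screening of covariates for multicollinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import ArealPanel
from .weights import SpatialWeights

__all__ = [
    "MoranResult",
    "event_rate",
    "morans_i",
    "bivariate_morans_i",
    "permutation_test",
    "spearman_matrix",
]


@dataclass(frozen=True)
class MoranResult:
    """A Moran statistic with its permutation-based significance.

    ``pseudo_p`` is (r + 1)/(M + 1) with r the number of the M permuted
    statistics at least as extreme as the observed one on the side of its
    deviation from the null expectation E[I] = -1/(n - 1); its floor is
    1/(M + 1) (1e-4 at the conventional 9,999 permutations).
    """

    statistic: float
    expectation_under_null: float
    pseudo_p: float
    n_permutations: int
    seed: int
    kind: str   # "univariate" | "bivariate"

    def __post_init__(self):
        lo = 1.0 / (self.n_permutations + 1)
        if not (lo - 1e-15 <= self.pseudo_p <= 1.0 + 1e-15):
            raise ValueError(f"pseudo_p {self.pseudo_p} outside [{lo}, 1]")


def event_rate(panel: ArealPanel, per: float = 100_000.0,
               period: int | None = None) -> np.ndarray:
    """Event rates per ``per`` persons: rate_it = per * y_it / P_it.

    With ``period`` given (a calendar label), returns the length-n vector
    for that period; otherwise the full (areas x periods) matrix.
    """
    if per <= 0:
        raise ValueError("per must be positive")
    rates = per * panel.counts / panel.population
    if period is None:
        return rates
    try:
        t = panel.periods.index(period)
    except ValueError:
        raise ValueError(f"period {period} not in panel") from None
    return rates[:, t]


def _centered(values, name: str) -> np.ndarray:
    z = np.asarray(values, dtype=float)
    if z.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector over areas")
    z = z - z.mean()
    if np.dot(z, z) == 0.0:
        raise ValueError(f"zero variance in {name}")
    return z


def morans_i(values, w: SpatialWeights) -> float:
    """Global Moran's I: (n/S0) * (z'Wz)/(z'z) with z the centred values.

    Positive values mean similar values cluster in space; the null
    expectation under exchangeability is -1/(n-1).  Islands contribute
    nothing to the numerator but stay in n.
    """
    z = _centered(values, "values")
    n = w.n
    if len(z) != n:
        raise ValueError(f"values length {len(z)} != number of areas {n}")
    W = w.to_sparse()
    s0 = w.total_weight
    if s0 == 0:
        raise ValueError("weights are all zero (every area is an island)")
    return float((n / s0) * (z @ (W @ z)) / (z @ z))


def bivariate_morans_i(values_t, values_t1, w: SpatialWeights) -> float:
    """Bivariate Moran's I between a map and the spatial lag of another.

    I = (n/S0) * (z_t' W z_{t+1}) / (||z_t|| ||z_{t+1}||), each vector
    centred — the cross-product normalization, under which the statistic
    reduces exactly to the univariate one when the two maps coincide.
    """
    zt = _centered(values_t, "values_t")
    zt1 = _centered(values_t1, "values_t1")
    n = w.n
    if len(zt) != n or len(zt1) != n:
        raise ValueError("vector lengths must equal the number of areas")
    W = w.to_sparse()
    s0 = w.total_weight
    if s0 == 0:
        raise ValueError("weights are all zero (every area is an island)")
    return float((n / s0) * (zt @ (W @ zt1)) / np.sqrt((zt @ zt) * (zt1 @ zt1)))


def permutation_test(kind: str, values, w: SpatialWeights, n_perm: int = 9_999,
                     seed: int = 0, values_t1=None) -> MoranResult:
    """Permutation inference for Moran's I against spatial randomness.

    ``kind`` is ``"univariate"`` or ``"bivariate"``.  For the bivariate
    statistic only the second map is permuted while the first stays fixed,
    so the null destroys the space-time alignment but keeps each map's
    own distribution.  The test is directional on the side of the observed
    deviation from E[I] = -1/(n-1).  Reproducible given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if kind not in ("univariate", "bivariate"):
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    n = w.n
    W = w.to_sparse()
    s0 = w.total_weight

    if kind == "univariate":
        observed = morans_i(values, w)
        z = _centered(values, "values")
        fixed, permuted, norm = z, z, z @ z
    else:
        if values_t1 is None:
            raise ValueError("bivariate test needs values_t1")
        observed = bivariate_morans_i(values, values_t1, w)
        fixed = _centered(values, "values_t")
        permuted = _centered(values_t1, "values_t1")
        norm = np.sqrt((fixed @ fixed) * (permuted @ permuted))

    # all permutations at once: columns of P are permuted copies of `permuted`
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    P = permuted[perm_idx.T]                    # (n, n_perm)
    if kind == "univariate":
        stats_perm = (n / s0) * np.einsum("ij,ij->j", P, W @ P) / norm
    else:
        stats_perm = (n / s0) * (fixed @ (W @ P)) / norm

    e_null = -1.0 / (n - 1)
    if observed >= e_null:
        r = int(np.sum(stats_perm >= observed))
    else:
        r = int(np.sum(stats_perm <= observed))
    return MoranResult(statistic=observed, expectation_under_null=e_null,
                       pseudo_p=(r + 1) / (n_perm + 1), n_permutations=n_perm,
                       seed=seed, kind=kind)


def spearman_matrix(covariates: dict) -> "pd.DataFrame":
    """Tie-corrected (average-rank) Spearman correlations between covariates.

    Each covariate's matrix is flattened over area-periods; a constant
    covariate yields NaN in its row/column plus a warning.  Diagonal is
    exactly 1, the matrix symmetric.
    """
    import pandas as pd

    names = list(covariates)
    if len(names) < 2:
        raise ValueError("need at least 2 covariates")
    cols = {k: np.asarray(v, dtype=float).ravel() for k, v in covariates.items()}
    m = len(next(iter(cols.values())))
    if m < 3:
        raise ValueError("need at least 3 observations")
    for k, v in cols.items():
        if len(v) != m:
            raise ValueError(f"covariate {k!r} length {len(v)} != {m}")
    X = np.column_stack([cols[k] for k in names])
    constant = X.std(axis=0) == 0
    if constant.any():
        bad = [names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant covariates {bad}: correlations undefined", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X).statistic
    if np.ndim(rho) == 0:           # scipy collapses the 2-variable case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=names, columns=names)
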