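"""Model specification and the deterministic likelihood machinery.

Five model families cover the analysis:

``null_parametric``
    no covariates; grand linear time trend gamma plus area-specific
    differential slopes delta_i, BYM area effects u_i + v_i.
``model1a``
    the parametric differential-trend model with all covariates linear.
``model1b``
    as 1a but a declared subset of covariates smoothed by second-order
    random walks over binned covariate values (non-linear effects).
``null_dynamic`` / ``model2``
    the linear trend replaced by a non-parametric dynamic one: an RW2
    period effect phi_t plus an exchangeable period effect psi_t.

All families share the Poisson likelihood y_it ~ Poisson(E_it exp(eta_it))
with internally standardized expected counts E_it as offset, so exp of
any linear predictor component is a relative risk against the study-wide
average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from .panel import ArealPanel

__all__ = [
    "ModelSpec",
    "LatentState",
    "CovariateBinning",
    "expected_counts",
    "linear_predictor",
    "poisson_loglik",
    "FAMILIES",
]

FAMILIES = ("null_parametric", "null_dynamic", "model1a", "model1b", "model2")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model family.

    ``covariate_roles`` maps covariate name -> "linear" | "rw2" |
    "excluded".  Covariates in ``log_covariates`` enter on the natural-log
    scale (population density, conventionally).  ``time_centering`` is the
    calendar period treated as t = 0; when None the middle period of the
    panel is used, so exp(gamma) is the relative risk per period around
    the study midpoint.  ``rw2_bins`` sets the number of equally spaced
    bins an RW2-smoothed covariate is discretized onto.
    """

    family: str
    covariate_roles: Mapping = field(default_factory=dict)
    log_covariates: frozenset = frozenset()
    time_centering: int | None = None
    rw2_bins: int = 100

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        object.__setattr__(self, "covariate_roles", dict(self.covariate_roles))
        object.__setattr__(self, "log_covariates", frozenset(self.log_covariates))
        roles = set(self.covariate_roles.values())
        if not roles <= {"linear", "rw2", "excluded"}:
            raise ValueError(f"invalid covariate roles {roles - {'linear', 'rw2', 'excluded'}}")
        included = {k for k, r in self.covariate_roles.items() if r != "excluded"}
        if self.family in ("null_parametric", "null_dynamic") and included:
            raise ValueError(f"{self.family} admits no covariates")
        if self.family in ("model1a", "model2") and self.rw2_covariates:
            raise ValueError(f"{self.family} requires all included covariates linear")
        if self.family == "model1b" and not self.rw2_covariates:
            raise ValueError("model1b needs at least one rw2 covariate")
        if self.rw2_bins < 3:
            raise ValueError("rw2_bins must be >= 3")

    @property
    def linear_covariates(self) -> tuple:
        return tuple(k for k, r in self.covariate_roles.items() if r == "linear")

    @property
    def rw2_covariates(self) -> tuple:
        return tuple(k for k, r in self.covariate_roles.items() if r == "rw2")

    @property
    def trend(self) -> str:
        """"linear_differential" or "rw2_dynamic", fixed by the family."""
        return ("rw2_dynamic" if self.family in ("null_dynamic", "model2")
                else "linear_differential")

    def validate_against(self, panel: ArealPanel) -> None:
        unknown = set(self.covariate_roles) - set(panel.covariate_names())
        if unknown:
            raise ValueError(f"covariates {sorted(unknown)} not in panel")

    def transformed(self, panel: ArealPanel, name: str) -> np.ndarray:
        """Covariate matrix on its modelling scale (log where declared)."""
        x = panel.covariates[name]
        if name in self.log_covariates:
            if np.any(x <= 0):
                raise ValueError(f"covariate {name!r} must be positive for a log transform")
            return np.log(x)
        return x


@dataclass
class LatentState:
    """One configuration of every latent component of the hierarchy.

    Components a family does not use are zero-length or zero-valued and
    contribute nothing to the linear predictor.  Sum-to-zero constraints
    (u per connected component, delta, phi, psi, every f_k) are enforced
    by the sampler/simulator, not here.
    """

    alpha: float
    beta: dict                       # linear covariate -> coefficient
    gamma: float
    delta: np.ndarray                # (n_areas,)
    u: np.ndarray                    # (n_areas,)
    v: np.ndarray                    # (n_areas,)
    f: dict                          # rw2 covariate -> (rw2_bins,)
    phi: np.ndarray                  # (n_periods,)
    psi: np.ndarray                  # (n_periods,)

    @classmethod
    def zeros(cls, spec: ModelSpec, n_areas: int, n_periods: int) -> "LatentState":
        return cls(alpha=0.0,
                   beta={k: 0.0 for k in spec.linear_covariates},
                   gamma=0.0,
                   delta=np.zeros(n_areas),
                   u=np.zeros(n_areas),
                   v=np.zeros(n_areas),
                   f={k: np.zeros(spec.rw2_bins) for k in spec.rw2_covariates},
                   phi=np.zeros(n_periods),
                   psi=np.zeros(n_periods))

    def copy(self) -> "LatentState":
        return LatentState(alpha=self.alpha, beta=dict(self.beta), gamma=self.gamma,
                           delta=self.delta.copy(), u=self.u.copy(), v=self.v.copy(),
                           f={k: a.copy() for k, a in self.f.items()},
                           phi=self.phi.copy(), psi=self.psi.copy())


@dataclass(frozen=True)
class CovariateBinning:
    """Equally spaced bins over each RW2 covariate's observed range.

    Each observation maps to its nearest bin; values outside the range a
    binning was built from are clamped to the boundary bin with a
    warning.  ``midpoints[name]`` carries the support the fitted curve
    exp(f) is reported on.
    """

    edges: Mapping          # name -> (m+1,) edges
    midpoints: Mapping      # name -> (m,) midpoints

    @classmethod
    def from_panel(cls, spec: ModelSpec, panel: ArealPanel) -> "CovariateBinning":
        edges, mids = {}, {}
        for name in spec.rw2_covariates:
            x = spec.transformed(panel, name)
            lo, hi = float(x.min()), float(x.max())
            if hi <= lo:
                raise ValueError(f"covariate {name!r} is constant; cannot bin")
            e = np.linspace(lo, hi, spec.rw2_bins + 1)
            edges[name] = e
            mids[name] = 0.5 * (e[:-1] + e[1:])
        return cls(edges=dict(edges), midpoints=dict(mids))

    def bin_index(self, name: str, x: np.ndarray) -> np.ndarray:
        e = self.edges[name]
        m = len(e) - 1
        if np.any(x < e[0] - 1e-12) or np.any(x > e[-1] + 1e-12):
            warnings.warn(f"covariate {name!r} values outside the binning range; "
                          "clamped to boundary bins", stacklevel=2)
        idx = np.floor((x - e[0]) / (e[-1] - e[0]) * m).astype(int)
        return np.clip(idx, 0, m - 1)


def expected_counts(panel: ArealPanel) -> np.ndarray:
    """Internally standardized expected counts E_it = P_it * overall rate.

    The overall rate is total events over total person-periods, so
    conservation Sum E = Sum y holds exactly and fitted relative risks
    are against the study-wide average.
    """
    total = panel.counts.sum()
    if total == 0:
        raise ValueError("panel has no events; overall rate undefined")
    return panel.population * (total / panel.population.sum())


def time_index(spec: ModelSpec, panel: ArealPanel) -> np.ndarray:
    """Centred time covariate t~ = period - reference (middle by default)."""
    periods = np.asarray(panel.periods, dtype=float)
    center = spec.time_centering
    if center is None:
        center = periods[len(periods) // 2]
    return periods - float(center)


def linear_predictor(spec: ModelSpec, state: LatentState, panel: ArealPanel,
                     binning: CovariateBinning | None = None) -> np.ndarray:
    """Assemble eta_it from the latent state.

    eta = alpha + sum_k beta_k x_itk + sum_k f_k[bin(x_itk)] + u_i + v_i
          + (gamma + delta_i) t~_t            (linear differential trend)
      or  ... + phi_t + psi_t                 (dynamic trend)
    """
    spec.validate_against(panel)
    n, T = panel.n_areas, panel.n_periods
    eta = np.full((n, T), state.alpha)
    for name in spec.linear_covariates:
        eta += state.beta[name] * spec.transformed(panel, name)
    if spec.rw2_covariates:
        if binning is None:
            binning = CovariateBinning.from_panel(spec, panel)
        for name in spec.rw2_covariates:
            idx = binning.bin_index(name, spec.transformed(panel, name))
            eta += state.f[name][idx]
    eta += state.u[:, None] + state.v[:, None]
    if spec.trend == "linear_differential":
        eta += (state.gamma + state.delta[:, None]) * time_index(spec, panel)[None, :]
    else:
        eta += (state.phi + state.psi)[None, :]
    return eta


def poisson_loglik(y: np.ndarray, E: np.ndarray, eta: np.ndarray) -> float:
    """Poisson log-likelihood with offset: sum over cells of
    y(log E + eta) - E exp(eta) - log(y!)."""
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if not (y.shape == E.shape == eta.shape):
        raise ValueError("y, E, eta must share a shape")
    if np.any(E <= 0):
        raise ValueError("offsets E must be strictly positive")
    if np.isnan(eta).any() or np.isnan(y).any():
        raise ValueError("NaN in likelihood inputs")
    ll = y * (np.log(E) + eta) - E * np.exp(eta) - gammaln(y + 1.0)
    return float(ll.sum())
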