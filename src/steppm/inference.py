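"""MCMC inference for the space-time Poisson hierarchy.

The posterior is explored by adaptive Metropolis-within-Gibbs: every
precision hyperparameter gets a conjugate Gamma update given its field's
quadratic form, and every latent coordinate (intercept, coefficients,
trend slope, and each element of the delta/u/v/f/phi/psi fields) gets a
single-site Gaussian random-walk update with a per-site step size adapted
toward 0.44 acceptance during burn-in and frozen afterwards.  Site
updates within a field are executed in conditional-independence batches —
colour classes of the neighbour graph for the ICAR field, every third
index for RW2 fields, all at once for exchangeable fields — which is
mathematically identical to sweeping the sites one at a time within a
class.  After each sweep the identifying sum-to-zero constraints are
re-imposed by centring, with the removed means folded into the intercept
(or the grand slope, for the differential field) so the linear predictor
is unchanged.

Reported summaries follow the disease-mapping conventions: relative risk
exp(posterior mean coefficient) with exp-quantile 95% credibility
intervals, per-area residual relative risks exp(u_i + v_i), differential
trends exp(delta_i), non-linear covariate curves exp(f), and the DIC with
the plug-in deviance taken at the posterior mean linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gmrf import GMRFStructure, icar_structure, iid_structure, rw2_structure, scale_structure
from .model import (
    CovariateBinning,
    LatentState,
    ModelSpec,
    expected_counts,
    linear_predictor,
    poisson_loglik,
    time_index,
)
from .panel import ArealPanel
from .weights import SpatialWeights, as_binary

__all__ = [
    "Hyperpriors",
    "MCMCConfig",
    "PosteriorDraws",
    "DICResult",
    "EffectSummary",
    "fit",
    "update_precision",
    "dic",
    "summarize",
    "sensitivity_rerun",
    "greedy_coloring",
]

_DIVERGENCE_BOUND = 50.0


@dataclass(frozen=True)
class Hyperpriors:
    """Gamma(shape, rate) priors on the precision hyperparameters.

    The default Gamma(1, 5e-5) is the vague precision prior conventional
    in disease mapping.  ``per_precision`` overrides individual
    precisions by name ("tau_u", "tau_v", "tau_delta", "tau_phi",
    "tau_psi", "tau_f:<covariate>").  ``sigma2_fixed`` is the variance of
    the vague Normal prior on the intercept, coefficients and grand
    slope.
    """

    shape: float = 1.0
    rate: float = 5e-5
    per_precision: Mapping = field(default_factory=dict)
    sigma2_fixed: float = 1000.0

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0 or self.sigma2_fixed <= 0:
            raise ValueError("hyperprior parameters must be positive")
        for a, b in dict(self.per_precision).values():
            if a <= 0 or b <= 0:
                raise ValueError("hyperprior parameters must be positive")

    def gamma_for(self, name: str) -> tuple:
        return tuple(self.per_precision.get(name, (self.shape, self.rate)))


@dataclass(frozen=True)
class MCMCConfig:
    n_iterations: int = 10_000
    n_burnin: int = 4_000
    thin: int = 1
    seed: int = 0
    adaptation_window: int = 50
    target_accept: float = 0.44

    def __post_init__(self):
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 < self.target_accept < 1):
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class PosteriorDraws:
    """Stored MCMC draws for every latent component and precision."""

    spec: ModelSpec
    seed: int
    area_ids: tuple
    periods: tuple
    alpha: np.ndarray                 # (S,)
    beta: dict                        # name -> (S,)
    gamma: np.ndarray                 # (S,)
    delta: np.ndarray                 # (S, n)
    u: np.ndarray                     # (S, n)
    v: np.ndarray                     # (S, n)
    f: dict                           # name -> (S, m)
    phi: np.ndarray                   # (S, T)
    psi: np.ndarray                   # (S, T)
    tau: dict                         # name -> (S,)
    acceptance: dict
    rhat: dict
    binning: CovariateBinning | None = None
    bin_counts: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.alpha)

    def state_at(self, s: int) -> LatentState:
        return LatentState(
            alpha=float(self.alpha[s]),
            beta={k: float(b[s]) for k, b in self.beta.items()},
            gamma=float(self.gamma[s]),
            delta=self.delta[s].copy(), u=self.u[s].copy(), v=self.v[s].copy(),
            f={k: a[s].copy() for k, a in self.f.items()},
            phi=self.phi[s].copy(), psi=self.psi[s].copy())


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion with the latent-field focus."""

    Dbar: float
    D_hat: float

    @property
    def pD(self) -> float:
        return self.Dbar - self.D_hat

    @property
    def DIC(self) -> float:
        return self.Dbar + self.pD


@dataclass(frozen=True)
class EffectSummary:
    """Posterior summaries as tidy tables.

    ``fixed`` has one row per fixed effect (Intercept, Year where the
    trend is parametric, each linear covariate) with RR and 95% CI;
    ``area`` has per-area differential trends exp(delta_i) and residual
    relative risks exp(u_i + v_i); ``curves`` the exp(f) non-linear
    curves over bin midpoints; ``period`` the dynamic trend exp(phi+psi);
    ``precisions`` posterior summaries of every tau.
    """

    fixed: pd.DataFrame
    area: pd.DataFrame
    curves: dict
    period: pd.DataFrame
    precisions: pd.DataFrame

    def tables(self) -> dict:
        out = {"fixed_effects": self.fixed, "area_effects": self.area,
               "period_effects": self.period, "precisions": self.precisions}
        for name, tab in self.curves.items():
            out[f"curve_{name}"] = tab
        return out


def update_precision(field_vec, s: GMRFStructure, prior: tuple, seed=None) -> float:
    """Conjugate Gamma update for a field's precision.

    tau | field ~ Gamma(a + (m - d)/2, b + field' Q field / 2), with d the
    structure's rank deficiency.  ``seed`` is an int or Generator.
    """
    a, b = prior
    if a <= 0 or b <= 0:
        raise ValueError("prior parameters must be positive")
    q = s.quad_form(field_vec)
    if q < -1e-10:
        raise ValueError("negative quadratic form: structure not PSD")
    q = max(q, 0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return float(rng.gamma(a + 0.5 * s.rank, 1.0 / (b + 0.5 * q)))


def greedy_coloring(neighbors: Sequence[Sequence[int]]) -> list:
    """Partition graph nodes into independent sets (colour classes).

    Greedy largest-degree-first colouring; within a class no two nodes
    are adjacent, so their full conditionals are independent given the
    rest of the field.
    """
    n = len(neighbors)
    order = sorted(range(n), key=lambda i: -len(neighbors[i]))
    color = [-1] * n
    for i in order:
        used = {color[j] for j in neighbors[i] if color[j] >= 0}
        c = 0
        while c in used:
            c += 1
        color[i] = c
    classes = [[] for _ in range(max(color) + 1)]
    for i, c in enumerate(color):
        classes[c].append(i)
    return [np.asarray(cls, dtype=int) for cls in classes]


class _Adaptive:
    """Per-site Robbins-Monro step-size adaptation toward a target rate."""

    def __init__(self, size: int, target: float, window: int, initial: float = 0.1):
        self.log_s = np.full(size, np.log(initial))
        self.target = target
        self.window = window
        self.accepted = np.zeros(size)
        self.proposed = np.zeros(size)
        self.batches = 0
        self.frozen = False
        self.total_acc = 0.0
        self.total_prop = 0.0

    @property
    def step(self) -> np.ndarray:
        return np.exp(self.log_s)

    def record(self, accepted):
        acc = np.asarray(accepted, dtype=float)
        self.total_acc += acc.sum()
        self.total_prop += acc.size if acc.ndim else 1
        if self.frozen:
            return
        self.accepted += acc
        self.proposed += 1.0
        if self.proposed[0] >= self.window:
            self.batches += 1
            rate = self.accepted / np.maximum(self.proposed, 1.0)
            gain = min(0.5, 2.0 / np.sqrt(self.batches))
            self.log_s += gain * (rate - self.target)
            np.clip(self.log_s, -15.0, 5.0, out=self.log_s)
            self.accepted[:] = 0.0
            self.proposed[:] = 0.0

    @property
    def overall_rate(self) -> float:
        return self.total_acc / max(self.total_prop, 1.0)


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter."""
    S = len(x)
    L = S // 2
    if L < 2:
        return float("nan")
    halves = np.stack([x[:L], x[S - L:]])
    within = halves.var(axis=1, ddof=1).mean()
    between = L * halves.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0 if between <= 0 else float("inf")
    var_hat = (L - 1) / L * within + between / L
    return float(np.sqrt(var_hat / within))


def fit(spec: ModelSpec, panel: ArealPanel, w: SpatialWeights,
        priors: Hyperpriors | None = None, cfg: MCMCConfig | None = None,
        binning: CovariateBinning | None = None, offset=None) -> PosteriorDraws:
    """Fit a model family to a panel by adaptive Metropolis-within-Gibbs.

    Deterministic given ``cfg.seed``.  Initialization is all latent
    components at zero and all precisions at one.  ``offset`` overrides
    the internally standardized expected counts (e.g. externally
    standardized E_it).  Raises on a non-finite log-posterior at
    initialization and on divergence (|eta| exceeding 50) with the
    offending iteration.
    """
    priors = priors or Hyperpriors()
    cfg = cfg or MCMCConfig()
    spec.validate_against(panel)
    if w.n != panel.n_areas:
        raise ValueError("weights dimension does not match the panel")

    rng = np.random.default_rng(cfg.seed)
    n, T = panel.n_areas, panel.n_periods
    y = panel.counts.astype(float)
    E = np.asarray(offset, dtype=float) if offset is not None else expected_counts(panel)
    if E.shape != y.shape or np.any(E <= 0):
        raise ValueError("offset must be positive with the panel's shape")
    tt = time_index(spec, panel)
    parametric = spec.trend == "linear_differential"

    # design pieces; covariates are centred at their grand mean inside the
    # sampler (a pure reparametrization that decorrelates the intercept
    # from the coefficients) and the stored intercept is mapped back
    xbar = {k: float(spec.transformed(panel, k).mean()) for k in spec.linear_covariates}
    X = {k: spec.transformed(panel, k) - xbar[k] for k in spec.linear_covariates}
    SYX = {k: float((y * X[k]).sum()) for k in X}
    Yrow, Ycol, Ytot = y.sum(axis=1), y.sum(axis=0), float(y.sum())
    Ytt_row = (y * tt[None, :]).sum(axis=1)
    Ytt_tot = float(Ycol @ tt)

    if spec.rw2_covariates and binning is None:
        binning = CovariateBinning.from_panel(spec, panel)
    m_bins = spec.rw2_bins
    idx_f = {k: binning.bin_index(k, spec.transformed(panel, k))
             for k in spec.rw2_covariates}
    SY_f = {k: np.bincount(idx_f[k].ravel(), weights=y.ravel(), minlength=m_bins)
            for k in spec.rw2_covariates}
    bin_counts = {k: np.bincount(idx_f[k].ravel(), minlength=m_bins)
                  for k in spec.rw2_covariates}

    # GMRF structures (scaled, per the modelling convention)
    wb = as_binary(w)
    s_u = icar_structure(wb)
    if len(wb.islands) < n:        # an edgeless graph has nothing to scale
        s_u = scale_structure(s_u)
    Q_u = sp.csr_matrix(s_u.Q)
    qdiag_u = s_u.Q.diagonal().copy()
    s_v = iid_structure(n)
    s_delta = iid_structure(n)
    s_phi = scale_structure(rw2_structure(T)) if (not parametric and T >= 3) else None
    s_psi = iid_structure(T)
    s_f = {k: scale_structure(rw2_structure(m_bins)) for k in spec.rw2_covariates}
    Q_f = {k: sp.csr_matrix(s_f[k].Q) for k in spec.rw2_covariates}
    if not parametric and s_phi is None:
        raise ValueError("dynamic trend needs at least 3 periods")
    Q_phi = sp.csr_matrix(s_phi.Q) if s_phi is not None else None

    islands = np.asarray(sorted(wb.islands), dtype=int)
    non_island = np.setdiff1d(np.arange(n), islands)
    u_classes = [cls[~np.isin(cls, islands)] for cls in greedy_coloring(wb.neighbors)]
    u_classes = [cls for cls in u_classes if cls.size]
    f_classes = [np.arange(c, m_bins, 3) for c in range(3)]
    phi_classes = [np.arange(c, T, 3) for c in range(3) if c < T]
    comp_labels = np.asarray(wb.component_labels)

    state = LatentState.zeros(spec, n, T)
    tau = {"tau_u": 1.0, "tau_v": 1.0}
    if parametric:
        tau["tau_delta"] = 1.0
    else:
        tau["tau_phi"] = 1.0
        tau["tau_psi"] = 1.0
    for k in spec.rw2_covariates:
        tau[f"tau_f:{k}"] = 1.0

    def eta_internal(st: LatentState) -> np.ndarray:
        out = np.full((n, T), st.alpha)
        for k in X:
            out += st.beta[k] * X[k]
        for k in spec.rw2_covariates:
            out += st.f[k][idx_f[k]]
        out += st.u[:, None] + st.v[:, None]
        if parametric:
            out += (st.gamma + st.delta[:, None]) * tt[None, :]
        else:
            out += (st.phi + st.psi)[None, :]
        return out

    eta = eta_internal(state)
    if not np.isfinite(poisson_loglik(y, E, eta)):
        raise RuntimeError("non-finite log-posterior at initialization")

    sig2 = priors.sigma2_fixed
    tgt, win = cfg.target_accept, cfg.adaptation_window
    ad = {"alpha": _Adaptive(1, tgt, win, 0.05),
          "gamma": _Adaptive(1, tgt, win, 0.02),
          "u": _Adaptive(n, tgt, win), "v": _Adaptive(n, tgt, win)}
    for k in X:
        ad[f"beta:{k}"] = _Adaptive(1, tgt, win, 0.02)
    if parametric:
        ad["delta"] = _Adaptive(n, tgt, win, 0.02)
    else:
        ad["phi"] = _Adaptive(T, tgt, win)
        ad["psi"] = _Adaptive(T, tgt, win)
    for k in spec.rw2_covariates:
        ad[f"f:{k}"] = _Adaptive(m_bins, tgt, win)

    S = (cfg.n_iterations - cfg.n_burnin + cfg.thin - 1) // cfg.thin
    store = {
        "alpha": np.empty(S), "gamma": np.empty(S),
        "beta": {k: np.empty(S) for k in X},
        "delta": np.empty((S, n)), "u": np.empty((S, n)), "v": np.empty((S, n)),
        "f": {k: np.empty((S, m_bins)) for k in spec.rw2_covariates},
        "phi": np.empty((S, T)), "psi": np.empty((S, T)),
        "tau": {k: np.empty(S) for k in tau},
    }
    s_out = 0

    def scalar_update(name, current, delta_ll_fn, adapter):
        """One Gaussian RW Metropolis step for a scalar with N(0, sig2) prior."""
        d = adapter.step[0] * rng.standard_normal()
        lap = delta_ll_fn(d) - ((current + d) ** 2 - current ** 2) / (2.0 * sig2)
        acc = np.log(rng.random()) < lap
        adapter.record([acc])
        return (current + d) if acc else current, acc, d

    for it in range(cfg.n_iterations):
        if it == cfg.n_burnin:
            for a in ad.values():
                a.frozen = True

        Eexp = E * np.exp(eta)

        # --- intercept ---
        tot = float(Eexp.sum())
        state.alpha, acc, d = scalar_update(
            "alpha", state.alpha,
            lambda d: d * Ytot - (np.exp(d) - 1.0) * tot, ad["alpha"])
        if acc:
            eta += d
            Eexp *= np.exp(d)

        # --- linear coefficients ---
        for k in X:
            Xk = X[k]

            def dll(d, Xk=Xk, k=k):
                return d * SYX[k] - float((Eexp * np.expm1(d * Xk)).sum())

            state.beta[k], acc, d = scalar_update(k, state.beta[k], dll, ad[f"beta:{k}"])
            if acc:
                eta += d * Xk
                Eexp *= np.exp(d * Xk)

        if parametric:
            # --- grand slope ---
            Ecol = Eexp.sum(axis=0)

            def dll_g(d):
                return d * Ytt_tot - float(Ecol @ np.expm1(d * tt))

            state.gamma, acc, d = scalar_update("gamma", state.gamma, dll_g, ad["gamma"])
            if acc:
                eta += d * tt[None, :]
                Eexp *= np.exp(d * tt)[None, :]

            # --- differential slopes (iid prior, likelihood separable by area) ---
            dprop = ad["delta"].step * rng.standard_normal(n)
            dE = np.expm1(np.outer(dprop, tt))
            dll = dprop * Ytt_row - (Eexp * dE).sum(axis=1)
            dlp = -0.5 * tau["tau_delta"] * ((state.delta + dprop) ** 2 - state.delta ** 2)
            acc = np.log(rng.random(n)) < dll + dlp
            ad["delta"].record(acc)
            if acc.any():
                state.delta[acc] += dprop[acc]
                eta[acc] += np.outer(dprop[acc], tt)
                Eexp[acc] *= np.exp(np.outer(dprop[acc], tt))

        # --- structured area effects, one colour class at a time ---
        # within a class no two sites are adjacent, so the batch is
        # identical to a site-by-site sweep of that class
        Erow = Eexp.sum(axis=1)
        acc_u = np.zeros(n, dtype=bool)
        for cls in u_classes:
            Qu = Q_u @ state.u
            dprop = ad["u"].step[cls] * rng.standard_normal(cls.size)
            dll = dprop * Yrow[cls] - Erow[cls] * np.expm1(dprop)
            dlp = -0.5 * tau["tau_u"] * (2.0 * dprop * Qu[cls] + dprop ** 2 * qdiag_u[cls])
            acc = np.log(rng.random(cls.size)) < dll + dlp
            acc_u[cls[acc]] = True
            if acc.any():
                da = dprop[acc]
                state.u[cls[acc]] += da
                eta[cls[acc]] += da[:, None]
                fac = np.exp(da)
                Eexp[cls[acc]] *= fac[:, None]
                Erow[cls[acc]] *= fac
        ad["u"].record(acc_u)

        # --- unstructured area effects (fully exchangeable: one batch) ---
        Erow = Eexp.sum(axis=1)
        dprop = ad["v"].step * rng.standard_normal(n)
        dll = dprop * Yrow - Erow * np.expm1(dprop)
        dlp = -0.5 * tau["tau_v"] * (2.0 * dprop * state.v + dprop ** 2)
        acc = np.log(rng.random(n)) < dll + dlp
        ad["v"].record(acc)
        if acc.any():
            da = dprop[acc]
            state.v[acc] += da
            eta[acc] += da[:, None]
            Eexp[acc] *= np.exp(da)[:, None]

        if not parametric:
            # --- dynamic trend: RW2 period effect, colour classes mod 3
            #     (RW2 couples indices up to distance 2) ---
            qd_phi = s_phi.Q.diagonal()
            acc_phi = np.zeros(T, dtype=bool)
            for cls in phi_classes:
                Ecol = Eexp.sum(axis=0)
                Qp = Q_phi @ state.phi
                dprop = ad["phi"].step[cls] * rng.standard_normal(cls.size)
                dll = dprop * Ycol[cls] - Ecol[cls] * np.expm1(dprop)
                dlp = -0.5 * tau["tau_phi"] * (2.0 * dprop * Qp[cls] + dprop ** 2 * qd_phi[cls])
                acc = np.log(rng.random(cls.size)) < dll + dlp
                acc_phi[cls[acc]] = True
                if acc.any():
                    da = dprop[acc]
                    state.phi[cls[acc]] += da
                    eta[:, cls[acc]] += da[None, :]
                    Eexp[:, cls[acc]] *= np.exp(da)[None, :]
            ad["phi"].record(acc_phi)

            # --- exchangeable period effect ---
            Ecol = Eexp.sum(axis=0)
            dprop = ad["psi"].step * rng.standard_normal(T)
            dll = dprop * Ycol - Ecol * np.expm1(dprop)
            dlp = -0.5 * tau["tau_psi"] * (2.0 * dprop * state.psi + dprop ** 2)
            acc = np.log(rng.random(T)) < dll + dlp
            ad["psi"].record(acc)
            if acc.any():
                da = dprop[acc]
                state.psi[acc] += da
                eta[:, acc] += da[None, :]
                Eexp[:, acc] *= np.exp(da)[None, :]

        # --- RW2 covariate curves ---
        for k in spec.rw2_covariates:
            idx = idx_f[k]
            SE = np.bincount(idx.ravel(), weights=Eexp.ravel(), minlength=m_bins)
            fk = state.f[k]
            adk = ad[f"f:{k}"]
            qd = s_f[k].Q.diagonal()
            changed = np.zeros(m_bins)
            acc_f = np.zeros(m_bins, dtype=bool)
            for cls in f_classes:
                Qf = Q_f[k] @ fk
                dprop = adk.step[cls] * rng.standard_normal(cls.size)
                dll = dprop * SY_f[k][cls] - SE[cls] * np.expm1(dprop)
                dlp = -0.5 * tau[f"tau_f:{k}"] * (2.0 * dprop * Qf[cls] + dprop ** 2 * qd[cls])
                acc = np.log(rng.random(cls.size)) < dll + dlp
                acc_f[cls[acc]] = True
                if acc.any():
                    da = dprop[acc]
                    fk[cls[acc]] += da
                    SE[cls[acc]] *= np.exp(da)
                    changed[cls[acc]] += da
            adk.record(acc_f)
            if changed.any():
                deta = changed[idx]
                eta += deta
                Eexp *= np.exp(deta)

        # --- conjugate precision updates ---
        tau["tau_u"] = update_precision(state.u, s_u, priors.gamma_for("tau_u"), rng)
        tau["tau_v"] = update_precision(state.v, s_v, priors.gamma_for("tau_v"), rng)
        if parametric:
            tau["tau_delta"] = update_precision(state.delta, s_delta,
                                                priors.gamma_for("tau_delta"), rng)
        else:
            tau["tau_phi"] = update_precision(state.phi, s_phi,
                                              priors.gamma_for("tau_phi"), rng)
            tau["tau_psi"] = update_precision(state.psi, s_psi,
                                              priors.gamma_for("tau_psi"), rng)
        for k in spec.rw2_covariates:
            tau[f"tau_f:{k}"] = update_precision(state.f[k], s_f[k],
                                                 priors.gamma_for(f"tau_f:{k}"), rng)

        # --- constraint re-projection (centring; eta-preserving sweeps) ---
        for c in np.unique(comp_labels):
            members = np.flatnonzero(comp_labels == c)
            if members.size == 1 and members[0] in wb.islands:
                state.u[members] = 0.0        # point constraint at islands
                continue
            mean_u = state.u[members].mean()
            state.u[members] -= mean_u
            state.v[members] += mean_u
        mean_v = state.v.mean()
        state.v -= mean_v
        state.alpha += mean_v
        if parametric:
            mean_d = state.delta.mean()
            state.delta -= mean_d
            state.gamma += mean_d
        else:
            for vec in (state.phi, state.psi):
                mv = vec.mean()
                vec -= mv
                state.alpha += mv
        for k in spec.rw2_covariates:
            mf = state.f[k].mean()
            state.f[k] -= mf
            state.alpha += mf

        # recompute eta exactly from the centred state (no drift)
        eta = eta_internal(state)
        if np.max(np.abs(eta)) > _DIVERGENCE_BOUND:
            raise RuntimeError(f"divergent chain: |eta| > {_DIVERGENCE_BOUND} "
                               f"at iteration {it}")

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            # map the internally centred intercept back to the raw scale
            store["alpha"][s_out] = state.alpha - sum(
                state.beta[k] * xbar[k] for k in X)
            store["gamma"][s_out] = state.gamma
            for k in X:
                store["beta"][k][s_out] = state.beta[k]
            store["delta"][s_out] = state.delta
            store["u"][s_out] = state.u
            store["v"][s_out] = state.v
            for k in spec.rw2_covariates:
                store["f"][k][s_out] = state.f[k]
            store["phi"][s_out] = state.phi
            store["psi"][s_out] = state.psi
            for k in tau:
                store["tau"][k][s_out] = tau[k]
            s_out += 1

    acceptance = {k: a.overall_rate for k, a in ad.items()}
    rhat = {"alpha": _split_rhat(store["alpha"])}
    if parametric:
        rhat["gamma"] = _split_rhat(store["gamma"])
    for k in X:
        rhat[f"beta:{k}"] = _split_rhat(store["beta"][k])

    return PosteriorDraws(
        spec=spec, seed=cfg.seed, area_ids=panel.area_ids, periods=panel.periods,
        alpha=store["alpha"], beta=store["beta"], gamma=store["gamma"],
        delta=store["delta"], u=store["u"], v=store["v"], f=store["f"],
        phi=store["phi"], psi=store["psi"], tau=store["tau"],
        acceptance=acceptance, rhat=rhat, binning=binning,
        bin_counts={k: c.copy() for k, c in bin_counts.items()})


def dic(draws: PosteriorDraws, panel: ArealPanel, spec: ModelSpec | None = None,
        offset=None) -> DICResult:
    """DIC = Dbar + pD with deviance D = -2 log-likelihood and the plug-in
    deviance evaluated at the posterior mean linear predictor."""
    spec = spec or draws.spec
    if draws.n_draws < 2:
        raise ValueError("need at least 2 stored draws")
    y = panel.counts.astype(float)
    E = np.asarray(offset, dtype=float) if offset is not None else expected_counts(panel)
    dev_sum = 0.0
    eta_sum = np.zeros((panel.n_areas, panel.n_periods))
    for s in range(draws.n_draws):
        eta = linear_predictor(spec, draws.state_at(s), panel, draws.binning)
        dev_sum += -2.0 * poisson_loglik(y, E, eta)
        eta_sum += eta
    Dbar = dev_sum / draws.n_draws
    D_hat = -2.0 * poisson_loglik(y, E, eta_sum / draws.n_draws)
    return DICResult(Dbar=Dbar, D_hat=D_hat)


def _rr_row(name, x):
    return {"effect": name, "RR": float(np.exp(np.mean(x))),
            "ci_2.5": float(np.exp(np.quantile(x, 0.025))),
            "ci_97.5": float(np.exp(np.quantile(x, 0.975)))}


def summarize(draws: PosteriorDraws) -> EffectSummary:
    """Posterior relative-risk summaries for every reported component."""
    if draws.n_draws == 0:
        raise ValueError("empty draws")
    spec = draws.spec
    rows = [_rr_row("Intercept", draws.alpha)]
    if spec.trend == "linear_differential":
        rows.append(_rr_row("Year", draws.gamma))
    for k, b in draws.beta.items():
        rows.append(_rr_row(k, b))
    fixed = pd.DataFrame(rows)

    uv = draws.u + draws.v
    area = pd.DataFrame({
        "area": list(draws.area_ids),
        "rr_differential_trend": np.exp(draws.delta.mean(axis=0)),
        "trend_ci_2.5": np.exp(np.quantile(draws.delta, 0.025, axis=0)),
        "trend_ci_97.5": np.exp(np.quantile(draws.delta, 0.975, axis=0)),
        "rr_residual": np.exp(uv.mean(axis=0)),
        "residual_ci_2.5": np.exp(np.quantile(uv, 0.025, axis=0)),
        "residual_ci_97.5": np.exp(np.quantile(uv, 0.975, axis=0)),
    })

    curves = {}
    for k, fdraws in draws.f.items():
        mids = draws.binning.midpoints[k] if draws.binning else np.arange(fdraws.shape[1])
        curves[k] = pd.DataFrame({
            "value": mids,
            "rr": np.exp(fdraws.mean(axis=0)),
            "ci_2.5": np.exp(np.quantile(fdraws, 0.025, axis=0)),
            "ci_97.5": np.exp(np.quantile(fdraws, 0.975, axis=0)),
            "n_obs": draws.bin_counts.get(k, np.zeros(fdraws.shape[1], dtype=int)),
        })

    trend = draws.phi + draws.psi
    period = pd.DataFrame({
        "period": list(draws.periods),
        "rr_trend": np.exp(trend.mean(axis=0)),
        "ci_2.5": np.exp(np.quantile(trend, 0.025, axis=0)),
        "ci_97.5": np.exp(np.quantile(trend, 0.975, axis=0)),
    })

    prec = pd.DataFrame([{"precision": k, "mean": float(np.mean(x)),
                          "ci_2.5": float(np.quantile(x, 0.025)),
                          "ci_97.5": float(np.quantile(x, 0.975))}
                         for k, x in draws.tau.items()])
    return EffectSummary(fixed=fixed, area=area, curves=curves, period=period,
                         precisions=prec)


def sensitivity_rerun(spec: ModelSpec, panel: ArealPanel, w: SpatialWeights,
                      prior_grid: Sequence[Hyperpriors], cfg: MCMCConfig) -> pd.DataFrame:
    """Refit under each hyperprior setting and report, per fixed effect,
    the maximum absolute shift in log-RR relative to the first setting."""
    if len(prior_grid) < 2:
        raise ValueError("need >= 2 prior settings")
    summaries = []
    for priors in prior_grid:
        summaries.append(summarize(fit(spec, panel, w, priors=priors, cfg=cfg)))
    base = summaries[0].fixed.set_index("effect")["RR"]
    rows = []
    for effect in base.index:
        shifts = [abs(float(np.log(s.fixed.set_index("effect").loc[effect, "RR"])
                            - np.log(base[effect])))
                  for s in summaries]
        rows.append({"effect": effect, "max_abs_logrr_shift": max(shifts)})
    return pd.DataFrame(rows)
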