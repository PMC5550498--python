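"""Synthetic areal panels with the structure the space-time models assume.

The simulator emulates a national district panel — around four hundred
areas observed over five yearly periods — on a rectangular lattice of
unit-square "districts" with queen contiguity.  Populations are
log-normal across areas; covariates are spatially smoothed Gaussian
fields (scaled-ICAR draws plus white noise around a plausible mean), the
time-varying ones evolving as stationary AR(1) processes across periods
and the static ones held fixed; counts are Poisson with a population
offset at a baseline rate of order 12 per 100,000 person-years and a
log-linear risk surface built from true coefficients, BYM area effects
and a linear-differential or dynamic time trend.  Ground truth is
recorded alongside the panel so parameter recovery is checkable.

Default true effects sit in the regime the analysis is designed for:
per-unit relative risks of 0.994 (income, per EUR 1,000), 1.015
(unemployment, per %), 0.959 (log population density) and a grand trend
of 1.008 per year, with weak effects for the remaining covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .gmrf import icar_structure, rw2_structure, sample_constrained, scale_structure
from .model import LatentState, ModelSpec
from .panel import ArealPanel
from .weights import SpatialWeights, queen_adjacency

__all__ = [
    "CovariateSpec",
    "SimulationScenario",
    "SimulationResult",
    "make_lattice",
    "simulate_covariates",
    "simulate_counts",
    "default_covariates",
]

_MEAN_OVERFLOW = 1e9


@dataclass(frozen=True)
class CovariateSpec:
    """Generator settings for one covariate field.

    The field is ``mean + spatial + noise`` with the spatial part a
    scaled-ICAR draw times ``spatial_sd`` and the noise white with
    ``noise_sd``.  Time-varying fields evolve as a stationary AR(1) with
    persistence ``rho`` (deviations from the mean); static fields are a
    single draw broadcast over periods.  ``log_scale`` simulates the
    Gaussian field for log(x) and exponentiates (population density).
    Values are clipped to [lower, upper] plausibility bounds.
    """

    name: str
    mean: float
    spatial_sd: float
    noise_sd: float
    time_varying: bool = False
    rho: float = 0.9
    lower: float = -math.inf
    upper: float = math.inf
    log_scale: bool = False
    unit: str = ""

    def __post_init__(self):
        if self.spatial_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("AR(1) persistence rho must be in [0, 1]")


def default_covariates() -> tuple:
    """The study-like covariate set: three time-varying fields (income in
    EUR 1,000, unemployment in %, population density in people/km2) and
    four static ones (depression prevalence in %, general practitioners,
    psychiatrists and psychotherapists per 100,000)."""
    return (
        CovariateSpec("income", 19.0, 1.5, 0.5, time_varying=True, rho=0.9,
                      lower=10.0, upper=35.0, unit="EUR 1,000"),
        CovariateSpec("unemployment", 8.0, 3.5, 0.6, time_varying=True, rho=0.9,
                      lower=0.5, upper=20.0, unit="%"),
        CovariateSpec("population_density", math.log(200.0), 0.9, 0.2,
                      time_varying=True, rho=0.98, lower=math.log(36.0),
                      upper=math.log(5000.0), log_scale=True, unit="people/km2"),
        CovariateSpec("depression", 8.0, 1.5, 0.5, lower=2.0, upper=15.0, unit="%"),
        CovariateSpec("gps", 65.0, 6.0, 3.0, lower=40.0, upper=90.0, unit="per 100,000"),
        CovariateSpec("psychiatrists", 5.0, 1.5, 0.5, lower=0.5, upper=15.0,
                      unit="per 100,000"),
        CovariateSpec("psychotherapists", 20.0, 5.0, 2.0, lower=2.0, upper=50.0,
                      unit="per 100,000"),
    )


def _default_beta() -> dict:
    return {
        "income": math.log(0.994),
        "unemployment": math.log(1.015),
        "population_density": math.log(0.959),
        "depression": math.log(1.010),
        "gps": math.log(1.003),
        "psychiatrists": 0.0,
        "psychotherapists": math.log(1.005),
    }


@dataclass(frozen=True)
class SimulationScenario:
    """Everything that defines one synthetic study.

    ``beta`` holds true per-unit log relative risks (log of the covariate
    transform where one is declared); ``nonlinear_truth`` replaces a
    covariate's linear effect with an arbitrary true curve g(x) on the
    modelling scale, exercising RW2 smoothing.  Field standard
    deviations ``sd_u``/``sd_v``/``sd_delta`` (and ``sd_phi``/``sd_psi``
    for dynamic trends) are on the log-risk scale; the corresponding
    precisions are their inverse squares.
    """

    rows: int = 20
    cols: int = 20
    n_periods: int = 5
    first_period: int = 2007
    seed: int = 0
    population_median: float = 150_000.0
    population_sigma: float = 0.6
    baseline_rate: float = 12e-5
    covariates: tuple = field(default_factory=default_covariates)
    beta: Mapping = field(default_factory=_default_beta)
    nonlinear_truth: Mapping = field(default_factory=dict)
    gamma: float = math.log(1.008)
    sd_u: float = 0.15
    sd_v: float = 0.05
    sd_delta: float = 0.005
    sd_phi: float = 0.02
    sd_psi: float = 0.01

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ValueError("lattice must be at least 2x2")
        if self.n_periods < 2:
            raise ValueError("need at least 2 periods")
        for sd in (self.sd_u, self.sd_v, self.sd_delta, self.sd_phi, self.sd_psi):
            if sd < 0:
                raise ValueError("field standard deviations must be >= 0")
        if self.baseline_rate <= 0 or self.population_median <= 0:
            raise ValueError("baseline rate and population must be positive")
        object.__setattr__(self, "beta", dict(self.beta))
        object.__setattr__(self, "nonlinear_truth", dict(self.nonlinear_truth))

    @property
    def n_areas(self) -> int:
        return self.rows * self.cols

    @property
    def periods(self) -> tuple:
        return tuple(self.first_period + t for t in range(self.n_periods))

    def covariate(self, name: str) -> CovariateSpec:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def model_spec(self, family: str, rw2: tuple = (), rw2_bins: int = 100) -> ModelSpec:
        """A ModelSpec over this scenario's covariates, density logged."""
        if family in ("null_parametric", "null_dynamic"):
            roles = {}
        else:
            roles = {c.name: ("rw2" if c.name in rw2 else "linear")
                     for c in self.covariates}
        log_covs = frozenset(c.name for c in self.covariates
                             if c.log_scale and c.name in roles)
        return ModelSpec(family=family, covariate_roles=roles,
                         log_covariates=log_covs, rw2_bins=rw2_bins)

    @classmethod
    def nonlinear(cls, **kwargs) -> "SimulationScenario":
        """Variant with a curved true unemployment effect: the log risk
        rises up to a peak near 11% unemployment and is flat beyond it."""
        def unemployment_curve(x):
            return 0.02 * (np.minimum(x, 11.0) - 11.0)

        beta = _default_beta()
        beta.pop("unemployment")
        return cls(beta=beta, nonlinear_truth={"unemployment": unemployment_curve},
                   **kwargs)


@dataclass
class SimulationResult:
    """A simulated panel plus its generating ground truth."""

    panel: ArealPanel
    weights: SpatialWeights
    polygons: dict
    truth: dict          # state components, offsets E, eta matrix, scenario seed

    def truth_state(self) -> LatentState:
        t = self.truth
        return LatentState(alpha=t["alpha"], beta=dict(t["beta"]), gamma=t["gamma"],
                           delta=np.asarray(t["delta"]), u=np.asarray(t["u"]),
                           v=np.asarray(t["v"]), f={},
                           phi=np.asarray(t["phi"]), psi=np.asarray(t["psi"]))


def make_lattice(rows: int, cols: int) -> tuple:
    """Unit-square grid polygons labelled "r_c" and their queen weights."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    polygons = {}
    for r in range(rows):
        for c in range(cols):
            polygons[f"{r}_{c}"] = [(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1), (c, r)]
    return polygons, queen_adjacency(polygons)


def _spatial_field(structure, spec: CovariateSpec, rng, n: int) -> np.ndarray:
    x = np.zeros(n)
    if spec.spatial_sd > 0:
        x += spec.spatial_sd * sample_constrained(structure, 1.0, rng)
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, n)
    return x


def simulate_covariates(scenario: SimulationScenario,
                        weights: SpatialWeights | None = None,
                        rng=None) -> dict:
    """Simulate every covariate field as an (areas x periods) matrix.

    Deterministic given the scenario seed (or a supplied Generator).
    Static covariates repeat one cross-section; time-varying ones run a
    stationary AR(1) on the deviations from the mean, so persistence 1.0
    with no innovation reproduces the static case.
    """
    if weights is None:
        _, weights = make_lattice(scenario.rows, scenario.cols)
    if rng is None:
        rng = np.random.default_rng([scenario.seed, 101])
    n, T = weights.n, scenario.n_periods
    structure = scale_structure(icar_structure(weights))
    out = {}
    for cs in scenario.covariates:
        dev = _spatial_field(structure, cs, rng, n)
        x = np.empty((n, T))
        x[:, 0] = cs.mean + dev
        for t in range(1, T):
            if cs.time_varying:
                innov = _spatial_field(structure, cs, rng, n)
                dev = cs.rho * dev + math.sqrt(max(0.0, 1.0 - cs.rho ** 2)) * innov
            x[:, t] = cs.mean + dev
        x = np.clip(x, cs.lower, cs.upper)
        out[cs.name] = np.exp(x) if cs.log_scale else x
    return out


def simulate_counts(scenario: SimulationScenario,
                    spec: ModelSpec | None = None) -> SimulationResult:
    """Draw a full synthetic panel: populations, covariates, latent
    effects, and Poisson counts y_it ~ Poisson(E_it exp(eta_it)).

    ``spec`` selects the trend family (its covariate roles decide nothing
    here; the true effects come from the scenario).  Covariate
    contributions are centred at their grand mean, so the realized
    overall rate stays near the baseline rate.  The returned truth dict
    holds every generating component plus the exact eta matrix.
    """
    spec = spec or scenario.model_spec("model1a")
    rng = np.random.default_rng([scenario.seed, 202])
    polygons, weights = make_lattice(scenario.rows, scenario.cols)
    n, T = weights.n, scenario.n_periods
    parametric = spec.trend == "linear_differential"

    covariates = simulate_covariates(scenario, weights,
                                     np.random.default_rng([scenario.seed, 101]))
    population = np.exp(rng.normal(math.log(scenario.population_median),
                                   scenario.population_sigma, n))
    population = np.repeat(population[:, None], T, axis=1)

    s_u = scale_structure(icar_structure(weights))
    u = (scenario.sd_u * sample_constrained(s_u, 1.0, rng)
         if scenario.sd_u > 0 else np.zeros(n))
    v = rng.normal(0.0, scenario.sd_v, n) if scenario.sd_v > 0 else np.zeros(n)
    v -= v.mean()

    delta = np.zeros(n)
    gamma = 0.0
    phi = np.zeros(T)
    psi = np.zeros(T)
    tt = np.arange(T, dtype=float) - (T // 2)
    if parametric:
        gamma = scenario.gamma
        if scenario.sd_delta > 0:
            delta = rng.normal(0.0, scenario.sd_delta, n)
            delta -= delta.mean()
        trend = (gamma + delta[:, None]) * tt[None, :]
    else:
        if T >= 3 and scenario.sd_phi > 0:
            phi = scenario.sd_phi * sample_constrained(
                scale_structure(rw2_structure(T)), 1.0, rng)
        phi = phi + scenario.gamma * tt          # dynamic trend around the grand slope
        phi -= phi.mean()
        if scenario.sd_psi > 0:
            psi = rng.normal(0.0, scenario.sd_psi, T)
            psi -= psi.mean()
        trend = (phi + psi)[None, :]

    def on_model_scale(name: str) -> np.ndarray:
        x = covariates[name]
        return np.log(x) if scenario.covariate(name).log_scale else x

    eta = u[:, None] + v[:, None] + trend
    centering = {}
    for name, b in scenario.beta.items():
        x = on_model_scale(name)
        centering[name] = float(x.mean())
        eta = eta + b * (x - centering[name])
    for name, g in scenario.nonlinear_truth.items():
        gx = np.asarray(g(on_model_scale(name)), dtype=float)
        centering[name] = float(gx.mean())
        eta = eta + gx - centering[name]

    E = population * scenario.baseline_rate
    mu = E * np.exp(eta)
    if np.max(mu) > _MEAN_OVERFLOW:
        raise ValueError("Poisson mean exceeds 1e9; choose smaller effects or rates")
    counts = rng.poisson(mu)

    panel = ArealPanel(area_ids=weights.ids, periods=scenario.periods,
                       counts=counts, population=population, covariates=covariates,
                       units={c.name: c.unit for c in scenario.covariates})
    truth = {
        "seed": scenario.seed, "family": spec.family,
        "alpha": 0.0, "beta": dict(scenario.beta), "gamma": gamma,
        "delta": delta, "u": u, "v": v, "phi": phi, "psi": psi,
        "centering": centering, "baseline_rate": scenario.baseline_rate,
        "E": E, "eta": eta,
    }
    return SimulationResult(panel=panel, weights=weights, polygons=polygons,
                            truth=truth)
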