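"""End-to-end orchestration: simulate -> explore -> fit -> report.

The pipeline is a pure function of (inputs, config, seed): every stage
draws its randomness from the single config seed, and rerunning with the
same config yields byte-identical data outputs.  The run manifest
records the command, a hash of the config, the seed, the package version
and all files written (plus wall-clock time, which is the one
non-reproducible field and lives only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exploratory import event_rate, permutation_test, spearman_matrix
from .inference import Hyperpriors, MCMCConfig, dic, fit, summarize
from .model import ModelSpec
from .panel import ArealPanel, PanelSchema, read_panel, write_summaries
from .simulate import SimulationScenario, simulate_counts
from .weights import read_gal, write_gal

__all__ = ["RunManifest", "run_pipeline", "load_config"]

_STAGES = ("simulate", "explore", "fit", "report")


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    version: str
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    wall_clock_s: float = 0.0

    def write(self, path: Path) -> None:
        doc = {"command": self.command, "config_hash": self.config_hash,
               "seed": self.seed, "version": self.version,
               "inputs": sorted(str(p) for p in self.inputs),
               "outputs": sorted(str(p) for p in self.outputs),
               "wall_clock_s": self.wall_clock_s}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML/JSON mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _model_spec(cfg: dict, scenario: SimulationScenario | None,
                panel: ArealPanel) -> ModelSpec:
    mc = dict(cfg.get("model", {}))
    family = mc.get("family", "model1a")
    if scenario is not None and "roles" not in mc:
        return scenario.model_spec(family, rw2=tuple(mc.get("rw2", ())),
                                   rw2_bins=int(mc.get("rw2_bins", 100)))
    roles = dict(mc.get("roles", {}))
    if not roles and family not in ("null_parametric", "null_dynamic"):
        rw2 = set(mc.get("rw2", ()))
        roles = {k: ("rw2" if k in rw2 else "linear") for k in panel.covariate_names()}
    return ModelSpec(family=family, covariate_roles=roles,
                     log_covariates=frozenset(mc.get("log_covariates", ())),
                     time_centering=mc.get("time_centering"),
                     rw2_bins=int(mc.get("rw2_bins", 100)))


def run_pipeline(config: dict, out_dir, stages=("simulate", "explore", "fit", "report"),
                 command: str = "all") -> RunManifest:
    """Execute the requested stages in order and write a run manifest.

    With a ``scenario`` block in the config the panel is simulated;
    otherwise ``inputs.panel``/``inputs.weights``/``inputs.schema`` must
    point at existing files.  Any stage error aborts the run with the
    stage name in the message.
    """
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    for s in stages:
        if s not in _STAGES:
            raise ValueError(f"unknown stage {s!r}")
    seed = int(config.get("seed", 0))
    manifest = RunManifest(command=command, config_hash=_config_hash(config),
                           seed=seed, version=__version__)

    scenario = None
    panel = weights = None
    spec = None   # validated early so config errors precede any compute
    if "scenario" in config:
        sc = dict(config["scenario"])
        nonlinear = bool(sc.pop("nonlinear", False))
        sc.setdefault("seed", seed)
        scenario = (SimulationScenario.nonlinear(**sc) if nonlinear
                    else SimulationScenario(**sc))
        spec = _model_spec(config, scenario, None)

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    if "simulate" in stages or (scenario is not None and
                                {"explore", "fit", "report"} & set(stages)):
        def do_simulate():
            nonlocal panel, weights
            if scenario is None:
                raise ValueError("no scenario block in config")
            result = simulate_counts(scenario, spec)
            panel, weights = result.panel, result.weights
            if "simulate" not in stages:
                return
            df = panel.to_frame()
            fp = out / "panel.csv"
            df.to_csv(fp, index=False, float_format="%.17g")
            manifest.outputs.append(fp)
            fp = out / "w.gal"
            write_gal(weights, fp)
            manifest.outputs.append(fp)
            fp = out / "polygons.geojson"
            features = [{"type": "Feature", "properties": {"id": label},
                         "geometry": {"type": "Polygon",
                                      "coordinates": [[list(pt) for pt in ring]]}}
                        for label, ring in result.polygons.items()]
            with open(fp, "w", encoding="utf-8") as fh:
                json.dump({"type": "FeatureCollection", "features": features}, fh)
                fh.write("\n")
            manifest.outputs.append(fp)
            fp = out / "truth.json"
            truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in result.truth.items()}
            with open(fp, "w", encoding="utf-8") as fh:
                json.dump(truth, fh, sort_keys=True)
                fh.write("\n")
            manifest.outputs.append(fp)
        _stage("simulate")(do_simulate)

    if panel is None and {"explore", "fit", "report"} & set(stages):
        def do_load():
            nonlocal panel, weights
            inputs = config.get("inputs", {})
            if "panel" not in inputs or "weights" not in inputs:
                raise ValueError("config needs a scenario block or inputs.panel + inputs.weights")
            schema = PanelSchema.from_mapping(inputs.get("schema", {}))
            panel = read_panel(inputs["panel"], schema)
            weights = read_gal(inputs["weights"])
            manifest.inputs.extend([inputs["panel"], inputs["weights"]])
        _stage("load")(do_load)

    if spec is None and {"fit", "report"} & set(stages):
        spec = _model_spec(config, scenario, panel)

    if "explore" in stages:
        def do_explore():
            ex = config.get("explore", {})
            n_perm = int(ex.get("permutations", 9_999))
            rates = event_rate(panel)
            uni_rows, biv_rows = [], []
            for t, period in enumerate(panel.periods):
                res = permutation_test("univariate", rates[:, t], weights,
                                       n_perm=n_perm, seed=seed + t)
                uni_rows.append({"period": period, "morans_i": res.statistic,
                                 "expectation": res.expectation_under_null,
                                 "pseudo_p": res.pseudo_p,
                                 "n_permutations": n_perm})
            for t in range(panel.n_periods - 1):
                res = permutation_test("bivariate", rates[:, t], weights,
                                       n_perm=n_perm, seed=seed + 1000 + t,
                                       values_t1=rates[:, t + 1])
                biv_rows.append({"period_t": panel.periods[t],
                                 "period_t1": panel.periods[t + 1],
                                 "bivariate_morans_i": res.statistic,
                                 "pseudo_p": res.pseudo_p,
                                 "n_permutations": n_perm})
            tables = {"explore_univariate": pd.DataFrame(uni_rows),
                      "explore_bivariate": pd.DataFrame(biv_rows)}
            if len(panel.covariate_names()) >= 2:
                rho = spearman_matrix(dict(panel.covariates))
                tables["spearman"] = rho.reset_index(names="covariate")
            manifest.outputs.extend(write_summaries(tables, out,
                                                    manifest={"stage": "explore", "seed": seed}))
        _stage("explore")(do_explore)

    draws = None
    if "fit" in stages or "report" in stages:
        def do_fit():
            nonlocal draws
            mcfg = dict(config.get("mcmc", {}))
            mcfg.setdefault("seed", seed)
            cfg_m = MCMCConfig(**mcfg)
            pr = config.get("priors", {})
            priors = Hyperpriors(shape=float(pr.get("shape", 1.0)),
                                 rate=float(pr.get("rate", 5e-5)))
            draws = fit(spec, panel, weights, priors=priors, cfg=cfg_m)
            if "fit" not in stages:
                return
            fp = out / "draws.npz"
            arrays = {"alpha": draws.alpha, "gamma": draws.gamma,
                      "delta": draws.delta, "u": draws.u, "v": draws.v,
                      "phi": draws.phi, "psi": draws.psi}
            arrays.update({f"beta_{k}": v for k, v in draws.beta.items()})
            arrays.update({f"f_{k}": v for k, v in draws.f.items()})
            arrays.update({f"tau_{k.split(':')[-1]}": v for k, v in draws.tau.items()})
            np.savez_compressed(fp, **arrays)
            manifest.outputs.append(fp)
            d = dic(draws, panel)
            fp = out / "dic.json"
            with open(fp, "w", encoding="utf-8") as fh:
                json.dump({"model": spec.family, "seed": seed, "DIC": d.DIC,
                           "Dbar": d.Dbar, "D_hat": d.D_hat, "pD": d.pD},
                          fh, indent=2, sort_keys=True)
                fh.write("\n")
            manifest.outputs.append(fp)
            fp = out / "fit_log.json"
            with open(fp, "w", encoding="utf-8") as fh:
                json.dump({"seed": seed, "model": spec.family,
                           "acceptance": {k: round(v, 4) for k, v in draws.acceptance.items()},
                           "rhat": {k: round(v, 4) for k, v in draws.rhat.items()}},
                          fh, indent=2, sort_keys=True)
                fh.write("\n")
            manifest.outputs.append(fp)
        _stage("fit")(do_fit)

    if "report" in stages:
        def do_report():
            summary = summarize(draws)
            d = dic(draws, panel)
            tables = summary.tables()
            manifest.outputs.extend(write_summaries(
                tables, out, manifest={"stage": "report", "model": spec.family,
                                       "seed": seed, "DIC": d.DIC}))
        _stage("report")(do_report)

    manifest.wall_clock_s = round(time.perf_counter() - t0, 3)
    mf = out / "run_manifest.json"
    manifest.write(mf)
    missing = [str(p) for p in manifest.outputs if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"manifest lists missing outputs: {missing}")
    return manifest
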