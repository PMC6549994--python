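"""Full-workflow orchestration from one flat INI configuration.

Stages: change analysis -> driver construction & screening -> per-origin MLP
sub-models -> Markov matrix with scenario edits -> spatial allocation ->
report bundle.  Every stochastic stage requires an explicit seed (absent
seeds are an error, not a default); every paper-underspecified default is a
named config key, echoed into the run log so a run is reconstructible from
config + log.
"""

from __future__ import annotations

import configparser
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .allocate import allocate
from .change import change_budget, cross_tabulate, transition_mask, trend_surface
from .drivers import (
    CRAMERS_V_THRESHOLD,
    DriverVariable,
    cramers_v,
    distance_to_class,
    evidence_likelihood,
    screen_variables,
)
from .grid import CategoricalRaster, Legend
from .io import read_legend_csv, read_raster, write_matrix_csv, write_raster
from .markov import apply_scenario, change_demand, estimate_matrix, parse_scenario_file
from .mlp import (
    PotentialStack,
    TrainingSettings,
    draw_samples,
    predict_potentials,
    submodel_to_json,
    train_submodel,
)

__all__ = ["RunConfig", "DriverDef", "run_pipeline", "load_config", "build_driver"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class DriverDef:
    """Declarative driver-variable definition from a config file."""

    name: str
    kind: str                       # continuous | distance | evidence
    path: str | None = None         # source raster (continuous, evidence)
    dynamic: bool = False
    target: list[str] = field(default_factory=list)       # distance target classes
    mask_from: list[str] = field(default_factory=list)    # evidence transition spec
    mask_to: list[str] = field(default_factory=list)
    el_mode: str = "relative_frequency"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "distance", "evidence"):
            raise ConfigError(f"driver {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "continuous" and not self.path:
            raise ConfigError(f"driver {self.name!r}: continuous driver needs a path")
        if self.kind == "distance" and not self.target:
            raise ConfigError(f"driver {self.name!r}: distance driver needs target classes")
        if self.kind == "evidence" and not (self.mask_from or self.mask_to):
            raise ConfigError(f"driver {self.name!r}: evidence driver needs from/to classes")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    t1_path: Path
    t2_path: Path
    legend_path: Path
    out_dir: Path
    drivers: list[DriverDef]
    threshold: float = CRAMERS_V_THRESHOLD
    n_samples: int = 10_000
    seed: int | None = None
    base_years: float = 1.0
    target_years: float = 1.0
    rescale: str = "power"
    scenarios: dict[str, Path | None] = field(default_factory=lambda: {"bau": None})
    training: TrainingSettings = field(default_factory=TrainingSettings)
    trend_order: int = 3
    min_transition_cells: int = 0
    raster_format: str = "asc"
    origins: list[str] = field(default_factory=list)   # empty -> all classes

    def __post_init__(self) -> None:
        for p in (self.t1_path, self.t2_path, self.legend_path):
            if not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")
        for name, path in self.scenarios.items():
            if path is not None and not Path(path).exists():
                raise ConfigError(f"scenario file for {name!r} does not exist: {path}")
        if self.seed is None:
            raise ConfigError("a seed is required (set [sampling] seed); none was given")


def load_config(path) -> RunConfig:
    """Parse a flat INI run configuration."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise ConfigError(f"cannot read config file {path}")
    base = Path(path).parent

    def _path(section, key, required=True):
        if not cp.has_option(section, key):
            if required:
                raise ConfigError(f"config missing [{section}] {key}")
            return None
        return (base / cp.get(section, key)).resolve()

    drivers: list[DriverDef] = []
    for section in cp.sections():
        if not section.startswith("driver:"):
            continue
        name = section.split(":", 1)[1]
        raw_path = cp.get(section, "path", fallback=None)
        drivers.append(DriverDef(
            name=name,
            kind=cp.get(section, "kind", fallback="continuous"),
            path=str(base / raw_path) if raw_path else None,
            dynamic=cp.getboolean(section, "dynamic", fallback=False),
            target=_split(cp.get(section, "target", fallback="")),
            mask_from=_split(cp.get(section, "from", fallback="")),
            mask_to=_split(cp.get(section, "to", fallback="")),
            el_mode=cp.get(section, "el_mode", fallback="relative_frequency"),
        ))
    scenarios: dict[str, Path | None] = {}
    if cp.has_section("scenarios"):
        for name, value in cp.items("scenarios"):
            scenarios[name] = (base / value).resolve() if value.strip() else None
    if not scenarios:
        scenarios = {"bau": None}
    training = TrainingSettings(
        hidden_nodes=cp.getint("mlp", "hidden_nodes", fallback=0) or None,
        learning_rate=cp.getfloat("mlp", "learning_rate", fallback=0.01),
        momentum=cp.getfloat("mlp", "momentum", fallback=0.5),
        max_epochs=cp.getint("mlp", "max_epochs", fallback=1000),
        patience=cp.getint("mlp", "patience", fallback=100),
    )
    seed = cp.getint("sampling", "seed", fallback=None)
    return RunConfig(
        t1_path=_path("inputs", "t1"),
        t2_path=_path("inputs", "t2"),
        legend_path=_path("inputs", "legend"),
        out_dir=Path(cp.get("output", "dir", fallback=str(base / "out"))),
        drivers=drivers,
        threshold=cp.getfloat("screening", "threshold", fallback=CRAMERS_V_THRESHOLD),
        n_samples=cp.getint("sampling", "n", fallback=10_000),
        seed=seed,
        base_years=cp.getfloat("markov", "base_years", fallback=1.0),
        target_years=cp.getfloat("markov", "target_years", fallback=1.0),
        rescale=cp.get("markov", "rescale", fallback="power"),
        scenarios=scenarios,
        training=training,
        trend_order=cp.getint("change", "trend_order", fallback=3),
        min_transition_cells=cp.getint("change", "min_transition_cells", fallback=0),
        raster_format=cp.get("output", "raster_format", fallback="asc"),
        origins=_split(cp.get("sampling", "origins", fallback="")),
    )


def _split(raw: str) -> list[str]:
    return [tok.strip() for tok in raw.split(",") if tok.strip()]


def build_driver(defn: DriverDef, t1: CategoricalRaster, t2: CategoricalRaster,
                 legend: Legend) -> DriverVariable:
    """Materialize one driver raster from its declarative definition."""
    if defn.kind == "continuous":
        raster = read_raster(defn.path, "continuous", crs_tag=t1.crs_tag)
        return DriverVariable(defn.name, raster, dynamic=defn.dynamic)
    if defn.kind == "distance":
        codes = [legend.resolve(t) for t in defn.target]
        raster = distance_to_class(t1, codes)
        return DriverVariable(defn.name, raster, dynamic=True,
                              distance_target=frozenset(codes))
    # evidence likelihood
    source = (t1 if defn.path in (None, "t1")
              else read_raster(defn.path, "categorical", crs_tag=t1.crs_tag))
    from_codes = [legend.resolve(c) for c in defn.mask_from] or legend.codes
    to_codes = [legend.resolve(c) for c in defn.mask_to] or legend.codes
    mask = transition_mask(t1, t2, from_codes, to_codes)
    raster = evidence_likelihood(source, mask, mode=defn.el_mode)
    return DriverVariable(defn.name, raster, dynamic=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run log (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
    }

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- inputs -----------------------------------------------------------
    legend = read_legend_csv(config.legend_path)
    t1 = _stage("read")(lambda: read_raster(config.t1_path, "categorical", legend=legend))
    t2 = _stage("read")(lambda: read_raster(config.t2_path, "categorical", legend=legend))

    # --- change analysis --------------------------------------------------
    def _change():
        counts = cross_tabulate(t1, t2)
        budget = change_budget(counts)
        counts.to_dataframe().to_csv(out / "transition_counts.csv")
        budget.to_dataframe().to_csv(out / "change_budget_t1_t2.csv")
        budget.contributions.to_csv(out / "contributions_t1_t2.csv")
        all_change = transition_mask(t1, t2, legend.codes, legend.codes)
        surface = trend_surface(all_change, order=config.trend_order)
        write_raster(surface, out / f"trend_surface.{config.raster_format}")
        dropped = counts.dropped_transitions(config.min_transition_cells)
        return counts, dropped

    counts, dropped = _stage("change")(_change)
    log["stages"]["change"] = {
        "n_valid": counts.n_valid,
        "min_transition_cells": config.min_transition_cells,
        "dropped_transitions": dropped,
        "trend_order": config.trend_order,
    }

    # --- drivers ----------------------------------------------------------
    def _drivers():
        variables = [build_driver(d, t1, t2, legend) for d in config.drivers]
        response = transition_mask(t1, t2, legend.codes, legend.codes)
        for var in variables:
            var.cramers_v = cramers_v(var.raster, response)
        screening = screen_variables(variables, config.threshold)
        screening.report().to_csv(out / "screening_report.csv", index=False)
        return screening

    screening = _stage("drivers")(_drivers)
    log["stages"]["drivers"] = {
        "threshold": config.threshold,
        "retained": [v.name for v in screening.retained],
        "dropped": [v.name for v in screening.dropped],
    }

    retained = {v.name: v.raster for v in screening.retained}
    dynamic_targets = {v.name: sorted(v.distance_target)
                       for v in screening.retained if v.distance_target}

    # --- transition sub-models -------------------------------------------
    def _train():
        origin_codes = ([legend.resolve(o) for o in config.origins]
                        if config.origins else list(legend.codes))
        models = {}
        rows = []
        seeds = np.random.SeedSequence(config.seed).generate_state(len(origin_codes))
        for origin, s in zip(origin_codes, seeds):
            i = legend.index(origin)
            # need at least two observed labels (destinations incl. persistence)
            if np.count_nonzero(counts.counts[i]) < 2 or not retained:
                continue
            samples = draw_samples(t1, t2, origin, retained, n=config.n_samples,
                                   seed=int(s))
            model = train_submodel(samples, config.training)
            models[origin] = model
            rows.append((legend.name_of(origin), model.accuracy, model.good, int(s)))
            (out / f"model_{origin}.json").write_text(json.dumps(submodel_to_json(model)))
        pd.DataFrame(rows, columns=["origin", "accuracy_pct", "good", "seed"]).to_csv(
            out / "submodel_accuracy.csv", index=False)
        return models

    models = _stage("train")(_train)
    log["stages"]["train"] = {
        "n_samples": config.n_samples,
        "settings": submodel_to_json(next(iter(models.values())))["settings"] if models else {},
        "origins": sorted(models),
    }

    # --- markov + scenarios + allocation ---------------------------------
    base_matrix = _stage("markov")(lambda: estimate_matrix(
        counts, config.base_years, config.target_years, rescale=config.rescale))
    write_matrix_csv(base_matrix.P, legend, out / "matrix_observed.csv")
    log["stages"]["markov"] = {
        "base_years": config.base_years,
        "target_years": config.target_years,
        "rescale": config.rescale,
    }

    areas = t2.class_areas_ha()
    log["stages"]["scenarios"] = {}
    for name, scn_path in config.scenarios.items():
        def _scenario(name=name, scn_path=scn_path):
            edits = parse_scenario_file(scn_path) if scn_path else []
            matrix = apply_scenario(base_matrix, edits) if edits else base_matrix
            write_matrix_csv(matrix.P, legend, out / f"matrix_{name}.csv")
            demand = change_demand(matrix, areas)
            demand.to_dataframe().to_csv(out / f"demand_{name}.csv")
            stack = PotentialStack({})
            for model in models.values():
                stack = stack.merge(predict_potentials(model, retained, t2))
            result = allocate(t2, stack, demand, seed=config.seed)
            write_raster(result.projected, out / f"projected_{name}.{config.raster_format}")
            pd.DataFrame(result.realized, index=legend.names, columns=legend.names).to_csv(
                out / f"realized_{name}.csv")
            pd.DataFrame(result.unmet, index=legend.names, columns=legend.names).to_csv(
                out / f"unmet_{name}.csv")
            proj_budget = change_budget(cross_tabulate(t2, result.projected))
            proj_budget.to_dataframe().to_csv(out / f"change_budget_{name}.csv")
            return {
                "edits": [str(e) for e in (parse_scenario_file(scn_path) if scn_path else [])],
                "seed": config.seed,
                "unmet_pixels": int(result.unmet.sum()),
                "conflicts": len(result.conflicts),
            }

        log["stages"]["scenarios"][name] = _stage(f"scenario:{name}")(_scenario)

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log
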