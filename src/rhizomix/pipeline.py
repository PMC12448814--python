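"""End-to-end orchestration: simulate (or load) -> adjust -> diversity
effects -> trait composition -> hierarchy/plasticity, with every stage's
output written to CSV and a JSON report tying the numbers together."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjust import (TUBE_TRAITS, mixture_pair_values, mixture_tube_values,
                     pure_reference_values, reference_table, tube_genotype_table,
                     tube_root_table)
from .design import mixture_pairs
from .effects import compare_treatments, effects_table, index_tests
from .hierarchy import bivariate_stats, hierarchy_table, plasticity_table
from .io import read_tables, write_csv
from .simulate import SCENARIOS, simulate_experiment
from .traits import DEFAULT_TRAITS, composition_analysis

log = logging.getLogger(__name__)

BIOMASS_COMPONENTS = ("total_biomass", "shoot_biomass", "root_biomass")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    scenario: str | None = "arms_race"     # or None when input paths are given
    inputs: dict | None = None              # {design: path, plants: path, tubes: path}
    column_map: dict | None = None
    seed: int = 0
    biomass_traits: tuple = BIOMASS_COMPONENTS
    composition_traits: tuple = DEFAULT_TRAITS
    responses: tuple = ("RYT", "CE", "SE")
    with_random_slope: bool = True
    averaging_mode: str = "full"
    top_models: int = 10
    out_dir: str = "rhizomix_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("biomass_traits", "composition_traits", "responses"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for name in ("biomass_traits", "composition_traits", "responses"):
            d[name] = list(d[name])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    config: dict
    provenance: dict
    counts: dict
    index_tests: list
    treatment_comparisons: list
    trait_composition: dict
    bivariate: list
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _obtain_tables(config: RunConfig):
    if config.inputs:
        tables = read_tables(config.inputs, config.column_map)
        return tables["design"], tables["plants"], tables["tubes"], None
    if config.scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario '{config.scenario}'; available: {sorted(SCENARIOS)}"
        )
    genotypes, design, params, rng = SCENARIOS[config.scenario](config.seed)
    plants, tubes = simulate_experiment(genotypes, design, params, rng)
    return design, plants, tubes, params


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write the outputs under ``config.out_dir``.

    Deterministic given (config, seed): running twice produces byte-identical
    CSVs.  Record counts are logged after each stage so the design totals
    (mixtures, pots, plants, oriented pairs) are auditable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design, plants, tubes, params = _obtain_tables(config)
    log.info("design: %d pots (%d control), %d plant records, %d tube records",
             len(design), int(design["is_control"].sum()), len(plants), len(tubes))
    pairs = mixture_pairs(design)
    log.info("distinct mixtures: %d", len(pairs))

    outputs = {}
    outputs["design"] = str(write_csv(design, out / "design.csv"))
    outputs["plants"] = str(write_csv(plants, out / "plants.csv"))
    outputs["tubes"] = str(write_csv(tubes, out / "tubes.csv"))
    if params is not None:
        (out / "params.yaml").write_text(
            yaml.safe_dump({"seed": config.seed, **params.to_dict()},
                           sort_keys=True, default_flow_style=None))
        outputs["params"] = str(out / "params.yaml")

    # adjusted references for biomass components and composition traits
    all_traits = tuple(dict.fromkeys(
        (*config.biomass_traits, *config.composition_traits)))
    references, ref_fits = reference_table(
        plants, tubes, design, all_traits, config.with_random_slope)
    outputs["references"] = str(write_csv(references, out / "references.csv"))

    # oriented pair values per biomass component
    pair_frames = []
    for trait in config.biomass_traits:
        t = tube_genotype_table(plants, design, trait)
        t = t[~t["is_control"] & t["is_mixture"]]
        vals, _ = mixture_pair_values(t, trait, config.with_random_slope)
        vals.insert(3, "trait", trait)
        pair_frames.append(vals)
    pair_values = pd.concat(pair_frames, ignore_index=True)
    pair_values = pair_values[["focal", "neighbor", "treatment", "trait", "value"]]
    outputs["pair_values"] = str(write_csv(pair_values, out / "pair_values.csv"))
    n_oriented = (pair_values["trait"] == config.biomass_traits[0]).sum() // \
        max(design["treatment"].nunique(), 1)
    log.info("oriented pair values per treatment: %d", n_oriented)

    # diversity effects per biomass component
    effect_frames, tests, comparisons = [], [], []
    for trait in config.biomass_traits:
        eff = effects_table(
            pair_values[pair_values["trait"] == trait],
            references[references["trait"] == trait],
        )
        eff.insert(3, "trait", trait)
        effect_frames.append(eff)
        t = index_tests(eff)
        t.insert(0, "trait", trait)
        tests.append(t)
        for index in config.responses:
            cmp_ = compare_treatments(eff, index)
            cmp_.insert(0, "index", index)
            cmp_.insert(0, "trait", trait)
            comparisons.append(cmp_)
    effects = pd.concat(effect_frames, ignore_index=True)
    tests = pd.concat(tests, ignore_index=True)
    comparisons = pd.concat(comparisons, ignore_index=True)
    outputs["effects"] = str(write_csv(effects, out / "effects.csv"))
    outputs["tests"] = str(write_csv(tests, out / "tests.csv"))
    outputs["comparisons"] = str(write_csv(comparisons, out / "comparisons.csv"))

    # trait-composition model averaging (on the first biomass component)
    main = effects[effects["trait"] == config.biomass_traits[0]]
    composition = {}
    averaged_frames, model_frames = [], []
    for response in config.responses:
        for k in sorted(main["treatment"].unique()):
            avg = composition_analysis(
                main, references, response=response, treatment=k,
                traits=config.composition_traits, top=config.top_models,
                mode=config.averaging_mode,
            )
            key = f"{response}:{k}"
            composition[key] = {
                "mean_adj_r2": avg.mean_adj_r2,
                "terms": avg.terms.to_dict("records"),
            }
            t = avg.terms.copy()
            t.insert(0, "treatment", k)
            t.insert(0, "response", response)
            averaged_frames.append(t)
            mt = pd.DataFrame(
                [{"response": response, "treatment": k,
                  "subset": "+".join(m.subset) or "(intercept)",
                  "aicc": m.aicc, "weight": m.weight, "adj_r2": m.adj_r2}
                 for m in avg.models])
            model_frames.append(mt)
    outputs["averaged"] = str(write_csv(
        pd.concat(averaged_frames, ignore_index=True), out / "averaged.csv"))
    outputs["model_table"] = str(write_csv(
        pd.concat(model_frames, ignore_index=True), out / "model_table.csv"))

    # hierarchy and plasticity on root area
    area_refs = references[references["trait"] == "root_area"]
    main_refs = references[references["trait"] == config.biomass_traits[0]]
    main_pairs = pair_values[pair_values["trait"] == config.biomass_traits[0]]
    hier = hierarchy_table(main_pairs, main_refs, area_refs)
    area_tab = tube_root_table(tubes, design, "root_area")
    mix_areas, _ = mixture_tube_values(
        area_tab[~area_tab["is_control"] & area_tab["is_mixture"]],
        "root_area", config.with_random_slope)
    plast = plasticity_table(mix_areas, area_refs, effects=main)
    outputs["hierarchy"] = str(write_csv(hier, out / "hierarchy.csv"))
    outputs["plasticity"] = str(write_csv(plast, out / "plasticity.csv"))
    bivar = pd.concat([
        bivariate_stats(hier, "pure_root_area", "RY"),
        bivariate_stats(hier, "HD", "RY"),
        bivariate_stats(plast, "P", "RYT"),
    ], ignore_index=True)
    outputs["bivariate"] = str(write_csv(bivar, out / "bivariate.csv"))

    report = RunReport(
        config=asdict(config),
        provenance={"package_version": __version__,
                    "config_digest": config.digest(), "seed": config.seed},
        counts={
            "pots": int(len(design)),
            "control_pots": int(design["is_control"].sum()),
            "non_control_pots": int((~design["is_control"]).sum()),
            "mixtures": int(len(pairs)),
            "plant_records": int(len(plants)),
            "oriented_pair_values_per_treatment": int(n_oriented),
        },
        index_tests=tests.to_dict("records"),
        treatment_comparisons=comparisons.to_dict("records"),
        trait_composition=composition,
        bivariate=bivar.to_dict("records"),
        outputs=outputs,
    )
    report.to_json(out / "report.json")
    config.to_yaml(out / "config.yaml")
    return report
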