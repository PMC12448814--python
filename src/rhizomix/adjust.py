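"""Design-adjusted reference values via mixed-model BLUPs.

Pure-stand references B_iik and per-variety-in-pair mixture values B_ijk are
built the same way: fit a linear mixed model with block, harvest/measurement
date and treatment as fixed effects and the grouping identity (variety, or
oriented pair) as a random intercept with an optional random treatment
slope, then sum the estimated treatment fixed effect (at an average block
and date) with the group's BLUP — intercept under the baseline treatment,
intercept + slope under the other one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .mixedlm import MixedFit, MixedModelSpec, fit_mixed_model

log = logging.getLogger(__name__)

#: traits summed over the plants of a genotype within a tube; leaf N is averaged
SUM_TRAITS = ("shoot_biomass", "root_biomass", "total_biomass", "n_leaves", "n_tillers")
MEAN_TRAITS = ("leaf_n",)
TUBE_TRAITS = ("root_length", "root_area")
#: root-image traits are all captured on a single date, so no date covariate
DATE_FREE_TRAITS = TUBE_TRAITS


def tube_genotype_table(
    plants: pd.DataFrame, design: pd.DataFrame, trait: str
) -> pd.DataFrame:
    """Aggregate per-plant records to one value per genotype per tube.

    Biomass and count traits are summed over a genotype's plants within the
    tube (six in pure stands, three in mixtures); leaf N is averaged.
    """
    if trait in SUM_TRAITS:
        agg = "sum"
    elif trait in MEAN_TRAITS:
        agg = "mean"
    else:
        raise ValueError(f"unknown per-plant trait '{trait}'")
    g = (
        plants.groupby(["tube_id", "genotype_id"], as_index=False)[trait]
        .agg(agg)
        .rename(columns={trait: "value", "genotype_id": "variety"})
    )
    meta = design[["tube_id", "treatment", "block", "harvest_date", "is_control",
                   "is_mixture"]]
    out = g.merge(meta, on="tube_id", how="left", validate="many_to_one")
    if out["treatment"].isna().any():
        missing = out.loc[out["treatment"].isna(), "tube_id"].unique()
        raise ValueError(f"plants reference tubes absent from the design: {missing[:5]}")
    return out


def tube_root_table(
    tubes: pd.DataFrame, design: pd.DataFrame, trait: str
) -> pd.DataFrame:
    """One tube-level root-image value per pot, with design covariates."""
    if trait not in TUBE_TRAITS:
        raise ValueError(f"unknown tube trait '{trait}'")
    pos_cols = [c for c in design.columns if c.startswith("pos")]
    meta = design.copy()
    meta["composition"] = [tuple(sorted(set(r))) for r in
                           meta[pos_cols].to_numpy()]
    meta = meta[["tube_id", "treatment", "block", "harvest_date", "is_control",
                 "is_mixture", "composition"]]
    out = tubes.rename(columns={trait: "value"})[["tube_id", "value"]].merge(
        meta, on="tube_id", how="left", validate="one_to_one"
    )
    return out


def _spec_for(trait: str, group: str, slope: bool) -> MixedModelSpec:
    fixed = ("block", "treatment") if trait in DATE_FREE_TRAITS else (
        "block", "harvest_date", "treatment")
    return MixedModelSpec(
        response="value", fixed=fixed, random_group=group,
        random_slope_on_treatment=slope,
    )


def _adjusted_group_values(
    table: pd.DataFrame, trait: str, group: str, with_random_slope: bool
) -> tuple[pd.DataFrame, MixedFit]:
    fit = fit_mixed_model(table, _spec_for(trait, group, with_random_slope))
    has_slope = "slope" in fit.blups.columns
    rows = []
    for level, blup in fit.blups.iterrows():
        for k in fit.treatment_levels:
            value = fit.treatment_fixed_effect(k) + float(blup["intercept"])
            if has_slope and k != fit.baseline:
                value += float(blup["slope"])
            rows.append({group: level, "treatment": k, "value": value})
    return pd.DataFrame(rows), fit


def pure_reference_values(
    pure_table: pd.DataFrame, trait: str = "total_biomass",
    with_random_slope: bool = True,
) -> tuple[pd.DataFrame, MixedFit]:
    """Adjusted pure-stand reference values B_iik.

    ``pure_table`` must hold only non-control pure stands, one aggregated
    value per variety per tube (see :func:`tube_genotype_table` /
    :func:`tube_root_table`).  Returns one reference per variety per
    treatment plus the underlying fit.
    """
    if pure_table.get("is_mixture", pd.Series(False, index=pure_table.index)).any():
        raise ValueError("pure_table contains mixture pots")
    table = pure_table.copy()
    if "variety" not in table.columns and "composition" in table.columns:
        table["variety"] = [c[0] for c in table["composition"]]
    refs, fit = _adjusted_group_values(table, trait, "variety", with_random_slope)
    return refs, fit


def mixture_pair_values(
    mixed_table: pd.DataFrame, trait: str = "total_biomass",
    with_random_slope: bool = True,
) -> tuple[pd.DataFrame, MixedFit]:
    """Adjusted per-variety-in-pair mixture values B_ijk.

    The grouping factor is the *oriented* pair identity (focal|neighbour
    concatenation), so each variety gets its own value within each mixture;
    a 54-mixture design yields 108 oriented values per treatment.
    """
    table = mixed_table.copy()
    if "neighbor" not in table.columns:
        # derive the neighbour from the tube's two varieties
        tube_pairs = table.groupby("tube_id")["variety"].agg(lambda s: sorted(set(s)))
        bad = tube_pairs[tube_pairs.map(len) != 2]
        if len(bad):
            raise ValueError(f"non-binary mixture tubes: {list(bad.index[:5])}")
        lookup = tube_pairs.to_dict()
        table["neighbor"] = [
            p[0] if p[1] == v else p[1]
            for v, p in zip(table["variety"], table["tube_id"].map(lookup))
        ]
    table["pair_id"] = table["variety"] + "|" + table["neighbor"]
    vals, fit = _adjusted_group_values(table, trait, "pair_id", with_random_slope)
    vals[["focal", "neighbor"]] = vals["pair_id"].str.split("|", expand=True)
    return vals[["focal", "neighbor", "treatment", "value"]], fit


def mixture_tube_values(
    mixed_tube_table: pd.DataFrame, trait: str = "root_area",
    with_random_slope: bool = True,
) -> tuple[pd.DataFrame, MixedFit]:
    """Adjusted tube-level values (e.g. observed mixture root area) per
    unordered pair per treatment."""
    table = mixed_tube_table.copy()
    table["pair"] = ["|".join(c) for c in table["composition"]]
    vals, fit = _adjusted_group_values(table, trait, "pair", with_random_slope)
    return vals, fit


def reference_table(
    plants: pd.DataFrame, tubes: pd.DataFrame, design: pd.DataFrame,
    traits: tuple[str, ...], with_random_slope: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Long table of adjusted pure-stand references for several traits."""
    frames, fits = [], {}
    pure_mask_cache: dict[str, pd.DataFrame] = {}
    for trait in traits:
        if trait in TUBE_TRAITS:
            t = tube_root_table(tubes, design, trait)
        else:
            t = tube_genotype_table(plants, design, trait)
        t = t[~t["is_control"] & ~t["is_mixture"]]
        refs, fit = pure_reference_values(t, trait, with_random_slope)
        refs.insert(2, "trait", trait)
        frames.append(refs)
        fits[trait] = fit
    return pd.concat(frames, ignore_index=True), fits
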