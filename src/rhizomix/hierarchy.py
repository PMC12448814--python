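"""Root-system hierarchy and plasticity diagnostics.

Hierarchical distance HD = (A_focal - A_neighbour) / A_focal compares the
two varieties' pure-stand root areas from the focal side (positive: the
focal genotype has the larger root system; the index is normalized by the
focal area, so HD(f, n) != -HD(n, f) in general).  Root-area plasticity
P = (A_mix_observed - A_pure_mean) / A_pure_mean is the relative change of
a mixture's observed root area against the mean of its components' pure
stands (positive: root area increased in the mixture).  Both indices are
computed on a consistent tube-level scale — pure and mixed tubes hold the
same number of plants, so tube-level and per-plant comparisons coincide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats


def hierarchical_distance(a_focal, a_neighbor):
    """(A_focal - A_neighbour) / A_focal; always < 1, unbounded below."""
    a_focal = np.asarray(a_focal, dtype=float)
    a_neighbor = np.asarray(a_neighbor, dtype=float)
    if np.any(a_focal <= 0):
        raise ValueError("focal root area must be positive")
    out = (a_focal - a_neighbor) / a_focal
    return float(out) if out.ndim == 0 else out


def plasticity_index(a_mix_obs, a_pure_i, a_pure_j, literal_order: bool = False):
    """Relative root-area change in mixture versus the pure-stand mean.

    With the default sign convention positive values mean the mixture's
    root area exceeded the pure-stand expectation; ``literal_order=True``
    flips the sign (pure-mean minus observed).
    """
    a_mix_obs = np.asarray(a_mix_obs, dtype=float)
    pure_mean = (np.asarray(a_pure_i, dtype=float)
                 + np.asarray(a_pure_j, dtype=float)) / 2.0
    if np.any(pure_mean <= 0):
        raise ValueError("pure-stand root areas must be positive")
    if np.any(a_mix_obs <= 0):
        raise ValueError("observed mixture root area must be positive")
    p = (a_mix_obs - pure_mean) / pure_mean
    if literal_order:
        p = -p
    return float(p) if p.ndim == 0 else p


def hierarchy_table(
    pair_values: pd.DataFrame, references: pd.DataFrame,
    area_references: pd.DataFrame,
) -> pd.DataFrame:
    """Oriented records: RY and hierarchical distance per focal variety.

    ``references`` are the biomass pure references (variety, treatment,
    value), ``area_references`` the root-area pure references.
    """
    ref_b = {(r.variety, r.treatment): r.value for r in references.itertuples()}
    ref_a = {(r.variety, r.treatment): r.value for r in area_references.itertuples()}
    rows = []
    for r in pair_values.itertuples():
        kb, ka = (r.focal, r.treatment), (r.neighbor, r.treatment)
        if kb not in ref_b or kb not in ref_a or ka not in ref_a:
            continue
        rows.append({
            "focal": r.focal, "neighbor": r.neighbor, "treatment": r.treatment,
            "RY": r.value / ref_b[kb],
            "pure_root_area": ref_a[kb],
            "HD": hierarchical_distance(ref_a[kb], ref_a[ka]),
        })
    return pd.DataFrame(rows)


def plasticity_table(
    mixture_areas: pd.DataFrame, area_references: pd.DataFrame,
    effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per mixture per treatment: plasticity index (and RYT if supplied).

    ``mixture_areas``: adjusted observed tube root area per unordered pair
    (columns pair, treatment, value) from
    :func:`rhizomix.adjust.mixture_tube_values`.
    """
    ref_a = {(r.variety, r.treatment): r.value for r in area_references.itertuples()}
    rows = []
    for r in mixture_areas.itertuples():
        i, j = r.pair.split("|")
        ki, kj = (i, r.treatment), (j, r.treatment)
        if ki not in ref_a or kj not in ref_a:
            continue
        rows.append({
            "variety_1": i, "variety_2": j, "treatment": r.treatment,
            "A_mix_obs": r.value,
            "P": plasticity_index(r.value, ref_a[ki], ref_a[kj]),
        })
    out = pd.DataFrame(rows)
    if effects is not None and len(out):
        out = out.merge(
            effects[["variety_1", "variety_2", "treatment", "RYT"]],
            on=["variety_1", "variety_2", "treatment"], how="left",
        )
    return out


def bivariate_stats(
    df: pd.DataFrame, x: str, y: str, by: str = "treatment"
) -> pd.DataFrame:
    """Pearson R, OLS slope/intercept and the two-sided p of R per stratum."""
    rows = []
    for k, sub in df.groupby(by):
        if len(sub) < 3:
            raise ValueError(f"stratum '{k}': need at least 3 observations")
        xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
        if np.var(xv, ddof=1) <= 0 or np.var(yv, ddof=1) <= 0:
            raise ValueError(f"stratum '{k}': degenerate variance in '{x}' or '{y}'")
        lr = scipy.stats.linregress(xv, yv)
        rows.append({by: k, "x": x, "y": y, "pearson_R": float(lr.rvalue),
                     "slope": float(lr.slope), "intercept": float(lr.intercept),
                     "p": float(lr.pvalue), "n": len(sub)})
    return pd.DataFrame(rows)
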