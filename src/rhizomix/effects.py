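"""Relative yields, relative yield totals and the additive partition of the
net biodiversity effect into complementarity and selection effects.

Definitions (binary mixtures, half density per component):

* RY_ijk = B_ijk / B_iik — variety i's adjusted biomass in mixture with j
  over its adjusted pure-stand reference, in treatment k.  Null value 0.5.
* RYT_(ij)k = RY_ijk + RY_jik.  Null value 1.
* NBE = Yo - YE = CE + SE with CE = N * mean(dRY) * mean(M) and
  SE = N * cov(dRY, M), where dRY = RY - 0.5, M is the pure-stand biomass,
  N = 2, and cov is the population (divisor-N) covariance — the only
  convention under which the additive identity CE + SE = sum(dRY_i * M_i)
  holds exactly for N = 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .mixedlm import MixedModelSpec, fit_mixed_model, treatment_anova

log = logging.getLogger(__name__)

EXPECTED_RY = 0.5


def relative_yield(b_mix, b_pure) -> float:
    """RY = B_ijk / B_iik; > 0.5 means the variety overproduced in mixture."""
    b_mix = np.asarray(b_mix, dtype=float)
    b_pure = np.asarray(b_pure, dtype=float)
    if np.any(b_pure <= 0):
        raise ValueError("pure-stand reference must be positive")
    if np.any(b_mix < 0):
        raise ValueError("mixture biomass must be non-negative")
    out = b_mix / b_pure
    return float(out) if out.ndim == 0 else out


def relative_yield_total(ry_i, ry_j) -> float:
    """RYT = RY_i + RY_j; 1 is the no-interaction null."""
    ry_i = np.asarray(ry_i, dtype=float)
    ry_j = np.asarray(ry_j, dtype=float)
    if np.any(ry_i < 0) or np.any(ry_j < 0):
        raise ValueError("relative yields must be non-negative")
    out = ry_i + ry_j
    return float(out) if out.ndim == 0 else out


def additive_partition(d_ry, m) -> tuple[float, float, float]:
    """(NBE, CE, SE) from the deviations d_ry = RY - expected and the
    pure-stand biomasses m, for a binary mixture (N = 2)."""
    d_ry = np.asarray(d_ry, dtype=float)
    m = np.asarray(m, dtype=float)
    if d_ry.shape != (2,) or m.shape != (2,):
        raise ValueError("binary mixtures only: d_ry and m must have length 2")
    n = 2
    ce = n * d_ry.mean() * m.mean()
    se = n * float(np.mean((d_ry - d_ry.mean()) * (m - m.mean())))  # divisor N
    return ce + se, ce, se


@dataclass
class TTestResult:
    statistic: float
    df: int
    p: float
    mean: float
    null_value: float
    n: int


def test_against_null(values, null_value: float) -> TTestResult:
    """Two-sided one-sample t-test of ``values`` against ``null_value``."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 values, got {len(x)}")
    if np.var(x, ddof=1) <= 0:
        raise ValueError("degenerate sample: zero variance, t-test undefined")
    t, p = scipy.stats.ttest_1samp(x, null_value)
    return TTestResult(float(t), len(x) - 1, float(p), float(x.mean()),
                       null_value, len(x))


def effects_table(
    pair_values: pd.DataFrame, references: pd.DataFrame
) -> pd.DataFrame:
    """One row per mixture per treatment: RYs, RYT, Yo, YE, NBE, CE, SE.

    ``pair_values``: oriented adjusted values (focal, neighbor, treatment,
    value); ``references``: (variety, treatment, value).  All partition
    inputs stay on the adjusted scale: Yo is the sum of the two oriented
    pair values and M_i the adjusted pure-stand reference.
    """
    ref = {(r.variety, r.treatment): r.value for r in references.itertuples()}
    seen = set()
    rows = []
    for r in pair_values.itertuples():
        pair = tuple(sorted((r.focal, r.neighbor)))
        key = (pair, r.treatment)
        if key in seen:
            continue
        seen.add(key)
        i, j = pair
        sub = pair_values[
            (pair_values["treatment"] == r.treatment)
            & (pair_values["focal"].isin(pair))
            & (pair_values["neighbor"].isin(pair))
        ].set_index("focal")["value"]
        if (i, r.treatment) not in ref or (j, r.treatment) not in ref:
            log.warning("mixture %s-%s skipped in %s: missing pure reference",
                        i, j, r.treatment)
            continue
        if i not in sub.index or j not in sub.index:
            log.warning("mixture %s-%s skipped in %s: missing oriented pair value",
                        i, j, r.treatment)
            continue
        m_i, m_j = ref[(i, r.treatment)], ref[(j, r.treatment)]
        ry_i = relative_yield(sub[i], m_i)
        ry_j = relative_yield(sub[j], m_j)
        ryt = relative_yield_total(ry_i, ry_j)
        d_ry = np.array([ry_i - EXPECTED_RY, ry_j - EXPECTED_RY])
        m = np.array([m_i, m_j])
        nbe, ce, se = additive_partition(d_ry, m)
        rows.append({
            "variety_1": i, "variety_2": j, "treatment": r.treatment,
            "RY_1": ry_i, "RY_2": ry_j, "RYT": ryt,
            "Yo": sub[i] + sub[j], "YE": (m_i + m_j) / 2.0,
            "NBE": nbe, "CE": ce, "SE": se,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["treatment", "variety_1", "variety_2"],
                              ignore_index=True)
    return out


def index_tests(effects: pd.DataFrame) -> pd.DataFrame:
    """t-tests of RYT against 1 and NBE/CE/SE against 0, per treatment."""
    rows = []
    for (index, null) in (("RYT", 1.0), ("NBE", 0.0), ("CE", 0.0), ("SE", 0.0)):
        for k, sub in effects.groupby("treatment"):
            r = test_against_null(sub[index].to_numpy(), null)
            rows.append({"index": index, "treatment": k, "mean": r.mean,
                         "sd": float(sub[index].std(ddof=1)),
                         "t": r.statistic, "df": r.df, "p": r.p, "n": r.n})
    return pd.DataFrame(rows)


def compare_treatments(effects: pd.DataFrame, index: str = "RYT") -> pd.DataFrame:
    """Treatment effect on RYT/CE/SE with (unordered) mixture identity as a
    random intercept; Satterthwaite-approximate ANOVA."""
    data = effects.copy()
    data["mixture"] = data["variety_1"] + "|" + data["variety_2"]
    data = data.rename(columns={index: "value"})
    spec = MixedModelSpec(
        response="value", fixed=("treatment",), random_group="mixture",
        random_slope_on_treatment=False,
    )
    fit = fit_mixed_model(data, spec)
    anova = treatment_anova(fit)
    effect_name = [n for n in fit.fe_params.index if "Treatment" in n]
    anova.insert(1, "estimate",
                 float(fit.fe_params[effect_name[0]]) if effect_name else np.nan)
    return anova
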