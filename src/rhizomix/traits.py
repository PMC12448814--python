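"""Explaining mixture performance from pure-stand trait composition.

For every mixture the candidate predictors are the average and the absolute
difference of the two varieties' adjusted pure-stand trait values (five
traits -> ten predictors).  Response and predictors are z-scored within
treatment, every predictor subset is fit by OLS, models are ranked by the
small-sample Akaike criterion AICc = AIC + 2k(k+1)/(n-k-1), and inference
is averaged over the top set with Akaike weights: full-model averaging
(absent terms contribute zero), unconditional sampling variance
sum_m w_m [SE_m^2 + (beta_m - beta_bar)^2], and importance = total weight
of the models containing the term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TRAITS = ("n_leaves", "n_tillers", "leaf_n", "root_length", "root_area")


def build_features(
    references: pd.DataFrame,
    mixtures: list[tuple[str, str]],
    treatment: str,
    traits: tuple[str, ...] = DEFAULT_TRAITS,
) -> pd.DataFrame:
    """Per-mixture composition features from pure-stand trait references.

    ``references`` is the long table (variety, treatment, trait, value).
    Returns one row per mixture with ``mean_<trait>`` and ``absdiff_<trait>``
    columns; mixtures with any missing reference are dropped with a warning.
    """
    import logging
    log = logging.getLogger(__name__)
    ref = references[references["treatment"] == treatment]
    lut = {(r.variety, r.trait): r.value for r in ref.itertuples()}
    rows = []
    for a, b in mixtures:
        row = {"variety_1": min(a, b), "variety_2": max(a, b)}
        ok = True
        for t in traits:
            if (a, t) not in lut or (b, t) not in lut:
                log.warning("mixture %s-%s dropped: missing %s reference in %s",
                            a, b, t, treatment)
                ok = False
                break
            va, vb = lut[(a, t)], lut[(b, t)]
            row[f"mean_{t}"] = (va + vb) / 2.0
            row[f"absdiff_{t}"] = abs(va - vb)
        if ok:
            rows.append(row)
    return pd.DataFrame(rows)


def standardize(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Z-score columns to mean 0, SD 1 (SD with divisor n-1)."""
    out = df.copy()
    for c in columns if columns is not None else df.columns:
        x = out[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"column '{c}' has zero variance; cannot standardize")
        out[c] = (x - x.mean()) / sd
    return out


@dataclass
class CandidateModel:
    subset: tuple[str, ...]
    coef: pd.Series                  # includes the intercept
    se: pd.Series
    adj_r2: float
    loglik: float
    k: int                           # intercept + slopes + residual variance
    aicc: float
    weight: float = np.nan


@dataclass
class AveragedModel:
    terms: pd.DataFrame              # estimate, uncond_sd, ci_low, ci_high, importance
    mean_adj_r2: float
    models: list = field(default_factory=list, repr=False)


def fit_candidate(y: np.ndarray, X: pd.DataFrame, subset: tuple[str, ...]) -> CandidateModel:
    """OLS fit of ``y ~ 1 + subset`` with Gaussian log-likelihood and AICc."""
    n = len(y)
    cols = list(subset)
    k = len(cols) + 2  # intercept + slopes + residual variance
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {len(cols)} predictors (AICc undefined)")
    M = np.column_stack([np.ones(n)] + [X[c].to_numpy(dtype=float) for c in cols])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError(f"rank-deficient design for subset {subset}")
    beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    p = M.shape[1]
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if p < n else np.nan
    sigma2_ml = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    aic = -2.0 * loglik + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    mse = rss / (n - p)
    cov = mse * np.linalg.inv(M.T @ M)
    names = ["Intercept"] + cols
    return CandidateModel(
        subset=tuple(cols),
        coef=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        adj_r2=float(adj_r2), loglik=float(loglik), k=k, aicc=float(aicc),
    )


def enumerate_and_rank(
    y, X: pd.DataFrame, top: int = 10, max_predictors: int = 20
) -> list[CandidateModel]:
    """Fit all predictor subsets, rank ascending by AICc, keep the top set.

    Exhaustive enumeration dominates any backward search: the best model it
    finds is at least as good (in AICc) as any stepwise endpoint.  Ties are
    broken by parameter count, then lexicographic subset order.
    """
    y = np.asarray(y, dtype=float)
    preds = list(X.columns)
    if len(preds) > max_predictors:
        raise ValueError(
            f"{len(preds)} predictors would require 2^{len(preds)} fits; "
            f"reduce the predictor set to at most {max_predictors}"
        )
    models = []
    for mask in itertools.product((0, 1), repeat=len(preds)):
        subset = tuple(p for p, m in zip(preds, mask) if m)
        models.append(fit_candidate(y, X, subset))
    models.sort(key=lambda m: (m.aicc, m.k, m.subset))
    best = models[:top]
    d = np.array([m.aicc - best[0].aicc for m in best])
    w = np.exp(-0.5 * d)
    w /= w.sum()
    for m, wi in zip(best, w):
        m.weight = float(wi)
    return best


def model_average(models: list[CandidateModel], mode: str = "full") -> AveragedModel:
    """Akaike-weighted multimodel inference over a ranked candidate set.

    mode="full": a model without the term contributes estimate 0 (and SE 0);
    mode="conditional": averaging is restricted to the models containing the
    term (weights renormalized).  The 95% CI is +/- 1.96 unconditional SD.
    """
    if not models:
        raise ValueError("no models to average")
    d = np.array([m.aicc - min(m.aicc for m in models) for m in models])
    w = np.exp(-0.5 * d)
    w /= w.sum()
    terms = sorted({t for m in models for t in m.subset})
    rows = []
    for t in terms:
        betas = np.array([m.coef.get(t, 0.0) for m in models])
        ses = np.array([m.se.get(t, 0.0) for m in models])
        contains = np.array([t in m.subset for m in models])
        importance = float(w[contains].sum())
        if mode == "full":
            ww = w
        elif mode == "conditional":
            if not contains.any():
                continue
            ww = np.where(contains, w, 0.0)
            ww = ww / ww.sum()
        else:
            raise ValueError(f"unknown averaging mode '{mode}'")
        est = float(ww @ betas)
        var = float(ww @ (ses ** 2 + (betas - est) ** 2))
        sd = np.sqrt(var)
        rows.append({"term": t, "estimate": est, "uncond_sd": sd,
                     "ci_low": est - 1.96 * sd, "ci_high": est + 1.96 * sd,
                     "importance": importance})
    table = pd.DataFrame(rows)
    mean_adj_r2 = float(np.mean([m.adj_r2 for m in models]))
    return AveragedModel(terms=table, mean_adj_r2=mean_adj_r2, models=models)


def composition_analysis(
    effects: pd.DataFrame, references: pd.DataFrame, response: str = "RYT",
    treatment: str = "R-", traits: tuple[str, ...] = DEFAULT_TRAITS,
    top: int = 10, mode: str = "full",
) -> AveragedModel:
    """End-to-end: features -> standardization -> enumeration -> averaging."""
    sub = effects[effects["treatment"] == treatment]
    mixtures = list(zip(sub["variety_1"], sub["variety_2"]))
    feats = build_features(references, mixtures, treatment, traits)
    merged = sub.merge(feats, on=["variety_1", "variety_2"], validate="one_to_one")
    pred_cols = [c for c in feats.columns if c.startswith(("mean_", "absdiff_"))]
    z = standardize(merged[[response] + pred_cols])
    models = enumerate_and_rank(z[response], z[pred_cols], top=top)
    return model_average(models, mode=mode)
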