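"""Linear mixed models: REML fits, BLUPs and approximate-df ANOVA.

Fitting is delegated to :class:`statsmodels` MixedLM (REML).  What this
module adds on top:

* a fixed-effects coding convention for reference construction — sum
  contrasts for block/date covariates (the intercept then sits at an
  average block and date) and treatment-baseline coding for the treatment
  factor, so that ``intercept + tau_k`` is the adjusted expectation of the
  response under treatment k;
* BLUP extraction (random intercepts and, optionally, random slopes on the
  treatment contrast) per grouping level;
* boundary handling: random-slope fits whose slope variance collapses are
  refit with an intercept-only random effect, and noiseless inputs (zero
  residual variance, where REML is degenerate) fall back to the exact
  shrinkage limit — group effects estimated as fixed effects by OLS;
* Type-III-style F tests with Satterthwaite denominator degrees of
  freedom, computed from the REML log-likelihood's curvature over the
  variance parameters (finite differences; the multi-df combination
  follows the eigencontrast recipe used by lmerTest).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

log = logging.getLogger(__name__)

_ZERO_RESID_TOL = 1e-10


@dataclass
class MixedModelSpec:
    """Specification of a one-grouping-factor linear mixed model."""

    response: str
    fixed: tuple[str, ...] = ("block", "harvest_date", "treatment")
    random_group: str = "variety"
    random_slope_on_treatment: bool = True
    treatment_col: str = "treatment"
    baseline: str | None = None  # reference treatment; default: first sorted level


@dataclass
class MixedFit:
    """A fitted mixed model with everything downstream stages need."""

    spec: MixedModelSpec
    fe_params: pd.Series
    cov_re: np.ndarray          # random-effect covariance (variance scale)
    scale: float                # residual variance
    blups: pd.DataFrame         # index: group level; columns: intercept[, slope]
    converged: bool
    singular: bool
    fallback: str               # "none" | "intercept_only" | "deterministic"
    baseline: str
    treatment_levels: tuple[str, ...]
    term_slices: dict[str, slice]
    exog: np.ndarray = field(repr=False)
    endog: np.ndarray = field(repr=False)
    groups: np.ndarray = field(repr=False)
    slope_col: np.ndarray | None = field(repr=False, default=None)
    n_obs: int = 0

    @property
    def variance_components(self) -> dict:
        out = {"sigma2_intercept": float(self.cov_re[0, 0]),
               "sigma2_residual": float(self.scale)}
        if self.cov_re.shape[0] > 1:
            out["sigma2_slope"] = float(self.cov_re[1, 1])
            out["cov_intercept_slope"] = float(self.cov_re[0, 1])
        return out

    def treatment_fixed_effect(self, treatment: str) -> float:
        """mu_hat + tau_hat_k at an average block/date (tau = 0 at baseline)."""
        value = float(self.fe_params.iloc[0])
        if treatment != self.baseline:
            name = _treatment_term_name(self.spec.treatment_col, self.baseline, treatment)
            value += float(self.fe_params[name])
        return value


def _treatment_term_name(col: str, baseline: str, level: str) -> str:
    return f"C({col}, Treatment(reference='{baseline}'))[T.{level}]"


def _build_formula(spec: MixedModelSpec, baseline: str) -> str:
    parts = []
    for f in spec.fixed:
        if f == spec.treatment_col:
            parts.append(f"C({f}, Treatment(reference='{baseline}'))")
        else:
            parts.append(f"C({f}, Sum)")
    return f"{spec.response} ~ " + (" + ".join(parts) if parts else "1")


def fit_mixed_model(data: pd.DataFrame, spec: MixedModelSpec) -> MixedFit:
    """REML fit of ``response ~ fixed factors`` with a random intercept (and
    optionally a random treatment slope) for ``spec.random_group``."""
    data = data.copy()
    for col in (*spec.fixed, spec.random_group, spec.response):
        if col not in data.columns:
            raise ValueError(f"column '{col}' missing from the data table")
    if data[spec.response].isna().any():
        raise ValueError("response contains missing values")
    levels = tuple(sorted(data[spec.treatment_col].astype(str).unique())) \
        if spec.treatment_col in spec.fixed else ()
    if spec.treatment_col in spec.fixed and len(levels) != 2:
        raise ValueError(f"treatment must have exactly 2 levels, got {levels}")
    n_groups = data[spec.random_group].nunique()
    if n_groups < 2:
        raise ValueError(f"need >= 2 levels of '{spec.random_group}', got {n_groups}")
    baseline = spec.baseline or (levels[0] if levels else "")
    formula = _build_formula(spec, baseline)

    use_slope = spec.random_slope_on_treatment and spec.treatment_col in spec.fixed
    if use_slope:
        data["_treat_ind"] = (
            data[spec.treatment_col].astype(str) != baseline
        ).astype(float)
        per_group = data.groupby(spec.random_group)["_treat_ind"].nunique()
        if (per_group < 2).any():
            log.warning(
                "%d group(s) observed in a single treatment; dropping the random slope",
                int((per_group < 2).sum()),
            )
            use_slope = False

    # Degenerate, effectively noiseless data: REML has no residual variance to
    # estimate.  Use the exact lambda -> 1 shrinkage limit (group fixed effects).
    det = _deterministic_fit(data, spec, formula, baseline, levels, use_slope)
    if det is not None:
        return det

    def _fit(with_slope: bool):
        model = smf.mixedlm(
            formula, data, groups=data[spec.random_group],
            re_formula="~_treat_ind" if with_slope else "~1",
        )
        last_err, fallback_result = None, None
        for method in (None, "powell", "cg"):
            kwargs = {} if method is None else {"method": method}
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    result = model.fit(reml=True, maxiter=500, **kwargs)
                warned = any(
                    issubclass(w.category, ConvergenceWarning) for w in caught
                )
                if result.converged and not warned:
                    return model, result, False
                if fallback_result is None:
                    fallback_result = (model, result, warned)
            except (np.linalg.LinAlgError, ValueError) as err:  # optimizer wandered
                last_err = err
        if fallback_result is not None:
            return fallback_result
        raise RuntimeError(
            f"mixed model for '{spec.response}' failed under every optimizer"
        ) from last_err

    fallback = "none"
    model, result, warned = _fit(use_slope)
    singular = warned or not result.converged
    if use_slope:
        cov = np.atleast_2d(result.cov_re.to_numpy())
        slope_collapsed = cov[1, 1] <= 1e-8 * max(cov[0, 0] + result.scale, 1e-12)
        if slope_collapsed or not result.converged:
            log.warning(
                "random treatment slope is singular for response '%s'; "
                "refitting with a random intercept only", spec.response,
            )
            use_slope = False
            fallback = "intercept_only"
            model, result, warned = _fit(False)
            singular = True
    if not result.converged:
        log.warning("mixed model for '%s' did not converge", spec.response)

    re = result.random_effects
    cols = ["intercept", "slope"] if use_slope else ["intercept"]
    blups = pd.DataFrame(
        {g: np.asarray(v, dtype=float) for g, v in re.items()}, index=cols
    ).T
    blups.index.name = spec.random_group

    design_info = model.data.design_info
    term_slices = {t.name(): design_info.term_name_slices[t.name()]
                   for t in design_info.terms}
    return MixedFit(
        spec=spec,
        fe_params=result.fe_params,
        cov_re=np.atleast_2d(result.cov_re.to_numpy()),
        scale=float(result.scale),
        blups=blups,
        converged=bool(result.converged),
        singular=bool(singular),
        fallback=fallback,
        baseline=baseline,
        treatment_levels=levels,
        term_slices=term_slices,
        exog=np.asarray(model.exog, dtype=float),
        endog=np.asarray(model.endog, dtype=float),
        groups=np.asarray(data[spec.random_group]),
        slope_col=data["_treat_ind"].to_numpy() if use_slope else None,
        n_obs=len(data),
    )


def _deterministic_fit(data, spec, formula, baseline, levels, use_slope):
    """Exact fit when the residual variance is (numerically) zero.

    Fits the fixed part plus sum-coded group deviations (and, when a random
    slope was requested, group x treatment deviations) by OLS; the group
    deviations play the role of unshrunken BLUPs — the lambda -> 1 limit of
    the mixed model.  Returns None when the data carry genuine residual noise.
    """
    g_term = f"C({spec.random_group}, Sum)"
    has_treatment = spec.treatment_col in spec.fixed
    if has_treatment and "_treat_ind" not in data.columns:
        data = data.copy()
        data["_treat_ind"] = (
            data[spec.treatment_col].astype(str) != baseline
        ).astype(float)
    # the treatment main effect enters as the plain indicator so that the
    # group x treatment interaction stays full rank (no duplicated column)
    parts = ["_treat_ind" if f == spec.treatment_col else f"C({f}, Sum)"
             for f in spec.fixed]
    group_formula = f"{spec.response} ~ " + " + ".join([*parts, g_term] or ["1"])
    if use_slope:
        group_formula += f" + {g_term}:_treat_ind"
    ols = smf.ols(group_formula, data).fit()
    ss_res = float(np.sum(ols.resid ** 2))
    ss_tot = float(np.sum((data[spec.response] - data[spec.response].mean()) ** 2))
    if ss_tot > 0 and ss_res / ss_tot > _ZERO_RESID_TOL:
        return None

    groups = np.sort(data[spec.random_group].unique())

    def _sum_coded(suffix: str) -> dict:
        prefix, tail = f"{g_term}[S.", "]" + suffix
        dev = {g: 0.0 for g in groups}
        for name, value in ols.params.items():
            if name.startswith(prefix) and name.endswith(tail):
                dev[name[len(prefix):len(name) - len(tail)]] = float(value)
        dev[groups[-1]] = -sum(v for g, v in dev.items() if g != groups[-1])
        return dev

    dev = _sum_coded("")
    cols = {"intercept": [dev[g] for g in groups]}
    if use_slope:
        dev_s = _sum_coded(":_treat_ind")
        cols["slope"] = [dev_s[g] for g in groups]
    blups = pd.DataFrame(cols, index=groups)
    blups.index.name = spec.random_group

    base_model = smf.ols(formula, data)
    design_info = base_model.data.design_info
    term_slices = {t.name(): design_info.term_name_slices[t.name()]
                   for t in design_info.terms}
    fe_names = list(base_model.exog_names)
    treat_name = (_treatment_term_name(spec.treatment_col, baseline, levels[1])
                  if has_treatment and len(levels) == 2 else None)
    fe_params = pd.Series(
        [ols.params.get("_treat_ind", 0.0) if n == treat_name
         else ols.params.get(n, 0.0) for n in fe_names],
        index=fe_names,
    )
    log.warning(
        "response '%s' has (near-)zero residual variance; using the exact "
        "deterministic limit with unshrunken group effects", spec.response,
    )
    return MixedFit(
        spec=spec, fe_params=fe_params,
        cov_re=np.array([[float(np.var(list(dev.values()), ddof=1))]]),
        scale=0.0, blups=blups, converged=True, singular=True,
        fallback="deterministic", baseline=baseline, treatment_levels=levels,
        term_slices=term_slices,
        exog=np.asarray(base_model.exog, dtype=float),
        endog=np.asarray(base_model.endog, dtype=float),
        groups=np.asarray(data[spec.random_group]), slope_col=None,
        n_obs=len(data),
    )


# ---------------------------------------------------------------------------
# Satterthwaite machinery

class _RemlSurface:
    """REML log-likelihood and GLS fixed-effect covariance as functions of the
    variance parameters, for one grouping factor."""

    def __init__(self, fit: MixedFit):
        self.q_re = fit.cov_re.shape[0]
        order = np.argsort(fit.groups, kind="stable")
        X, y = fit.exog[order], fit.endog[order]
        g = fit.groups[order]
        z1 = fit.slope_col[order] if fit.slope_col is not None else None
        self.blocks = []
        start = 0
        for i in range(1, len(g) + 1):
            if i == len(g) or g[i] != g[start]:
                Z = np.ones((i - start, 1))
                if z1 is not None:
                    Z = np.column_stack([Z, z1[start:i]])
                self.blocks.append((y[start:i], X[start:i], Z))
                start = i
        self.p = X.shape[1]
        self.n = len(y)

    def theta0(self, fit: MixedFit) -> np.ndarray:
        if self.q_re == 1:
            return np.array([fit.scale, fit.cov_re[0, 0]])
        return np.array([fit.scale, fit.cov_re[0, 0], fit.cov_re[0, 1],
                         fit.cov_re[1, 1]])

    def _psi(self, theta: np.ndarray) -> np.ndarray:
        if self.q_re == 1:
            return np.array([[theta[1]]])
        return np.array([[theta[1], theta[2]], [theta[2], theta[3]]])

    def _v_invs(self, theta):
        s2, psi = max(theta[0], 1e-12), self._psi(theta)
        for y, X, Z in self.blocks:
            V = s2 * np.eye(len(y)) + Z @ psi @ Z.T
            yield y, X, V

    def beta_cov(self, theta: np.ndarray) -> np.ndarray:
        XtViX = np.zeros((self.p, self.p))
        for y, X, V in self._v_invs(theta):
            XtViX += X.T @ np.linalg.solve(V, X)
        return np.linalg.inv(XtViX)

    def loglik(self, theta: np.ndarray) -> float:
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        logdet = 0.0
        parts = []
        for y, X, V in self._v_invs(theta):
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return -np.inf
            logdet += ld
            Vi_X = np.linalg.solve(V, X)
            XtViX += X.T @ Vi_X
            XtViy += Vi_X.T @ y
            parts.append((y, X, V))
        beta = np.linalg.solve(XtViX, XtViy)
        quad = sum(
            float(r @ np.linalg.solve(V, r))
            for (y, X, V), r in ((b, b[0] - b[1] @ beta) for b in parts)
        )
        sign, ld_x = np.linalg.slogdet(XtViX)
        return -0.5 * (logdet + quad + ld_x)


def _fd_hessian(f, x0, rel=1e-4):
    k = len(x0)
    h = np.maximum(np.abs(x0) * rel, 1e-10)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            def ev(si, sj):
                x = x0.copy()
                x[i] += si * h[i]
                x[j] += sj * h[j]
                return f(x)
            H[i, j] = H[j, i] = (
                ev(1, 1) - ev(1, -1) - ev(-1, 1) + ev(-1, -1)
            ) / (4 * h[i] * h[j])
    return H


def _fd_grad(f, x0, rel=1e-4):
    k = len(x0)
    h = np.maximum(np.abs(x0) * rel, 1e-10)
    g = np.zeros(k)
    for i in range(k):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        g[i] = (f(xp) - f(xm)) / (2 * h[i])
    return g


def treatment_anova(fit: MixedFit) -> pd.DataFrame:
    """Type-III-style F tests per fixed term with Satterthwaite denominator df.

    With sum/treatment coding and no interactions, the Type-III test of a
    term is the joint test that its coefficient block is zero.  For boundary
    or deterministic fits, the tests use the boundary variances with a
    residual-df denominator and the fit's ``singular`` flag is propagated.
    """
    surf = _RemlSurface(fit)
    resid_df = max(fit.n_obs - surf.p, 1)
    beta = fit.fe_params.to_numpy()

    use_satt = not fit.singular and fit.scale > 0
    if use_satt:
        theta0 = surf.theta0(fit)
        C0 = surf.beta_cov(theta0)
        H = _fd_hessian(surf.loglik, theta0)
        try:
            A = np.linalg.inv(-H)
            if not np.all(np.isfinite(A)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            use_satt = False
    if not use_satt:
        scale = fit.scale if fit.scale > 0 else 1e-300
        C0 = scale * np.linalg.inv(fit.exog.T @ fit.exog) if fit.fallback == \
            "deterministic" else _RemlSurface(fit).beta_cov(
                np.concatenate([[max(fit.scale, 1e-12)],
                                fit.cov_re[np.triu_indices(fit.cov_re.shape[0])]]))

    rows = []
    for term, sl in fit.term_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        q = len(idx)
        W = C0[np.ix_(idx, idx)]
        b = beta[idx]
        if fit.scale <= 0:
            # noiseless data: the F statistic degenerates to 0 or infinity
            scale_y = max(1.0, float(np.max(np.abs(fit.endog))))
            F = 0.0 if np.max(np.abs(b)) < 1e-8 * scale_y else np.inf
        else:
            F = float(b @ np.linalg.solve(W, b)) / q
        if use_satt:
            evals, evecs = np.linalg.eigh(W)
            nus = []
            for m in range(q):
                lvec = np.zeros(surf.p)
                lvec[idx] = evecs[:, m]
                gfun = lambda th, l=lvec: float(l @ surf.beta_cov(th) @ l)
                grad = _fd_grad(gfun, theta0)
                denom = float(grad @ A @ grad)
                nus.append(2 * evals[m] ** 2 / denom if denom > 1e-300 else np.inf)
            if q == 1:
                df_den = nus[0]
            else:
                finite = [nu for nu in nus if np.isfinite(nu) and nu > 2]
                if len(finite) < q:
                    df_den = resid_df
                else:
                    E = sum(nu / (nu - 2) for nu in finite)
                    df_den = 2 * E / (E - q) if E > q else resid_df
            if not np.isfinite(df_den) or df_den <= 0:
                df_den = resid_df
        else:
            df_den = resid_df
        p = float(scipy.stats.f.sf(F, q, df_den)) if np.isfinite(F) else 0.0
        rows.append({"term": term, "F": F, "df_num": q,
                     "df_den": float(df_den), "p": p,
                     "singular": bool(fit.singular)})
    return pd.DataFrame(rows)


def classical_anova(data: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Ordinary fixed-effects ANOVA (Type III), used as an oracle cross-check."""
    ols = smf.ols(formula, data).fit()
    return sm.stats.anova_lm(ols, typ=3)
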