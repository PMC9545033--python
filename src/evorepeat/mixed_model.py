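"""Linear mixed model for log fitness, with Tukey-adjusted contrasts.

Model: log population size ~ week * treatment (fixed; reference cell =
week 0, "no" bottleneck) with random intercepts for replicate and for
assessment day nested within replicate x week, fitted by REML.  Numerical
optimisation is delegated to statsmodels' MixedLM; this module owns the
model specification, the reference-cell parameterisation, the
least-squares-means contrast algebra, and the Tukey (studentized-range)
multiplicity adjustment.

Degrees of freedom for contrasts use the residual method
(N - rank of the fixed-effect design), declared in the output; mixed-model
df approximations differ across software and exact agreement with any
particular one is not promised.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .data_model import ExperimentTable, TREATMENT_ORDER

__all__ = ["LMMFit", "Contrast", "fit_lmm", "pairwise_contrasts"]

_ZERO_NOISE_SSR = 1e-10


class DesignError(ValueError):
    """The fixed-effect design is singular (e.g. a treatment missing a week)."""


class FitError(RuntimeError):
    """The REML optimizer failed to converge."""


@dataclass(frozen=True)
class Contrast:
    label: str
    estimate: float
    se: float
    df: float
    t_ratio: float
    p_unadjusted: float
    adjusted_p: float

    def to_dict(self) -> dict:
        return {
            "contrast": self.label,
            "estimate": self.estimate,
            "SE": self.se,
            "df": self.df,
            "t_ratio": self.t_ratio,
            "p_unadjusted": self.p_unadjusted,
            "adjusted_p": self.adjusted_p,
        }


@dataclass
class LMMFit:
    """Result of the mixed-model stage.

    ``fixed_effects`` maps term labels (intercept, week15, <treatment>,
    week15 x <treatment>) to estimate/SE/t/p; ``variance_components`` holds
    the replicate, assessment-day and residual variances (log-units^2).
    """

    fixed_effects: dict[str, dict[str, float]]
    variance_components: dict[str, float]
    r2_marginal: float
    r2_conditional: float
    method: str
    df_method: str
    df_resid: float
    n_obs: int
    treatments: tuple[str, ...]
    converged: bool
    contrasts: list[Contrast] = field(default_factory=list)
    # internal state needed by the contrast algebra
    _params: pd.Series = field(default=None, repr=False)
    _cov: pd.DataFrame = field(default=None, repr=False)

    @property
    def reference_treatment(self) -> str:
        return self.treatments[0]

    def cell_mean_row(self, treatment: str, week: int) -> pd.Series:
        """Design-row L such that L @ beta is the (treatment, week) cell mean."""
        L = pd.Series(0.0, index=self._params.index)
        L["intercept"] = 1.0
        if treatment != self.reference_treatment:
            L[f"trt[{treatment}]"] = 1.0
        if week == 15:
            L["week15"] = 1.0
            if treatment != self.reference_treatment:
                L[f"week15:trt[{treatment}]"] = 1.0
        return L

    def cell_mean(self, treatment: str, week: int) -> float:
        return float(self.cell_mean_row(treatment, week) @ self._params)

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed_effects,
            "variance_components": self.variance_components,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "method": self.method,
            "df_method": self.df_method,
            "df_resid": self.df_resid,
            "n_obs": self.n_obs,
            "treatments": list(self.treatments),
            "converged": self.converged,
            "contrasts": [c.to_dict() for c in self.contrasts],
        }


def _design_frame(table: ExperimentTable) -> tuple[pd.DataFrame, tuple[str, ...], list[str]]:
    df = table.with_log_size()
    present = df["treatment"].unique().tolist()
    treatments = tuple(
        [t for t in TREATMENT_ORDER if t in present]
        + sorted(t for t in present if t not in TREATMENT_ORDER)
    )
    if len(treatments) < 2:
        raise DesignError("fit_lmm requires at least 2 treatments")
    for t in treatments:
        weeks = set(df.loc[df["treatment"] == t, "week"].unique())
        if weeks != {0, 15}:
            raise DesignError(f"treatment {t!r} lacks one of the weeks (singular design)")

    ref = treatments[0]
    df = df.copy()
    df["intercept"] = 1.0
    df["week15"] = (df["week"] == 15).astype(float)
    terms = ["intercept", "week15"]
    for t in treatments[1:]:
        df[f"trt[{t}]"] = (df["treatment"] == t).astype(float)
        terms.append(f"trt[{t}]")
    for t in treatments[1:]:
        df[f"week15:trt[{t}]"] = df["week15"] * df[f"trt[{t}]"]
        terms.append(f"week15:trt[{t}]")
    df["rep_id"] = df["treatment"] + ":" + df["replicate"]
    df["day_id"] = df["rep_id"] + ":" + df["week"].astype(str) + ":" + df["assessment_day"]
    assert ref == treatments[0]
    return df, treatments, terms


def fit_lmm(
    table: ExperimentTable,
    method: str = "reml",
    random_effects: tuple[str, ...] = ("replicate", "assessment_day"),
) -> LMMFit:
    """Fit the log-fitness mixed model.

    ``method='reml'`` is the standard fit; ``method='ols'`` forces all
    variance components to zero (ordinary least squares on the same fixed
    design), which is also used automatically for exactly noise-free data,
    where the REML likelihood is degenerate.  ``random_effects`` selects
    which random intercepts enter the model: the full set (default) or
    ``("replicate",)`` for a single-random-effect fit.
    """
    if not set(random_effects) <= {"replicate", "assessment_day"} or "replicate" not in random_effects:
        raise ValueError("random_effects must be ('replicate',) or ('replicate', 'assessment_day')")
    df, treatments, terms = _design_frame(table)
    y = df["log_size"].to_numpy()
    X = df[terms].to_numpy()
    if np.linalg.matrix_rank(X) < len(terms):
        raise DesignError("fixed-effect design matrix is rank-deficient")

    ols = sm.OLS(y, X).fit()
    df_resid = float(len(y) - len(terms))

    if method == "ols" or ols.ssr < _ZERO_NOISE_SSR:
        params = pd.Series(ols.params, index=terms)
        cov = pd.DataFrame(ols.cov_params(), index=terms, columns=terms)
        bse = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, params.to_numpy() / bse, np.inf * np.sign(params.to_numpy()))
        pvals = 2 * sps.t.sf(np.abs(tvals), df_resid)
        vc = {"replicate": 0.0, "assessment_day": 0.0, "residual": float(ols.scale)}
        var_f = float(np.var(X @ params.to_numpy()))
        denom = var_f + sum(vc.values())
        fit = LMMFit(
            fixed_effects={
                t: {
                    "estimate": float(params[t]),
                    "SE": float(bse[i]),
                    "t_value": float(tvals[i]),
                    "p_value": float(pvals[i]),
                }
                for i, t in enumerate(terms)
            },
            variance_components=vc,
            r2_marginal=var_f / denom if denom > 0 else 1.0,
            r2_conditional=var_f / denom if denom > 0 else 1.0,
            method="ols" if method == "ols" else "ols (noise-free data)",
            df_method="residual",
            df_resid=df_resid,
            n_obs=len(y),
            treatments=treatments,
            converged=True,
            _params=params,
            _cov=cov,
        )
        return fit
    if method != "reml":
        raise ValueError(f"method must be 'reml' or 'ols', got {method!r}")

    vc_formula = (
        {"assessment_day": "0 + C(day_id)"} if "assessment_day" in random_effects else None
    )
    model = sm.MixedLM.from_formula(
        "log_size ~ 0 + " + " + ".join(f"Q('{t}')" for t in terms),
        groups="rep_id",
        re_formula="1",
        vc_formula=vc_formula,
        data=df,
    )
    try:
        with warnings.catch_warnings():
            # pgtol/factr are forwarded to scipy's L-BFGS despite the
            # "not used by MixedLM.fit" notice; they tighten convergence.
            warnings.filterwarnings("ignore", message="Argument .* not used by MixedLM.fit")
            res = model.fit(reml=True, method="lbfgs", maxiter=2000, pgtol=1e-10, factr=100.0)
            if not res.converged:
                res = model.fit(reml=True, method="powell", maxiter=2000)
    except Exception as exc:  # optimizer blow-up
        raise FitError(f"REML fit failed: {exc}") from exc
    if not res.converged:
        raise FitError("REML fit did not converge (lbfgs and powell)")

    clean = {f"Q('{t}')": t for t in terms}
    params = res.fe_params.rename(index=clean).reindex(terms)
    cov_all = res.cov_params()
    cov = cov_all.rename(index=clean, columns=clean).reindex(index=terms, columns=terms)

    sigma_rep = float(np.asarray(res.cov_re)[0, 0])
    sigma_day = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    sigma_res = float(res.scale)
    vc = {"replicate": sigma_rep, "assessment_day": sigma_day, "residual": sigma_res}

    bse = np.sqrt(np.diag(cov))
    tvals = params.to_numpy() / bse
    pvals = 2 * sps.t.sf(np.abs(tvals), df_resid)

    var_f = float(np.var(X @ params.to_numpy()))
    total = var_f + sigma_rep + sigma_day + sigma_res
    fit = LMMFit(
        fixed_effects={
            t: {
                "estimate": float(params[t]),
                "SE": float(bse[i]),
                "t_value": float(tvals[i]),
                "p_value": float(pvals[i]),
            }
            for i, t in enumerate(terms)
        },
        variance_components=vc,
        r2_marginal=var_f / total,
        r2_conditional=(var_f + sigma_rep + sigma_day) / total,
        method="reml",
        df_method="residual",
        df_resid=df_resid,
        n_obs=len(y),
        treatments=treatments,
        converged=True,
        _params=params,
        _cov=cov,
    )
    return fit


def _tukey_p(t_ratio: float, n_means: int, df: float) -> float:
    """Tukey adjusted p: studentized-range tail at q = |t| * sqrt(2)."""
    if not np.isfinite(t_ratio):
        return 0.0
    q = abs(t_ratio) * np.sqrt(2.0)
    return float(sps.studentized_range.sf(q, n_means, df))


def pairwise_contrasts(fit: LMMFit, family: str) -> list[Contrast]:
    """Tukey-adjusted least-squares-means contrasts.

    Families: ``within_treatment_between_weeks`` (week 0 minus week 15 per
    treatment) and ``within_week_between_treatments`` (all treatment pairs
    within each week, first-listed minus second).  The Tukey adjustment
    treats all 2 x n_treatments cell means as one family, as pairwise
    comparison of the full week x treatment grid does.
    """
    if family == "within_treatment_between_weeks":
        pairs = [((t, 0), (t, 15), f"{t} bottleneck (week 0 - 15)") for t in fit.treatments]
    elif family == "within_week_between_treatments":
        pairs = [
            ((a, w), (b, w), f"week {w} ({a} - {b})")
            for w in (0, 15)
            for a, b in itertools.combinations(fit.treatments, 2)
        ]
    else:
        raise ValueError(f"unknown contrast family: {family!r}")

    n_means = 2 * len(fit.treatments)
    out = []
    for (t1, w1), (t2, w2), label in pairs:
        L = (fit.cell_mean_row(t1, w1) - fit.cell_mean_row(t2, w2)).to_numpy()
        est = float(L @ fit._params.to_numpy())
        se = float(np.sqrt(L @ fit._cov.to_numpy() @ L))
        if se > 0:
            t_ratio = est / se
            p_un = float(2 * sps.t.sf(abs(t_ratio), fit.df_resid))
        else:
            t_ratio = np.inf * np.sign(est) if est != 0 else 0.0
            p_un = 0.0 if est != 0 else 1.0
        out.append(
            Contrast(
                label=label,
                estimate=est,
                se=se,
                df=fit.df_resid,
                t_ratio=t_ratio,
                p_unadjusted=p_un,
                adjusted_p=_tukey_p(t_ratio, n_means, fit.df_resid) if se > 0 else p_un,
            )
        )
    return out
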