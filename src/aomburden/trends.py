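"""Trend testing for annual incidence series.

Two complementary tools:

* the Mann-Kendall test for monotonic trend — the statistic S is the sum of
  signs over all pairs, its variance carries the standard tie correction,
  and the normal approximation is used *without* continuity correction;
* a two-period segmented (interrupted time series) count regression with a
  log link and log person-years offset,

  .. math::

     \\log \\mu = b_0 + b_1 (year - first) + b_2\\,[year \\ge break]
                + b_3 (year - break)[year \\ge break] + covariates

  fit by maximum likelihood under a negative-binomial family whose
  dispersion is profiled (the fit reduces to Poisson as the dispersion goes
  to zero). exp(b1) is the early-period annual rate ratio; exp(b1 + b3) the
  late-period one; exp(b2) the immediate level change at the break.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

logger = logging.getLogger(__name__)

_MIN_ALPHA = 1e-8
_MAX_ALPHA = 20.0


@dataclass(frozen=True)
class MKResult:
    s_statistic: int
    variance: float
    z_score: float
    p_value: float
    n: int


def mann_kendall(series) -> MKResult:
    """Mann-Kendall test for a monotonic trend in an ordered series.

    Two-sided p-value from the normal approximation without continuity
    correction; the variance uses the tie correction
    Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18.
    """
    x = np.asarray(list(series), dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Mann-Kendall test needs at least 3 observations")
    if not np.isfinite(x).all():
        raise ValueError("series values must be finite")
    s = 0
    for i in range(n - 1):
        s += int(np.sign(x[i + 1 :] - x[i]).sum())
    _, counts = np.unique(x, return_counts=True)
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in counts if t > 1)
    var = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var <= 0:  # fully tied series
        return MKResult(s, 0.0, 0.0, 1.0, n)
    z = s / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return MKResult(s, var, float(z), float(p), n)


@dataclass(frozen=True)
class ITSSpec:
    breakpoint_year: int = 2014
    covariates: tuple[str, ...] = ("age_band", "sex")
    family: str = "negative_binomial"  # or "poisson"
    alpha: float = 0.05

    def __post_init__(self):
        if self.family not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown family: {self.family!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ITSResult:
    """Segmented-regression fit summary.

    ``coefficients`` has one row per model term (coef on the log scale, se,
    rate_ratio with Wald CI, p-value); ``period_trends`` holds the early and
    late annual rate ratios; ``dispersion`` is the negative-binomial alpha
    (0 means the fit collapsed to Poisson).
    """

    coefficients: pd.DataFrame
    period_trends: pd.DataFrame
    dispersion: float
    loglike: float
    converged: bool
    n_obs: int
    breakpoint_year: int
    first_year: int
    fitted: pd.DataFrame = field(repr=False, default=None)
    profile: list = field(repr=False, default_factory=list)


def _design(counts: pd.DataFrame, spec: ITSSpec):
    df = counts.loc[counts["person_years"] > 0].copy()
    if not len(df):
        raise ValueError("no strata with positive person-years")
    years = np.sort(df["year"].unique())
    first = int(years.min())
    bp = spec.breakpoint_year
    if (years < bp).sum() < 2 or (years >= bp).sum() < 2:
        raise ValueError("need at least 2 years on each side of the breakpoint")
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["trend"] = df["year"] - first
    X["level_change"] = (df["year"] >= bp).astype(float)
    X["trend_change"] = (df["year"] - bp).clip(lower=0).astype(float)
    for cov in spec.covariates:
        if cov not in df.columns:
            continue
        dummies = pd.get_dummies(df[cov].astype(str), prefix=cov, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return df, X, first


def _glm_fit(y, X, offset, alpha, start_params=None):
    fam = (
        sm.families.Poisson()
        if alpha is None
        else sm.families.NegativeBinomial(alpha=max(alpha, _MIN_ALPHA))
    )
    model = sm.GLM(y, X, family=fam, offset=offset)
    with warnings.catch_warnings():
        # an exactly saturated (noise-free) series trips the separation
        # heuristic; non-finite coefficients are caught explicitly downstream
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        return model.fit(start_params=start_params, maxiter=200, tol=1e-10)


def fit_its(counts: pd.DataFrame, spec: ITSSpec = ITSSpec()) -> ITSResult:
    """Fit the segmented count regression to a stratum-count table.

    ``counts`` needs columns year, events, person_years, plus any covariate
    factors named in the spec. The negative-binomial dispersion is estimated
    by profiling the full likelihood over alpha; a boundary solution at
    alpha -> 0 reports dispersion 0 (Poisson-equivalent fit).
    """
    df, X, first = _design(counts, spec)
    y = df["events"].to_numpy(dtype=float)
    offset = np.log(df["person_years"].to_numpy(dtype=float))

    pois = _glm_fit(y, X, offset, alpha=None)
    profile_evals: list[tuple[float, float]] = []

    if spec.family == "poisson":
        res, dispersion = pois, 0.0
    else:
        start = pois.params

        def nll(log_a):
            r = _glm_fit(y, X, offset, alpha=np.exp(log_a), start_params=start)
            profile_evals.append((float(np.exp(log_a)), float(r.llf)))
            return -r.llf

        opt = optimize.minimize_scalar(
            nll,
            bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        alpha_hat = float(np.exp(opt.x))
        res = _glm_fit(y, X, offset, alpha=alpha_hat, start_params=start)
        # boundary: no overdispersion beyond Poisson
        if alpha_hat <= _MIN_ALPHA * 10 or res.llf <= pois.llf + 1e-6:
            dispersion = 0.0
        else:
            dispersion = alpha_hat

    if not np.isfinite(res.params).all():
        raise RuntimeError(
            f"ITS fit produced non-finite coefficients (possible separation): {res.params}"
        )
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise RuntimeError(f"ITS fit did not converge; history: {res.fit_history}")

    z = stats.norm.ppf(1 - spec.alpha / 2)
    old_err = np.seterr(over="ignore")  # near-empty strata give infinite CI bounds
    coef = pd.DataFrame(
        {
            "term": X.columns,
            "coef": res.params.values,
            "se": res.bse.values,
            "rate_ratio": np.exp(res.params.values),
            "ci_low": np.exp(res.params.values - z * res.bse.values),
            "ci_high": np.exp(res.params.values + z * res.bse.values),
            "p_value": res.pvalues.values,
        }
    )

    k = X.shape[1]
    rows = []
    for name, contrast in (
        ("early", {"trend": 1.0}),
        ("late", {"trend": 1.0, "trend_change": 1.0}),
    ):
        L = np.zeros(k)
        for term, w in contrast.items():
            L[X.columns.get_loc(term)] = w
        t = res.t_test(L)
        eff, se = float(t.effect.squeeze()), float(t.sd.squeeze())
        rows.append(
            {
                "period": name,
                "annual_rate_ratio": np.exp(eff),
                "ci_low": np.exp(eff - z * se),
                "ci_high": np.exp(eff + z * se),
                "p_value": float(t.pvalue.squeeze()),
            }
        )
    period = pd.DataFrame(rows)
    np.seterr(**old_err)

    fitted = df[["year"]].copy()
    fitted["mu"] = res.fittedvalues.to_numpy() if hasattr(res.fittedvalues, "to_numpy") else res.fittedvalues
    fitted["person_years"] = df["person_years"].to_numpy()

    return ITSResult(
        coefficients=coef,
        period_trends=period,
        dispersion=dispersion,
        loglike=float(res.llf),
        converged=converged,
        n_obs=len(df),
        breakpoint_year=spec.breakpoint_year,
        first_year=first,
        fitted=fitted,
        profile=profile_evals,
    )


def trend_report(
    annual_tables: dict[str, pd.DataFrame],
    counts_tables: dict[str, pd.DataFrame | None],
    spec: ITSSpec = ITSSpec(),
    figure_path=None,
    panel_names: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, dict[str, ITSResult], list[str]]:
    """Run Mann-Kendall and ITS over a family of annual IR series.

    ``annual_tables`` maps a series name (overall, an age band, simple,
    recurrent, ...) to an annual incidence table with ``year`` and ``ir``
    columns; ``counts_tables`` maps the same names to stratum-count tables
    for the ITS fit (None to skip). Returns a tidy results frame (one row
    per series and model term, MK columns repeated), the fitted ITS models,
    and a list of notes for degenerate series. Renders a multi-panel figure
    to ``figure_path`` when given.
    """
    rows, fits, notes = [], {}, []
    for name, annual in annual_tables.items():
        if annual is None or len(annual) == 0:
            notes.append(f"{name}: no episodes; series skipped")
            continue
        series = annual.sort_values("year")["ir"]
        if len(series) < 3:
            notes.append(f"{name}: fewer than 3 annual points; MK not applicable")
            mk = None
        else:
            mk = mann_kendall(series)
        its = None
        counts = counts_tables.get(name)
        if counts is not None and len(counts) and counts["events"].sum() > 0:
            try:
                its = fit_its(counts, spec)
                fits[name] = its
            except (ValueError, RuntimeError) as exc:
                notes.append(f"{name}: ITS not fitted ({exc})")
        elif counts is not None:
            notes.append(f"{name}: no events; ITS not attempted")
        base = {
            "series": name,
            "mk_s": mk.s_statistic if mk else np.nan,
            "mk_p_value": mk.p_value if mk else np.nan,
        }
        if its is None:
            rows.append({**base, "term": None, "rate_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "dispersion": np.nan})
        else:
            for _, c in its.coefficients.iterrows():
                rows.append({**base, "term": c["term"], "rate_ratio": c["rate_ratio"],
                             "ci_low": c["ci_low"], "ci_high": c["ci_high"],
                             "p_value": c["p_value"], "dispersion": its.dispersion})
            for _, c in its.period_trends.iterrows():
                rows.append({**base, "term": f"{c['period']}_annual_rr",
                             "rate_ratio": c["annual_rate_ratio"], "ci_low": c["ci_low"],
                             "ci_high": c["ci_high"], "p_value": c["p_value"],
                             "dispersion": its.dispersion})
    report = pd.DataFrame(
        rows,
        columns=["series", "mk_s", "mk_p_value", "term", "rate_ratio",
                 "ci_low", "ci_high", "p_value", "dispersion"],
    )
    if figure_path is not None:
        from .plots import plot_its_panels

        names = panel_names or tuple(annual_tables)
        panels = {
            name: (annual_tables[name], fits.get(name))
            for name in names
            if annual_tables.get(name) is not None and len(annual_tables[name])
        }
        if panels:
            plot_its_panels(panels, path=figure_path)
    return report, fits, notes


def fitted_annual_rates(result: ITSResult) -> pd.DataFrame:
    """Aggregate fitted means to annual rates per 1000 PY (for plotting)."""
    g = result.fitted.groupby("year", as_index=False).agg(
        mu=("mu", "sum"), person_years=("person_years", "sum")
    )
    g["ir"] = 1000.0 * g["mu"] / g["person_years"]
    return g
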