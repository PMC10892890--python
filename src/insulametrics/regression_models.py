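"""Count and proportion regressions with small-sample model selection.

The analysis pairs two GLM families over the same four island predictors
(Area, Topography, Isolation, Population):

* **Negative binomial (NB2)** regression for taxon counts, log link, linear
  predictor on the untransformed predictors, with the dispersion ``theta``
  estimated by maximum likelihood (variance ``mu + mu^2/theta``).  The
  dispersion is profiled out: for each candidate ``theta`` the mean
  coefficients are the IRLS solution of the fixed-dispersion GLM, and the
  profile log-likelihood is maximised over ``log theta``.
* **Beta regression** for endemic proportions, logit mean link with a
  constant precision ``phi`` (``y ~ Beta(mu*phi, (1-mu)*phi)``), fitted by
  joint ML.

Model comparison uses the small-sample corrected Akaike criterion
``AICc = AIC + 2k(k+1)/(n-k-1)`` with the dispersion/precision parameter
counted in ``k``; the plain ``AIC`` (the convention some published tables
print under the AICc heading) is carried on every fit as well.

Predictors are standardised internally for numerical stability — island
areas span five orders of magnitude — and coefficients, covariances and
Wald p-values are transformed back to the raw scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

from .errors import BoundaryValueError, ConvergenceError, ValidationError
from .island_data import PREDICTORS, IslandTable

Response = Literal["count", "proportion"]

#: Response column used for each family.
RESPONSE_COLUMNS = {"count": "Spp", "proportion": "Prop"}

#: The labelled specifications of the published NB (Table-1-style) and
#: beta (Table-2-style) model suites.
NB_SUITE = {
    "A1": ("Area", "Topography", "Isolation", "Population"),
    "B1": ("Area", "Topography", "Isolation"),
    "C1": ("Area", "Topography"),
    "D1": ("Topography",),
    "E1": ("Area",),
}
BETA_SUITE = {
    "A2": ("Area", "Topography", "Isolation", "Population"),
    "B2": ("Area", "Topography", "Isolation"),
    "C2": ("Area", "Topography"),
    "D2": ("Topography",),
}


# ---------------------------------------------------------------------------
# simple statistics
# ---------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; undefined for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r needs two equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("pearson_r needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    return float(scipy.stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class PowerLawFit:
    """Species–area power law S = c * A**z, fitted on the log–log scale."""

    c: float
    z: float
    r_loglog: float


def fit_species_area_power_law(table: IslandTable | pd.DataFrame) -> PowerLawFit:
    """OLS of log S on log A; c = exp(intercept), z = slope."""
    df = table.to_dataframe() if isinstance(table, IslandTable) else table
    S = np.asarray(df["Spp"], dtype=float)
    A = np.asarray(df["Area"], dtype=float)
    if np.any(S <= 0) or np.any(A <= 0):
        raise ValidationError("power law requires strictly positive S and A")
    logS, logA = np.log(S), np.log(A)
    if np.ptp(logA) == 0:
        raise ValidationError("slope undefined: Area constant across islands")
    z, logc = np.polyfit(logA, logS, 1)
    return PowerLawFit(c=float(np.exp(logc)), z=float(z), r_loglog=pearson_r(logS, logA))


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1); undefined for n <= k+1."""
    if n <= k + 1:
        raise ValidationError(f"AICc correction undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, predictors: Sequence[str]):
    """Raw and standardised design matrices plus the std->raw coefficient map."""
    n = len(df)
    p = len(predictors)
    X = np.column_stack([np.ones(n)] + [np.asarray(df[v], dtype=float) for v in predictors])
    means = X[:, 1:].mean(axis=0) if p else np.empty(0)
    sds = X[:, 1:].std(axis=0) if p else np.empty(0)
    if p and np.any(sds == 0):
        bad = [predictors[j] for j in range(p) if sds[j] == 0]
        raise ValidationError(f"constant predictor(s): {bad}")
    Xs = X.copy()
    if p:
        Xs[:, 1:] = (X[:, 1:] - means) / sds
    # raw_beta = A @ std_beta
    A = np.eye(p + 1)
    for j in range(p):
        A[0, j + 1] = -means[j] / sds[j]
        A[j + 1, j + 1] = 1.0 / sds[j]
    return X, Xs, A


def _wald_p(beta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    se = np.sqrt(np.diag(cov))
    z = np.where(se > 0, beta / se, np.inf)
    return 2.0 * scipy.stats.norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# negative binomial (NB2) regression with profiled ML dispersion
# ---------------------------------------------------------------------------

def nb2_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Exact NB2 log-likelihood."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(
        np.sum(
            scipy.special.gammaln(y + theta)
            - scipy.special.gammaln(theta)
            - scipy.special.gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def nb2_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 deviance 2*sum[y log(y/mu) - (y+theta) log((y+theta)/(mu+theta))]."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


@dataclass(frozen=True)
class NBFit:
    """A fitted NB2 count regression (log link, ML dispersion)."""

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]      # raw scale, incl. "Intercept"
    se: dict[str, float]
    wald_p: dict[str, float]
    theta: float
    loglik: float
    null_deviance: float
    residual_deviance: float
    explained_deviance: float           # 1 - residual/null
    aic: float                          # -2 loglik + 2k, k counts theta
    aicc: float
    n: int
    k: int                              # predictors + intercept + theta

    @property
    def params(self) -> np.ndarray:
        return np.array([self.coefficients["Intercept"]] +
                        [self.coefficients[p] for p in self.predictors])

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(df), self.coefficients["Intercept"])
        for p in self.predictors:
            eta = eta + self.coefficients[p] * np.asarray(df[p], dtype=float)
        return eta

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.exp(self.linear_predictor(df))


_LOG_THETA_BOUNDS = (-6.0, 18.0)


def fit_negative_binomial(
    table: IslandTable | pd.DataFrame,
    predictors: Sequence[str],
    response: str = "Spp",
    theta: float | None = None,
) -> NBFit:
    """NB2 GLM of a count response on untransformed predictors.

    ``theta=None`` (default) estimates the dispersion by profile maximum
    likelihood; a fixed positive value skips profiling (useful for deviance
    decompositions at a common dispersion).
    """
    df = table.to_dataframe() if isinstance(table, IslandTable) else table
    predictors = tuple(predictors)
    y = np.asarray(df[response], dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValidationError("count response must be non-negative integers")
    n = len(y)
    k = len(predictors) + 2
    if n <= len(predictors) + 1:
        raise ValidationError(f"n={n} too small for {len(predictors)} predictors")
    X, Xs, A = _design(df, predictors)

    state: dict = {"start": None}

    def _glm_at(th: float):
        fam = sm.families.NegativeBinomial(alpha=1.0 / th)
        model = sm.GLM(y, Xs, family=fam)
        res = model.fit(start_params=state["start"], maxiter=200, tol=1e-10)
        state["start"] = res.params
        return res

    def _profile_negll(log_th: float) -> float:
        th = float(np.exp(log_th))
        res = _glm_at(th)
        return -nb2_loglik(y, res.mu, th)

    if theta is None:
        opt = scipy.optimize.minimize_scalar(
            _profile_negll, bounds=_LOG_THETA_BOUNDS, method="bounded",
            options={"xatol": 1e-10},
        )
        if not opt.success:
            raise ConvergenceError(f"dispersion profile failed: {opt.message}")
        theta_hat = float(np.exp(opt.x))
    else:
        if theta <= 0:
            raise ValidationError("theta must be positive")
        theta_hat = float(theta)

    res = _glm_at(theta_hat)
    if not res.converged:
        raise ConvergenceError("IRLS did not converge at the fitted dispersion")
    mu = np.asarray(res.mu)
    ll = nb2_loglik(y, mu, theta_hat)
    beta_raw = A @ np.asarray(res.params)
    cov_raw = A @ np.asarray(res.cov_params()) @ A.T
    pvals = _wald_p(beta_raw, cov_raw)
    names = ("Intercept",) + predictors
    resid_dev = nb2_deviance(y, mu, theta_hat)
    null_dev = nb2_deviance(y, np.full(n, y.mean()), theta_hat)
    explained = 1.0 - resid_dev / null_dev if null_dev > 0 else 0.0
    return NBFit(
        response=response,
        predictors=predictors,
        coefficients=dict(zip(names, beta_raw)),
        se=dict(zip(names, np.sqrt(np.diag(cov_raw)))),
        wald_p=dict(zip(names, pvals)),
        theta=theta_hat,
        loglik=ll,
        null_deviance=null_dev,
        residual_deviance=resid_dev,
        explained_deviance=explained,
        aic=-2.0 * ll + 2.0 * k,
        aicc=aicc(ll, k, n) if n > k + 1 else np.inf,
        n=n,
        k=k,
    )


# ---------------------------------------------------------------------------
# beta regression
# ---------------------------------------------------------------------------

def smithson_verkuilen(y: np.ndarray) -> np.ndarray:
    """Boundary shrinkage (y*(n-1) + 0.5)/n pulling 0/1 off the boundary."""
    y = np.asarray(y, dtype=float)
    return (y * (len(y) - 1) + 0.5) / len(y)


@dataclass(frozen=True)
class BetaFit:
    """A fitted beta regression (logit mean link, constant precision)."""

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]      # raw logit scale, incl. "Intercept"
    se: dict[str, float]
    wald_p: dict[str, float]
    phi: float
    loglik: float
    pseudo_r2: float                    # corr(eta_hat, logit y)^2
    aic: float
    aicc: float
    n: int
    k: int

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(df), self.coefficients["Intercept"])
        for p in self.predictors:
            eta = eta + self.coefficients[p] * np.asarray(df[p], dtype=float)
        return eta

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return scipy.special.expit(self.linear_predictor(df))


def fit_beta_regression(
    table: IslandTable | pd.DataFrame,
    predictors: Sequence[str],
    response: str = "Prop",
    boundary: Literal["error", "shrink"] = "error",
) -> BetaFit:
    """Beta regression of a (0,1) response on untransformed predictors.

    Proportions exactly 0 or 1 raise :class:`BoundaryValueError` unless
    ``boundary="shrink"`` applies the Smithson–Verkuilen transform to the
    whole response vector (explicit, never silent).
    """
    df = table.to_dataframe() if isinstance(table, IslandTable) else table
    predictors = tuple(predictors)
    y = np.asarray(df[response], dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValidationError("proportion response must lie in [0, 1]")
    if np.any((y == 0) | (y == 1)):
        if boundary == "error":
            raise BoundaryValueError(
                "response contains 0/1 values; pass boundary='shrink' to apply the "
                "Smithson-Verkuilen transform"
            )
        y = smithson_verkuilen(y)
    n = len(y)
    k = len(predictors) + 2
    if n <= len(predictors) + 1:
        raise ValidationError(f"n={n} too small for {len(predictors)} predictors")
    X, Xs, A = _design(df, predictors)

    model = BetaModel(y, Xs)
    with np.errstate(all="ignore"):
        res = model.fit(disp=0, maxiter=2000)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=0, method="nm", maxiter=8000)
            res = model.fit(disp=0, start_params=res.params, maxiter=2000)
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"beta regression failed to converge: {res.mle_retvals}")

    params = np.asarray(res.params)
    mean_std, log_phi = params[:-1], params[-1]
    beta_raw = A @ mean_std
    cov_std = np.asarray(res.cov_params())[: len(mean_std), : len(mean_std)]
    cov_raw = A @ cov_std @ A.T
    pvals = _wald_p(beta_raw, cov_raw)
    names = ("Intercept",) + predictors
    eta = Xs[:, : len(mean_std)] @ mean_std
    logit_y = scipy.special.logit(y)
    pseudo_r2 = float(np.corrcoef(eta, logit_y)[0, 1] ** 2) if np.ptp(eta) > 0 else 0.0
    ll = float(res.llf)
    return BetaFit(
        response=response,
        predictors=predictors,
        coefficients=dict(zip(names, beta_raw)),
        se=dict(zip(names, np.sqrt(np.diag(cov_raw)))),
        wald_p=dict(zip(names, pvals)),
        phi=float(np.exp(log_phi)),
        loglik=ll,
        pseudo_r2=pseudo_r2,
        aic=-2.0 * ll + 2.0 * k,
        aicc=aicc(ll, k, n) if n > k + 1 else np.inf,
        n=n,
        k=k,
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    label: str
    predictors: tuple[str, ...]
    response: Response = "count"


@dataclass
class ModelTable:
    """Fits ranked by AICc, ties broken by fewer parameters then label."""

    fits: list[tuple[ModelSpec, NBFit | BetaFit]]
    failures: list[tuple[ModelSpec, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fits.sort(key=lambda sf: (sf[1].aicc, sf[1].k, sf[0].label))
        labels = [s.label for s, _ in self.fits] + [s.label for s, _ in self.failures]
        if len(set(labels)) != len(labels):
            raise ValidationError("model labels must be unique within a table")

    @property
    def best(self) -> tuple[ModelSpec, NBFit | BetaFit]:
        if not self.fits:
            raise ValidationError("no successful fits to rank")
        return self.fits[0]

    def __getitem__(self, label: str) -> NBFit | BetaFit:
        for spec, fit in self.fits:
            if spec.label == label:
                return fit
        raise KeyError(label)


def _fit_for(
    df: pd.DataFrame, spec: ModelSpec, **fit_kwargs
) -> NBFit | BetaFit:
    if spec.response == "count":
        return fit_negative_binomial(df, spec.predictors, **fit_kwargs)
    return fit_beta_regression(df, spec.predictors, **fit_kwargs)


def best_subsets(
    table: IslandTable | pd.DataFrame,
    response: Response = "count",
    candidates: Sequence[str] = PREDICTORS,
    specs: Sequence[ModelSpec] | None = None,
    **fit_kwargs,
) -> ModelTable:
    """Fit every non-empty predictor subset (or an explicit labelled list).

    Individual fit failures are recorded on ``ModelTable.failures``; the
    remaining models are still ranked.
    """
    df = table.to_dataframe() if isinstance(table, IslandTable) else table
    if specs is None:
        if not candidates:
            raise ValidationError("candidate predictor set must be non-empty")
        specs = []
        i = 0
        for size in range(1, len(candidates) + 1):
            for combo in itertools.combinations(candidates, size):
                i += 1
                specs.append(ModelSpec(label=f"M{i:02d}", predictors=combo, response=response))
    fits: list[tuple[ModelSpec, NBFit | BetaFit]] = []
    failures: list[tuple[ModelSpec, str]] = []
    for spec in specs:
        try:
            fits.append((spec, _fit_for(df, spec, **fit_kwargs)))
        except Exception as e:  # noqa: BLE001 - per-subset isolation is the contract
            failures.append((spec, f"{type(e).__name__}: {e}"))
    return ModelTable(fits=fits, failures=failures)


# ---------------------------------------------------------------------------
# reporting and prediction surfaces
# ---------------------------------------------------------------------------

def model_report(mt: ModelTable, alpha: float = 0.05) -> pd.DataFrame:
    """One row per model: label, per-predictor p-values, fit summaries.

    Full numeric precision; use :func:`format_report` for the printed-table
    styling (2-dp deviances, 1-dp percents, significance marking).
    """
    if not mt.fits:
        raise ValidationError("empty model table")
    rows = []
    for spec, fit in mt.fits:
        row: dict = {"Model": spec.label, "Predictors": ", ".join(spec.predictors)}
        for p in spec.predictors:
            row[f"p({p})"] = fit.wald_p[p]
        if isinstance(fit, NBFit):
            row.update(
                NullDeviance=fit.null_deviance,
                ResidualDeviance=fit.residual_deviance,
                ExplainedPct=100.0 * fit.explained_deviance,
                Theta=fit.theta,
            )
        else:
            row.update(PseudoR2=fit.pseudo_r2, Phi=fit.phi)
        row.update(LogLik=fit.loglik, AIC=fit.aic, AICc=fit.aicc, k=fit.k, n=fit.n)
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(mt: ModelTable, alpha: float = 0.05) -> str:
    """Printed-table rendering: significant predictors marked with ``**``."""
    lines = []
    for spec, fit in mt.fits:
        pv = []
        for p in spec.predictors:
            val = fit.wald_p[p]
            if val < 1e-4:
                shown = "<0.0001"
            elif val < 1e-3:
                shown = "<0.001"
            else:
                shown = format(val, ".3f")
            txt = f"{p}, {shown}"
            pv.append(f"**{txt}**" if val < alpha else txt)
        if isinstance(fit, NBFit):
            body = (
                f"null dev {fit.null_deviance:.2f}  resid dev {fit.residual_deviance:.2f} "
                f"({100 * fit.explained_deviance:.1f}%)  AIC {fit.aic:.2f}  AICc {fit.aicc:.2f}"
            )
        else:
            body = f"pseudo-R2 {fit.pseudo_r2:.3f}  AICc {fit.aicc:.2f}"
        lines.append(f"{spec.label}\t{'  '.join(pv)}\t{body}")
    for spec, msg in mt.failures:
        lines.append(f"{spec.label}\tFAILED: {msg}")
    return "\n".join(lines)


def predict_surface(
    fit: NBFit,
    x_name: str,
    y_name: str,
    x_values: Sequence[float],
    y_values: Sequence[float],
    fixed: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Predicted counts exp(eta) over a rectangular grid of two predictors.

    Remaining predictors of the fit must be pinned via ``fixed``.  Returns a
    DataFrame indexed by ``y_values`` with ``x_values`` as columns.
    """
    fixed = dict(fixed or {})
    if len(fit.predictors) < 2:
        raise ValidationError("surface needs a fit with at least two predictors")
    for name in (x_name, y_name):
        if name not in fit.predictors:
            raise ValidationError(f"predictor {name!r} not in fit {fit.predictors}")
    others = [p for p in fit.predictors if p not in (x_name, y_name)]
    missing = [p for p in others if p not in fixed]
    if missing:
        raise ValidationError(f"fix remaining predictors {missing} to evaluate the surface")
    x = np.asarray(x_values, dtype=float)
    yv = np.asarray(y_values, dtype=float)
    eta = fit.coefficients["Intercept"] + sum(fit.coefficients[p] * fixed[p] for p in others)
    grid = (
        eta
        + fit.coefficients[x_name] * x[np.newaxis, :]
        + fit.coefficients[y_name] * yv[:, np.newaxis]
    )
    return pd.DataFrame(np.exp(grid), index=yv, columns=x)
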