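"""Asymptotic edge-effect regression with spatial autocorrelation.

The response is per-pixel canopy-height change dTCH; candidate mean
functions range from a plain linear model in TPI and initial canopy height
to the asymptotic form

    dTCH = b0 + b1*TPI + b2*TCH_2014 - b*exp(-c*D_Edge)       (c > 0)

optionally with TCH x TPI and TCH x D_Edge interactions.  Fitting is by
nonlinear least squares (multi-start in the decay rate c) or by maximum
likelihood with an exponential residual correlogram corr(i,j) =
exp(-d_ij / rho) on the pixel coordinates (dense-covariance GLS, profiled
residual variance, 1-D search over rho).  Model choice is by AIC.
Uncertainty at landscape scale comes from an ensemble of random pixel
subsets; intervals from a subset of n pixels are rescaled to the full N
pixels by the factor sqrt(n/N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ModelSpec",
    "ModelFit",
    "EnsembleResult",
    "build_candidates",
    "aic",
    "fit_nls",
    "fit_gls_spatial",
    "select_by_aic",
    "subset_ensemble",
    "corrected_intervals",
    "predict_delta_tch",
    "edge_penetration_distance",
    "prediction_curves",
]

#: Multi-start grid for the exponential decay rate (1/m).
C_STARTS = (0.001, 0.005, 0.02)

#: Default subset sizes and repetitions of the stability ensemble.
DEFAULT_SIZES = (3000, 4000, 5000)
DEFAULT_REPS = 24

#: Fig-5-style prediction settings: short/medium/tall canopies on
#: valleys (5th TPI quantile) and hilltops (95th quantile).
DEFAULT_TCH_SET = (5.0, 20.0, 35.0)
DEFAULT_TPI_SET = (-8.2, 9.0)


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A candidate mean function for dTCH.

    ``kind`` is "linear" (optionally with a linear D_Edge term) or
    "asymptotic" (exponential saturation in D_Edge, optionally with the two
    TCH interactions).  Parameter order is fixed by ``param_names``.
    """

    name: str
    kind: str
    with_dedge: bool = False
    with_interactions: bool = False

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.kind == "linear":
            base = ("beta0", "beta_tpi", "beta_tch")
            return base + (("beta_d",) if self.with_dedge else ())
        base = ("beta0", "beta_tpi", "beta_tch", "edge_amp", "edge_rate")
        return base + (("beta_tch_tpi", "beta_tch_d") if self.with_interactions else ())

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def is_nonlinear(self) -> bool:
        return self.kind == "asymptotic"

    def predict(self, theta: np.ndarray, tpi, tch, d_edge) -> np.ndarray:
        tpi = np.asarray(tpi, float)
        tch = np.asarray(tch, float)
        d = np.asarray(d_edge, float)
        if self.kind == "linear":
            out = theta[0] + theta[1] * tpi + theta[2] * tch
            if self.with_dedge:
                out = out + theta[3] * d
            return out
        out = theta[0] + theta[1] * tpi + theta[2] * tch - theta[3] * np.exp(-theta[4] * d)
        if self.with_interactions:
            out = out + theta[5] * tch * tpi + theta[6] * tch * d
        return out

    def jacobian(self, theta: np.ndarray, tpi, tch, d_edge) -> np.ndarray:
        """d predict / d theta, shape (n, k)."""
        tpi = np.asarray(tpi, float)
        tch = np.asarray(tch, float)
        d = np.asarray(d_edge, float)
        one = np.ones_like(tpi)
        if self.kind == "linear":
            cols = [one, tpi, tch] + ([d] if self.with_dedge else [])
            return np.column_stack(cols)
        e = np.exp(-theta[4] * d)
        cols = [one, tpi, tch, -e, theta[3] * d * e]
        if self.with_interactions:
            cols += [tch * tpi, tch * d]
        return np.column_stack(cols)


def build_candidates() -> list[ModelSpec]:
    """The candidate set compared by AIC, from plain linear to the full asymptotic form."""
    return [
        ModelSpec("linear", "linear"),
        ModelSpec("linear_dedge", "linear", with_dedge=True),
        ModelSpec("asymptotic", "asymptotic"),
        ModelSpec("asymptotic_interactions", "asymptotic", with_interactions=True),
    ]


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

def aic(k: int, loglik: float) -> float:
    """Akaike information criterion, 2k - 2 lnL."""
    return 2.0 * k - 2.0 * loglik


@dataclass
class ModelFit:
    spec: ModelSpec
    params: dict[str, float]
    cov: np.ndarray                 # parameter covariance (order = spec.param_names)
    sigma: float                    # residual sd
    loglik: float
    aic: float
    n: int
    rho_m: float | None = None      # correlogram range when spatial
    row_key: int = 0                # identity of the fitted row set

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params[p] for p in self.spec.param_names])

    @property
    def se(self) -> dict[str, float]:
        s = np.sqrt(np.clip(np.diag(self.cov), 0.0, None))
        return dict(zip(self.spec.param_names, s))


@dataclass
class EnsembleResult:
    subset_size: int
    reps: int
    param_names: tuple[str, ...]
    estimates: np.ndarray           # (reps, k) fitted parameter vectors
    seed: int

    @property
    def mean(self) -> np.ndarray:
        return self.estimates.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.estimates.std(axis=0, ddof=1)

    @property
    def cv_pct(self) -> np.ndarray:
        """Coefficient of variation per parameter, 100 * sd / |mean|."""
        return 100.0 * self.sd / np.abs(self.mean)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.estimates, axis=0)

    @property
    def ensemble_se(self) -> np.ndarray:
        """Standard error of the ensemble mean/median, sd / sqrt(reps)."""
        return self.sd / np.sqrt(self.reps)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": self.mean,
                "median": self.median,
                "sd": self.sd,
                "cv_pct": self.cv_pct,
            }
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _gaussian_loglik(n: int, rss: float, logdet: float = 0.0) -> tuple[float, float]:
    sigma2 = max(rss / n, 1e-300)  # keep the noiseless limit finite
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return ll, float(np.sqrt(sigma2))

def _table_arrays(table: pd.DataFrame):
    return (
        table["delta_tch"].to_numpy(float),
        table["tpi"].to_numpy(float),
        table["tch_2014"].to_numpy(float),
        table["d_edge"].to_numpy(float),
    )


def _row_key(table: pd.DataFrame) -> int:
    """Content hash of the fitted rows (coordinates + response)."""
    cols = table[["x", "y", "delta_tch"]].to_numpy(float)
    return hash((len(table), float(cols.sum()), float(np.abs(cols).sum())))


def _linear_start(y, tpi, tch) -> np.ndarray:
    X = np.column_stack([np.ones_like(tpi), tpi, tch])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _nls_theta(spec: ModelSpec, y, tpi, tch, d, theta0: np.ndarray | None = None):
    """Minimize the (optionally whitened) residual sum of squares; return (theta, J, rss)."""

    if not spec.is_nonlinear:
        J = spec.jacobian(np.zeros(spec.n_params), tpi, tch, d)
        theta, *_ = np.linalg.lstsq(J, y, rcond=None)
        rss = float(np.sum((y - J @ theta) ** 2))
        return theta, J, rss

    def residual(theta):
        return spec.predict(theta, tpi, tch, d) - y

    def jac(theta):
        return spec.jacobian(theta, tpi, tch, d)

    lo = np.full(spec.n_params, -np.inf)
    hi = np.full(spec.n_params, np.inf)
    lo[4], hi[4] = 1e-8, 1.0  # decay rate constrained positive

    starts = []
    if theta0 is not None:
        starts.append(np.clip(theta0, lo + 1e-12, hi - 1e-12))
    beta = _linear_start(y, tpi, tch)
    b0 = max(float(np.ptp(y)), 1e-3)
    for c0 in C_STARTS:
        t0 = np.zeros(spec.n_params)
        t0[:3] = beta
        t0[3], t0[4] = b0, c0
        starts.append(t0)

    best = None
    for t0 in starts:
        sol = optimize.least_squares(
            residual, t0, jac=jac, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e12:
        raise RuntimeError(f"nonlinear least squares failed for {spec.name}")
    theta = best.x
    return theta, jac(theta), float(2.0 * best.cost)


def fit_nls(spec: ModelSpec, table: pd.DataFrame) -> ModelFit:
    """Ordinary (unweighted) least squares fit of a candidate mean function.

    Nonlinear specs are solved by trust-region least squares from a
    multi-start grid over the decay rate; linear specs reduce to one lstsq.
    AIC uses the Gaussian log-likelihood with k = mean parameters + 1 for
    the residual sd.
    """
    y, tpi, tch, d = _table_arrays(table)
    n = len(y)
    if n < 10 * spec.n_params:
        raise ValueError(f"need >= {10 * spec.n_params} rows to fit {spec.name}, got {n}")
    theta, J, rss = _nls_theta(spec, y, tpi, tch, d)
    ll, sigma = _gaussian_loglik(n, rss)
    JtJ = J.T @ J
    cov = sigma**2 * np.linalg.pinv(JtJ) * n / max(n - spec.n_params, 1)
    return ModelFit(
        spec=spec,
        params=dict(zip(spec.param_names, theta)),
        cov=cov,
        sigma=sigma,
        loglik=ll,
        aic=aic(spec.n_params + 1, ll),
        n=n,
        row_key=_row_key(table),
    )


def fit_gls_spatial(
    spec: ModelSpec,
    table: pd.DataFrame,
    rho_bounds_m: tuple[float, float] = (1.0, 1000.0),
    rho: float | None = None,
    nugget: float = 0.0,
    max_n: int = 6000,
) -> ModelFit:
    """Maximum-likelihood fit with an exponential residual correlogram.

    corr(i, j) = exp(-d_ij / rho) on the pixel (x, y) coordinates, with an
    optional nugget: corr = nugget*I + (1-nugget)*exp(-d/rho).  The residual
    variance is profiled out; the mean parameters are re-optimized on
    whitened residuals for each trial rho, and rho itself is found by
    bounded 1-D search on the profile likelihood (skipped when ``rho`` is
    given).  Dense covariance: n is capped at ``max_n`` rows.
    """
    y, tpi, tch, d = _table_arrays(table)
    n = len(y)
    if n > max_n:
        raise ValueError(f"spatial GLS is limited to {max_n} rows (dense covariance); got {n}")
    xy = table[["x", "y"]].to_numpy(float)
    D = squareform(pdist(xy))
    theta_ols, _, _ = _nls_theta(spec, y, tpi, tch, d)

    def profile(rho_m: float):
        C = np.exp(-D / rho_m)
        if nugget > 0:
            C = (1.0 - nugget) * C + nugget * np.eye(n)
        jitter = 0.0
        for jitter in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                L = np.linalg.cholesky(C + jitter * np.eye(n))
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise RuntimeError(f"correlation matrix not positive definite at rho={rho_m}")
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        yw = linalg.solve_triangular(L, y, lower=True)

        if spec.is_nonlinear:
            def residual(theta):
                return linalg.solve_triangular(
                    L, spec.predict(theta, tpi, tch, d), lower=True
                ) - yw

            def jac(theta):
                return linalg.solve_triangular(L, spec.jacobian(theta, tpi, tch, d), lower=True)

            lo = np.full(spec.n_params, -np.inf)
            hi = np.full(spec.n_params, np.inf)
            lo[4], hi[4] = 1e-8, 1.0
            sol = optimize.least_squares(
                residual, np.clip(theta_ols, lo + 1e-12, hi - 1e-12),
                jac=jac, bounds=(lo, hi), method="trf",
                xtol=1e-11, ftol=1e-11, max_nfev=200,
            )
            theta, Jw, rss = sol.x, jac(sol.x), float(2.0 * sol.cost)
        else:
            Jw = linalg.solve_triangular(L, spec.jacobian(np.zeros(spec.n_params), tpi, tch, d), lower=True)
            theta, *_ = np.linalg.lstsq(Jw, yw, rcond=None)
            rss = float(np.sum((yw - Jw @ theta) ** 2))
        ll, sigma = _gaussian_loglik(n, rss, logdet)
        return ll, theta, Jw, sigma

    if rho is None:
        res = optimize.minimize_scalar(
            lambda lr: -profile(np.exp(lr))[0],
            bounds=(np.log(rho_bounds_m[0]), np.log(rho_bounds_m[1])),
            method="bounded",
            options={"xatol": 0.02},
        )
        rho = float(np.exp(res.x))
    ll, theta, Jw, sigma = profile(rho)
    cov = sigma**2 * np.linalg.pinv(Jw.T @ Jw)
    k = spec.n_params + 2  # + residual sd + correlogram range
    return ModelFit(
        spec=spec,
        params=dict(zip(spec.param_names, theta)),
        cov=cov,
        sigma=sigma,
        loglik=ll,
        aic=aic(k, ll),
        n=n,
        rho_m=rho,
        row_key=_row_key(table),
    )


def select_by_aic(fits: list[ModelFit]) -> tuple[ModelFit, pd.DataFrame]:
    """Lowest-AIC fit plus a dAIC table; all fits must share the same rows."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    if len({f.row_key for f in fits}) != 1 or len({f.n for f in fits}) != 1:
        raise ValueError("fits were made on differing row sets; AIC is not comparable")
    order = sorted(fits, key=lambda f: f.aic)
    best = order[0]
    tab = pd.DataFrame(
        {
            "model": [f.spec.name for f in order],
            "k": [f.spec.n_params for f in order],
            "aic": [f.aic for f in order],
            "delta_aic": [f.aic - best.aic for f in order],
        }
    )
    return best, tab


# ---------------------------------------------------------------------------
# Subset ensemble and corrected intervals
# ---------------------------------------------------------------------------

def subset_ensemble(
    table: pd.DataFrame,
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    spec: ModelSpec | None = None,
    method: str = "nls",
) -> list[EnsembleResult]:
    """Fit the model on ``reps`` random pixel subsets of each size.

    Subsets are drawn without replacement, independently across repetitions;
    everything is reproducible from ``seed``.  ``method`` is "nls" or
    "gls" (spatial; subject to the dense-covariance size cap).
    """
    if spec is None:
        spec = ModelSpec("asymptotic", "asymptotic")
    n = len(table)
    if max(sizes) >= n:
        raise ValueError(f"subset sizes {sizes} must be smaller than the table ({n} rows)")
    rng = np.random.default_rng(seed)
    results = []
    for size in sizes:
        est = np.empty((reps, spec.n_params))
        for r in range(reps):
            idx = rng.choice(n, size=size, replace=False)
            sub = table.iloc[idx]
            fit = fit_nls(spec, sub) if method == "nls" else fit_gls_spatial(spec, sub)
            est[r] = fit.theta
        results.append(EnsembleResult(size, reps, spec.param_names, est, seed))
    return results


def corrected_intervals(fit: ModelFit, n: int, N: int, level: float = 0.95) -> pd.DataFrame:
    """Scale subset-fit confidence intervals to the full pixel set.

    Interval half-widths from a fit on n of N pixels are multiplied by
    sqrt(n/N) about the point estimates.
    """
    if not 0 < n <= N:
        raise ValueError("require 0 < n <= N")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    scale = np.sqrt(n / N)
    se = np.array([fit.se[p] for p in fit.spec.param_names])
    est = fit.theta
    return pd.DataFrame(
        {
            "parameter": fit.spec.param_names,
            "estimate": est,
            "lo": est - z * se * scale,
            "hi": est + z * se * scale,
            "scale_factor": scale,
        }
    )


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

_ASYMPTOTIC = ModelSpec("asymptotic", "asymptotic")


def _coerce_params(params) -> np.ndarray:
    if isinstance(params, dict):
        return np.array([params[p] for p in _ASYMPTOTIC.param_names])
    return np.asarray(params, float)


def predict_delta_tch(params, tpi, tch_2014, d_edge, cov: np.ndarray | None = None):
    """dTCH prediction from asymptotic-model parameters; delta-method CI when cov given.

    ``params`` is a dict or vector in the order (beta0, beta_tpi, beta_tch,
    edge_amp, edge_rate).  Returns the prediction, or (prediction, lo, hi)
    at 95% when a parameter covariance is supplied.
    """
    theta = _coerce_params(params)
    d = np.asarray(d_edge, float)
    if np.any(d < 0):
        raise ValueError("d_edge must be >= 0")
    pred = _ASYMPTOTIC.predict(theta, tpi, tch_2014, d)
    if cov is None:
        return pred
    G = _ASYMPTOTIC.jacobian(theta, np.broadcast_to(tpi, d.shape), np.broadcast_to(tch_2014, d.shape), d)
    var = np.einsum("ij,jk,ik->i", G, cov, G)
    half = 1.959963984540054 * np.sqrt(np.clip(var, 0.0, None))
    return pred, pred - half, pred + half


def edge_penetration_distance(params, tpi, tch_2014) -> float | None:
    """Distance from the edge at which predicted dTCH crosses zero.

    With interior level A = beta0 + beta_tpi*TPI + beta_tch*TCH the crossing
    is D0 = ln(edge_amp / A) / edge_rate, defined when 0 < A < edge_amp
    (growth positive in the interior, negative at the edge); otherwise the
    prediction never changes sign and None is returned.
    """
    theta = _coerce_params(params)
    if theta[4] <= 0:
        raise ValueError("edge_rate must be > 0")
    A = theta[0] + theta[1] * tpi + theta[2] * tch_2014
    b = theta[3]
    if not (0.0 < A < b):
        return None
    return float(np.log(b / A) / theta[4])


def prediction_curves(
    ensemble: EnsembleResult,
    n_total: int,
    tch_set: tuple[float, ...] = DEFAULT_TCH_SET,
    tpi_set: tuple[float, ...] = DEFAULT_TPI_SET,
    d_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Prediction curves over distance for canopy-height / TPI combinations.

    The central curve uses the ensemble median parameter vector; the 95%
    band comes from the pointwise 2.5/97.5 percentiles of the per-member
    predictions, with half-widths rescaled by sqrt(n/N) to correct the
    subset fit to the full ``n_total`` pixels.
    """
    if d_grid is None:
        d_grid = np.arange(0.0, 1501.0, 10.0)
    d_grid = np.asarray(d_grid, float)
    if d_grid.size == 0:
        raise ValueError("d_grid must be non-empty")
    scale = np.sqrt(ensemble.subset_size / n_total)
    med = ensemble.median
    rows = []
    for tch in tch_set:
        for tpi in tpi_set:
            centre = _ASYMPTOTIC.predict(med, np.full_like(d_grid, tpi), np.full_like(d_grid, tch), d_grid)
            member = np.stack(
                [
                    _ASYMPTOTIC.predict(est, np.full_like(d_grid, tpi), np.full_like(d_grid, tch), d_grid)
                    for est in ensemble.estimates
                ]
            )
            lo = np.percentile(member, 2.5, axis=0)
            hi = np.percentile(member, 97.5, axis=0)
            rows.append(
                pd.DataFrame(
                    {
                        "tch_2014": tch,
                        "tpi": tpi,
                        "d_edge": d_grid,
                        "delta_tch": centre,
                        "lo": centre - scale * (centre - lo),
                        "hi": centre + scale * (hi - centre),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
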