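"""Count-based validation of habitat-quality rasters.

Habitat-quality scores are validated against roadside point-count data: the
mean quality within a detection buffer (400 m by default) around each survey
stop becomes a covariate in a negative binomial regression of pooled bird
counts, chosen because roadside counts are over-dispersed.  Competing models
(intercept-only, baseline-suitability covariate, degraded-quality covariate)
are compared by small-sample-corrected AIC, with a difference above 2 taken
as decisive, plus likelihood-ratio pseudo-R².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .grid import QualityRaster

__all__ = [
    "SurveyStop",
    "RegressionResult",
    "mean_quality_at_stops",
    "fit_negbin",
    "aicc",
    "select_model",
    "pseudo_r2",
]

logger = logging.getLogger(__name__)


@dataclass
class SurveyStop:
    """One point-count stop: location (m), pooled count, detection radius (m)."""

    id: str
    x: float
    y: float
    count: int = 0
    buffer_radius: float = 400.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be nonnegative")
        if self.buffer_radius <= 0:
            raise ValueError("buffer_radius must be positive")


@dataclass
class RegressionResult:
    """A fitted count model and its model-selection statistics.

    ``beta1`` is the slope on the habitat covariate (None for the
    intercept-only model); the confidence interval is a Wald interval at
    ``ci_level``.  ``K`` counts every estimated parameter including the
    dispersion parameter.
    """

    model_name: str
    n: int
    K: int
    log_likelihood: float
    aicc: float
    beta0: float
    beta1: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float = 0.95
    alpha: float | None = None  # NB2 dispersion; variance = mu + alpha*mu^2
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def theta(self) -> float | None:
        """Dispersion theta = 1/alpha (variance = mu + mu^2/theta)."""
        if self.alpha is None or self.alpha <= 0:
            return None
        return 1.0 / self.alpha


def mean_quality_at_stops(
    qual: QualityRaster, stops: list[SurveyStop]
) -> pd.DataFrame:
    """Mean quality over pixels whose centres fall inside each stop's buffer.

    NaN (nodata) pixels are excluded from the mean.  A buffer containing no
    valid pixel centre yields NaN and is flagged in the ``missing`` column;
    stops whose buffer only partially overlaps the grid are kept with a
    warning.
    """
    spec = qual.spec
    X, Y = spec.cell_centers()
    rows = []
    for stop in stops:
        if not spec.contains(stop.x, stop.y):
            logger.warning("stop %s lies outside the grid extent", stop.id)
        d2 = (X - stop.x) ** 2 + (Y - stop.y) ** 2
        inside = d2 <= stop.buffer_radius**2
        vals = qual.values[inside]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("stop %s buffer contains no valid pixels", stop.id)
            rows.append({"id": stop.id, "mean_quality": np.nan, "missing": True})
        else:
            rows.append(
                {"id": stop.id, "mean_quality": float(vals.mean()), "missing": False}
            )
    return pd.DataFrame(rows, columns=["id", "mean_quality", "missing"])


def aicc(log_likelihood: float, K: int, n: int) -> float:
    """Small-sample-corrected AIC: -2*logLik + 2K + 2K(K+1)/(n-K-1)."""
    if n <= K + 1:
        raise ValueError("AICc undefined for n <= K + 1")
    return -2.0 * log_likelihood + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def fit_negbin(
    counts: np.ndarray,
    covariate: np.ndarray | None = None,
    model_name: str | None = None,
    ci_level: float = 0.95,
) -> RegressionResult:
    """Fit a negative binomial (NB2) regression with log link by ML.

    ``covariate=None`` fits the intercept-only model.  The mean is
    mu_i = exp(beta0 + beta1 * x_i) and the variance mu + alpha*mu^2, with
    the dispersion ``alpha`` estimated jointly by maximum likelihood.
    Non-convergence is reported through the ``converged`` flag and
    diagnostics, never silently.
    """
    y = np.asarray(counts, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if covariate is None:
        exog = np.ones((n, 1))
        name = model_name or "Null"
    else:
        x = np.asarray(covariate, dtype=float)
        if x.shape != y.shape:
            raise ValueError("counts and covariate must have the same length")
        if not np.all(np.isfinite(x)):
            raise ValueError("covariate contains non-finite values")
        if np.ptp(x) < 1e-12:
            raise ValueError(
                "covariate is constant; the slope is unidentifiable — "
                "fit the intercept-only model instead"
            )
        exog = sm.add_constant(x)
        name = model_name or "Quality"

    model = NegativeBinomial(y, exog, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False, maxiter=200)
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        logger.warning("NB fit for %s did not converge", name)

    K = len(res.params)  # intercept (+ slope) + dispersion alpha
    ll = float(res.llf)
    beta0 = float(res.params[0])
    alpha = float(res.params[-1])
    beta1 = ci_low = ci_high = None
    if covariate is not None:
        beta1 = float(res.params[1])
        ci = res.conf_int(alpha=1.0 - ci_level)
        ci_low, ci_high = float(ci[1][0]), float(ci[1][1])
    return RegressionResult(
        model_name=name,
        n=n,
        K=K,
        log_likelihood=ll,
        aicc=aicc(ll, K, n),
        beta0=beta0,
        beta1=beta1,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
        alpha=alpha,
        converged=converged,
        diagnostics={"mle_retvals": dict(res.mle_retvals)},
    )


def select_model(results: list[RegressionResult]) -> pd.DataFrame:
    """Rank fitted models by AICc; report ΔAICc and Akaike weights.

    A win is conventionally decisive when the runner-up's ΔAICc exceeds 2.
    All models must be fitted to the same observations (same n).
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    ns = {r.n for r in results}
    if len(ns) != 1:
        raise ValueError(f"models fitted to different n: {sorted(ns)}")
    df = pd.DataFrame(
        {
            "model": [r.model_name for r in results],
            "K": [r.K for r in results],
            "log_likelihood": [r.log_likelihood for r in results],
            "aicc": [r.aicc for r in results],
        }
    )
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    rel = np.exp(-0.5 * df["delta_aicc"])
    df["weight"] = rel / rel.sum()
    return df.sort_values("aicc", ignore_index=True)


def pseudo_r2(
    fitted: RegressionResult, null: RegressionResult, method: str = "nagelkerke"
) -> float:
    """Likelihood-ratio pseudo-R² of ``fitted`` against the intercept-only fit.

    ``nagelkerke`` (default) rescales the Cox–Snell statistic to a [0, 1]
    range; ``mcfadden`` is 1 - logL1/logL0.  A fit no better than the null
    returns 0 with a warning.
    """
    if fitted.n != null.n:
        raise ValueError("models fitted to different data")
    n = fitted.n
    ll1, ll0 = fitted.log_likelihood, null.log_likelihood
    if ll1 < ll0:
        logger.warning("fitted model is worse than the null; pseudo-R² set to 0")
        return 0.0
    if method == "nagelkerke":
        cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
        max_cs = 1.0 - np.exp(2.0 * ll0 / n)
        return float(cox_snell / max_cs) if max_cs > 0 else 0.0
    if method == "mcfadden":
        return float(1.0 - ll1 / ll0) if ll0 != 0 else 0.0
    raise ValueError(f"unknown pseudo-R² method {method!r}")
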