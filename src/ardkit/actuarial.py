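"""Actuarial classification of ageing-relatedness.

Rates of onset of ageing-related diseases are expected to grow with age the
way mortality does, so each disease's onset curve is confronted with two
actuarial models on the log scale:

- Gompertz: q_x = α e^{βx}, i.e. log q_x = log α + β x. α is the baseline
  onset level and β the senescent slope per year of age. A negative β means
  onset *falls* with age — such a disease has a very low likelihood of being
  ageing-related, whatever else its curve does.
- Gompertz–Makeham (exponential-quadratic): log q_x = log a + b x + c x².
  The quadratic term accommodates non-monotone curves (early bumps, late
  plateaus) that are still ageing-driven overall. Note this is the
  exponential-polynomial usage of the name, not the classical additive-
  constant Makeham hazard.

The step-wise banding algorithm: if β < 0 the disease is banded very-low;
otherwise the adjusted R² of the GM fit is banded at thresholds 0.95, 0.90,
0.85 and 0.80 — higher adjusted R² (a better actuarial fit, penalised for
the extra quadratic term) means higher likelihood of being ageing-related.

Fits are ordinary least squares of log q_x on age over the ages with q_x > 0
(log of a zero rate is undefined); a disease needs a minimum number of
positive-rate ages to be classified at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import FitError, InsufficientDataError
from .grid import AGES

__all__ = [
    "GompertzFit",
    "GompertzMakehamFit",
    "ArdVerdict",
    "BANDS",
    "fit_gompertz",
    "fit_gompertz_makeham",
    "classify_ard",
    "classify_all",
    "AgeingRelatednessClassifier",
]

#: bands in decreasing likelihood of being ageing-related (very_low last,
#: since it is decided by the slope sign, not the adjusted R²)
BANDS = (
    "very_high",
    "band_090_095",
    "band_085_090",
    "band_080_085",
    "low",
    "very_low_beta_negative",
)

#: adjusted-R² thresholds separating the positive-slope bands
R2_THRESHOLDS = (0.95, 0.90, 0.85, 0.80)

DEFAULT_MIN_POSITIVE_AGES = 10


@dataclass(frozen=True)
class GompertzFit:
    alpha: float
    beta: float
    r_squared: float
    adjusted_r_squared: float
    n_fit: int


@dataclass(frozen=True)
class GompertzMakehamFit:
    a: float
    b: float
    c: float
    r_squared: float
    adjusted_r_squared: float
    n_fit: int


@dataclass(frozen=True)
class ArdVerdict:
    disease_id: str
    band: str
    beta: float
    adjusted_r_squared: float


def _positive_log_rates(q, ages, min_positive: int):
    q = np.asarray(q, dtype=float)
    ages = AGES.astype(float) if ages is None else np.asarray(ages, dtype=float)
    if q.shape != ages.shape:
        raise ValueError("q and ages must align")
    if (q < 0).any() or (q > 1).any():
        raise ValueError("onset rates must lie in [0, 1]")
    mask = q > 0
    if int(mask.sum()) < min_positive:
        raise InsufficientDataError(
            f"only {int(mask.sum())} ages with q_x > 0 (need >= {min_positive})"
        )
    return np.log(q[mask]), ages[mask]


def _ols(y: np.ndarray, design: np.ndarray):
    model = sm.OLS(y, design)
    res = model.fit()
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("rank-deficient design (too few distinct ages)")
    return res


def _is_flat(y: np.ndarray) -> bool:
    # a perfectly flat response has zero total variance: define R² = 0 and
    # slope 0 (the age terms explain nothing that was not already constant)
    return bool(np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())))


def _r2_stats(res, n: int, p: int) -> tuple[float, float]:
    r2 = float(res.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2, float(adj)


def fit_gompertz(q, ages=None, min_positive: int = DEFAULT_MIN_POSITIVE_AGES) -> GompertzFit:
    """OLS fit of log q_x = log α + β x over ages with q_x > 0."""
    y, x = _positive_log_rates(q, ages, min_positive)
    if _is_flat(y):
        return GompertzFit(
            alpha=float(np.exp(y.mean())), beta=0.0,
            r_squared=0.0, adjusted_r_squared=0.0, n_fit=int(y.size),
        )
    design = sm.add_constant(x)
    res = _ols(y, design)
    r2, adj = _r2_stats(res, n=y.size, p=1)
    intercept, slope = (float(res.params[0]), float(res.params[1]))
    return GompertzFit(
        alpha=float(np.exp(intercept)),
        beta=slope,
        r_squared=r2,
        adjusted_r_squared=adj,
        n_fit=int(y.size),
    )


def fit_gompertz_makeham(
    q, ages=None, min_positive: int = DEFAULT_MIN_POSITIVE_AGES
) -> GompertzMakehamFit:
    """OLS fit of log q_x = log a + b x + c x² over ages with q_x > 0."""
    y, x = _positive_log_rates(q, ages, max(min_positive, 4))
    if _is_flat(y):
        return GompertzMakehamFit(
            a=float(np.exp(y.mean())), b=0.0, c=0.0,
            r_squared=0.0, adjusted_r_squared=0.0, n_fit=int(y.size),
        )
    design = np.column_stack([np.ones_like(x), x, x**2])
    if np.unique(x).size < 3:
        raise FitError("Gompertz–Makeham fit needs at least 3 distinct ages")
    res = _ols(y, design)
    r2, adj = _r2_stats(res, n=y.size, p=2)
    return GompertzMakehamFit(
        a=float(np.exp(res.params[0])),
        b=float(res.params[1]),
        c=float(res.params[2]),
        r_squared=r2,
        adjusted_r_squared=adj,
        n_fit=int(y.size),
    )


def band_from_fit(beta: float, gm_adjusted_r2: float) -> str:
    """The step-wise banding rule: slope sign first, then adjusted R²."""
    if beta < 0:
        return "very_low_beta_negative"
    r2 = gm_adjusted_r2
    if r2 >= 0.95:
        return "very_high"
    if r2 >= 0.90:
        return "band_090_095"
    if r2 >= 0.85:
        return "band_085_090"
    if r2 >= 0.80:
        return "band_080_085"
    return "low"


def classify_ard(gomp: GompertzFit, gm: GompertzMakehamFit, disease_id: str = "") -> ArdVerdict:
    """Assign the ageing-relatedness likelihood band for one disease."""
    band = band_from_fit(gomp.beta, gm.adjusted_r_squared)
    return ArdVerdict(
        disease_id=disease_id,
        band=band,
        beta=gomp.beta,
        adjusted_r_squared=gm.adjusted_r_squared,
    )


def classify_all(
    rates: pd.DataFrame, min_positive: int = DEFAULT_MIN_POSITIVE_AGES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit both models and band every disease in a wide rates table.

    Per-disease failures (too few positive ages, degenerate fits) are
    collected, never abort the batch: such diseases appear in the verdicts
    table with ``band = "unclassified"`` and the error message in ``note``.

    Returns (fits, verdicts): fits has one row per successfully fitted
    disease with Gompertz and GM parameters; verdicts has one row per input
    disease.
    """
    fit_rows, verdict_rows = [], []
    for disease_id, row in rates.iterrows():
        q = row.to_numpy(dtype=float)
        try:
            g = fit_gompertz(q, min_positive=min_positive)
            m = fit_gompertz_makeham(q, min_positive=min_positive)
        except (InsufficientDataError, FitError) as exc:
            verdict_rows.append(
                {
                    "disease_id": disease_id,
                    "band": "unclassified",
                    "beta": np.nan,
                    "gm_adj_r2": np.nan,
                    "note": str(exc),
                }
            )
            continue
        v = classify_ard(g, m, disease_id=str(disease_id))
        fit_rows.append(
            {
                "disease_id": disease_id,
                "alpha": g.alpha,
                "beta": g.beta,
                "gomp_r2": g.r_squared,
                "gomp_adj_r2": g.adjusted_r_squared,
                "gm_a": m.a,
                "gm_b": m.b,
                "gm_c": m.c,
                "gm_r2": m.r_squared,
                "gm_adj_r2": m.adjusted_r_squared,
                "n_fit": g.n_fit,
            }
        )
        verdict_rows.append(
            {
                "disease_id": disease_id,
                "band": v.band,
                "beta": v.beta,
                "gm_adj_r2": v.adjusted_r_squared,
                "note": "",
            }
        )
    fit_cols = [
        "disease_id", "alpha", "beta", "gomp_r2", "gomp_adj_r2",
        "gm_a", "gm_b", "gm_c", "gm_r2", "gm_adj_r2", "n_fit",
    ]
    verdict_cols = ["disease_id", "band", "beta", "gm_adj_r2", "note"]
    fits = pd.DataFrame(fit_rows, columns=fit_cols).set_index("disease_id")
    verdicts = pd.DataFrame(verdict_rows, columns=verdict_cols).set_index("disease_id")
    return fits, verdicts


class AgeingRelatednessClassifier(BaseEstimator):
    """Sklearn-style wrapper over the banding algorithm.

    Rows of X are per-disease onset-rate curves on the 64-point age grid.
    ``fit`` performs the per-curve Gompertz and Gompertz–Makeham fits;
    ``predict`` returns the likelihood band per row. The rule is stateless
    across diseases (each row is banded on its own fits), so ``predict``
    may be called with or without a prior ``fit`` on the same X.
    """

    def __init__(self, min_positive_ages: int = DEFAULT_MIN_POSITIVE_AGES):
        self.min_positive_ages = min_positive_ages

    def fit(self, X, y=None):
        X = check_array(X)
        rates = pd.DataFrame(X)
        self.fits_, self.verdicts_ = classify_all(rates, min_positive=self.min_positive_ages)
        self.bands_ = self.verdicts_["band"].to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = check_array(X)
        _, verdicts = classify_all(pd.DataFrame(X), min_positive=self.min_positive_ages)
        return verdicts["band"].to_numpy()

    def fit_predict(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.bands_

    def score(self, X, y) -> float:
        """Fraction of rows whose band matches y (exact band accuracy)."""
        check_is_fitted(self, "n_features_in_")
        return float(np.mean(self.predict(X) == np.asarray(y)))
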