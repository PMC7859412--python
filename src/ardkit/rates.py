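"""Age-specific rates of disease onset and their standardisation.

For each disease and integer age x in 21..84 the rate of onset is
q_x = d_x / l_x, where d_x counts patients first recorded with the disease at
age x and l_x counts patients with no prior record at age x. For clustering,
each curve is standardised to unit mass, q̂_x = q_x / Σ_{i=21..84} q_i, so
that curve *shape* is compared independently of disease frequency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from .exceptions import AgeGridError, StandardisationError, UndefinedMedianError
from .grid import AGE_MAX, AGE_MIN, AGES, check_age_grid

__all__ = [
    "counts_to_wide",
    "onset_rates",
    "standardise",
    "CurveStandardiser",
    "median_age_of_onset",
    "median_onset_table",
]


def counts_to_wide(counts: pd.DataFrame, trim: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot a long counts table (disease_id, age, d, l) to wide d and l tables.

    Each disease must cover exactly the ages 21..84. With ``trim=True``, rows
    outside that window are dropped first; otherwise they are an error — the
    age window is an explicit contract, not a silent truncation.
    """
    required = {"disease_id", "age", "d", "l"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    counts = counts.copy()
    outside = (counts["age"] < AGE_MIN) | (counts["age"] > AGE_MAX)
    if outside.any():
        if not trim:
            raise AgeGridError(
                f"{int(outside.sum())} rows outside ages {AGE_MIN}..{AGE_MAX}; "
                "pass trim=True to drop them"
            )
        counts = counts.loc[~outside]
    d_wide = counts.pivot(index="disease_id", columns="age", values="d")
    l_wide = counts.pivot(index="disease_id", columns="age", values="l")
    if d_wide.isna().any().any() or list(d_wide.columns) != list(AGES):
        raise AgeGridError(f"every disease needs exactly one row per age {AGE_MIN}..{AGE_MAX}")
    d_arr, l_arr = d_wide.to_numpy(), l_wide.to_numpy()
    if (d_arr < 0).any() or (l_arr < 0).any() or (d_arr > l_arr).any():
        raise ValueError("counts must satisfy 0 <= d_x <= l_x at every age")
    return d_wide, l_wide


def onset_rates(d, l, ages=None) -> np.ndarray:
    """q_x = d_x / l_x elementwise; ages with l_x = 0 get q_x = 0.

    Accepts per-disease vectors or (n_diseases, 64) arrays. When *ages* is
    given it is validated against the 21..84 grid.
    """
    if ages is not None:
        check_age_grid(ages)
    d = np.asarray(d, dtype=float)
    l = np.asarray(l, dtype=float)
    if d.shape != l.shape:
        raise ValueError("d and l must have the same shape")
    if (d < 0).any() or (l < 0).any() or (d > l).any():
        raise ValueError("counts must satisfy 0 <= d_x <= l_x")
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(l > 0, d / np.where(l > 0, l, 1.0), 0.0)
    return q


def rates_table(counts: pd.DataFrame, trim: bool = False) -> pd.DataFrame:
    """Wide table of onset rates q_x (rows: diseases, columns: ages 21..84)."""
    d_wide, l_wide = counts_to_wide(counts, trim=trim)
    q = onset_rates(d_wide.to_numpy(), l_wide.to_numpy())
    return pd.DataFrame(q, index=d_wide.index, columns=AGES)


def standardise(q) -> np.ndarray:
    """Standardise onset curves to unit mass: q̂_x = q_x / Σ_i q_i.

    Accepts a vector or an (n, 64) array; raises StandardisationError naming
    the offending rows when a curve is identically zero (such a disease has
    no shape to cluster).
    """
    arr = np.atleast_2d(np.asarray(q, dtype=float))
    totals = arr.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise StandardisationError(
            f"cannot standardise all-zero onset curve(s) at row(s) {zero.tolist()}"
        )
    out = arr / totals[:, None]
    return out[0] if np.asarray(q).ndim == 1 else out


def standardised_table(rates: pd.DataFrame) -> pd.DataFrame:
    """Standardise a wide rates table, naming zero-curve diseases in errors."""
    totals = rates.sum(axis=1)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise StandardisationError(f"all-zero onset curves cannot be standardised: {zero}")
    return rates.div(totals, axis=0)


class CurveStandardiser(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer mapping onset curves to unit-mass curves.

    Stateless (``fit`` only validates); composes with pipelines feeding the
    clusterer. Rows must be nonnegative with positive sum.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        if (X < 0).any():
            raise ValueError("onset rates must be nonnegative")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = check_array(X, ensure_min_features=2)
        return standardise(X)


def _weighted_quantile(ages: np.ndarray, weights: np.ndarray, p: float) -> float:
    """Inverse-CDF quantile with midpoint interpolation at exact boundaries.

    Equivalent to numpy's ``averaged_inverted_cdf`` on the expansion of each
    age repeated weights[x] times.
    """
    cum = np.cumsum(weights)
    total = cum[-1]
    target = p * total
    idx = int(np.searchsorted(cum, target, side="left"))
    if np.isclose(cum[idx], target):
        # exactly at a mass boundary: average with the next age carrying mass
        later = np.flatnonzero(weights[idx + 1 :] > 0)
        if later.size:
            return 0.5 * (ages[idx] + ages[idx + 1 + later[0]])
    return float(ages[idx])


def median_age_of_onset(d, ages=None) -> tuple[float, float, float]:
    """Median and quartiles (median, q25, q75) of the onset-age distribution.

    The distribution puts mass d_x at integer age x over 21..84. Quantiles
    use the inverse-CDF convention with midpoint averaging when a quantile
    falls exactly on a half-mass boundary.
    """
    if ages is None:
        ages = AGES
    else:
        ages = check_age_grid(ages)
    w = np.asarray(d, dtype=float)
    if w.shape != ages.shape:
        raise ValueError("d must align with the 64-point age grid")
    if (w < 0).any():
        raise ValueError("counts must be nonnegative")
    if w.sum() <= 0:
        raise UndefinedMedianError("median onset age undefined for zero total cases")
    med = _weighted_quantile(ages, w, 0.5)
    q25 = _weighted_quantile(ages, w, 0.25)
    q75 = _weighted_quantile(ages, w, 0.75)
    return med, q25, q75


def median_onset_table(counts: pd.DataFrame, trim: bool = False) -> pd.DataFrame:
    """Per-disease median onset age with quartiles, from a long counts table."""
    d_wide, _ = counts_to_wide(counts, trim=trim)
    rows = []
    for disease_id, row in d_wide.iterrows():
        med, q25, q75 = median_age_of_onset(row.to_numpy())
        rows.append({"disease_id": disease_id, "median": med, "q25": q25, "q75": q75})
    return pd.DataFrame(rows).set_index("disease_id")
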