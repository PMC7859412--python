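"""Synthetic disease-onset cohorts with known ground truth.

Real first-diagnosis counts from linked primary-care/hospital records are
access-restricted, so this module generates stand-in cohorts: each disease
gets an age-specific hazard drawn from a parametric curve family (exponential
growth, linear rise, early peak then decline, exponential decline), and
first-diagnosis counts d_x are sampled binomially from a depleting at-risk
pool l_x. Family membership and ageing-relatedness are recorded as ground
truth, so every downstream stage (rates, clustering, actuarial
classification) can be tested against a known answer.

The at-risk pool depletes only by diagnosis (l_{x+1} = l_x - d_x): mortality
and censoring are deliberately not modelled, because the downstream rate
q_x = d_x / l_x is defined against patients with no prior record of the
disease, not against survivors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidFamilyError
from .grid import AGES

HAZARD_FORMS = (
    "gompertz",
    "gompertz_makeham",
    "linear_rise",
    "early_peak_decline",
    "declining_exponential",
    "constant",
)

#: parameters rescaled multiplicatively (log-normal jitter) — overall level
_AMPLITUDE_PARAMS = {"alpha", "base", "start", "level", "peak_rate"}


@dataclass(frozen=True)
class CurveFamilySpec:
    """A parametric age-hazard family with known ageing-relatedness.

    Parameters by form (hazard h(x) for integer age x in 21..84):

    - ``gompertz``: ``alpha * exp(beta * x)`` — exponential growth
      (or decline for beta < 0).
    - ``gompertz_makeham``: ``exp(log_a + b*x + c*x**2)`` — log-quadratic.
    - ``linear_rise``: ``base + slope * (x - 21)``.
    - ``early_peak_decline``: ``peak_rate * exp(-(x - peak_age)**2 /
      (2 * width**2))`` — a log-quadratic bump peaking at ``peak_age``.
    - ``declining_exponential``: ``start * exp(-decay * (x - 21))``.
    - ``constant``: ``level`` at every age.

    ``is_ageing_related`` is ground truth: True exactly when the noise-free
    hazard, pushed through the actuarial banding algorithm, lands in the
    very-high band (fitted Gompertz slope positive and Gompertz–Makeham
    adjusted R^2 above 0.95).
    """

    family_id: str
    hazard_form: str
    parameters: dict = field(default_factory=dict)
    is_ageing_related: bool = False

    def hazard(self, ages: np.ndarray | None = None) -> np.ndarray:
        """Evaluate the noise-free hazard on the age grid (validated)."""
        if ages is None:
            ages = AGES
        h = _evaluate_hazard(self.hazard_form, self.parameters, np.asarray(ages, float))
        _validate_hazard(h, self.family_id)
        return h


def _evaluate_hazard(form: str, p: dict, x: np.ndarray) -> np.ndarray:
    if form == "gompertz":
        return p["alpha"] * np.exp(p["beta"] * x)
    if form == "gompertz_makeham":
        return np.exp(p["log_a"] + p["b"] * x + p["c"] * x**2)
    if form == "linear_rise":
        return p["base"] + p["slope"] * (x - 21.0)
    if form == "early_peak_decline":
        return p["peak_rate"] * np.exp(-((x - p["peak_age"]) ** 2) / (2.0 * p["width"] ** 2))
    if form == "declining_exponential":
        return p["start"] * np.exp(-p["decay"] * (x - 21.0))
    if form == "constant":
        return np.full_like(x, float(p["level"]))
    raise InvalidFamilyError(f"unknown hazard form {form!r}")


def _validate_hazard(h: np.ndarray, family_id: str) -> None:
    # per-age probabilities: zero allowed (no onsets), one is not (the whole
    # pool would be diagnosed in a single year, and log-rates degenerate)
    if not np.all(np.isfinite(h)) or np.any(h < 0.0) or np.any(h >= 1.0):
        raise InvalidFamilyError(
            f"family {family_id!r}: hazard must lie in [0, 1) at every age 21..84"
        )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-level knobs for :func:`generate_cohort`.

    noise_scale controls per-disease parameter jitter within a family:
    amplitude-like parameters (alpha, base, start, level, peak_rate) are
    rescaled by exp(N(0, noise_scale)); shape parameters (beta, slope, decay,
    peak_age, width, b, c) get additive N(0, noise_scale * |value|) jitter.
    """

    n_diseases_per_family: int = 20
    cohort_size_at_21: int = 1_000_000
    noise_scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_size_at_21 < 1:
            raise ValueError("cohort_size_at_21 must be >= 1")
        if self.n_diseases_per_family < 1:
            raise ValueError("n_diseases_per_family must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def default_family_panel() -> list[CurveFamilySpec]:
    """The five-family panel used as the package's reference study condition.

    Three ageing-related shapes (late exponential, mid-life exponential,
    linear rise) and two non-ageing-related shapes (early peak then decline,
    monotone exponential decline), mirroring the archetypes seen among
    age-specific onset curves of high-burden diseases: dementia-like late
    exponentials, cardiovascular/cancer mid-life exponentials, gradual
    linear risers (digestive disease), young-adult peaks, and conditions of
    early adulthood whose onset falls with age.
    """
    return [
        CurveFamilySpec(
            "late_exponential",
            "gompertz",
            {"alpha": 2e-6, "beta": 0.12},
            is_ageing_related=True,
        ),
        CurveFamilySpec(
            "mid_exponential",
            "gompertz",
            {"alpha": 5e-5, "beta": 0.07},
            is_ageing_related=True,
        ),
        CurveFamilySpec(
            "linear_rise",
            "linear_rise",
            {"base": 2e-4, "slope": 6e-5},
            is_ageing_related=True,
        ),
        CurveFamilySpec(
            "early_peak_decline",
            "early_peak_decline",
            {"peak_rate": 4e-3, "peak_age": 30.0, "width": 12.0},
            is_ageing_related=False,
        ),
        CurveFamilySpec(
            "declining_exponential",
            "declining_exponential",
            {"start": 1e-2, "decay": 0.06},
            is_ageing_related=False,
        ),
    ]


def _jitter_parameters(spec: CurveFamilySpec, rng: np.random.Generator, scale: float) -> dict:
    """Per-disease parameter jitter: log-normal on amplitudes, Gaussian on shapes."""
    out = {}
    for name, value in spec.parameters.items():
        if scale == 0.0:
            out[name] = value
        elif name in _AMPLITUDE_PARAMS:
            out[name] = value * float(np.exp(rng.normal(0.0, scale)))
        else:
            out[name] = value + float(rng.normal(0.0, scale * abs(value)))
    return out


def _disease_rng(seed: int, disease_index: int) -> np.random.Generator:
    # one stream per disease, split from the master seed by disease index, so
    # adding/removing diseases never perturbs the draws of the others
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(disease_index,)))


def sample_onset_counts(
    hazard: np.ndarray, cohort_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Binomially sample first-diagnosis counts from a depleting at-risk pool.

    Returns (d, l, depleted): d[x] ~ Binomial(l[x], hazard[x]) and
    l[x+1] = l[x] - d[x], starting from l[21] = cohort_size. ``depleted``
    flags that the pool hit zero before age 84 (d_x = 0 is emitted from
    there on).
    """
    d = np.zeros(AGES.size, dtype=np.int64)
    l = np.zeros(AGES.size, dtype=np.int64)
    at_risk = int(cohort_size)
    depleted = False
    for i in range(AGES.size):
        l[i] = at_risk
        if at_risk == 0:
            depleted = True
            d[i] = 0
            continue
        d[i] = rng.binomial(at_risk, hazard[i])
        at_risk -= int(d[i])
    return d, l, depleted


def generate_cohort(
    config: SyntheticCohortConfig,
    families: Sequence[CurveFamilySpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic onset-count table plus its ground-truth table.

    Returns
    -------
    counts : DataFrame
        Long format with columns ``disease_id, age, d, l`` — one row per
        disease and integer age 21..84.
    truth : DataFrame
        One row per disease: ``disease_id, family_id, is_ageing_related,
        depleted, parameters`` (JSON-encoded jittered generative parameters).
    """
    if families is None:
        families = default_family_panel()
    # validate every family before sampling anything
    for spec in families:
        spec.hazard()

    count_frames = []
    truth_rows = []
    disease_index = 0
    for spec in families:
        for j in range(config.n_diseases_per_family):
            rng = _disease_rng(config.seed, disease_index)
            params = _jitter_parameters(spec, rng, config.noise_scale)
            hazard = _evaluate_hazard(spec.hazard_form, params, AGES.astype(float))
            _validate_hazard(hazard, spec.family_id)
            d, l, depleted = sample_onset_counts(hazard, config.cohort_size_at_21, rng)
            disease_id = f"{spec.family_id}_{j:03d}"
            count_frames.append(
                pd.DataFrame(
                    {"disease_id": disease_id, "age": AGES, "d": d, "l": l}
                )
            )
            truth_rows.append(
                {
                    "disease_id": disease_id,
                    "family_id": spec.family_id,
                    "is_ageing_related": spec.is_ageing_related,
                    "depleted": depleted,
                    "parameters": json.dumps(params, sort_keys=True),
                }
            )
            disease_index += 1

    counts = pd.concat(count_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return counts, truth


def noise_free_curves(families: Iterable[CurveFamilySpec]) -> pd.DataFrame:
    """Exact hazards (one row per family) on the age grid, as a wide table."""
    rows = {spec.family_id: spec.hazard() for spec in families}
    return pd.DataFrame.from_dict(rows, orient="index", columns=AGES)
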