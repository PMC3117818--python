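"""Synthetic two-wave screening cohorts with known age/period/cohort effects.

The generator emulates the structure of a large Taiwanese health-screening
cohort: two examination waves (1996 and 2006), ages 20-59 at examination,
birth year = exam year - age exactly, sex strata, lifestyle confounders
(education years, smoking, alcohol, betel-quid categories) whose
distribution drifts with birth year (younger cohorts are more educated),
and a continuous outcome composed of known age, period and cohort effect
curves plus confounder effects and Gaussian noise.  Because the truth is
known, these cohorts support parameter-recovery and coverage tests for the
PLS age-period-cohort pipeline.

Also provides the small worked-example fixture whose centred cross-product
vector X^T y equals the printed reference values used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EffectSpec",
    "generate_cohort",
    "piecewise_linear",
    "appendix_fixture",
    "AppendixFixture",
]


def piecewise_linear(slope, changepoint=None, extra_slope=0.0, ref=0.0):
    """Curve ``f(v) = slope*(v-ref) + extra_slope*max(v-changepoint, 0)``.

    With a changepoint this is a hinge: the slope changes by ``extra_slope``
    at ``changepoint``, emulating a sudden shift in a cohort trend.
    """

    def f(v):
        v = np.asarray(v, dtype=float)
        out = slope * (v - ref)
        if changepoint is not None:
            out = out + extra_slope * np.clip(v - changepoint, 0.0, None)
        return out

    return f


@dataclass
class EffectSpec:
    """Generating truth for one synthetic cohort.

    Effect curves are callables in outcome units; defaults describe an
    SBP-like outcome (mmHg): age slope 0.4/yr, a mild cohort decline of
    0.05 mmHg per birth year, a -2 mmHg shift in the 2006 wave, residual
    noise sd 10.  ``cohort_changepoint``/``cohort_extra_slope`` add a hinge
    to the default cohort curve (pass e.g. changepoint 1970, extra slope
    -0.4 to emulate a sudden trend shift).  All randomness flows from the
    single integer ``seed``; the draw order is fixed (ages, sex, education,
    smoking, alcohol, betel, noise) so identical seeds give identical
    tables.
    """

    n_per_wave: int = 5000
    waves: tuple = (1996, 2006)
    age_range: tuple = (20, 59)
    intercept: float = 115.0
    age_effect: object = None  # callable over age, defaults to slope 0.4 from age 20
    cohort_effect: object = None  # callable over birth year, defaults below
    cohort_changepoint: float = None
    cohort_extra_slope: float = 0.0
    period_effect: float = -2.0  # offset for the later wave
    noise_sd: float = 10.0
    sex_effect: float = 5.0  # added for men
    # confounder model: dependence on birth year and effects on the outcome
    education_per_birthyr: float = 0.15  # years of education per birth year
    education_sd: float = 2.5
    confounder_effects: dict = field(
        default_factory=lambda: {
            "education": -0.2,  # per year of schooling
            "smoking": 1.2,  # per ordinal level 0-3
            "alcohol": 0.8,
            "betel": 0.6,
        }
    )
    # qualitative decade weights: most participants in their 30s, fewest in their 50s
    age_decade_weights: tuple = (0.30, 0.35, 0.20, 0.15)
    outcome_name: str = "sbp"
    seed: int = 0

    def resolved_age_effect(self):
        return self.age_effect or piecewise_linear(0.4, ref=self.age_range[0])

    def resolved_cohort_effect(self):
        if self.cohort_effect is not None:
            return self.cohort_effect
        return piecewise_linear(
            -0.05,
            changepoint=self.cohort_changepoint,
            extra_slope=self.cohort_extra_slope,
            ref=self.waves[0] - self.age_range[1],
        )


_ORDINAL_P = (0.55, 0.20, 0.15, 0.10)  # never / occasional / regular / heavy


def generate_cohort(spec: EffectSpec = None, **overrides) -> pd.DataFrame:
    """Generate one synthetic cohort table under ``spec``.

    Returns a DataFrame with columns ``age``, ``exam_year``, ``birth_year``,
    ``sex``, ``education``, ``smoking``, ``alcohol``, ``betel`` and the
    outcome.  ``exam_year = age + birth_year`` holds exactly for every row.
    """
    if spec is None:
        spec = EffectSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a spec or keyword overrides, not both")
    if spec.n_per_wave <= 0:
        raise ValueError("n_per_wave must be positive")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages_all = np.arange(lo, hi + 1)
    decades = (ages_all - lo) // 10
    w = np.asarray(spec.age_decade_weights, dtype=float)[decades]
    w = w / w.sum()

    # draw order: ages per wave, then sex, education, smoking, alcohol, betel, noise
    parts = []
    for wave in spec.waves:
        age = rng.choice(ages_all, size=spec.n_per_wave, p=w)
        parts.append(pd.DataFrame({"age": age, "exam_year": wave}))
    df = pd.concat(parts, ignore_index=True)
    df["birth_year"] = df["exam_year"] - df["age"]
    n = len(df)

    df["sex"] = np.where(rng.random(n) < 0.5, "M", "F")
    byr = df["birth_year"].to_numpy(dtype=float)
    byr0 = float(spec.waves[0] - hi)  # earliest birth year
    edu = 6.0 + spec.education_per_birthyr * (byr - byr0) + rng.normal(0, spec.education_sd, n)
    df["education"] = np.clip(edu, 0.0, 22.0)
    for col in ("smoking", "alcohol", "betel"):
        df[col] = rng.choice(4, size=n, p=_ORDINAL_P)

    age_f = spec.resolved_age_effect()
    coh_f = spec.resolved_cohort_effect()
    ce = spec.confounder_effects
    y = (
        spec.intercept
        + age_f(df["age"].to_numpy(dtype=float))
        + np.where(df["exam_year"] == spec.waves[1], spec.period_effect, 0.0)
        + coh_f(byr)
        + np.where(df["sex"] == "M", spec.sex_effect, 0.0)
        + ce.get("education", 0.0) * df["education"].to_numpy()
        + ce.get("smoking", 0.0) * df["smoking"].to_numpy()
        + ce.get("alcohol", 0.0) * df["alcohol"].to_numpy()
        + ce.get("betel", 0.0) * df["betel"].to_numpy()
        + rng.normal(0.0, spec.noise_sd, n)
    )
    df[spec.outcome_name] = y
    return df


# ---------------------------------------------------------------------------
# worked-example fixture


@dataclass(frozen=True)
class AppendixFixture:
    """Reference numbers for the three-covariate worked example.

    ``xty`` is the printed centred cross-product vector between the APC
    covariates and SBP; ``weight`` its unit normalisation (the first PLS
    weight vector), ``q1`` the printed score-regression coefficient and
    ``coefficients`` the implied one-component PLS coefficients.  ``X`` and
    ``y`` form a small synthetic (and deliberately rank-one) regression
    problem whose centred cross-products reproduce ``xty`` exactly and
    whose one-component PLS fit reproduces ``q1`` and ``coefficients``.
    """

    xty: tuple
    singular_value: float
    weight: tuple
    q1: float
    coefficients: tuple
    X: np.ndarray
    y: np.ndarray


def appendix_fixture() -> AppendixFixture:
    """Construct the worked-example fixture.

    The printed inputs are the cross-product vector (35105.27, -27746.77,
    -62852.03) and the score-regression coefficient 0.026.  A synthetic
    (X, y) is built by placing each covariate column proportional to a
    centred y: with x_j = v_j * y / (y'y) the cross-products X'y equal v
    exactly, and choosing y'y = 0.026 * ||v|| makes the score regression
    coefficient exactly 0.026, so a one-component PLS fit on (X, y)
    reproduces the printed weights and coefficients end to end.
    """
    v = np.array([35105.27, -27746.77, -62852.03])
    sv = float(np.linalg.norm(v))
    w = v / sv
    q1 = 0.026
    coef = w * q1
    base = np.array([3.0, -1.0, 2.0, -4.0, 1.5, -1.5])  # centred pattern, mean 0
    y = base * np.sqrt(q1 * sv / (base @ base))
    X = np.outer(y, v) / (y @ y)
    return AppendixFixture(
        xty=tuple(v),
        singular_value=sv,
        weight=tuple(w),
        q1=q1,
        coefficients=tuple(coef),
        X=X,
        y=y,
    )
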