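"""Jackknife confidence intervals for PLS regression coefficients.

PLS coefficients carry no closed-form sampling distribution, so standard
errors come from resampling: delete one observation (or one random group)
at a time, re-run the whole pipeline — centering, scaling, PLS extraction at
a fixed number of components, back-transformation — and combine the
leave-out estimates with the Tukey jackknife variance formula.  Intervals
use normal critical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pls import PLS1Regression

__all__ = ["JackknifeCI", "jackknife_ci"]


@dataclass
class JackknifeCI:
    """Per-term jackknife interval at a fixed component count."""

    terms: list
    estimate: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_deletions: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimate,
                "se": self.se,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _groups(n, scheme, seed):
    if scheme in (None, "auto"):
        scheme = "delete-one" if n <= 2000 else 30
    if scheme == "delete-one":
        return [np.array([i]) for i in range(n)]
    G = int(scheme)
    if G < 2:
        raise ValueError("need at least 2 deletion groups")
    if G > n:
        raise ValueError(f"cannot form {G} groups from n={n} rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.array_split(perm, G)


def jackknife_ci(
    X,
    y,
    n_components,
    level=0.95,
    scheme="auto",
    seed=None,
    scale=False,
    terms=None,
) -> JackknifeCI:
    """Jackknife CIs for PLS1 coefficients at a fixed ``n_components``.

    scheme : "delete-one", "auto", or an integer number of seeded random
        deletion groups.  "auto" deletes single rows up to n = 2000 and 30
        groups beyond.  The component count is held fixed across refits so
        the estimand does not drift.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    full = PLS1Regression(n_components=n_components, scale=scale).fit(X, y)
    est, _ = full.coefficients(full.n_components_)
    groups = _groups(n, scheme, seed)
    G = len(groups)
    reps = np.empty((G, p))
    for g, idx in enumerate(groups):
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        fit = PLS1Regression(n_components=n_components, scale=scale).fit(X[mask], y[mask])
        reps[g], _ = fit.coefficients(min(int(n_components), fit.n_components_))
    mean_rep = reps.mean(axis=0)
    se = np.sqrt((G - 1) / G * ((reps - mean_rep) ** 2).sum(axis=0))
    z = stats.norm.ppf(0.5 + level / 2)
    return JackknifeCI(
        terms=list(terms),
        estimate=est,
        se=se,
        lower=est - z * se,
        upper=est + z * se,
        level=level,
        n_deletions=G,
    )
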