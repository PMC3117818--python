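"""PRESS cross-validation for choosing the number of PLS components.

PRESS (predictive residual error sum of squares) sums, over every
observation, the squared error of the prediction made when that observation
is held out of the fit.  Every refit re-estimates centering and scaling on
the training rows only, so nothing leaks from the held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls import PLS1Regression

__all__ = ["PRESSResult", "press", "select_ncomp"]


@dataclass
class PRESSResult:
    press: np.ndarray  # PRESS value for h = 0..H
    scheme: str  # "loo" or "group-k"
    selected_h: int

    def to_dict(self):
        return {
            "press": self.press.tolist(),
            "scheme": self.scheme,
            "selected_h": int(self.selected_h),
        }


def _fold_indices(n, scheme, seed):
    if scheme in (None, "auto"):
        scheme = "loo" if n <= 2000 else 20
    if scheme == "loo":
        return "loo", [np.array([i]) for i in range(n)]
    k = int(scheme)
    if not 2 <= k <= n:
        raise ValueError(f"number of groups must lie in [2, n={n}], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return f"group-{k}", np.array_split(perm, k)


def press(X, y, n_components, scheme="auto", seed=None, scale=False) -> PRESSResult:
    """Cross-validated PRESS for component counts 0..``n_components``.

    scheme : "loo", "auto", or an integer number of seeded random groups.
        "auto" uses leave-one-out up to n = 2000 and 20 groups beyond.
    Ties in PRESS (within 1e-10 relative) resolve to the smallest h, the
    parsimonious choice.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    name, folds = _fold_indices(n, scheme, seed)
    H = int(n_components)
    press_vals = np.zeros(H + 1)
    achieved = H
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        fit = PLS1Regression(n_components=H, scale=scale).fit(X[mask], y[mask])
        achieved = min(achieved, fit.n_components_)
        for h in range(H + 1):
            hh = min(h, fit.n_components_)
            err = y[test_idx] - fit.predict(X[test_idx], h=hh)
            press_vals[h] += err @ err
    result = PRESSResult(press_vals, name, 0)
    result.selected_h = select_ncomp(result)
    return result


def select_ncomp(result: PRESSResult) -> int:
    """Smallest component count attaining the minimum PRESS.

    Values within 1e-10 relative of the minimum count as ties and resolve
    to the smaller h.
    """
    p = np.asarray(result.press, dtype=float)
    lo = p.min()
    tol = 1e-10 * max(lo, 1.0)
    return int(np.flatnonzero(p <= lo + tol)[0])
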