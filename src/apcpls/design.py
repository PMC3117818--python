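"""APC design matrices: centering, period coding, restricted cubic splines.

Age at examination, examination period and birth cohort satisfy the exact
identity ``exam_year = age + birth_year``, so the linear age-period-cohort
(APC) design is perfectly collinear (rank 2 with 3 columns).  This module
builds that design under fixed conventions — age centred on a reference age,
birth year centred on a reference year, the two examination waves coded 0/1 —
and optionally expands age and birth year into restricted-cubic-spline bases
with percentile knots.  No column is ever dropped: downstream PLS regression
resolves the collinearity itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SplineBasis",
    "DesignSpec",
    "ColumnInfo",
    "DesignMatrix",
    "choose_knots",
    "rcs_basis",
    "build_design",
    "APCDesignBuilder",
]

DEFAULT_KNOT_PERCENTILES = (0.05, 0.275, 0.5, 0.725, 0.95)


def choose_knots(x, percentiles=DEFAULT_KNOT_PERCENTILES) -> np.ndarray:
    """Place spline knots at percentiles of ``x``.

    Uses the linear-interpolation quantile convention (Hyndman-Fan type 7,
    the numpy default).  Knots must come out strictly increasing; ties
    between adjacent percentiles raise a ``ValueError`` naming the colliding
    percentiles, since coincident knots make the spline basis degenerate.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a 1-d vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    p = np.asarray(percentiles, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("percentiles must be a non-empty 1-d sequence")
    if x.size < p.size + 2:
        raise ValueError(
            f"need at least {p.size + 2} observations to place {p.size} knots, got {x.size}"
        )
    if np.any(p <= 0) or np.any(p >= 1) or np.any(np.diff(p) <= 0):
        raise ValueError("percentiles must be strictly increasing within (0, 1)")
    knots = np.quantile(x, p, method="linear")
    d = np.diff(knots)
    if np.any(d <= 0):
        i = int(np.argmax(d <= 0))
        raise ValueError(
            "degenerate knots: percentiles "
            f"{p[i]} and {p[i + 1]} both map to {knots[i]:g}"
        )
    return knots


@dataclass(frozen=True)
class SplineBasis:
    """Restricted-cubic-spline basis for one variable.

    ``knots`` are k >= 3 strictly increasing locations in the variable's own
    units.  The basis spans k-1 regression terms: the identity (linear) term
    plus k-2 nonlinear terms, each a truncated-power cubic restricted to be
    linear beyond the boundary knots and normalised by the squared span of
    the boundary knots so that coefficients stay on comparable scales.
    """

    variable: str
    knots: tuple = ()

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        if k.size < 3:
            raise ValueError("restricted cubic spline needs at least 3 knots")
        if np.any(np.diff(k) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", tuple(float(v) for v in k))

    @property
    def n_terms(self) -> int:
        return len(self.knots) - 1

    @property
    def normalization(self) -> float:
        """Squared span of the boundary knots, the divisor of the cubic terms."""
        return (self.knots[-1] - self.knots[0]) ** 2

    def transform(self, x) -> np.ndarray:
        return rcs_basis(x, self)


def rcs_basis(x, basis: SplineBasis) -> np.ndarray:
    """Evaluate a restricted-cubic-spline basis, returning k-1 columns.

    Column 0 is ``x`` itself.  For interior knots j = 1..k-2 the nonlinear
    column is::

        [(x - t_j)+^3 - (x - t_{k-1})+^3 * (t_k - t_j)/(t_k - t_{k-1})
                     + (x - t_k)+^3 * (t_{k-1} - t_j)/(t_k - t_{k-1})]
        / (t_k - t_1)^2

    which vanishes below the first knot and is linear in ``x`` beyond the
    last knot, so the implied function is linear in both tails.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    t = np.asarray(basis.knots, dtype=float)
    k = t.size
    out = np.empty(x.shape + (k - 1,), dtype=float)
    out[..., 0] = x
    norm = (t[-1] - t[0]) ** 2
    span = t[-1] - t[-2]

    def cube(v):
        return np.clip(v, 0.0, None) ** 3

    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / span
            + cube(x - t[-1]) * (t[-2] - t[j]) / span
        )
        out[..., j + 1] = term / norm
    return out


@dataclass(frozen=True)
class DesignSpec:
    """Conventions for building the APC design.

    Defaults follow the two-wave screening setup: age centred on 20 years,
    birth year centred on 1937, examination waves 1996 -> 0 and 2006 -> 1,
    five spline knots at the 0.05/0.275/0.5/0.725/0.95 percentiles.
    """

    age_center: float = 20.0
    birthyr_center: float = 1937.0
    period_coding: dict = field(default_factory=lambda: {1996: 0.0, 2006: 1.0})
    period_units: str = "wave"
    spline: bool = False
    knot_percentiles: tuple = DEFAULT_KNOT_PERCENTILES
    scale_to_unit_variance: bool = False

    def __post_init__(self):
        p = np.asarray(self.knot_percentiles, dtype=float)
        if np.any(p <= 0) or np.any(p >= 1) or np.any(np.diff(p) <= 0):
            raise ValueError("knot_percentiles must be strictly increasing in (0,1)")
        if len(self.period_coding) != 2:
            raise ValueError("exactly two period levels are supported")


@dataclass(frozen=True)
class ColumnInfo:
    """Provenance of one design column."""

    name: str
    source: str  # "age" | "period" | "birthyr"
    kind: str  # "linear" | "spline" | "period"
    offset: float  # centering offset subtracted from the source variable
    scale: float  # divisor applied to the finished column (1.0 if unscaled)


@dataclass
class DesignMatrix:
    """Numeric design with per-column provenance metadata."""

    values: np.ndarray
    columns: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values shape does not match column metadata")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite values")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def shape(self):
        return self.values.shape

    @property
    def names(self):
        return [c.name for c in self.columns]

    @property
    def scales(self) -> np.ndarray:
        return np.array([c.scale for c in self.columns])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def metadata(self) -> list:
        return [
            {
                "name": c.name,
                "source": c.source,
                "kind": c.kind,
                "offset": c.offset,
                "scale": c.scale,
            }
            for c in self.columns
        ]

    def recover_covariates(self) -> pd.DataFrame:
        """Undo scaling and centering on the linear/period columns.

        Returns the raw ``age``, ``exam_year`` (via the period code mapping
        stored in the offset/scale of the period column is not enough, so the
        coded level is returned as ``period``) and ``birth_year`` values.
        """
        out = {}
        for j, c in enumerate(self.columns):
            if c.kind == "period":
                out["period"] = self.values[:, j] * c.scale
            elif c.kind == "linear":
                key = "age" if c.source == "age" else "birth_year"
                out[key] = self.values[:, j] * c.scale + c.offset
        return pd.DataFrame(out)


class APCDesignBuilder(TransformerMixin, BaseEstimator):
    """Transformer building the APC design from individual cohort records.

    Parameters
    ----------
    age_center, birthyr_center : float
        Reference values subtracted from age and birth year.
    spline : bool
        If True, expand centred age and birth year into restricted cubic
        splines (k percentile knots -> k-1 columns each); the period column
        stays binary.  If False, the design is the 3-column linear one.
    knot_percentiles : sequence of float
        Percentile locations of the spline knots, on the centred variables.
    scale : bool
        Standardise every finished column to unit sample variance; the
        factors are recorded in the column metadata.
    period_coding : dict or None
        Mapping of the two exam years to {0, 1}.  None derives it from the
        data (earlier wave -> 0).
    period_units : {"wave", "years"}
        "wave" keeps the binary 0/1 column, so its coefficient is the full
        later-vs-earlier wave contrast and the implicit identification
        constraint carries the wave gap: b_age + b_cohort = gap * b_period.
        "years" multiplies the code by the gap between the waves (the
        column becomes exam_year minus the first wave), restoring the exact
        year-unit identity age + cohort = period under which the constraint
        reads b_age + b_cohort = b_period.

    Fitted attributes: ``knots_`` (dict of SplineBasis, spline mode only),
    ``scales_``, ``period_coding_``, ``columns_``.
    """

    _column_order = ("age", "period", "birthyr")

    def __init__(
        self,
        age_center=20.0,
        birthyr_center=1937.0,
        spline=False,
        knot_percentiles=DEFAULT_KNOT_PERCENTILES,
        scale=False,
        period_coding=None,
        period_units="wave",
        age_col="age",
        exam_col="exam_year",
        birth_col="birth_year",
    ):
        self.age_center = age_center
        self.birthyr_center = birthyr_center
        self.spline = spline
        self.knot_percentiles = knot_percentiles
        self.scale = scale
        self.period_coding = period_coding
        self.period_units = period_units
        self.age_col = age_col
        self.exam_col = exam_col
        self.birth_col = birth_col

    # -- internal helpers -------------------------------------------------
    def _extract(self, data: pd.DataFrame):
        for col in (self.age_col, self.exam_col, self.birth_col):
            if col not in data.columns:
                raise ValueError(f"column {col!r} missing from data")
        age = data[self.age_col].to_numpy(dtype=float)
        exam = data[self.exam_col].to_numpy(dtype=float)
        birth = data[self.birth_col].to_numpy(dtype=float)
        if not (np.all(np.isfinite(age)) and np.all(np.isfinite(exam)) and np.all(np.isfinite(birth))):
            raise ValueError("age / exam_year / birth_year contain non-finite values")
        if not np.allclose(exam, age + birth):
            raise ValueError("records violate exam_year = age + birth_year")
        return age, exam, birth

    def fit(self, X: pd.DataFrame, y=None):
        age, exam, birth = self._extract(X)
        years = np.unique(exam)
        if years.size != 2:
            raise ValueError(f"expected exactly 2 distinct exam years, found {years.size}")
        if self.period_coding is None:
            self.period_coding_ = {float(years[0]): 0.0, float(years[1]): 1.0}
        else:
            self.period_coding_ = {float(k): float(v) for k, v in self.period_coding.items()}
            if sorted(self.period_coding_.values()) != [0.0, 1.0]:
                raise ValueError("period_coding must map the two waves to 0 and 1")
            if set(self.period_coding_) != set(years.tolist()):
                raise ValueError("period_coding keys do not match the exam years present")
        if self.period_units not in ("wave", "years"):
            raise ValueError("period_units must be 'wave' or 'years'")
        self.wave_gap_ = float(years[1] - years[0])
        self.period_multiplier_ = self.wave_gap_ if self.period_units == "years" else 1.0
        self.observed_range_ = {
            "age": (float(age.min()), float(age.max())),
            "birthyr": (float(birth.min()), float(birth.max())),
        }
        age_c = age - self.age_center
        birth_c = birth - self.birthyr_center
        if self.spline:
            self.knots_ = {
                "age": SplineBasis("age", tuple(choose_knots(age_c, self.knot_percentiles))),
                "birthyr": SplineBasis("birthyr", tuple(choose_knots(birth_c, self.knot_percentiles))),
            }
        else:
            self.knots_ = {}
        raw, columns = self._assemble(age_c, exam, birth_c)
        n, p = raw.shape
        if n < p:
            raise ValueError(f"n = {n} < p = {p}: this design targets n >> p")
        if self.scale:
            sd = raw.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                bad = [columns[j].name for j in np.flatnonzero(sd <= 0)]
                raise ValueError(f"zero-variance design columns: {bad}")
            self.scales_ = sd
        else:
            self.scales_ = np.ones(p)
        self.columns_ = [
            ColumnInfo(c.name, c.source, c.kind, c.offset, float(s))
            for c, s in zip(columns, self.scales_)
        ]
        self.n_features_out_ = p
        return self

    def _assemble(self, age_c, exam, birth_c):
        period = np.array([self.period_coding_[float(e)] for e in exam]) * self.period_multiplier_
        cols, infos = [], []
        if self.spline:
            for src, x_c, center in (
                ("age", age_c, self.age_center),
                (None, None, None),  # placeholder: period goes between the blocks
                ("birthyr", birth_c, self.birthyr_center),
            ):
                if src is None:
                    cols.append(period)
                    infos.append(ColumnInfo("Examyr", "period", "period", 0.0, 1.0))
                    continue
                basis = self.knots_[src]
                B = basis.transform(x_c)
                label = "Ages" if src == "age" else "Birthyr"
                for j in range(B.shape[-1]):
                    cols.append(B[..., j])
                    infos.append(
                        ColumnInfo(
                            f"{label}_{j + 1}",
                            src,
                            "linear" if j == 0 else "spline",
                            center,
                            1.0,
                        )
                    )
        else:
            cols = [age_c, period, birth_c]
            infos = [
                ColumnInfo("Age", "age", "linear", self.age_center, 1.0),
                ColumnInfo("Examyr", "period", "period", 0.0, 1.0),
                ColumnInfo("Birthyr", "birthyr", "linear", self.birthyr_center, 1.0),
            ]
        return np.column_stack(cols), infos

    def transform(self, X: pd.DataFrame) -> DesignMatrix:
        check_is_fitted(self, "columns_")
        age, exam, birth = self._extract(X)
        unknown = set(np.unique(exam).tolist()) - set(self.period_coding_)
        if unknown:
            raise ValueError(f"exam years not seen in fit: {sorted(unknown)}")
        raw, _ = self._assemble(age - self.age_center, exam, birth - self.birthyr_center)
        return DesignMatrix(raw / self.scales_, list(self.columns_))

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "columns_")
        return np.asarray([c.name for c in self.columns_], dtype=object)


def build_design(data: pd.DataFrame, spec: DesignSpec = DesignSpec(), **cols) -> DesignMatrix:
    """Build a :class:`DesignMatrix` from cohort records under ``spec``.

    Thin wrapper over :class:`APCDesignBuilder` (fit + transform on the same
    records).  ``cols`` forwards the column-name keywords (``age_col``, ...).
    """
    builder = APCDesignBuilder(
        age_center=spec.age_center,
        birthyr_center=spec.birthyr_center,
        spline=spec.spline,
        knot_percentiles=spec.knot_percentiles,
        scale=spec.scale_to_unit_variance,
        period_coding=spec.period_coding,
        period_units=spec.period_units,
        **cols,
    )
    return builder.fit(data).transform(data)
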