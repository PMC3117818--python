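"""End-to-end age-period-cohort PLS pipeline.

For every outcome and sex stratum: confounder-adjust the outcome within
sex x exam-year strata, build linear and restricted-cubic-spline APC
designs, run PRESS component selection, fit one- and two-component PLS
models (the two-component fit is a robustness companion even when PRESS
prefers one), attach jackknife confidence intervals, and evaluate fitted
age and cohort trend curves on the observed covariate grid.

Because the APC design is rank deficient, every reported coefficient set
is constraint-resolved: it satisfies the implicit identification constraint
that the age and cohort effects sum to the period effect (variance-weighted
when covariates are scaled).  Trend curves are point estimates only; no
confidence bands are drawn for them, and one- vs two-component curves are
reported side by side as the robustness check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adjustment import ConfounderAdjuster
from .design import APCDesignBuilder, DesignMatrix
from .model_selection import press
from .pls import PLS1Regression
from .uncertainty import jackknife_ci

__all__ = ["PipelineConfig", "APCReport", "run_apc", "trend_curves"]


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_apc`.

    ``input`` is a CSV path (ignored if ``data`` is passed to run_apc
    directly).  ``columns`` maps the canonical names (age, exam_year,
    birth_year, sex) to the columns of the input file.
    """

    input: str = None
    columns: dict = field(
        default_factory=lambda: {
            "age": "age",
            "exam_year": "exam_year",
            "birth_year": "birth_year",
            "sex": "sex",
        }
    )
    outcomes: list = field(default_factory=list)
    confounders: list = field(default_factory=list)
    age_center: float = 20.0
    birthyr_center: float = 1937.0
    knot_percentiles: tuple = (0.05, 0.275, 0.5, 0.725, 0.95)
    components: tuple = (1, 2)
    scale: bool = True  # unit-variance scaling inside the PLS fit
    press_scheme: object = "auto"
    jackknife_scheme: object = "auto"
    level: float = 0.95
    seed: int = 0
    curve_points: int = 0  # 0 -> one point per integer year

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if not cfg.outcomes:
            raise ValueError("config must name at least one outcome")
        for h in cfg.components:
            if int(h) < 1:
                raise ValueError("components must be >= 1")
        return cfg


@dataclass
class APCReport:
    """Coefficient tables, PRESS and R² traces, and fitted trend curves."""

    coefficients: pd.DataFrame  # outcome, sex, model, n_components, term, estimate, se, lower, upper
    press_traces: pd.DataFrame  # outcome, sex, model, h, press, selected
    r2_traces: pd.DataFrame  # outcome, sex, model, h, r2
    curves: pd.DataFrame  # outcome, sex, n_components, variable, grid, value
    exclusions: dict  # outcome -> rows dropped for missingness
    seeds: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.coefficients.to_csv(outdir / "coefficients.csv", index=False)
        self.press_traces.to_csv(outdir / "press.csv", index=False)
        self.r2_traces.to_csv(outdir / "r2.csv", index=False)
        self.curves.to_csv(outdir / "curves.csv", index=False)
        meta = {"exclusions": self.exclusions, "seeds": self.seeds}
        (outdir / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def trend_curves(fit: PLS1Regression, builder: APCDesignBuilder, grid, variable, h=None):
    """Fitted spline contribution of ``variable`` over ``grid``.

    ``variable`` is "age" or "birthyr"; ``grid`` is in the variable's
    original units and must lie inside the observed range.  The curve is
    anchored to zero at the centering reference, matching the reporting
    convention for coefficient trends.
    """
    if variable not in ("age", "birthyr"):
        raise ValueError("variable must be 'age' or 'birthyr'")
    if not builder.spline:
        raise ValueError("trend curves require a spline design")
    grid = np.asarray(grid, dtype=float)
    lo, hi = builder.observed_range_[variable]
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid [{grid.min():g}, {grid.max():g}] outside observed "
            f"{variable} range [{lo:g}, {hi:g}]"
        )
    center = builder.age_center if variable == "age" else builder.birthyr_center
    basis = builder.knots_[variable]
    coef, _ = fit.coefficients(h)
    idx = [j for j, c in enumerate(builder.columns_) if c.source == variable]
    B_grid = basis.transform(grid - center)
    B_ref = basis.transform(np.array([0.0]))  # the centering reference
    contrib = (B_grid - B_ref) @ coef[idx]
    return pd.DataFrame({"grid": grid, "value": contrib})


def _int_grid(lo, hi):
    return np.arange(np.ceil(lo), np.floor(hi) + 1.0)


def run_apc(config, data: pd.DataFrame = None) -> APCReport:
    """Run the full adjust / design / PRESS / fit / jackknife pipeline."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    if data is None:
        if not config.input:
            raise ValueError("config.input is required when no data is passed")
        data = pd.read_csv(config.input)
    cols = config.columns
    for canon in ("age", "exam_year", "birth_year", "sex"):
        if cols.get(canon) not in data.columns:
            raise ValueError(f"mapped column for {canon!r} missing from data")
    data = data.rename(columns={v: k for k, v in cols.items() if v != k})

    coef_rows, press_rows, r2_rows, curve_rows = [], [], [], []
    exclusions, seeds = {}, {"seed": int(config.seed)}
    rng = np.random.default_rng(config.seed)

    for outcome in config.outcomes:
        if outcome not in data.columns:
            raise ValueError(f"outcome column {outcome!r} missing from data")
        if data[outcome].notna().sum() == 0:
            raise ValueError(f"outcome column {outcome!r} is empty")
        adj = ConfounderAdjuster(
            outcome, config.confounders, strata=["sex", "exam_year"]
        ).adjust(data)
        exclusions[outcome] = adj.n_dropped
        for sex, sub in adj.data.groupby("sex", observed=True):
            y = sub[adj.adjusted_col].to_numpy(dtype=float)
            for model, spline in (("linear", False), ("spline", True)):
                builder = APCDesignBuilder(
                    age_center=config.age_center,
                    birthyr_center=config.birthyr_center,
                    spline=spline,
                    knot_percentiles=config.knot_percentiles,
                )
                design = builder.fit(sub).transform(sub)
                X = design.values
                H = max(int(h) for h in config.components)
                sub_seed = int(rng.integers(0, 2**31 - 1))
                pr = press(
                    X, y, H, scheme=config.press_scheme, seed=sub_seed, scale=config.scale
                )
                for h, v in enumerate(pr.press):
                    press_rows.append(
                        dict(outcome=outcome, sex=sex, model=model, h=h, press=v,
                             selected=h == pr.selected_h)
                    )
                for h in config.components:
                    jk_seed = int(rng.integers(0, 2**31 - 1))
                    ci = jackknife_ci(
                        X, y, int(h), level=config.level, scheme=config.jackknife_scheme,
                        seed=jk_seed, scale=config.scale, terms=design.names,
                    )
                    fit = PLS1Regression(n_components=int(h), scale=config.scale).fit(X, y)
                    for hh, r2 in enumerate(fit.explained_variance()):
                        r2_rows.append(
                            dict(outcome=outcome, sex=sex, model=model,
                                 n_components=int(h), h=hh, r2=r2)
                        )
                    for term, est, se, lo_, up in zip(
                        ci.terms, ci.estimate, ci.se, ci.lower, ci.upper
                    ):
                        coef_rows.append(
                            dict(outcome=outcome, sex=sex, model=model,
                                 n_components=int(h), term=term, estimate=est,
                                 se=se, lower=lo_, upper=up)
                        )
                    if spline:
                        for variable in ("age", "birthyr"):
                            g = _int_grid(*builder.observed_range_[variable])
                            curve = trend_curves(fit, builder, g, variable)
                            for gv, cv in zip(curve["grid"], curve["value"]):
                                curve_rows.append(
                                    dict(outcome=outcome, sex=sex,
                                         n_components=int(h), variable=variable,
                                         grid=gv, value=cv)
                                )
    return APCReport(
        coefficients=pd.DataFrame(coef_rows),
        press_traces=pd.DataFrame(press_rows),
        r2_traces=pd.DataFrame(r2_rows),
        curves=pd.DataFrame(curve_rows),
        exclusions=exclusions,
        seeds=seeds,
    )
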