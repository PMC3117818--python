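"""Stage-one confounder adjustment within sex x exam-year strata.

Before any age-period-cohort modelling, each outcome is adjusted for
lifestyle confounders (education years, smoking, alcohol, betel-quid
chewing) by ordinary least squares within every stratum.  The adjusted
value is defined as stratum mean + OLS residual, which keeps the adjusted
outcome in its original units and preserves every stratum mean, so
downstream period contrasts remain interpretable.  Records with missing
values in any modelled field are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["AdjustedOutcome", "ConfounderAdjuster", "adjusted_values"]


@dataclass
class AdjustedOutcome:
    """Adjusted records plus a per-stratum adjustment report."""

    data: pd.DataFrame  # surviving rows with an added adjusted column
    adjusted_col: str
    confounders: list
    n_dropped: int
    report: dict = field(default_factory=dict)  # stratum -> {n, coefficients}


def _expand(df: pd.DataFrame, confounders):
    """Numeric design for the confounders; categoricals become indicator
    columns with the lowest category as reference."""
    blocks = []
    for c in confounders:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8:
            blocks.append(col.to_frame())
        else:
            d = pd.get_dummies(col.astype("category"), prefix=c, drop_first=True)
            blocks.append(d.astype(float))
    if not blocks:
        return pd.DataFrame(index=df.index)
    return pd.concat(blocks, axis=1)


class ConfounderAdjuster(TransformerMixin, BaseEstimator):
    """Transformer producing stratum-wise confounder-adjusted outcomes.

    Parameters
    ----------
    outcome : str
        Name of the outcome column to adjust.
    confounders : sequence of str
        Confounder columns; numeric columns enter linearly, categorical or
        low-cardinality columns are expanded to indicators.
    strata : sequence of str
        Columns defining the strata (typically sex and exam year).
    anchor : {"stratum", "grand"}
        Location given to the residuals: the stratum mean (default, keeps
        within-stratum means intact) or the grand mean.
    suffix : str
        Suffix of the added adjusted column.

    This transformer is stateless across calls: adjustment is re-estimated
    on whatever data ``transform`` receives (it is a within-sample residual
    operation, not a learned mapping).
    """

    def __init__(self, outcome, confounders=(), strata=(), anchor="stratum", suffix="_adj"):
        self.outcome = outcome
        self.confounders = confounders
        self.strata = strata
        self.anchor = anchor
        self.suffix = suffix

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> AdjustedOutcome:
        return self.adjust(X)

    def adjust(self, data: pd.DataFrame) -> AdjustedOutcome:
        confounders = list(self.confounders)
        strata = list(self.strata)
        modeled = [self.outcome, *confounders, *strata]
        missing_cols = [c for c in modeled if c not in data.columns]
        if missing_cols:
            raise ValueError(f"columns missing from data: {missing_cols}")
        keep = data[modeled].notna().all(axis=1)
        n_dropped = int((~keep).sum())
        df = data.loc[keep].copy()
        if df.empty:
            raise ValueError(f"no complete records for outcome {self.outcome!r}")
        adj_col = f"{self.outcome}{self.suffix}"
        adjusted = np.empty(len(df))
        report = {}
        groups = df.groupby(strata, observed=True) if strata else [((), df)]
        grand_mean = float(df[self.outcome].mean())
        pos = {idx: i for i, idx in enumerate(df.index)}
        for key, g in groups:
            y = g[self.outcome].to_numpy(dtype=float)
            Z = _expand(g, confounders)
            names = list(Z.columns)
            Zv = Z.to_numpy(dtype=float) if names else np.empty((len(g), 0))
            # drop constant indicator columns within the stratum
            if Zv.shape[1]:
                varying = Zv.std(axis=0) > 0
                Zv = Zv[:, varying]
                names = [n for n, v in zip(names, varying) if v]
            if len(g) <= Zv.shape[1] + 1:
                raise ValueError(
                    f"stratum {key!r}: {len(g)} rows cannot support "
                    f"{Zv.shape[1]} confounder terms"
                )
            A = np.column_stack([np.ones(len(g)), Zv])
            if np.linalg.matrix_rank(A) < A.shape[1]:
                raise ValueError(f"singular confounder design in stratum {key!r}")
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ beta
            base = y.mean() if self.anchor == "stratum" else grand_mean
            vals = base + resid
            rows = [pos[idx] for idx in g.index]
            adjusted[rows] = vals
            report[str(key)] = {
                "n": int(len(g)),
                "coefficients": dict(zip(["intercept", *names], beta.tolist())),
            }
        df[adj_col] = adjusted
        return AdjustedOutcome(
            data=df,
            adjusted_col=adj_col,
            confounders=confounders,
            n_dropped=n_dropped,
            report=report,
        )


def adjusted_values(data, outcome, confounders, strata, anchor="stratum") -> AdjustedOutcome:
    """Functional wrapper over :class:`ConfounderAdjuster`."""
    return ConfounderAdjuster(outcome, confounders, strata, anchor=anchor).adjust(data)
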