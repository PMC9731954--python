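"""Technical validation: demographics-corrected residual correlations.

Cognitive scores show a *positive manifold*: performance on different tasks
correlates positively across individuals.  To check that structure while
controlling for demographics, each subtest's raw score is regressed (OLS) on
age (continuous) plus education and gender as categorical predictors; the
model predictions are subtracted from the raw scores to give residual
scores, and Pearson correlations between subtests' residuals are examined
per battery.  Only participants with a complete battery and complete
demographics enter (listwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .norming import completeness_flags, orient_scores
from .registry import get_battery, get_subtest

__all__ = [
    "ResidualScoreTable",
    "CorrelationReport",
    "residualize",
    "correlation_matrix",
    "positive_manifold_check",
]


@dataclass
class ResidualScoreTable:
    """Residual scores for one battery: runs x subtests, plus fit metadata."""

    battery_id: int
    residuals: pd.DataFrame            # index: test_run_id, columns: subtest_id
    n_participants: int
    models: dict[int, object] = field(default_factory=dict)


@dataclass
class CorrelationReport:
    """Per-battery residual correlation matrices and their extremes."""

    matrices: dict[int, pd.DataFrame]
    min_offdiag: float
    max_offdiag: float
    all_positive: bool

    def offdiagonal(self, battery_id: int) -> np.ndarray:
        m = self.matrices[battery_id].to_numpy()
        return m[~np.eye(m.shape[0], dtype=bool)]


def _complete_demographics(frame: pd.DataFrame) -> pd.Series:
    # Unlike the norm sample, education 99 ("Other") counts as complete here:
    # validation needs reported, not binnable, demographics.
    return (
        frame["age"].notna()
        & frame["education_level"].notna()
        & frame["gender"].notna()
    )


def residualize(
    frame: pd.DataFrame,
    completeness: Optional[Mapping[str, bool]] = None,
    orient: bool = True,
) -> dict[int, ResidualScoreTable]:
    """Demographics-corrected residual scores, one table per battery.

    Per subtest, fits ``raw_score ~ age + C(education_level) + C(gender)``
    by ordinary least squares and subtracts the fitted values.  Education
    and gender always enter as indicator sets, never as a single numeric
    predictor.  Categorical levels observed exactly once are dropped (with a
    warning) since they would fit their own observation perfectly.

    By default time-based scores (go/no-go, trail making) are negated first
    so that every subtest's residual points in the higher-is-better
    direction — the orientation under which the positive manifold is the
    expected structure; ``orient=False`` analyses raw scores as released.
    Orientation is a sign flip, so it changes only the sign, never the
    magnitude, of the resulting correlations.
    """
    if completeness is None:
        completeness = completeness_flags(frame)
    keep = frame["test_run_id"].astype(str).map(
        lambda r: bool(completeness.get(r, False))
    ) & _complete_demographics(frame)
    df = frame[keep].copy()
    score = df["raw_score"].to_numpy(dtype=float)
    if orient:
        score = orient_scores(df["specific_subtest_id"].to_numpy(dtype=int), score)
    df["_score"] = score

    out: dict[int, ResidualScoreTable] = {}
    for bid, bgrp in df.groupby("battery_id", sort=False):
        bid = int(bid)
        battery = get_battery(bid)
        resid_cols = {}
        models = {}
        for sid in battery.subtest_ids:
            sub = bgrp[bgrp["specific_subtest_id"] == sid][
                ["test_run_id", "age", "education_level", "gender", "_score"]
            ].copy()
            if sub.empty:
                continue
            for col in ("education_level", "gender"):
                counts = sub[col].value_counts()
                singletons = counts[counts < 2].index
                if len(singletons):
                    warnings.warn(
                        f"battery {bid} subtest {sid}: dropping {col} level(s) "
                        f"{list(singletons)} observed only once", stacklevel=2)
                    sub = sub[~sub[col].isin(singletons)]
            sub["age"] = sub["age"].astype(float)
            sub["education_level"] = sub["education_level"].astype(int).astype(str)
            model = smf.ols("_score ~ age + C(education_level) + C(gender)", data=sub)
            if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
                raise np.linalg.LinAlgError(
                    f"battery {bid} subtest {sid}: singular design matrix")
            fit = model.fit()
            models[sid] = fit
            resid_cols[sid] = pd.Series(fit.resid.to_numpy(),
                                        index=sub["test_run_id"].astype(str))
        table = pd.DataFrame(resid_cols)
        table = table.dropna()  # listwise: only runs residualized on every subtest
        out[bid] = ResidualScoreTable(
            battery_id=bid, residuals=table, n_participants=len(table), models=models
        )
    return out


def correlation_matrix(
    tables: Mapping[int, ResidualScoreTable], min_pairs: int = 3
) -> CorrelationReport:
    """Pairwise Pearson correlations between subtests' residual scores.

    Matrices are symmetric with unit diagonal.  A pair with fewer than
    ``min_pairs`` joint observations, or a residual vector with zero
    variance, is an error.
    """
    matrices: dict[int, pd.DataFrame] = {}
    offdiags = []
    for bid, table in tables.items():
        r = table.residuals
        if len(r) < min_pairs:
            raise ValueError(
                f"battery {bid}: {len(r)} participants; need at least {min_pairs}")
        sds = r.std(ddof=1)
        zero = sds[sds == 0].index.tolist()
        if zero:
            raise ValueError(
                f"battery {bid}: zero-variance residuals for subtest(s) {zero}; "
                "correlation undefined")
        corr = r.corr(method="pearson")
        np.fill_diagonal(corr.values, 1.0)
        matrices[bid] = corr
        m = corr.to_numpy()
        offdiags.append(m[~np.eye(m.shape[0], dtype=bool)])
    if not matrices:
        raise ValueError("no residual tables supplied")
    flat = np.concatenate(offdiags) if offdiags else np.empty(0)
    return CorrelationReport(
        matrices=matrices,
        min_offdiag=float(flat.min()) if flat.size else float("nan"),
        max_offdiag=float(flat.max()) if flat.size else float("nan"),
        all_positive=bool((flat > 0).all()) if flat.size else True,
    )


def positive_manifold_check(report: CorrelationReport) -> tuple[bool, dict]:
    """True iff every off-diagonal correlation is strictly positive.

    The summary names any non-positive entries (battery, subtest pair,
    value) along with the global min and max off-diagonal correlation.
    """
    violations = []
    for bid, corr in report.matrices.items():
        cols = list(corr.columns)
        m = corr.to_numpy()
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if m[i, j] <= 0:
                    violations.append(
                        {"battery_id": bid, "subtests": (cols[i], cols[j]),
                         "r": float(m[i, j])})
    summary = {
        "min": report.min_offdiag,
        "max": report.max_offdiag,
        "violations": violations,
    }
    return len(violations) == 0, summary
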