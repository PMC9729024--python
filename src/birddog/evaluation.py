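"""Relating pose indices to clinician ratings.

Ordinary least squares with an intercept, backward stepwise model selection
by AIC, and the three-model comparison (selected indices with duration,
selected indices only, duration only) that asks whether the fine-grained
indices add predictive value beyond the conventional hold-duration score.

By default both predictors and the response are z-scored before fitting, so
coefficients are standardized effect sizes; raw-scale fitting is available
everywhere via ``standardize=False`` flags.  AIC uses the full Gaussian
log-likelihood and counts the residual variance as a parameter:

    AIC = n log(2 pi RSS / n) + n + 2 (k + 1)

with k the number of mean parameters including the intercept (drop
``aic_includes_scale`` to get the convention that omits the +2 for the
variance; only the constant differs, so model selection is unaffected).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SingularDesignError, ValidationError, ZeroVarianceError
from .simulate import TrialRecord

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ("spb1", "spb2", "spb3", "ag1", "ag2", "ag3")
TRIALS_CSV_COLUMNS = ("trial_id", "cohort", "clinician_score") + INDEX_COLUMNS + ("duration_s",)


@dataclass(eq=False)
class RegressionResult:
    """One fitted linear model in the style of a regression table row set."""

    predictors: tuple[str, ...]
    beta: dict[str, float]        # includes "const"
    se: dict[str, float]
    p_value: dict[str, float]
    aic: float
    adjusted_r2: float
    n_obs: int
    aic_includes_scale: bool = True

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "beta": self.beta, "se": self.se, "p_value": self.p_value,
            "aic": self.aic, "adjusted_r2": self.adjusted_r2, "n_obs": self.n_obs,
            "aic_includes_scale": self.aic_includes_scale,
        }


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records; rows with a missing rating are dropped listwise."""
    rows = []
    n_dropped = 0
    for rec in records:
        if rec.clinician_score is None or not np.isfinite(rec.clinician_score):
            n_dropped += 1
            continue
        row = {"trial_id": rec.trial_id, "cohort": rec.cohort,
               "clinician_score": rec.clinician_score}
        for col in INDEX_COLUMNS + ("duration_s",):
            row[col] = getattr(rec.indices, col)
        rows.append(row)
    if n_dropped:
        logger.info("records_to_frame: dropped %d record(s) without a clinician score", n_dropped)
    return pd.DataFrame(rows)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Read a trials table, validating the expected columns."""
    df = pd.read_csv(path)
    missing = [c for c in TRIALS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: trials CSV lacks columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: trials CSV contains no rows")
    return df


def standardize(
    df: pd.DataFrame,
    variables: Sequence[str],
    include_response: bool = True,
    response: str = "clinician_score",
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score the given columns (and optionally the response), ddof = 1.

    Returns the transformed copy and the per-column (mean, sd) pairs needed
    to undo the transformation.  A constant column raises
    :class:`ZeroVarianceError`.
    """
    if len(df) < 3:
        raise ValidationError("standardization needs at least 3 records")
    cols = list(variables) + ([response] if include_response and response in df.columns else [])
    out = df.copy()
    scale: dict[str, tuple[float, float]] = {}
    for col in cols:
        mu = float(df[col].mean())
        sd = float(df[col].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ZeroVarianceError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (df[col] - mu) / sd
        scale[col] = (mu, sd)
    return out, scale


def fit_ols(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    aic_includes_scale: bool = True,
) -> RegressionResult:
    """OLS with intercept; SEs from the unbiased residual variance.

    ``X`` may have zero columns (intercept-only model).  A rank-deficient
    design raises :class:`SingularDesignError`.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValidationError(f"need more observations ({n}) than parameters ({k} + intercept)")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient; columns: {list(design.columns)}"
        )
    res = sm.OLS(y, design).fit()
    k_params = k + 1 + (1 if aic_includes_scale else 0)  # mean params (+ sigma^2)
    aic = float(-2 * res.llf + 2 * k_params)
    adj_r2 = float(res.rsquared_adj) if k > 0 else 0.0
    return RegressionResult(
        predictors=tuple(X.columns),
        beta={nm: float(v) for nm, v in res.params.items()},
        se={nm: float(v) for nm, v in res.bse.items()},
        p_value={nm: float(v) for nm, v in res.pvalues.items()},
        aic=aic, adjusted_r2=adj_r2, n_obs=int(res.nobs),
        aic_includes_scale=aic_includes_scale,
    )


def backward_stepwise_aic(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    candidates: Sequence[str] | None = None,
    aic_includes_scale: bool = True,
) -> RegressionResult:
    """Backward stepwise selection: greedily drop the predictor whose removal
    lowers AIC the most; stop when no removal lowers it.

    Deterministic: ties are broken by predictor name order.  The final model
    never has higher AIC than the full model; predictors may be removed all
    the way down to the intercept-only model.
    """
    X = pd.DataFrame(X)
    current = sorted(candidates if candidates is not None else X.columns)
    best = fit_ols(X[current], y, aic_includes_scale)
    while current:
        trials = []
        for name in current:  # sorted, so ties resolve by name order
            remaining = [c for c in current if c != name]
            trials.append((fit_ols(X[remaining], y, aic_includes_scale), name))
        candidate = min(trials, key=lambda item: item[0].aic)
        if candidate[0].aic < best.aic:
            best = candidate[0]
            current = [c for c in current if c != candidate[1]]
            logger.debug("stepwise: dropped %s (AIC %.3f)", candidate[1], best.aic)
        else:
            break
    return best


@dataclass(eq=False)
class DurationComparison:
    """The three-model comparison against the conventional duration score.

    ``delta_aic`` = AIC(duration only) − AIC(selected + duration); positive
    values mean the indices add predictive value beyond duration.
    """

    with_duration: RegressionResult
    selected_only: RegressionResult
    duration_only: RegressionResult
    delta_aic: float
    delta_aic_selected_only: float

    def to_dict(self) -> dict:
        return {
            "with_duration": self.with_duration.to_dict(),
            "selected_only": self.selected_only.to_dict(),
            "duration_only": self.duration_only.to_dict(),
            "delta_aic": self.delta_aic,
            "delta_aic_selected_only": self.delta_aic_selected_only,
        }


def compare_duration_models(
    df: pd.DataFrame,
    selected: Sequence[str],
    duration: str = "duration_s",
    response: str = "clinician_score",
    standardize_variables: bool = True,
    aic_includes_scale: bool = True,
) -> DurationComparison:
    """Fit selected+duration, selected-only and duration-only on identical rows."""
    selected = list(selected)
    variables = selected + ([duration] if duration not in selected else [])
    data = df.dropna(subset=variables + [response])
    if standardize_variables:
        data, _ = standardize(data, variables, include_response=True, response=response)
    y = data[response]
    fit = lambda cols: fit_ols(data[cols], y, aic_includes_scale)
    with_duration = fit(variables if duration not in selected else selected)
    selected_only = fit(selected)
    duration_only = fit([duration])
    return DurationComparison(
        with_duration=with_duration,
        selected_only=selected_only,
        duration_only=duration_only,
        delta_aic=duration_only.aic - with_duration.aic,
        delta_aic_selected_only=duration_only.aic - selected_only.aic,
    )


def format_model_table(models: Mapping[str, RegressionResult]) -> str:
    """Regression-table text rendering: predictor, beta (SE), p, AIC, adj R^2."""
    lines = [f"{'Model':<34}{'Predictor':<14}{'beta (SE)':<18}{'p value':<10}{'AIC':<10}{'Adj R2':<8}"]
    lines.append("-" * len(lines[0]))
    for label, res in models.items():
        names = list(res.predictors) or ["const"]
        for i, nm in enumerate(names):
            beta = res.beta.get(nm, float("nan"))
            se = res.se.get(nm, float("nan"))
            p = res.p_value.get(nm, float("nan"))
            p_str = "<0.001" if p < 0.001 else f"{p:.3g}"
            first = label if i == 0 else ""
            tail = f"{res.aic:<10.2f}{res.adjusted_r2:<8.2f}" if i == 0 else ""
            lines.append(f"{first:<34}{nm:<14}{f'{beta:.2f} ({se:.2f})':<18}{p_str:<10}{tail}")
        lines.append("")
    return "\n".join(lines)


def write_comparison_report(comparison: DurationComparison, out_dir: str | Path) -> Path:
    """Write the comparison as JSON plus a human-readable table; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "model_comparison.json"
    json_path.write_text(json.dumps(comparison.to_dict(), indent=2, sort_keys=True) + "\n")
    table = format_model_table({
        "Selected variables with duration": comparison.with_duration,
        "Selected variables only": comparison.selected_only,
        "Duration only": comparison.duration_only,
    })
    (out_dir / "model_comparison.txt").write_text(
        table + f"\ndelta AIC (duration-only minus with-duration): {comparison.delta_aic:.2f}\n"
    )
    return json_path
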