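"""OLS retention models on the pesticide property table.

The response throughout is the relative retention
``(R_t - R_t0) / R_t0`` where R_t0 is the retention time of the
reference compound (the one with least R_t; it maps to exactly 0).
Predictors are the octanol-water partition coefficient log P and the
molecular fractal dimensions: D over all atoms, D' averaged over
non-buried atoms (both computed externally and carried as inputs).

Fit statistics follow QSPR reporting conventions: multiple correlation
r = sqrt(R^2), residual standard error s, F with (p, n-p-1) degrees of
freedom, AEV = 1 - r^2, and MAPE over observations with nonzero
response (the reference's ratio is identically zero and would blow up
a percentage error).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .datamodel import CompoundRecord, RegressionResult

__all__ = ["retention_ratio", "fit_ols", "fit_quadratic_Dprime", "MODEL_SPECS", "fit_model"]


def retention_ratio(
    records: Sequence[CompoundRecord], reference_name: str
) -> dict[str, float]:
    """Relative retention (R_t - R_t0)/R_t0 per compound.

    ``reference_name`` must match a record with positive retention time.
    """
    ref = next((r for r in records if r.name == reference_name), None)
    if ref is None:
        raise ValueError(f"reference compound {reference_name!r} not found")
    if not ref.retention_time or ref.retention_time <= 0:
        raise ValueError(f"reference {reference_name!r} has missing or nonpositive R_t")
    rt0 = ref.retention_time
    out: dict[str, float] = {}
    for rec in records:
        if rec.retention_time is None:
            raise ValueError(f"{rec.name}: missing retention time")
        out[rec.name] = (rec.retention_time - rt0) / rt0
    return out


def fit_ols(
    y: np.ndarray,
    X: np.ndarray,
    predictor_names: Sequence[str] = (),
) -> RegressionResult:
    """Least-squares fit with intercept and the QSPR statistics bundle."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    r2 = fit.rsquared
    yhat = fit.fittedvalues
    nz = y != 0
    mape = float(100.0 * np.mean(np.abs((y[nz] - yhat[nz]) / y[nz]))) if nz.any() else float("nan")
    r = float(np.sqrt(max(r2, 0.0)))
    return RegressionResult(
        coefficients=np.asarray(fit.params),
        n=n,
        r=r,
        s=float(np.sqrt(fit.ssr / fit.df_resid)),
        F=float(fit.fvalue),
        MAPE=mape,
        AEV=1.0 - r**2,
        predictor_names=tuple(predictor_names),
    )


def _table(records: Sequence[CompoundRecord], reference_name: str):
    ratio = retention_ratio(records, reference_name)
    y = np.array([ratio[r.name] for r in records])
    logP = np.array([r.logP for r in records], dtype=float)
    D = np.array([r.D for r in records], dtype=float)
    Dp = np.array([r.Dprime for r in records], dtype=float)
    if np.isnan(logP).any() or np.isnan(D).any() or np.isnan(Dp).any():
        raise ValueError("records must carry logP, D and D' for the retention models")
    return y, logP, D, Dp


def fit_quadratic_Dprime(
    records: Sequence[CompoundRecord],
    reference_name: str,
    include_IS: bool = True,
) -> RegressionResult:
    """Quadratic-in-D' retention model, optionally dropping the internal standard."""
    recs = [r for r in records if include_IS or not r.is_internal_standard]
    y, _, _, Dp = _table(recs, reference_name)
    return fit_ols(y, np.column_stack([Dp, Dp**2]), ("D'", "D'^2"))


#: The five published retention models: predictors + internal-standard handling.
MODEL_SPECS: dict[str, dict] = {
    "eq1": {"predictors": ("logP", "D'-D"), "include_IS": True},
    "eq2": {"predictors": ("logP", "D'-D"), "include_IS": False},
    "eq3": {"predictors": ("logP", "D'"), "include_IS": False},
    "eq4": {"predictors": ("D'", "D'^2"), "include_IS": True},
    "eq5": {"predictors": ("D'", "D'^2"), "include_IS": False},
}


def fit_model(
    records: Sequence[CompoundRecord],
    model: str,
    reference_name: str | None = None,
) -> RegressionResult:
    """Fit one of the named retention models (``eq1`` .. ``eq5``).

    The reference defaults to the compound with least retention time.
    """
    if model not in MODEL_SPECS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_SPECS)}")
    spec = MODEL_SPECS[model]
    if reference_name is None:
        with_rt = [r for r in records if r.retention_time is not None]
        reference_name = min(with_rt, key=lambda r: r.retention_time).name
    recs = [r for r in records if spec["include_IS"] or not r.is_internal_standard]
    y, logP, D, Dp = _table(recs, reference_name)
    cols = {"logP": logP, "D'-D": Dp - D, "D'": Dp, "D'^2": Dp**2}
    X = np.column_stack([cols[p] for p in spec["predictors"]])
    return fit_ols(y, X, spec["predictors"])
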