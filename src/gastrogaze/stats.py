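"""Mixed-effects candidate-model ledger and pairwise correlations.

Candidate sets are explicit lists of model specifications — never
automatic selection.  Estimation delegates to standard linear
mixed-effects routines with random intercepts for participant and
parent/carer; maximum likelihood (not REML) is used because information
criteria are compared across fixed-effect structures.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as scistats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import InputError

__all__ = [
    "standardise",
    "ModelSpec",
    "ModelFit",
    "ModelLedger",
    "fit_ledger",
    "CorrelationMatrix",
    "correlate",
]


def standardise(values, ddof: int = 1):
    """Z-score: mean 0, SD 1 (sample SD by default, ``ddof=0`` for the
    population convention).  Missing values are propagated untouched."""
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    if mask.sum() < 2:
        raise InputError("standardise needs at least 2 non-missing values")
    sd = arr[mask].std(ddof=ddof)
    if sd == 0:
        raise InputError("cannot standardise values with zero spread")
    out = arr.copy()
    out[mask] = (arr[mask] - arr[mask].mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: an outcome, a fixed-effects formula right-hand
    side, and the random-intercept grouping columns."""

    label: str
    outcome: str
    fixed: str = "1"
    random_intercepts: tuple[str, ...] = ("participant_id", "parent_id")

    @property
    def formula(self) -> str:
        return f"{self.outcome} ~ {self.fixed}"

    def variables(self, columns) -> list[str]:
        """Data columns referenced by this spec (token match against the
        available columns)."""
        tokens = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", self.formula))
        return [c for c in columns if c in tokens] + [
            c for c in self.random_intercepts if c in columns
        ]


@dataclass
class ModelFit:
    spec: ModelSpec
    converged: bool
    singular: bool
    llf: float
    aic: float
    bic: float
    n_obs: int
    coefficients: pd.DataFrame  # term, beta, z, p
    error: str | None = None
    delta_aic: float = np.nan
    delta_bic: float = np.nan


@dataclass
class ModelLedger:
    fits: list[ModelFit]

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "label": f.spec.label,
                "formula": f.spec.formula,
                "converged": f.converged,
                "singular": f.singular,
                "n_obs": f.n_obs,
                "llf": f.llf,
                "aic": f.aic,
                "bic": f.bic,
                "delta_aic": f.delta_aic,
                "delta_bic": f.delta_bic,
                "error": f.error,
            }
            for f in self.fits
        ]
        return pd.DataFrame(rows)

    def fit(self, label: str) -> ModelFit:
        for f in self.fits:
            if f.spec.label == label:
                return f
        raise KeyError(label)


def _fit_one(spec: ModelSpec, rows: pd.DataFrame, reml: bool) -> ModelFit:
    groups_col = spec.random_intercepts[-1] if spec.random_intercepts else None
    vc = {}
    if len(spec.random_intercepts) > 1:
        # Nested/crossed intercepts: outermost grouping (parent) as the
        # model group, remaining factors as variance components within it.
        for col in spec.random_intercepts[:-1]:
            vc[col] = f"0 + C({col})"
    try:
        singular = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if groups_col is None:
                raise InputError("at least one random-intercept column is required")
            model = smf.mixedlm(
                spec.formula,
                data=rows,
                groups=rows[groups_col],
                re_formula="1",
                vc_formula=vc or None,
            )
            result = model.fit(reml=reml, method=["lbfgs", "powell"])
            converged = bool(result.converged)
            for w in caught:
                text = str(w.message).lower()
                if "singular" in text or "boundary" in text:
                    singular = True
                if issubclass(w.category, ConvergenceWarning) and "converge" in text:
                    converged = False
        # Information criteria on the ML likelihood; parameter count covers
        # fixed effects plus all (co)variance parameters and the residual.
        k = len(result.fe_params) + model.k_re2 + model.k_vc + 1
        llf = float(result.llf)
        n = int(result.nobs)
        aic = -2 * llf + 2 * k
        bic = -2 * llf + np.log(n) * k
        fe = result.fe_params
        coefficients = pd.DataFrame(
            {
                "term": fe.index,
                "beta": fe.to_numpy(),
                "z": result.tvalues[fe.index].to_numpy(),
                "p": result.pvalues[fe.index].to_numpy(),
            }
        )
        return ModelFit(spec, converged, singular, llf, aic, bic, n, coefficients)
    except (np.linalg.LinAlgError, ValueError) as exc:
        return ModelFit(
            spec,
            converged=False,
            singular=True,
            llf=np.nan,
            aic=np.nan,
            bic=np.nan,
            n_obs=len(rows),
            coefficients=pd.DataFrame(columns=["term", "beta", "z", "p"]),
            error=str(exc),
        )


def fit_ledger(
    data: pd.DataFrame,
    candidates: list[ModelSpec],
    standardise_cols: tuple[str, ...] = (),
    reml: bool = False,
) -> ModelLedger:
    """Fit every candidate on identical rows and report delta-criteria.

    Rows are restricted listwise to completeness over the union of all
    candidates' variables, so criteria are comparable.  Columns named in
    ``standardise_cols`` are z-scored on the fitting rows before entry.
    Convergence failures are recorded per model, never dropped.
    """
    if not candidates:
        raise InputError("candidate list must not be empty")
    used: list[str] = []
    for spec in candidates:
        for col in spec.variables(data.columns):
            if col not in used:
                used.append(col)
        for col in spec.random_intercepts:
            if col not in data.columns:
                raise InputError(f"random-intercept column {col!r} not in data")
    rows = data.dropna(subset=used).copy().reset_index(drop=True)
    for col in standardise_cols:
        rows[col] = standardise(rows[col])

    fits = [_fit_one(spec, rows, reml) for spec in candidates]
    finite_aic = [f.aic for f in fits if np.isfinite(f.aic)]
    finite_bic = [f.bic for f in fits if np.isfinite(f.bic)]
    best_aic = min(finite_aic) if finite_aic else np.nan
    best_bic = min(finite_bic) if finite_bic else np.nan
    for f in fits:
        f.delta_aic = f.aic - best_aic
        f.delta_bic = f.bic - best_bic
    fits.sort(key=lambda f: (not np.isfinite(f.aic), f.aic))
    return ModelLedger(fits)


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with per-cell n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def correlate(data: pd.DataFrame, measures: list[str], min_n: int = 3) -> CorrelationMatrix:
    """Bivariate Pearson correlations over pairwise-complete rows.

    Cells with fewer than ``min_n`` complete pairs are flagged missing
    (NaN).  No multiplicity correction is applied.
    """
    missing = [m for m in measures if m not in data.columns]
    if missing:
        raise InputError(f"measures not in data: {missing}")
    k = len(measures)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i, a in enumerate(measures):
        for j, b in enumerate(measures):
            if j < i:
                continue
            pair = data[[a, b]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if i == j:
                if len(pair) >= min_n:
                    r[i, j], p[i, j] = 1.0, 0.0
                continue
            if len(pair) < min_n:
                continue
            res = scistats.pearsonr(pair[a], pair[b])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    frame = lambda m: pd.DataFrame(m, index=measures, columns=measures)  # noqa: E731
    return CorrelationMatrix(frame(r), frame(p), frame(n))
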