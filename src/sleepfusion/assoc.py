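"""Clinical association statistics for night-level REM architecture.

Spearman rank correlations between automated REM% (of TST) and symptom
scales (PSQI, ESS, RBDSQ), Benjamini–Hochberg FDR correction across the
submitted family of tests, and standardized multivariable linear
regression adjusting for age, sex, BMI and medication use.  Spearman and
BH-FDR follow the explicit formulas below; the regression is ordinary
least squares via statsmodels on z-scored continuous variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult", "RegressionResult", "AssociationReport",
    "spearman", "bh_fdr", "standardized_ols", "association_suite",
]


@dataclass
class AssociationResult:
    pair: str
    rho: float
    p: float
    q: float = float("nan")


@dataclass
class RegressionResult:
    """Standardized OLS for one outcome ~ predictor + covariates model.

    ``beta``/``ci_low``/``ci_high``/``p`` refer to the predictor of
    interest.  Continuous variables are z-scored; binary covariates stay
    0/1 (their coefficients are therefore unstandardized), recorded in
    ``covariate_encoding``.
    """

    outcome: str
    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    covariates: list[str] = field(default_factory=list)
    covariate_encoding: dict = field(default_factory=dict)


@dataclass
class AssociationReport:
    correlations: list[AssociationResult]
    regressions: list[RegressionResult]
    alpha: float = 0.05

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pair": c.pair, "rho": c.rho, "p": c.p, "q": c.q}
                for c in self.correlations
            ]
        )

    def regression_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": r.outcome, "predictor": r.predictor,
                    "beta": r.beta, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "p": r.p,
                }
                for r in self.regressions
            ]
        )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    rho is the Pearson correlation of the rank vectors; the two-sided p
    value uses the t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.clip(np.mean(rx * ry), -1.0, 1.0))
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, returned in the
    original order.  Guarantees q >= p elementwise and monotonicity in
    the sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


_BINARY_COVARIATES = ("sex", "medication")


def standardized_ols(
    outcome,
    predictor,
    covariates: pd.DataFrame | None = None,
    outcome_name: str = "outcome",
    predictor_name: str = "predictor",
) -> RegressionResult:
    """OLS of a z-scored outcome on a z-scored predictor plus covariates.

    Continuous covariates (age, BMI, ...) are z-scored; binary covariates
    (sex, medication) stay 0/1.  The 95% CI comes from the t distribution
    of the fit.  A rank-deficient design raises, naming the offending
    column.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("outcome and predictor must be 1-D and paired")

    def zscore(v: np.ndarray, name: str) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {name!r} is constant")
        return (v - v.mean()) / sd

    cols = {predictor_name: zscore(x, predictor_name)}
    encoding = {predictor_name: "z-scored"}
    cov_names: list[str] = []
    if covariates is not None:
        for name in covariates.columns:
            v = np.asarray(covariates[name], dtype=float)
            if name.lower() in _BINARY_COVARIATES or set(np.unique(v)) <= {0.0, 1.0}:
                cols[name] = v
                encoding[name] = "binary 0/1 (unstandardized)"
            else:
                cols[name] = zscore(v, name)
                encoding[name] = "z-scored"
            cov_names.append(name)

    X = pd.DataFrame(cols)
    n_params = X.shape[1] + 1
    if y.size <= n_params + 2:
        raise ValueError(
            f"need n > {n_params + 2} observations for {n_params} parameters"
        )
    design = np.column_stack([np.ones(y.size), X.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify a column whose removal restores full rank; check
        # covariates before the predictor of interest so the report names
        # the redundant adjustment term
        for j, name in reversed(list(enumerate(X.columns))):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"collinear design: column {name!r}")
        raise ValueError("collinear design")

    yz = zscore(y, outcome_name)
    fit = sm.OLS(yz, sm.add_constant(X)).fit()
    ci = fit.conf_int(alpha=0.05).loc[predictor_name]
    return RegressionResult(
        outcome=outcome_name,
        predictor=predictor_name,
        beta=float(fit.params[predictor_name]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[predictor_name]),
        covariates=cov_names,
        covariate_encoding=encoding,
    )


def association_suite(
    rem_pct: pd.Series | np.ndarray,
    scales: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    predictor_name: str = "rem_pct",
    alpha: float = 0.05,
) -> AssociationReport:
    """Correlations (with one FDR family) plus adjusted regressions.

    ``rem_pct``, ``scales`` and ``covariates`` must share an index of
    subject IDs (positional alignment is accepted for plain arrays).  The
    FDR family is exactly the set of scale correlations submitted in this
    call.
    """
    if isinstance(rem_pct, pd.Series) and isinstance(scales, pd.DataFrame):
        mismatch = set(rem_pct.index).symmetric_difference(scales.index)
        if mismatch:
            raise ValueError(f"misaligned subject IDs: {sorted(mismatch)}")
        scales = scales.loc[rem_pct.index]
        if covariates is not None:
            missing = set(rem_pct.index) - set(covariates.index)
            if missing:
                raise ValueError(f"misaligned subject IDs: {sorted(missing)}")
            covariates = covariates.loc[rem_pct.index]
    x = np.asarray(rem_pct, dtype=float)

    correlations = []
    for scale in scales.columns:
        rho, p = spearman(x, np.asarray(scales[scale], dtype=float))
        correlations.append(
            AssociationResult(pair=f"{predictor_name}~{scale}", rho=rho, p=p)
        )
    qs = bh_fdr([c.p for c in correlations])
    for c, q in zip(correlations, qs):
        c.q = float(q)

    regressions = [
        standardized_ols(
            np.asarray(scales[scale], dtype=float), x,
            covariates=covariates,
            outcome_name=scale, predictor_name=predictor_name,
        )
        for scale in scales.columns
    ]
    return AssociationReport(
        correlations=correlations, regressions=regressions, alpha=alpha
    )
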