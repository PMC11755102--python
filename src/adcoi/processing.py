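"""Survey cleaning, missingness diagnosis, imputation and input averages.

The adult cohort's treatment-cost column arrives with missing entries.
Before averaging, the missingness mechanism is diagnosed (Little-type MCAR
chi-square over missingness patterns plus a logistic regression of the
missingness indicator on observed covariates) and the column is completed
by chained equations with predictive-mean-matching draws.  The per-severity
arithmetic means of the completed table are the per-patient inputs the
costing engine scales to national counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.imputation.mice import MICEData

from . import records as rc
from .extrapolate import SEVERITIES, Segment

Conclusion = Literal["MCAR", "MAR", "MNAR_assumed"]


# ---------------------------------------------------------------------------
# missingness diagnosis
# ---------------------------------------------------------------------------


@dataclass
class MissingnessReport:
    """Outcome of the missing-data mechanism diagnosis for one column."""

    target: str
    mcar_statistic: float
    mcar_df: int
    mcar_p: float
    mar_logit_coefficients: dict[str, tuple[float, float]]  # name -> (coef, p)
    conclusion: Conclusion
    alpha: float = 0.05
    n_missing: int = 0
    n_total: int = 0

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "mcar_statistic": self.mcar_statistic,
            "mcar_df": self.mcar_df,
            "mcar_p": self.mcar_p,
            "mar_logit_coefficients": {
                k: {"coef": c, "p": p} for k, (c, p) in self.mar_logit_coefficients.items()
            },
            "conclusion": self.conclusion,
            "alpha": self.alpha,
            "n_missing": self.n_missing,
            "n_total": self.n_total,
        }


def _as_numeric(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce columns to numeric; non-numeric columns are factorized."""
    out = {}
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            codes, _ = pd.factorize(s, use_na_sentinel=True)
            out[col] = pd.Series(codes, index=s.index, dtype=float).where(s.notna())
    return pd.DataFrame(out, index=df.index)


def _em_mvn(y: np.ndarray, max_iter: int = 100, tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """ML mean/covariance of a multivariate normal with missing entries (EM).

    Rows are grouped by missingness pattern; rows with every entry missing
    are dropped.  The covariance update includes the conditional-covariance
    correction, so the estimate is the proper observed-data MLE.
    """
    y = y[~np.all(np.isnan(y), axis=1)]
    n, p = y.shape
    mu = np.nanmean(y, axis=0)
    # start from pairwise-complete covariance, ridge-stabilised
    sigma = np.atleast_2d(pd.DataFrame(y).cov(min_periods=1).to_numpy())
    sigma = np.where(np.isnan(sigma), 0.0, sigma)
    sigma += 1e-8 * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    miss = np.isnan(y)
    for key in np.unique(miss, axis=0):
        rows = np.where((miss == key).all(axis=1))[0]
        patterns[key.tobytes()] = rows

    for _ in range(max_iter):
        ey = y.copy()
        cov_add = np.zeros((p, p))
        for key, rows in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            if not m.any():
                continue
            o = ~m
            soo = sigma[np.ix_(o, o)]
            smo = sigma[np.ix_(m, o)]
            smm = sigma[np.ix_(m, m)]
            beta = np.linalg.solve(soo, smo.T).T  # (n_m, n_o)
            resid_cov = smm - beta @ smo.T
            ey[np.ix_(rows, m)] = mu[m] + (y[np.ix_(rows, o)] - mu[o]) @ beta.T
            cov_add[np.ix_(m, m)] += len(rows) * resid_cov
        mu_new = ey.mean(axis=0)
        centered = ey - mu_new
        sigma_new = (centered.T @ centered + cov_add) / n
        shift = np.max(np.abs(mu_new - mu)) + np.max(np.abs(sigma_new - sigma))
        mu, sigma = mu_new, sigma_new + 1e-10 * np.eye(p)
        if shift < tol:
            break
    return mu, sigma


def little_mcar_test(data: pd.DataFrame) -> tuple[float, int, float]:
    """Little's MCAR chi-square over the missingness patterns of ``data``.

    ``d2 = sum_j m_j (ybar_j - mu_oj)' Sigma_oj^{-1} (ybar_j - mu_oj)``
    with EM-estimated ``mu``/``Sigma``; ``df = sum_j p_j - p``.  Returns
    ``(statistic, df, p_value)``.  With no missing entries the statistic is
    0 with p = 1 (degenerate, nothing to test).
    """
    y = _as_numeric(data).to_numpy(dtype=float)
    y = y[~np.all(np.isnan(y), axis=1)]
    if y.shape[0] == 0:
        raise ValueError("all rows are entirely missing; nothing to estimate")
    n, p = y.shape
    miss = np.isnan(y)
    if not miss.any():
        return 0.0, 1, 1.0
    # z-score on available cases: the statistic is affine-invariant in exact
    # arithmetic, and standardizing makes that hold to machine precision
    loc = np.nanmean(y, axis=0)
    scale = np.nanstd(y, axis=0)
    scale[scale == 0] = 1.0
    y = (y - loc) / scale
    mu, sigma = _em_mvn(y)
    d2 = 0.0
    sum_pj = 0
    n_patterns = 0
    for key in np.unique(miss, axis=0):
        rows = (miss == key).all(axis=1)
        o = ~key
        if not o.any():
            continue
        yo = y[np.ix_(rows, o)]
        mj = yo.shape[0]
        diff = yo.mean(axis=0) - mu[o]
        soo = sigma[np.ix_(o, o)]
        d2 += mj * float(diff @ np.linalg.solve(soo, diff))
        sum_pj += int(o.sum())
        n_patterns += 1
    df = max(sum_pj - p, 1)
    return float(d2), df, float(stats.chi2.sf(d2, df))


def test_mcar(
    records: pd.DataFrame,
    covariates: Sequence[str],
    target: str = rc.COST_TREATMENT,
    alpha: float = 0.05,
) -> MissingnessReport:
    """Diagnose the missingness mechanism of ``target``.

    Little's chi-square runs on ``[target] + covariates``; a logistic
    regression of the missingness indicator on the (complete) covariates
    screens for MAR.  Conclusion: MCAR when the chi-square is
    non-significant and no covariate predicts missingness; MAR when some
    covariate does; otherwise the mechanism is assumed MNAR (it cannot be
    confirmed from observed data alone).
    """
    if len(covariates) < 2:
        raise ValueError("need at least two covariates")
    cols = [target, *covariates]
    data = records[cols]
    missing = data[target].isna()
    if missing.all():
        raise ValueError(f"column {target!r} is entirely missing")
    if not missing.any():
        return MissingnessReport(
            target=target,
            mcar_statistic=0.0,
            mcar_df=1,
            mcar_p=1.0,
            mar_logit_coefficients={},
            conclusion="MCAR",
            alpha=alpha,
            n_missing=0,
            n_total=len(data),
        )
    stat, df, pval = little_mcar_test(data)

    x = _as_numeric(records[list(covariates)])
    keep = x.notna().all(axis=1)
    x = sm.add_constant(x[keep], has_constant="add")
    ind = missing[keep].astype(float)
    logit_coefs: dict[str, tuple[float, float]] = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(ind, x).fit(disp=0, maxiter=200)
        for name in covariates:
            logit_coefs[name] = (float(fit.params[name]), float(fit.pvalues[name]))
    except Exception:  # perfect separation or singular design: flag, don't abort
        logit_coefs = {name: (np.nan, np.nan) for name in covariates}

    logit_ps = [p for _, p in logit_coefs.values() if np.isfinite(p)]
    if pval >= alpha and all(p >= alpha for p in logit_ps):
        conclusion: Conclusion = "MCAR"
    elif any(p < alpha for p in logit_ps):
        conclusion = "MAR"
    else:
        conclusion = "MNAR_assumed"
    return MissingnessReport(
        target=target,
        mcar_statistic=stat,
        mcar_df=df,
        mcar_p=pval,
        mar_logit_coefficients=logit_coefs,
        conclusion=conclusion,
        alpha=alpha,
        n_missing=int(missing.sum()),
        n_total=len(data),
    )


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


@dataclass
class ImputationResult:
    """Completed records plus the per-imputation audit trail."""

    completed: pd.DataFrame
    imputations: pd.DataFrame  # rows = originally-missing index, cols = imp_1..m
    trace: list[float]  # completed-column mean after each imputation
    dropped_predictors: list[str] = field(default_factory=list)


def impute_treatment(
    records: pd.DataFrame,
    m: int = 5,
    iterations: int = 10,
    seed: int = 0,
    target: str = rc.COST_TREATMENT,
    predictors: Sequence[str] | None = None,
    k_pmm: int = 5,
) -> ImputationResult:
    """Complete ``target`` by chained equations with PMM draws.

    ``m`` completed datasets are produced (``iterations`` Gibbs sweeps
    between draws, k=5 donor pool); the released point value for each
    originally-missing cell is the mean across imputations.  Observed cells
    are never altered.  Deterministic under ``seed``.
    """
    if predictors is None:
        predictors = [
            c
            for c in (
                rc.SEVERITY,
                rc.AGE_GROUP,
                rc.EMPLOYMENT,
                rc.COST_MEDICAL_SERVICES,
                rc.COST_ASSOCIATED,
                rc.DAYS_MISSED,
            )
            if c in records.columns
        ]
    missing_mask = records[target].isna()
    if not missing_mask.any():
        return ImputationResult(
            completed=records.copy(),
            imputations=pd.DataFrame(index=records.index[missing_mask]),
            trace=[float(records[target].mean())],
        )
    if missing_mask.all():
        raise ValueError(f"column {target!r} has no observed entries to learn from")

    frame = _as_numeric(records[[target, *predictors]])
    dropped = [c for c in predictors if frame[c].nunique(dropna=True) <= 1]
    if dropped:
        warnings.warn(f"dropping zero-variance predictors: {dropped}", stacklevel=2)
        frame = frame.drop(columns=dropped)

    np.random.seed(seed % (2**31))  # MICEData draws from the global numpy state
    frame = frame.reset_index(drop=True)
    md = MICEData(frame, k_pmm=k_pmm)
    md.set_imputer(target, k_pmm=k_pmm)

    miss_idx = records.index[missing_mask]
    draws = np.empty((missing_mask.sum(), m))
    trace: list[float] = []
    for j in range(m):
        md.update_all(iterations)
        col = md.data[target].to_numpy()
        draws[:, j] = col[missing_mask.to_numpy()]
        trace.append(float(col.mean()))

    completed = records.copy()
    completed.loc[miss_idx, target] = draws.mean(axis=1)
    imputations = pd.DataFrame(
        draws, index=miss_idx, columns=[f"imp_{j + 1}" for j in range(m)]
    )
    return ImputationResult(
        completed=completed, imputations=imputations, trace=trace, dropped_predictors=dropped
    )


# ---------------------------------------------------------------------------
# per-severity input averages
# ---------------------------------------------------------------------------


@dataclass
class SeverityAverages:
    """Per-severity per-patient annual input averages (EUR, days).

    ``cost_medical_services`` is None for the pediatric segment, whose
    survey does not collect that category.  Employment shares are fractions
    of the severity stratum; mean missed days are per worker of the class.
    """

    segment: Segment
    n: tuple[int, int, int]
    cost_treatment: tuple[float, float, float]
    cost_medical_services: tuple[float, float, float] | None
    cost_associated: tuple[float, float, float]
    employment_share_full_time: tuple[float, float, float]
    employment_share_part_time: tuple[float, float, float]
    days_missed_full_time: tuple[float, float, float]
    days_missed_part_time: tuple[float, float, float]
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "segment": self.segment,
            "n": list(self.n),
            "cost_treatment": list(self.cost_treatment),
            "cost_medical_services": (
                None if self.cost_medical_services is None else list(self.cost_medical_services)
            ),
            "cost_associated": list(self.cost_associated),
            "employment_share_full_time": list(self.employment_share_full_time),
            "employment_share_part_time": list(self.employment_share_part_time),
            "days_missed_full_time": list(self.days_missed_full_time),
            "days_missed_part_time": list(self.days_missed_part_time),
            "flags": self.flags,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SeverityAverages":
        return cls(
            segment=d["segment"],
            n=tuple(d["n"]),
            cost_treatment=tuple(d["cost_treatment"]),
            cost_medical_services=(
                None
                if d.get("cost_medical_services") is None
                else tuple(d["cost_medical_services"])
            ),
            cost_associated=tuple(d["cost_associated"]),
            employment_share_full_time=tuple(d["employment_share_full_time"]),
            employment_share_part_time=tuple(d["employment_share_part_time"]),
            days_missed_full_time=tuple(d["days_missed_full_time"]),
            days_missed_part_time=tuple(d["days_missed_part_time"]),
            flags=list(d.get("flags", [])),
        )


def severity_averages(records: pd.DataFrame, segment: Segment) -> SeverityAverages:
    """Arithmetic per-severity means of the completed survey table.

    Empty strata yield zero means with a flag (the costing engine then
    contributes nothing for them); a warning is emitted so silent zeros
    cannot slip through a pipeline run.
    """
    flags: list[str] = []

    def stratum(sev: str) -> pd.DataFrame:
        return records[records[rc.SEVERITY] == sev]

    def mean_of(df: pd.DataFrame, col: str) -> float:
        if col not in df.columns or df[col].dropna().empty:
            return 0.0
        return float(df[col].mean())

    n, c_tr, c_ms, c_as = [], [], [], []
    sh_ft, sh_pt, d_ft, d_pt = [], [], [], []
    has_medical = rc.COST_MEDICAL_SERVICES in records.columns
    for sev in SEVERITIES:
        df = stratum(sev)
        n.append(len(df))
        if df.empty:
            flags.append(f"empty stratum: {sev}")
            warnings.warn(f"severity stratum {sev!r} is empty; means set to 0", stacklevel=2)
            for acc in (c_tr, c_ms, c_as, sh_ft, sh_pt, d_ft, d_pt):
                acc.append(0.0)
            continue
        c_tr.append(mean_of(df, rc.COST_TREATMENT))
        c_ms.append(mean_of(df, rc.COST_MEDICAL_SERVICES))
        c_as.append(mean_of(df, rc.COST_ASSOCIATED))
        for cls, share_acc, days_acc in (
            ("full_time", sh_ft, d_ft),
            ("part_time", sh_pt, d_pt),
        ):
            workers = df[df[rc.EMPLOYMENT] == cls]
            share_acc.append(len(workers) / len(df))
            days_acc.append(mean_of(workers, rc.DAYS_MISSED))
    return SeverityAverages(
        segment=segment,
        n=tuple(n),
        cost_treatment=tuple(c_tr),
        cost_medical_services=tuple(c_ms) if has_medical else None,
        cost_associated=tuple(c_as),
        employment_share_full_time=tuple(sh_ft),
        employment_share_part_time=tuple(sh_pt),
        days_missed_full_time=tuple(d_ft),
        days_missed_part_time=tuple(d_pt),
        flags=flags,
    )


# pytest must not collect the MCAR diagnosis operation as a test
test_mcar.__test__ = False  # type: ignore[attr-defined]
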