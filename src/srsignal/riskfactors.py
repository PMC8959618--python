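"""Logistic model of serious vs non-serious reports.

The unit of analysis is the report. Factors are dummy-coded against fixed
references (male, age 18-35, spring, typical class, hospital level 1,
general hospital, single disease, non-polypharmacy); records missing any
modeled covariate are excluded complete-case and counted. Estimates are
maximum-likelihood with Wald CIs and p-values, plus a likelihood-ratio test
per factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .preprocess import derive_covariates
from .records import ADRReport, DrugDictionary, Sex


class ModelFitError(RuntimeError):
    """Degenerate input or a fit that did not converge."""


#: factor -> (reference level, non-reference levels in output order)
FACTOR_LEVELS: dict[str, tuple[str, list[str]]] = {
    "sex": ("male", ["female"]),
    "age_bin": ("18-35", ["<18", "35-65", ">=65"]),
    "season": ("spring", ["summer", "autumn", "winter"]),
    "apd_class": ("typical", ["atypical"]),
    "hospital_level": ("1", ["2", "3"]),
    "hospital_type": ("general", ["psychiatric"]),
    "multiple_disease": ("single", ["multiple"]),
    "polypharmacy": ("no", ["yes"]),
}


@dataclass
class DesignInfo:
    X: pd.DataFrame  # includes "const"
    y: pd.Series
    n_used: int
    n_excluded_missing: int
    dropped_factors: list[str]
    factor_columns: dict[str, list[str]]  # factor -> dummy column names kept


def _covariate_frame(
    reports: Sequence[ADRReport], drug_dict: DrugDictionary
) -> pd.DataFrame:
    rows = []
    for report in reports:
        cov = derive_covariates(report, drug_dict)
        rows.append(
            {
                "serious": int(report.serious),
                "sex": None if cov.sex is Sex.UNKNOWN else cov.sex.value,
                "age_bin": cov.age_bin,
                "season": cov.season.value,
                "apd_class": None if cov.apd_class is None else cov.apd_class.value,
                "hospital_level": str(cov.hospital_level),
                "hospital_type": cov.hospital_type,
                "multiple_disease": "multiple" if cov.multiple_disease else "single",
                "polypharmacy": "yes" if cov.polypharmacy else "no",
            }
        )
    return pd.DataFrame(rows)


def encode_design(
    reports: Sequence[ADRReport], drug_dict: DrugDictionary
) -> DesignInfo:
    """Dummy-code the modeled factors against their fixed reference levels.

    Factors with a single observed level (after complete-case filtering) are
    dropped with a warning rather than producing a rank-deficient design.
    """
    frame = _covariate_frame(reports, drug_dict)
    complete = frame.dropna()
    n_excluded = len(frame) - len(complete)

    columns: dict[str, np.ndarray] = {}
    factor_columns: dict[str, list[str]] = {}
    dropped: list[str] = []
    for factor, (reference, levels) in FACTOR_LEVELS.items():
        observed = set(complete[factor].unique())
        if len(observed) < 2:
            dropped.append(factor)
            warnings.warn(
                f"factor {factor!r} has a single observed level; dropped",
                stacklevel=2,
            )
            continue
        kept = []
        for level in levels:
            if level not in observed:
                continue
            name = f"{factor}[{level}]"
            columns[name] = (complete[factor] == level).to_numpy(dtype=float)
            kept.append(name)
        factor_columns[factor] = kept
    X = pd.DataFrame(columns, index=complete.index)
    X.insert(0, "const", 1.0)
    return DesignInfo(
        X=X,
        y=complete["serious"].astype(float),
        n_used=len(complete),
        n_excluded_missing=n_excluded,
        dropped_factors=dropped,
        factor_columns=factor_columns,
    )


@dataclass(frozen=True)
class RiskFactorRow:
    factor: str
    level: str
    reference: str
    coef: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class RiskFactorResult:
    rows: list[RiskFactorRow]
    factor_lr_pvalues: dict[str, float]
    n_used: int
    n_excluded_missing: int
    converged: bool
    log_likelihood: float
    dropped_factors: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "factor": r.factor,
                    "level": r.level,
                    "reference": r.reference,
                    "adjusted_or": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "factor_lr_p": self.factor_lr_pvalues.get(r.factor),
                }
                for r in self.rows
            ]
        )


def _fit_logit(X: pd.DataFrame, y: pd.Series):
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", False):
        raise ModelFitError("logistic fit did not converge")
    return fit


def fit_serious_model(
    design: DesignInfo, z: float = 1.96, lr_tests: bool = True
) -> RiskFactorResult:
    """Fit the seriousness model and report adjusted ORs with Wald 95% CIs.

    With ``lr_tests`` a likelihood-ratio p-value per factor is also computed
    (full model vs the model with that factor's columns removed).
    """
    y = design.y
    if y.nunique() < 2:
        raise ModelFitError("outcome has a single class; cannot fit")
    if len(y) == 0:
        raise ModelFitError("no complete-case records to fit")
    fit = _fit_logit(design.X, y)

    rows: list[RiskFactorRow] = []
    for factor, (reference, _) in FACTOR_LEVELS.items():
        for name in design.factor_columns.get(factor, []):
            level = name[name.index("[") + 1 : -1]
            coef = float(fit.params[name])
            se = float(fit.bse[name])
            rows.append(
                RiskFactorRow(
                    factor=factor,
                    level=level,
                    reference=reference,
                    coef=coef,
                    odds_ratio=float(np.exp(coef)),
                    ci_low=float(np.exp(coef - z * se)),
                    ci_high=float(np.exp(coef + z * se)),
                    p_value=float(fit.pvalues[name]),
                )
            )

    lr_pvalues: dict[str, float] = {}
    for factor, cols in design.factor_columns.items() if lr_tests else []:
        reduced_cols = [c for c in design.X.columns if c not in cols]
        reduced_fit = _fit_logit(design.X[reduced_cols], y)
        lr = 2 * (fit.llf - reduced_fit.llf)
        lr_pvalues[factor] = float(stats.chi2.sf(max(lr, 0.0), df=len(cols)))

    return RiskFactorResult(
        rows=rows,
        factor_lr_pvalues=lr_pvalues,
        n_used=design.n_used,
        n_excluded_missing=design.n_excluded_missing,
        converged=True,
        log_likelihood=float(fit.llf),
        dropped_factors=design.dropped_factors,
    )


def risk_factor_table(
    reports: Sequence[ADRReport], drug_dict: DrugDictionary
) -> RiskFactorResult:
    """Convenience wrapper: encode the design and fit in one step."""
    return fit_serious_model(encode_design(reports, drug_dict))
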