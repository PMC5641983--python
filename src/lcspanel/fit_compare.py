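"""Fit statistics, information criteria, Akaike weights and invariance tests.

The likelihood-ratio chi-square against the saturated model, RMSEA with its
noncentral-chi-square confidence interval, CFI against an independence
baseline, and SRMR over the covariance residuals follow the standard SEM
definitions.  Model comparison uses AIC/BIC and Akaike weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2), the normalized relative
likelihood of each model being the best of the candidate set.

Conventions (documented for reproducibility): RMSEA uses the df*N
denominator; k in AIC/BIC counts all free parameters including means and
variances, and N in BIC is the number of subjects; the CFI baseline frees
all means and variances and fixes every covariance to zero; SRMR excludes
mean residuals and standardizes each covariance residual by the sample
standard deviations of its pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .estimation import (
    BaselineResult,
    FitOptions,
    FitResult,
    PanelDataset,
    SaturatedResult,
    baseline_fit,
    fit_model,
    saturated_fit,
)
from .model_core import model_df

__all__ = [
    "FitIndices",
    "ComparisonTable",
    "chi_square",
    "rmsea_with_ci",
    "cfi",
    "srmr",
    "information_criteria",
    "akaike_weights",
    "evidence_ratios",
    "lr_test",
    "fit_indices",
    "compare_models",
    "invariance_sequence",
]


class ChiSquare(NamedTuple):
    T: float
    df: int
    p: float


class LrTest(NamedTuple):
    delta_T: float
    delta_df: int
    p: float


@dataclass
class FitIndices:
    """Per-model fit statistics in the layout of a standard SEM fit table."""

    T: float
    df: int
    p: float
    rmsea: float
    rmsea_lo: float
    rmsea_hi: float
    cfi: float
    srmr: float
    aic: float
    bic: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def chi_square(model_fit: FitResult, saturated: SaturatedResult) -> ChiSquare:
    """Likelihood-ratio statistic of a model against the saturated fit."""
    if len(saturated.mu) != len(model_fit.spec.variables.observed):
        raise ValueError(
            "saturated fit covers a different observed-variable set than the model"
        )
    T = 2.0 * (saturated.loglik - model_fit.loglik)
    if T < -1e-6:
        raise RuntimeError(
            f"model log-likelihood exceeds the saturated one by {-T/2:.3g}: "
            "optimizer inconsistency"
        )
    T = max(T, 0.0)
    df = model_df(model_fit.spec)
    p = float(stats.chi2.sf(T, df)) if df > 0 else 1.0
    return ChiSquare(float(T), df, p)


def _ncp_root(T: float, df: int, q: float, lo: float, hi: float) -> float:
    """Noncentrality lambda with ncx2.cdf(T, df, lambda) == q."""
    f = lambda lam: stats.ncx2.cdf(T, df, lam) - q
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e8:
            break
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def rmsea_with_ci(T: float, df: int, n: int, level: float = 0.90):
    """RMSEA point estimate and confidence interval.

    point = sqrt(max(T - df, 0) / (df * N)); the interval inverts the
    noncentral chi-square distribution of T (lower bound: noncentrality with
    upper tail (1+level)/2 at T; upper: with (1-level)/2), each mapped
    through sqrt(lambda / (df * N)) and clipped at zero.
    """
    if df < 1:
        raise ValueError("RMSEA undefined for df = 0")
    if n < 2:
        raise ValueError("RMSEA needs N >= 2")
    point = float(np.sqrt(max(T - df, 0.0) / (df * n)))
    q_lo = 0.5 + level / 2.0
    q_hi = 0.5 - level / 2.0
    lam_lo = 0.0 if stats.chi2.cdf(T, df) <= q_lo else _ncp_root(T, df, q_lo, 0.0, max(T, 1.0))
    lam_hi = 0.0 if stats.chi2.cdf(T, df) <= q_hi else _ncp_root(T, df, q_hi, 0.0, max(4 * T, 1.0))
    lo = float(np.sqrt(lam_lo / (df * n)))
    hi = float(np.sqrt(lam_hi / (df * n)))
    return point, lo, hi


def cfi(T: float, df: int, T_baseline: float, df_baseline: int) -> float:
    """Comparative fit index, capped into [0, 1].

    1 - max(T - df, 0) / max(T_b - df_b, T - df, 0); when the baseline
    noncentrality does not exceed the model's, the index degenerates to 0
    (with a warning) or to 1 when the model itself fits (T <= df).
    """
    num = max(T - df, 0.0)
    den = max(T_baseline - df_baseline, num, 0.0)
    if den == 0.0:
        return 1.0
    if T_baseline - df_baseline < num:
        warnings.warn("baseline fits no worse than the model; CFI degenerates", RuntimeWarning)
    return float(min(max(1.0 - num / den, 0.0), 1.0))


def srmr(sample_mu, sample_sigma, implied_mu, implied_sigma) -> float:
    """Standardized root-mean-square residual over unique covariance cells.

    Residuals of the p(p+1)/2 unique cells of (sample - implied) covariance,
    each standardized by sqrt(s_ii * s_jj) of the sample moments; the mean
    structure is excluded.  Sample moments should be the saturated-fit FIML
    estimates so the index remains defined under missingness.
    """
    S = np.asarray(sample_sigma, dtype=float)
    C = np.asarray(implied_sigma, dtype=float)
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        raise ValueError("degenerate variable: zero sample variance")
    R = (S - C) / np.outer(d, d)
    iu = np.triu_indices_from(R)
    return float(np.sqrt(np.mean(R[iu] ** 2)))


def information_criteria(fit, n: int | None = None) -> tuple[float, float]:
    """AIC and BIC: -2 loglik + 2k and -2 loglik + k ln(N).

    ``fit`` is anything exposing ``loglik`` and ``n_free`` (model, saturated
    or baseline results); N defaults to the fit's subject count.
    """
    n = n if n is not None else fit.n_subjects
    k = fit.n_free
    aic = -2.0 * fit.loglik + 2.0 * k
    bic = -2.0 * fit.loglik + k * np.log(n)
    return float(aic), float(bic)


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights of a candidate set (overflow-safe, sum to 1)."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0:
        raise ValueError("empty model set")
    delta = aics - aics.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def evidence_ratios(aics: Sequence[float]) -> np.ndarray:
    """Evidence ratio of the best model against each candidate: exp(Delta_i / 2)."""
    aics = np.asarray(aics, dtype=float)
    return np.exp(0.5 * (aics - aics.min()))


def lr_test(general: FitResult, restricted: FitResult) -> LrTest:
    """Likelihood-ratio test of a restricted model nested in a general one."""
    delta_df = general.n_free - restricted.n_free
    if delta_df <= 0:
        raise ValueError("not a nested pair: the general model must free more parameters")
    delta_T = 2.0 * (general.loglik - restricted.loglik)
    if delta_T < -1e-6:
        raise RuntimeError("restricted model fits better than the general one")
    delta_T = max(delta_T, 0.0)
    return LrTest(float(delta_T), delta_df, float(stats.chi2.sf(delta_T, delta_df)))


def fit_indices(
    fit: FitResult,
    saturated: SaturatedResult,
    baseline: BaselineResult,
) -> FitIndices:
    """All fit statistics of one model against shared reference fits."""
    T, df, p = chi_square(fit, saturated)
    T_b = max(2.0 * (saturated.loglik - baseline.loglik), 0.0)
    p_obs = len(saturated.mu)
    df_b = p_obs * (p_obs + 3) // 2 - baseline.n_free
    point, lo, hi = rmsea_with_ci(T, df, fit.n_subjects)
    mu_i, sigma_i = fit.implied_moments()
    return FitIndices(
        T=T,
        df=df,
        p=p,
        rmsea=point,
        rmsea_lo=lo,
        rmsea_hi=hi,
        cfi=cfi(T, df, T_b, df_b),
        srmr=srmr(saturated.mu, saturated.sigma, mu_i, sigma_i),
        aic=information_criteria(fit)[0],
        bic=information_criteria(fit)[1],
    )


@dataclass
class ComparisonTable:
    """Cross-model AIC/BIC summary with Akaike weights."""

    frame: pd.DataFrame

    @classmethod
    def from_fits(cls, fits: dict[str, FitResult]) -> "ComparisonTable":
        names = list(fits)
        aic = np.array([information_criteria(fits[m])[0] for m in names])
        bic = np.array([information_criteria(fits[m])[1] for m in names])
        w = akaike_weights(aic)
        frame = pd.DataFrame(
            {
                "model": names,
                "k": [fits[m].n_free for m in names],
                "loglik": [fits[m].loglik for m in names],
                "aic": aic,
                "bic": bic,
                "delta_aic": aic - aic.min(),
                "weight": w,
                "evidence_ratio": evidence_ratios(aic),
            }
        ).sort_values("aic", ignore_index=True)
        return cls(frame)

    @property
    def best(self) -> str:
        return str(self.frame.iloc[0]["model"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def compare_models(
    fits: dict[str, FitResult],
    saturated: SaturatedResult,
    baseline: BaselineResult,
) -> tuple[ComparisonTable, pd.DataFrame]:
    """Comparison table plus per-model fit-index table for a candidate set."""
    table = ComparisonTable.from_fits(fits)
    rows = []
    for name, fit in fits.items():
        idx = fit_indices(fit, saturated, baseline)
        rows.append({"model": name, **idx.as_dict()})
    return table, pd.DataFrame(rows)


def invariance_sequence(
    data: PanelDataset,
    levels: Sequence[str] = ("configural", "weak", "strong"),
    threshold: float = 0.01,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Longitudinal measurement-invariance sequence for the g-factor family.

    Fits the common-factor model with cumulative cross-wave equality
    constraints (weak: loadings; strong: loadings and intercepts) and
    reports the CFI drop between consecutive levels; a level passes when
    Delta CFI does not exceed ``threshold``.  Non-convergence at a level is
    flagged and the sequence continues.
    """
    from .theory_models import build_g_model

    options = options or FitOptions()
    sat = saturated_fit(data)
    base = baseline_fit(data)
    records = []
    prev_cfi = None
    for level in levels:
        spec = build_g_model(invariance=level)
        fit = fit_model(spec, data, options)
        idx = fit_indices(fit, sat, base)
        delta = np.nan if prev_cfi is None else prev_cfi - idx.cfi
        records.append(
            {
                "level": level,
                "converged": fit.converged,
                **idx.as_dict(),
                "delta_cfi": delta,
                "pass": bool(delta <= threshold) if np.isfinite(delta) else True,
            }
        )
        if fit.converged:
            prev_cfi = idx.cfi
        else:
            prev_cfi = idx.cfi  # flagged above; keep the sequence going
    return pd.DataFrame(records)
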