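"""Causal-effect estimators for two-sample summary-data MR.

Given allele-aligned per-SNP effects (gamma_j on the exposure, Gamma_j on the
outcome, with standard errors), the causal log-odds effect of the exposure is
estimated by:

* the per-SNP Wald ratio Gamma_j / gamma_j,
* the inverse-variance weighted (IVW) estimator — a weighted regression of
  Gamma on gamma through the origin with weights 1/se_Gamma^2; the default
  "multiplicative random effects" mode inflates the standard error by the
  residual scale sqrt(Q/(J-1)) when it exceeds 1,
* MR-Egger — the same weighted regression with a free intercept, fitted after
  orienting all gamma_j >= 0; the intercept estimates directional pleiotropy
  and the slope is a pleiotropy-robust causal estimate under InSIDE.

IVW p-values use the normal reference; Egger p-values use t with J-2 degrees
of freedom.  Effects are reported as odds ratios with Wald confidence
intervals, OR = exp(beta -/+ z * se).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .errors import DegenerateInstrumentError, DomainError, InsufficientInstrumentsError
from .summary_io import HarmonizedSet

_MIN_P = 5e-324  # keep p in (0, 1] even when the tail probability underflows

Method = Literal["wald", "ivw_fe", "ivw_mre", "egger_slope", "egger_intercept"]


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal estimate for an exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    method: Method
    nsnp: int
    beta: float
    se: float
    pvalue: float
    or_point: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95

    def __post_init__(self):
        if not self.se > 0:
            raise DomainError("MREstimate.se must be > 0")
        if not self.ci_low <= self.or_point <= self.ci_high:
            raise DomainError("CI must bracket the point estimate")


def normal_pvalue(beta: float, se: float) -> float:
    """Two-sided normal-tail p-value for beta/se (the IVW reference)."""
    if not se > 0:
        raise DomainError("se must be > 0")
    return max(float(2.0 * stats.norm.sf(abs(beta) / se)), _MIN_P)


def t_pvalue(beta: float, se: float, df: int) -> float:
    """Two-sided t-tail p-value for beta/se (the MR-Egger reference, df=J-2)."""
    if not se > 0:
        raise DomainError("se must be > 0")
    if df < 1:
        raise DomainError("df must be >= 1")
    return max(float(2.0 * stats.t.sf(abs(beta) / se, df)), _MIN_P)


def beta_to_or(beta: float, se: float, level: float = 0.95
               ) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect into (OR, CI low, CI high)."""
    if not se > 0:
        raise DomainError("se must be > 0")
    if not 0 < level < 1:
        raise DomainError("level must be in (0, 1)")
    z = stats.norm.ppf((1 + level) / 2)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def _estimate(h: HarmonizedSet, method: Method, nsnp: int, beta: float,
              se: float, pvalue: float, level: float) -> MREstimate:
    orp, lo, hi = beta_to_or(beta, se, level)
    return MREstimate(exposure_id=h.exposure_id, outcome_id=h.outcome_id,
                      method=method, nsnp=nsnp, beta=float(beta), se=float(se),
                      pvalue=max(float(pvalue), _MIN_P), or_point=orp,
                      ci_low=lo, ci_high=hi, ci_level=level)


def wald_ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP causal estimates beta_j = Gamma_j/gamma_j, se_j = se_Gamma_j/|gamma_j|.

    The first-order (NOME) approximation ignores uncertainty in gamma.
    """
    if np.any(h.gamma == 0):
        bad = h.snps[int(np.flatnonzero(h.gamma == 0)[0])]
        raise DegenerateInstrumentError(
            f"{bad.rsid}: exposure effect is exactly 0; Wald ratio undefined")
    return h.Gamma / h.gamma, h.se_Gamma / np.abs(h.gamma)


def ivw(h: HarmonizedSet, mode: Literal["fixed", "mre"] = "mre",
        ci_level: float = 0.95) -> MREstimate:
    """Inverse-variance weighted causal estimate.

    ``mode="fixed"`` uses the analytic fixed-effect SE; ``mode="mre"``
    (multiplicative random effects, the default) multiplies it by the
    residual scale sqrt(Q/(J-1)) floored at 1, absorbing between-SNP
    heterogeneity.  p-value from the two-sided normal tail.
    """
    j = h.nsnp
    minimum = 1 if mode == "fixed" else 2
    if j < minimum:
        raise InsufficientInstrumentsError(minimum, j, f"IVW ({mode})")
    w = 1.0 / h.se_Gamma**2
    swg2 = float(np.sum(w * h.gamma**2))
    beta = float(np.sum(w * h.gamma * h.Gamma)) / swg2
    se = math.sqrt(1.0 / swg2)
    if mode == "mre" and j >= 2:
        q = float(np.sum(w * (h.Gamma - beta * h.gamma) ** 2))
        se *= max(1.0, math.sqrt(q / (j - 1)))
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return _estimate(h, "ivw_fe" if mode == "fixed" else "ivw_mre",
                     j, beta, se, p, ci_level)


def egger(h: HarmonizedSet, ci_level: float = 0.95
          ) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted LS of Gamma on gamma with intercept.

    All gamma are oriented non-negative first (jointly flipping the sign of
    (gamma_j, Gamma_j) where gamma_j < 0) so the intercept is identified
    under allele recoding.  Standard errors are scaled by the residual scale
    max(1, sqrt(RSS_w/(J-2))); p-values are two-sided t(J-2).

    Returns (slope estimate, intercept estimate).
    """
    j = h.nsnp
    if j < 3:
        raise InsufficientInstrumentsError(3, j, "MR-Egger")
    sign = np.where(h.gamma < 0, -1.0, 1.0)
    g = sign * h.gamma
    G = sign * h.Gamma
    w = 1.0 / h.se_Gamma**2

    # closed-form 2x2 weighted normal equations
    sw, swg, swg2 = np.sum(w), np.sum(w * g), np.sum(w * g**2)
    swG, swgG = np.sum(w * G), np.sum(w * g * G)
    xtwx = np.array([[sw, swg], [swg, swg2]])
    coef = np.linalg.solve(xtwx, np.array([swG, swgG]))
    alpha, beta = float(coef[0]), float(coef[1])

    resid = G - alpha - beta * g
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (j - 2)))
    cov = np.linalg.inv(xtwx) * scale**2
    se_alpha, se_beta = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])

    df = j - 2
    p_beta = 2.0 * stats.t.sf(abs(beta) / se_beta, df)
    p_alpha = 2.0 * stats.t.sf(abs(alpha) / se_alpha, df)
    return (
        _estimate(h, "egger_slope", j, beta, se_beta, p_beta, ci_level),
        _estimate(h, "egger_intercept", j, alpha, se_alpha, p_alpha, ci_level),
    )
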