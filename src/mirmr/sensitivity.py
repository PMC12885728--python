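"""Heterogeneity, pleiotropy and stability diagnostics for a fitted pair.

Three checks accompany every headline IVW estimate: Cochran's Q against the
fixed-effect IVW fit (chi-square with J-1 df under homogeneity), the MR-Egger
intercept test for directional horizontal pleiotropy (t with J-2 df), and a
leave-one-out scan refitting IVW with each SNP excluded in turn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .mr_core import MREstimate, egger, ivw
from .summary_io import HarmonizedSet, VariantKey


def q_pvalue(q_stat: float, df: int) -> float:
    """Upper-tail chi-square probability for a Cochran Q statistic."""
    return float(stats.chi2.sf(q_stat, df))


def cochran_q(h: HarmonizedSet, beta_ivw: float | None = None
              ) -> tuple[float, int, float]:
    """Cochran's Q for heterogeneity around the IVW line.

    Q = sum_j (Gamma_j - beta*gamma_j)^2 / se_Gamma_j^2 with df = J-1 and an
    upper-tail chi-square p-value.  ``beta_ivw`` defaults to the fixed-effect
    IVW estimate (the estimator Q is derived from).
    """
    if h.nsnp < 2:
        raise InsufficientInstrumentsError(2, h.nsnp, "Cochran Q")
    if beta_ivw is None:
        beta_ivw = ivw(h, mode="fixed").beta
    q = float(np.sum((h.Gamma - beta_ivw * h.gamma) ** 2 / h.se_Gamma**2))
    df = h.nsnp - 1
    return q, df, q_pvalue(q, df)


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """MR-Egger intercept (directional pleiotropy): (estimate, se, p).

    An intercept near zero with p > .05 is consistent with no directional
    pleiotropy bias.
    """
    _, intercept = egger(h)
    return intercept.beta, intercept.se, intercept.pvalue


def leave_one_out(h: HarmonizedSet, mode: Literal["fixed", "mre"] = "mre"
                  ) -> list[tuple[VariantKey, MREstimate]]:
    """IVW refit excluding each SNP in turn, in the HarmonizedSet's order."""
    if h.nsnp < 3:
        raise InsufficientInstrumentsError(3, h.nsnp, "leave-one-out")
    out = []
    for j, snp in enumerate(h.snps):
        mask = np.ones(h.nsnp, dtype=bool)
        mask[j] = False
        out.append((snp, ivw(h.subset(mask), mode=mode)))
    return out


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pvalue: float
    loo: list[tuple[VariantKey, MREstimate]]

    def to_row(self) -> dict:
        return {
            "Outcome": self.outcome_id,
            "Exposure": self.exposure_id,
            "Egger intercept": self.egger_intercept,
            "SE": self.egger_intercept_se,
            "P-value": self.egger_intercept_pvalue,
            "Q": self.q_stat,
            "Q_df": self.q_df,
            "Q_Pval": self.q_pvalue,
        }

    def loo_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Outcome": self.outcome_id,
                "Exposure": self.exposure_id,
                "left_out": [v.rsid for v, _ in self.loo],
                "nSNPs": [e.nsnp for _, e in self.loo],
                "Beta": [e.beta for _, e in self.loo],
                "SE": [e.se for _, e in self.loo],
                "P-value": [e.pvalue for _, e in self.loo],
            }
        )


def sensitivity_report(h: HarmonizedSet, mode: Literal["fixed", "mre"] = "mre"
                       ) -> SensitivityReport:
    """Run all three diagnostics on a harmonized set (requires J >= 3)."""
    q, df, qp = cochran_q(h)
    a, a_se, a_p = egger_intercept_test(h)
    return SensitivityReport(
        exposure_id=h.exposure_id,
        outcome_id=h.outcome_id,
        q_stat=q, q_df=df, q_pvalue=qp,
        egger_intercept=a, egger_intercept_se=a_se, egger_intercept_pvalue=a_p,
        loo=leave_one_out(h, mode=mode),
    )
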