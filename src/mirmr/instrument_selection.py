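"""Selection of valid genetic instruments from exposure summary statistics.

An eQTL SNP qualifies as an instrument when it is cis-acting, not in a coding
region (synonymous/missense consequences are excluded as a pleiotropy guard),
significant after Benjamini-Hochberg FDR correction (q < 0.1), and strong
(F = (beta/se)^2 > 10).  Instruments are then thinned to approximate linkage
independence by greedy p-value clumping (default r^2 < 0.5 within 10 kb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, DomainError
from .summary_io import ExposureRecord, HarmonizedSet, VariantKey

logger = logging.getLogger("mirmr")

#: default coding consequences excluded from the instrument set
CODING_CONSEQUENCES = frozenset({"synonymous", "missense"})


@dataclass
class InstrumentSet:
    """Post-filter instruments for one exposure, with q-values and F statistics."""

    exposure_id: str
    records: list[ExposureRecord]
    qvalues: np.ndarray
    f_stats: np.ndarray
    filter_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        j = len(self.records)
        self.qvalues = np.asarray(self.qvalues, dtype=float)
        self.f_stats = np.asarray(self.f_stats, dtype=float)
        if self.qvalues.shape != (j,) or self.f_stats.shape != (j,):
            raise AlignmentError("qvalues/f_stats misaligned with records")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": [r.variant.rsid for r in self.records],
                "chr": [r.variant.chrom for r in self.records],
                "pos": [r.variant.pos for r in self.records],
                "effect_allele": [r.variant.effect_allele for r in self.records],
                "other_allele": [r.variant.other_allele for r in self.records],
                "beta": [r.beta_gamma for r in self.records],
                "se": [r.se_gamma for r in self.records],
                "pval": [r.pvalue for r in self.records],
                "qval": self.qvalues,
                "F": self.f_stats,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR).

    q_(i) = min_{k >= i} ( m * p_(k) / k ), capped at 1, returned in the
    input order.  All p must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DomainError("bh_fdr requires a non-empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def f_statistic(beta_gamma: float, se_gamma: float) -> float:
    """Per-SNP instrument-strength F statistic, (beta/se)^2."""
    if not se_gamma > 0:
        raise DomainError("se_gamma must be > 0")
    return (beta_gamma / se_gamma) ** 2


def filter_instruments(
    records: Sequence[ExposureRecord],
    fdr_threshold: float = 0.1,
    f_threshold: float = 10.0,
    require_cis: bool = True,
    excluded_consequences: frozenset[str] | set[str] = CODING_CONSEQUENCES,
    p_threshold: float | None = None,
    use_fdr: bool = True,
) -> InstrumentSet:
    """Apply the instrument filters in order: cis, consequence, FDR, F.

    The cis and consequence filters only act when the corresponding
    annotation is present on at least one record (validation-cohort tables
    lack them; a warning is logged and the stage passes everything through).
    ``p_threshold``/``use_fdr=False`` support cohorts whose instruments are
    pre-selected by a raw p-value cut (e.g. p < 1e-5) instead of FDR.
    """
    records = list(records)
    ids = {r.exposure_id for r in records}
    if len(ids) > 1:
        raise ConfigurationError(f"records span multiple exposures: {sorted(ids)}")
    exposure_id = next(iter(ids)) if ids else ""
    filter_log: dict[str, int] = {}

    if require_cis:
        if any(r.cis is not None for r in records):
            kept = [r for r in records if r.cis is not False]
            filter_log["cis"] = len(records) - len(kept)
            records = kept
        else:
            logger.warning("%s: no cis annotation present; cis filter skipped",
                           exposure_id)
            filter_log["cis"] = 0
    excluded = {c.lower() for c in excluded_consequences}
    if excluded:
        if any(r.consequence is not None for r in records):
            kept = [r for r in records
                    if r.consequence is None or r.consequence.lower() not in excluded]
            filter_log["consequence"] = len(records) - len(kept)
            records = kept
        else:
            logger.warning("%s: no consequence annotation present; "
                           "consequence filter skipped", exposure_id)
            filter_log["consequence"] = 0

    if records and use_fdr:
        q = bh_fdr([r.pvalue for r in records])
        keep = q < fdr_threshold
        filter_log["fdr"] = int((~keep).sum())
        records = [r for r, k in zip(records, keep) if k]
        q = q[keep]
    elif records and p_threshold is not None:
        keep = np.array([r.pvalue < p_threshold for r in records])
        filter_log["pvalue"] = int((~keep).sum())
        records = [r for r, k in zip(records, keep) if k]
        q = np.array([r.pvalue for r in records])  # no FDR family: q := p
    else:
        q = np.zeros(len(records))

    f = np.array([f_statistic(r.beta_gamma, r.se_gamma) for r in records])
    keep = f > f_threshold
    filter_log["f_stat"] = int((~keep).sum())
    records = [r for r, k in zip(records, keep) if k]
    q, f = q[keep], f[keep]

    # canonical order for order-insensitivity / reproducibility
    order = sorted(range(len(records)), key=lambda i: records[i].variant.sort_key)
    return InstrumentSet(
        exposure_id=exposure_id,
        records=[records[i] for i in order],
        qvalues=q[order] if len(order) else q,
        f_stats=f[order] if len(order) else f,
        filter_log=filter_log,
    )


def ld_clump(
    records: Sequence[ExposureRecord],
    ld_r2: Callable[[VariantKey, VariantKey], float],
    r2_threshold: float = 0.5,
    window_bp: int = 10_000,
) -> list[ExposureRecord]:
    """Greedy p-value clumping: keep each SNP unless an already-kept SNP on
    the same chromosome lies within ``window_bp`` AND has r^2 >= threshold.

    Records are visited by ascending p-value (ties broken by chrom, pos,
    rsid); the kept set is returned in (chrom, pos) order.
    """
    if window_bp < 0:
        raise ConfigurationError("window_bp must be >= 0")
    if not 0 <= r2_threshold <= 1:
        raise ConfigurationError("r2_threshold must lie in [0, 1]")
    ordered = sorted(records, key=lambda r: (r.pvalue,) + r.variant.sort_key)
    kept: list[ExposureRecord] = []
    for rec in ordered:
        v = rec.variant
        pruned = any(
            k.variant.chrom == v.chrom
            and abs(k.variant.pos - v.pos) <= window_bp
            and ld_r2(k.variant, v) >= r2_threshold
            for k in kept
        )
        if not pruned:
            kept.append(rec)
    return sorted(kept, key=lambda r: r.variant.sort_key)


def filter_outcome_significant(
    harmonized: HarmonizedSet,
    outcome_pvalues: Sequence[float] | np.ndarray | None = None,
    threshold: float = 5e-8,
) -> HarmonizedSet:
    """Drop SNPs already genome-wide significant for the outcome (p <= 5e-8).

    Such SNPs plausibly act on the disease through pathways other than the
    exposure.  ``outcome_pvalues`` defaults to the vector carried by the
    HarmonizedSet.
    """
    if outcome_pvalues is None:
        outcome_pvalues = harmonized.outcome_pvalues
    if outcome_pvalues is None:
        raise AlignmentError("no outcome p-values supplied or carried")
    p = np.asarray(outcome_pvalues, dtype=float)
    if p.shape != (harmonized.nsnp,):
        raise AlignmentError(
            f"outcome_pvalues length {p.shape} != number of SNPs {harmonized.nsnp}")
    keep = p > threshold
    dropped = [(s, "outcome genome-wide significant")
               for s, k in zip(harmonized.snps, keep) if not k]
    return harmonized.subset(keep, dropped)


# ---------------------------------------------------------------------------
# LD input: square matrix or long-format triplets
# ---------------------------------------------------------------------------

def load_ld(path: str | Path) -> Callable[[VariantKey, VariantKey], float]:
    """Load pairwise r^2 from a TSV and return a symmetric lookup function.

    Accepts either a square matrix (rsid header row and first column) or a
    long format with columns rsid_a, rsid_b, r2.  Absent pairs return 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    table: dict[frozenset, float] = {}
    if set(df.columns[:3]) >= {"rsid_a", "rsid_b", "r2"}:
        for a, b, r2 in zip(df["rsid_a"], df["rsid_b"], df["r2"]):
            table[frozenset((a, b))] = float(r2)
    else:
        rsids = list(df.columns[1:])
        for i, row in enumerate(df.itertuples(index=False)):
            for j, rs in enumerate(rsids):
                table[frozenset((row[0], rs))] = float(row[j + 1])
    missing_warned = set()

    def lookup(a: VariantKey, b: VariantKey) -> float:
        if a.rsid == b.rsid:
            return 1.0
        key = frozenset((a.rsid, b.rsid))
        if key not in table:
            if key not in missing_warned:
                missing_warned.add(key)
                logger.debug("LD unknown for pair %s; assuming r2=0", sorted(key))
            return 0.0
        return table[key]

    return lookup
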