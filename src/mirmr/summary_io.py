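"""Data model and I/O for GWAS/eQTL summary statistics, plus harmonization.

The two-sample MR workflow consumes two per-SNP association tables: an
*exposure* table (miRNA-eQTL effects, gamma) and an *outcome* table (disease
GWAS log-odds, Gamma).  This module defines the record types, reads delimited
text exports (IEU OpenGWAS column layout by default), and aligns the two
tables to a common effect allele — flipping outcome signs where the allele
pair is swapped, and dropping palindromic (A/T, C/G) and inconsistent SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, DomainError, EmptyInputError

logger = logging.getLogger("mirmr")

VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: Standard field -> column name in IEU OpenGWAS exports.
IEU_DIALECT: dict[str, str] = {
    "rsid": "SNP",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "eaf": "eaf",
    "n": "n",
    "consequence": "consequence",
    "cis": "cis",
    "id": "id",
}

_MANDATORY_FIELDS = (
    "rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue",
)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic SNP: rsID, locus, and the two alleles."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self):
        for a in (self.effect_allele, self.other_allele):
            if a not in VALID_ALLELES:
                raise DomainError(f"allele {a!r} is not a single A/C/G/T nucleotide")
        if self.effect_allele == self.other_allele:
            raise DomainError(f"{self.rsid}: effect and other allele are identical")

    @property
    def sort_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.rsid)


@dataclass(frozen=True)
class ExposureRecord:
    """Per-SNP association with a miRNA's expression level (gamma, se_gamma)."""

    variant: VariantKey
    exposure_id: str
    beta_gamma: float
    se_gamma: float
    pvalue: float
    n: int | None = None
    consequence: str | None = None
    cis: bool | None = None
    eaf: float | None = None

    def __post_init__(self):
        if not self.se_gamma > 0:
            raise DomainError(f"{self.variant.rsid}: se_gamma must be > 0")
        if not 0 < self.pvalue <= 1:
            raise DomainError(f"{self.variant.rsid}: pvalue must be in (0, 1]")


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-SNP association with the disease outcome (Gamma, se_Gamma, log-odds)."""

    variant: VariantKey
    outcome_id: str
    beta_Gamma: float
    se_Gamma: float
    pvalue: float
    eaf: float | None = None

    def __post_init__(self):
        if not self.se_Gamma > 0:
            raise DomainError(f"{self.variant.rsid}: se_Gamma must be > 0")
        if not 0 < self.pvalue <= 1:
            raise DomainError(f"{self.variant.rsid}: pvalue must be in (0, 1]")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    for a in (effect_allele, other_allele):
        if a not in VALID_ALLELES:
            raise DomainError(f"allele {a!r} is not a single A/C/G/T nucleotide")
    return frozenset((effect_allele, other_allele)) in _PALINDROMIC_PAIRS


@dataclass
class HarmonizedSet:
    """Allele-aligned per-SNP effect vectors for one exposure-outcome pair.

    All vectors share length J = len(snps).  ``flipped[j]`` records that the
    outcome effect sign was negated to put both tables on the same effect
    allele; ``dropped`` keeps the provenance of every SNP removed on the way.
    ``outcome_pvalues`` carries the outcome association p-values aligned to
    ``snps`` (used by the outcome-significance filter downstream).
    """

    exposure_id: str
    outcome_id: str
    snps: list[VariantKey]
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    flipped: np.ndarray
    dropped: list[tuple[VariantKey, str]] = field(default_factory=list)
    outcome_pvalues: np.ndarray | None = None

    def __post_init__(self):
        j = len(self.snps)
        for name in ("gamma", "se_gamma", "Gamma", "se_Gamma", "flipped"):
            v = np.asarray(getattr(self, name))
            if v.shape != (j,):
                raise AlignmentError(f"{name} has length {v.shape}, expected ({j},)")
            setattr(self, name, v)
        if self.outcome_pvalues is not None:
            self.outcome_pvalues = np.asarray(self.outcome_pvalues, dtype=float)
            if self.outcome_pvalues.shape != (j,):
                raise AlignmentError("outcome_pvalues misaligned with snps")

    @property
    def nsnp(self) -> int:
        return len(self.snps)

    def subset(self, keep: np.ndarray, extra_dropped: Sequence[tuple[VariantKey, str]] = ()) -> "HarmonizedSet":
        """New HarmonizedSet restricted to boolean mask / index array ``keep``."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        snps = [self.snps[i] for i in idx]
        return HarmonizedSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            snps=snps,
            gamma=self.gamma[idx],
            se_gamma=self.se_gamma[idx],
            Gamma=self.Gamma[idx],
            se_Gamma=self.se_Gamma[idx],
            flipped=self.flipped[idx],
            dropped=list(self.dropped) + list(extra_dropped),
            outcome_pvalues=None if self.outcome_pvalues is None else self.outcome_pvalues[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [s.rsid for s in self.snps],
                "chrom": [s.chrom for s in self.snps],
                "pos": [s.pos for s in self.snps],
                "ea": [s.effect_allele for s in self.snps],
                "oa": [s.other_allele for s in self.snps],
                "gamma": self.gamma,
                "se_gamma": self.se_gamma,
                "Gamma": self.Gamma,
                "se_Gamma": self.se_Gamma,
                "flipped": self.flipped.astype(bool),
            }
        )

    def to_tsv(self, path: str | Path, drop_log: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if drop_log is not None:
            pd.DataFrame(
                {
                    "rsid": [v.rsid for v, _ in self.dropped],
                    "chrom": [v.chrom for v, _ in self.dropped],
                    "pos": [v.pos for v, _ in self.dropped],
                    "reason": [r for _, r in self.dropped],
                }
            ).to_csv(drop_log, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reading / writing summary-statistic tables
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_table(
    path: str | Path,
    role: Literal["exposure", "outcome"],
    dialect: Mapping[str, str] | None = None,
    dataset_id: str | None = None,
) -> tuple[list[ExposureRecord] | list[OutcomeRecord], list[tuple[int, str]]]:
    """Read a delimited summary-statistics table into typed records.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    role
        ``"exposure"`` yields :class:`ExposureRecord`, ``"outcome"``
        :class:`OutcomeRecord`.
    dialect
        Standard-field -> source-column mapping; defaults to the IEU OpenGWAS
        export header (:data:`IEU_DIALECT`).
    dataset_id
        Exposure/outcome identifier; falls back to an ``id`` column, then to
        the file stem.

    Returns
    -------
    (records, rejects)
        ``rejects`` is a parse report: one ``(row_index, reason)`` entry per
        rejected data row (0-based, in file order).
    """
    path = Path(path)
    mapping = dict(IEU_DIALECT)
    if dialect:
        mapping.update(dialect)
    if role not in ("exposure", "outcome"):
        raise ConfigurationError(f"role must be 'exposure' or 'outcome', got {role!r}")

    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    missing = [f for f in _MANDATORY_FIELDS if mapping[f] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing mandatory column(s) "
            + ", ".join(f"{mapping[f]} (for {f})" for f in missing)
        )

    def col(fieldname, row):
        c = mapping.get(fieldname)
        if c is None or c not in df.columns:
            return None
        v = row[c]
        return None if pd.isna(v) else v

    records: list = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        ea, oa = col("effect_allele", row), col("other_allele", row)
        try:
            if ea is None or oa is None:
                raise DomainError("missing allele")
            ea, oa = str(ea).upper(), str(oa).upper()
            if len(ea) != 1 or len(oa) != 1:
                raise DomainError("multi-nucleotide allele")
            beta, se = col("beta", row), col("se", row)
            if beta is None or se is None:
                raise DomainError("missing beta or SE")
            beta, se = float(beta), float(se)
            if not np.isfinite(beta) or not np.isfinite(se):
                raise DomainError("non-finite beta or SE")
            if se <= 0:
                raise DomainError("SE <= 0")
            pval = col("pvalue", row)
            pval = float(pval) if pval is not None else None
            if pval is None or not 0 < pval <= 1:
                raise DomainError("p-value missing or outside (0, 1]")
            vk = VariantKey(str(col("rsid", row)), str(col("chrom", row)),
                            int(float(col("pos", row))), ea, oa)
            eaf = col("eaf", row)
            eaf = float(eaf) if eaf is not None else None
            ds = dataset_id or col("id", row) or path.stem
            if role == "exposure":
                n = col("n", row)
                cis = col("cis", row)
                records.append(
                    ExposureRecord(
                        variant=vk, exposure_id=str(ds), beta_gamma=beta,
                        se_gamma=se, pvalue=pval,
                        n=int(float(n)) if n is not None else None,
                        consequence=col("consequence", row),
                        cis=None if cis is None else str(cis).lower() in ("true", "1", "yes"),
                        eaf=eaf,
                    )
                )
            else:
                records.append(
                    OutcomeRecord(variant=vk, outcome_id=str(ds), beta_Gamma=beta,
                                  se_Gamma=se, pvalue=pval, eaf=eaf)
                )
        except DomainError as exc:
            rejects.append((i, str(exc)))
    if not records:
        raise EmptyInputError(f"{path.name}: no valid rows ({len(rejects)} rejected)")
    return records, rejects


def write_summary_table(records: Sequence[ExposureRecord] | Sequence[OutcomeRecord],
                        path: str | Path) -> None:
    """Write records back to the default (IEU-layout) TSV format."""
    rows = []
    for r in records:
        v = r.variant
        base = {"SNP": v.rsid, "chr": v.chrom, "pos": v.pos,
                "effect_allele": v.effect_allele, "other_allele": v.other_allele,
                "pval": r.pvalue, "eaf": r.eaf}
        if isinstance(r, ExposureRecord):
            base.update(beta=r.beta_gamma, se=r.se_gamma, id=r.exposure_id,
                        n=r.n, consequence=r.consequence, cis=r.cis)
        else:
            base.update(beta=r.beta_Gamma, se=r.se_Gamma, id=r.outcome_id)
        rows.append(base)
    cols = ["SNP", "chr", "pos", "effect_allele", "other_allele", "beta", "se",
            "pval", "eaf", "id"] + (["n", "consequence", "cis"]
                                    if rows and "n" in rows[0] else [])
    pd.DataFrame(rows)[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _dedupe(records, dropped):
    """Keep, per rsid, the record with the smallest p-value (stable ties)."""
    best: dict[str, object] = {}
    for r in records:
        cur = best.get(r.variant.rsid)
        if cur is None or r.pvalue < cur.pvalue:
            best[r.variant.rsid] = r
    for r in records:
        if best[r.variant.rsid] is not r:
            dropped.append((r.variant, "duplicate"))
    return best


def harmonize(exposure: Sequence[ExposureRecord],
              outcome: Sequence[OutcomeRecord]) -> HarmonizedSet:
    """Align exposure and outcome effects to a common effect allele.

    SNPs are matched by rsid.  Matches with identical allele pairs are kept
    as-is; matches whose outcome alleles are swapped have Gamma negated and
    are marked ``flipped``; palindromic SNPs and inconsistent allele pairs are
    dropped with a reason.  Output is ordered by (chrom, pos, rsid) so every
    downstream statistic is bit-reproducible.
    """
    if not exposure or not outcome:
        raise EmptyInputError("harmonize requires non-empty exposure and outcome tables")
    exposure_ids = {r.exposure_id for r in exposure}
    outcome_ids = {r.outcome_id for r in outcome}
    if len(exposure_ids) != 1 or len(outcome_ids) != 1:
        raise ConfigurationError(
            f"harmonize expects one exposure and one outcome dataset, got "
            f"{sorted(exposure_ids)} / {sorted(outcome_ids)}")

    dropped: list[tuple[VariantKey, str]] = []
    exp_by_rsid = _dedupe(exposure, dropped)
    out_by_rsid = _dedupe(outcome, dropped)

    matched = sorted(
        (exp_by_rsid[rsid] for rsid in exp_by_rsid.keys() & out_by_rsid.keys()),
        key=lambda r: r.variant.sort_key,
    )

    snps, gam, seg, Gam, seG, flip, opv = [], [], [], [], [], [], []
    for er in matched:
        orec = out_by_rsid[er.variant.rsid]
        ev, ov = er.variant, orec.variant
        if ev.pos != ov.pos or ev.chrom != ov.chrom:
            logger.warning("position mismatch at %s: exposure %s:%d vs outcome %s:%d "
                           "(kept; builds differ)", ev.rsid, ev.chrom, ev.pos,
                           ov.chrom, ov.pos)
        if is_palindromic(ev.effect_allele, ev.other_allele):
            dropped.append((ev, "palindromic"))
            continue
        if (ov.effect_allele, ov.other_allele) == (ev.effect_allele, ev.other_allele):
            flipped = False
            Gval = orec.beta_Gamma
        elif (ov.effect_allele, ov.other_allele) == (ev.other_allele, ev.effect_allele):
            flipped = True
            Gval = -orec.beta_Gamma
        else:
            dropped.append((ev, "allele mismatch"))
            continue
        snps.append(ev)
        gam.append(er.beta_gamma)
        seg.append(er.se_gamma)
        Gam.append(Gval)
        seG.append(orec.se_Gamma)
        flip.append(flipped)
        opv.append(orec.pvalue)

    return HarmonizedSet(
        exposure_id=next(iter(exposure_ids)),
        outcome_id=next(iter(outcome_ids)),
        snps=snps,
        gamma=np.array(gam, dtype=float),
        se_gamma=np.array(seg, dtype=float),
        Gamma=np.array(Gam, dtype=float),
        se_Gamma=np.array(seG, dtype=float),
        flipped=np.array(flip, dtype=bool),
        dropped=dropped,
        outcome_pvalues=np.array(opv, dtype=float),
    )
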