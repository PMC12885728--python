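"""Discovery across exposures x outcomes, high-confidence criteria, replication.

A miRNA is called causal in discovery when all four criteria hold for its
IVW fit against one outcome GWAS: p < .05; Benjamini-Hochberg FDR < 0.1
across all miRNAs tested against that outcome; IVW and MR-Egger slopes agree
in sign; and at least 3 SNPs enter the fit.  A discovery call is upgraded to
high confidence only when the IVW fit re-run with instruments from an
independent validation eQTL cohort is itself significant (and, by default,
direction-consistent).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, EmptyInputError
from .instrument_selection import (bh_fdr, filter_instruments,
                                   filter_outcome_significant, ld_clump)
from .mr_core import MREstimate, egger, ivw
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_io import ExposureRecord, OutcomeRecord, VariantKey, harmonize

MIN_NSNP = 3


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and modes of the analysis, with the defaults used throughout."""

    fdr_instrument: float = 0.1     # BH q cut for discovery-cohort instruments
    fdr_decision: float = 0.1       # BH q cut across exposures per outcome
    p_causal: float = 0.05          # IVW significance for a causal call
    f_min: float = 10.0             # weak-instrument F cut
    r2_clump: float = 0.5           # LD pruning threshold
    window_bp: int = 10_000         # LD pruning window
    p_outcome_exclude: float = 5e-8  # drop outcome genome-wide significant SNPs
    p_validation_instrument: float = 1e-5  # validation-cohort instrument cut
    ivw_mode: str = "mre"           # "mre" or "fixed"
    ci_level: float = 0.95
    require_replication_direction: bool = True
    seed: int = 0                   # only used by simulation subcommands

    def validate(self) -> None:
        if self.ivw_mode not in ("mre", "fixed"):
            raise ConfigurationError(f"ivw_mode must be mre|fixed, got {self.ivw_mode!r}")
        for name in ("fdr_instrument", "fdr_decision", "p_causal",
                     "p_outcome_exclude", "p_validation_instrument", "ci_level"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        if self.window_bp < 0 or not 0 <= self.r2_clump <= 1:
            raise ConfigurationError("invalid clumping parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CausalCall:
    """Decision record for one exposure against one outcome."""

    exposure_id: str
    outcome_id: str
    ivw: MREstimate | None
    egger_slope: MREstimate | None
    egger_intercept: MREstimate | None
    sensitivity: SensitivityReport | None
    nsnp: int
    ivw_qvalue: float = float("nan")
    pass_pvalue: bool = False
    pass_fdr: bool = False
    pass_direction: bool = False
    pass_nsnp: bool = False
    discovery_pass: bool = False
    replication_pass: bool | None = None   # None = validation data unavailable
    replication_ivw: MREstimate | None = None
    high_confidence: bool = False
    harmonized_dropped: list[tuple[VariantKey, str]] = field(default_factory=list)


def _direction_consistent(a: float, b: float) -> bool:
    """Strict sign agreement; a zero estimate is inconsistent with any sign."""
    return (a > 0 and b > 0) or (a < 0 and b < 0)


def _fit_one(exp_id: str,
             exposure: Sequence[ExposureRecord],
             outcome: Sequence[OutcomeRecord],
             config: PipelineConfig) -> CausalCall:
    """Harmonize one pair, apply the outcome-significance filter, and fit."""
    out_id = outcome[0].outcome_id
    try:
        h = harmonize(exposure, outcome)
    except EmptyInputError:
        return CausalCall(exp_id, out_id, None, None, None, None, nsnp=0)
    h = filter_outcome_significant(h, threshold=config.p_outcome_exclude)
    if h.nsnp < MIN_NSNP:
        return CausalCall(exp_id, out_id, None, None, None, None,
                          nsnp=h.nsnp, harmonized_dropped=h.dropped)
    est_ivw = ivw(h, mode=config.ivw_mode, ci_level=config.ci_level)
    slope, intercept = egger(h, ci_level=config.ci_level)
    sens = sensitivity_report(h, mode=config.ivw_mode)
    return CausalCall(
        exp_id, out_id, ivw=est_ivw, egger_slope=slope,
        egger_intercept=intercept, sensitivity=sens, nsnp=h.nsnp,
        pass_pvalue=est_ivw.pvalue < config.p_causal,
        pass_direction=_direction_consistent(est_ivw.beta, slope.beta),
        pass_nsnp=True,
        harmonized_dropped=h.dropped,
    )


def run_discovery(exposures: Mapping[str, Sequence[ExposureRecord]],
                  outcome: Sequence[OutcomeRecord],
                  config: PipelineConfig = PipelineConfig()) -> list[CausalCall]:
    """Fit every exposure against one outcome and populate the decision flags.

    ``exposures`` must already be instrument-ready (filtered and clumped).
    The decision-level BH FDR family is the set of exposures actually fitted
    (those passing the nSNP gate) for this outcome.
    """
    if not exposures:
        raise ConfigurationError("run_discovery needs at least one exposure")
    calls = [_fit_one(eid, exposures[eid], outcome, config)
             for eid in sorted(exposures)]
    fitted = [c for c in calls if c.ivw is not None]
    if fitted:
        q = bh_fdr([c.ivw.pvalue for c in fitted])
        for c, qv in zip(fitted, q):
            c.ivw_qvalue = float(qv)
            c.pass_fdr = qv < config.fdr_decision
    for c in calls:
        c.discovery_pass = (c.pass_pvalue and c.pass_fdr
                            and c.pass_direction and c.pass_nsnp)
    return calls


def replicate(calls: Sequence[CausalCall],
              validation_exposures: Mapping[str, Sequence[ExposureRecord]],
              outcome: Sequence[OutcomeRecord],
              config: PipelineConfig = PipelineConfig()) -> list[CausalCall]:
    """Re-run IVW with independent validation instruments for passing calls.

    ``replication_pass`` is True when the validation IVW is significant at
    ``p_causal`` (and direction-consistent with discovery, unless disabled);
    None when the exposure is absent from the validation cohort.
    """
    out = []
    for call in calls:
        call = dataclasses.replace(call)
        if call.discovery_pass and call.exposure_id in validation_exposures:
            try:
                h = harmonize(validation_exposures[call.exposure_id], outcome)
                h = filter_outcome_significant(h, threshold=config.p_outcome_exclude)
                rep = ivw(h, mode=config.ivw_mode, ci_level=config.ci_level) \
                    if h.nsnp >= 2 else None
            except EmptyInputError:
                rep = None
            call.replication_ivw = rep
            if rep is None:
                call.replication_pass = None
            else:
                ok = rep.pvalue < config.p_causal
                if config.require_replication_direction:
                    ok = ok and _direction_consistent(rep.beta, call.ivw.beta)
                call.replication_pass = ok
        call.high_confidence = bool(call.discovery_pass
                                    and call.replication_pass is True)
        out.append(call)
    return out


def intersect_causal(calls_by_outcome: Mapping[str, Sequence[CausalCall]]
                     ) -> tuple[list[str], pd.DataFrame]:
    """Union of discovery-passing exposures across outcomes, with membership.

    Returns the sorted exposure list and a boolean DataFrame (exposure rows,
    outcome columns) flagging per-outcome discovery passes.
    """
    if not calls_by_outcome:
        raise ConfigurationError("intersect_causal needs at least one outcome")
    passing: dict[str, dict[str, bool]] = {}
    for oid, calls in calls_by_outcome.items():
        for c in calls:
            if c.discovery_pass:
                passing.setdefault(c.exposure_id, {})[oid] = True
    exposures = sorted(passing)
    member = pd.DataFrame(
        [[passing[e].get(o, False) for o in sorted(calls_by_outcome)]
         for e in exposures],
        index=exposures, columns=sorted(calls_by_outcome), dtype=bool)
    return exposures, member


# ---------------------------------------------------------------------------
# Full analysis: instrument selection -> discovery -> replication
# ---------------------------------------------------------------------------

def prepare_instruments(raw: Mapping[str, Sequence[ExposureRecord]],
                        ld: Mapping[str, Callable[[VariantKey, VariantKey], float]] | None,
                        config: PipelineConfig,
                        validation: bool = False
                        ) -> dict[str, list[ExposureRecord]]:
    """Filter and clump each exposure's candidate SNPs into instruments.

    Discovery cohorts use the cis/consequence/FDR/F filters; validation
    cohorts use the relaxed raw p-value cut (no FDR, no annotations expected).
    """
    prepared: dict[str, list[ExposureRecord]] = {}
    for eid in sorted(raw):
        if validation:
            inst = filter_instruments(
                raw[eid], f_threshold=config.f_min, require_cis=False,
                excluded_consequences=frozenset(), use_fdr=False,
                p_threshold=config.p_validation_instrument)
        else:
            inst = filter_instruments(
                raw[eid], fdr_threshold=config.fdr_instrument,
                f_threshold=config.f_min)
        records = inst.records
        if ld is not None and eid in ld:
            records = ld_clump(records, ld[eid], r2_threshold=config.r2_clump,
                               window_bp=config.window_bp)
        prepared[eid] = records
    return prepared


def run_full_analysis(
    exposures_raw: Mapping[str, Sequence[ExposureRecord]],
    outcomes: Mapping[str, Sequence[OutcomeRecord]],
    validation_raw: Mapping[str, Sequence[ExposureRecord]] | None = None,
    ld: Mapping[str, Callable[[VariantKey, VariantKey], float]] | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, list[CausalCall]]:
    """End-to-end: select instruments, run discovery per outcome, replicate."""
    config.validate()
    prepared = prepare_instruments(exposures_raw, ld, config)
    prepared = {e: r for e, r in prepared.items() if r}
    if not prepared:
        raise EmptyInputError("no exposure retained any instrument")
    valid_prepared = (prepare_instruments(validation_raw, ld, config,
                                          validation=True)
                      if validation_raw else {})
    results: dict[str, list[CausalCall]] = {}
    for oid in sorted(outcomes):
        calls = run_discovery(prepared, outcomes[oid], config)
        if valid_prepared:
            calls = replicate(calls, valid_prepared, outcomes[oid], config)
        results[oid] = calls
    return results
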