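"""Generative model for paired exposure/outcome summary statistics.

Emulates the statistical structure the MR analysis assumes, so that every
pipeline stage is testable without cohort data.  For SNP j:

    MAF_j        ~ Uniform(maf_range)
    gamma_j      ~ Normal(gamma_mean, gamma_sd)          (true eQTL effect)
    se_gamma_j   = 1 / sqrt(2 * n_exp * MAF_j (1-MAF_j))  (standardized trait)
    gamma_hat_j  ~ Normal(gamma_j, se_gamma_j^2)
    alpha_j      = mu_alpha + tau * Z_j [+ 0.5 * gamma_j if InSIDE violated]
    se_Gamma_j   = sqrt( (1/(2 MAF_j(1-MAF_j))) * (1/n_cases + 1/n_controls) )
    Gamma_hat_j  ~ Normal(beta * gamma_j + alpha_j, se_Gamma_j^2)

p-values are two-sided normal.  Alleles are drawn uniformly with a
configurable fraction of palindromic (A/T, C/G) pairs; positions are laid on
one chromosome at fixed spacing; LD is block-constant (r^2 = ld_rho^2 within
blocks of ld_block_size, 0 across blocks).  All draws flow from one root seed
through named substreams, so adding a draw to one stream never perturbs the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ConfigurationError
from .summary_io import ExposureRecord, OutcomeRecord, VariantKey

# fixed substream indices: adding streams must append, never reorder
_STREAMS = {"maf": 0, "gamma": 1, "noise": 2, "alleles": 3, "pleiotropy": 4}

_NONPALINDROMIC = [(a, b) for a in "ACGT" for b in "ACGT"
                   if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the two-cohort generative model.

    Defaults mirror a whole-blood miRNA-eQTL discovery cohort (a few
    thousand genotyped donors) paired with a biobank-scale case-control
    breast-cancer GWAS.
    """

    n_snps: int = 30
    n_exposure: int = 5000
    n_outcome_cases: int = 35_000
    n_outcome_controls: int = 388_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_dist: tuple[float, float] = (0.3, 0.05)  # (mean, sd) of true effects
    causal_beta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False
    ld_block_size: int = 5
    ld_rho: float = 0.7
    positions_spacing_bp: int = 2000
    palindromic_frac: float = 0.1
    chrom: str = "1"
    exposure_id: str = "hsa-miR-sim"
    outcome_id: str = "sim-gwas"
    rsid_prefix: str = "rs"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if min(self.n_exposure, self.n_outcome_cases, self.n_outcome_controls) < 2:
            raise ConfigurationError("all sample sizes must be >= 2")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        if not 0 <= self.palindromic_frac <= 1:
            raise ConfigurationError("palindromic_frac must lie in [0, 1]")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        if self.ld_block_size < 1 or self.positions_spacing_bp < 1:
            raise ConfigurationError("ld_block_size and spacing must be >= 1")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    from scipy import stats
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)


@dataclass
class SimulatedTruth:
    """Latent quantities behind one simulated SNP panel (for test oracles)."""

    maf: np.ndarray
    gamma_true: np.ndarray
    alpha: np.ndarray
    variants: list[VariantKey]


def _draw_panel(config: SimulationConfig) -> SimulatedTruth:
    config.validate()
    j = config.n_snps
    maf = _rng(config, "maf").uniform(*config.maf_range, size=j)
    mean, sd = config.gamma_dist
    gamma_true = mean + sd * _rng(config, "gamma").standard_normal(j)
    prng = _rng(config, "pleiotropy")
    alpha = config.pleiotropy_mean + config.pleiotropy_sd * prng.standard_normal(j)
    if config.inside_violation:
        alpha = alpha + 0.5 * gamma_true
    arng = _rng(config, "alleles")
    pal = arng.random(j) < config.palindromic_frac
    variants = []
    for i in range(j):
        pool = _PALINDROMIC if pal[i] else _NONPALINDROMIC
        ea, oa = pool[arng.integers(len(pool))]
        variants.append(VariantKey(
            rsid=f"{config.rsid_prefix}{i + 1}",
            chrom=config.chrom,
            pos=1 + i * config.positions_spacing_bp,
            effect_allele=ea, other_allele=oa))
    return SimulatedTruth(maf=maf, gamma_true=gamma_true, alpha=alpha,
                          variants=variants)


def simulate_pair(config: SimulationConfig
                  ) -> tuple[list[ExposureRecord], list[OutcomeRecord],
                             Callable[[VariantKey, VariantKey], float]]:
    """Draw one exposure table, one outcome table, and a block-LD lookup."""
    truth = _draw_panel(config)
    return (*_observe(config, truth), make_block_ld(config))


def _observe(config: SimulationConfig, truth: SimulatedTruth,
             consequence: str | None = "intergenic", cis: bool | None = True,
             ) -> tuple[list[ExposureRecord], list[OutcomeRecord]]:
    """Generate observed summary statistics for a fixed latent panel."""
    nrng = _rng(config, "noise")
    maf, g_true = truth.maf, truth.gamma_true
    het = 2.0 * maf * (1.0 - maf)
    se_g = 1.0 / np.sqrt(config.n_exposure * het)
    g_hat = g_true + se_g * nrng.standard_normal(config.n_snps)
    se_G = np.sqrt((1.0 / het) * (1.0 / config.n_outcome_cases
                                  + 1.0 / config.n_outcome_controls))
    G_hat = (config.causal_beta * g_true + truth.alpha
             + se_G * nrng.standard_normal(config.n_snps))
    p_g = _two_sided_p(g_hat / se_g)
    p_G = _two_sided_p(G_hat / se_G)

    exposure = [
        ExposureRecord(variant=v, exposure_id=config.exposure_id,
                       beta_gamma=float(g_hat[i]), se_gamma=float(se_g[i]),
                       pvalue=float(p_g[i]), n=config.n_exposure,
                       consequence=consequence, cis=cis, eaf=float(maf[i]))
        for i, v in enumerate(truth.variants)
    ]
    outcome = [
        OutcomeRecord(variant=v, outcome_id=config.outcome_id,
                      beta_Gamma=float(G_hat[i]), se_Gamma=float(se_G[i]),
                      pvalue=float(p_G[i]), eaf=float(maf[i]))
        for i, v in enumerate(truth.variants)
    ]
    return exposure, outcome


def make_block_ld(config: SimulationConfig
                  ) -> Callable[[VariantKey, VariantKey], float]:
    """r^2 lookup: ld_rho^2 within a position block, 0 across blocks."""
    span = config.ld_block_size * config.positions_spacing_bp

    def lookup(a: VariantKey, b: VariantKey) -> float:
        if a.rsid == b.rsid:
            return 1.0
        if a.chrom != b.chrom:
            return 0.0
        if (a.pos - 1) // span == (b.pos - 1) // span:
            return config.ld_rho**2
        return 0.0

    return lookup


# ---------------------------------------------------------------------------
# Calibration studies: estimator behavior under known generative truth
# ---------------------------------------------------------------------------

def _replicate_seeds(seed: int, n_reps: int) -> np.ndarray:
    """Independent per-replicate root seeds derived from one study seed."""
    return np.random.SeedSequence(seed).generate_state(n_reps) % 2**31


def type_i_error_study(seed: int = 0, n_reps: int = 1000, n_snps: int = 30
                       ) -> float:
    """IVW rejection rate at p < .05 under the null (no effect, no pleiotropy).

    Uses the fixed-effect IVW, whose null z-score is exactly standard normal
    under this generative model, so the rate calibrates against the nominal
    5 percent level.
    """
    from .mr_core import ivw
    from .summary_io import harmonize

    rejections = 0
    for s in _replicate_seeds(seed, n_reps):
        cfg = SimulationConfig(n_snps=n_snps, causal_beta=0.0,
                               palindromic_frac=0.0, seed=int(s))
        exposure, outcome, _ = simulate_pair(cfg)
        rejections += ivw(harmonize(exposure, outcome), mode="fixed").pvalue < 0.05
    return rejections / n_reps


def ivw_recovery_study(seed: int = 0, n_reps: int = 500,
                       causal_beta: float = -0.3, n_snps: int = 50) -> float:
    """Mean IVW estimate over replicates of a no-pleiotropy causal model."""
    from .mr_core import ivw
    from .summary_io import harmonize

    betas = []
    for s in _replicate_seeds(seed, n_reps):
        cfg = SimulationConfig(n_snps=n_snps, causal_beta=causal_beta,
                               palindromic_frac=0.0, seed=int(s))
        exposure, outcome, _ = simulate_pair(cfg)
        betas.append(ivw(harmonize(exposure, outcome)).beta)
    return float(np.mean(betas))


def egger_intercept_recovery_study(seed: int = 0, n_reps: int = 500,
                                   mu_alpha: float = 0.02, n_snps: int = 100
                                   ) -> float:
    """Mean MR-Egger intercept under injected directional pleiotropy.

    The scenario uses uniformly strong, well-spread instruments (true effects
    N(0.5, 0.1), a 20k-donor exposure cohort) so that no instrument sign is
    ambiguous and instrument-measurement noise (NOME violation) is
    negligible — the conditions under which the intercept is a consistent
    estimate of the directional pleiotropy mean.
    """
    from .mr_core import egger
    from .summary_io import harmonize

    intercepts = []
    for s in _replicate_seeds(seed, n_reps):
        cfg = SimulationConfig(n_snps=n_snps, n_exposure=20_000,
                               causal_beta=-0.1, gamma_dist=(0.5, 0.1),
                               pleiotropy_mean=mu_alpha, pleiotropy_sd=0.01,
                               palindromic_frac=0.0, seed=int(s))
        exposure, outcome, _ = simulate_pair(cfg)
        _, intercept = egger(harmonize(exposure, outcome))
        intercepts.append(intercept.beta)
    return float(np.mean(intercepts))


# ---------------------------------------------------------------------------
# Multi-exposure, multi-outcome fixture exercising every pipeline branch
# ---------------------------------------------------------------------------

@dataclass
class PaperLikeFixture:
    """Deterministic multi-cohort dataset for end-to-end pipeline tests.

    Five exposures against two outcome GWAS datasets plus one independent
    validation eQTL cohort:

    * ``miR-sim-causal``      — protective effect, replicates in validation
      (the high-confidence branch);
    * ``miR-sim-discovery``   — protective in discovery, validation
      instruments reversed so replication fails on direction;
    * ``miR-sim-null``        — no causal effect;
    * ``miR-sim-twosnp``      — only 2 instruments, fails the nSNP >= 3 gate;
    * ``miR-sim-novalid``     — protective but absent from the validation
      cohort (replication unavailable).
    """

    discovery_exposures: dict[str, list[ExposureRecord]]
    validation_exposures: dict[str, list[ExposureRecord]]
    outcomes: dict[str, list[OutcomeRecord]]
    ld: dict[str, Callable[[VariantKey, VariantKey], float]]
    true_beta: dict[str, float]


def make_paper_like_fixture(seed: int, out_dir: str | Path | None = None
                            ) -> PaperLikeFixture:
    """Build the five-exposure / two-outcome / one-validation-cohort fixture.

    Strong instruments and large samples push every intended discovery and
    replication decision far from its threshold, so the branch structure is
    stable across seeds.  With ``out_dir`` set, all tables are also written
    as TSVs in the layout the CLI consumes (byte-identical per seed).
    """
    # (exposure_id, causal beta, n_snps, present in validation, validation
    #  instrument effects reversed).  |beta| = 0.09 keeps per-SNP outcome
    #  associations well below genome-wide significance while the pooled IVW
    #  z-score stays ~10, so the intended decisions are far from thresholds.
    specs = [
        ("miR-sim-causal", -0.09, 20, True, False),
        ("miR-sim-discovery", -0.09, 20, True, True),   # validation reversed
        ("miR-sim-null", 0.0, 20, True, False),
        ("miR-sim-twosnp", -0.09, 2, True, False),
        ("miR-sim-novalid", -0.09, 20, False, False),
    ]
    outcome_ids = ["sim-gwas-A", "sim-gwas-B"]
    base = SimulationConfig(
        n_exposure=5000, n_outcome_cases=35_000, n_outcome_controls=388_000,
        gamma_dist=(0.3, 0.1), palindromic_frac=0.2,
        ld_block_size=2, ld_rho=0.8,
    )

    discovery: dict[str, list[ExposureRecord]] = {}
    validation: dict[str, list[ExposureRecord]] = {}
    outcomes: dict[str, list[OutcomeRecord]] = {o: [] for o in outcome_ids}
    ld: dict[str, Callable] = {}
    true_beta: dict[str, float] = {}

    for k, (exp_id, beta, j, in_valid, reverse_valid) in enumerate(specs):
        cfg = replace(base, n_snps=j, causal_beta=beta, exposure_id=exp_id,
                      rsid_prefix=f"rs{k + 1}0", chrom=str(k + 1),
                      seed=(seed * 1009 + 13 * k) % 2**31)
        truth = _draw_panel(cfg)
        true_beta[exp_id] = beta
        ld[exp_id] = make_block_ld(cfg)

        exp_records, _ = _observe(cfg, truth)
        if j >= 3:  # one coding SNP per panel exercises the consequence filter
            v0 = exp_records[0]
            exp_records[0] = ExposureRecord(
                variant=v0.variant, exposure_id=v0.exposure_id,
                beta_gamma=v0.beta_gamma, se_gamma=v0.se_gamma,
                pvalue=v0.pvalue, n=v0.n, consequence="missense",
                cis=v0.cis, eaf=v0.eaf)
        discovery[exp_id] = exp_records

        for m, oid in enumerate(outcome_ids):
            ocfg = replace(cfg, outcome_id=oid,
                           seed=(cfg.seed + 7919 * (m + 1)) % 2**31)
            _, out_records = _observe(ocfg, truth)
            outcomes[oid].extend(out_records)

        if in_valid:
            vtruth = truth
            if reverse_valid:
                vtruth = SimulatedTruth(maf=truth.maf,
                                        gamma_true=-truth.gamma_true,
                                        alpha=truth.alpha,
                                        variants=truth.variants)
            vcfg = replace(cfg, n_exposure=710,
                           seed=(cfg.seed + 104729) % 2**31)
            v_records, _ = _observe(vcfg, vtruth, consequence=None, cis=None)
            validation[exp_id] = v_records

    fx = PaperLikeFixture(discovery_exposures=discovery,
                          validation_exposures=validation,
                          outcomes=outcomes, ld=ld, true_beta=true_beta)
    if out_dir is not None:
        write_fixture(fx, out_dir)
    return fx


def write_fixture(fx: PaperLikeFixture, out_dir: str | Path) -> None:
    """Write a fixture to TSV files in the directory layout the CLI reads."""
    from .summary_io import write_summary_table

    out = Path(out_dir)
    (out / "discovery").mkdir(parents=True, exist_ok=True)
    (out / "validation").mkdir(parents=True, exist_ok=True)
    for exp_id, recs in sorted(fx.discovery_exposures.items()):
        write_summary_table(recs, out / "discovery" / f"{exp_id}.tsv")
        write_ld_triplets(recs, fx.ld[exp_id], out / "discovery" / f"{exp_id}.ld.tsv")
    for exp_id, recs in sorted(fx.validation_exposures.items()):
        write_summary_table(recs, out / "validation" / f"{exp_id}.tsv")
    for oid, recs in sorted(fx.outcomes.items()):
        write_summary_table(recs, out / f"{oid}.tsv")


def write_ld_triplets(records: list[ExposureRecord],
                      ld: Callable[[VariantKey, VariantKey], float],
                      path: str | Path) -> None:
    """Serialize pairwise r^2 for a SNP panel as a long-format TSV."""
    import pandas as pd

    variants = [r.variant for r in records]
    rows = []
    for i, a in enumerate(variants):
        for b in variants[i + 1:]:
            r2 = ld(a, b)
            if r2 > 0:
                rows.append({"rsid_a": a.rsid, "rsid_b": b.rsid, "r2": r2})
    pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
        path, sep="\t", index=False)
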