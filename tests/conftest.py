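import numpy as np
import pytest
from hypothesis import settings

from mirmr import ExposureRecord, HarmonizedSet, OutcomeRecord, VariantKey

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")

_NONPAL = [("A", "G"), ("A", "C"), ("G", "T"), ("C", "T"),
           ("G", "A"), ("C", "A"), ("T", "G"), ("T", "C")]


def make_variant(i: int, chrom: str = "1", pos: int | None = None,
                 alleles: tuple[str, str] | None = None) -> VariantKey:
    ea, oa = alleles or _NONPAL[i % len(_NONPAL)]
    return VariantKey(rsid=f"rs{i}", chrom=chrom, pos=pos or 1000 * (i + 1),
                      effect_allele=ea, other_allele=oa)


def make_exposure(i: int, beta: float, se: float = 0.05, p: float | None = None,
                  exposure_id: str = "miR-x", **kw) -> ExposureRecord:
    from scipy import stats
    if p is None:
        p = max(2 * stats.norm.sf(abs(beta) / se), 5e-324)
    variant = kw.pop("variant", None) or make_variant(i, chrom=kw.pop("chrom", "1"),
                                                      pos=kw.pop("pos", None),
                                                      alleles=kw.pop("alleles", None))
    return ExposureRecord(variant=variant, exposure_id=exposure_id,
                          beta_gamma=beta, se_gamma=se, pvalue=p, **kw)


def make_outcome(variant: VariantKey, beta: float, se: float = 0.02,
                 p: float = 0.5, outcome_id: str = "gwas-y") -> OutcomeRecord:
    return OutcomeRecord(variant=variant, outcome_id=outcome_id,
                         beta_Gamma=beta, se_Gamma=se, pvalue=p)


def make_harmonized(gamma, Gamma, se_Gamma, se_gamma=None,
                    exposure_id="miR-x", outcome_id="gwas-y") -> HarmonizedSet:
    gamma = np.asarray(gamma, dtype=float)
    j = gamma.size
    return HarmonizedSet(
        exposure_id=exposure_id, outcome_id=outcome_id,
        snps=[make_variant(i) for i in range(j)],
        gamma=gamma,
        se_gamma=np.full(j, 0.05) if se_gamma is None else np.asarray(se_gamma, float),
        Gamma=np.asarray(Gamma, dtype=float),
        se_Gamma=np.asarray(se_Gamma, dtype=float),
        flipped=np.zeros(j, dtype=bool),
    )


def random_harmonized(rng: np.random.Generator, j: int = 8) -> HarmonizedSet:
    return make_harmonized(
        gamma=rng.normal(0.3, 0.2, j),
        Gamma=rng.normal(0.0, 0.05, j),
        se_Gamma=rng.uniform(0.01, 0.05, j),
        se_gamma=rng.uniform(0.01, 0.05, j),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
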