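# Methods

## Scope and data model

`mirmr` implements summary-data two-sample Mendelian randomization: the
exposure associations (miRNA-eQTL effects γ, standard errors σ_γ) and the
outcome associations (disease GWAS log-odds Γ, σ_Γ) come from different
cohorts and are consumed as per-SNP tables. No individual-level genotypes
are touched anywhere; LD is an input (square matrix or triplet TSV), never
computed from a reference panel, and there is no proxy-SNP search, no
strand inference from allele frequency, and no liftover.

## Harmonization

SNPs are matched across tables by rsid alone: the supported sources are
rsid-keyed, and a position disagreement at a matching rsid usually reflects
a genome-build difference, so it is logged as a warning rather than used to
drop the SNP. Matching rows with identical allele pairs are kept as-is;
swapped pairs have Γ negated and are flagged `flipped`; any other allele
combination is dropped as `allele mismatch` — including complementary pairs
such as A/G vs T/C, which could be strand-rescued but are not (the rescue
needs a strand assumption the input does not justify). Palindromic SNPs
(A/T, C/G) are removed unconditionally, with no allele-frequency rescue.
Duplicate rsids within one table keep the row with the smallest p-value.
Output order is fixed to (chrom, pos, rsid) so every downstream statistic
is bit-reproducible. Two properties pin the implementation down: harmonizing
is idempotent on aligned inputs, and jointly flipping the outcome's alleles
and effect signs leaves the harmonized vectors unchanged (involution).

## Instrument selection

Filters apply in order: cis-eQTL restriction, exclusion of coding
consequences (`synonymous`, `missense` — a guard against pleiotropy through
protein-altering effects), Benjamini–Hochberg FDR < 0.1 computed within one
exposure's candidate SNPs, and per-SNP F = (γ/σ_γ)² > 10 (the conventional
weak-instrument cut; the summary-data approximation to the first-stage F).
The FDR family is per-exposure: candidate cis-SNPs of one miRNA are one
testing family, the conservative reading when instruments are selected per
miRNA. When the annotation columns are absent (typical of validation
cohorts), the cis/consequence stages log a warning and pass everything
through; validation-cohort instruments instead use a raw p < 1e−5 cut with
no FDR. BH is implemented in-package (sort, scale by m/k, cumulative
minimum from the tail) and cross-checked against statsmodels in the tests.

LD clumping is greedy by ascending p-value (ties broken by chrom, pos,
rsid): a SNP is pruned only when an already-kept SNP on the same chromosome
is BOTH within the window (default 10 kb) AND correlated at r² ≥ threshold
(default 0.5). Pruning on distance alone would ignore the r² condition that
defines the method; the joint condition is the conventional windowed clump.
The defaults are deliberately liberal and both are exposed in the config.
Unknown LD pairs count as r² = 0.

After harmonization, SNPs with outcome p ≤ 5e−8 are removed: a variant
already genome-wide significant for the disease plausibly acts through
pathways other than the miRNA.

## Estimators

IVW is the weighted through-origin regression of Γ on γ with weights
1/σ_Γ². The default standard error is multiplicative random effects: the
fixed-effect SE times max(1, √(Q/(J−1))). The floor at 1 never lets
under-dispersion shrink the SE; p-values use the normal reference. MR-Egger
adds a free intercept and is fitted after orienting all γ ≥ 0 (jointly
flipping (γ, Γ) pairs), without which the intercept is not identified under
allele recoding; its SEs carry the same residual-scale floor and its
p-values use t(J−2). CIs use the normal quantile at all J. These
conventions are the ones the published per-row numbers are consistent with
(normal for IVW, t(J−2) for Egger) and match mainstream two-sample MR
software. The closed-form 2×2 normal-equation solve is cross-checked
against statsmodels WLS to 1e−10 in the tests; that library is never the
implementation path.

Cochran Q uses the fixed-effect IVW β (the estimator it is derived from);
df = J−1, upper-tail χ² p-value. The regression-residual form equals the
Wald-ratio form Σ(γ²/σ_Γ²)(β_j − β_IVW)² algebraically, and at df = 2 the
p-value reduces to exp(−Q/2) — both are regression tests. Leave-one-out
refits IVW (same mode as the headline fit) excluding each SNP in turn;
diagnostics are reported, never acted on automatically (no outlier
removal).

## Decision rules

Per outcome GWAS, a miRNA passes discovery when: IVW p < .05; BH q < 0.1
with the family being all miRNAs fitted against that outcome (the only
family that makes the criterion non-vacuous in a per-outcome screen);
strict sign agreement of the IVW and Egger slopes (a zero estimate is
inconsistent with any sign); and ≥ 3 SNPs in the fit. Replication re-runs
harmonization + IVW with the validation cohort's instruments against the
same outcome; it passes when p < .05 and, by default, the sign matches
discovery (configurable — a significance-only rule is defensible, but
direction agreement is what a replicated protective effect means).
Exposures absent from the validation cohort get `replication_pass = None`
(unavailable) and can never be high-confidence. `intersect_causal` reports
the union of per-outcome discovery hits with a membership matrix.

## Synthetic data generator

For SNP j: MAF ~ U(0.05, 0.5); true effect γ_j ~ N(mean, sd); exposure SE
1/√(2·n·MAF(1−MAF)) (standardized quantitative trait); outcome SE
√((1/(2MAF(1−MAF)))·(1/n_cases + 1/n_controls)) (logistic per-allele
approximation); pleiotropy α_j = μ_α + τZ_j, optionally plus 0.5·γ_j when
the InSIDE violation is switched on; observed effects are the truths plus
the stated Gaussian noise, p-values two-sided normal. These SE formulas are
internally consistent rather than cohort-exact — sufficient for testing the
estimators, not a model of any particular assay. Defaults mirror the study
conditions the pipeline targets: a few-thousand-donor whole-blood eQTL
cohort (n = 5000) against a biobank-scale case-control GWAS
(35,000/388,000). Alleles are drawn with a configurable palindromic
fraction (default 0.1); positions sit on one chromosome at 2 kb spacing; LD
is block-constant (r² = ρ² within blocks, 0 across) — the simplest
structure that makes clumping non-trivial. All draws flow from one root
seed through named substreams (maf, gamma, noise, alleles, pleiotropy), so
adding a draw to one stream never perturbs another and output files are
byte-identical per seed.

What the generator does *not* emulate: realistic allele-frequency spectra,
miRNA effect-size distributions, sample overlap between cohorts, population
stratification, or non-Gaussian noise. Passing calibration tests therefore
show estimator correctness under the model's own assumptions, not
robustness to real-data pathologies.

### Calibration studies

- **Type-I error** uses the fixed-effect IVW: under this generative model
  the null z-score is exactly standard normal, so the rejection rate
  calibrates against the nominal 5%. (The multiplicative-random-effects SE
  is floored at 1 and is deliberately conservative under the null,
  rejecting at ≈ 3%.)
- **Causal recovery** (β = −0.3, J = 50): mean IVW estimate across
  replicates; the residual attenuation from instrument-measurement noise is
  ≈ 0.2% at the default settings.
- **Egger intercept recovery** (μ_α = 0.02, τ = 0.01, J = 100) uses
  uniformly strong, well-spread instruments (γ ~ N(0.5, 0.1), n = 20,000):
  with weak or sign-ambiguous instruments the γ ≥ 0 orientation and NOME
  violation leak slope attenuation into the intercept, which is a property
  of MR-Egger itself, not of this implementation.

### The pipeline fixture

`make_paper_like_fixture` builds five exposures against two outcome GWAS
plus one validation cohort, one per decision branch: causal-and-replicated,
discovery-only (its validation instruments are reversed so replication
fails on the direction criterion deterministically), null, two-SNP
(nSNP-gate failure), and absent-from-validation. Effect sizes (|β| = 0.09,
γ ~ N(0.3, 0.1)) keep every intended decision far from its threshold: the
pooled IVW z-score is ≈ 10 while per-SNP outcome associations stay well
below genome-wide significance, so the branch structure is stable across
seeds. The null exposure's discovery outcome is genuinely stochastic
(≈ 5% of seeds pass per outcome, as it should be); no fixture assertion
depends on it.

## Numerical choices and edge cases

- p-values are clamped to [5e−324, 1] so the (0, 1] invariant survives
  underflow.
- Rounding in report output: beta/SE/p to 5 decimals, OR/CI to 3, trailing
  zeros trimmed and the leading zero of p-values dropped ("0.99", ".01170").
- Ties everywhere break lexicographically by (p-value, chrom, pos, rsid).
- γ_j = 0 raises a degenerate-instrument error naming the SNP (Wald ratio
  undefined); J below an estimator's minimum (1 fixed-IVW, 2 MRE-IVW,
  3 Egger/leave-one-out) raises an insufficient-instruments error; an
  empty harmonization is signalled to the caller, who applies the ≥ 3 gate.
- The pipeline is deterministic given input files and config; the run
  manifest records config, input digests and per-stage counts, and repeated
  runs are byte-identical apart from the manifest timestamp.

## Known limitations

Weighted-median/mode estimators, MR-PRESSO, Steiger filtering and
multivariable MR are out of scope, as are funnel plots and the Rücker
framework. Simulation sizes in the test suite (hundreds to 1000 replicates,
J ≤ 100) are chosen to give Monte-Carlo error comfortably inside the
asserted tolerances while keeping the suite fast; they are not cohort-scale.
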