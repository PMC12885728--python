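# mirmr

Two-sample Mendelian randomization (MR) of circulating miRNA expression
against disease GWAS outcomes, from summary statistics alone.

`mirmr` is aimed at genetic epidemiologists who want a tested, scriptable
pipeline for the standard miRNA-eQTL → disease workflow: select genetic
instruments from eQTL summary statistics, harmonize them against outcome
GWAS summary statistics, estimate causal effects with IVW and MR-Egger, run
heterogeneity/pleiotropy/stability diagnostics, apply multi-cohort decision
rules, and replicate candidate hits in an independent eQTL cohort. A
synthetic summary-statistics generator with a known causal structure makes
every stage testable without access to cohort-scale data.

## The model

Each SNP *j* contributes a per-allele effect γ<sub>j</sub> (± σ<sub>γj</sub>)
on the exposure (miRNA expression, standardized units) and
Γ<sub>j</sub> (± σ<sub>Γj</sub>) on the outcome (log-odds of disease). With
valid instruments, Γ<sub>j</sub> = β·γ<sub>j</sub>, where β is the causal
log-odds effect of the exposure:

- **Wald ratio** — β̂<sub>j</sub> = Γ<sub>j</sub>/γ<sub>j</sub>,
  se = σ<sub>Γj</sub>/|γ<sub>j</sub>|.
- **IVW** — weighted regression of Γ on γ through the origin, weights
  w<sub>j</sub> = 1/σ<sub>Γj</sub>²:
  β̂ = Σw<sub>j</sub>γ<sub>j</sub>Γ<sub>j</sub> / Σw<sub>j</sub>γ<sub>j</sub>².
  Default multiplicative-random-effects SE inflates the fixed-effect SE by
  max(1, √(Q/(J−1))). Normal reference for p-values.
- **MR-Egger** — the same regression with a free intercept after orienting
  all γ<sub>j</sub> ≥ 0; the intercept estimates directional pleiotropy and
  the slope is a pleiotropy-robust causal estimate under InSIDE; t(J−2)
  reference.
- **Cochran Q** — Σ<sub>j</sub> w<sub>j</sub>(Γ<sub>j</sub> − β̂γ<sub>j</sub>)²,
  χ²(J−1) under homogeneity.
- Effects are reported as odds ratios OR = e<sup>β̂</sup> with Wald CIs.

Instrument filters: cis-eQTLs only, coding (synonymous/missense) SNPs
excluded, Benjamini–Hochberg FDR < 0.1, F = (γ/σ<sub>γ</sub>)² > 10, greedy
LD clumping (r² < 0.5 within 10 kb), removal of palindromic SNPs at
harmonization and of SNPs already genome-wide significant for the outcome
(p ≤ 5×10⁻⁸). A miRNA is called causal in discovery when IVW p < .05, BH
FDR < 0.1 across the miRNAs tested against that outcome, IVW and Egger
slopes agree in sign, and ≥ 3 SNPs enter the fit; the call is
*high-confidence* only if IVW on instruments from an independent validation
eQTL cohort is itself significant and direction-consistent.

## Worked example

```python
from mirmr import make_paper_like_fixture, run_full_analysis
from mirmr.cli import calls_to_frame, render_table

fx = make_paper_like_fixture(7)          # 5 miRNAs x 2 GWAS + validation cohort
res = run_full_analysis(fx.discovery_exposures, fx.outcomes,
                        validation_raw=fx.validation_exposures, ld=fx.ld)
df = calls_to_frame(res)
sub = df[(df["Outcome"] == "sim-gwas-A")
         & df["Method"].isin(["IVW", "IVW (validation)"])]
print(render_table(sub[["Exposure", "Method", "nSNPs", "Beta", "SE",
                        "P-value", "OR (95% CI)", "discovery_pass",
                        "replication_pass", "high_confidence"]]))
```

```
         Exposure           Method  nSNPs     Beta      SE P-value         OR (95% CI)  discovery_pass replication_pass  high_confidence
   miR-sim-causal              IVW      9 -0.09616 0.00877  .00000 0.908 (0.893–0.924)            True             True             True
   miR-sim-causal IVW (validation)      7 -0.10052 0.00961  .00000 0.904 (0.887–0.922)            True             True             True
miR-sim-discovery              IVW      7 -0.06509 0.00927  .00000  0.937 (0.92–0.954)            True            False            False
miR-sim-discovery IVW (validation)      6  0.05239 0.00931  .00000 1.054 (1.035–1.073)            True            False            False
  miR-sim-novalid              IVW      7 -0.08098 0.01330  .00000 0.922 (0.898–0.947)            True               NA            False
     miR-sim-null              IVW      7 -0.00126 0.01233  .91889 0.999 (0.975–1.023)           False               NA            False
   miR-sim-twosnp              IVW      1      NaN     NaN                         NaN           False               NA            False
```

The truly causal miRNA (simulated β = −0.09, OR ≈ 0.91 per unit expression)
passes discovery and replicates; the reversed-validation miRNA is
significant in validation but with the opposite sign, so replication fails;
the miRNA absent from the validation cohort stays `NA`; the null miRNA
fails the p-value criterion; and the two-SNP miRNA never reaches the ≥ 3
SNP gate.

The same analysis runs from the shell on TSV summary-statistic tables
(IEU OpenGWAS column layout by default):

```sh
mirmr simulate --paper-like --seed 7 --out fixture/
mirmr run --exposure-dir fixture/discovery \
          --outcome fixture/sim-gwas-A.tsv --outcome fixture/sim-gwas-B.tsv \
          --validation-dir fixture/validation --out results/
mirmr forest-table results/calls.tsv
```

`results/` contains `calls.tsv` (estimates + decision flags),
`sensitivity.tsv` (Egger intercept and Cochran Q per pair), `loo.tsv`
(leave-one-out scans) and `manifest.json` (config snapshot, input digests,
per-stage counts).

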