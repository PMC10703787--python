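# Methods

## Metagene scoring and stratification

A metagene score is the unweighted arithmetic mean of log₂-scale expression
over the signature's features (a weighted mean is supported for signatures
published with per-gene weights; single-gene "signatures" return the gene's
row). Scores are computed on the log scale because both microarray
intensities and FPKM values are analysed after log₂ transformation; matrices
declared linear-scale at load time are log₂(x+1)-transformed. Missing entries
are first imputed with the global minimum of observed values (the detection
floor), matching the lowest-value imputation used for sparse normalized
arrays; any entry still missing at scoring time falls back to the
within-sample mean of the available signature features.

Feature resolution is platform-dependent. On Affymetrix-tagged matrices the
bundled MKS/ERS signature matches its 12+4 probe-set IDs directly. On every
other platform matching is by gene symbol, case-insensitively, and all
features mapping to a signature gene are kept — duplicates included — and
passed jointly to the discordant-probe filter rather than being averaged per
gene first. This mirrors probe-level filtering: the filter sees exactly what
would be averaged.

**Discordant-probe filter.** The rule "exclude probes correlating < 0.4 in
the dendrogram" is operationalised deterministically: pairwise Pearson
correlation r across samples, average-linkage hierarchical clustering on
distance 1 − r, tree cut at height 0.6, and retention of the largest
resulting cluster (ties broken toward the cluster containing the
lexicographically smallest feature ID). A pair correlated at exactly 0.4 is
retained; 0.39 is split. Zero-variance features are removed before clustering
with a warning, and feature pairs with no usable sample overlap are treated
as uncorrelated (distance 1). The filter is idempotent. In panel scoring the
filter runs automatically only when some gene resolves to more than one
feature (a multi-probe platform); with one feature per gene, removing a gene
would change the metagene's definition rather than clean its measurement, so
single-feature panels are scored unfiltered unless filtering is forced.

**Thresholds and labels.** The default threshold is the cohort-specific
median of each score (midpoint of the central order statistics for even n);
predefined cutoffs can be supplied for cohorts classified with external
thresholds. "High" means strictly above the cutoff; a score exactly equal to
the cutoff is low, so that "high" always means above the median. Four-group
mode crosses the two calls; ERS-only mode (for cohorts where every tumour is
known proliferative) splits on ERS alone. The tie rule and mode are
configurable. For cohorts where each of the four subgroups is reported with
exactly n/4 members, a single joint median split cannot guarantee that
partition — within-stratum splitting would; both threshold modes are exposed
and the joint split is the default.

## Endpoint coding and receptor calls

- Pathological response: RCB 0/I → pathR, RCB II/III → RD; pCR flag true only
  for RCB 0. NA propagates.
- Endocrine response: post-treatment Ki67 strictly below 10% is a responder.
  Exactly 10.0% is coded non-responder: "below 10%" defines response and the
  complementary statistic is reported as "Ki67 > 10%", leaving 10.0 ambiguous;
  the strict-below reading is implemented.
- Receptor status: the pathology IHC call always wins; mRNA is the fallback
  when IHC is missing, with strict cutoffs ESR1 log₂ FPKM > 2.145 (ER+) and
  ERBB2 log₂ FPKM > 6.32 (HER2+). Both sources missing → status NA.
- Survival endpoints (distant event-free survival, overall survival) are
  handled identically as (time, event) pairs; the endpoint name is metadata.

## Mutation analysis

TMB is the raw per-sample count of coding mutations — synonymous and
non-synonymous alike — not a per-megabase rate. The coding class list is
Missense, Nonsense, Nonstop, Silent, Splice_Site, Frame_Shift_Ins/Del,
In_Frame_Ins/Del and Translation_Start_Site; Intron, UTR/Flank, IGR, RNA,
Targeted_Region and Splice_Region records are excluded. Unknown
classification strings warn and are excluded by default, or raise in strict
mode. Top-k gene ranking uses the fraction of samples with ≥1 coding
mutation, after removing a configurable non-driver exclusion list (bundled
default: TTN, MUC16 and similar recurrent large passengers), with
alphabetical tie-breaks. Frequency differences across subgroups are tested
with the Cochran–Mantel–Haenszel general-association statistic on 2×G tables
(df = G−1); with a single stratum and G = 2 this reduces to the classical
Mantel–Haenszel chi-square, i.e. (N−1)/N times the Pearson statistic. An
optional stratum column enables the fully stratified form.

## Odds-ratio estimation

Under the conditional model with both table margins fixed, the
exposed-responder count follows Fisher's noncentral hypergeometric
distribution with noncentrality ψ (the odds ratio). The implementation
computes the pmf by normalised weight summation in log space over the full
support, which is numerically safe for any margins and ψ. The point estimate
solves the mid-p equation ½P(X=a;ψ) + P(X>a;ψ) = ½; confidence limits solve
the mid-p tail equations at α/2. "Median-unbiased with mid-p" is the standard
reading of this estimator in epidemiology toolkits, and it reproduces both
published example odds ratios and their intervals from the reconstructed
tables; the non-mid-p exact variant (geometric mean of the two exact tail
roots, Fisher-exact interval) is available via `midp=False`.

Numerics: the tail functions are monotone in ψ; monotonicity is checked on
the bracket before root-finding, the bracket [10⁻⁸, 10⁸] is expanded
geometrically until it straddles the target, and bisection (Brent) runs on
log ψ to relative tolerance well below 10⁻⁸. A count at the support minimum or
maximum yields the explicit one-sided limits 0 or ∞; a zero response or
non-response margin makes the odds ratio undefined and raises.

## Survival, t-test, interaction

Kaplan–Meier, the log-rank test and univariate Cox regression are delegated
to lifelines behind the module's stable interface: product-limit curves with
right-continuous step lookup and events-first handling of ties with
censoring; the multivariate log-rank with df = groups − 1 (no events at all →
p = 1 with a warning); Cox partial likelihood with Efron tie handling (more
accurate than Breslow when follow-up granularity creates ties) and Wald
intervals on the log-hazard scale. Monotone likelihood — no events in one
covariate level — is flagged and the interval reported unbounded. The t-test
is the pooled-variance Student's test (as named; Welch behind a flag). The
arm×stratum interaction is a binomial GLM fitted by IRLS with a Wald p-value
on the interaction coefficient; whether the original analysis used a Wald,
score or likelihood-ratio form is unknowable from the printed value alone, so
agreement is treated as a consistency check (the reconstructed trial counts
give p ≈ 0.49 against a printed 0.494). Separation is detected by exploding
coefficient/standard-error estimates and flagged with p = NA.

## Synthetic cohort generator

The generator exists so every pipeline stage has a ground truth. Two latent
axes are drawn bivariate normal with correlation −0.3 (proliferation m and ER
signalling e; modestly negative, consistent with the observed inverse
relation between immune/proliferative activity and ER signalling). Each
signature gene is baseline + loading·latent + noise with baseline ~ N(7, 1)
log₂ units, loadings ~ N(1, 0.1), and noise SD 0.5 — a signal-to-noise ratio
at which metagene averaging visibly helps, as on real arrays. The biomarker
panel is wired to the latents (RBsig, CCNE1 → +m; IRPS weakly +m; TILs and
T-cell-inflamed GEP → −0.8·e, reproducing the inverse TILs–ERS correlation),
plus independent noise genes. The true subgroup is the sign pattern of
(m, e).

Outcome models and their defaults (all config-overridable; these are the
study conditions, not tuning knobs):

| component | model | defaults |
|---|---|---|
| pCR | Bernoulli, logit by (subgroup, arm) | 20.9/41.7% (ERS^lo chemo / +pembrolizumab), 9.8/12.5% (ERS^hi), 5–6% (MKS^lo) |
| pathR | RCB I tops pCR up to the subgroup pathR rate; remainder RCB II/III (70/30) | 22% (MKS^hi/ERS^lo), 8% elsewhere |
| survival | exponential per subgroup; independent exponential censoring (5%/yr) + 5-year administrative cutoff | 4-year event-free survival 70% (MKS^hi/ERS^lo), 94% (MKS^hi/ERS^hi), 95% (MKS^lo) |
| driver mutations | Bernoulli per (gene, subgroup) | TP53 34/16/12/6%, PIK3CA 52 vs 32–33%, CDH1/MAP3K1 enriched in MKS^lo/ERS^hi, PTEN 10 vs 4% |
| TMB | negative binomial (dispersion 8), passenger records fill to the drawn count, plus non-coding records that TMB must ignore | medians 43/27/25/22 by subgroup; the NB mean is solved by bisection so the distribution median equals the planted median |
| post-AI Ki67 | clip(3.6 + 8·m − 6·[ERS^hi] + N(0,8), 0, 100) % | chosen so ~50% of MKS^hi/ERS^lo and ~24% of MKS^hi/ERS^hi samples exceed 10% |

The generator is byte-for-byte reproducible from its seed. Two deterministic
fixtures reconstruct printed trial tables by rounding rate × n (the
reconstruction is asserted to reproduce the printed rate to one decimal at
build time): the two-arm pCR tables by ERS stratum (10/24 vs 9/43 and 2/16
vs 5/51) and the post-AI Ki67 table (21/42 and 10/41 above 10%).

What the generator does **not** emulate: platform-specific microarray noise,
batch structure, probe-level cross-hybridisation, copy-number, non-exponential
hazards, or correlation between mutation status and expression beyond the
subgroup labels. Passing recovery tests therefore demonstrates that the
pipeline's arithmetic and inference are correct under the assumed generative
structure — not that the biology of any real cohort is captured.

Recovery tests compare pipeline estimates against planted values using the
binomial/Monte-Carlo error of the estimate plus an explicit
misclassification-bias bound: samples near the median boundary are labelled
into adjacent subgroups, attenuating planted contrasts by at most f × spread,
where f is the measured label-disagreement fraction and spread the largest
planted between-subgroup difference. Both terms are computed, not tuned.

## Problem sizes used in the test suite

Synthetic recovery runs use n = 2,000 samples (shared across tests via a
session fixture); latent-correlation convergence uses n = 5,000; oracle
agreement for the odds-ratio root uses 500 random tables against a dense
ψ-grid (step 10⁻⁴); survival oracles use 2,000 permutations and 100–200
simulation replicates. These sizes give comfortable margins for every
assertion while keeping the whole suite under half a minute.

## Pipeline configuration

The worked example in the README uses this config:

```yaml
expression: demo/expression.tsv
clinical: demo/clinical.csv
mutations: demo/mutations.maf.tsv
out_dir: demo/out
comparisons:
  - name: pathR_MKShi_ERSlo_vs_ERShi
    endpoint: pathr
    groups: [MKShi_ERSlo, MKShi_ERShi]
  - name: DEFS_MKShi_ERSlo_vs_ERShi
    endpoint: defs
    groups: [MKShi_ERSlo, MKShi_ERShi]
    horizon_years: 4.0
```

Unknown keys are rejected before any stage runs. Every threshold actually
applied (median cutoffs, excluded probes, panel feature counts) is logged and
written into the provenance block of `results.json` together with a
content-based hash of config + inputs, the seed and the package version — no
timestamps, so identical runs are byte-identical.

## Bundled gene sets and limitations

`data/mks_ers.gmt` ships the two metagenes verbatim (12 + 4 members with
their probe-set IDs). The member lists for RBsig (Malorni et al., Rb
loss-of-function), IRPS (De Angelis et al., 35 interferon-related genes),
the TILs metagene (Rody et al.) and the T-cell-inflamed GEP (Ayers et al.)
are **synthetic placeholders** (`data/biomarker_panel_synthetic.gmt`):
plausible genes of the right biology and size, not the published lists, which
are not redistributed here. Users analysing real data should supply the
published GMTs; the GEP supports per-gene weights via the `SYMBOL|weight`
member syntax (placeholder weights default to 1). Other limitations: no
microarray normalisation, batch correction or probe summarisation from raw
data; no variant calling or driver inference; no multivariable Cox or
multiple-testing correction (none is applied by design); predefined external
cutoffs must be supplied as numbers, not reconstructed.
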