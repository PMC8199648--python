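# Methods

`cernet` implements a clinically stratified competing-endogenous-RNA (ceRNA)
inference workflow for paired tumor / adjacent non-tumor expression profiles
of three RNA classes (circRNA, miRNA, mRNA), together with a synthetic-cohort
generator that plants every kind of structure the workflow is meant to
detect. This note records the statistical model of each stage, the defaults
and why, and the design decisions that were genuinely open.

## Pipeline model

### Differential expression

Each feature is tested with a two-sided **paired t-test** on per-patient
tumor minus non-tumor log2 differences (df = n−1). The design is matched
pairs, so the paired test is the default; an unpaired Welch test is
available via `paired: false` for unmatched cohorts. P-values are adjusted
by Benjamini–Hochberg step-up (Benjamini–Yekutieli selectable), and features
are gated on the **linear** fold change FC = 2^(mean log2 difference):

- up: FC ≥ `fc_threshold` (default 1.5) and q ≤ `de_fdr` (default 0.05)
- down: FC ≤ 1/`fc_threshold` and q ≤ `de_fdr`

Degenerate features (zero variance of differences, nonzero mean) are
reported with p = 0 and a `degenerate` flag; features with fewer than three
complete pairs are dropped with a log entry. The sample heatmap view is
supported by agglomerative clustering of samples (Euclidean distance,
average linkage) restricted to DE features; samples are pre-sorted by id so
the leaf order is deterministic and permutation-invariant.

### Clinical association and prognosis calls

Tumor-sample expression of each DE feature is compared between binary
clinical subgroups with a Welch t-test; the group fold change is
2^(mean_worse − mean_better). Every supported variable carries a declared
*worse* level (total coding table): grade 3–4 vs 1–2, large vs small tumor,
capsule absent/incomplete vs present/complete, invasion present vs absent,
late vs early stage. Significance needs |group FC| beyond `clin_fc`
(default 1.5) and p ≤ `clin_p` (default 0.05, **uncorrected** — raw
per-variable p-values are the convention this workflow follows; BH across
variables can be enabled with `clin_adjust`).

Overall survival is tested with a two-group **log-rank** test between
median-split tumor-expression groups, implemented by direct risk-set
tabulation (hypergeometric variance). The sign of the observed-minus-
expected events in the high-expression group gives the direction
(higher-in-worse vs higher-in-better); the implementation is cross-checked
against lifelines in the test suite.

A feature is called **worse-prognostic** when it is up in tumors and every
significant association points to higher expression in the worse stratum,
**better-prognostic** when it is down and every association points the
other way, and **unclear** for mixed evidence. Features with no significant
association are not called.

### Co-expression network and nodal circRNAs

All-pairs Pearson correlation between clinically associated DE circRNAs and
DE mRNAs, two-sided t-based p (df = n−2), BH across all tested pairs, and
retention at |r| ≥ `coexpr_r` (default 0.7, inclusive) and q ≤
`coexpr_fdr` (0.05). Correlations are computed over **all** samples (tumor
and non-tumor jointly) by default; `tumor_only` restricts to tumor samples.
Neither choice is privileged by the data model; the joint set doubles n and
lets the tumor/non-tumor contrast contribute to co-deregulation, which is
the phenomenon of interest.

Connected components are reported largest-first. Within the largest
component, **nodal** circRNAs are selected by greedy maximum coverage:
repeatedly take the circRNA covering the most uncovered genes (ties: higher
total degree, then lexicographically smaller id) until the covered fraction
reaches `coverage_target` (default 0.93). Greedy set cover carries the
classical (1 − 1/e) guarantee, asserted against exhaustive optima in the
tests. Host-gene concordance (Pearson r of circRNA vs host-gene log2 fold
changes, with concordant/discordant quadrant labels) is available as a
library operation when a circRNA annotation is supplied.

### ceRNA scoring

1. **Interaction filter.** A predicted miRNA→target link is retained when
   called by ≥ `min_predictors` algorithms (default 2) *and* Spearman rho <
   0 with p ≤ 0.05. The target table is a plug-in interface; a built-in
   7-mer seed-match predictor (reverse complement of miRNA positions 2–8
   searched in a supplied target sequence) lets the pipeline run without
   external prediction tools.
2. **Shared-miRNA test.** For each candidate pair (two targets sharing ≥ 1
   retained miRNA) the shared count m out of per-target counts K1, K2 is
   tested with the upper-tail hypergeometric P(X ≥ m) over universe N =
   distinct miRNAs in the retained interaction set. The universe choice is
   deliberately conservative: restricting N to post-filter miRNAs makes
   overlaps harder to call significant than using all assayed miRNAs.
3. **Conditional statistics.** Pearson correlation (PC); first-order
   partial Pearson correlation (PPC) given each shared miRNA separately,
   with the pair-level p the **maximum** (most conservative) across shared
   miRNAs (`ppc_aggregate`); the sensitivity correlation (SPPC) = mean of
   r − r|z over shared miRNAs; and Gaussian conditional mutual information
   CMI = −½·ln(1 − r²_xy|z) in nats, with a permutation p that shuffles x
   within contiguous z-rank strata (~10 samples per stratum, `cmi_perms`
   draws, default 1000, seeded). The permutation p is computed only for
   pairs that already pass the four cheaper gates — pairs failing any of
   them cannot reach the top tier, so the skip cannot change any tier.
4. **Tiers.** *highly_confident* = hypergeometric ∧ PC (r > 0, p ≤ 0.05) ∧
   PPC ∧ SPPC ∧ CMI; *moderate* = PC ∧ PPC. The SPPC pass level
   (`sppc_min`, default 0.1) and the CMI permutation α are artifact
   parameters — no published numeric criterion exists for these two tests —
   and both are exposed in the config; 0.1 corresponds to conditioning
   removing at least a tenth of the correlation, which on the simulated
   cohorts cleanly separates planted pairs (drops ≈ 0.15–0.3) from
   confounded ones. Tier assignment is monotone in every threshold.

One triplet is emitted per (pair, shared miRNA); a triplet is *clinically
relevant* when its (ceRNA1, ceRNA2) pair is also a retained clinically
relevant co-expression edge.

### Biomarkers and enrichment

Each nodal circRNA is scored as a single-marker classifier on three
contrasts — non-tumor vs grade 1–2, grade 1–2 vs grade 3–4, non-tumor vs
grade 3–4 — using the rank-based (Mann–Whitney) AUC with midrank tie
handling; the AUC p-value is the two-sided normal approximation of U with
tie correction (the standard choice when no method is otherwise specified).
The operating point maximizes Youden's J with a smallest-threshold
tie-break. The combined panel is a maximum-likelihood logistic regression
fitted by IRLS with a small L2 ridge (default 1e−6, intercept unpenalized)
to keep separable fits finite; separability and non-convergence are
flagged, and a 1000× larger ridge is retried once on failure. AUCs are
in-sample (no cross-validation) by design. Gene-set over-representation
uses the upper-tail hypergeometric per set with BH across sets.

## Synthetic cohorts

`simulate_cohort` emulates a 49-patient paired design (98 samples). The
generative model, per feature f and patient p:

- baseline b_fp ~ Normal(`baseline_mean` = 8, `baseline_sd` = 1) shared by
  the patient's two samples, plus Normal(0, `noise_sd` = 0.5) per sample —
  log2 microarray-like scales;
- DE features (fraction `frac_de` = 0.10 per class) add ±`log2fc_de` = 1.5
  to tumor samples;
- `n_clin_assoc` = 15 DE features per class additionally add
  ±`grade_shift`·(grade − 1) (0.6 log2/step) in tumor samples; grades are
  assigned 1–4 uniformly before expression, so clinical effects are causal;
- planted ceRNA triplets: `n_triplets` = 10 triplets over 5 circRNA–mRNA
  pairs, each pair sharing `mirnas_per_pair` = 2 miRNAs (mirroring the
  multi-miRNA sharing that makes the hypergeometric overlap informative).
  Each planted miRNA's tumor abundance is m_p = −`mirna_grade_coef`·(grade
  − mean) + Normal(0, `mirna_spread` = 1.5), i.e. the miRNA is lower in
  higher-grade tumors; the pair's circRNA and mRNA receive
  −`coupling_b`·(m_p − mean m) (b = 1.0) in tumor samples. Planted members
  follow the canonical sponge pattern (circRNA and mRNA up, miRNA down in
  tumors) and the circRNA/mRNA ends are preferentially grade-associated, so
  the planted triplets are exactly the clinically relevant kind the
  pipeline is designed to find. This induces miRNA–target inverse
  correlation and circRNA–mRNA positive correlation that attenuates when
  conditioning on the miRNA;
- survival: a latent per-patient frailty u ~ N(0,1) scales an exponential
  hazard (`survival_scale` = 36 months baseline, hazard ×
  `survival_effect`^u = 2^u), with independent uniform censoring on [0,
  120] months; `n_survival` = 5 DE features per class add
  `survival_coupling`·u (1 log2 unit) in tumor samples;
- the target table holds all planted links labelled by both registry
  predictors plus `decoy_factor` = 5× decoy links (half two-predictor, half
  one-predictor) to exercise the predictor-count and inverse-correlation
  filters.

All draws flow from one `numpy` Generator seeded by the config, so a seed
fully determines the cohort, the truth, and every downstream file.

**What the generator does not emulate:** microarray intensity-dependent
noise, batch effects, probe cross-hybridization, correlated co-expression
modules beyond the planted structure, copy-number confounding, or realistic
miRNA target multiplicity. Passing recovery tests therefore demonstrates
that the statistical machinery detects the structure it formalizes, not
that real cohorts are this clean; on real data the gates interact with far
heavier correlation and annotation noise.

Default cohort sizes (200 circRNA, 120 miRNA, 400 mRNA) keep a full
pipeline run under a second while leaving dozens of null features per
planted one; null-calibration tests use 1000 features and 2000 replicates.

## Numerical choices

- Edge and DE retention thresholds are inclusive (≥ / ≤).
- BH is an exact step-up with tail-cummin; ties preserved.
- Partial correlations are clipped to [−1, 1]; conditioners with
  (1−r²_xz)(1−r²_yz) ≤ 1e−12 are flagged degenerate and excluded (a pair
  whose conditioners are all degenerate cannot be highly confident).
- The CMI permutation p uses the add-one estimator (1 + #{perm ≥ obs}) /
  (n_perm + 1), with a 1e−15 slack on the ≥ comparison to absorb float
  round-off of identical statistics.
- Greedy-cover ties resolve by degree then id; component ties by size then
  smallest member id; every writer sorts rows and fixes the float format
  (`%.10g`), so identical inputs give byte-identical outputs.
- Stages never pass results in memory: each stage reads its predecessor's
  files, which makes the stage-by-stage CLI provably identical to
  `run_all`.

## Known limitations

- The Gaussian CMI estimator is exact only for elliptical dependence; a
  rank/kNN estimator would be needed for strongly nonlinear coupling.
- Single-conditioner (first-order) partial correlations: conditioning on
  all shared miRNAs jointly is not implemented.
- In-sample AUCs are optimistic; the panel evaluation performs no
  train/test split.
- The pipeline assumes already-normalized expression matrices; no
  microarray preprocessing or probe-to-gene mapping is provided.
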