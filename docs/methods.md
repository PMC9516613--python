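# Methods

## The data model

The unit of observation is one person's permanent-dentition examination at
tooth-surface resolution. Teeth carry two-digit FDI codes (quadrant 1–4,
position 1–8); all indices run over the 28 index teeth, positions 1–7.
Third molars are accepted in raw exports and dropped with a logged count —
they are representable but never contribute to any phenotype. The DMFS
surface universe is fixed: anterior teeth (positions 1–3) have four
surfaces {M, D, B, L}, posterior teeth (positions 4–7) five {O, M, D, B, L},
giving 12×4 + 16×5 = 128 index surfaces. Incisal edges are not separate
surfaces; primary/mixed dentition and root-surface caries are out of scope.

Surface status is one of SOUND, DECAYED, FILLED, MISSING (whole tooth), or
EXCLUDED. Inputs may carry ICDAS severity integers 0–6 instead of tokens;
these are thresholded at the moderate-lesion cutoff (default ICDAS ≥ 3 →
DECAYED), and raising the threshold can only reduce the number of DECAYED
surfaces (a tested monotonicity invariant). Missingness is a whole-tooth
property: one MISSING row propagates to every surface of that tooth, and a
tooth with both MISSING and non-MISSING rows is a reported data error, not
a silent fix. Surfaces without rows are governed by an explicit
`unlisted_policy`; the default is `error` because silent imputation hides
cohort-specific data problems, with `sound` provided for compact exports
that list only affected surfaces. EXCLUDED marks unerupted or unscorable
surfaces; how contributing cohorts handled these is generally unstated, so
the package takes its own position: EXCLUDED surfaces count toward nothing
and the 128/28 denominators stay fixed, keeping indices comparable across
subjects at the cost of a small downward bias for people with unscorable
surfaces.

## Phenotype tiers

*Tier 1 — case status*: DMFS > 0 (or equivalently DMFT > 0; the two agree on
every record, which is a tested invariant).

*Tier 2 — severity*: the DMF family with teeth missing due to **all causes**
in the M component ("tooth morbidity" encoding, DM_T_FS / DM_T_FT). This
choice deliberately conflates caries-driven and other tooth loss: at
population scale most adult tooth loss is attributable to dental disease,
and the encoding avoids unverifiable cause-of-loss adjudication across
cohorts. A missing tooth contributes all 4–5 of its surfaces to the surface
index and one tooth to the tooth index; an edentulous person scores 128/28.
At tooth level a tooth counts once with precedence MISSING > DECAYED >
FILLED (the standard "D over F" epidemiologic convention; mixed-status teeth
classify as decayed).

*Tier 3 — cluster scores*: for a partition of the 128 surfaces into five
clusters, score_c = affected-surfaces-in-c / |c|. The denominator is the
fixed cluster size, not the number of scorable surfaces for that person —
the literal reading of "divided by the number of tooth surfaces in the
cluster" — so edentulous subjects score 1.0 everywhere and subjects with
EXCLUDED surfaces are slightly shrunk toward 0. Cohort summaries report
population SDs by default (`ddof=1` available); at cohort n the difference
is negligible.

The builtin default map is a documented **reconstruction** from the five
classical cluster names, not a published table: C1 = molar occlusal +
mandibular-molar buccal + maxillary-molar lingual (16 surfaces); C2 = all
surfaces of mandibular incisors and canines (24); C3 = molar
mesial/distal + maxillary-molar buccal + mandibular-molar lingual +
premolar occlusal/mesial/distal (48); C4 = maxillary incisor surfaces (16);
C5 = maxillary canine surfaces + premolar buccal/lingual (24). Any 128-row
CSV/JSON assignment can replace it; the loader rejects non-partitions with
specific errors (duplicate surface, missing surface, empty cluster).

## Cluster re-derivation

To check that a predefined structure is recoverable from data, the 128
surfaces are clustered agglomeratively from their binary affection
indicators: distance 1 − Pearson correlation between surface columns, Ward
linkage, tree cut at k (default 5). Correlation distance groups surfaces by
*pattern* of caries experience rather than raw prevalence, which is the
phenomenon of interest. The original derivations in the literature do not
state their metric or linkage; these defaults are declared, not inferred.
Edentulous subjects are constant rows with no pattern information and are
dropped by default. Zero-variance columns (never/always affected in the
sample) have undefined correlations and are attached to their nearest
informative column by Hamming distance. Partition agreement is measured by
the adjusted Rand index (chance-corrected; label-permutation invariant).

## Registry roll-ups

The registry mirrors printed consortium tables: one denormalized row per
cohort with region, n (a leading `~` marks approximate sizes, which
roll-ups sum at face value — exactly how printed total rows are computed —
while preserving the flag), three independent tier-availability flags, and
an optional summary block. Pooled caries-free = Σ(n − cases) with percent
100·Σ(n − cases)/Σn; coverage = 100·current/target. Bundled fixtures: a
21-cohort overview (`table1.csv`) and the 8 surface-level cohorts with full
summary blocks (`table2.csv`). Footnote qualifiers (tooth-level-only data,
intraoral-photograph assessment, half-mouth exams) are carried as free-text
notes. One 8-cohort cell (COHRA2 cluster 3 SD 0.46 with mean 0.24) exceeds
the maximum SD of a fixed-denominator [0,1] proportion with that mean; it
is carried verbatim and excluded from self-consistency checks, which cover
the prevalence percents.

## Meta-regression

Cohort-level estimates (e.g. mean cluster scores) regress on a cohort-level
covariate (mean age) by fixed-effect weighted least squares. Default
weights are 1/SE² (inverse variance, the standard meta-regression
estimator); a literal 1/SE scheme is provided because "inverse standard
error-weighted" admits both readings. Coefficient covariance uses the
sandwich form with the per-point variances taken as known, which collapses
to (X'WX)⁻¹ under inverse-variance weights — no residual variance is
estimated and no between-cohort heterogeneity (τ²) component is fit; 95%
CIs use normal quantiles. This is deliberately the simplest model
consistent with a weighted linear fit; random-effects meta-regression is
out of scope. Note the weighted normal equations are solved directly (a
2-parameter closed form); generic WLS implementations scale the covariance
by the residual mean square, which is the wrong quantity when the SEs are
known (the test suite cross-checks point estimates against statsmodels WLS
and the SE after unscaling).

## Power analysis

A single-variant test is 1-df chi-square; power = P[χ²₁(λ) > c_α] with c_α
the central upper-α quantile. Quantitative traits: λ = n·q/(1−q) for a
variant explaining fraction q of trait variance — the exact noncentrality
of the marginal-test F/chi-square limit; at q ≈ 10⁻⁴ the /(1−q) correction
is invisible but the convention is fixed. The minimal detectable q inverts
this by monotone Brent root-finding (relative tolerance 1e−8; inversion is
verified to 1e−6 in tests). Binary traits: the allelic trend/score test
under Hardy–Weinberg equilibrium, λ = (ln OR)²·2·maf·(1−maf)·
n_cases·n_controls/n. α defaults to the genome-wide 5×10⁻⁸ and is a flag
everywhere. Both analytic forms are validated against Monte-Carlo oracles
(20,000 replicates each: a Wald-test linear-regression simulation at
n = 500, q = 2%; and a retrospective case-control score-test simulation at
1000/1000, MAF 0.3, OR 1.5, with genotype distributions implied by a
logistic model — the per-allele retrospective OR is invariant to baseline
prevalence, fixed at 10%), agreeing within two MC standard errors.

## Synthetic cohorts

The generator produces surface-level records from a logistic model: subject
i draws age (truncated normal on [18, 100]), sex, and frailty u_i ~ N(0,
σ²); each tooth is missing with probability logistic(m0 + m1·age + u_i);
each surface s of a present tooth is affected with probability
logistic(a_c(s) + b·age + u_i + v_i,c(s)), affected surfaces splitting
50/50 between DECAYED and FILLED (the indices treat D and F identically).
Defaults: n = 500; age 55 ± 12; 55% female; baseline logits a_c set so a
50-year-old's per-surface probabilities are (0.60, 0.05, 0.40, 0.20, 0.25)
for clusters 1–5 — the molar-highest / lower-anterior-lowest ordering seen
across real cohorts at roughly the magnitudes of the older cohort tables;
b = 0.03 per year (a mild, plausible cumulative age trend); σ = 1.0
(substantial within-mouth correlation); tooth loss m0 = −4.5, m1 = 0.04
(≈ 3% per-tooth missingness at age 30, ≈ 15% at 70, matching the observed
23–26 mean remaining teeth). Identical parameters and seed give
bit-identical cohorts; consortium generation derives child seeds from a
master seed via numpy's SeedSequence.

The per-cluster frailty v_ic (SD `cluster_frailty_sd`, **default 0**) is a
deliberate extension of the minimal shared-frailty model: a purely shared
frailty correlates all 128 surfaces equally, so correlation-distance
clustering has no signal to recover the generating partition (empirically,
ARI ≈ 0.1). With cluster-level frailty the within-cluster correlation
exceeds the between-cluster one and recovery is essentially exact; the
"strong separation" regime used by derivation tests is frailty_sd = 0.5,
cluster_frailty_sd = 1.0 (median ARI = 1.0 over 20 seeds at n = 500).

What the generator does *not* emulate: measurement error and
examiner/protocol heterogeneity, half-mouth designs, cause-specific tooth
loss, non-logistic age profiles, genetic effects, and any calibration to a
specific real cohort's cell values. Passing recovery tests therefore show
the analysis chain is correct under its own assumptions, not that real
consortium data satisfy them.

## Numerical and design choices

- Problem sizes in tests are desk-scale choices: 20,000-replicate MC
  oracles, 20 derivation replicates at n = 500, 200 coverage replicates of
  20 cohorts, recovery-chain consortia of 8 × 200–400 subjects.
- The recovery-chain magnitude check runs at σ = 0 with tooth loss disabled
  and regresses the **logit** of cohort mean scores on mean age: without
  frailty the expected score is logistic(a_c + b·age), so the logit-scale
  slope is b itself (delta-method SEs); on the raw proportion scale the
  slope is attenuated by p(1−p) and b is not identified without further
  modelling.
- Pipeline and simulation configs are JSON; outputs are deterministic CSVs
  plus a SHA-256 manifest, and reruns with the same config are
  byte-identical.
- CLI exit codes: 0 success, 1 data validation failure, 2 configuration
  error.

## Known limitations

The default cluster map is a name-based reconstruction, replaceable by
config. The fixed-denominator convention for EXCLUDED surfaces and
edentulous cluster scores of 1.0 are package decisions where field practice
varies. The binary-trait power approximation assumes HWE and small effects;
the meta-regression assumes known per-cohort SEs and no heterogeneity.
GWAS execution, meta-analysis of summary statistics, replicability
assessment, and periodontitis phenotyping are out of scope.
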