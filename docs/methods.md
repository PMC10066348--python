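# Methods

## The analysis

The pipeline estimates the population burden of pathogenic and likely
pathogenic (P/LP) germline variation in a 17-gene gynecologic cancer panel
and compares it, gene by gene, with a large control population. Its unit of
observation is the *unique heterozygote carrier*: an individual carrying at
least one P/LP variant in a gene counts once for that gene, regardless of
how many such variants they carry there. An individual with P/LP variants
in two different genes contributes to both genes, and therefore twice to
the whole-panel "Sum" row — the Sum row is the sum of the per-gene counts,
matching the arithmetic of the published table it mirrors, not the number
of distinct carrier individuals.

## Prefilter

Three predicates, conjoined; the retained set is independent of evaluation
order, and the stage recorded for an excluded variant follows the fixed
audit order effect → frequency → ClinVar.

* **Effect** — consequence in the moderate/high-impact set (in-frame
  indel, frameshift, missense, canonical splice, start/stop loss, stop
  gain, UTR deletion), or max(dbscSNV ada, rf) > 0.5. Absent splice scores
  are treated as 0: an unscored variant is never rescued, because rescue
  requires a score *above* the cutoff. UTR deletions are the only UTR
  consequence admitted; UTR SNVs fall under "noncoding".
* **Frequency** — excluded when strictly above any cutoff: > 10 gnomAD
  heterozygotes, > 20 local-cohort carriers, > 3 homozygotes in either
  population. "Local carriers" counts heterozygous-or-homozygous
  individuals.
* **ClinVar** — benign, likely benign, and benign/likely-benign-vs-VUS
  conflicts are excluded; additionally, noncoding and synonymous variants
  without a splice signal that are absent from ClinVar or recorded as VUS
  are excluded. P/LP-vs-VUS conflicts are *not* exclusions and proceed to
  classification.
* **Bypass** — variants with multiple unanimous pathogenic ClinVar
  submissions are retained regardless of the effect and frequency filters
  (founder variants can be common). The audit reports both with-bypass and
  without-bypass retained totals.

## Classification engine

Criteria are assigned at fixed strengths from annotation fields; the engine
never computes predictor scores itself (the in-silico consensus,
conservation, pext, NMD position flag and literature fields are inputs).

* **PVS1** (loss-of-function decision tree): requires a haploinsufficient
  gene, a null consequence (frameshift, stop gain, canonical splice, start
  loss), and a biologically relevant transcript (exon pext > 0.5). Strength
  is very strong when nonsense-mediated decay is predicted — the premature
  stop lies 5′ of the last 50 nt of the penultimate exon, or known
  pathogenic variants lie downstream — and strong for NMD-escaping nulls.
  Canonical splice variants substitute reading-frame disruption for the NMD
  position rule (disrupted → very strong, preserved → strong); when frame
  impact was never assessed the evidence is unassessable and the variant is
  forced to VUS with an audit note. This override is the single place where
  the final class is not a pure function of the assigned criteria set.
  Start-loss variants carry no NMD rule and are treated as NMD-escaping
  nulls (strong) — the tree's default for nulls without a decay prediction.
* **PS4** (case burden): at gnomAD frequency ≥ 0.001% a reported
  case-control OR > 5 gives strong; below 0.001% the tier comes from
  previously reported patient counts (> 4 strong, > 2 moderate,
  > 1 supporting). Equality with the 0.001% boundary uses the case-control
  branch (the tiering text leaves equality unassigned; the common-variant
  branch is the conservative choice).
* **Frequency criteria**: BA1 stand-alone at af ≥ 5% (the canonical
  stand-alone cutoff; configurable), else BS1 strong above the per-gene
  benign cutoff, else PM2 at supporting strength (PM2_SUP) at af ≤ 2×10⁻⁵
  or absence from gnomAD. Mutually exclusive by construction.
* **Remaining criteria**: PP2 for missense in genes with missense-constraint
  z > 3.09; PS1/PM5 from prior ClinVar pathogenicity at the same amino-acid
  change / residue (PS1 pre-empts PM5); PS3/BS3 from functional studies;
  PP1/BS4 from segregation; PP3/BP4 from the in-silico consensus field
  (pathogenic/benign/mixed — the engine does not run predictors and no tool
  list or vote rule is modeled); PM1 for missense in annotated functional
  domains; PM4/BP3 for protein-length changes outside/inside repeat
  regions; BP7 for non-conserved synonymous variants (PhastCons < 0.2,
  configurable) without a splice-site impact.
* **PMS2 homology mask**: PMS2 variants outside the pseudogene-free region
  are dropped from classification and burden entirely.
* **Gene profile**: per-gene haploinsufficiency, z-score and BS1 cutoff ship
  as a YAML table. The haploinsufficiency flags (all true), z-scores and
  BS1 cutoffs are *placeholders* standing in for curated values; deployments
  against real data must override them. Gene-specific expert-panel rule
  sets (e.g. for ATM) are supported only to the extent the profile fields
  express them.

### Point combination

Evidence combines on the Bayesian point scale: very strong 8, strong 4,
moderate 2, supporting 1; benign-side strong −4, supporting −1; BA1
short-circuits to benign. Thresholds: pathogenic ≥ 10, likely pathogenic
6–9, VUS 0–5, likely benign −6…−1, benign ≤ −7. The scale reproduces the
three pinned combination rules: very strong + moderate = 10 → pathogenic;
two strong = 8 → likely pathogenic; PVS1 + PM2_SUP = 9 → likely pathogenic
(so PVS1 alone, 8 points, is likely pathogenic, and PM2 alone, 1 point,
is VUS).

The test suite contains an independently coded count-combination rule list
(classic criteria-combination table plus the three amendments) and compares
it with the point engine over every subset of ≤ 5 criteria (12,616 cases).
Disagreements fall into documented classes — mixed-evidence subsets, where
the classic table has no netting rule, and 25 pure-side interpolation cases
(e.g. a single strong benign criterion is LB by points but uncombined in
the classic table) — each asserted against a whitelist; any disagreement
outside those classes fails the suite.

## Burden statistics

Per-gene 2×2 tables (carriers vs non-carriers, study vs control) are tested
with the two-tailed Pearson χ² (df = 1, no Yates continuity correction by
default; switchable) via `scipy.stats.chi2_contingency`, and effect sizes
are odds ratios with Woolf log-normal 95% CIs (z = 1.96). Any zero cell, or
zero study carriers, yields NA statistics, matching the NA rows of the
published table. Display rounding is half-up: 2 decimals for percentages
and odds ratios, 3 for χ². Control counts may be supplied directly or
reconstructed from printed percentages by half-up rounding; because printed
percentages are rounded, per-gene χ²/OR values reconstructed this way are
best-effort and can differ in the last digit from the originally published
per-gene statistics (the exact control counts were never published). The
Sum-row reconstruction is exact: 2.10% of 134,187 gives 2,818 controls and
an OR of 1.02.

No multiple-testing correction is applied, deliberately mirroring the
published analysis.

## Synthetic cohort generator

The generator emulates the study design, not any real sequence data. Its
defaults are the study conditions: 7,091 individuals, a 134,187-individual
control, 694 distinct candidate variants, per-gene P/LP carrier
prevalences equal to the published study column (e.g. ATM 36/7091), control
prevalences equal to the published control column, and a truth-class mix
taken from the published cascade (8.7% pathogenic, 2.0% likely pathogenic,
60.1% VUS, 24.8% likely benign, 4.4% benign).

Carriage is an independent Bernoulli draw per individual per gene; each
carrier is assigned one of the gene's P/LP variants uniformly, so no
individual carries two variants of the same gene (compound genotypes and
linkage are not modeled). Non-P/LP variants receive small background
carriage only in genes with non-zero prevalence; with all prevalences zero
the cohort carries nothing. Annotation regimes per truth class are
constructed so the engine recovers the intended class (a pathogenic-regime
variant is an NMD-predicted null in a haploinsufficient gene with damaging
functional studies; roughly one in seven is instead a founder-like known
pathogenic variant that is common in gnomAD and exercises the bypass);
unconstrained fields are drawn from documented defaults, e.g.
pext ~ U(0.6, 1) and PhastCons ~ U(0.7, 1) for coding variants.

What passing tests show — and what they do not: the generator's bundles are
*clean by construction*. Recovery and truth-compatibility results
demonstrate that the plumbing (filters, criteria, points, counting,
statistics) is correct under the assumed annotation regimes; they say
nothing about annotation quality, missing or conflicting evidence,
population structure, compound heterozygosity, or copy-number variation in
real cohorts.

## Numerical conventions and problem sizes

Rounding is decimal half-up throughout (never banker's). Determinism comes
from a single `numpy` generator seeded from the config (the control sampler
uses a spawned stream so cohort and control draws are independent).
Calibration checks use seeded simulation at the study's sample sizes
(7,091 vs 134,187): 1,000 null tables for the χ² type-I error against the
binomial 99% interval around 0.05, 2,000–5,000 tables at a true OR of 2 for
the 94–96% Woolf-CI coverage band, and one full cohort run for per-gene
prevalence recovery against exact binomial 99% intervals — sizes chosen so
the whole suite runs in seconds while keeping Monte-Carlo error well inside
the tested bands. With thirteen genes checked at the 99% level jointly, an
occasional single-gene excursion is expected (about one run in eight);
the analysis driver reports the per-gene outcome rather than hiding it.

## Known limitations

* The per-gene published χ²/OR values are not exactly reproducible from
  public information (rounded control frequencies); only the Sum row and
  all prevalence arithmetic are pinned.
* BS1 cutoffs, z-scores and haploinsufficiency flags are placeholder
  profile values, not a curated release.
* The classification engine consumes annotations; it neither fetches
  ClinVar nor computes predictor scores, so its output is only as good as
  the input bundle.
* One published total is internally ambiguous in the source material
  (a 649 vs 694 candidate-variant count); the audit reports both
  with-bypass and without-bypass retained totals instead of resolving it.
* Copy-number and methylation events, de novo status, and phenotype-linked
  criteria (PS2, PM3, PM6, PP4, BP2, BP5), as well as PP5/BP6, are outside
  scope by design.
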