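# Methods

This note records the models and procedures the package implements, the
parameters that matter, the numerical choices made where the underlying
field practice is loose, and what the synthetic-data tests do and do not
demonstrate.

## Barcode identity

Pairwise identity is computed from a global alignment with free terminal
gaps ("overlap" alignment): match +1, mismatch −1, gap open −2, gap extend
−0.5, end gaps free. These scores are conventional for closely related
mitochondrial fragments and are configurable (`AlignmentParams`). Percent
identity is matches / aligned columns × 100 over the overlapping fragment:
terminal gap columns (outside either sequence's own first–last residue span)
are excluded from the denominator, internal gap columns are counted as
mismatches, and two IUPAC codes match whenever their base sets intersect.
Published identity values rarely state these conventions; fragments differing
only in overhang handling typically differ by < 0.3 percentage points at
barcode length, which is why any comparison against externally reported
identities should carry a tolerance of that order.

To make the statistic symmetric despite tie-breaking inside the aligner, the
pair is aligned in a canonical order (sorted by sequence then id) and the
result mapped back. Ranking against a reference set is exhaustive — every
query–reference pair is aligned — because reference libraries at this scale
are hundreds of sequences at most; ties are broken by longer aligned overlap,
then lexicographic reference id. There is no heuristic seeding step and no
external alignment dependency beyond Biopython's `PairwiseAligner`.

One property worth stating precisely: matches/overlap-columns is *not*
strictly monotone under sequence corruption. A substitution at a fragment end
can be shed into free overhangs, shrinking the denominator and raising the
ratio by up to about two columns' worth (≈ 100·2/L points, i.e. +3 points on
a 60-nt toy but +0.03 at 550 nt). The test suite asserts exactly this bounded
form; at barcode fragment length the statistic is effectively monotone.

In-silico fragment extraction slides each primer over the template (reverse
primer as its reverse complement, downstream of the forward site), accepts
the placement with fewest mismatches within `max_mismatch` (default 2,
leftmost on ties; IUPAC-aware), and returns the inter-primer insert. A
reverse site found only upstream of the forward site is reported as an
orientation error, distinct from a missing site.

## Identification verdicts

Thresholds (configurable via `Thresholds`): nominal ≥ 99.0% identity,
candidate ≤ 97.0% (> 3% divergence), margin to the best other-species hit
≥ 1.0 percentage point. The 97–99% band is ambiguous by default. Adult
references take precedence; tadpole references are used only when no adult
reference exists, and the fallback is recorded in the rationale. Region
matching is an exact string comparison on a controlled locality vocabulary —
"same region" is an operational judgement of the reference library curator,
not a geometric computation.

Three routes lead to a *candidate* verdict:

1. identity to every described species ≤ the candidate threshold;
2. the only close (≥ nominal-threshold) reference is itself flagged as an
   unassigned divergent lineage — high identity to something that is not a
   described species is evidence for, not against, an undescribed lineage;
3. identity below the nominal threshold to an allopatric reference with no
   same-region reference available. This third route carries weaker evidence
   than the divergence rule and says so in its rationale; it reflects actual
   taxonomic practice, where a sub-nominal match to a population from a
   different massif is flagged rather than silently binned as ambiguous.

A geographic-parsimony flag can promote any non-nominal verdict to nominal
(recorded in `overrides`): a query collected at a species' type locality with
a sub-threshold match is provisionally assigned to that species. The verdict
is monotone in identity in the sense that raising the best identity never
moves a verdict toward candidate.

Candidate confirmation is deliberately binary: a lineage is a *confirmed*
candidate only when its divergence is corroborated by at least one consistent
morphological character **and** sympatry with its sister form; either failure
is named in the rationale.

## Ratios and descriptors

Measurements are millimetres; counts dimensionless; ratios are carried as
percentages (100 = equal). The verbal descriptor scale — 97–103 "equal",
95–96/104–105 "almost equal", 47–53 "in the middle", 45–46/54–55 "almost in
the middle" — is defined on integer percentages, so values are rounded
half-away-from-zero first; this makes boundary values like 96.5 deterministic
(→ 97 → "equal"). Anything outside those bands is "unclassified" rather than
an error, because most ratios (e.g. tail/body ≈ 150–280%) are simply not on
this scale.

Missing measurements are first-class: the standard 11-ratio panel contains a
ratio only when both operands are present and the denominator is positive,
and every downstream consumer tolerates partial panels. Total length is
stored as measured, never derived from body + tail; a TL vs BL + TAL mismatch
beyond 5% of TL is a validation *warning* (the three lengths are measured
independently and published values occasionally disagree).

## Cluster rules and guilds

The three cluster rule-sets are fixed transcriptions, not inferred clusters.
Hard constraints are the diagnostic categorical characters: dorsal papilla
gap present/absent, upper jaw sheath present/absent (unconstrained for
cluster 2, where one species group always lacks it), oral-disc margin state,
and the allowed LTRF patterns. Soft constraints are the published numeric
ranges (ratios in percent, papilla/keratodont counts), kept verbatim even
where internally inconsistent — the cluster-3 count ranges do not cover the
largest submarginal count (606) reported for the same voucher series — so the
rule file (`rheotad fixture --rules`, `data/cluster_rules.tsv`) can be
audited line by line against the source.

Assignment logic: clusters whose hard constraints all pass are candidates. A
*uniquely* hard-passing cluster is assigned outright; the categorical traits
and LTRF are diagnostic, and the numeric ranges summarise single-voucher
series too noisy to veto them. When several clusters hard-pass, the soft
score — the fraction of in-range soft constraints among those measurable,
with missing values excluded from numerator and denominator, and a ±2
percentage-point tolerance on ratio ranges only — decides: the maximum must
reach `soft_threshold` (default 0.6) and be unique, otherwise the specimen
stays unassigned with a per-rule report. A record with no measurable soft
constraint but passing hard constraints is assigned (vacuous soft evidence);
a record missing a categorically required trait hard-fails that cluster.

Guild mapping is fixed: cluster 1 → clasping, 2 → adherent, 3 → suctorial.

## Electivity and the ANOVA

E = (r − p)/(r + p) with r the within-stream use proportion and p the
availability proportion; E ∈ [−1, 1], antisymmetric in (r, p), undefined when
r + p = 0 (carried as NaN, never imputed). r > 0 with p = 0 gives the limit
+1; r = 0 with p > 0 gives −1. E is computed per stream so streams act as
replicates; a pooled-across-streams mode (counts summed, availability
averaged) is provided as a secondary option. The eight-specimen stream filter
(default `min_specimens=8`) removes streams whose sparse occupancy would
contribute many spurious −1 values.

The electivity ANOVA is an ordinary two-factor linear model,
`E ~ C(microhabitat) + C(species)`, with the interaction omitted by default
to avoid overparameterisation at realistic replicate counts; per-microhabitat
one-factor subset ANOVAs probe species differences within each microhabitat
instead. Undefined E cells are dropped and counted. A zero-variance response
is flagged `degenerate` (F reported as NaN) rather than raising. Fitting is
delegated to statsmodels (OLS + type-II ANOVA table).

Note that Ê = (r̂ − p)/(r̂ + p) is a ratio estimator with O(1/n) negative
bias (Jensen: E is concave in r). At n = 100 specimens over 8 microhabitats
the bias is ≈ 0.01–0.02 — smaller than the sampling spread of a single
replicate but *larger* than the standard error of a 200-replicate mean.
Recovery checks therefore compare the replicate mean against the analytic
value within the Monte-Carlo 95% spread of the replicates (±1.96 sd), which
tests consistency without demanding the estimator be unbiased.

## PCA of habitat variables

PCA runs on the correlation matrix (standardising away unequal variances) via
an eigendecomposition; loadings are orthonormal eigenvectors with a canonical
sign (largest-magnitude loading positive), scores are the standardised data
projected onto them. The number of retained components automates the visual
scree criterion as the largest second difference of the eigenvalue profile,
with a manual override. Species incidence (binary presence per stream) is
correlated with the retained scores as supplementary variables (Pearson r and
p) and never influences the decomposition; a species present everywhere or
nowhere is skipped. Optional Box-Cox preprocessing uses maximum-likelihood
lambda (scipy), shifting zero-containing variables by half their smallest
positive value and recording both lambda and offset in the transform log.
Constant variables are an error; rank deficiency is a warning.

## Synthetic data: what it emulates, and what it does not

All generators use numpy's seeded PCG64 (`default_rng`); a fixed seed gives
byte-identical output, and every generator returns a machine-readable truth
object.

* **Sequences** — uniform substitutions (Jukes–Cantor-like, no rate
  heterogeneity, no secondary structure), optional uniform single-site
  deletions. Appropriate because the identification statistic is raw percent
  identity, not a model-corrected distance. Default fragment 550 nt.
* **Morphometrics** — ratios drawn uniformly inside a cluster's soft ranges
  (shrunk 5% at each end), absolute measurements back-solved from a body
  length in the observed 6.0–13.5 mm span; the linked eye/naris ratios
  (NH/BH = EH/BH · NH/EH) are rejection-sampled jointly. `jitter` displaces
  exactly one ratio per affected record beyond the classifier's tolerance.
  No covariance between ratios beyond the arithmetic links is modelled.
* **Communities** — per stream and species, a Poisson specimen total (default
  mean 10) distributed multinomially with cell probabilities ∝ availability ×
  preference weight; availability is Dirichlet(3) per stream unless fixed.
  The truth is the analytic E of the normalised availability-weighted
  preference. Defaults mirror the study scale: 33 streams, 8 microhabitats,
  3 focal species. No spatial autocorrelation or detection error.
* **Habitat matrices** — X = F L′ + noise with factor scores exactly
  orthogonalised in-sample and loading columns built as constant-magnitude,
  mutually orthogonal sign patterns with strengths decaying by 0.7 per
  factor. This is deliberate: a planted factor basis is identifiable by PCA
  only up to rotation of its span unless the factors are uncorrelated
  in-sample, of distinct strength, and homogeneous in per-variable variance
  (so the correlation rescaling preserves the planted directions). With the
  naive construction (i.i.d. factor scores, random loadings), factor–PC
  loading correlations of 0.7–0.9 arise from rotation alone at n = 33 and a
  recovery criterion would measure the generator, not the PCA.

Passing recovery tests therefore show that the estimators recover *their own
generating model*; they say nothing about rate heterogeneity in real 16S,
measurement covariance in real tadpoles, or non-factor structure in real
habitat data.

## The voucher fixture

`data/voucher_fixture.csv` transcribes the printed values of the 22 published
DNA-voucher accounts — lengths, stage, LTRF, papilla counts where printed,
best-reference identity with accession, reference role/status flags, and the
published cluster/guild — with nothing imputed and a SHA-256 checksum guard.
The `same_region` column records the operational judgement applied in the
source accounts (e.g. a reference from a different locality accepted as
regionally consistent), which is irreducible to coarse geographic labels.
Two source quirks are carried verbatim and documented in the module: one
nominal account prints the same BL/TL pair as another species' account
despite a conflicting tail ratio, and one candidate's total length (29.5 mm)
exceeds the summary size range quoted for the strongly rheophilous forms.
For that reason the size-range summary reports both the full-fixture bounds
and the bounds over the strongly rheophilous subset (adherent + suctorial
guilds), the clasping-guild vouchers being explicitly excluded from that
comparison in the source's own framing.

## Problem sizes used by the checks

The shipped checks run at desk scale, chosen to match the study design while
keeping runs quick: 22 fixture vouchers; 200 multinomial replicates of 100
specimens for electivity recovery; a 33-stream × 10-variable habitat matrix
for PCA recovery; 1000 null simulations (6 streams × 3 species × 8
microhabitats, normal errors) for ANOVA type-I calibration, which lands at
≈ 0.04–0.06 against the nominal 0.05.

## Known limitations

* The identification classifier consumes one ranked list per query; it does
  not build trees or run coalescent delimitation, and the margin criterion is
  vacuous when the library holds a single relevant reference.
* Cluster rules are transcriptions; they cannot assign specimens whose LTRF
  falls outside the published patterns, by design ("unassigned" is an
  informative outcome, not a failure).
* The electivity ANOVA treats E values as exchangeable replicates across
  streams; no random stream effect is modelled.
* Box-Cox lambda is fitted per variable independently; no multivariate
  normality criterion is optimised.
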