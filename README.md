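# rheotad

Integrative larval taxonomy for strongly rheophilous stream tadpoles
(*Boophis*, Mantellidae, Madagascar): DNA-barcode species identification with
candidate-species flagging, oral-disc morphometrics with labial tooth row
formula (LTRF) handling, rule-based ecomorphological guild assignment, and
microhabitat-electivity analysis. The package is aimed at herpetologists and
molecular ecologists matching tadpoles to species in species-rich tropical
stream communities, where many lineages are known only from larvae
("reverse taxonomy").

## What it computes

**Barcode identification.** A tadpole's mitochondrial 16S fragment is compared
against a reference library by global alignment with free terminal gaps;
percent identity is matches / aligned columns × 100 over the overlapping
fragment (internal gaps count as mismatches, IUPAC codes match on set
intersection). The verdict is *unequivocal nominal* (≥ 99% identity to a
described species from the same region, clearly less similar to all others),
*candidate species* (≤ 97% identity to every described species, i.e. > 3%
divergence — or the only close reference is itself an unassigned divergent
lineage, or the best match is sub-nominal and allopatric), or *ambiguous*.
Candidates are labelled `Binomial [CaN evidence]`, and are *confirmed* when
genetic divergence is corroborated by consistent morphology **and** sympatry.

**LTRF.** Formulas such as `8(5–8)/3` (eight upper keratodont rows, rows 5–8
medially interrupted; three uninterrupted lower rows) are parsed, canonically
formatted, and summarised into interrupted/uninterrupted row counts.

**Clusters and guilds.** Three fixed oral-disc rule-sets (categorical traits +
LTRF patterns as hard constraints, published ratio/count ranges as soft
constraints) assign specimens to morphological clusters that map onto the
classical guilds: 1 → clasping, 2 → adherent, 3 → suctorial.

**Ecology.** Ivlev's electivity index E = (r − p)/(r + p) per stream ×
species × microhabitat (8 microhabitats = {fast, slow} × {rock, gravel,
leaves, sand}), an eight-specimen stream filter, occupancy summaries,
Box-Cox preprocessing, correlation-matrix PCA with scree-elbow retention and
species incidence as supplementary variables, and a two-factor ANOVA of E
(microhabitat + species, no interaction) with per-microhabitat subset ANOVAs.

**Synthetic data.** Seeded generators with recorded ground truth emulate every
input — sequence sets at controlled divergence, morphometric records inside a
cluster's envelope, multinomial microhabitat counts, and habitat matrices
with planted factor structure — standing in for the unpublished field data.

A packaged fixture transcribes the 22 published DNA-voucher tadpole accounts
(lengths, stage, LTRF, papilla counts, best-reference identities and flags).

## Worked example

```python
>>> import rheotad as rt
>>> rt.ltrf_summary(rt.parse_ltrf("7(5–7)/3"))["uninterrupted_upper"]
4
>>> report = rt.fixture_report()
>>> (report.verdict == "candidate").sum()
12
>>> report.assigned_cluster.value_counts().sort_index().tolist()
[3, 12, 7]
>>> rt.fixture_size_range()
{'TL_min': 12.7, 'TL_max': 27.1, 'BL_min': 6.0, 'BL_max': 13.5,
 'TL_min_all': 12.7, 'TL_max_all': 29.5, 'SMP_max': 606, 'n_entries': 22}
```

Of the 22 vouchers, 12 are flagged as undescribed candidate species and 10
identified to nominal species; the cluster rules place 3 vouchers in the
clasping guild, 12 in the adherent guild and 7 in the suctorial guild. The
strongly rheophilous subset (adherent + suctorial) spans 12.7–27.1 mm total
length, and the largest submarginal papilla count on record is 606.

The same steps are available from the shell (`rheotad identify`, `rheotad
classify`, `rheotad electivity`, `rheotad pca`, `rheotad simulate`, `rheotad
fixture`, `rheotad report`), and the numbered scripts under `analysis/` run
the full narrative — simulate inputs, identify, classify, electivity ANOVA,
habitat PCA — writing tables under `results/`. For example:

```text
$ python analysis/04_microhabitat_electivity.py
sp_A: occupies 33/33 streams, mean 9.0 specimens (min 3, max 14)
  23 streams reach the 8-specimen threshold
...
two-factor ANOVA (no interaction): F_9,582 = 11.953, p = 0.0000
mean E in slow gravel (avoided by construction): -0.80
```

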