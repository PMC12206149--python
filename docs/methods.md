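# Methods

## Cohort model

A cohort is a set of pedigrees (6-column PED), a genotype matrix
(multi-sample VCF), per-variant annotations (gene symbol, per-panel allele
counts, four prediction-tool columns), a gene → retina nTPM table, and an
optional per-patient clinical table. Coordinates are 1-based as in VCF; no
reference checking or liftover is performed — annotations are taken as
given. Multiallelic sites are decomposed to one biallelic record per
alternate allele; a genotype allele referring to a different alternate
counts as reference for the current record (the simplest consistent
convention, logged when it occurs). Phase separators are ignored on input;
the phase needed for compound-heterozygote checks is inferred from parents
instead. Pedigree members absent from the VCF are marked unsequenced and
drop out of segregation testing rather than failing variants; whether all
members of a family were sequenced is therefore an explicit per-individual
flag, never an assumption.

## Filters

**Frequency.** The cap for panel (N, c) is ⌊2Nc⌋ with an inclusive
comparison: 27/108,000 equals 2.5×10⁻⁴ exactly and still passes, which is
what makes the five shipped panels produce caps 30/70/0/27/1. An absent
allele count means unobserved and is treated as 0 at filter time (the
missingness itself is preserved by I/O). Allosomes are treated as diploid
for cap purposes because panel sex composition is unknown; this slightly
overstates 2N on chrX and is a documented limitation. The in-house panel's
AC is filtered as supplied — no attempt is made to subtract the proband's
own allele.

**Segregation.** Strict full penetrance and no phenocopies by default: one
unaffected carrier kills a variant. `max_unaffected_carriers` relaxes
this; `allow_hom_alt_affected` (default true) accepts homozygous affected
carriers under the dominant model. Missing genotypes and unknown-affection
members are excluded from both sides of the comparison; a family whose
only affected member is uninformative fails the variant (no informative
affected = no evidence of segregation). Families with a single sequenced
affected member pass trivially and inflate candidate counts — they are
flagged per family in the report rather than silently handled. In the
recessive mode, trans phase for a compound-het pair is enforced only when
both parents of an affected are sequenced and genotyped at both sites: if
no assignment puts the two variants on opposite parental sides the pair is
rejected as cis; a de novo (parent-absent) allele is unphaseable and gets
the benefit of the doubt, the permissive choice for unphased exomes.

**Consensus.** Per-tool defaults follow each tool's published convention:
SIFT ≤ 0.05, PolyPhen-2 ≥ 0.446, PROVEAN ≤ −2.5, MutationTaster label
"disease_causing" (and its automatic/single-letter variants). Each slot
accepts a raw score or a categorical label; unresolvable values become
unknown, which counts as not-damaging — conservative for a rule that keeps
variants. A strict mode requires all four calls resolvable. Variants with
no scores at all (e.g. non-missense) resolve to 0 damaging calls and are
excluded, matching a missense-oriented cascade.

**Expression.** Exclusion applies strictly below 1 nTPM, so exactly 1.0
is retained. A gene absent from the table is excluded by default
(`keep_unannotated_genes` retains it). Symbols match case-insensitively
after whitespace stripping; no alias resolution.

**Order.** Filters are applied frequency → segregation → consensus →
expression for exclusion-reason attribution. Because each filter is a pure
per-(variant, family) predicate, the surviving set is invariant under any
permutation of the four; this is asserted by a property test, not assumed.

## Recurrence

A pedigree contributes at most once per gene; the denominator is every
analyzed pedigree, including those with empty candidate lists. Percentages
are rounded half-up to two decimals. With 78 pedigrees this yields 33.33
(26), 16.67 (13), 7.69 (6), 5.13 (4) and 1.28 (1); ranking is descending
by pedigree count with lexicographic tie-break, so reruns are
byte-deterministic.

## Clinical statistics

Stages Ia, Ib, IIa, IIb, IIIa, IIIb map to 1–6; correlations use this
ordinal encoding with midranks for ties. Spearman's coefficient is
computed as the Pearson correlation of midranks with a two-sided t-based
p-value (scipy), and a test keeps an independently computed
Pearson-of-midranks oracle agreeing to 1e-12. Welch's t reports the
Welch–Satterthwaite df; Mann-Whitney U uses the normal approximation with
tie correction; Levene centers on group means by default (median gives
Brown–Forsythe). Constant inputs raise an explicit degenerate-input error
rather than returning NaN. Because a summary such as "median 34.75 ± 3.63"
mixes location and dispersion conventions, the summary emitter reports
median, mean and SEM separately. Patients contribute one record each.

## Synthetic cohort generator

The generator emulates the study design the cascade assumes: by default 78
two-to-three-generation families (sizes 4–7) grown from a founder couple,
with 13 families segregating a dominant causal variant in a
retina-expressed gene (defaults mirror the published cohort arithmetic:
13/78 carrier families, full penetrance, a stage distribution of 17:4:1
over IIb/IIIa/IIIb, and a stage-onset rank-correlation target of −0.447).
The causal allele is dropped Mendelianly from the carrier founder (p=1/2
per meiosis), so the dominant pattern is genetically consistent rather
than painted on; at penetrance 1, carriers are exactly the affecteds.
Non-causal families receive one phenocopy affected (disease of unmodelled
cause), guaranteeing every pedigree at least one affected and — via the
non-carrier founder — at least one unaffected member.

Each background variant lives in its own gene and is independently
*constructed* to pass or fail each filter with configured probabilities
(defaults 0.1 / 0.2 / 0.4 / 0.7 for frequency / segregation / consensus /
expression — not stated by any source; chosen once as a plausible post-QC
missense mix whose rates exercise every filter in both directions). A
segregating background variant is heterozygous in the affecteds of one
random host family; a failing one additionally in a random unaffected host
member. Truth records the host family and the per-filter construction
flags, plus the full non-reference genotype matrix.

Clinical tables use a Gaussian copula: latent Pearson correlation
2·sin(πρₛ/6) targets the requested Spearman ρₛ, onsets map to a 3–60-year
range, and stages are quantile-binned (equal bins by default; the cohort
generator uses the 17:4:1 distribution). Binning attenuates the realized
coefficient somewhat — tests therefore check Monte-Carlo bands, not point
equality. At ρₛ = ±1 a comonotone construction replaces the copula: onset
is a strictly monotone function of the stage ordinal, so the tie structure
matches and the realized coefficient is exactly ±1.

Determinism: one RNG stream per output table (pedigrees, background /
annotations, clinical), all spawned from the master seed, and all files
written with fixed ordering and number formats, so identical config + seed
reproduce identical bytes.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra (panel ACs are drawn directly against the caps),
sequencing error, incomplete sequencing of family members, locus or allelic
heterogeneity of the causal gene, and age-dependent penetrance. Passing
tests therefore demonstrate the cascade's correctness under its own model
assumptions, not robustness to real-exome artifacts.

## Problem sizes

The test suite and the acceptance script run cohorts of 78 families with
300–1,200 background variants, oracle cross-checks on 100 random
20-family × 200-variant cohorts, and clinical recoveries at n = 200–300 —
sizes at which the binomial and Monte-Carlo bands used in assertions are
informative while the whole suite stays fast on a single CPU.

## Known limitations

X-linked and mitochondrial models, imputation, burden testing and live
frequency-database queries are out of scope. The cohort-wide union of
candidate genes depends on a dedup rule the report makes explicit (union
of per-family gene sets); per-family counts are reported alongside it.
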