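# Methods

## Study design being modeled

The pipeline implements the analysis used in family-based exome studies of
left-sided congenital heart disease: multiplex families (two or more
affected relatives) are exome sequenced, and a variant is a candidate only
if it is rare, predicted damaging, inside the capture regions shared by all
kits used, and co-segregates with disease in the family. Because left-sided
defects show reduced penetrance and familial clustering of moderately rare
alleles, the frequency ceiling is configurable between 0.01 (default) and
0.05 (relaxed), and the dominant model can tolerate unaffected carriers
when reduced penetrance is suspected.

## Filtering model

Three independent per-variant predicates are applied in a fixed order
(region → frequency → impact); because they are independent, permuting the
order changes the recorded funnel but never the surviving set (property
tested).

- **Region**: the variant's VCF POS (converted once to 0-based) must lie in
  the intersection of the capture-kit BEDs. Membership is a point test on
  the anchor base; an indel's REF span is not required to be fully
  contained — the simplest defensible reading of "contained in mutually
  covered regions". Padding is off by default; a symmetric `pad` (bp) is
  available because coverage summaries are often computed over exonic
  regions padded by a few bases.
- **Frequency**: maximum allele frequency over all populations of both
  exome and genome cohorts must be ≤ `maf_max` (inclusive). "MAF" is taken
  as the alternate-allele frequency; at these thresholds minor/alternate
  coincide, and frequencies above 0.5 are folded with a warning.
- **Impact**: Phred-scaled CADD ≥ `cadd_min` (default 20). Tiers are
  I (≥ 30), II ([20, 30)), III (< 20). Variants without a CADD score
  (common for indels) are retained with an `unscored_cadd` flag by default
  (`unscored_policy: retain_flagged`), since real causative indels would
  otherwise be silently dropped; a `drop` policy is available.

**Low-coverage rescue.** The original workflow rescued plausibly
disease-causing calls with thin coverage after manual alignment review.
The automated proxy here is deterministic and auditable: a variant in a
configured gene of interest whose affected-member calls include one at
depth ≤ `rescue_depth_max` (default 10) is (re-)admitted iff every
sequenced affected member has ≥ 1 variant-supporting read; rescued
variants carry a needs-orthogonal-confirmation flag, and rescue is the only
path by which a missing affected genotype can count as a carrier call in
segregation. Rescue re-admissions are tracked outside the funnel, whose
steps remain monotone by construction.

## Segregation models

- **Dominant**: every sequenced affected member carries ≥ 1 alternate
  allele; sequenced unaffected members carry none unless
  `allow_unaffected_carriers` is set, in which case carriers are recorded
  (`carrier_unaffected`) and the result is marked as having used reduced
  penetrance. Missing genotypes in unaffected members are ignored; in
  affected members they fail the variant (conservative) unless rescued.
- **Recessive (homozygous)**: affected members homozygous alternate, no
  unaffected member homozygous, and sequenced non-affected parents of
  affected members must be heterozygous carriers.
- **Compound heterozygous**: unordered pairs of variants in one gene, each
  heterozygous in every sequenced affected member. Phase uses parental
  transmission only (no read-backed phasing): when for some affected member
  each variant has exactly one carrier parent and the parents differ, the
  pair is trans-confirmed; when they coincide, the pair is provably cis and
  excluded; otherwise phase is unknown and the pair is retained flagged
  (ranked below trans-confirmed pairs by consumers). A trans-confirmed pair
  additionally fails if a sequenced unaffected member carries both
  variants.

Which models run for which family is configuration, not inference — in the
modeled study recessive/compound-het models were added only for families
whose structure warranted them. X-linked logic is not modeled; X sites are
processed as autosomal with a warning. Verdicts for both single-site models
are verified against exhaustive genotype-enumeration oracles on pedigrees
up to six members, and the compound-het path against a transmission oracle
over all trio configurations.

## Prioritization and oligogenic pairs

Gene evidence drives ranking: `strong` (human CHD report) > `supported`
(mouse model or cardiac-development role) > `unsupported`; within a class,
CADD tier I > II > unscored > III, then higher CADD, then lower frequency,
then genomic position as the final deterministic tie-break. Homozygotes in
the population database or a frequency more than 10× a typical
family-private allele (10 × 10⁻³) attach demotion *flags* without changing
rank, because the corresponding decisions in practice mix in clinical
judgment that is out of scope.

For two co-segregating candidates in different genes, the co-occurrence
probability is the product of their maximum population allele frequencies,
`P = f_A × f_B` — the probability that a single individual drawn from the
population carries both alleles, reproducing the arithmetic as printed in
the modeled analyses (0.014 × 0.012 = 0.000168). A Hardy–Weinberg carrier
variant, `(2p(1−p)) · (2q(1−q))`, is available behind `carrier_model=True`
for users who prefer genotype-frequency semantics.

Percentages (diagnostic yield, allele fractions) round half-up to the
nearest integer, matching 8/19 → 42% and 38/227 → 17%.

## Synthetic cohorts

The generator emulates a family exome callset, not reads:

- **Background sites**: allele frequencies log-uniform on [10⁻⁵, 0.05]
  (rare-variant-dominated, as in an exome after common-variant removal);
  CADD mass 85% below 20, 10% in [20, 30), 5% ≥ 30 — so ~15% of background
  survives the impact filter and, combined with the frequency filter,
  ~12% survives overall, which the tests check against the analytic
  expectation within binomial error.
- **Transmission**: founders are Hardy–Weinberg draws at each site's
  frequency; each non-founder receives one allele per recorded parent,
  chosen uniformly per site (linkage equilibrium — sufficient for
  filter/segregation testing; a stated limitation for phase realism).
  Unrecorded parents contribute founder-like draws.
- **Causal injection** (template mode, the default): causal genotypes are
  overwritten to be consistent with the declared model and the pedigree's
  affection pattern — dominant alleles propagate through a carrier closure
  (affected members plus the minimal connecting parents), recessive sites
  set affected members homozygous with carrier parents, and pair models
  place one variant on the paternal and one on the maternal transmitted
  haplotype so the pair is unambiguously trans. All overwrites preserve
  Mendelian consistency, which `mendelian_check` verifies to be violation-
  free at zero missingness for every seed.
- **Genotype mode**: a founder carrier is seeded, alleles drop naturally,
  and affection is assigned as risk-genotype × penetrance — used to check
  the penetrance semantics themselves.
- **Depth**: negative binomial with mean 70 and size 8 (overdispersed
  exome-like coverage); allele depths split Binomial(depth, ½) for
  heterozygotes; designated genes can be forced to depths of 3–10 to
  exercise the rescue path. Identical seeds give byte-identical output
  files.

What passing simulator-based tests does *not* show: behaviour under linkage
disequilibrium, caller artifacts, strand or mapping biases, population
stratification of frequencies, or segmental duplications — the generator
has none of these.

## Problem sizes and numerical choices

The recovery sweep runs 200 seeded simulations per inheritance model
(pedigree shapes with 2–4 affected members, 1,000 background variants,
causal MAF 0.001 / CADD 35 / penetrance 1.0) and requires ≥ 99% recovery
and ≥ 95% rank-first; observed rates are 200/200 on all models. Interval
oracles use 10 kb genomes where per-base sets are exact. All thresholds are
inclusive (`maf ≤ 0.01` passes at exactly 0.01; CADD 30.0 is tier I);
ties in ranking fall through to genomic position so output is total and
deterministic. Half-calls (`0/.`) are treated as missing genotypes.
Multi-allelic records are split per alternate with genotypes recoded
against each alternate; inputs are otherwise assumed caller-normalized (no
left-alignment is performed).

## Known limitations

- Genomic coordinates in the packaged candidate table are placeholders;
  the upstream publication reports transcript-level HGVS only.
- The pipeline's `causative` outcome class (a strong-evidence candidate
  survives) is a mechanical proxy for a judgment that, in the modeled
  study, also weighed functional validation.
- No de-novo model, no linkage/LOD statistics, no structural variants, no
  gVCF, no read-backed phasing.
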