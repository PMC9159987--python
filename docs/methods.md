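# Methods

This note documents the inference model, the choices made where the
procedure was genuinely open, the simulator's scope, and known limitations.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The inference problem

In a complex of hybridizing ferns, each collected plant yields:

* a **chloroplast haplotype** (here a concatenated *rbcL*+*matK* stand-in),
  maternally inherited, so shared haplotypes mean shared maternal lineage;
* **nuclear allele calls** at one or two low-copy loci (*Knox3*-like and
  *IBR3*-like), biparentally inherited, with allele labels grouped into
  clade-level **lineage groups** (A–H, etc.);
* a **ploidy** from flow cytometry (2x, 3x, or unknown) constraining how
  many allele copies the genotype can hold;
* a **spore count** per sporangium: 64 = sexual, ≤32 = apogamous
  (asexual); counts in between or above do not fit either mode and are
  left unknown.

The unit of bookkeeping is the **genotype record**: a distinct combination
of (taxon, per-locus nuclear genotype string, chloroplast haplotype),
carried by one or more samples. Parentage runs on a single primary nuclear
locus (the *Knox3*-like one by default — it resolves more lineages); the
second locus is carried through and reported but not enforced.

## Genotype assembly

A genotype is the multiset of distinct alleles retained for a sample at a
locus, canonically ordered by letter prefix then numeric value (A5 < A12 <
D7). With known ploidy:

* distinct alleles = ploidy → plain genotype;
* one allele in a diploid → doubled homozygote (`A7` → `A7A7`) — the
  standard reading of a single clean amplicon product in a diploid;
* any other shortfall → the **unassorted flag** `*` (e.g. `A1D7*` for a
  triploid with two distinct alleles): dosage cannot be asserted, and the
  assembler never invents it (in particular it never emits a triple
  homozygote; the one such string in the packaged table is carried
  verbatim from the source, not regenerated);
* more alleles than ploidy → an error (contamination or a wrong ploidy
  call), never silent truncation.

With unknown ploidy the observed alleles are kept and the flag is unknown.

## Parental vs hybrid classification

A record is **parental** when it has a chloroplast haplotype, has nuclear
data, and either

1. is homozygous (one distinct allele), or
2. carries alleles of a single lineage group, is diploid or
   ploidy-unknown, and is *sexual*, or *anchored*: it shares an allele
   with a homozygous **diploid** record of the same taxon and carries a
   chloroplast haplotype seen among that taxon's homozygotes.

Everything else — multi-group genotypes, unanchored same-group
heterozygotes, records lacking nuclear data — is treated as being of
hybrid origin.

Why the anchoring clause: a same-group heterozygote is ambiguous between
(a) segregating allelic variation within one (possibly facultatively
sexual) parental taxon and (b) a cryptic hybrid between two related
lineages of the same group. Sharing an allele with a sexual-capable
(diploid) homozygote of the same taxon, on the same maternal background,
is the observable signature of case (a); a same-group heterozygote whose
anchor is only a triploid (apomictic, hence not producing the
heterozygote by segregation), or whose maternal haplotype differs from
all of its taxon's homozygotes, is parsimoniously a hybrid. The
no-chloroplast gate exists because a parental record serves as the anchor
of maternal-lineage inference; a record that cannot anchor anything is
not usable as a parent even if homozygous.

Records without nuclear data cannot be classified positively; they are
reported in the hybrid bucket with a note, which keeps
parental + hybrid = total as a strict partition.

## Maternal-lineage inference

For each chloroplast haplotype, the maternal nuclear group is decided by a
cascade over its carrier records:

1. **parental carriers** — if exactly one lineage group occurs among the
   haplotype's parental-status carriers, that group is the maternal
   lineage (confident);
2. **universal co-occurrence** — otherwise, the group(s) present in
   *every* carrier of the haplotype (a haplotype that always travels with
   group A alleles had an A-lineage mother even if no parental carrier
   was sampled);
3. **ambiguity set** — otherwise all co-occurring groups, flagged.

The cascade order is a design choice: parental carriers are direct
observations of the maternal lineage, universal co-occurrence is an
inference over hybrids only, and the ambiguity set is a refusal to guess.

## Parentage assignment

For a hybrid record, the maternal side collects its alleles belonging to
the maternal group(s). Two refinements:

* **Intra-group hybrids**: when several alleles fall in the maternal group
  (e.g. `D4D7` where both are group D), the alleles carried by the
  haplotype's own parental carriers pin the maternal one (the `cy`
  haplotype's parental carrier is the D4 homozygote, so D4 is maternal and
  D7 paternal).
* **Unreduced maternal gametes**: a triploid may legitimately carry two
  maternal-group alleles (e.g. `A1A6D7` from an unreduced A1+A6 gamete);
  both stay maternal.

Parents are then attributed per allele through the **parental registry**:
the taxa whose parental records carry that exact allele. When no parental
taxon carries the allele, attribution falls back to the allele's group
*only if exactly one parental taxon owns that group* (group F → the
F-homozygous taxon); a group owned by several parental taxa, or by none,
yields an undiscovered-lineage placeholder (`unknown[D5]`) rather than an
ambiguity set — attaching every group-D hybrid to both group-D parental
taxa would fabricate parentages the data cannot support. Ambiguity that
does survive (several exact carriers, ambiguous maternal group) is kept
as a set and flagged.

Records with no chloroplast data get contributing lineages listed unsided;
records whose maternal group is absent from the genotype are flagged
unresolved with the reason.

## The reticulogram and summary counts

Network nodes are distinct (taxon, genotype string) units — parental
genotypes, hybrid genotypes, and dashed placeholder nodes for undiscovered
lineages. Edges run parent → hybrid, typed maternal or paternal; ambiguity
sets expand to parallel edges flagged ambiguous; a hybrid missing either
side carries an `incomplete` flag. Exports: GML (networkx) and DOT
(maternal edges red, paternal blue, placeholders dashed).

Summary counts report: total genotype records, parental and hybrid record
counts, distinct parental taxa, and per-parental-taxon hybrid
contributions. The contribution counts use the (taxon, genotype string)
unit — several records differing only at the secondary locus are one
"hybrid taxon" — and are reported under all three role definitions (taxon
as maternal parent, as paternal parent, in either role), since "X was a
parent of N hybrids" is ambiguous between them.

## The packaged fixture

`fixtures/table1.tsv` transcribes the study's 72-row genotype table (one
row per distinct multilocus genotype, one representative voucher each);
`fixtures/PROVENANCE.md` documents every transcription judgment call, and
a checksum test freezes the content. `fixtures/characters.tsv` is a
**reconstruction**, not a transcription: the raw per-specimen morphology
matrix lives in a monographic treatment not packaged here, so states were
scored from the published association claims (see PROVENANCE). Association
results on it exercise the mining logic; they are not independent
biological evidence.

## The forward simulator

The generative model is deliberately the simplest one able to produce
diagnosable private alleles:

* **Parental divergence**: a star phylogeny. Each locus draws a random
  ancestral sequence; each parental taxon applies
  Binomial(length, rate) private substitutions, each to a uniformly
  chosen different base (a Jukes–Cantor-like choice). Parents are
  diploid and homozygous by default; `within_group_divergence` (in
  substitutions) optionally gives each parent two nearby alleles.
* **Default loci**: 2184 bp maternal (concatenated chloroplast stand-in),
  493 and 397 bp biparental — the dataset sizes of the study's markers.
* **Substitution rate**: 0.03/site per lineage branch, so two parents sit
  ~6% apart. The value is this package's choice (no published rate):
  it places between-parent distances several standard deviations above
  both the 0.99 read-clustering identity (1% radius) and the 0.02
  group-clustering cut, so lineage groups separate reliably at any seed,
  while staying in the range of between-clade divergences typical of
  low-copy nuclear markers in such complexes.
* **Hybridization**: an event names a maternal and a paternal taxon and
  the gamete type on each side — reduced (one allele copy) or unreduced
  (the full somatic pair, the route to triploids, in either direction).
  Child ploidy = contributed copies ∈ {2, 3}; the child's chloroplast
  sequence is the maternal taxon's, always; sexual children get 64
  spores per sporangium, apogamous children 32. Each event yields
  clonal child samples (default 2, matching the design assumption that
  a genotype is observed in at least two samples); each parent
  contributes 2 samples.
* **Reads**: per distinct allele, Poisson(depth) merged reads of the form
  barcode (8 bases, unique per sample) + forward primer + allele +
  reverse-complemented reverse primer, with independent per-base
  substitution errors on the allele insert. Barcodes and primers are
  treated as synthesised sequence (error-free); each locus gets its own
  primer pair, which is how pooled amplicons are assigned to loci
  downstream.

**What the simulator does not emulate** — and what passing tests therefore
do not show about real data: indels and length variation (all comparisons
are equal-length; real amplicons need alignment), chimeric reads and PCR
recombination (only a simple left/right-mosaic check is provided),
quality-score structure, backcrossing and introgression, allele dropout
and amplification bias, within-taxon chloroplast variation beyond what is
explicitly configured, and morphological evolution. Perfect recovery on
noiseless simulations demonstrates the *logic* is sound (no bookkeeping
losses anywhere in the chain), not that the thresholds are optimal for
any particular sequencing chemistry.

## Numerical and procedural choices

* **Read clustering** is single-linkage over pairwise identity on
  equal-length reads (length-binned first; identical reads are
  deduplicated before linking). `identity >= t` is implemented as
  `mismatches <= floor((1-t)*L + 1e-9)`; the epsilon guards against the
  binary representation of `1-t` (e.g. `1-0.9` is fractionally below
  0.1). Consensus is the count-weighted per-column majority with ties to
  the lexicographically smallest base. Clusters sort by read count
  descending, then consensus lexicographically — so equal-count ties at
  the retention boundary keep the smaller consensus, deterministically.
* **Retention rule**: top-3 clusters for diploids, top-4 for triploid or
  ploidy-unknown samples, then remove clusters under `min_reads`
  (default 100). Both constants are exposed as parameters.
* **Identity threshold** default 0.99: the source pipeline's equivalent
  setting is unpublished; 0.99 separates alleles ≥1% apart while
  absorbing sub-percent sequencing noise at the defaults used here.
* **Haplotype collapsing** is an exact-identity partition; with
  `sites_with_gaps_excluded`, alignment columns containing any gap are
  dropped first (gaps as missing data). The alternative
  `gaps_as_missing` policy treats a gap as matching anything and assigns
  greedily in input order (documented as order-dependent; the default
  policy is order-independent). Labels are assigned in first-appearance
  order, so reruns are label-stable.
* **Rare-allele filter**: an allele must occur in ≥2 distinct samples
  (per allele across the whole dataset); singletons are reported with
  their carrier, and the filter is idempotent.
* **Group clustering** (when no curated map is supplied): single-linkage
  on p-distance cut at 0.02, groups named by descending size with
  lexicographic tie-break.
* **Degenerate inputs**: empty read sets cluster to an empty list; empty
  record sets summarize to zeros; unknowns are explicit (`None`/`-`)
  and never silently defaulted; duplicate sample ids, duplicate
  barcodes, non-IUPAC characters and unknown-taxon events raise with
  the offending item named.
* **Determinism**: all randomness flows through explicitly threaded
  numpy generators seeded from a single user seed; two runs with the
  same config and seed produce byte-identical TSV/JSON artifacts
  (timestamps appear only in logs).

## Limitations

* No phylogenetic tree estimation or Bayesian subgenome phasing: lineage
  groups come from a curated map or distance clustering, and maternal
  calls that the source resolved by within-group tree positions (e.g.
  haplotypes carried only by multi-group hybrids) remain ambiguity sets
  here, honestly flagged.
* Indel-free sequence model throughout; real amplicon data must be
  merged and length-consistent before entering the clusterer.
* The parental-classification anchoring rule encodes a specific
  parsimony judgment (documented above); complexes with pervasive
  within-taxon chloroplast polymorphism may need the cp-consistency
  clause relaxed.
* No backcross or introgression edges are inferred; the network is
  strictly parent → first-generation hybrid.
* Trait associations are descriptive set operations, not statistical
  tests; with few carriers per state they over-fit by construction.
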