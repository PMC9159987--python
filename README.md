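# reticulator

Reticulate-evolution inference for the *Pteris fauriei* species group
(Pteridaceae) — and for any plant complex where hybridization, polyploidy and
apomixis tangle the species tree into a network.

The *P. fauriei* group spreads across Eastern Asia as ~20 named taxa of
confusingly similar ferns. Most of them are not "species" in the tree-like
sense: they are hybrids, many of them triploid and apogamous (reproducing
asexually from 32-spore sporangia rather than sexually from 64-spore ones).
Given chloroplast haplotypes (maternally inherited), nuclear allele calls at
one or two low-copy loci, ploidy from flow cytometry, and spore counts, this
package reconstructs who hybridized with whom:

1. **Amplicon allele calling** — demultiplex 8-base-barcoded reads, trim
   primers, single-link reads at an identity threshold, and apply the
   ploidy-aware retention rule: keep the top-3 read clusters for diploids,
   top-4 for triploids/unknown, then drop clusters under 100 reads.
2. **Haplotyping** — collapse sequences into labelled haplotypes/allele
   types, assign alleles to lineage groups (curated map or single-linkage
   p-distance clustering), and drop alleles seen in only one sample.
3. **Genotype assembly** — ploidy-constrained allele multisets with the
   `*` convention for unassorted dosage (`A1D7*` = a triploid showing two
   distinct alleles) and homozygous completion for diploids (`A7` → `A7A7`).
4. **Parentage** — classify genotypes as parental (homozygous, or anchored
   single-group diploids) vs hybrid; infer each chloroplast haplotype's
   maternal nuclear group from co-occurrence (parental carriers →
   universal co-occurrence → ambiguity set); assign each hybrid a formula
   *maternal × paternal*; export the hybridization network (reticulogram)
   as GML/DOT; report summary counts.
5. **Trait association** — which alleles/lineage groups travel with which
   morphological or habitat states (strict and lenient carrier sets).
6. **Forward simulator** — parental panels on a star phylogeny, hybrid
   events with reduced/unreduced gametes (diploid or triploid offspring),
   strictly maternal cpDNA, apogamous vs sexual spore counts, and noisy
   barcoded reads — with ground truth, so the whole pipeline is testable
   without any external data.

A transcription of the study's 72-row genotype table ships as a package
fixture, so the published bookkeeping can be reproduced offline.

## Worked example

```sh
python examples/01_fixture_inference.py
```

prints, among other things:

```
genotypes: 72 (14 parental, 58 of hybrid origin)
parental taxa (7): P. arisanensis, P. biaurita, P. boninensis, P. latipinna,
P. minor, P. oshimensis var. oshimensis, P. wulaiensis

hybrid contributions per parental taxon (as maternal / as paternal / either role):
  P. latipinna                       5 /  13 /  18
  P. arisanensis                     3 /   9 /  10
  P. wulaiensis                      5 /   3 /   8
  ...

example formulas (maternal x paternal):
  P. fauriei         A1A6D7     cp=cf   -> P. minor x P. latipinna
  P. biaurita        F16G1      cp=cxx  -> P. arisanensis x P. biaurita
  P. cf. fauriei     D4D7       cp=cy   -> P. wulaiensis x P. latipinna
```

Reading this: of the 72 distinct multilocus genotypes in the group, 14 are
plausible parents belonging to 7 taxa, and 58 arose by hybridization. The
shade-dwelling diploid *P. latipinna* (homozygous D7D7) contributed to 18
distinct hybrid genotypes — more than any other lineage. Each hybrid's
formula names its maternal parent (pinned by the chloroplast haplotype,
e.g. the `cf` haplotype always travels with group-A alleles, so `A1A6D7/cf`
had an A-lineage mother) and its paternal parent (the lineage behind the
remaining alleles).

The other examples: `02_simulate_and_recover.py` (perfect parent-pair
recovery on a noiseless simulated radiation), `03_amplicon_calling.py`
(read clustering and the retention rule on noisy reads),
`04_trait_associations.py` (trait mining, e.g. red-brown stipes ⇔ allele
D4; areolate costal veins ⇔ lineage group G).

A thin CLI wraps the same functions: `reticulator fixture`,
`reticulator simulate --seed 1`, `reticulator run --mode simulated --seed 1`,
`reticulator amplicon/haplotype/genotype/infer/traits --help`.

## Layout

```
src/reticulator/
  simulate.py    forward simulator (panels, hybrid events, reads, truth)
  io.py          TSV/FASTA/FASTQ IO, packaged fixture, domain types
  amplicon.py    demultiplex, primer trim, clustering, retention rule
  haplotypes.py  haplotype collapsing, group assignment, rare-allele filter
  genotypes.py   ploidy-aware genotype assembly, spore-count mode calls
  parentage.py   parental/hybrid classification, maternal inference,
                 hybrid formulas, reticulogram, summary counts
  traits.py      allele-trait association mining
  pipeline.py    end-to-end orchestration and run reports
  cli.py         thin command-line interface
  fixtures/      genotype table + character matrix + provenance notes
docs/methods.md  model, assumptions, parameter choices, limitations
examples/        one narrative script per capability
```
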